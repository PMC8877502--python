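"""Two-replicate Wstat signal-to-noise procedure."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from ticquant.diff_replicated import fold_change_filter, wstat_diff
from ticquant.errors import DegeneratePopulationError, DesignError, ParameterError

from conftest import DESIGN_2REP, matrix_from_log2


# 5 null proteins with small symmetric replicate deviations plus one
# four-fold-shifted protein: WT reps (10, 10), mutant reps (12, 12).
FIXTURE = [
    (10.0, 10.2, 10.1, 10.0),
    (11.0, 10.9, 11.1, 11.0),
    (9.5, 9.6, 9.4, 9.5),
    (10.5, 10.4, 10.6, 10.6),
    (10.0, 10.1, 9.9, 10.0),
    (10.0, 10.0, 12.0, 12.0),
]


def wstat_oracle(table):
    """Plain-loop restatement of the statistic, independent of the module."""
    r0 = [wt1 - wt2 for wt1, wt2, _, _ in table]
    r1 = [m1 - m2 for _, _, m1, m2 in table]
    z0 = [m1 - wt1 for wt1, _, m1, _ in table]
    z1 = [m2 - wt2 for _, wt2, _, m2 in table]
    center = lambda xs: [x - sum(xs) / len(xs) for x in xs]
    r0c, r1c, z0c, z1c = center(r0), center(r1), center(z0), center(z1)
    pooled = r0c + r1c
    mean = sum(pooled) / len(pooled)
    noise = (sum((x - mean) ** 2 for x in pooled) / (len(pooled) - 1)) ** 0.5
    snr = [abs(a + b) / noise for a, b in zip(z0c, z1c)]
    mean_diff = [(a + b) / 2 for a, b in zip(z0c, z1c)]
    return snr, mean_diff


class TestWstatFixture:
    def test_matches_independent_oracle(self):
        m = matrix_from_log2(FIXTURE, DESIGN_2REP)
        res = wstat_diff(m)
        snr_exp, md_exp = wstat_oracle(FIXTURE)
        np.testing.assert_allclose(res["snr"], snr_exp, rtol=1e-9)
        np.testing.assert_allclose(res["mean_diff"], md_exp, rtol=1e-9)

    def test_shifted_protein_flagged_more_abundant(self):
        m = matrix_from_log2(FIXTURE, DESIGN_2REP)
        res = wstat_diff(m)
        top = res.loc[res["snr"].idxmax()]
        assert top["protein_id"] == "P0006"
        assert top["snr"] == res["snr"].max()
        assert abs(top["mean_diff"]) >= 1.0
        assert top["flagged"]
        assert top["direction"] == "more-abundant"
        # null proteins never pass the conjunctive rule
        assert not res.loc[res["protein_id"] != "P0006", "flagged"].any()

    def test_raw_difference_columns_are_uncentred(self):
        m = matrix_from_log2(FIXTURE, DESIGN_2REP)
        row = wstat_diff(m).set_index("protein_id").loc["P0006"]
        assert row["r0"] == pytest.approx(0.0)
        assert row["z0"] == pytest.approx(2.0)
        assert row["z1"] == pytest.approx(2.0)


class TestWstatCalibration:
    def test_null_flagged_fraction_matches_analytic_tail(self):
        # Z0c + Z1c ~ N(0, 4 sigma^2); noise estimates sqrt(2) sigma, so
        # S/N ~ sqrt(2)|N(0,1)| and P(S/N >= 2.8) = 2(1 - Phi(2.8/sqrt(2)))
        rng = np.random.default_rng(21)
        n = 50_000
        log2 = rng.normal(10.0, 0.5, size=(n, 4))
        m = matrix_from_log2(log2, DESIGN_2REP)
        res = wstat_diff(m, fc_cutoff=0.0)
        expected = 2 * (1 - norm.cdf(2.8 / np.sqrt(2)))
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(res["flagged"].mean() - expected) < 3 * se

    def test_global_run_offset_invariance(self):
        rng = np.random.default_rng(22)
        log2 = rng.normal(10.0, 0.5, size=(500, 4))
        base = wstat_diff(matrix_from_log2(log2, DESIGN_2REP))
        shifted = log2.copy()
        shifted[:, 2] += 5.0  # constant offset on one mutant run
        off = wstat_diff(matrix_from_log2(shifted, DESIGN_2REP))
        np.testing.assert_allclose(off["snr"], base["snr"], atol=1e-9)
        assert (off["flagged"] == base["flagged"]).all()

    def test_power_monotone_in_effect_size(self):
        # 10% of proteins carry the effect; power measured among those
        rng = np.random.default_rng(23)
        n, n_de = 2_000, 200
        fractions = []
        for delta in (0.0, 0.5, 1.0, 1.5, 2.0, 3.0):
            log2 = 10.0 + rng.normal(0.0, 0.3, size=(n, 4))
            log2[:n_de, 2:] += delta
            res = wstat_diff(matrix_from_log2(log2, DESIGN_2REP), fc_cutoff=0.0)
            fractions.append(res["flagged"].iloc[:n_de].mean())
        assert all(b >= a - 0.03 for a, b in zip(fractions, fractions[1:]))
        assert fractions[-1] > 0.99

    def test_flagged_up_shift_is_more_abundant(self):
        rng = np.random.default_rng(24)
        log2 = rng.normal(10.0, 0.3, size=(500, 4))
        log2[:50, 2:] += 2.5
        res = wstat_diff(matrix_from_log2(log2, DESIGN_2REP))
        up = res.iloc[:50]
        assert up["flagged"].all()
        assert (up["direction"] == "more-abundant").all()

    def test_crossed_pairing_equivalent_under_null(self):
        rng = np.random.default_rng(25)
        log2 = rng.normal(10.0, 0.5, size=(3_000, 4))
        m = matrix_from_log2(log2, DESIGN_2REP)
        matched = wstat_diff(m, fc_cutoff=0.0)["flagged"].mean()
        crossed = wstat_diff(m, fc_cutoff=0.0, pairing="crossed")["flagged"].mean()
        assert abs(matched - crossed) < 0.02


class TestFoldChangeFilter:
    def _results(self, mean_diffs):
        return pd.DataFrame({"protein_id": [f"P{i}" for i in range(len(mean_diffs))], "mean_diff": mean_diffs})

    def test_inclusive_at_exactly_two_fold(self):
        res = fold_change_filter(self._results([1.0]), 1.0)
        assert len(res) == 1

    def test_just_below_two_fold_removed(self):
        res = fold_change_filter(self._results([0.99]), 1.0)
        assert len(res) == 0

    def test_mixed_fixture_count(self):
        mds = [0.2, -1.3, 1.0, 0.5, -0.99, 2.4, 0.0, -1.0, 0.7, 0.3]
        res = fold_change_filter(self._results(mds), 1.0)
        assert len(res) == sum(1 for v in mds if abs(v) >= 1.0) == 4

    def test_negative_cutoff_rejected(self):
        with pytest.raises(ParameterError):
            fold_change_filter(self._results([1.0]), -0.5)


class TestWstatErrors:
    def test_single_replicate_design_rejected(self):
        design = {k: v for k, v in DESIGN_2REP.items() if v.replicate == 1}
        m = matrix_from_log2([[10.0, 11.0]], design)
        with pytest.raises(DesignError):
            wstat_diff(m)

    def test_zero_replicate_noise_is_degenerate(self):
        log2 = [[10.0, 10.0, 10.0, 10.0], [11.0, 11.0, 11.0, 11.0], [9.0, 9.0, 9.0, 9.0]]
        with pytest.raises(DegeneratePopulationError):
            wstat_diff(matrix_from_log2(log2, DESIGN_2REP))

    def test_bad_pairing_rejected(self):
        m = matrix_from_log2([[10.0, 10.1, 10.2, 10.0]], DESIGN_2REP)
        with pytest.raises(ParameterError):
            wstat_diff(m, pairing="sideways")
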