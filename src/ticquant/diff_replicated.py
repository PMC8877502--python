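"""Two-replicate differential abundance via the Wstat signal-to-noise statistic.

With two runs per strain, within-strain replicate differences estimate
technical noise while between-strain differences carry the biological
signal.  Per protein *i* (log2 TIC values wt1, wt2, mut1, mut2):

* within-strain differences  ``R0 = wt1 - wt2``,  ``R1 = mut1 - mut2``
* between-strain differences ``Z0 = mut1 - wt1``, ``Z1 = mut2 - wt2``
  (replicate-matched pairing; a crossed pairing is available for
  sensitivity checks)

Each of the four across-protein populations is centred to mean 0, which
removes global run offsets.  The noise scale is the sample SD of the pooled
centred {R0, R1} values, and the statistic is

    S/N_i = |Z0c_i + Z1c_i| / SD(pooled centred R)

Under i.i.d. Gaussian replicate noise sigma, Z0c + Z1c ~ N(0, 4 sigma^2)
and the pooled R SD estimates sqrt(2) sigma, so S/N ~ sqrt(2) |N(0,1)| and
P(S/N >= 2.8) = 2 (1 - Phi(2.8 / sqrt(2))) ~ 0.048 — the 2.8 cut-off is a
p < 0.05 rule.  A protein is called differential when additionally its mean
centred between-strain difference is at least two-fold (|mean_diff| >= 1 on
the log2 scale); both cut-offs are inclusive.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd

from .errors import DegeneratePopulationError, DesignError, ParameterError
from .quantify import MUTANT, WT, ExpressionMatrix

__all__ = ["wstat_diff", "fold_change_filter", "SNR_CUTOFF", "FC_CUTOFF"]

#: Significance cut-off on the signal-to-noise statistic (p < 0.05).
SNR_CUTOFF = 2.8
#: Minimum absolute mean log2 difference (1.0 = two-fold).
FC_CUTOFF = 1.0


def wstat_diff(
    m: ExpressionMatrix,
    snr_cutoff: float = SNR_CUTOFF,
    fc_cutoff: float = FC_CUTOFF,
    pairing: Literal["matched", "crossed"] = "matched",
) -> pd.DataFrame:
    """Signal-to-noise differential test for a two-replicates-per-strain design.

    Restricted to proteins detected in all four runs.  Set ``fc_cutoff=0`` to
    disable the fold-change filter (used for null-calibration studies).

    Returns a DataFrame with columns ``protein_id``, ``r0``, ``r1``, ``z0``,
    ``z1`` (raw, uncentred differences), ``mean_diff`` (mean of the centred
    between-strain differences), ``snr``, ``direction`` and ``flagged``.

    Raises
    ------
    DesignError
        If either strain does not have exactly two replicates.
    ParameterError
        If a cutoff is negative or the pairing is unknown.
    DegeneratePopulationError
        If the pooled within-strain differences have zero SD.
    """
    if snr_cutoff < 0 or fc_cutoff < 0:
        raise ParameterError("cutoffs must be non-negative")
    if pairing not in ("matched", "crossed"):
        raise ParameterError(f"unknown pairing {pairing!r}")
    wt_samples = m.samples_of(WT)
    mut_samples = m.samples_of(MUTANT)
    if len(wt_samples) != 2 or len(mut_samples) != 2:
        raise DesignError(
            f"Wstat procedure needs exactly two replicates per strain, got "
            f"{len(wt_samples)} WT and {len(mut_samples)} mutant"
        )
    all_detected = m.detected[wt_samples + mut_samples].all(axis=1)
    log2 = m.log2_tic.loc[all_detected]
    wt1, wt2 = (log2[s].to_numpy() for s in wt_samples)
    mut1, mut2 = (log2[s].to_numpy() for s in mut_samples)

    r0 = wt1 - wt2
    r1 = mut1 - mut2
    if pairing == "matched":
        z0 = mut1 - wt1
        z1 = mut2 - wt2
    else:
        z0 = mut1 - wt2
        z1 = mut2 - wt1

    # centre each across-protein population to mean 0 (removes run offsets)
    r0c = r0 - r0.mean()
    r1c = r1 - r1.mean()
    z0c = z0 - z0.mean()
    z1c = z1 - z1.mean()

    pooled = np.concatenate([r0c, r1c])
    noise = float(np.std(pooled, ddof=1))
    if noise == 0.0 or not np.isfinite(noise):
        raise DegeneratePopulationError("within-strain replicate differences have zero variance")

    signal = z0c + z1c
    snr = np.abs(signal) / noise
    mean_diff = signal / 2.0
    flagged = (snr >= snr_cutoff) & (np.abs(mean_diff) >= fc_cutoff)
    direction = np.where(~flagged, "unchanged", np.where(mean_diff > 0, "more-abundant", "less-abundant"))
    return pd.DataFrame(
        {
            "protein_id": log2.index,
            "r0": r0,
            "r1": r1,
            "z0": z0,
            "z1": z1,
            "mean_diff": mean_diff,
            "snr": snr,
            "direction": direction,
            "flagged": flagged,
        }
    ).reset_index(drop=True)


def fold_change_filter(results: pd.DataFrame, fc_cutoff: float = FC_CUTOFF) -> pd.DataFrame:
    """Retain results whose |mean_diff| meets the log2 fold-change cutoff.

    ``fc_cutoff=1.0`` keeps proteins differing at least two-fold between the
    strains; the comparison is inclusive.
    """
    if fc_cutoff < 0:
        raise ParameterError("fc_cutoff must be non-negative")
    if "mean_diff" not in results.columns:
        raise ParameterError("results lack a mean_diff column")
    return results.loc[np.abs(results["mean_diff"]) >= fc_cutoff].reset_index(drop=True)
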