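"""Single-replicate differential abundance by normalised log2-difference z-scores.

With one run per strain there is no replicate noise estimate, so the
population of per-protein log2 differences itself serves as the null model:
differences are centred and scaled to unit SD, and proteins in the extreme
5% tails (|z| > 1.96) are called differentially abundant.  Because the
statistic standardises the difference population, a constant offset between
runs (loading, instrument response) cancels exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DegeneratePopulationError, DesignError, StatisticsError
from .quantify import MUTANT, WT, ExpressionMatrix

__all__ = ["zscore_diff", "Z_CUTOFF"]

#: Two-sided 95% confidence cut-off on the standardised score.
Z_CUTOFF = 1.96


def zscore_diff(m: ExpressionMatrix, z_cutoff: float = Z_CUTOFF) -> pd.DataFrame:
    """Standardised log2-difference test for a one-replicate-per-strain design.

    For every protein detected in both runs the raw difference is
    ``d = log2_tic[mutant] - log2_tic[wt]``; the population of *d* values is
    standardised with its own mean and sample SD (n-1 denominator), and a
    protein is flagged when ``|z| > z_cutoff`` (strict inequality).

    Returns a DataFrame with columns ``protein_id``, ``d``, ``z``,
    ``direction`` (more-abundant / less-abundant / unchanged) and ``flagged``.

    Raises
    ------
    DesignError
        If either strain has other than exactly one sample.
    StatisticsError
        If fewer than 3 proteins are detected in both runs (the SD is
        meaningless).
    DegeneratePopulationError
        If the difference population has zero SD.
    """
    wt_samples = m.samples_of(WT)
    mut_samples = m.samples_of(MUTANT)
    if len(wt_samples) != 1 or len(mut_samples) != 1:
        raise DesignError(
            f"z-score procedure needs exactly one sample per strain, got "
            f"{len(wt_samples)} WT and {len(mut_samples)} mutant"
        )
    log2 = m.log2_tic
    both = m.detected[wt_samples[0]] & m.detected[mut_samples[0]]
    d = (log2.loc[both, mut_samples[0]] - log2.loc[both, wt_samples[0]]).astype(float)
    if len(d) < 3:
        raise StatisticsError(f"only {len(d)} proteins detected in both strains; need >= 3")
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        raise DegeneratePopulationError("log2-difference population has zero variance")
    z = (d - float(d.mean())) / sd
    flagged = np.abs(z.to_numpy()) > z_cutoff
    direction = np.where(~flagged, "unchanged", np.where(z.to_numpy() > 0, "more-abundant", "less-abundant"))
    return pd.DataFrame(
        {
            "protein_id": d.index,
            "d": d.to_numpy(),
            "z": z.to_numpy(),
            "direction": direction,
            "flagged": flagged,
        }
    ).reset_index(drop=True)
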