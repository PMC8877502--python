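"""Synthetic PSM-level data with ground truth, for end-to-end testing.

The generator emulates the statistical structure the analysis assumes:

* per-protein log2 baseline abundances are Gaussian (log-normal TIC),
* a sparse fraction of proteins carries a strain effect of fixed log2
  magnitude with random sign,
* each run adds i.i.d. Gaussian log2 replicate noise,
* protein TIC is split across a random number of peptides by symmetric
  Dirichlet weights (lossless: rollup recovers the protein value exactly),
* whole protein-sample cells drop out with probability tilted toward the
  low-abundance tail (probit link on the standardised baseline).

It does **not** simulate spectra, retention-time drift, identification
error, or the abundance distribution of any real organism; all PSM records
carry identification fields that pass the acceptance filters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigError
from .io_formats import PSM_COLUMNS
from .quantify import MUTANT, WT, ExpressionMatrix, SampleInfo

__all__ = ["SyntheticConfig", "generate", "null_calibration", "matrix_from_log2"]

_AMINO_ACIDS = np.array(list("ACDEFGHILMNPQSTVWY"))  # K/R reserved for the C-terminus


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters of the generator.

    Defaults describe a deep label-free experiment on the log2-TIC scale:
    baselines Normal(mu0=10, tau=2), replicate noise SD 0.5, 10% of proteins
    shifted by +/-2 log2 units (four-fold), 5% dropout concentrated in the
    low-abundance tail, two replicates per strain.
    """

    n_proteins: int = 1000
    peptides_per_protein: tuple[int, int] = (2, 8)
    mu0: float = 10.0
    tau: float = 2.0
    sigma_rep: float = 0.5
    pi_de: float = 0.1
    delta: float = 2.0
    dropout_rate: float = 0.05
    dropout_link: Literal["probit", "uniform"] = "probit"
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.peptides_per_protein
        if not (1 <= lo <= hi):
            raise ConfigError(f"invalid peptides_per_protein range {self.peptides_per_protein}")
        if not 0.0 <= self.pi_de <= 1.0:
            raise ConfigError("pi_de must be in [0, 1]")
        if self.sigma_rep <= 0:
            raise ConfigError("sigma_rep must be positive")
        if self.delta < 0:
            raise ConfigError("delta must be non-negative")
        if not 0.0 <= self.dropout_rate <= 0.5:
            raise ConfigError("dropout_rate must be in [0, 0.5]")
        if self.n_replicates not in (1, 2):
            raise ConfigError("n_replicates must be 1 or 2")
        if self.n_proteins < 1 or self.tau <= 0:
            raise ConfigError("n_proteins must be >= 1 and tau positive")

    def design(self) -> dict[str, SampleInfo]:
        """Sample design implied by the replicate count (WT first)."""
        out: dict[str, SampleInfo] = {}
        for strain, prefix in ((WT, "wt"), (MUTANT, "mut")):
            for rep in range(1, self.n_replicates + 1):
                out[f"{prefix}_{rep}"] = SampleInfo(strain=strain, replicate=rep)
        return out


def _dropout_probability(cfg: SyntheticConfig, baseline: np.ndarray) -> np.ndarray:
    """Per-protein dropout probability.

    Probit link: p_i = 2 * rate * Phi(-(b_i - mu0)/tau), so low-abundance
    proteins drop out preferentially while the average rate stays ~= rate.
    """
    if cfg.dropout_link == "uniform":
        return np.full_like(baseline, cfg.dropout_rate)
    z = (baseline - cfg.mu0) / cfg.tau
    return np.clip(2.0 * cfg.dropout_rate * norm.cdf(-z), 0.0, 1.0)


def generate(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a PSM table and the paired ground truth.

    Returns ``(psms, truth)``.  ``psms`` has the canonical PSM columns and
    every record passes the identification filters.  ``truth`` has one row
    per protein with the signed true effect (0 for nulls), the latent log2
    TIC per sample (``log2_<sample>``) and the detection flag per sample
    (``detected_<sample>``).  Identical config (including seed) yields a
    byte-identical table.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_proteins
    protein_ids = [f"SYN{i:05d}" for i in range(1, n + 1)]
    design = cfg.design()
    samples = list(design)

    baseline = rng.normal(cfg.mu0, cfg.tau, size=n)
    is_de = rng.random(n) < cfg.pi_de
    signs = rng.choice([-1.0, 1.0], size=n)
    effect = np.where(is_de, signs * cfg.delta, 0.0)

    # latent log2 TIC per protein x sample
    log2 = np.empty((n, len(samples)))
    for j, s in enumerate(samples):
        strain_term = effect if design[s].strain == MUTANT else 0.0
        log2[:, j] = baseline + strain_term + rng.normal(0.0, cfg.sigma_rep, size=n)

    p_drop = _dropout_probability(cfg, baseline)
    detected = rng.random((n, len(samples))) >= p_drop[:, None]

    lo, hi = cfg.peptides_per_protein
    n_peptides = rng.integers(lo, hi + 1, size=n)

    rows: dict[str, list] = {c: [] for c in PSM_COLUMNS}
    for i in range(n):
        k = int(n_peptides[i])
        weights = rng.dirichlet(np.ones(k))
        lengths = rng.integers(8, 16, size=k)
        peptides = [
            "".join(rng.choice(_AMINO_ACIDS, size=int(L))) + str(rng.choice(["K", "R"]))
            for L in lengths
        ]
        charges = rng.choice([2, 3, 4], size=k, p=[0.6, 0.3, 0.1])
        mzs = rng.uniform(400.0, 1200.0, size=k)
        rts = rng.uniform(5.0, 175.0, size=k)
        log_es = rng.uniform(-5.0, -2.0, size=k)
        missed = rng.choice([0, 1], size=k, p=[0.8, 0.2])
        for j, s in enumerate(samples):
            if not detected[i, j]:
                continue
            tic = float(2.0 ** log2[i, j])
            for q in range(k):
                rows["protein_id"].append(protein_ids[i])
                rows["peptide"].append(peptides[q])
                rows["charge"].append(int(charges[q]))
                rows["parent_mz"].append(float(mzs[q]))
                rows["retention_time"].append(float(rts[q]))
                rows["fragment_intensity_sum"].append(weights[q] * tic)
                rows["sample_id"].append(s)
                rows["log_e"].append(float(log_es[q]))
                rows["missed_cleavages"].append(int(missed[q]))

    psms = pd.DataFrame(rows, columns=PSM_COLUMNS)
    truth = pd.DataFrame({"protein_id": protein_ids, "true_effect": effect})
    for j, s in enumerate(samples):
        truth[f"log2_{s}"] = log2[:, j]
    for j, s in enumerate(samples):
        truth[f"detected_{s}"] = detected[:, j]
    return psms, truth


def matrix_from_log2(log2: np.ndarray, design: Mapping[str, SampleInfo]) -> ExpressionMatrix:
    """Build an :class:`ExpressionMatrix` directly from latent log2 values
    (proteins x samples, fully detected)."""
    samples = list(design)
    tic = pd.DataFrame(2.0 ** np.asarray(log2, dtype=float), columns=samples)
    tic.index = [f"SYN{i:05d}" for i in range(1, len(tic) + 1)]
    tic.index.name = "protein_id"
    return ExpressionMatrix(tic=tic, design=dict(design))


def null_calibration(
    n_proteins: int,
    sigma_rep: float = 0.5,
    seed: int = 0,
    procedure: Literal["zscore", "wstat"] = "wstat",
    mu0: float = 10.0,
) -> float:
    """Flagged fraction of a pure-null simulation under a differential rule.

    Draws per-sample log2 values i.i.d. Normal(mu0, sigma_rep) with no
    strain effect, runs the requested procedure with its default
    significance cut-off and the fold-change filter disabled, and returns
    the fraction of proteins flagged.  The Monte-Carlo standard error is
    ~sqrt(0.05 * 0.95 / n); below 1000 proteins a warning is emitted.
    """
    from . import diff_replicated, diff_single

    if n_proteins < 1000:
        warnings.warn("null_calibration with n_proteins < 1000 has large Monte-Carlo error", stacklevel=2)
    rng = np.random.default_rng(seed)
    n_rep = 1 if procedure == "zscore" else 2
    cfg = SyntheticConfig(n_proteins=n_proteins, sigma_rep=sigma_rep, pi_de=0.0, n_replicates=n_rep, seed=seed)
    design = cfg.design()
    log2 = rng.normal(mu0, sigma_rep, size=(n_proteins, len(design)))
    m = matrix_from_log2(log2, design)
    if procedure == "zscore":
        result = diff_single.zscore_diff(m)
    elif procedure == "wstat":
        result = diff_replicated.wstat_diff(m, fc_cutoff=0.0)
    else:
        raise ConfigError(f"unknown procedure {procedure!r}")
    return float(result["flagged"].mean())
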