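"""Peptide-to-protein rollup and the log2 expression matrix.

Protein abundance is measured by total ion current (TIC): the sum of MS/MS
fragment-ion intensities over all accepted peptide-spectrum matches of a
protein within one run.  TIC is a *relative* measure within a run; the
differential modules absorb global run offsets by centering the difference
populations, so no cross-run normalisation happens here.

Undetected cells (TIC = 0) have no log2 value — log2 is left undefined
(NaN), never imputed and never -inf; quantitative tests downstream use only
cells where detection holds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, DesignError

__all__ = [
    "SampleInfo",
    "ExpressionMatrix",
    "DetectionCall",
    "rollup_tic",
    "detection_calls",
    "write_expression_matrix",
    "read_expression_matrix",
]

log = logging.getLogger(__name__)

WT = "wt"
MUTANT = "mutant"
STRAINS = (WT, MUTANT)

DetectionStatus = Literal["both-strains", "mutant-only", "wild-type-only", "undetected"]


@dataclass(frozen=True)
class SampleInfo:
    """Strain assignment and replicate index of one run."""

    strain: str
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.strain not in STRAINS:
            raise ConfigError(f"unknown strain {self.strain!r}; expected one of {STRAINS}")


@dataclass(frozen=True)
class DetectionCall:
    protein_id: str
    status: DetectionStatus


@dataclass
class ExpressionMatrix:
    """Proteins x samples TIC matrix with sample design attached.

    ``tic`` holds summed fragment-ion intensities (0 = undetected);
    ``log2_tic`` is log2(tic) where detected and NaN elsewhere.
    """

    tic: pd.DataFrame  # index: protein ids; columns: sample ids
    design: Mapping[str, SampleInfo]

    def __post_init__(self) -> None:
        unknown = [s for s in self.tic.columns if s not in self.design]
        if unknown:
            raise ConfigError(f"samples without design entry: {unknown}")
        if (self.tic.to_numpy() < 0).any():
            raise ValueError("TIC values must be non-negative")
        # canonical column order: WT then mutant, by replicate
        order = sorted(self.tic.columns, key=lambda s: (STRAINS.index(self.design[s].strain), self.design[s].replicate))
        self.tic = self.tic.loc[:, order]

    @property
    def protein_ids(self) -> list[str]:
        return list(self.tic.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.tic.columns)

    @property
    def detected(self) -> pd.DataFrame:
        return self.tic > 0

    @property
    def log2_tic(self) -> pd.DataFrame:
        with np.errstate(divide="ignore"):
            out = np.log2(self.tic.where(self.tic > 0))
        return out

    def samples_of(self, strain: str) -> list[str]:
        """Sample ids of one strain, ordered by replicate index."""
        cols = [s for s in self.tic.columns if self.design[s].strain == strain]
        return sorted(cols, key=lambda s: self.design[s].replicate)

    def n_replicates(self, strain: str) -> int:
        return len(self.samples_of(strain))


def rollup_tic(psms: pd.DataFrame, design: Mapping[str, SampleInfo]) -> ExpressionMatrix:
    """Sum accepted PSM fragment intensities into per-protein, per-sample TIC.

    ``tic[i, s]`` is the sum of ``fragment_intensity_sum`` over all PSMs of
    protein *i* in sample *s*; every PSM counts toward the single protein it
    is assigned to (no shared-peptide inference).  Proteins with no signal in
    any sample are dropped with a warning.

    Raises :class:`ConfigError` if a PSM carries a sample id absent from the
    design.
    """
    unknown = sorted(set(psms["sample_id"]) - set(design))
    if unknown:
        raise ConfigError(f"PSM table references sample(s) not in the design: {unknown}")
    tic = (
        psms.pivot_table(
            index="protein_id",
            columns="sample_id",
            values="fragment_intensity_sum",
            aggfunc="sum",
            fill_value=0.0,
        )
        .reindex(columns=list(design), fill_value=0.0)
        .astype(float)
    )
    all_zero = tic.sum(axis=1) == 0
    if all_zero.any():
        log.warning("rollup_tic: dropping %d protein(s) with zero total intensity", int(all_zero.sum()))
        tic = tic.loc[~all_zero]
    tic.index.name = "protein_id"
    tic.columns.name = "sample_id"
    return ExpressionMatrix(tic=tic.sort_index(), design=dict(design))


def detection_calls(
    m: ExpressionMatrix, rule: Literal["strict", "lenient"] | None = None
) -> pd.DataFrame:
    """Classify every protein's detection pattern across the two strains.

    A strain "carries" a protein under the *strict* rule if the protein is
    detected in **all** of that strain's samples, under the *lenient* rule if
    it is detected in at least one.  Status is then:

    ==============  ===========================================
    both-strains    carried by WT and mutant
    mutant-only     carried by mutant, not by WT
    wild-type-only  carried by WT, not by mutant
    undetected      carried by neither
    ==============  ===========================================

    Default rule: strict for replicated designs, lenient for
    single-replicate designs.  Returns a DataFrame with one row per protein
    (columns ``protein_id``, ``status``).
    """
    for strain in STRAINS:
        if m.n_replicates(strain) == 0:
            raise DesignError(f"no samples for strain {strain!r}")
    if rule is None:
        replicated = all(m.n_replicates(s) >= 2 for s in STRAINS)
        rule = "strict" if replicated else "lenient"
    if rule not in ("strict", "lenient"):
        raise ConfigError(f"unknown detection rule {rule!r}")

    det = m.detected
    carried = {}
    for strain in STRAINS:
        cols = m.samples_of(strain)
        carried[strain] = det[cols].all(axis=1) if rule == "strict" else det[cols].any(axis=1)
    status = np.select(
        [
            carried[WT] & carried[MUTANT],
            carried[MUTANT] & ~carried[WT],
            carried[WT] & ~carried[MUTANT],
        ],
        ["both-strains", "mutant-only", "wild-type-only"],
        default="undetected",
    )
    return pd.DataFrame({"protein_id": m.protein_ids, "status": status})


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    """Write the TIC matrix as TSV (empty cell = undetected) with the design
    recorded in ``#`` header comments."""
    path = Path(path)
    lines = [
        f"# sample {s} strain={m.design[s].strain} replicate={m.design[s].replicate}"
        for s in m.sample_ids
    ]
    tic = m.tic.where(m.tic > 0)
    body = tic.to_csv(sep="\t")
    path.write_text("\n".join(lines) + "\n" + body)


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Round-trip counterpart of :func:`write_expression_matrix`."""
    path = Path(path)
    design: dict[str, SampleInfo] = {}
    for line in path.read_text().splitlines():
        if line.startswith("# sample "):
            _, _, sample, strain_kv, rep_kv = line.split()
            design[sample] = SampleInfo(
                strain=strain_kv.split("=", 1)[1], replicate=int(rep_kv.split("=", 1)[1])
            )
    tic = pd.read_csv(path, sep="\t", comment="#", index_col="protein_id").fillna(0.0)
    return ExpressionMatrix(tic=tic, design=design)
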