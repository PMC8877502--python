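"""Readers and writers for the pipeline's external formats.

Formats handled here:

* **PSM tables** — tab-separated peptide-spectrum-match exports with one row
  per identified peptide observation.  Identification-quality filters
  (expectation score, missed cleavages, charge range) are applied on read.
* **MGF spectra** — Mascot Generic Format, parsed with :mod:`pyteomics.mgf`.
* **Gene sets** — plain-text accession lists (one id per line, or a named TSV
  column), collapsed to set semantics.
* **Result tables** — TSV with ``#`` provenance comments (tool version,
  config hash, input digests) so reruns are byte-comparable.

The PSM table dialect is fixed by this package: UTF-8, tab-separated,
``#`` comment lines, and the column names in :data:`PSM_COLUMNS`.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .errors import FormatError

__all__ = [
    "PSM_COLUMNS",
    "PsmFilters",
    "PsmRecord",
    "SpectrumRecord",
    "GeneSet",
    "read_psm_table",
    "read_mgf",
    "read_gene_set",
    "write_results",
    "read_results",
    "file_digest",
    "config_hash",
]

log = logging.getLogger(__name__)

#: Required columns of a PSM table, in canonical order.
PSM_COLUMNS = [
    "protein_id",
    "peptide",
    "charge",
    "parent_mz",
    "retention_time",
    "fragment_intensity_sum",
    "sample_id",
    "log_e",
    "missed_cleavages",
]

_NUMERIC_PSM_COLUMNS = [
    "charge",
    "parent_mz",
    "retention_time",
    "fragment_intensity_sum",
    "log_e",
    "missed_cleavages",
]


@dataclass(frozen=True)
class PsmRecord:
    """One identified peptide observation — the unit of quantitation."""

    protein_id: str
    peptide: str
    charge: int
    parent_mz: float
    retention_time: float
    fragment_intensity_sum: float
    sample_id: str
    log_e: float
    missed_cleavages: int


@dataclass(frozen=True)
class PsmFilters:
    """Identification-quality filters applied when reading a PSM table.

    Defaults follow the search-engine acceptance rules used throughout:
    expectation score log10(e) strictly below -1.5, at most one missed
    tryptic cleavage, and precursor charge states +2..+4.
    """

    max_log_e: float = -1.5
    max_missed_cleavages: int = 1
    charges: tuple[int, ...] = (2, 3, 4)


@dataclass
class SpectrumRecord:
    """One MS/MS spectrum from an MGF block."""

    charge: int | None
    parent_mz: float
    retention_time: float  # minutes
    fragment_mz: np.ndarray
    fragment_intensity: np.ndarray
    title: str = ""

    @property
    def fragment_intensity_sum(self) -> float:
        """Summed fragment-ion intensity, the quantity rolled up into TIC."""
        return float(np.sum(self.fragment_intensity))


@dataclass(frozen=True)
class GeneSet:
    """A named set of accession ids (compartment list, stress signature...)."""

    name: str
    ids: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("GeneSet name must be non-empty")
        object.__setattr__(self, "ids", frozenset(self.ids))

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, item: str) -> bool:
        return item in self.ids


def read_psm_table(path: str | Path, filters: PsmFilters | None = None) -> pd.DataFrame:
    """Read a PSM TSV and apply identification filters.

    Returns a DataFrame with :data:`PSM_COLUMNS`; only records passing the
    filters are kept.  The rejected count is logged and exposed through
    ``df.attrs["n_input"]`` / ``df.attrs["n_rejected"]``.

    Raises
    ------
    FormatError
        If a required column is missing (the error names it) or a numeric
        field fails to parse (the error carries the 1-based data row).
    """
    filters = filters or PsmFilters()
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"protein_id": str, "peptide": str, "sample_id": str})
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    for col in _NUMERIC_PSM_COLUMNS:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise FormatError(f"{path}: non-numeric value in column '{col}' at data row {row}")
        df[col] = parsed
    if (df["fragment_intensity_sum"] < 0).any():
        raise FormatError(f"{path}: negative fragment_intensity_sum")

    keep = (
        (df["log_e"] < filters.max_log_e)
        & (df["missed_cleavages"] <= filters.max_missed_cleavages)
        & df["charge"].isin(filters.charges)
    )
    n_input = len(df)
    out = df.loc[keep, PSM_COLUMNS].reset_index(drop=True)
    n_rejected = n_input - len(out)
    if n_rejected:
        log.info("read_psm_table(%s): rejected %d of %d records by identification filters", path, n_rejected, n_input)
    out.attrs["n_input"] = n_input
    out.attrs["n_rejected"] = n_rejected
    return out


def iter_psms(df: pd.DataFrame) -> Iterable[PsmRecord]:
    """Yield typed :class:`PsmRecord` objects from a PSM DataFrame."""
    for row in df.itertuples(index=False):
        yield PsmRecord(
            protein_id=row.protein_id,
            peptide=row.peptide,
            charge=int(row.charge),
            parent_mz=float(row.parent_mz),
            retention_time=float(row.retention_time),
            fragment_intensity_sum=float(row.fragment_intensity_sum),
            sample_id=row.sample_id,
            log_e=float(row.log_e),
            missed_cleavages=int(row.missed_cleavages),
        )


def read_mgf(path: str | Path) -> list[SpectrumRecord]:
    """Read an MGF file into :class:`SpectrumRecord` objects.

    Only ``BEGIN IONS``/``END IONS`` blocks with TITLE, PEPMASS, CHARGE and
    RTINSECONDS keys are interpreted; unknown keys are ignored.  RTINSECONDS
    is converted to minutes.  Blocks without PEPMASS are skipped with a
    warning; an unterminated block raises :class:`FormatError` with the byte
    offset of the offending ``BEGIN IONS``.
    """
    path = Path(path)
    text = path.read_bytes()
    begins = text.count(b"BEGIN IONS")
    ends = text.count(b"END IONS")
    if begins != ends:
        offset = text.rfind(b"BEGIN IONS")
        raise FormatError(f"{path}: unterminated MGF block (BEGIN IONS at byte {offset} has no END IONS)")

    records: list[SpectrumRecord] = []
    with _mgf.MGF(str(path), convert_arrays=1) as reader:
        for spectrum in reader:
            params = spectrum.get("params", {})
            if "pepmass" not in params:
                log.warning("read_mgf(%s): block %r lacks PEPMASS, skipped", path, params.get("title", "?"))
                continue
            charge_list = params.get("charge")
            charge = int(charge_list[0]) if charge_list else None
            rt = params.get("rtinseconds")
            rt_min = float(rt) / 60.0 if rt is not None else float("nan")
            records.append(
                SpectrumRecord(
                    charge=charge,
                    parent_mz=float(params["pepmass"][0]),
                    retention_time=rt_min,
                    fragment_mz=np.asarray(spectrum["m/z array"], dtype=float),
                    fragment_intensity=np.asarray(spectrum["intensity array"], dtype=float),
                    title=str(params.get("title", "")),
                )
            )
    return records


def write_mgf(records: Sequence[SpectrumRecord], path: str | Path) -> None:
    """Write spectra to MGF (round-trip counterpart of :func:`read_mgf`)."""
    spectra = []
    for rec in records:
        params: dict = {"pepmass": rec.parent_mz, "title": rec.title}
        if rec.charge is not None:
            params["charge"] = rec.charge
        if np.isfinite(rec.retention_time):
            params["rtinseconds"] = rec.retention_time * 60.0
        spectra.append(
            {"params": params, "m/z array": rec.fragment_mz, "intensity array": rec.fragment_intensity}
        )
    with open(path, "w") as handle:
        _mgf.write(spectra, handle)


def read_gene_set(path: str | Path, name: str | None = None, column: str | None = None) -> GeneSet:
    """Read a gene set from a plain-text list or a named TSV column.

    Duplicates are collapsed; ordering is irrelevant; accession case is
    preserved.  An empty file raises :class:`FormatError` — an empty set must
    be constructed explicitly, never read silently.
    """
    path = Path(path)
    if column is not None:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        if column not in df.columns:
            raise FormatError(f"{path}: no column named '{column}'")
        ids = {v for v in df[column].dropna().str.strip() if v}
    else:
        ids = set()
        for line in path.read_text().splitlines():
            entry = line.strip()
            if entry and not entry.startswith("#"):
                ids.add(entry)
    if not ids:
        raise FormatError(f"{path}: empty gene set")
    return GeneSet(name=name or path.stem, ids=frozenset(ids), source=str(path))


def file_digest(path: str | Path) -> str:
    """SHA-256 hex digest of a file's bytes."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def config_hash(config: Mapping) -> str:
    """Stable short hash of a JSON-serialisable configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_results(
    table: pd.DataFrame,
    path: str | Path,
    *,
    config: Mapping | None = None,
    inputs: Sequence[str | Path] = (),
) -> None:
    """Write a result table as TSV with a provenance comment header.

    The header records tool version, config hash and SHA-256 digests of the
    input files; two runs with identical config and inputs produce
    byte-identical output.  Values round-trip through :func:`read_results`
    exactly (floats are written at full precision).
    """
    if table is None:
        raise ValueError("result table must not be None")
    from . import __version__

    path = Path(path)
    lines = [f"# ticquant {__version__}"]
    if config is not None:
        lines.append(f"# config_hash={config_hash(config)}")
    for inp in inputs:
        lines.append(f"# input {Path(inp).name} sha256={file_digest(inp)}")
    body = table.to_csv(sep="\t", index=False)
    path.write_text("\n".join(lines) + "\n" + body)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_results`, skipping comments."""
    return pd.read_csv(path, sep="\t", comment="#")
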