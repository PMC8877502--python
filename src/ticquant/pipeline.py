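"""End-to-end orchestration: quantify -> differential -> set analysis -> report.

A run is a pure function of its inputs and configuration: outputs carry a
config hash, logs go to standard error, and reruns with identical inputs
produce identical files.  The differential procedure is dispatched by
replicate count (one sample per strain -> z-score; two -> Wstat),
overridable in the config; a mismatch is a design error raised before any
computation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import diff_replicated, diff_single, io_formats, quantify, set_analysis
from .errors import ConfigError, DesignError
from .io_formats import GeneSet, PsmFilters
from .quantify import MUTANT, WT, ExpressionMatrix, SampleInfo

__all__ = ["RunConfig", "RunResult", "run_pipeline", "parse_design"]

log = logging.getLogger(__name__)


def parse_design(raw: Mapping[str, object]) -> dict[str, SampleInfo]:
    """Build a sample design from a JSON-style mapping.

    Accepts ``{"wt_1": {"strain": "wt", "replicate": 1}}`` or
    ``{"wt_1": ["wt", 1]}``.
    """
    design: dict[str, SampleInfo] = {}
    for sample, value in raw.items():
        if isinstance(value, Mapping):
            design[sample] = SampleInfo(strain=str(value["strain"]), replicate=int(value.get("replicate", 1)))
        else:
            strain, rep = value  # type: ignore[misc]
            design[sample] = SampleInfo(strain=str(strain), replicate=int(rep))
    return design


@dataclass
class RunConfig:
    """Full configuration of one pipeline run."""

    psm_path: str
    design: dict[str, SampleInfo]
    out_dir: str
    compartments: dict[str, str] = field(default_factory=dict)  # name -> gene-set path
    signatures: dict[str, str] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)
    log_e_max: float = -1.5
    missed_cleavages_max: int = 1
    z_cutoff: float = diff_single.Z_CUTOFF
    snr_cutoff: float = diff_replicated.SNR_CUTOFF
    fc_cutoff: float = diff_replicated.FC_CUTOFF
    detection_rule: str | None = None  # strict | lenient | None = auto
    pairing: str = "matched"
    procedure: str | None = None  # zscore | wstat | None = auto by replicate count
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        raw["design"] = parse_design(raw["design"])
        return cls(**raw)

    def as_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["design"] = {s: [i.strain, i.replicate] for s, i in self.design.items()}
        return out

    def validate(self) -> None:
        for strain in (WT, MUTANT):
            if not any(info.strain == strain for info in self.design.values()):
                raise ConfigError(f"design names no sample for strain {strain!r}")
        if self.z_cutoff <= 0 or self.snr_cutoff <= 0 or self.fc_cutoff < 0:
            raise ConfigError("thresholds must be positive (fc_cutoff may be 0)")
        paths = [self.psm_path, *self.compartments.values(), *self.signatures.values(), *self.categories.values()]
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise ConfigError(f"input path(s) do not exist: {missing}")
        n_wt = sum(1 for i in self.design.values() if i.strain == WT)
        n_mut = sum(1 for i in self.design.values() if i.strain == MUTANT)
        wanted = self.procedure or ("zscore" if (n_wt, n_mut) == (1, 1) else "wstat")
        if wanted == "zscore" and (n_wt, n_mut) != (1, 1):
            raise DesignError(f"z-score procedure needs 1 sample per strain, design has {n_wt}+{n_mut}")
        if wanted == "wstat" and (n_wt, n_mut) != (2, 2):
            raise DesignError(f"Wstat procedure needs 2 replicates per strain, design has {n_wt}+{n_mut}")


@dataclass
class RunResult:
    matrix: ExpressionMatrix
    detection: pd.DataFrame
    differential: pd.DataFrame
    procedure: str
    compartments: set_analysis.CompartmentAnnotation | None
    overlaps: pd.DataFrame | None
    venn: set_analysis.VennResult | None
    enrichment: pd.DataFrame | None
    summary: dict


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full analysis described by ``config`` and write the report
    bundle to ``config.out_dir``."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.as_dict()
    cfg_hash = io_formats.config_hash(cfg_dict)

    filters = PsmFilters(max_log_e=config.log_e_max, max_missed_cleavages=config.missed_cleavages_max)
    psms = io_formats.read_psm_table(config.psm_path, filters)
    matrix = quantify.rollup_tic(psms, config.design)
    detection = quantify.detection_calls(matrix, rule=config.detection_rule)  # type: ignore[arg-type]

    n_wt = matrix.n_replicates(WT)
    procedure = config.procedure or ("zscore" if n_wt == 1 else "wstat")
    if procedure == "zscore":
        differential = diff_single.zscore_diff(matrix, z_cutoff=config.z_cutoff)
    else:
        differential = diff_replicated.wstat_diff(
            matrix, snr_cutoff=config.snr_cutoff, fc_cutoff=config.fc_cutoff, pairing=config.pairing  # type: ignore[arg-type]
        )
    log.info("run_pipeline: %s procedure on %d proteins", procedure, len(differential))

    both_ids = frozenset(detection.loc[detection["status"] == "both-strains", "protein_id"])
    flagged = differential.loc[differential["flagged"]]
    up_ids = frozenset(flagged.loc[flagged["direction"] == "more-abundant", "protein_id"])
    down_ids = frozenset(flagged.loc[flagged["direction"] == "less-abundant", "protein_id"])

    compartments = None
    if config.compartments:
        comp_sets = [io_formats.read_gene_set(p, name=n) for n, p in config.compartments.items()]
        compartments = set_analysis.annotate_compartments(both_ids, comp_sets)

    overlaps = None
    venn_result = None
    if config.signatures and up_ids:
        up_set = GeneSet(name="more-abundant", ids=up_ids, source="pipeline")
        sig_sets = [io_formats.read_gene_set(p, name=n) for n, p in config.signatures.items()]
        rows = []
        for sig in sig_sets:
            count, fraction = set_analysis.compare_overlap_fraction(up_set, sig)
            rows.append({"signature": sig.name, "n_query": len(up_set), "overlap": count, "fraction": fraction})
        overlaps = pd.DataFrame(rows)
        if len(sig_sets) >= 2:
            venn_result = set_analysis.venn([up_set, *sig_sets[:2]])

    enrichment = None
    if config.categories and both_ids:
        universe = GeneSet(name="detected-both-strains", ids=both_ids, source="pipeline")
        cat_sets = [io_formats.read_gene_set(p, name=n) for n, p in config.categories.items()]
        frames = []
        for name, ids in (("more-abundant", up_ids), ("less-abundant", down_ids)):
            if not ids:
                continue
            query = GeneSet(name=name, ids=frozenset(ids) & universe.ids, source="pipeline")
            if not query.ids:
                continue
            part = set_analysis.enrich(query, cat_sets, universe)
            part.insert(0, "query", name)
            frames.append(part)
        if frames:
            enrichment = pd.concat(frames, ignore_index=True)

    summary = {
        "config_hash": cfg_hash,
        "procedure": procedure,
        "n_proteins": len(matrix.protein_ids),
        "n_detected_both": len(both_ids),
        "n_differential": int(differential["flagged"].sum()),
        "n_more_abundant": len(up_ids),
        "n_less_abundant": len(down_ids),
    }

    inputs = [config.psm_path]
    quantify.write_expression_matrix(matrix, out_dir / "expression_matrix.tsv")
    io_formats.write_results(detection, out_dir / "detection_calls.tsv", config=cfg_dict, inputs=inputs)
    io_formats.write_results(differential, out_dir / "differential.tsv", config=cfg_dict, inputs=inputs)
    if compartments is not None:
        io_formats.write_results(compartments.to_frame(), out_dir / "compartment_counts.tsv", config=cfg_dict)
    if overlaps is not None:
        io_formats.write_results(overlaps, out_dir / "signature_overlaps.tsv", config=cfg_dict)
    if venn_result is not None:
        io_formats.write_results(venn_result.to_frame(), out_dir / "venn_regions.tsv", config=cfg_dict)
    if enrichment is not None:
        io_formats.write_results(enrichment, out_dir / "enrichment.tsv", config=cfg_dict)
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")

    return RunResult(
        matrix=matrix,
        detection=detection,
        differential=differential,
        procedure=procedure,
        compartments=compartments,
        overlaps=overlaps,
        venn=venn_result,
        enrichment=enrichment,
        summary=summary,
    )
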