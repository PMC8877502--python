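"""Packaged gene lists used in the stress-signature overlap analysis.

Three plain-text accession lists ship with the package: proteins more
abundant in the VDAC-less *N. crassa* strain that are shared with the
ER unfolded-protein-response induction signature, with the menadione
oxidative-stress signature, and with both.
"""

from __future__ import annotations

from importlib.resources import files

from .io_formats import GeneSet, read_gene_set

__all__ = ["upr_er_shared", "menadione_shared", "triple_shared"]


def _load(filename: str, name: str) -> GeneSet:
    path = files("ticquant").joinpath("data", filename)
    return read_gene_set(str(path), name=name)


def upr_er_shared() -> GeneSet:
    """Proteins more abundant in the VDAC-less strain and predicted
    upregulated under ER unfolded-protein-response induction."""
    return _load("porin_null_upr_er_shared.txt", "upr_er_shared")


def menadione_shared() -> GeneSet:
    """Proteins more abundant in the VDAC-less strain and in
    menadione-treated (oxidatively stressed) cells."""
    return _load("porin_null_menadione_shared.txt", "menadione_shared")


def triple_shared() -> GeneSet:
    """Proteins more abundant in all three conditions (VDAC-less strain,
    menadione treatment, ER unfolded-protein response)."""
    return _load("porin_null_triple_shared.txt", "triple_shared")
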