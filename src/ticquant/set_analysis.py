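"""Gene-set operations: compartment annotation, Venn overlaps, enrichment.

Compartment annotation counts intersections of a protein list with curated
localisation lists (multi-label: a protein may sit in several lists).
Venn decomposition reports the disjoint regions of 2-3 named sets.
Over-representation of functional categories is tested with the
hypergeometric upper tail and Benjamini-Hochberg adjustment across
categories; the adjusted values are an optional addition on top of the raw
overlap counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, ParameterError
from .io_formats import GeneSet

__all__ = [
    "VennResult",
    "CompartmentAnnotation",
    "annotate_compartments",
    "venn",
    "enrich",
    "compare_overlap_fraction",
]


@dataclass
class VennResult:
    """Disjoint-region decomposition of 2-3 named sets.

    Regions are keyed by the sorted tuple of set names the region belongs to
    exclusively; a 3-set Venn has 7 regions.
    """

    set_names: tuple[str, ...]
    region_members: dict[tuple[str, ...], frozenset[str]]

    @property
    def region_counts(self) -> dict[tuple[str, ...], int]:
        return {k: len(v) for k, v in self.region_members.items()}

    def count(self, *names: str) -> int:
        """Size of the region belonging exclusively to the given sets."""
        return len(self.region_members[tuple(sorted(names))])

    def intersection_count(self, *names: str) -> int:
        """Size of the plain intersection of the given sets (union of all
        regions containing them all)."""
        names_set = set(names)
        return sum(len(v) for k, v in self.region_members.items() if names_set <= set(k))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": "&".join(k), "count": len(v), "members": ";".join(sorted(v))}
            for k, v in sorted(self.region_members.items(), key=lambda kv: (len(kv[0]), kv[0]))
        ]
        return pd.DataFrame(rows)


@dataclass
class CompartmentAnnotation:
    """Per-compartment intersection counts for a protein list."""

    counts: dict[str, int]
    members: dict[str, frozenset[str]]
    multi_label: frozenset[str]
    unassigned: frozenset[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"compartment": name, "count": self.counts[name]} for name in self.counts]
        )


def annotate_compartments(
    proteins: Sequence[str] | frozenset[str], compartments: Sequence[GeneSet]
) -> CompartmentAnnotation:
    """Count how many of ``proteins`` fall in each compartment list.

    Multi-membership is allowed — the counts come from independent list
    intersections, so a protein may contribute to several compartments; such
    proteins are reported in ``multi_label``.  Proteins in no list are the
    ``unassigned`` remainder.
    """
    proteins = frozenset(proteins)
    if not proteins:
        raise ParameterError("protein list is empty")
    names = [c.name for c in compartments]
    if len(set(names)) != len(names):
        raise ConfigError("duplicate compartment names")
    members = {c.name: frozenset(proteins & c.ids) for c in compartments}
    hits_per_protein: dict[str, int] = {p: 0 for p in proteins}
    for mem in members.values():
        for p in mem:
            hits_per_protein[p] += 1
    multi = frozenset(p for p, n in hits_per_protein.items() if n > 1)
    unassigned = frozenset(p for p, n in hits_per_protein.items() if n == 0)
    return CompartmentAnnotation(
        counts={name: len(mem) for name, mem in members.items()},
        members=members,
        multi_label=multi,
        unassigned=unassigned,
    )


def venn(sets: Sequence[GeneSet]) -> VennResult:
    """Disjoint-region decomposition of 2 or 3 gene sets.

    Region counts sum to the size of the union, and members are disjoint
    across regions.  More than three sets are unsupported (report pairwise
    overlaps instead).
    """
    if not 2 <= len(sets) <= 3:
        raise ParameterError(f"venn supports 2-3 sets, got {len(sets)}; report pairwise overlaps instead")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ConfigError("duplicate set names")
    by_name = {s.name: s.ids for s in sets}
    universe = frozenset().union(*by_name.values())
    regions: dict[tuple[str, ...], frozenset[str]] = {}
    for r in range(1, len(sets) + 1):
        for combo in combinations(sorted(names), r):
            inside = set(universe)
            for n in combo:
                inside &= by_name[n]
            for n in set(names) - set(combo):
                inside -= by_name[n]
            regions[combo] = frozenset(inside)
    return VennResult(set_names=tuple(names), region_members=regions)


def enrich(
    query: GeneSet,
    categories: Sequence[GeneSet],
    universe: GeneSet,
    method: str = "fdr_bh",
) -> pd.DataFrame:
    """Hypergeometric over-representation of each category in the query.

    For a universe of size N, category of size K (after intersecting with
    the universe), query of size n and overlap k, the p-value is the upper
    tail P(X >= k) of Hypergeom(N, K, n).  Adjusted q-values are computed
    across categories (Benjamini-Hochberg by default).

    The query must be a subset of the universe; offending ids are listed in
    the error otherwise.
    """
    stray = query.ids - universe.ids
    if stray:
        raise ParameterError(f"query ids outside the universe: {sorted(stray)}")
    N = len(universe.ids)
    n = len(query.ids)
    rows = []
    for cat in categories:
        cat_in_universe = cat.ids & universe.ids
        K = len(cat_in_universe)
        k = len(query.ids & cat_in_universe)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"category": cat.name, "k": k, "K": K, "n": n, "N": N, "p_value": min(p, 1.0)})
    table = pd.DataFrame(rows)
    if len(table):
        table["q_value"] = multipletests(table["p_value"].to_numpy(), method=method)[1]
    else:
        table["q_value"] = []
    return table.sort_values("p_value", kind="stable").reset_index(drop=True)


def compare_overlap_fraction(diff_list: GeneSet, signature: GeneSet) -> tuple[int, float]:
    """Overlap of a differential list with a signature: (count, count/|diff_list|)."""
    if not diff_list.ids:
        raise ParameterError("differential list is empty; overlap fraction undefined")
    count = len(diff_list.ids & signature.ids)
    return count, count / len(diff_list.ids)
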