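"""Pathway co-membership filtering and set over-representation.

The high-confidence map keeps an associated (gene, metabolite, cell type)
triple only when the gene and the metabolite are members of the same
metabolic pathway, recording one (metabolite, gene, cell type, pathway)
quadruplet per shared pathway.  Pathway annotations are supplied as local
files: a GMT of pathway gene sets and a pathway-metabolite membership TSV.

Over-representation of a query gene set against a GMT uses the upper-tail
hypergeometric probability P(X >= k) with the highly-variable gene list as
the default universe, with BH adjustment across sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .covariation import adjust_bh
from .util import get_logger

__all__ = [
    "PathwayAnnotation", "build_high_confidence_map", "rank_by_frequency",
    "direction_of_effect_summary", "set_enrichment", "hypergeom_upper_tail",
]

log = get_logger("pathways")

HC_COLUMNS = ["metabolite", "gene", "cell_type", "pathway_id", "direction"]


@dataclass
class PathwayAnnotation:
    """One pathway's gene and metabolite membership (ids are opaque)."""
    pathway_id: str
    gene_members: set[str]
    metabolite_members: set[str]


def annotations_from_files(gene_sets: dict[str, set[str]],
                           pathway_metabolites: dict[str, set[str]]
                           ) -> list[PathwayAnnotation]:
    """Join a GMT-derived gene-set dict with the metabolite membership dict
    on pathway id; pathways missing from either side get empty sets."""
    ids = sorted(set(gene_sets) | set(pathway_metabolites))
    return [PathwayAnnotation(pw, set(gene_sets.get(pw, ())),
                              set(pathway_metabolites.get(pw, ())))
            for pw in ids]


def build_high_confidence_map(assoc: pd.DataFrame,
                              annotations: list[PathwayAnnotation],
                              alpha: float) -> pd.DataFrame:
    """All (metabolite, gene, cell type, pathway) quadruplets where the pair
    is associated at ``alpha`` and gene and metabolite share the pathway.
    A pair co-occurring in k pathways yields k quadruplets."""
    sig = assoc[assoc["p"] <= alpha]
    rows = []
    for ann in annotations:
        if not ann.gene_members or not ann.metabolite_members:
            continue
        hit = sig[sig["gene"].isin(ann.gene_members)
                  & sig["metabolite"].isin(ann.metabolite_members)]
        for rec in hit.itertuples(index=False):
            rows.append((rec.metabolite, rec.gene, rec.cell_type,
                         ann.pathway_id, int(rec.direction)))
    out = pd.DataFrame(rows, columns=HC_COLUMNS)
    out = out.sort_values(HC_COLUMNS[:4]).reset_index(drop=True)
    log.info("high-confidence map: %d quadruplets", len(out))
    return out


def rank_by_frequency(hc: pd.DataFrame, axis: str,
                      distinct_pairs: bool = False) -> pd.DataFrame:
    """Frequency ranking of high-confidence quadruplets along one axis
    (metabolite, gene, or pathway_id), aggregated across cell types.

    With ``distinct_pairs`` the count is over distinct (gene, metabolite,
    cell type) triples instead of quadruplets.  Descending counts, id ties
    lexicographic."""
    if axis not in ("metabolite", "gene", "pathway_id"):
        raise ValueError(f"unknown axis {axis!r}")
    if hc.empty:
        return pd.DataFrame(columns=[axis, "count"])
    data = hc.drop_duplicates(["metabolite", "gene", "cell_type", axis]) \
        if distinct_pairs else hc
    counts = data.groupby(axis).size()
    out = pd.DataFrame({axis: counts.index, "count": counts.to_numpy()})
    out = out.sort_values(["count", axis],
                          ascending=[False, True]).reset_index(drop=True)
    return out


def direction_of_effect_summary(hc: pd.DataFrame) -> float:
    """Fraction of quadruplets where higher gene expression accompanies
    lower metabolite abundance.

    Direction convention: an association's ``direction`` is the sign of
    (mean expression in the high-metabolite group) minus (mean in the
    low-metabolite group), so direction = -1 means expression is higher in
    the LOW-metabolite group — the inverse trend this summary reports.
    """
    if hc.empty:
        raise ValueError("empty high-confidence map")
    return float((hc["direction"] == -1).mean())


def hypergeom_upper_tail(k: int, universe: int, successes: int,
                         draws: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(universe, successes, draws)."""
    return float(stats.hypergeom.sf(k - 1, universe, successes, draws))


def set_enrichment(query: set[str], gene_sets: dict[str, set[str]],
                   universe: set[str]) -> pd.DataFrame:
    """Over-representation of ``query`` in each gene set.

    p = upper-tail hypergeometric P(X >= k) with population |universe|,
    successes |set ∩ universe|, draws |query|.  Requires query ⊆ universe.
    """
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    if not query <= set(universe):
        raise ValueError("query must be a subset of the universe")
    rows = []
    for name in sorted(gene_sets):
        members = gene_sets[name] & set(universe)
        k = len(query & members)
        p = hypergeom_upper_tail(k, len(universe), len(members), len(query))
        rows.append((name, len(members), k, p))
    out = pd.DataFrame(rows, columns=["gene_set", "set_size", "overlap", "p"])
    out["p_adj"] = adjust_bh(out["p"].to_numpy()) if len(out) else []
    return out
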