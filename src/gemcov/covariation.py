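"""Per-cell-type gene-metabolite association mapping and hub statistics.

The association procedure: each metabolite's patients are split at the 75th
quantile of abundance (Group 1 = abundance >= threshold, Group 2 = rest),
and every gene's pseudo-bulk expression in a cell type is compared between
the two groups with a two-sample t-test.  A pair is "associated" when its
nominal p-value is <= the association threshold (0.005 by default).

Hub statistics on the resulting bipartite association graph:

* per-cell-type hubs — the top 50 metabolites by gene-association count and
  top 100 genes by metabolite-association count (top 5% of 1000 / 2000);
* specificity score — a cell type's association count minus the mean count
  over the other cell types, with the top 10 entities per cell type called
  cell-type-specific hubs;
* pan-cell-type hubs — entities ranked by the geometric mean of their
  per-cell-type degree ranks (rank 1 = most associations), top 50;
* hub interconnection density — the edge density between the hub-gene and
  hub-metabolite sets, with a permutation p-value from repeatedly drawing
  equally sized non-hub sets;
* the binomial null Binomial(n_celltypes, 0.05) for how many cell types an
  entity would be a hub for if hub calls were independent 5% draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import OmicsCohort
from .config import AnalysisConfig
from .util import child_rng, get_logger

__all__ = [
    "MetaboliteGrouping", "DegreeTable", "HubTable",
    "discretize_metabolite", "two_sample_t", "build_association_map",
    "adjust_bh", "compute_degrees", "select_hub_sets", "specificity_scores",
    "pan_celltype_ranks", "bipartite_density", "density_permutation_pvalue",
    "hub_sharing_counts", "hub_sharing_null_pmf",
]

log = get_logger("covariation")

ASSOC_COLUMNS = ["cell_type", "gene", "metabolite", "t", "p", "p_adj",
                 "direction", "n1", "n2"]


@dataclass
class MetaboliteGrouping:
    """Binary patient split at the q-th abundance quantile.

    ``group_labels`` is indexed by patient: 1 where abundance >= threshold
    (the high-abundance group), 2 otherwise.
    """
    metabolite_id: str
    group_labels: pd.Series
    threshold_value: float
    q: float

    @property
    def group1(self) -> pd.Index:
        return self.group_labels.index[self.group_labels == 1]

    @property
    def group2(self) -> pd.Index:
        return self.group_labels.index[self.group_labels == 2]


def discretize_metabolite(abundance: pd.Series, q: float = 0.75,
                          min_group: int = 5) -> MetaboliteGrouping | None:
    """Split patients at the q-th quantile of a metabolite's abundance.

    Returns None (and logs the reason) when either side would have fewer
    than ``min_group`` patients — in particular for constant vectors, where
    every value is >= the threshold and Group 2 is empty.
    """
    values = abundance.to_numpy(dtype=float)
    threshold = float(np.quantile(values, q))
    labels = pd.Series(np.where(values >= threshold, 1, 2),
                       index=abundance.index)
    n1 = int((labels == 1).sum())
    n2 = int((labels == 2).sum())
    if n1 < min_group or n2 < min_group:
        log.debug("skipping metabolite %s: group sizes %d/%d below %d",
                  abundance.name, n1, n2, min_group)
        return None
    return MetaboliteGrouping(
        metabolite_id=str(abundance.name), group_labels=labels,
        threshold_value=threshold, q=q)


def _t_kernel(x1: np.ndarray, x2: np.ndarray,
              welch: bool = False) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized two-sample t over the last-but-one axis (columns = tests).

    Returns (t, p, direction).  Zero-variance tests yield (0, 1, 0).
    """
    n1, n2 = x1.shape[0], x2.shape[0]
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    v1 = x1.var(axis=0, ddof=1)
    v2 = x2.var(axis=0, ddof=1)
    diff = m1 - m2
    if welch:
        se2 = v1 / n1 + v2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / ((v1 / n1)**2 / (n1 - 1) + (v2 / n2)**2 / (n2 - 1))
    else:
        pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = pooled * (1.0 / n1 + 1.0 / n2)
        df = np.full_like(se2, float(n1 + n2 - 2))
    degenerate = se2 <= 0
    se2 = np.where(degenerate, 1.0, se2)
    t = diff / np.sqrt(se2)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    direction = np.sign(diff)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    direction = np.where(degenerate, 0.0, direction)
    return t, p, direction


def two_sample_t(x1, x2, welch: bool = False) -> tuple[float, float, int]:
    """Two-sample t-test (pooled-variance Student's t by default).

    Returns (t, two-sided p, direction) with direction = sign of
    mean(x1) - mean(x2).  Both groups need >= 2 observations.  A zero
    pooled variance yields the degenerate (0, 1, 0).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("each group needs at least 2 observations")
    t, p, d = _t_kernel(x1[:, None], x2[:, None], welch=welch)
    return float(t[0]), float(p[0]), int(d[0])


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def build_association_map(cohort: OmicsCohort,
                          config: AnalysisConfig) -> pd.DataFrame:
    """Test every (cell type, gene, metabolite) triple.

    For each cell type only patients with a complete pseudo-bulk row are
    used; the metabolite split is recomputed on those patients and skipped
    if either group falls below ``config.min_group``.  BH adjustment is
    applied within each cell type over all its gene x metabolite tests.
    """
    q = config.metabolite_split_quantile
    frames = []
    n_skipped = 0
    for ct in cohort.cell_types:
        mat = cohort.pseudobulk[ct]
        patients = cohort.celltype_patients(ct)
        X = mat.loc[patients]
        drop = set(cohort.zero_variance_flags.get(f"expr_{ct}", []))
        genes = [g for g in X.columns if g not in drop]
        Xv = X[genes].to_numpy(dtype=float)
        met_drop = set(cohort.zero_variance_flags.get("metabolites", []))
        ct_rows = []
        for met in cohort.metabolites.columns:
            if met in met_drop:
                continue
            grouping = discretize_metabolite(
                cohort.metabolites.loc[patients, met], q=q,
                min_group=config.min_group)
            if grouping is None:
                n_skipped += 1
                continue
            mask1 = (grouping.group_labels == 1).to_numpy()
            t, p, d = _t_kernel(Xv[mask1], Xv[~mask1], welch=config.welch)
            ct_rows.append(pd.DataFrame({
                "cell_type": ct, "gene": genes, "metabolite": met,
                "t": t, "p": p, "direction": d.astype(int),
                "n1": int(mask1.sum()), "n2": int((~mask1).sum()),
            }))
        if ct_rows:
            ct_df = pd.concat(ct_rows, ignore_index=True)
            ct_df["p_adj"] = adjust_bh(ct_df["p"].to_numpy())
            frames.append(ct_df)
        log.info("cell type %s: %d tests",
                 ct, 0 if not ct_rows else len(ct_df))
    if n_skipped:
        log.info("skipped %d (cell type, metabolite) groupings", n_skipped)
    if not frames:
        return pd.DataFrame(columns=ASSOC_COLUMNS)
    return pd.concat(frames, ignore_index=True)[ASSOC_COLUMNS]


@dataclass
class DegreeTable:
    """Per-cell-type association counts (degrees) for genes and metabolites.

    Each attribute is an entity x cell-type integer matrix covering the full
    feature universe (zero rows included).
    """
    genes: pd.DataFrame
    metabolites: pd.DataFrame

    def table(self, kind: str) -> pd.DataFrame:
        return {"gene": self.genes, "metabolite": self.metabolites}[kind]


def compute_degrees(assoc: pd.DataFrame, alpha: float,
                    gene_universe=None, metabolite_universe=None,
                    cell_types=None) -> DegreeTable:
    """Count associated partners per entity per cell type at threshold
    ``alpha`` (significance operator: p <= alpha)."""
    sig = assoc[assoc["p"] <= alpha]
    cts = list(cell_types) if cell_types is not None \
        else sorted(assoc["cell_type"].unique())
    genes = pd.Index(sorted(gene_universe)) if gene_universe is not None \
        else pd.Index(sorted(assoc["gene"].unique()))
    mets = pd.Index(sorted(metabolite_universe)) \
        if metabolite_universe is not None \
        else pd.Index(sorted(assoc["metabolite"].unique()))
    gd = (sig.groupby(["gene", "cell_type"]).size().unstack(fill_value=0)
          .reindex(index=genes, columns=cts, fill_value=0).astype(int))
    md = (sig.groupby(["metabolite", "cell_type"]).size().unstack(fill_value=0)
          .reindex(index=mets, columns=cts, fill_value=0).astype(int))
    return DegreeTable(genes=gd, metabolites=md)


def _top_by_count(counts: pd.Series, n: int) -> list[str]:
    """Top n ids by count, ties at the cutoff broken lexicographically."""
    order = sorted(counts.index, key=lambda e: (-counts[e], str(e)))
    return order[:n]


@dataclass
class HubTable:
    """Hub calls for one entity kind (genes or metabolites)."""
    kind: str
    per_celltype: dict[str, list[str]]
    specificity: pd.DataFrame = field(default=None)
    specific_hubs: dict[str, list[str]] = field(default=None)
    pan_hubs: pd.DataFrame = field(default=None)


def select_hub_sets(degrees: DegreeTable,
                    config: AnalysisConfig) -> dict[str, dict[str, list[str]]]:
    """Per-cell-type hub sets: top ``n_hub_metabolites`` metabolites and
    ``n_hub_genes`` genes by association count, per cell type."""
    out: dict[str, dict[str, list[str]]] = {}
    for kind, n in (("gene", config.n_hub_genes),
                    ("metabolite", config.n_hub_metabolites)):
        table = degrees.table(kind)
        if len(table) < n:
            raise ValueError(
                f"need at least {n} {kind}s, have {len(table)}")
        out[kind] = {ct: _top_by_count(table[ct], n) for ct in table.columns}
    return out


def specificity_scores(degrees: DegreeTable, kind: str,
                       n_top: int = 10) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Cell-type specificity: count(i) minus the mean count over the other
    cell types.  Returns the full score matrix and the top ``n_top``
    positive-score entities per cell type (descending score, id ties
    lexicographic)."""
    table = degrees.table(kind)
    C = table.shape[1]
    if C < 2:
        raise ValueError("need >= 2 cell types for specificity")
    totals = table.sum(axis=1)
    scores = table.apply(lambda col: col - (totals - col) / (C - 1))
    top: dict[str, list[str]] = {}
    for ct in table.columns:
        s = scores[ct]
        order = sorted(s.index, key=lambda e: (-s[e], str(e)))
        top[ct] = [e for e in order if s[e] > 0][:n_top]
    return scores, top


def pan_celltype_ranks(degrees: DegreeTable, kind: str,
                       n: int | None = None) -> pd.DataFrame:
    """Pan-cell-type ranking by geometric mean of per-cell-type degree ranks.

    Rank 1 = most associations in a cell type; ties receive average ranks.
    Entities are sorted by geometric mean ascending, ties broken by smaller
    minimum rank, then id.  Returns the top ``n`` (all if None) with columns
    geom_mean_rank, min_rank, combined_rank.
    """
    table = degrees.table(kind)
    ranks = table.apply(
        lambda col: pd.Series(
            stats.rankdata(-col.to_numpy(), method="average"),
            index=col.index))
    gm = np.exp(np.log(ranks).mean(axis=1))
    min_rank = ranks.min(axis=1)
    out = pd.DataFrame({
        "entity": table.index,
        "geom_mean_rank": gm.to_numpy(),
        "min_rank": min_rank.to_numpy(),
    })
    out = out.sort_values(
        ["geom_mean_rank", "min_rank", "entity"]).reset_index(drop=True)
    out["combined_rank"] = np.arange(1, len(out) + 1)
    return out if n is None else out.head(n)


def _adjacency(assoc: pd.DataFrame, cell_type: str,
               alpha: float) -> set[tuple[str, str]]:
    sub = assoc[(assoc["cell_type"] == cell_type) & (assoc["p"] <= alpha)]
    return set(zip(sub["gene"], sub["metabolite"]))


def bipartite_density(assoc: pd.DataFrame, genes, metabolites,
                      cell_type: str, alpha: float) -> float:
    """Fraction of realized (gene, metabolite) edges between two node sets
    in a cell type's association graph."""
    genes = list(genes)
    metabolites = list(metabolites)
    if not genes or not metabolites:
        raise ValueError("node sets must be nonempty")
    edges = _adjacency(assoc, cell_type, alpha)
    gset, mset = set(genes), set(metabolites)
    k = sum(1 for g, m in edges if g in gset and m in mset)
    return k / (len(genes) * len(metabolites))


def density_permutation_pvalue(assoc: pd.DataFrame, hub_genes, hub_metabolites,
                               cell_type: str, n_perm: int, seed: int,
                               alpha: float,
                               gene_pool=None,
                               metabolite_pool=None) -> tuple[float, float]:
    """Permutation test of hub interconnection density.

    Draws ``n_perm`` random non-hub gene/metabolite sets of the same sizes
    (without replacement) and reports p = fraction of draws whose density
    strictly exceeds the observed hub density (resolution 1/n_perm).
    """
    hub_genes = list(hub_genes)
    hub_metabolites = list(hub_metabolites)
    sub = assoc[assoc["cell_type"] == cell_type]
    all_genes = sorted(set(gene_pool) if gene_pool is not None
                       else set(sub["gene"]))
    all_mets = sorted(set(metabolite_pool) if metabolite_pool is not None
                      else set(sub["metabolite"]))
    non_hub_genes = [g for g in all_genes if g not in set(hub_genes)]
    non_hub_mets = [m for m in all_mets if m not in set(hub_metabolites)]
    if len(non_hub_genes) < len(hub_genes) or \
            len(non_hub_mets) < len(hub_metabolites):
        raise ValueError("not enough non-hub entities to permute")
    observed = bipartite_density(assoc, hub_genes, hub_metabolites,
                                 cell_type, alpha)
    # dense boolean lookup for speed
    edges = _adjacency(assoc, cell_type, alpha)
    gi = {g: i for i, g in enumerate(non_hub_genes)}
    mi = {m: i for i, m in enumerate(non_hub_mets)}
    adj = np.zeros((len(non_hub_genes), len(non_hub_mets)), dtype=bool)
    for g, m in edges:
        if g in gi and m in mi:
            adj[gi[g], mi[m]] = True
    rng = child_rng(seed, "density_perm")
    log.debug("density permutation: seed %d, %d draws", seed, n_perm)
    denom = len(hub_genes) * len(hub_metabolites)
    exceed = 0
    for _ in range(n_perm):
        gsel = rng.choice(len(non_hub_genes), size=len(hub_genes),
                          replace=False)
        msel = rng.choice(len(non_hub_mets), size=len(hub_metabolites),
                          replace=False)
        if adj[np.ix_(gsel, msel)].sum() / denom > observed:
            exceed += 1
    return observed, exceed / n_perm


def hub_sharing_counts(hub_sets: dict[str, list[str]]) -> pd.Series:
    """For each entity, the number of cell types it is a hub for."""
    counts: dict[str, int] = {}
    for ct, members in hub_sets.items():
        for e in members:
            counts[e] = counts.get(e, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()


def hub_sharing_null_pmf(n_celltypes: int, p: float = 0.05) -> np.ndarray:
    """Binomial(n_celltypes, p) pmf — the null for the number of cell types
    an entity is a hub for when hub membership is an independent p-fraction
    draw per cell type."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    return stats.binom.pmf(np.arange(n_celltypes + 1), n_celltypes, p)
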