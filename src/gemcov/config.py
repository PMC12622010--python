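"""Configuration objects for the analysis pipeline and the cohort simulator.

Two dataclasses are defined:

* :class:`AnalysisConfig` — every tunable of the downstream analysis
  (quantile conventions, significance levels, hub-set sizes, random-forest
  protocol parameters, linking thresholds).
* :class:`SimConfig` — the synthetic-cohort generator's knobs (cohort size,
  cell-type composition, planted effect structure).

Configs can be loaded from YAML or JSON files; unknown keys are rejected so
typos fail loudly.  Precedence when assembling an effective config is
CLI flag > config file > dataclass default, handled in :mod:`gemcov.cli`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

__all__ = ["AnalysisConfig", "SimConfig", "load_config", "DEFAULT_CELL_TYPES"]


#: 17 bone-marrow cell types used by the default simulator, with mean
#: proportions dominated by lymphocytes/monocytes and three rare populations
#: (HSPC ~1.8%, megakaryocytes ~0.67%, MSC ~0.12%).
DEFAULT_CELL_TYPES: tuple[str, ...] = (
    "CD4_T", "CD8_T", "CD14_monocyte", "NK", "naive_B", "mature_B",
    "macrophage", "CD16_monocyte", "trans_B", "pre_B", "pro_B", "cDC",
    "HSPC", "plasma_B", "pDC", "megakaryocyte", "MSC",
)

DEFAULT_PROPORTION_MEANS: tuple[float, ...] = (
    0.24, 0.16, 0.12, 0.10, 0.08, 0.06,
    0.0521, 0.04, 0.03, 0.025, 0.02, 0.02,
    0.018, 0.015, 0.012, 0.0067, 0.0012,
)


@dataclass
class AnalysisConfig:
    """Tunable parameters of the covariation analysis.

    Defaults mirror the study design: 2000 highly variable genes, 1000 named
    metabolites, 95th-quantile outlier saturation, 75th-quantile metabolite
    discretization, nominal association threshold 0.005, top-5% hub sets
    (50 metabolites / 100 genes per cell type), 200-draw density permutation
    null, 100-repeat (metabolite) and 30-repeat (severity) random-forest
    protocols with 70/30 splits, and 0.65 / four-or-more linking rules.
    """

    n_hvg_genes: int = 2000
    n_hvg_metabolites: int = 1000
    saturation_quantile: float = 0.95
    metabolite_split_quantile: float = 0.75
    assoc_alpha: float = 0.005
    de_alpha: float = 0.05
    n_hub_metabolites: int = 50
    n_hub_genes: int = 100
    n_specific_hubs: int = 10
    n_pan_hubs: int = 50
    n_density_perms: int = 200
    rf_repeats_metabolite: int = 100
    rf_repeats_severity: int = 30
    train_fraction: float = 0.70
    link_accuracy_threshold: float = 0.65
    pan_link_min_celltypes: int = 4
    overlap_accuracy_threshold: float = 0.6
    #: effective n in the reported-accuracy CI: an int, or one of the tokens
    #: "repeats" (standard error of the mean over the repeats), "test_size",
    #: "one" (the literal sd = sqrt(a(1-a)) reading).
    ci_n_eff: int | str = "repeats"
    #: minimum patients on each side of the 75th-percentile split for a
    #: metabolite to be tested at all.
    min_group: int = 5
    #: Welch's t instead of pooled-variance Student's t.
    welch: bool = False
    #: specific-link margin: another cell type within `margin` of the link
    #: threshold removes specificity (0 = any other cell type at/above the
    #: threshold does).
    specific_link_margin: float = 0.0
    #: count distinct (gene, metabolite, cell type) triples instead of
    #: quadruplets in high-confidence frequency rankings.
    count_distinct_pairs: bool = False
    # --- random-forest runtime knobs (protocol-preserving) ---
    rf_search: bool = True
    rf_search_candidates: int = 20
    rf_cv_folds: int = 5
    #: used when rf_search is False.
    rf_n_estimators_fixed: int = 100
    #: cap on metabolites attempted by the prediction stage (None = all);
    #: a runtime control for pipeline runs, not part of the protocol.
    predict_max_metabolites: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("saturation_quantile", "metabolite_split_quantile",
                     "assoc_alpha", "de_alpha", "train_fraction",
                     "link_accuracy_threshold", "overlap_accuracy_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v!r}")
        for name in ("n_hvg_genes", "n_hvg_metabolites", "n_hub_metabolites",
                     "n_hub_genes", "n_specific_hubs", "n_pan_hubs",
                     "n_density_perms", "rf_repeats_metabolite",
                     "rf_repeats_severity", "pan_link_min_celltypes",
                     "min_group"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if not self.assoc_alpha < self.de_alpha:
            raise ValueError(
                "assoc_alpha must be smaller than de_alpha "
                f"({self.assoc_alpha} vs {self.de_alpha})")
        if isinstance(self.ci_n_eff, str) and self.ci_n_eff not in (
                "repeats", "test_size", "one"):
            raise ValueError(f"unknown ci_n_eff token {self.ci_n_eff!r}")


@dataclass
class SimConfig:
    """Parameters of the synthetic multi-omics cohort generator.

    The defaults emulate the study's data structure: ~119 patients from a
    handful of sites, 17 cell types with highly skewed proportions, 2000
    genes, 1000 metabolites, radiographic severity grades in {2, 3, 4}.
    Planted structure (gene-metabolite pairs, hubs, severity signals) is
    returned as a ground-truth table for recovery testing.
    """

    n_patients: int = 119
    n_celltypes: int = 17
    n_genes: int = 2000
    n_metabolites: int = 1000
    cell_type_names: Sequence[str] | None = None
    proportion_means: Sequence[float] | None = None
    proportion_concentration: float = 300.0
    n_sites: int = 5
    n_planted_pairs: int = 20
    effect_size: float = 2.0
    #: fraction of planted pairs with a negative sign (expression higher in
    #: the low-metabolite group) — the inverse enzyme-metabolite trend.
    negative_sign_fraction: float = 0.72
    n_planted_hub_genes: int = 2
    n_planted_hub_metabolites: int = 2
    hub_fanout: int = 40
    pathway_count: int = 25
    pathway_cover_fraction: float = 0.5
    kl_probs: tuple[float, float, float] = (0.34, 0.33, 0.33)
    n_kl_metabolites: int = 10
    kl_effect: float = 1.5
    #: severity gene signal: genes shifted in one cell type for one grade.
    n_kl_genes: int = 0
    kl_gene_celltype: str | None = None
    kl_gene_effect: float = 1.5
    kl_gene_target: int = 4
    noise_sd: float = 1.0
    #: sigma of the per-metabolite log-normal abundance (log scale).
    metabolite_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_type_names is None and self.proportion_means is None:
            if self.n_celltypes == len(DEFAULT_CELL_TYPES):
                self.cell_type_names = DEFAULT_CELL_TYPES
                self.proportion_means = DEFAULT_PROPORTION_MEANS
            else:
                self.cell_type_names = tuple(
                    f"celltype_{i:02d}" for i in range(self.n_celltypes))
                # geometric decay, normalized: skewed but generic
                w = [0.6 ** i for i in range(self.n_celltypes)]
                s = sum(w)
                self.proportion_means = tuple(x / s for x in w)
        if self.cell_type_names is None or self.proportion_means is None:
            raise ValueError(
                "cell_type_names and proportion_means must be given together")
        if len(self.cell_type_names) != self.n_celltypes:
            raise ValueError("cell_type_names length != n_celltypes")
        if len(self.proportion_means) != self.n_celltypes:
            raise ValueError("proportion_means length != n_celltypes")
        if abs(sum(self.proportion_means) - 1.0) > 1e-8:
            raise ValueError("proportion_means must sum to 1")
        if abs(sum(self.kl_probs) - 1.0) > 1e-8:
            raise ValueError("kl_probs must sum to 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        for name in ("n_patients", "n_celltypes", "n_genes", "n_metabolites"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_kl_genes > 0 and self.kl_gene_celltype is None:
            self.kl_gene_celltype = self.cell_type_names[0]


def _from_mapping(cls, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown {cls.__name__} keys: {', '.join(sorted(unknown))}")
    return cls(**data)


def load_config(path: str | Path, kind: str = "analysis"):
    """Load an :class:`AnalysisConfig` (``kind='analysis'``) or
    :class:`SimConfig` (``kind='sim'``) from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    cls = {"analysis": AnalysisConfig, "sim": SimConfig}[kind]
    if "kl_probs" in data:
        data["kl_probs"] = tuple(data["kl_probs"])
    return _from_mapping(cls, data)
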