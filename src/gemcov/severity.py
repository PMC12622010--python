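"""Disease-severity (KL grade) association analyses.

Three analyses relate the omics profiles to the radiographic Kellgren-
Lawrence (KL) severity grade, coded 2 (low), 3 (medium), 4 (high):

* a per-cell-type random-forest classifier of KL-target vs the rest, using
  only that cell type's hub genes as the feature pool (30 repeated splits;
  the median-accuracy run supplies the reported ROC curve and AUROC);
* a one-sided two-proportion test per metabolite, asking whether the
  high-abundance group (75th-quantile split) is over-represented in the
  target KL grade — the continuity-corrected chi-square construction of the
  classical prop.test;
* a hypergeometric enrichment between transcriptome-predictable metabolites
  (confounder-filtered) and severity-associated metabolites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve
from sklearn.model_selection import train_test_split

from .config import AnalysisConfig
from .covariation import MetaboliteGrouping
from .pathways import hypergeom_upper_tail
from .predict import (PredictionRecord, _make_classifier, balanced_accuracy,
                      de_feature_select)
from .util import child_seed, get_logger

__all__ = [
    "SeverityResult", "kl_binarize", "severity_classification", "roc_auc",
    "metabolite_kl_association", "metabolite_kl_table", "overlap_enrichment",
    "select_predictable_metabolites",
]

log = get_logger("severity")

VALID_GRADES = {2, 3, 4}


def kl_binarize(kl_grades, target: int) -> np.ndarray:
    """1 where the KL grade equals the target (2 or 4), else 0."""
    grades = np.asarray(kl_grades, dtype=int)
    if not set(np.unique(grades)) <= VALID_GRADES:
        raise ValueError("KL grades must be in {2, 3, 4}")
    if target not in (2, 4):
        raise ValueError("target grade must be 2 or 4")
    return (grades == target).astype(int)


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC curve by threshold sweep and its trapezoidal area.

    Returns (points, auroc) where points is an (n, 2) array of (false
    positive rate, true positive rate) from (0, 0) to (1, 1).  The area
    equals the normalized Mann-Whitney U count of concordant
    (case, control) score pairs, with ties counted half.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("need both classes for a ROC curve")
    fpr, tpr, _ = roc_curve(labels, np.asarray(scores, dtype=float))
    points = np.column_stack([fpr, tpr])
    return points, float(np.trapezoid(tpr, fpr))


@dataclass
class SeverityResult:
    cell_type: str
    target: int
    repeat_accuracies: np.ndarray
    median_run: int
    median_accuracy: float
    roc_points: np.ndarray
    auroc: float
    seed: int


def severity_classification(expr: pd.DataFrame, hub_genes: list[str],
                            labels: np.ndarray, config: AnalysisConfig,
                            seed: int, cell_type: str = "",
                            target: int = 4) -> SeverityResult:
    """Repeated-split random-forest classification of KL-target vs rest.

    Features come only from ``hub_genes`` (the cell type's hub set), with
    per-split DE selection at ``de_alpha`` inside the training fold.  Of the
    30 repeats, the run whose balanced accuracy is the median (lower median
    for even counts) supplies the test-set scores for the reported ROC.
    """
    if not hub_genes:
        raise ValueError("hub_genes must be nonempty")
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class")
    if min(np.bincount(labels)) < 10:
        raise ValueError("need >= 10 patients in each class")
    hub_genes = [g for g in hub_genes if g in expr.columns]
    X = expr[hub_genes]
    accs: list[float] = []
    fold_scores: list[tuple[np.ndarray, np.ndarray]] = []
    for r in range(config.rf_repeats_severity):
        split_seed = child_seed(seed, "severity", 2 * r)
        model_seed = child_seed(seed, "severity", 2 * r + 1)
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, labels, train_size=config.train_fraction, stratify=labels,
            random_state=split_seed)
        feats = de_feature_select(X_tr, y_tr, config.de_alpha,
                                  welch=config.welch)
        clf = _make_classifier(config, model_seed, model_seed)
        clf.fit(X_tr[feats], y_tr)
        accs.append(balanced_accuracy(y_te, clf.predict(X_te[feats])))
        fold_scores.append((clf.predict_proba(X_te[feats])[:, 1], y_te))
    accs_arr = np.asarray(accs)
    order = np.argsort(accs_arr, kind="stable")
    median_run = int(order[(len(accs_arr) - 1) // 2])  # lower median
    scores, y_te = fold_scores[median_run]
    points, auroc = roc_auc(scores, y_te)
    log.info("severity %s KL-%d: median acc %.3f, AUROC %.3f",
             cell_type or "?", target, accs_arr[median_run], auroc)
    return SeverityResult(
        cell_type=cell_type, target=target, repeat_accuracies=accs_arr,
        median_run=median_run, median_accuracy=float(accs_arr[median_run]),
        roc_points=points, auroc=auroc, seed=seed)


def metabolite_kl_association(grouping: MetaboliteGrouping,
                              kl_binary) -> tuple[float, float, float]:
    """One-sided two-proportion test of high-abundance enrichment in the
    target KL group.

    Compares (a) the proportion of high-abundance (Group 1) patients among
    the target-grade patients with (b) that proportion among the rest, via
    the continuity-corrected chi-square statistic of the classical two-group
    prop.test; the one-sided (greater) p-value is the upper normal tail of
    the signed square root of the statistic.  Returns
    (prop_in, prop_out, p).
    """
    kl_binary = np.asarray(kl_binary, dtype=int)
    in_mask = kl_binary == 1
    n1, n2 = int(in_mask.sum()), int((~in_mask).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both KL groups must be nonempty")
    g1 = (grouping.group_labels.to_numpy() == 1)
    x1, x2 = int(g1[in_mask].sum()), int(g1[~in_mask].sum())
    p1, p2 = x1 / n1, x2 / n2
    pool = (x1 + x2) / (n1 + n2)
    if pool in (0.0, 1.0):
        return p1, p2, 1.0
    observed = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    expected = np.outer([n1, n2], [pool, 1.0 - pool])
    yates = min(0.5, abs(x1 - n1 * pool))
    statistic = float((((np.abs(observed - expected) - yates) ** 2)
                       / expected).sum())
    z = np.sign(p1 - p2) * np.sqrt(statistic)
    return p1, p2, float(stats.norm.sf(z))


def metabolite_kl_table(groupings: dict[str, MetaboliteGrouping],
                        kl_grades, targets=(2, 4)) -> pd.DataFrame:
    """Run the metabolite-severity proportion test for every metabolite and
    target grade."""
    rows = []
    for target in targets:
        kb = kl_binarize(kl_grades, target)
        for met in sorted(groupings):
            prop_in, prop_out, p = metabolite_kl_association(
                groupings[met], kb)
            rows.append((met, target, prop_in, prop_out, p))
    return pd.DataFrame(
        rows, columns=["metabolite", "target", "prop_in", "prop_out", "p"])


def select_predictable_metabolites(records: list[PredictionRecord],
                                   cell_type: str,
                                   config: AnalysisConfig) -> set[str]:
    """Metabolites predictable from one cell type's transcriptome after the
    confounder filter: reported accuracy > the overlap threshold for the
    cell type AND confounder (proportion-baseline) accuracy below it."""
    thr = config.overlap_accuracy_threshold
    by_met: dict[str, dict[str, float]] = {}
    for rec in records:
        by_met.setdefault(rec.metabolite, {})[rec.cell_type] = rec.reported_acc
    out = set()
    for met, accs in by_met.items():
        if accs.get(cell_type, 0.0) > thr and \
                accs.get("proportions", 0.0) < thr:
            out.add(met)
    return out


def overlap_enrichment(predictable: set[str], severity_associated: set[str],
                       universe_size: int) -> tuple[int, float]:
    """Hypergeometric enrichment of the intersection of two metabolite sets
    against a universe of ``universe_size``.  Returns (k, upper-tail p)."""
    if len(predictable) > universe_size or \
            len(severity_associated) > universe_size:
        raise ValueError("sets cannot exceed the universe")
    k = len(set(predictable) & set(severity_associated))
    p = hypergeom_upper_tail(k, universe_size, len(predictable),
                             len(severity_associated))
    return k, p
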