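"""Random-forest attribution of metabolites to cell types.

For each (metabolite, cell type) the question is: can the metabolite's
high/low abundance class (75th-quantile split) be predicted from that cell
type's pseudo-bulk transcriptome?  The protocol per repeat:

1. stratified 70/30 train/test split;
2. within the training set, select differentially expressed genes between
   the two classes (two-sample t-test at the 0.05 level) — features are
   chosen inside the split, never on the full data, to avoid leakage;
3. tune a random-forest classifier by randomized hyperparameter search with
   cross-validation on the training set;
4. score balanced accuracy on the held-out test set.

This is repeated 100 times; a 95% CI around the mean accuracy decides the
reporting rule (mean when the CI reaches below 0.5, otherwise the median of
the top 20 accuracies).  A metabolite is linked to a cell type when the
reported accuracy reaches 0.65, and flagged pan-cell-type when four or more
cell types qualify.  A proportion-only baseline (features = the patient's
cell-type composition) serves as the confounder model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RandomizedSearchCV, train_test_split

from .config import AnalysisConfig
from .covariation import MetaboliteGrouping, _t_kernel
from .util import child_seed, get_logger

__all__ = [
    "PredictionRecord", "balanced_accuracy", "de_feature_select",
    "repeat_metabolite_prediction", "reported_accuracy",
    "binomial_significance", "link_metabolites_to_celltypes",
    "proportion_baseline",
]

log = get_logger("predict")

RF_PARAM_GRID = {
    "n_estimators": [100, 300, 500],
    "max_depth": [3, 5, 10, None],
    "min_samples_leaf": [1, 3, 5],
}


def balanced_accuracy(y_true, y_pred) -> float:
    """(sensitivity + specificity) / 2 for binary labels."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = np.unique(y_true)
    if len(classes) != 2:
        raise ValueError("y_true must contain both classes")
    pos, neg = classes[1], classes[0]
    sens = np.mean(y_pred[y_true == pos] == pos)
    spec = np.mean(y_pred[y_true == neg] == neg)
    return float((sens + spec) / 2.0)


def de_feature_select(train_expr: pd.DataFrame, train_labels: np.ndarray,
                      alpha: float, fallback_n: int = 10,
                      welch: bool = False) -> list[str]:
    """Genes differentially expressed between the two training classes
    (two-sample t, p <= alpha), computed on training patients only.

    An empty selection falls back to the ``fallback_n`` smallest-p genes
    (logged) so the classifier always has input features.
    """
    train_labels = np.asarray(train_labels)
    classes = np.unique(train_labels)
    if len(classes) != 2 or min((train_labels == c).sum() for c in classes) < 2:
        raise ValueError("need >= 2 training patients in each class")
    X = train_expr.to_numpy(dtype=float)
    mask = train_labels == classes[0]
    _, p, _ = _t_kernel(X[mask], X[~mask], welch=welch)
    selected = [g for g, pv in zip(train_expr.columns, p) if pv <= alpha]
    if not selected:
        order = np.argsort(p, kind="stable")[:fallback_n]
        selected = [train_expr.columns[i] for i in order]
        log.debug("no DE genes at alpha=%g; falling back to %d smallest-p",
                  alpha, len(selected))
    return selected


def reported_accuracy(accs, n_eff: int, z: float = 1.96
                      ) -> tuple[float, float, float, float]:
    """The repeat-accuracy reporting rule.

    mean = mean(accs); sd = sqrt(mean*(1-mean)/n_eff); CI = mean ± z*sd.
    Report the mean when ci_low < 0.5, otherwise the median of the 20
    largest accuracies.
    """
    accs = np.asarray(accs, dtype=float)
    if accs.size == 0:
        raise ValueError("empty accuracy vector")
    if n_eff < 1:
        raise ValueError("n_eff must be >= 1")
    a_hat = float(accs.mean())
    sd = float(np.sqrt(max(a_hat * (1.0 - a_hat), 0.0) / n_eff))
    ci_low, ci_high = a_hat - z * sd, a_hat + z * sd
    if ci_low < 0.5:
        reported = a_hat
    else:
        top = np.sort(accs)[-min(20, accs.size):]
        reported = float(np.median(top))
    return a_hat, ci_low, ci_high, reported


def binomial_significance(n_correct: int, n_test: int,
                          p0: float = 0.5) -> float:
    """One-sided exact binomial upper tail P(X >= n_correct)."""
    if n_correct > n_test:
        raise ValueError("n_correct cannot exceed n_test")
    return float(stats.binom.sf(n_correct - 1, n_test, p0))


@dataclass
class PredictionRecord:
    """Per (metabolite, feature set) repeated-split prediction result.

    ``cell_type`` is a cell-type id, or "proportions" for the composition
    baseline, or "bulk" for the whole-transcriptome baseline.
    """
    metabolite: str
    cell_type: str
    repeat_accuracies: np.ndarray
    mean_acc: float
    ci_low: float
    ci_high: float
    reported_acc: float
    n_test: int
    features_per_repeat: list[int]
    seed: int
    #: test-set (scores, labels) of the final repeat, for ROC plotting
    last_scores: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False)


def _resolve_n_eff(config: AnalysisConfig, n_repeats: int, n_test: int) -> int:
    token = config.ci_n_eff
    if token == "repeats":
        return n_repeats
    if token == "test_size":
        return n_test
    if token == "one":
        return 1
    return int(token)


def _make_classifier(config: AnalysisConfig, model_seed: int,
                     search_seed: int):
    base = RandomForestClassifier(random_state=model_seed)
    if not config.rf_search:
        base.set_params(n_estimators=config.rf_n_estimators_fixed)
        return base
    return RandomizedSearchCV(
        base, RF_PARAM_GRID, n_iter=config.rf_search_candidates,
        cv=config.rf_cv_folds, scoring="balanced_accuracy",
        random_state=search_seed, n_jobs=None)


def _repeated_prediction(X: pd.DataFrame, y: np.ndarray, n_repeats: int,
                         config: AnalysisConfig, seed: int,
                         select_features: bool) -> tuple[np.ndarray, list[int],
                                                         int, tuple]:
    accs: list[float] = []
    n_feats: list[int] = []
    n_test = 0
    last_scores = None
    for r in range(n_repeats):
        split_seed = child_seed(seed, "rf_splits", r)
        model_seed = child_seed(seed, "rf_model", r)
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, train_size=config.train_fraction, stratify=y,
            random_state=split_seed)
        if min(np.bincount(y_tr)) < 2 or len(np.unique(y_te)) < 2:
            log.debug("repeat %d skipped: degenerate split", r)
            continue
        if select_features:
            feats = de_feature_select(X_tr, y_tr, config.de_alpha,
                                      welch=config.welch)
        else:
            feats = list(X.columns)
        clf = _make_classifier(config, model_seed,
                               child_seed(seed, "rf_model", n_repeats + r))
        clf.fit(X_tr[feats], y_tr)
        y_pred = clf.predict(X_te[feats])
        accs.append(balanced_accuracy(y_te, y_pred))
        n_feats.append(len(feats))
        n_test = len(y_te)
        proba = clf.predict_proba(X_te[feats])[:, 1]
        last_scores = (proba, y_te.copy())
    return np.asarray(accs), n_feats, n_test, last_scores


def repeat_metabolite_prediction(expr: pd.DataFrame,
                                 grouping: MetaboliteGrouping,
                                 config: AnalysisConfig, seed: int,
                                 cell_type: str = "",
                                 select_features: bool = True
                                 ) -> PredictionRecord:
    """Run the full repeated-split protocol for one metabolite against one
    feature matrix (a cell type's pseudo-bulk expression)."""
    patients = expr.index.intersection(grouping.group_labels.index)
    if len(patients) < 20:
        raise ValueError("need at least 20 patients")
    X = expr.loc[patients]
    y = (grouping.group_labels.loc[patients] == 1).to_numpy(dtype=int)
    log.debug("metabolite %s vs %s: seed %d", grouping.metabolite_id,
              cell_type, seed)
    accs, n_feats, n_test, last_scores = _repeated_prediction(
        X, y, config.rf_repeats_metabolite, config, seed, select_features)
    if accs.size == 0:
        raise ValueError("all repeats degenerate; grouping too unbalanced")
    n_eff = _resolve_n_eff(config, accs.size, n_test)
    mean_acc, ci_low, ci_high, reported = reported_accuracy(accs, n_eff)
    return PredictionRecord(
        metabolite=grouping.metabolite_id, cell_type=cell_type,
        repeat_accuracies=accs, mean_acc=mean_acc, ci_low=ci_low,
        ci_high=ci_high, reported_acc=reported, n_test=n_test,
        features_per_repeat=n_feats, seed=seed, last_scores=last_scores)


def proportion_baseline(proportions: pd.DataFrame,
                        grouping: MetaboliteGrouping,
                        config: AnalysisConfig, seed: int) -> PredictionRecord:
    """The confounder model: identical protocol with the patients'
    cell-type composition as features (no DE selection; all columns)."""
    return repeat_metabolite_prediction(
        proportions, grouping, config, seed, cell_type="proportions",
        select_features=False)


def link_metabolites_to_celltypes(records: list[PredictionRecord],
                                  config: AnalysisConfig) -> pd.DataFrame:
    """Apply the linking rules to a set of prediction records.

    Link: reported accuracy >= the link threshold (0.65).  Pan flag: four
    or more linked cell types.  A specific link requires exactly one
    qualifying cell type with no other within ``specific_link_margin`` of
    the threshold.  "proportions"/"bulk" records are excluded from linking.
    """
    thr = config.link_accuracy_threshold
    per_met: dict[str, dict[str, float]] = {}
    for rec in records:
        if rec.cell_type in ("proportions", "bulk"):
            continue
        per_met.setdefault(rec.metabolite, {})[rec.cell_type] = rec.reported_acc
    rows = []
    for met in sorted(per_met):
        acc = per_met[met]
        linked = sorted(ct for ct, a in acc.items() if a >= thr)
        near = [ct for ct, a in acc.items()
                if a >= thr - config.specific_link_margin]
        specific = linked[0] if len(linked) == 1 and len(near) == 1 else ""
        rows.append({
            "metabolite": met,
            "linked_celltypes": ";".join(linked),
            "n_linked": len(linked),
            "pan": len(linked) >= config.pan_link_min_celltypes,
            "specific_celltype": specific,
            "best_acc": max(acc.values()) if acc else np.nan,
        })
    return pd.DataFrame(rows, columns=[
        "metabolite", "linked_celltypes", "n_linked", "pan",
        "specific_celltype", "best_acc"])
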