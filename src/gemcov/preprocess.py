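"""Preprocessing: outlier saturation, standardization, pseudo-bulk
averaging, highly-variable feature selection, cell-type proportions.

The preprocessing convention applied to every matrix (bulk metabolites and
each per-cell-type pseudo-bulk expression matrix) is: saturate each feature
at its 95th quantile, then center to mean zero and scale to unit sample
standard deviation.  Highly variable features are selected by plain variance
ranking on the saturated (unstandardized) values — a deterministic stand-in
for upstream single-cell HVG selection.

Quantiles use linear interpolation between closest order statistics
(numpy's default, "type 7"), and scaling uses the n-1 sample standard
deviation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import OmicsCohort
from .config import AnalysisConfig
from .util import get_logger

__all__ = [
    "saturate_quantile", "standardize_features", "pseudobulk_average",
    "select_highly_variable", "cell_type_proportions", "preprocess_cohort",
]

log = get_logger("preprocess")


def saturate_quantile(values: np.ndarray, q: float) -> np.ndarray:
    """Cap values at their q-th quantile.

    Values >= Q_q are replaced by Q_q; smaller values pass through.  NaNs
    are preserved.  The quantile is computed by linear interpolation of
    order statistics.
    """
    values = np.asarray(values, dtype=float)
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must be in (0, 1), got {q}")
    finite = values[~np.isnan(values)]
    if finite.size < 2:
        raise ValueError("need at least 2 finite values to saturate")
    cap = np.quantile(finite, q)
    return np.where(values >= cap, cap, values)


def standardize_features(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Center each column to mean 0 and scale to sample sd 1.

    Zero-variance columns become all-zero and are returned as flags rather
    than dropped, preserving matrix shape.  NaNs are ignored in the moments
    and preserved in the output.
    """
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1)
    zero_var = sd.index[(sd == 0) | sd.isna()].tolist()
    safe_sd = sd.replace(0.0, 1.0).fillna(1.0)
    out = (matrix - mean) / safe_sd
    if zero_var:
        out[zero_var] = out[zero_var] * 0.0
        log.warning("%d zero-variance feature(s) set to all-zero", len(zero_var))
    return out, zero_var


def pseudobulk_average(cell_matrix: pd.DataFrame,
                       cell_type_labels: np.ndarray,
                       patient_labels: np.ndarray) -> dict[str, pd.DataFrame]:
    """Average cell-level expression within (patient, cell type) groups.

    Returns one patients x genes matrix per cell type.  (patient, type)
    combinations with zero cells are NaN and are excluded from downstream
    testing for that type.
    """
    if len(cell_matrix) == 0:
        raise ValueError("empty cell matrix")
    cell_type_labels = np.asarray(cell_type_labels)
    patient_labels = np.asarray(patient_labels)
    if not len(cell_matrix) == len(cell_type_labels) == len(patient_labels):
        raise ValueError("labels must align with cell rows")
    patients = list(pd.unique(patient_labels))
    out: dict[str, pd.DataFrame] = {}
    for ct in pd.unique(cell_type_labels):
        sub = cell_matrix[cell_type_labels == ct]
        means = sub.groupby(patient_labels[cell_type_labels == ct]).mean()
        out[str(ct)] = means.reindex(patients)
    return out


def select_highly_variable(matrix: pd.DataFrame, n: int) -> list[str]:
    """The n features with largest sample variance; ties broken by feature
    id (lexicographic).  Deterministic."""
    if n > matrix.shape[1]:
        raise ValueError(
            f"requested {n} features but matrix has {matrix.shape[1]}")
    var = matrix.var(axis=0, ddof=1)
    order = sorted(var.index, key=lambda f: (-var[f], str(f)))
    return order[:n]


def cell_type_proportions(cell_type_labels: np.ndarray,
                          patient_labels: np.ndarray) -> pd.DataFrame:
    """Per-patient cell-type composition: counts normalized to row sums 1."""
    cell_type_labels = np.asarray(cell_type_labels)
    patient_labels = np.asarray(patient_labels)
    counts = pd.crosstab(pd.Series(patient_labels, name="patient"),
                         pd.Series(cell_type_labels, name="cell_type"))
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("patient with zero cells")
    props = counts.div(totals, axis=0)
    return props.reindex(pd.unique(patient_labels))


def preprocess_cohort(cohort: OmicsCohort,
                      config: AnalysisConfig) -> OmicsCohort:
    """Apply the full preprocessing convention to a raw cohort.

    Order: select highly variable genes/metabolites on saturated values,
    then saturate and standardize the retained features.  Gene variance is
    pooled across cell types (pseudo-bulk matrices stacked on the patient
    axis) so one gene set serves every cell type.
    """
    q = config.saturation_quantile

    def saturate_df(df: pd.DataFrame) -> pd.DataFrame:
        return df.apply(lambda col: pd.Series(
            saturate_quantile(col.to_numpy(), q), index=col.index))

    sat_pb = {ct: saturate_df(m) for ct, m in cohort.pseudobulk.items()}
    sat_met = saturate_df(cohort.metabolites)

    n_genes = min(config.n_hvg_genes, len(cohort.genes))
    n_mets = min(config.n_hvg_metabolites, sat_met.shape[1])
    stacked = pd.concat(sat_pb.values(), axis=0)
    hvg = select_highly_variable(stacked.dropna(how="any"), n_genes)
    hvm = select_highly_variable(sat_met, n_mets)
    log.info("selected %d highly variable genes, %d metabolites",
             len(hvg), len(hvm))

    flags: dict[str, list[str]] = {}
    pb = {}
    for ct, m in sat_pb.items():
        std, zv = standardize_features(m[hvg])
        pb[ct] = std
        flags[f"expr_{ct}"] = zv
    met, zv = standardize_features(sat_met[hvm])
    flags["metabolites"] = zv

    return OmicsCohort(
        patient_ids=list(cohort.patient_ids),
        cell_types=list(cohort.cell_types),
        pseudobulk=pb,
        metabolites=met,
        proportions=cohort.proportions,
        metadata=cohort.metadata,
        zero_variance_flags=flags,
    )
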