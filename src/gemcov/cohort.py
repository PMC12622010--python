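"""The multi-omics cohort container and its on-disk representation.

An :class:`OmicsCohort` bundles, for one patient cohort:

* per-cell-type pseudo-bulk expression matrices (patients x genes),
* a bulk metabolite abundance matrix (patients x metabolites),
* cell-type proportions per patient,
* patient metadata (site, sex, KL grade in {2, 3, 4}).

All tables share one patient axis in identical order.  On disk a cohort is a
directory of TSV files: ``expr_<celltype>.tsv``, ``metabolites.tsv``,
``proportions.tsv``, ``metadata.tsv`` (columns patient_id, site, sex,
kl_grade).  CSV input is accepted by delimiter sniffing; output is always
TSV so identifiers containing commas (lipid shorthand such as "PC(38:4)")
round-trip losslessly.  Identifiers are opaque strings and never parsed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .util import get_logger

__all__ = ["OmicsCohort", "read_cohort", "write_cohort", "read_table"]

log = get_logger("cohort")

VALID_KL_GRADES = frozenset({2, 3, 4})


class CohortError(ValueError):
    """Fatal cohort validation failure."""


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_table(path: str | Path, numeric: bool = True) -> pd.DataFrame:
    """Read a delimited matrix with a header row of feature ids and patient
    ids in the first column.  Tab or comma delimited (sniffed)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    df.index = df.index.astype(str)
    if numeric:
        try:
            df = df.astype(float)
        except (TypeError, ValueError) as exc:
            bad = _locate_non_numeric(df)
            raise CohortError(
                f"non-numeric cell in {path.name} at row {bad[0]!r}, "
                f"column {bad[1]!r}") from exc
    return df


def _locate_non_numeric(df: pd.DataFrame) -> tuple[str, str]:
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        mask = coerced.isna() & df[col].notna()
        if mask.any():
            return str(df.index[mask.argmax()]), str(col)
    return "?", "?"


@dataclass
class OmicsCohort:
    patient_ids: list[str]
    cell_types: list[str]
    pseudobulk: dict[str, pd.DataFrame]
    metabolites: pd.DataFrame
    proportions: pd.DataFrame
    metadata: pd.DataFrame
    #: set by preprocessing: features scaled to zero variance.
    zero_variance_flags: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        pts = list(self.patient_ids)
        for ct, mat in self.pseudobulk.items():
            if list(mat.index) != pts:
                raise CohortError(f"pseudobulk[{ct}] patient axis mismatch")
        for name, mat in (("metabolites", self.metabolites),
                          ("proportions", self.proportions),
                          ("metadata", self.metadata)):
            if list(mat.index) != pts:
                raise CohortError(f"{name} patient axis mismatch")
        if set(self.proportions.columns) != set(self.cell_types):
            raise CohortError("proportions columns != cell types")
        rowsums = self.proportions.sum(axis=1).to_numpy()
        if not np.allclose(rowsums, 1.0, atol=1e-9):
            raise CohortError("proportions rows must sum to 1")
        grades = set(self.metadata["kl_grade"].tolist())
        if not grades <= VALID_KL_GRADES:
            bad = self.metadata.index[
                ~self.metadata["kl_grade"].isin(VALID_KL_GRADES)][0]
            raise CohortError(
                f"invalid kl_grade for patient {bad!r} "
                f"(expected one of {sorted(VALID_KL_GRADES)})")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def genes(self) -> list[str]:
        first = self.pseudobulk[self.cell_types[0]]
        return list(first.columns)

    def celltype_patients(self, cell_type: str) -> pd.Index:
        """Patients with a complete pseudo-bulk row for this cell type
        (patient/cell-type combinations with zero cells are missing)."""
        mat = self.pseudobulk[cell_type]
        return mat.index[~mat.isna().any(axis=1)]


def _celltype_from_filename(name: str) -> str:
    return name[len("expr_"):-len(".tsv")]


def read_cohort(path: str | Path, config=None) -> OmicsCohort:
    """Read a cohort directory, aligning all tables on the common patient set.

    Patients missing from any table are dropped with a logged warning; an
    empty intersection, a non-numeric cell, or a KL grade outside {2, 3, 4}
    is fatal.
    """
    path = Path(path)
    expr_files = sorted(path.glob("expr_*.tsv")) + sorted(path.glob("expr_*.csv"))
    if not expr_files:
        raise CohortError(f"no expr_<celltype>.tsv files in {path}")
    pseudobulk = {
        _celltype_from_filename(f.name.replace(".csv", ".tsv")): read_table(f)
        for f in expr_files
    }
    metabolites = read_table(path / "metabolites.tsv")
    proportions = read_table(path / "proportions.tsv")
    meta_path = path / "metadata.tsv"
    metadata = pd.read_csv(meta_path, sep=_sniff_sep(meta_path), dtype=str)
    required = {"patient_id", "site", "sex", "kl_grade"}
    if not required <= set(metadata.columns):
        raise CohortError(
            f"metadata.tsv must have columns {sorted(required)}")
    metadata = metadata.set_index("patient_id")
    metadata.index = metadata.index.astype(str)
    try:
        metadata["kl_grade"] = metadata["kl_grade"].astype(int)
    except ValueError:
        bad = metadata.index[
            pd.to_numeric(metadata["kl_grade"], errors="coerce").isna()][0]
        raise CohortError(f"invalid kl_grade for patient {bad!r}") from None

    tables: list[pd.Index] = [m.index for m in pseudobulk.values()]
    tables += [metabolites.index, proportions.index, metadata.index]
    common = tables[0]
    for idx in tables[1:]:
        common = common.intersection(idx)
    union = tables[0]
    for idx in tables[1:]:
        union = union.union(idx)
    if len(common) == 0:
        raise CohortError("empty intersection of patient ids across tables")
    dropped = union.difference(common)
    if len(dropped) > 0:
        log.warning("dropping %d patient(s) missing from some table: %s",
                    len(dropped), ", ".join(map(str, dropped[:10])))
    # preserve the order of the first expression table
    order = [p for p in pseudobulk[next(iter(pseudobulk))].index if p in common]
    pseudobulk = {ct: m.loc[order] for ct, m in pseudobulk.items()}
    return OmicsCohort(
        patient_ids=list(order),
        cell_types=sorted(pseudobulk),
        pseudobulk=pseudobulk,
        metabolites=metabolites.loc[order],
        proportions=proportions.loc[order],
        metadata=metadata.loc[order],
    )


def write_cohort(cohort: OmicsCohort, out_dir: str | Path) -> list[Path]:
    """Write the cohort as the TSV file set :func:`read_cohort` consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for ct in cohort.cell_types:
        p = out / f"expr_{ct}.tsv"
        cohort.pseudobulk[ct].to_csv(p, sep="\t", index_label="patient_id")
        written.append(p)
    for name, df in (("metabolites", cohort.metabolites),
                     ("proportions", cohort.proportions)):
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index_label="patient_id")
        written.append(p)
    p = out / "metadata.tsv"
    cohort.metadata.to_csv(p, sep="\t", index_label="patient_id")
    written.append(p)
    return written
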