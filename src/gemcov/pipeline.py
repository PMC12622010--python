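"""Stage functions chaining the full analysis, shared by the CLI.

Each stage reads/writes the canonical TSV file set and logs its timing and
record counts.  ``run_all`` executes simulate-to-severity in memory and
writes one flat result directory with a machine-readable ``summary.json``
that echoes the effective configuration.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import covariation as cov
from . import pathways as pw
from . import predict as ml
from . import severity as sev
from .cohort import OmicsCohort, read_cohort, write_cohort
from .config import AnalysisConfig, SimConfig
from .io import (read_gmt, read_pathway_metabolites, write_gmt,
                 write_pathway_metabolites, write_results)
from .preprocess import preprocess_cohort
from .simulate import generate_cohort
from .util import child_seed, get_logger

__all__ = [
    "stage_simulate", "stage_preprocess", "stage_associate", "stage_hubs",
    "stage_highconf", "stage_enrich", "stage_predict", "stage_severity",
    "run_all",
]

log = get_logger("pipeline")


def _timed(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            log.info("stage %s finished in %.2fs", name,
                     time.perf_counter() - self.t0)
    return _Timer()


def stage_simulate(sim: SimConfig, out_dir: str | Path) -> Path:
    """Generate a cohort and write the full input file set plus truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with _timed("simulate"):
        cohort, truth, gene_sets, met_sets = generate_cohort(sim)
        write_cohort(cohort, out)
        write_gmt(gene_sets, out / "pathways.gmt")
        write_pathway_metabolites(met_sets, out / "pathway_metabolites.tsv")
        write_results(truth.to_frames(), out)
    return out


def stage_preprocess(cohort: OmicsCohort,
                     config: AnalysisConfig) -> OmicsCohort:
    with _timed("preprocess"):
        return preprocess_cohort(cohort, config)


def stage_associate(pre: OmicsCohort, config: AnalysisConfig) -> pd.DataFrame:
    with _timed("associate"):
        assoc = cov.build_association_map(pre, config)
        n_sig = int((assoc["p"] <= config.assoc_alpha).sum())
        log.info("association map: %d records, %d significant at %g",
                 len(assoc), n_sig, config.assoc_alpha)
        return assoc


def stage_hubs(assoc: pd.DataFrame, pre: OmicsCohort,
               config: AnalysisConfig) -> dict:
    """Degrees, per-cell-type hubs, specificity, pan hubs, density test."""
    with _timed("hubs"):
        degrees = cov.compute_degrees(
            assoc, config.assoc_alpha, gene_universe=pre.genes,
            metabolite_universe=list(pre.metabolites.columns),
            cell_types=pre.cell_types)
        hub_sets = cov.select_hub_sets(degrees, config)
        spec_scores, specific = {}, {}
        pan = {}
        for kind in ("gene", "metabolite"):
            spec_scores[kind], specific[kind] = cov.specificity_scores(
                degrees, kind, n_top=config.n_specific_hubs)
            pan[kind] = cov.pan_celltype_ranks(degrees, kind,
                                               n=config.n_pan_hubs)
        density = []
        for ct in pre.cell_types:
            obs, p = cov.density_permutation_pvalue(
                assoc, hub_sets["gene"][ct], hub_sets["metabolite"][ct], ct,
                config.n_density_perms,
                seed=child_seed(config.seed, "density_perm",
                                pre.cell_types.index(ct)),
                alpha=config.assoc_alpha, gene_pool=pre.genes,
                metabolite_pool=list(pre.metabolites.columns))
            density.append((ct, obs, p))
        sharing = {kind: cov.hub_sharing_counts(hub_sets[kind])
                   for kind in ("gene", "metabolite")}
        return {
            "degrees": degrees, "hub_sets": hub_sets,
            "specificity": spec_scores, "specific_hubs": specific,
            "pan_hubs": pan,
            "density": pd.DataFrame(
                density, columns=["cell_type", "density", "p"]),
            "sharing": sharing,
        }


def stage_highconf(assoc: pd.DataFrame, gene_sets: dict[str, set[str]],
                   met_sets: dict[str, set[str]],
                   config: AnalysisConfig) -> dict:
    with _timed("highconf"):
        anns = pw.annotations_from_files(gene_sets, met_sets)
        hc = pw.build_high_confidence_map(assoc, anns, config.assoc_alpha)
        rankings = {
            axis: pw.rank_by_frequency(hc, axis,
                                       distinct_pairs=config.count_distinct_pairs)
            for axis in ("metabolite", "gene", "pathway_id")
        }
        frac_neg = pw.direction_of_effect_summary(hc) if len(hc) else None
        return {"highconf": hc, "rankings": rankings,
                "fraction_negative": frac_neg}


def stage_enrich(hub_sets: dict[str, dict[str, list[str]]],
                 gene_sets: dict[str, set[str]], universe: set[str],
                 config: AnalysisConfig) -> pd.DataFrame:
    """Over-representation of each cell type's hub-gene set in the pathway
    gene sets, against the highly-variable-gene universe."""
    with _timed("enrich"):
        frames = []
        for ct, hubs in sorted(hub_sets["gene"].items()):
            res = pw.set_enrichment(set(hubs) & universe, gene_sets, universe)
            res.insert(0, "cell_type", ct)
            frames.append(res)
        return pd.concat(frames, ignore_index=True)


def _groupings(pre: OmicsCohort, config: AnalysisConfig
               ) -> dict[str, cov.MetaboliteGrouping]:
    out = {}
    for met in pre.metabolites.columns:
        g = cov.discretize_metabolite(
            pre.metabolites[met], q=config.metabolite_split_quantile,
            min_group=config.min_group)
        if g is not None:
            out[met] = g
    return out


def stage_predict(pre: OmicsCohort, config: AnalysisConfig) -> dict:
    """Repeated-split RF prediction of every metabolite from every cell
    type's transcriptome, plus the proportion-baseline confounder model."""
    with _timed("predict"):
        groupings = _groupings(pre, config)
        mets = sorted(groupings)
        if config.predict_max_metabolites is not None:
            mets = mets[:config.predict_max_metabolites]
        records: list[ml.PredictionRecord] = []
        for i, met in enumerate(mets):
            for ct in pre.cell_types:
                expr = pre.pseudobulk[ct].loc[pre.celltype_patients(ct)]
                records.append(ml.repeat_metabolite_prediction(
                    expr, groupings[met], config,
                    seed=child_seed(config.seed, "rf_splits", i * 1000 +
                                    pre.cell_types.index(ct)),
                    cell_type=ct))
            records.append(ml.proportion_baseline(
                pre.proportions, groupings[met], config,
                seed=child_seed(config.seed, "rf_splits", i * 1000 + 999)))
        links = ml.link_metabolites_to_celltypes(records, config)
        table = pd.DataFrame([{
            "metabolite": r.metabolite, "cell_type": r.cell_type,
            "mean_acc": r.mean_acc, "ci_low": r.ci_low,
            "ci_high": r.ci_high, "reported_acc": r.reported_acc,
            "n_test": r.n_test,
        } for r in records])
        log.info("prediction: %d records, %d linked metabolites",
                 len(records), int((links["n_linked"] > 0).sum())
                 if len(links) else 0)
        return {"records": records, "predictions": table, "links": links}


def stage_severity(pre: OmicsCohort,
                   hub_sets: dict[str, dict[str, list[str]]],
                   predict_records: list | None,
                   config: AnalysisConfig) -> dict:
    """Severity classifiers per cell type (plus a bulk baseline), the
    metabolite-KL proportion tests, and the predictable/severity overlap."""
    with _timed("severity"):
        grades = pre.metadata["kl_grade"].to_numpy()
        results: list[sev.SeverityResult] = []
        for target in (2, 4):
            labels_all = sev.kl_binarize(grades, target)
            if min(np.bincount(labels_all, minlength=2)) < 10:
                log.warning("KL-%d group too small; skipping classifiers",
                            target)
                continue
            for ct in pre.cell_types:
                patients = pre.celltype_patients(ct)
                idx = [pre.patient_ids.index(p) for p in patients]
                results.append(sev.severity_classification(
                    pre.pseudobulk[ct].loc[patients],
                    hub_sets["gene"][ct], labels_all[idx], config,
                    seed=child_seed(config.seed, "severity",
                                    100 * target + pre.cell_types.index(ct)),
                    cell_type=ct, target=target))
            # bulk baseline: all cell types' matrices averaged, all HVGs
            bulk = sum(pre.pseudobulk[ct].fillna(0.0)
                       for ct in pre.cell_types) / len(pre.cell_types)
            results.append(sev.severity_classification(
                bulk, list(bulk.columns), labels_all, config,
                seed=child_seed(config.seed, "severity", 100 * target + 99),
                cell_type="bulk", target=target))
        groupings = _groupings(pre, config)
        met_kl = sev.metabolite_kl_table(groupings, grades)
        overlap = None
        if predict_records is not None and results:
            target = 4
            kl4 = met_kl[(met_kl["target"] == target)
                         & (met_kl["p"] < config.de_alpha)]
            severity_mets = set(kl4["metabolite"])
            ct_results = [r for r in results
                          if r.target == target and r.cell_type != "bulk"]
            if ct_results and severity_mets:
                best_ct = max(ct_results, key=lambda r: r.auroc).cell_type
                predictable = sev.select_predictable_metabolites(
                    predict_records, best_ct, config)
                k, p = sev.overlap_enrichment(
                    predictable, severity_mets,
                    universe_size=pre.metabolites.shape[1])
                overlap = {"cell_type": best_ct, "target": target,
                           "n_predictable": len(predictable),
                           "n_severity": len(severity_mets),
                           "overlap": k, "p": p}
        table = pd.DataFrame([{
            "cell_type": r.cell_type, "target": r.target,
            "median_run_accuracy": r.median_accuracy, "auroc": r.auroc,
        } for r in results])
        return {"results": results, "severity": table, "met_kl": met_kl,
                "overlap": overlap}


def run_all(in_dir: str | Path, out_dir: str | Path,
            config: AnalysisConfig) -> Path:
    """Run preprocess → associate → hubs → highconf → enrich → predict →
    severity on a cohort directory; write all tables and summary.json."""
    in_dir, out = Path(in_dir), Path(out_dir)
    cohort = read_cohort(in_dir, config)
    gene_sets = read_gmt(in_dir / "pathways.gmt")
    met_sets = read_pathway_metabolites(in_dir / "pathway_metabolites.tsv")

    pre = stage_preprocess(cohort, config)
    assoc = stage_associate(pre, config)
    hubs = stage_hubs(assoc, pre, config)
    hc = stage_highconf(assoc, gene_sets, met_sets, config)
    enrich = stage_enrich(hubs["hub_sets"], gene_sets, set(pre.genes), config)
    pred = stage_predict(pre, config)
    sev_out = stage_severity(pre, hubs["hub_sets"], pred["records"], config)

    tables = {
        "associations": assoc,
        "degrees_genes": hubs["degrees"].genes.reset_index(names="gene"),
        "degrees_metabolites":
            hubs["degrees"].metabolites.reset_index(names="metabolite"),
        "hubs_celltype": pd.DataFrame(
            [(kind, ct, e) for kind in ("gene", "metabolite")
             for ct, members in hubs["hub_sets"][kind].items()
             for e in members],
            columns=["kind", "cell_type", "entity"]),
        "hubs_specific": pd.DataFrame(
            [(kind, ct, e) for kind in ("gene", "metabolite")
             for ct, members in hubs["specific_hubs"][kind].items()
             for e in members],
            columns=["kind", "cell_type", "entity"]),
        "hubs_pan": pd.concat(
            [hubs["pan_hubs"][kind].assign(kind=kind)
             for kind in ("gene", "metabolite")], ignore_index=True),
        "density_test": hubs["density"],
        "highconf": hc["highconf"],
        "enrichment": enrich,
        "predictions": pred["predictions"],
        "links": pred["links"],
        "severity": sev_out["severity"],
        "met_kl": sev_out["met_kl"],
    }
    summary = {
        "config": {k: v for k, v in
                   dataclasses.asdict(config).items()},
        "n_association_records": int(len(assoc)),
        "n_significant": int((assoc["p"] <= config.assoc_alpha).sum()),
        "n_highconf_quadruplets": int(len(hc["highconf"])),
        "fraction_negative_direction": hc["fraction_negative"],
        "n_linked_metabolites":
            int((pred["links"]["n_linked"] > 0).sum())
            if len(pred["links"]) else 0,
        "n_pan_metabolites": int(pred["links"]["pan"].sum())
            if len(pred["links"]) else 0,
        "density_pvalues": {
            row.cell_type: row.p for row in
            hubs["density"].itertuples(index=False)},
        "severity_auroc": {
            f"{r.cell_type}_KL{r.target}": r.auroc
            for r in sev_out["results"]},
        "overlap": sev_out["overlap"],
    }
    write_results(tables, out, summary=summary)
    for r in sev_out["results"]:
        roc = pd.DataFrame(r.roc_points, columns=["fpr", "tpr"])
        roc.to_csv(out / f"roc_{r.cell_type}_KL{r.target}.tsv", sep="\t",
                   index=False, float_format="%.10g")
    return out
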