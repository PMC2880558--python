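"""End-to-end orchestration: simulate/ingest -> filter -> co-twin normalize ->
classify -> map SNPs -> residualize -> associate -> meta-analyze -> enrichment.

Every intermediate is written as a plain TSV so each stage is independently
auditable, and a manifest records the configuration, seed and per-stage row
counts. Outputs are pure functions of (inputs, config, seed); reruns are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, enrich, io as cio, prep, simulate as sim
from . import classify as tc
from .types import PipelineError, ValidationError

FLOAT_FORMAT = cio.FLOAT_FORMAT


@dataclass
class PipelineConfig:
    """Paths, thresholds and mode flags for a full run."""

    out_dir: str = "cotwin_run"
    seed: int = 0
    #: when true, inputs are generated with :mod:`cotwin.simulate`
    simulate: bool = True
    sim_params: dict = field(default_factory=dict)

    # explicit inputs (used when simulate is false)
    twin_expression: str | None = None
    twin_pairs: str | None = None
    unrelated_expression: str | None = None
    unrelated_phenotypes: str | None = None
    cohort_genotypes: list = field(default_factory=list)
    cohort_phenotypes: list = field(default_factory=list)
    annotation: str | None = None
    probe_gene_map: str | None = None

    # thresholds (defaults follow the study design)
    expr_threshold: float = 50.0
    min_fraction: float = 0.5
    pseudocount: float = 0.0
    alpha_reactive: float = 0.05
    alpha_corr: float = 1e-4
    alpha_nominal: float = 0.05
    twin_test_mode: str = "log_ratio_one_sample"
    flank: int = 1000
    maf_floor: float = 0.01
    n_bins: int = 20
    best_snp: bool = True
    extra_covariates: list = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT,
              lineterminator="\n")
    return len(df)


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    manifest = {"config": config.to_dict(), "seed": config.seed, "stages": counts}

    # ---- inputs ----------------------------------------------------------
    stage = "simulate" if config.simulate else "ingest"
    try:
        if config.simulate:
            sim_cfg = sim.SimulationConfig(**{**config.sim_params, "seed": config.seed})
            paths = sim.write_dataset(sim_cfg, out / "inputs")
        else:
            paths = {
                "twin_expression": config.twin_expression,
                "twin_pairs": config.twin_pairs,
                "unrelated_expression": config.unrelated_expression,
                "unrelated_phenotypes": config.unrelated_phenotypes,
                "cohort_genotypes": list(config.cohort_genotypes),
                "cohort_phenotypes": list(config.cohort_phenotypes),
                "annotation": config.annotation,
                "probe_gene_map": config.probe_gene_map,
            }
        required = ["twin_expression", "twin_pairs", "unrelated_expression",
                    "unrelated_phenotypes", "annotation", "probe_gene_map"]
        missing = [k for k in required if not paths.get(k)]
        if missing:
            raise ValidationError(f"missing inputs: {missing}")
        if not paths["cohort_genotypes"] or not paths["cohort_phenotypes"]:
            raise ValidationError("missing inputs: cohort genotype/phenotype files")
        expr_twin = cio.read_expression_matrix(paths["twin_expression"])
        pairs = cio.read_twin_pairs(paths["twin_pairs"])
        expr_unrel = cio.read_expression_matrix(paths["unrelated_expression"])
        pheno_unrel = cio.read_phenotypes(paths["unrelated_phenotypes"])
        annotation = cio.read_gene_annotation(paths["annotation"])
        probe_map = pd.read_csv(paths["probe_gene_map"], sep="\t", dtype=str)
        cohorts = [
            (cio.read_genotypes(g), cio.read_phenotypes(p))
            for g, p in zip(paths["cohort_genotypes"], paths["cohort_phenotypes"])
        ]
        counts[stage] = {"twin_probes": expr_twin.n_probes,
                         "unrelated_probes": expr_unrel.n_probes,
                         "cohorts": len(cohorts)}
    except Exception as exc:
        raise PipelineError(f"{stage}: {exc}") from exc

    # ---- expression filter ----------------------------------------------
    try:
        expr_twin_f = prep.filter_by_expression(
            expr_twin, config.expr_threshold, config.min_fraction)
        expr_unrel_f = prep.filter_by_expression(
            expr_unrel, config.expr_threshold, config.min_fraction)
        cio.write_expression_matrix(expr_twin_f, out / "filtered_twin_expression.tsv")
        cio.write_expression_matrix(expr_unrel_f, out / "filtered_unrelated_expression.tsv")
        counts["filter"] = {"twin_probes": expr_twin_f.n_probes,
                            "unrelated_probes": expr_unrel_f.n_probes}
    except Exception as exc:
        raise PipelineError(f"filter: {exc}") from exc

    # ---- co-twin normalization ------------------------------------------
    try:
        ratios = prep.cotwin_normalize(expr_twin_f, pairs, config.pseudocount)
        ratio_df = pd.DataFrame(ratios.ratios, columns=ratios.pair_ids)
        ratio_df.insert(0, "probe_id", ratios.probe_ids)
        counts["cotwin"] = {"probes": len(ratio_df), "pairs": ratios.n_pairs}
        _write(ratio_df, out / "pair_ratios.tsv")
    except Exception as exc:
        raise PipelineError(f"cotwin: {exc}") from exc

    # ---- classification --------------------------------------------------
    try:
        differential = tc.test_intrapair_difference(
            ratios, config.twin_test_mode, matrix=expr_twin_f, pairs=pairs)
        correlation = tc.correlate_with_bmi(expr_unrel_f, pheno_unrel)
        # restrict to probes passing the filter in BOTH datasets
        shared = sorted(set(differential["probe_id"]) & set(correlation["probe_id"]))
        differential_s = differential[differential["probe_id"].isin(shared)]
        correlation_s = correlation[correlation["probe_id"].isin(shared)]
        labels = tc.classify(differential_s, correlation_s,
                             config.alpha_reactive, config.alpha_corr)
        gene_labels = tc.collapse_probes_to_genes(labels, probe_map)
        table = (labels.merge(correlation, on="probe_id")
                       .merge(differential[["probe_id", "median_fold_change", "p_value"]]
                              .rename(columns={"p_value": "p_twin"}), on="probe_id")
                       .merge(probe_map, on="probe_id", how="left"))
        table = table[["gene_id", "probe_id", "pearson_r", "p_value",
                       "median_fold_change", "p_twin", "label"]]
        table = table.rename(columns={"p_value": "p_corr",
                                      "median_fold_change": "fold_change"})
        _write(differential, out / "intrapair_tests.tsv")
        _write(correlation, out / "bmi_correlations.tsv")
        _write(labels, out / "probe_classification.tsv")
        _write(gene_labels, out / "gene_classification.tsv")
        _write(table, out / "classification_table.tsv")
        counts["classify"] = labels["label"].value_counts().to_dict()
    except Exception as exc:
        raise PipelineError(f"classify: {exc}") from exc

    # ---- SNP -> gene mapping --------------------------------------------
    try:
        gene_sets = gene_labels[gene_labels["label"].isin(
            ["causative", "correlated_and_reactive"])].copy()
        gene_sets["gene_set"] = np.where(
            gene_sets["label"] == "causative", "causative", "reactive")
        snp_meta = cohorts[0][0].snps
        assignments = assoc.map_snps_to_genes(
            annotation, snp_meta, gene_sets[["gene_id", "gene_set"]], config.flank)
        _write(assignments, out / "snp_assignments.tsv")
        counts["map"] = {"assignments": len(assignments),
                         "causative_genes": int((gene_sets["gene_set"] == "causative").sum()),
                         "reactive_genes": int((gene_sets["gene_set"] == "reactive").sum())}
    except Exception as exc:
        raise PipelineError(f"map: {exc}") from exc

    # ---- residualize + associate + meta ---------------------------------
    try:
        tested = assignments["snp_id"].unique()
        records = []
        for geno, pheno in cohorts:
            resid = assoc.prepare_phenotype(pheno, tuple(config.extra_covariates))
            keep = geno.snps["snp_id"].isin(tested).to_numpy()
            sub = cio.GenotypeDosageMatrix(
                geno.snps[keep].reset_index(drop=True),
                geno.sample_ids, geno.dosages[keep])
            for stratum in ("female", "male", "pooled"):
                records.append(assoc.associate(sub, resid, stratum, config.maf_floor))
        records = pd.concat(records, ignore_index=True)
        meta = assoc.meta_fixed_effects(records)
        result = (assignments[["snp_id", "gene_id", "gene_set"]]
                  .drop_duplicates("snp_id")
                  .merge(meta, on="snp_id"))
        _write(records, out / "association_records.tsv")
        _write(result, out / "meta_analysis.tsv")
        counts["assoc"] = {"records": len(records), "meta_snps": len(meta)}
    except Exception as exc:
        raise PipelineError(f"assoc: {exc}") from exc

    # ---- enrichment ------------------------------------------------------
    try:
        chisq_rows, qq_frames = [], []
        for set_label in ("causative", "reactive"):
            sub = result[result["gene_set"] == set_label]
            if len(sub) >= 10:
                test = enrich.chisq_uniformity(sub["p_overall"], config.n_bins, set_label)
                chisq_rows.append((set_label, test.n, test.n_bins,
                                   test.chi2_statistic, test.df, test.p_value))
                qq_frames.append(enrich.qq_series(sub["p_overall"], set_label).to_frame())
            if config.best_snp and not sub.empty:
                best = enrich.best_snp_per_gene(sub, assignments)
                if len(best) >= 10:
                    t2 = enrich.chisq_uniformity(best["p_overall"], config.n_bins,
                                                 f"{set_label}_best_snp")
                    chisq_rows.append((f"{set_label}_best_snp", t2.n, t2.n_bins,
                                       t2.chi2_statistic, t2.df, t2.p_value))
        chisq = pd.DataFrame(chisq_rows, columns=["set", "n", "n_bins", "chi2", "df", "p"])
        n_snps, n_genes = enrich.count_nominal_hits(
            result[result["gene_set"] == "causative"], assignments, config.alpha_nominal)
        hits = pd.DataFrame({"set": ["causative"], "alpha": [config.alpha_nominal],
                             "n_snps": [n_snps], "n_genes": [n_genes]})
        _write(chisq, out / "enrichment_chisq.tsv")
        if qq_frames:
            _write(pd.concat(qq_frames, ignore_index=True), out / "qq_series.tsv")
        _write(hits, out / "nominal_hits.tsv")
        counts["enrich"] = {"sets": len(chisq), "nominal_snps": n_snps,
                            "nominal_genes": n_genes}
    except Exception as exc:
        raise PipelineError(f"enrich: {exc}") from exc

    from . import __version__

    manifest["version"] = __version__
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest
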