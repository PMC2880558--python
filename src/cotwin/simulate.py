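"""Synthetic twin-pair, unrelated-cohort and GWAS-panel data generation.

The generator plants the exact causal structure the classification stage is
designed to detect:

* **Causal genes** carry a cis-SNP explaining ``snp_h2`` of their (log)
  expression variance; their expression feeds forward into BMI, so in
  unrelated individuals each causal gene correlates with BMI at
  ``causal_r``, while monozygotic co-twins — who share the genotype — show
  no expected intrapair expression difference.
* **Reactive genes** respond to the individual's own BMI, so they both
  correlate with BMI in unrelated individuals and differ within discordant
  pairs (median obese/lean fold change ``reactive_fc``).
* **Null genes** are noise.

A geometric constraint shapes the BMI model: k independent expression traits
cannot each correlate r with one outcome unless k * r^2 <= 1. With the
default 20 causal genes at r = 0.45 that bound is violated, so causal-gene
expression shares a common co-regulation factor (pairwise correlation
``s``), solved so that each gene attains exactly ``causal_r`` given
``expr_bmi_frac`` — the fraction of ln-BMI variance driven by expression.
Configurations that would need s >= 1 - snp_h2 are rejected.

BMI is generated on the natural-log scale and exponentiated (matching the
analysis of logarithmized BMI); expression noise is normal on the log2 scale
and intensities are exponentiated to be positive. Everything is a pure
function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import (
    ExpressionMatrix,
    GenotypeDosageMatrix,
    ParameterizationError,
    TwinPairSet,
    ValidationError,
)

GENE_BODY = 10_000  # bases
GENE_SPACING = 1_000_000
N_CHROMS = 22

_STAGE_PANEL, _STAGE_UNRELATED, _STAGE_TWINS, _STAGE_COHORTS, _STAGE_GENO = range(5)


def _rng(seed: int, stage: int) -> np.random.Generator:
    """Deterministic per-stage generator: stages never share streams."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stage,)))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic datasets.

    Defaults emulate the study design this pipeline targets: 13 MZ pairs
    discordant for BMI (obese co-twin ~22% heavier), 77 unrelated adults
    with BMI 26.6 +- 4.1 kg/m^2, and a reduced-scale multi-cohort GWAS panel
    (4 cohorts x 500) standing in for a consortium meta-analysis.
    """

    n_pairs: int = 13
    n_unrelated: int = 77
    n_cohorts: int = 4
    n_per_cohort: int = 500
    n_causal_genes: int = 20
    n_reactive_genes: int = 20
    n_null_genes: int = 200
    snps_per_gene: int = 3
    #: target |Pearson r| of each causal gene's expression with BMI (unrelated)
    causal_r: float = 0.45
    #: target median obese/lean fold change of reactive genes in twins
    reactive_fc: float = 1.3
    #: fraction of causal-gene log-expression variance explained by its cis-SNP
    snp_h2: float = 0.3
    maf_range: tuple = (0.05, 0.5)
    bmi_mean: float = 26.6  # kg/m^2
    bmi_sd: float = 4.1  # kg/m^2
    #: mean obese/lean weight excess within a pair, percent
    discordance_pct: float = 22.0
    #: residual log2-intensity noise sd (technical + biological)
    noise_sd: float = 0.2
    #: max fraction of ln-BMI variance driven by causal expression
    expr_bmi_frac: float = 0.8
    sex_effect: float = 0.04  # ln-BMI shift for males (cohort panels)
    age_effect: float = 0.003  # ln-BMI per year of age (cohort panels)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_pairs", "n_unrelated", "n_cohorts", "n_per_cohort", "snps_per_gene"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        for name in ("n_causal_genes", "n_reactive_genes", "n_null_genes"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0 < self.causal_r < 1:
            raise ValidationError("causal_r must be in (0, 1)")
        if not 0 <= self.snp_h2 < 1:
            raise ValidationError("snp_h2 must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range must be within (0, 0.5]")
        if self.reactive_fc <= 0:
            raise ValidationError("reactive_fc must be > 0")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if not 0 < self.expr_bmi_frac < 1:
            raise ValidationError("expr_bmi_frac must be in (0, 1)")
        if self.bmi_mean <= 0 or self.bmi_sd <= 0:
            raise ValidationError("bmi_mean and bmi_sd must be > 0")
        if self.discordance_pct <= 0:
            raise ValidationError("discordance_pct must be > 0")


@dataclass
class SyntheticTruth:
    """Planted ground truth: gene classes, the SNP panel and model constants."""

    genes: pd.DataFrame  # gene_id, probe_id, gene_class, chrom, start, end, baseline_log2, cis_snp
    snps: pd.DataFrame  # snp_id, chrom, pos, ref, alt, freq, gene_id, functional
    params: dict = field(default_factory=dict)

    def gene_class_of(self) -> dict:
        return dict(zip(self.genes["gene_id"], self.genes["gene_class"]))

    def probe_gene_map(self) -> pd.DataFrame:
        return self.genes[["probe_id", "gene_id"]].copy()

    def annotation(self) -> pd.DataFrame:
        ann = self.genes[["gene_id", "chrom", "start", "end"]].copy()
        ann["strand"] = "unknown"
        return ann

    def to_frame(self) -> pd.DataFrame:
        """Truth TSV contents: gene_id, class, snp_id of the functional cis-SNP."""
        cis = self.genes[["gene_id", "gene_class", "cis_snp"]].rename(
            columns={"gene_class": "class", "cis_snp": "snp_id"}
        )
        return cis


def derive_model_params(config: SimulationConfig) -> dict:
    """Solve the generative constants implied by the configuration.

    Returns tau/mu_ln for the ln-BMI scale, the causal shared-factor
    correlation ``s`` and expression-variance fraction ``v``, the reactive
    slope (log2 expression per log2 BMI) and the causal expression scale.
    Raises :class:`ParameterizationError` when ``causal_r`` is unattainable.
    """
    cv2 = (config.bmi_sd / config.bmi_mean) ** 2
    tau = math.sqrt(math.log1p(cv2))
    mu_ln = math.log(config.bmi_mean) - tau**2 / 2
    nc, r, vmax = config.n_causal_genes, config.causal_r, config.expr_bmi_frac
    if nc == 0:
        s, v = 0.0, 0.0
    elif nc * r**2 <= vmax:
        v, s = nc * r**2, 0.0
    else:
        v = vmax
        s = (nc * r**2 / v - 1.0) / (nc - 1)
        if s >= 1.0 - config.snp_h2:
            raise ParameterizationError(
                f"causal_r={r} with {nc} causal genes needs shared-factor "
                f"correlation {s:.3f} >= 1 - snp_h2 = {1 - config.snp_h2:.3f}; "
                "lower causal_r, n_causal_genes or snp_h2"
            )
    d = config.discordance_pct / 100.0
    delta_l2 = math.log(config.reactive_fc) / math.log1p(d)
    sigma_expr = config.noise_sd / math.sqrt(max(1.0 - config.snp_h2 - s, 1e-12))
    return {
        "tau": tau,
        "mu_ln": mu_ln,
        "s_shared": s,
        "v_frac": v,
        "delta_log2": delta_l2,
        "sigma_expr": sigma_expr,
        "log_discordance": math.log1p(d),
    }


def _build_truth(config: SimulationConfig) -> SyntheticTruth:
    rng = _rng(config.seed, _STAGE_PANEL)
    classes = (
        ["causal"] * config.n_causal_genes
        + ["reactive"] * config.n_reactive_genes
        + ["null"] * config.n_null_genes
    )
    if not classes:
        raise ValidationError("no genes configured")
    gene_rows, snp_rows = [], []
    for i, cls in enumerate(classes):
        gene_id = f"{cls.upper()[:4]}{i + 1:04d}"
        chrom = f"chr{(i % N_CHROMS) + 1}"
        start = GENE_SPACING * (i // N_CHROMS + 1)
        end = start + GENE_BODY
        # causal/reactive genes sit comfortably above the intensity filter;
        # null baselines reach lower so some get filtered, as on a real array
        lo = 5.0 if cls == "null" else 7.0
        baseline = rng.uniform(lo, 11.0)
        cis = ""
        for j in range(config.snps_per_gene):
            pos = start + (j + 1) * GENE_BODY // (config.snps_per_gene + 1)
            snp_id = f"snp_{gene_id}_{j + 1}"
            freq = rng.uniform(*config.maf_range)
            functional = cls == "causal" and j == 0
            if functional:
                cis = snp_id
            snp_rows.append((snp_id, chrom, pos, "A", "G", freq, gene_id, functional))
        gene_rows.append((gene_id, f"{gene_id}_at", cls, chrom, start, end, baseline, cis))
    genes = pd.DataFrame(
        gene_rows,
        columns=["gene_id", "probe_id", "gene_class", "chrom", "start", "end",
                 "baseline_log2", "cis_snp"],
    )
    snps = pd.DataFrame(
        snp_rows,
        columns=["snp_id", "chrom", "pos", "ref", "alt", "freq", "gene_id", "functional"],
    )
    return SyntheticTruth(genes, snps, derive_model_params(config))


def build_truth(config: SimulationConfig) -> SyntheticTruth:
    """Public wrapper: the SNP panel and gene classes for ``config``."""
    return _build_truth(config)


def simulate_genotypes(
    config: SimulationConfig,
    n_samples: int,
    n_snps: int | None = None,
    rng: np.random.Generator | None = None,
    freqs: np.ndarray | None = None,
    snps: pd.DataFrame | None = None,
) -> GenotypeDosageMatrix:
    """Independent binomial(2, f) genotypes; f drawn uniformly from maf_range.

    Standalone use draws its own allele frequencies (and generic SNP
    metadata); internal callers pass the truth panel's ``snps``/``freqs`` so
    every dataset shares one frequency spectrum.
    """
    if rng is None:
        rng = _rng(config.seed, _STAGE_GENO)
    if snps is not None:
        freqs = snps["freq"].to_numpy(dtype=float) if freqs is None else freqs
        meta = snps[["snp_id", "chrom", "pos", "ref", "alt"]].copy()
    else:
        if n_snps is None:
            n_snps = (
                config.n_causal_genes + config.n_reactive_genes + config.n_null_genes
            ) * config.snps_per_gene or config.snps_per_gene
        if freqs is None:
            freqs = rng.uniform(*config.maf_range, size=n_snps)
        meta = pd.DataFrame(
            {
                "snp_id": [f"snp{i + 1:05d}" for i in range(n_snps)],
                "chrom": "chr1",
                "pos": np.arange(n_snps) * 1000 + 500,
                "ref": "A",
                "alt": "G",
            }
        )
    dosages = rng.binomial(2, freqs[:, None], size=(len(freqs), n_samples)).astype(float)
    return GenotypeDosageMatrix(meta, [f"S{i + 1:05d}" for i in range(n_samples)], dosages)


def _standardized_dosage(truth: SyntheticTruth, dosages: np.ndarray) -> np.ndarray:
    """(G - 2f)/sqrt(2f(1-f)) for the functional causal SNPs, given all dosages."""
    functional = truth.snps["functional"].to_numpy()
    f = truth.snps.loc[functional, "freq"].to_numpy()[:, None]
    G = dosages[functional]
    return (G - 2 * f) / np.sqrt(2 * f * (1 - f))


def _causal_expression_std(
    config: SimulationConfig, truth: SyntheticTruth, g_std: np.ndarray,
    rng: np.random.Generator, shared: np.ndarray | None = None,
) -> np.ndarray:
    """Unit-variance causal log-expression: cis-SNP + shared factor + noise."""
    s = truth.params["s_shared"]
    h2 = config.snp_h2
    n = g_std.shape[1]
    if shared is None:
        shared = rng.standard_normal(n)  # co-regulation factor, one per sample
    eps = rng.standard_normal(g_std.shape)
    return (
        math.sqrt(h2) * g_std
        + math.sqrt(s) * shared
        + math.sqrt(max(1.0 - h2 - s, 0.0)) * eps
    )


def _latent_bmi(
    config: SimulationConfig, truth: SyntheticTruth, x_std: np.ndarray | None,
    n: int, rng: np.random.Generator,
) -> np.ndarray:
    """Standard-normal ln-BMI latent: causal expression plus environment."""
    v, s = truth.params["v_frac"], truth.params["s_shared"]
    env = rng.standard_normal(n)
    if x_std is None or x_std.shape[0] == 0 or v == 0:
        return env
    nc = x_std.shape[0]
    z = x_std.sum(axis=0) / math.sqrt(nc * (1 + (nc - 1) * s))
    return math.sqrt(v) * z + math.sqrt(1.0 - v) * env


def _assemble_expression(
    config: SimulationConfig, truth: SyntheticTruth, x_std: np.ndarray,
    ln_bmi: np.ndarray, rng: np.random.Generator,
) -> np.ndarray:
    """Positive intensities for all genes given causal X and each sample's BMI."""
    p = truth.params
    n = ln_bmi.size
    classes = truth.genes["gene_class"].to_numpy()
    baseline = truth.genes["baseline_log2"].to_numpy()[:, None]
    log2 = np.tile(baseline, (1, n))
    causal_rows = np.flatnonzero(classes == "causal")
    if causal_rows.size:
        log2[causal_rows] += p["sigma_expr"] * x_std
    reactive_rows = np.flatnonzero(classes == "reactive")
    if reactive_rows.size:
        log2_bmi_dev = (ln_bmi - math.log(config.bmi_mean)) / math.log(2)
        log2[reactive_rows] += (
            p["delta_log2"] * log2_bmi_dev
            + config.noise_sd * rng.standard_normal((reactive_rows.size, n))
        )
    null_rows = np.flatnonzero(classes == "null")
    if null_rows.size:
        log2[null_rows] += config.noise_sd * rng.standard_normal((null_rows.size, n))
    return np.exp2(log2)


def simulate_unrelated(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, GenotypeDosageMatrix, SyntheticTruth]:
    """Expression, phenotypes and genotypes for the unrelated adult sample.

    Generative order: cis-SNP genotypes -> causal expression -> latent
    ln-BMI (plus environment) -> reactive expression responding to BMI.
    BMI is log-normal with mean ``bmi_mean`` and sd ``bmi_sd``; sex is
    balanced and age is drawn around 51 +- 11.6 years, neither influencing
    BMI here (the unrelated-sample analysis is an unadjusted correlation).
    """
    truth = _build_truth(config)
    rng = _rng(config.seed, _STAGE_UNRELATED)
    n = config.n_unrelated
    p = truth.params
    geno = simulate_genotypes(config, n, rng=rng, snps=truth.snps)
    sample_ids = [f"U{i + 1:04d}" for i in range(n)]
    geno = GenotypeDosageMatrix(geno.snps, sample_ids, geno.dosages)
    g_std = _standardized_dosage(truth, geno.dosages)
    x_std = _causal_expression_std(config, truth, g_std, rng)
    latent = _latent_bmi(config, truth, x_std, n, rng)
    ln_bmi = p["mu_ln"] + p["tau"] * latent
    intensities = _assemble_expression(config, truth, x_std, ln_bmi, rng)
    expr = ExpressionMatrix(truth.genes["probe_id"].tolist(), sample_ids, intensities)
    sexes = np.array(["female", "male"])[rng.permuted(np.arange(n) % 2)]
    phenotypes = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "bmi": np.exp(ln_bmi),
            "sex": sexes,
            "age": np.clip(rng.normal(51.0, 11.6, size=n), 27.0, 69.0).round(1),
            "cohort": "unrelated",
        }
    )
    return expr, phenotypes, geno, truth


def simulate_twin_pairs(
    config: SimulationConfig, truth: SyntheticTruth
) -> tuple[ExpressionMatrix, TwinPairSet, pd.DataFrame]:
    """Expression and phenotypes for BMI-discordant monozygotic pairs.

    Co-twins share one genotype vector. The lean co-twin's BMI sits near the
    population mean; the obese co-twin's is inflated by ~``discordance_pct``
    percent — an acquired, environmental difference, so causal-gene
    expression (genotype-driven plus individual noise) has expected
    intrapair log-ratio 0, while reactive genes track each twin's own BMI.
    """
    rng = _rng(config.seed, _STAGE_TWINS)
    p = truth.params
    k = config.n_pairs
    pair_geno = simulate_genotypes(config, k, rng=rng, snps=truth.snps)
    dosages = np.repeat(pair_geno.dosages, 2, axis=1)  # obese, lean per pair
    pair_ids = [f"TW{i + 1:03d}" for i in range(k)]
    obese_ids = [f"{pid}_ob" for pid in pair_ids]
    lean_ids = [f"{pid}_le" for pid in pair_ids]
    sample_ids = [sid for pair in zip(obese_ids, lean_ids) for sid in pair]

    ln_lean = math.log(config.bmi_mean) - p["tau"] ** 2 / 2 + 0.5 * p["tau"] * rng.standard_normal(k)
    ln_obese = ln_lean + p["log_discordance"] + 0.03 * rng.standard_normal(k)
    ln_bmi = np.empty(2 * k)
    ln_bmi[0::2] = ln_obese
    ln_bmi[1::2] = ln_lean

    g_std = _standardized_dosage(truth, dosages)
    # co-twins share the expression co-regulation factor (early shared
    # environment), like their genotype; only the residual noise is individual
    shared = np.repeat(rng.standard_normal(k), 2)
    x_std = _causal_expression_std(config, truth, g_std, rng, shared=shared)
    intensities = _assemble_expression(config, truth, x_std, ln_bmi, rng)
    expr = ExpressionMatrix(truth.genes["probe_id"].tolist(), sample_ids, intensities)

    sexes = rng.choice(["female", "male"], size=k)
    ages = rng.uniform(24.0, 28.0, size=k).round(1)
    phenotypes = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "bmi": np.exp(ln_bmi),
            "sex": np.repeat(sexes, 2),
            "age": np.repeat(ages, 2),
            "cohort": "twins",
        }
    )
    pairs = TwinPairSet(pair_ids, obese_ids, lean_ids)
    return expr, pairs, phenotypes


def simulate_cohort_panel(
    config: SimulationConfig, truth: SyntheticTruth
) -> list[tuple[GenotypeDosageMatrix, pd.DataFrame]]:
    """Independent genotype/phenotype panels for the meta-analysis cohorts.

    BMI depends on the causal SNPs only through the (latent) expression
    mechanism, plus cohort-specific intercepts and sex/age effects that the
    phenotype-preparation stage residualizes away. Null and reactive-gene
    SNPs carry no BMI effect.
    """
    rng = _rng(config.seed, _STAGE_COHORTS)
    p = truth.params
    panels = []
    for c in range(config.n_cohorts):
        n = config.n_per_cohort
        geno = simulate_genotypes(config, n, rng=rng, snps=truth.snps)
        sample_ids = [f"C{c + 1}S{i + 1:05d}" for i in range(n)]
        geno = GenotypeDosageMatrix(geno.snps, sample_ids, geno.dosages)
        g_std = _standardized_dosage(truth, geno.dosages)
        x_std = _causal_expression_std(config, truth, g_std, rng)
        latent = _latent_bmi(config, truth, x_std, n, rng)
        male = rng.random(n) < 0.5
        age = np.clip(rng.normal(50.0, 10.0, size=n), 25.0, 75.0).round(1)
        mu_c = p["mu_ln"] + rng.normal(0.0, 0.03)
        ln_bmi = (
            mu_c
            + config.sex_effect * male
            + config.age_effect * (age - 50.0)
            + p["tau"] * latent
        )
        phenotypes = pd.DataFrame(
            {
                "sample_id": sample_ids,
                "bmi": np.exp(ln_bmi),
                "sex": np.where(male, "male", "female"),
                "age": age,
                "cohort": f"cohort{c + 1}",
            }
        )
        panels.append((geno, phenotypes))
    return panels


def write_dataset(config: SimulationConfig, out_dir) -> dict:
    """Generate every dataset and write the TSV/BED files the pipeline reads.

    Returns a manifest dict of the written paths.
    """
    from pathlib import Path

    from . import io as cio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr_u, pheno_u, geno_u, truth = simulate_unrelated(config)
    expr_t, pairs, pheno_t = simulate_twin_pairs(config, truth)
    panels = simulate_cohort_panel(config, truth)

    paths = {
        "unrelated_expression": out / "unrelated_expression.tsv",
        "unrelated_phenotypes": out / "unrelated_phenotypes.tsv",
        "unrelated_genotypes": out / "unrelated_genotypes.tsv",
        "twin_expression": out / "twin_expression.tsv",
        "twin_pairs": out / "twin_pairs.tsv",
        "twin_phenotypes": out / "twin_phenotypes.tsv",
        "annotation": out / "genes.bed",
        "probe_gene_map": out / "probe_gene_map.tsv",
        "truth": out / "truth.tsv",
    }
    cio.write_expression_matrix(expr_u, paths["unrelated_expression"])
    cio.write_phenotypes(pheno_u, paths["unrelated_phenotypes"])
    cio.write_dosage_tsv(geno_u, paths["unrelated_genotypes"])
    cio.write_expression_matrix(expr_t, paths["twin_expression"])
    cio.write_twin_pairs(pairs, paths["twin_pairs"])
    cio.write_phenotypes(pheno_t, paths["twin_phenotypes"])
    cio.write_bed(truth.annotation(), paths["annotation"])
    truth.probe_gene_map().to_csv(paths["probe_gene_map"], sep="\t", index=False,
                                  lineterminator="\n")
    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False, lineterminator="\n")
    cohort_geno, cohort_pheno = [], []
    for i, (geno, pheno) in enumerate(panels):
        gp = out / f"cohort{i + 1}_genotypes.tsv"
        pp = out / f"cohort{i + 1}_phenotypes.tsv"
        cio.write_dosage_tsv(geno, gp)
        cio.write_phenotypes(pheno, pp)
        cohort_geno.append(gp)
        cohort_pheno.append(pp)
    paths["cohort_genotypes"] = cohort_geno
    paths["cohort_phenotypes"] = cohort_pheno
    return {k: ([str(x) for x in v] if isinstance(v, list) else str(v))
            for k, v in paths.items()}
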