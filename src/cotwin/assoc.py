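"""SNP-to-gene mapping, phenotype residualization, additive association and
inverse-variance fixed-effects meta-analysis.

The association model follows standard GWAS practice for a quantitative
trait: within each cohort, ln(BMI) is stratified by sex and adjusted for age
(plus any extra covariates) by OLS; the standardized residuals are regressed
on alt-allele dosage (additive model) per SNP; cohort estimates are combined
with fixed-effects weights 1/se^2. "Overall" statistics come from a pooled
analysis in which both sexes' standardized residuals enter one regression
per cohort.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from intervaltree import IntervalTree
from scipy import stats

from .types import (
    GenotypeDosageMatrix,
    ValidationError,
    validate_gene_annotation,
    validate_phenotype_table,
)

_TINY = np.finfo(float).tiny

STRATA = ("female", "male", "pooled")


# ---------------------------------------------------------------------------
# SNP -> gene assignment


def map_snps_to_genes(
    annotation: pd.DataFrame,
    snps: pd.DataFrame,
    gene_sets: pd.DataFrame,
    flank: int = 1000,
) -> pd.DataFrame:
    """Assign SNPs to genes whose span +- ``flank`` contains them.

    A SNP at 0-based position p is assigned to gene g iff
    p in [start - flank, end + flank), half-open on the right. A SNP may hit
    several genes; assignments carry the gene's set label from ``gene_sets``
    (columns gene_id, gene_set) and the distance to the unflanked gene span
    (0 if inside). Genes absent from ``gene_sets`` are not mapped.
    """
    annotation = validate_gene_annotation(annotation)
    set_of = dict(zip(gene_sets["gene_id"].astype(str), gene_sets["gene_set"]))
    trees: dict[str, IntervalTree] = {}
    spans: dict[str, tuple[int, int]] = {}
    for _, rec in annotation.iterrows():
        if rec["gene_id"] not in set_of:
            continue
        trees.setdefault(rec["chrom"], IntervalTree()).addi(
            rec["start"] - flank, rec["end"] + flank, rec["gene_id"]
        )
        spans[rec["gene_id"]] = (rec["start"], rec["end"])
    unmatched = sorted(set(snps["chrom"]) - set(annotation["chrom"]))
    if unmatched:
        warnings.warn(
            f"SNP chromosomes absent from annotation: {unmatched}", stacklevel=2
        )
    rows = []
    for snp_id, chrom, pos in zip(snps["snp_id"], snps["chrom"], snps["pos"]):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for iv in sorted(tree.at(int(pos))):
            gene = iv.data
            start, end = spans[gene]
            distance = max(0, start - int(pos), int(pos) - (end - 1))
            rows.append((snp_id, gene, set_of[gene], distance))
    return pd.DataFrame(rows, columns=["snp_id", "gene_id", "gene_set", "distance"])


# ---------------------------------------------------------------------------
# phenotype preparation


def prepare_phenotype(
    phenotypes: pd.DataFrame, extra_covariates: tuple = ()
) -> pd.DataFrame:
    """Sex-stratified, age-adjusted, standardized ln(BMI) residuals.

    Within each (cohort, sex) stratum, fit ln(BMI) ~ 1 + age [+ extras] by
    OLS and standardize the residuals to mean 0, sd 1 (denominator n-1).
    Strata with fewer samples than parameters are skipped with a warning.

    Returns a DataFrame with sample_id, cohort, stratum, residual.
    """
    phenotypes = validate_phenotype_table(phenotypes)
    for cov in extra_covariates:
        if cov not in phenotypes.columns:
            raise ValidationError(f"extra covariate {cov!r} absent from phenotype table")
    pieces = []
    n_params = 2 + len(extra_covariates)
    for (cohort, sex), grp in phenotypes.groupby(["cohort", "sex"], sort=False):
        if len(grp) <= n_params:
            warnings.warn(
                f"stratum ({cohort}, {sex}) has {len(grp)} samples <= {n_params} "
                "parameters; skipped",
                stacklevel=2,
            )
            continue
        y = np.log(grp["bmi"].to_numpy(dtype=float))
        X = sm.add_constant(
            grp[["age", *extra_covariates]].to_numpy(dtype=float), has_constant="add"
        )
        resid = sm.OLS(y, X).fit().resid
        sd = resid.std(ddof=1)
        if sd == 0:
            warnings.warn(
                f"stratum ({cohort}, {sex}) has zero residual variance; skipped",
                stacklevel=2,
            )
            continue
        pieces.append(
            pd.DataFrame(
                {
                    "sample_id": grp["sample_id"].to_numpy(),
                    "cohort": cohort,
                    "stratum": sex,
                    "residual": (resid - resid.mean()) / sd,
                }
            )
        )
    if not pieces:
        raise ValidationError("no stratum had enough samples to residualize")
    return pd.concat(pieces, ignore_index=True)


# ---------------------------------------------------------------------------
# per-SNP additive regression


def associate(
    genotypes: GenotypeDosageMatrix,
    residuals: pd.DataFrame,
    stratum: str = "pooled",
    maf_floor: float = 0.01,
) -> pd.DataFrame:
    """OLS of standardized residual on dosage with intercept, per SNP.

    ``stratum`` selects ``female``/``male`` rows of ``residuals`` or pools
    both sexes. Regressions run per cohort. Individuals with a missing
    dosage are dropped per SNP (so N varies by SNP). Two-sided P from the t
    distribution on n - 2 df. SNPs that are monomorphic in the analyzed
    samples, below the MAF floor, or left with < 3 samples are flagged and
    carry no estimate.
    """
    if stratum not in STRATA:
        raise ValidationError(f"stratum must be one of {STRATA}, got {stratum!r}")
    sel = residuals if stratum == "pooled" else residuals[residuals["stratum"] == stratum]
    if sel.empty:
        raise ValidationError(f"no residuals available for stratum {stratum!r}")
    out = []
    geno_samples = set(genotypes.sample_ids)
    for cohort, grp in sel.groupby("cohort", sort=False):
        ids = [s for s in grp["sample_id"] if s in geno_samples]
        if len(ids) < 3:
            raise ValidationError(
                f"cohort {cohort!r}: fewer than 3 samples overlap the genotypes"
            )
        y = grp.set_index("sample_id").loc[ids, "residual"].to_numpy(dtype=float)
        X = genotypes.sample_dosages(ids)
        res = _regress_block(X, y)
        res.insert(0, "snp_id", genotypes.snps["snp_id"].to_numpy())
        res.insert(1, "cohort", cohort)
        res.insert(2, "stratum", stratum)
        maf = res["maf"].to_numpy()
        low = (~np.isnan(maf)) & (np.minimum(maf, 1 - maf) < maf_floor)
        res.loc[low & (res["flag"] == ""), "flag"] = "low_maf"
        res.loc[res["flag"] != "", ["beta", "se", "t", "p"]] = np.nan
        out.append(res)
    return pd.concat(out, ignore_index=True)


def _regress_block(X: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Vectorized simple OLS of y on each row of X, NaN-aware."""
    mask = ~np.isnan(X)
    n = mask.sum(axis=1).astype(float)
    Xz = np.where(mask, X, 0.0)
    sx = Xz.sum(axis=1)
    sy = mask @ y
    sxx = (Xz**2).sum(axis=1)
    sxy = Xz @ y
    syy = mask @ (y**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        ssx = sxx - sx**2 / n
        ssy = syy - sy**2 / n
        sxy_c = sxy - sx * sy / n
        beta = sxy_c / ssx
        alpha_resid = ssy - beta * sxy_c  # residual sum of squares
        sigma2 = alpha_resid / (n - 2)
        se = np.sqrt(sigma2 / ssx)
        t = beta / se
        maf = sx / (2 * n)
    p = np.full_like(beta, np.nan)
    ok = np.isfinite(t)
    p[ok] = np.clip(2.0 * stats.t.sf(np.abs(t[ok]), df=n[ok] - 2), _TINY, 1.0)
    p[np.isinf(t)] = _TINY  # zero residual variance: perfectly linear signal
    flag = np.where(n < 3, "insufficient_n", np.where(ssx <= 1e-12, "monomorphic", ""))
    return pd.DataFrame(
        {"beta": beta, "se": se, "t": t, "p": p, "n": n.astype(int), "maf": maf,
         "flag": flag}
    )


# ---------------------------------------------------------------------------
# fixed-effects meta-analysis


def _meta_group(beta: np.ndarray, se: np.ndarray):
    w = 1.0 / se**2
    beta_meta = float((w * beta).sum() / w.sum())
    se_meta = float(1.0 / np.sqrt(w.sum()))
    z = beta_meta / se_meta
    p = float(np.clip(2.0 * stats.norm.sf(abs(z)), _TINY, 1.0))
    return beta_meta, se_meta, z, p


def meta_fixed_effects(records: pd.DataFrame) -> pd.DataFrame:
    """Combine per-cohort association records across cohorts per SNP.

    ``records`` holds rows from :func:`associate`, possibly for several
    strata. Within each (snp_id, stratum) the estimates are combined with
    weights 1/se^2; the combined z gets a two-sided normal P. Output is one
    row per SNP with the pooled-stratum estimate (beta_meta, se_meta, z,
    p_overall, n) plus p_women/p_men where those strata are present. When no
    pooled records exist the single available stratum fills the estimate
    columns.
    """
    usable = records[(records["flag"] == "") & (records["se"] > 0)]
    if usable.empty:
        raise ValidationError("no usable association records to meta-analyze")
    long = []
    for (snp, stratum), grp in usable.groupby(["snp_id", "stratum"], sort=False):
        beta_meta, se_meta, z, p = _meta_group(
            grp["beta"].to_numpy(), grp["se"].to_numpy()
        )
        long.append((snp, stratum, beta_meta, se_meta, z, p, int(grp["n"].sum()),
                     len(grp)))
    long = pd.DataFrame(
        long,
        columns=["snp_id", "stratum", "beta_meta", "se_meta", "z", "p", "n", "k_cohorts"],
    )
    rows = []
    stratum_p = {"pooled": "p_overall", "female": "p_women", "male": "p_men"}
    for snp, grp in long.groupby("snp_id", sort=False):
        by = grp.set_index("stratum")
        primary = next((s for s in ("pooled", "female", "male") if s in by.index), None)
        rec = {
            "snp_id": snp,
            "beta_meta": by.loc[primary, "beta_meta"],
            "se_meta": by.loc[primary, "se_meta"],
            "z": by.loc[primary, "z"],
            "n": int(by.loc[primary, "n"]),
            "p_overall": np.nan,
            "p_women": np.nan,
            "p_men": np.nan,
        }
        for stratum, col in stratum_p.items():
            if stratum in by.index:
                rec[col] = by.loc[stratum, "p"]
        rows.append(rec)
    return pd.DataFrame(rows)
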