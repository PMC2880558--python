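"""SNP-gene mapping, residualization, additive regression and meta-analysis."""

import numpy as np
import pandas as pd
import pytest

import oracles
from cotwin.assoc import (
    associate,
    map_snps_to_genes,
    meta_fixed_effects,
    prepare_phenotype,
)
from cotwin.types import GenotypeDosageMatrix, ValidationError


def _annotation(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def _snps(rows):
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "ref", "alt"])


GENE_SETS = pd.DataFrame({"gene_id": ["G"], "gene_set": ["causative"]})


class TestMapSnpsToGenes:
    def test_flank_boundary_inclusive_left(self):
        ann = _annotation([("G", "chr1", 1000, 2000, "+")])
        snps = _snps([("rs1", "chr1", 999, "A", "G")])
        out = map_snps_to_genes(ann, snps, GENE_SETS, flank=1000)
        assert len(out) == 1
        assert out.iloc[0]["distance"] == 1

    def test_half_open_right_edge_excluded(self):
        ann = _annotation([("G", "chr1", 1000, 2000, "+")])
        snps = _snps([("rs1", "chr1", 3000, "A", "G")])
        assert map_snps_to_genes(ann, snps, GENE_SETS, flank=1000).empty

    def test_matches_brute_force_interval_scan(self, rng):
        genes = _annotation(
            [
                (f"g{i}", f"chr{rng.integers(1, 4)}", s := int(rng.integers(0, 900_000)),
                 s + int(rng.integers(100, 50_000)), "+")
                for i in range(100)
            ]
        )
        gene_sets = pd.DataFrame({"gene_id": genes["gene_id"], "gene_set": "causative"})
        snps = _snps(
            [
                (f"rs{j}", f"chr{rng.integers(1, 4)}", int(rng.integers(0, 1_000_000)),
                 "A", "G")
                for j in range(10_000)
            ]
        )
        out = map_snps_to_genes(genes, snps, gene_sets, flank=1000)
        got = set(zip(out["snp_id"], out["gene_id"]))
        expected = set()
        for _, s in snps.iterrows():
            for _, g in genes.iterrows():
                if s["chrom"] == g["chrom"] and g["start"] - 1000 <= s["pos"] < g["end"] + 1000:
                    expected.add((s["snp_id"], g["gene_id"]))
        assert got == expected

    def test_unmatched_chromosome_warns(self):
        ann = _annotation([("G", "chr1", 0, 100, "+")])
        snps = _snps([("rs1", "chrX", 50, "A", "G")])
        with pytest.warns(UserWarning, match="chrX"):
            map_snps_to_genes(ann, snps, GENE_SETS)


class TestPreparePhenotype:
    def _pheno(self, n, rng, cohort="c1"):
        return pd.DataFrame(
            {
                "sample_id": [f"{cohort}s{i}" for i in range(n)],
                "bmi": rng.uniform(20, 35, size=n),
                "sex": rng.choice(["female", "male"], size=n),
                "age": rng.uniform(25, 70, size=n),
                "cohort": cohort,
            }
        )

    def test_residual_moments(self, rng):
        resid = prepare_phenotype(self._pheno(200, rng))
        for (_, _), grp in resid.groupby(["cohort", "stratum"]):
            assert abs(grp["residual"].mean()) < 1e-10
            assert grp["residual"].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        pheno = self._pheno(6, rng)
        pheno["sex"] = "female"  # one stratum, six samples
        resid = prepare_phenotype(pheno).set_index("sample_id")["residual"]
        raw = oracles.multi_ols_residuals(np.log(pheno["bmi"]), [pheno["age"]])
        expected = (raw - raw.mean()) / raw.std(ddof=1)
        for sid, want in zip(pheno["sample_id"], expected):
            assert resid[sid] == pytest.approx(want, abs=1e-10)

    def test_null_covariate_recovers_z_scores(self, rng):
        """With no age effect the residuals equal direct ln(BMI) z-scores."""
        pheno = self._pheno(100, rng)
        pheno["age"] = np.linspace(30, 60, 100)  # independent of BMI by construction
        resid = prepare_phenotype(pheno)
        merged = resid.merge(pheno, on="sample_id")
        for _, grp in merged.groupby("stratum"):
            z = (np.log(grp["bmi"]) - np.log(grp["bmi"]).mean())
            z /= z.std(ddof=1)
            corr = np.corrcoef(z, grp["residual"])[0, 1]
            assert corr > 0.99

    def test_small_stratum_skipped_with_warning(self, rng):
        pheno = self._pheno(40, rng)
        pheno.loc[pheno.index[:2], "sex"] = "male"
        pheno.loc[pheno.index[2:], "sex"] = "female"
        with pytest.warns(UserWarning, match="male"):
            resid = prepare_phenotype(pheno)
        assert set(resid["stratum"]) == {"female"}

    def test_extra_covariate_regressed_out(self, rng):
        pheno = self._pheno(150, rng)
        pheno["mets"] = rng.integers(0, 2, size=150).astype(float)
        pheno["bmi"] = pheno["bmi"] * np.exp(0.2 * pheno["mets"])
        resid = prepare_phenotype(pheno, ("mets",)).merge(pheno, on="sample_id")
        for _, grp in resid.groupby("stratum"):
            r = np.corrcoef(grp["mets"], grp["residual"])[0, 1]
            assert abs(r) < 1e-8


def _geno_from_vector(x, ids=None):
    x = np.asarray(x, dtype=float)[None, :]
    ids = ids or [f"s{i}" for i in range(x.shape[1])]
    snps = _snps([("rs1", "chr1", 100, "A", "G")])
    return GenotypeDosageMatrix(snps, ids, x)


def _residuals(y, ids=None, stratum="female", cohort="c1"):
    ids = ids or [f"s{i}" for i in range(len(y))]
    return pd.DataFrame(
        {"sample_id": ids, "cohort": cohort, "stratum": stratum, "residual": y}
    )


class TestAssociate:
    def test_monomorphic_flagged(self):
        geno = _geno_from_vector([1.0] * 10)
        out = associate(geno, _residuals(np.random.default_rng(0).normal(size=10)))
        assert out.iloc[0]["flag"] == "monomorphic"
        assert np.isnan(out.iloc[0]["beta"])

    def test_exact_linear_signal(self):
        rng = np.random.default_rng(1)
        x = rng.binomial(2, 0.4, size=50).astype(float)
        out = associate(_geno_from_vector(x), _residuals(0.5 * x), maf_floor=0.0)
        row = out.iloc[0]
        assert row["beta"] == pytest.approx(0.5, abs=1e-12)
        assert row["p"] <= 1e-200

    def test_matches_ols_oracle(self, rng):
        for _ in range(100):
            x = rng.binomial(2, rng.uniform(0.1, 0.5), size=30).astype(float)
            if np.ptp(x) == 0:
                continue
            y = rng.normal(size=30) + 0.2 * x
            out = associate(_geno_from_vector(x), _residuals(y), maf_floor=0.0).iloc[0]
            beta, se, p = oracles.simple_ols(x, y)
            assert out["beta"] == pytest.approx(beta, abs=1e-10)
            assert out["se"] == pytest.approx(se, abs=1e-10)
            assert out["p"] == pytest.approx(p, abs=1e-10)

    def test_missing_dosages_dropped_per_snp(self, rng):
        x = rng.binomial(2, 0.5, size=20).astype(float)
        x[:5] = np.nan
        y = rng.normal(size=20)
        out = associate(_geno_from_vector(x), _residuals(y), maf_floor=0.0).iloc[0]
        beta, se, p = oracles.simple_ols(x[5:], y[5:])
        assert out["n"] == 15
        assert out["beta"] == pytest.approx(beta, abs=1e-10)

    def test_maf_floor_flags(self):
        x = np.zeros(200)
        x[0] = 1.0  # maf 1/400
        out = associate(_geno_from_vector(x), _residuals(np.arange(200.0)))
        assert out.iloc[0]["flag"] == "low_maf"


class TestMetaFixedEffects:
    def _records(self, betas, ses, stratum="pooled"):
        return pd.DataFrame(
            {
                "snp_id": "rs1",
                "cohort": [f"c{i}" for i in range(len(betas))],
                "stratum": stratum,
                "beta": betas,
                "se": ses,
                "t": np.asarray(betas) / np.asarray(ses),
                "p": 0.5,
                "n": 100,
                "maf": 0.3,
                "flag": "",
            }
        )

    def test_single_cohort_identity(self):
        out = meta_fixed_effects(self._records([0.21], [0.07])).iloc[0]
        assert out["beta_meta"] == pytest.approx(0.21)
        assert out["se_meta"] == pytest.approx(0.07)

    def test_two_equal_cohorts_symmetry(self):
        out = meta_fixed_effects(self._records([0.2, 0.2], [0.1, 0.1])).iloc[0]
        assert out["beta_meta"] == pytest.approx(0.2)
        assert out["se_meta"] == pytest.approx(0.1 / np.sqrt(2))

    def test_closed_form_weighted_mean(self):
        out = meta_fixed_effects(self._records([0.1, 0.3], [0.1, 0.2])).iloc[0]
        assert out["beta_meta"] == pytest.approx(0.14, abs=1e-12)
        assert out["se_meta"] == pytest.approx(np.sqrt(1 / 125), abs=1e-12)
        assert out["p_overall"] == pytest.approx(0.11752, abs=1e-4)

    def test_matches_meta_oracle(self, rng):
        for _ in range(100):
            k = int(rng.integers(2, 8))
            betas = rng.normal(0, 0.2, size=k)
            ses = rng.uniform(0.02, 0.3, size=k)
            out = meta_fixed_effects(self._records(betas, ses)).iloc[0]
            beta, se, z, p = oracles.fixed_effects_meta(betas, ses)
            assert out["beta_meta"] == pytest.approx(beta, abs=1e-10)
            assert out["se_meta"] == pytest.approx(se, abs=1e-10)
            assert out["p_overall"] == pytest.approx(p, abs=1e-10)

    def test_replicated_cohorts_shrink_se_by_sqrt_k(self):
        for k in (2, 4, 9):
            out = meta_fixed_effects(self._records([0.15] * k, [0.06] * k)).iloc[0]
            assert out["se_meta"] == pytest.approx(0.06 / np.sqrt(k), abs=1e-12)

    def test_se_meta_never_exceeds_min_cohort_se(self, rng):
        ses = rng.uniform(0.05, 0.5, size=5)
        out = meta_fixed_effects(self._records(rng.normal(size=5), ses)).iloc[0]
        assert out["se_meta"] <= ses.min()

    def test_sex_strata_fill_their_columns(self):
        records = pd.concat(
            [
                self._records([0.2, 0.1], [0.1, 0.1], stratum="female"),
                self._records([0.0, 0.05], [0.1, 0.1], stratum="male"),
                self._records([0.1, 0.08], [0.07, 0.07], stratum="pooled"),
            ]
        )
        out = meta_fixed_effects(records).iloc[0]
        assert not np.isnan(out["p_women"]) and not np.isnan(out["p_men"])
        bw, sw, _, pw = oracles.fixed_effects_meta([0.2, 0.1], [0.1, 0.1])
        assert out["p_women"] == pytest.approx(pw, abs=1e-12)

    def test_no_usable_records_raises(self):
        rec = self._records([0.1], [0.1])
        rec["flag"] = "monomorphic"
        with pytest.raises(ValidationError, match="no usable"):
            meta_fixed_effects(rec)


def test_single_cohort_association_equals_its_own_meta(rng):
    """Meta-analysis of one cohort reproduces the per-cohort estimates."""
    x = rng.binomial(2, 0.3, size=80).astype(float)
    y = rng.normal(size=80) + 0.1 * x
    rec = associate(_geno_from_vector(x), _residuals(y, stratum="pooled"), "pooled",
                    maf_floor=0.0)
    out = meta_fixed_effects(rec).iloc[0]
    assert out["beta_meta"] == pytest.approx(rec.iloc[0]["beta"], abs=1e-12)
    assert out["se_meta"] == pytest.approx(rec.iloc[0]["se"], abs=1e-12)
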