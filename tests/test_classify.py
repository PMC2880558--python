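"""Intrapair testing, BMI correlation and the causative/reactive set logic."""

import numpy as np
import pandas as pd
import pytest

import oracles
from cotwin.classify import (
    classify,
    collapse_probes_to_genes,
    correlate_with_bmi,
    test_intrapair_difference as intrapair_difference,
)
from cotwin.types import ExpressionMatrix, PairRatioMatrix, TwinPairSet, ValidationError


def _ratios(values, probes=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    return PairRatioMatrix(probes, [f"P{j}" for j in range(values.shape[1])], values)


class TestIntrapairDifference:
    def test_null_pair_set(self):
        out = intrapair_difference(_ratios([[1.0] * 5]))
        row = out.iloc[0]
        assert row["t_statistic"] == 0.0
        assert row["p_value"] == 1.0
        assert row["median_fold_change"] == 1.0

    def test_degenerate_variance_nonzero_mean(self):
        with pytest.raises(ValidationError, match="zero variance"):
            intrapair_difference(_ratios([[2.0, 2.0, 2.0, 2.0]]))

    def test_matches_independent_t_oracle(self, rng):
        """13-pair ratios vs a textbook t CDF coded through betainc."""
        for _ in range(100):
            ratios = rng.lognormal(mean=0.3, sigma=0.4, size=(1, 13))
            out = intrapair_difference(_ratios(ratios)).iloc[0]
            t, p = oracles.one_sample_t(np.log2(ratios[0]))
            assert out["t_statistic"] == pytest.approx(t, abs=1e-10)
            assert out["p_value"] == pytest.approx(p, abs=1e-10)

    def test_welch_mode_matches_oracle(self, rng):
        obese = rng.uniform(50, 500, size=(3, 13))
        lean = rng.uniform(50, 500, size=(3, 13))
        m = ExpressionMatrix(
            ["a", "b", "c"],
            [f"ob{i}" for i in range(13)] + [f"le{i}" for i in range(13)],
            np.hstack([obese, lean]),
        )
        pairs = TwinPairSet(
            [f"P{i}" for i in range(13)],
            [f"ob{i}" for i in range(13)],
            [f"le{i}" for i in range(13)],
        )
        ratios = PairRatioMatrix(["a", "b", "c"], pairs.pair_ids, obese / lean)
        out = intrapair_difference(
            ratios, "welch_two_sample", matrix=m, pairs=pairs
        )
        for i in range(3):
            t, p = oracles.welch_t(obese[i], lean[i])
            assert out["t_statistic"].iloc[i] == pytest.approx(t, abs=1e-10)
            assert out["p_value"].iloc[i] == pytest.approx(p, abs=1e-10)


class TestCorrelateWithBmi:
    def _pheno(self, bmi, ids=None):
        ids = ids or [f"s{i}" for i in range(len(bmi))]
        return pd.DataFrame(
            {"sample_id": ids, "bmi": bmi, "sex": "female", "age": 40.0, "cohort": "x"}
        )

    def test_perfect_linearity(self):
        x = np.arange(1.0, 11.0)
        m = ExpressionMatrix(["p"], [f"s{i}" for i in range(10)], 2 * x[None, :])
        out = correlate_with_bmi(m, self._pheno(x)).iloc[0]
        assert out["pearson_r"] == pytest.approx(1.0)
        assert 0 < out["p_value"] <= 1e-300  # underflow clamps to smallest positive

    def test_t_transform_reference_value(self):
        """r=0.41 at n=77 corresponds to a two-sided P near 2.1e-4."""
        from scipy import stats

        r, n = 0.41, 77
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
        p = 2 * stats.t.sf(t, n - 2)
        assert p == pytest.approx(2.1e-4, rel=0.05)

    def test_matches_pearson_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 40))
            x = rng.normal(size=n)
            y = rng.normal(size=n) + 0.3 * x
            m = ExpressionMatrix(["p"], [f"s{i}" for i in range(n)],
                                 np.abs(x[None, :]) + 5.0)
            out = correlate_with_bmi(m, self._pheno(np.abs(y) + 15.0)).iloc[0]
            r, p = oracles.pearson(np.abs(x) + 5.0, np.abs(y) + 15.0)
            assert out["pearson_r"] == pytest.approx(r, abs=1e-10)
            assert out["p_value"] == pytest.approx(p, abs=1e-10)

    def test_permutation_oracle_agrees_with_t_transform(self, rng):
        n, b = 20, 100_000
        x = rng.normal(size=n)
        y = rng.normal(size=n) + 0.5 * x
        m = ExpressionMatrix(["p"], [f"s{i}" for i in range(n)], np.abs(x[None, :]) + 5)
        p_t = correlate_with_bmi(m, self._pheno(np.abs(y) + 15)).iloc[0]["p_value"]
        xa = np.abs(x) + 5
        ya = np.abs(y) + 15
        r_obs = abs(np.corrcoef(xa, ya)[0, 1])
        perms = np.array([np.corrcoef(xa, rng.permutation(ya))[0, 1] for _ in range(b)])
        p_perm = (np.sum(np.abs(perms) >= r_obs) + 1) / (b + 1)
        # Monte-Carlo error ~ 3 sd of a binomial proportion
        assert abs(p_perm - p_t) < 3 * np.sqrt(p_t * (1 - p_t) / b) + 1e-4

    def test_constant_probe_raises(self):
        m = ExpressionMatrix(["p"], ["a", "b", "c"], np.full((1, 3), 7.0))
        with pytest.raises(ValidationError, match="constant"):
            correlate_with_bmi(m, self._pheno([20.0, 25.0, 30.0], ["a", "b", "c"]))


class TestClassify:
    def _lists(self, p_twin, p_corr):
        probes = [f"p{i}" for i in range(len(p_twin))]
        d = pd.DataFrame({"probe_id": probes, "p_value": p_twin})
        c = pd.DataFrame({"probe_id": probes, "p_value": p_corr})
        return d, c

    def test_published_set_arithmetic(self):
        """84 BMI-correlated probes of which 56 reactive leave 28 causative."""
        n = 17026
        p_corr = np.ones(n)
        p_corr[:84] = 1e-6
        p_twin = np.ones(n)
        p_twin[:56] = 1e-3  # the shared 2/3
        d, c = self._lists(p_twin, p_corr)
        labels = classify(d, c)
        counts = labels["label"].value_counts()
        assert counts["causative"] == 28
        assert counts["correlated_and_reactive"] == 56

    def test_empty_reactive_set(self):
        d, c = self._lists([0.9, 0.8], [1e-6, 0.5])
        labels = classify(d, c)
        assert labels["label"].tolist() == ["causative", "unclassified"]

    def test_matches_brute_force_set_logic(self, rng):
        p_twin = rng.uniform(size=300)
        p_corr = 10.0 ** rng.uniform(-6, 0, size=300)
        d, c = self._lists(p_twin, p_corr)
        labels = classify(d, c).set_index("probe_id")["label"]
        for i in range(300):
            in_r, in_c = p_twin[i] < 0.05, p_corr[i] < 1e-4
            expected = (
                "causative" if in_c and not in_r
                else "correlated_and_reactive" if in_c and in_r
                else "reactive" if in_r
                else "unclassified"
            )
            assert labels[f"p{i}"] == expected

    def test_partition_property(self, rng):
        d, c = self._lists(rng.uniform(size=100), rng.uniform(size=100))
        labels = classify(d, c)
        assert len(labels) == 100
        assert set(labels["label"]) <= {
            "causative", "correlated_and_reactive", "reactive", "unclassified"
        }

    def test_lowering_alpha_corr_never_grows_causative(self, rng):
        d, c = self._lists(rng.uniform(size=500), 10.0 ** rng.uniform(-8, 0, size=500))
        sizes = []
        for alpha in (1e-2, 1e-4, 1e-6):
            labels = classify(d, c, alpha_corr=alpha)
            sizes.append((labels["label"] == "causative").sum())
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_mismatched_universe_raises(self):
        d, _ = self._lists([0.5], [0.5])
        _, c = self._lists([0.5, 0.6], [0.5, 0.6])
        with pytest.raises(ValidationError, match="universes differ"):
            classify(d, c)


class TestCollapseProbesToGenes:
    def test_fixture_probes_collapse_to_27_genes(self):
        from cotwin.io import load_fixture_tables

        t1 = load_fixture_tables().table1
        classification = pd.DataFrame(
            {"probe_id": t1["probe_id"], "label": "causative"}
        )
        pmap = pd.DataFrame({"probe_id": t1["probe_id"], "gene_id": t1["gene_symbol"]})
        genes = collapse_probes_to_genes(classification, pmap)
        assert len(genes) == 27
        assert (genes["label"] == "causative").all()

    def test_any_probe_causative_rule(self):
        classification = pd.DataFrame(
            {"probe_id": ["a", "b"], "label": ["causative", "unclassified"]}
        )
        genes = collapse_probes_to_genes(classification, {"a": "G1", "b": "G1"})
        assert genes["label"].tolist() == ["causative"]

    def test_bijection_preserves_count(self):
        classification = pd.DataFrame(
            {"probe_id": [f"p{i}" for i in range(10)], "label": "unclassified"}
        )
        pmap = {f"p{i}": f"g{i}" for i in range(10)}
        assert len(collapse_probes_to_genes(classification, pmap)) == 10
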