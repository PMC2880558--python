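"""Q-Q coordinates and chi-square uniformity testing for P-value sets.

A gene set enriched for true association shows an excess of small P-values:
its ordered observed P's fall below the uniform order-statistic expectation
(the y = x line of a Q-Q plot), and a Pearson chi-square test of the P-values
categorized into equal-width bins rejects uniformity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import ValidationError


@dataclass
class QqSeries:
    """Ordered observed P-values paired with uniform expectations (i - 0.5)/n."""

    label: str
    expected: np.ndarray
    observed: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"set": self.label, "expected_p": self.expected, "observed_p": self.observed}
        )


@dataclass
class UniformityTestResult:
    """Pearson chi-square test of binned P-values against the uniform."""

    label: str
    n: int
    n_bins: int
    observed_counts: np.ndarray
    expected_count: float
    chi2_statistic: float
    df: int
    p_value: float


def _check_pvalues(pvalues) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValidationError("empty P-value list")
    if not np.all((p > 0) & (p <= 1)):
        raise ValidationError("P-values must lie in (0, 1]")
    return p


def qq_series(pvalues, label: str = "") -> QqSeries:
    """Pair the i-th ascending observed P with expected (i - 0.5)/n."""
    p = np.sort(_check_pvalues(pvalues))
    n = p.size
    expected = (np.arange(1, n + 1) - 0.5) / n
    return QqSeries(label, expected, p)


def chisq_uniformity(pvalues, n_bins: int = 20, label: str = "") -> UniformityTestResult:
    """Pearson X^2 of P-values binned into equal-width bins on [0, 1].

    X^2 = sum_b (O_b - n/n_bins)^2 / (n/n_bins), upper-tail P from chi-square
    with n_bins - 1 df. If n < 5 * n_bins the bin count is reduced so every
    expected count is >= 5. Fewer than 10 P-values is an error (the test is
    meaningless there).
    """
    p = _check_pvalues(pvalues)
    n = p.size
    if n < 10:
        raise ValidationError(f"need >= 10 P-values for the uniformity test, have {n}")
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    bins = min(int(n_bins), n // 5)
    counts, _ = np.histogram(p, bins=bins, range=(0.0, 1.0))
    chi2, pval = stats.chisquare(counts)
    return UniformityTestResult(
        label=label,
        n=n,
        n_bins=bins,
        observed_counts=counts,
        expected_count=n / bins,
        chi2_statistic=float(chi2),
        df=bins - 1,
        p_value=float(pval),
    )


def best_snp_per_gene(meta: pd.DataFrame, assignments: pd.DataFrame) -> pd.DataFrame:
    """Keep, per gene, the record with the smallest overall P.

    Ties break by lexicographic SNP id. A SNP assigned to two genes may
    represent both, so the output has one row per gene (column ``gene_id``
    prepended to the meta record's columns).
    """
    meta = meta.drop(columns=[c for c in ("gene_id", "gene_set") if c in meta.columns])
    merged = assignments[["snp_id", "gene_id"]].merge(meta, on="snp_id", how="inner")
    if merged.empty:
        raise ValidationError("no overlap between meta records and assignments")
    merged = merged.sort_values(["p_overall", "snp_id"], kind="mergesort")
    best = merged.groupby("gene_id", sort=False).head(1)
    return best.reset_index(drop=True)


def count_nominal_hits(
    meta: pd.DataFrame, assignments: pd.DataFrame, alpha: float = 0.05
) -> tuple[int, int]:
    """Count SNPs with overall P < alpha and the unique genes they map to."""
    hits = meta[meta["p_overall"] < alpha]
    n_snps = hits["snp_id"].nunique()
    genes = assignments.loc[
        assignments["snp_id"].isin(hits["snp_id"]), "gene_id"
    ].nunique()
    return int(n_snps), int(genes)
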