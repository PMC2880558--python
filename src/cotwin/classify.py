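"""Reactive vs putatively causative transcript classification.

The design: a transcript whose adipose expression differs within
BMI-discordant monozygotic pairs is *reactive* to obesity (the co-twins share
DNA, sex, age and upbringing, so intrapair differences are acquired). A
transcript whose expression correlates with BMI across unrelated individuals
but shows *no* intrapair difference is a candidate for sitting upstream of
obesity — *putatively causative*. Classification is plain set logic over two
nominal thresholds: a liberal one for the twin test (so borderline reactive
transcripts are not mistaken for causative) and a stringent one for the
population correlation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    CLASS_LABELS,
    ExpressionMatrix,
    PairRatioMatrix,
    TwinPairSet,
    ValidationError,
)

_TINY = np.finfo(float).tiny

INTRAPAIR_MODES = ("log_ratio_one_sample", "welch_two_sample")


def test_intrapair_difference(
    ratios: PairRatioMatrix,
    mode: str = "log_ratio_one_sample",
    *,
    matrix: ExpressionMatrix | None = None,
    pairs: TwinPairSet | None = None,
) -> pd.DataFrame:
    """Per-probe test of obese vs lean co-twin expression.

    Default mode: two-sided one-sample t of the mean log2 co-twin ratio
    against 0 on n_pairs - 1 df — the coherent test on one-ratio-per-pair
    data. ``welch_two_sample`` instead compares raw obese-twin vs lean-twin
    intensities with Welch-Satterthwaite df (unpaired, for sensitivity
    analysis) and requires ``matrix`` and ``pairs``.

    Returns a DataFrame with probe_id, median_fold_change (linear obese/lean
    scale), t_statistic and p_value.
    """
    if mode not in INTRAPAIR_MODES:
        raise ValidationError(f"mode must be one of {INTRAPAIR_MODES}, got {mode!r}")
    if ratios.n_pairs < 2:
        raise ValidationError("need at least 2 twin pairs")
    median_fc = np.median(ratios.ratios, axis=1)

    if mode == "log_ratio_one_sample":
        logr = np.log2(ratios.ratios)
        n = ratios.n_pairs
        mean = logr.mean(axis=1)
        sd = logr.std(axis=1, ddof=1)
        zero_var = sd == 0
        degenerate = zero_var & (mean != 0)
        if degenerate.any():
            probe = ratios.probe_ids[int(np.argmax(degenerate))]
            raise ValidationError(
                f"probe {probe!r}: zero variance of log-ratios with nonzero mean; "
                "t statistic undefined"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(zero_var, 0.0, mean / (sd / np.sqrt(n)))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    else:
        if matrix is None or pairs is None:
            raise ValidationError("welch_two_sample mode needs matrix= and pairs=")
        obese = matrix.sample_values(pairs.obese_ids)
        lean = matrix.sample_values(pairs.lean_ids)
        # align to the ratio matrix's probe universe
        index = {pid: i for i, pid in enumerate(matrix.probe_ids)}
        rows = [index[pid] for pid in ratios.probe_ids]
        t, p = stats.ttest_ind(obese[rows], lean[rows], axis=1, equal_var=False)

    p = np.clip(p, _TINY, 1.0)
    return pd.DataFrame(
        {
            "probe_id": ratios.probe_ids,
            "median_fold_change": median_fc,
            "t_statistic": t,
            "p_value": p,
        }
    )


def correlate_with_bmi(
    matrix: ExpressionMatrix, phenotypes: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of each probe's intensity with BMI.

    P-values come from the exact null transform t = r sqrt(n-2)/sqrt(1-r^2)
    on n - 2 df, two-sided. Samples are the overlap between the matrix and
    the phenotype table (>= 3 required). Constant expression or constant BMI
    makes the correlation undefined and raises.
    """
    pheno = phenotypes.set_index("sample_id")["bmi"]
    shared = [s for s in matrix.sample_ids if s in pheno.index]
    n = len(shared)
    if n < 3:
        raise ValidationError(f"need >= 3 overlapping samples, have {n}")
    x = matrix.sample_values(shared)
    y = pheno.loc[shared].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValidationError("BMI is constant across samples; correlation undefined")
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    constant = sx == 0
    if constant.any():
        probe = matrix.probe_ids[int(np.argmax(constant))]
        raise ValidationError(f"probe {probe!r} has constant expression; correlation undefined")
    r = np.clip(xc @ yc / (sx * np.sqrt((yc**2).sum())), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = np.where(np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    p = np.clip(p, _TINY, 1.0)
    return pd.DataFrame(
        {"probe_id": matrix.probe_ids, "pearson_r": r, "p_value": p, "n": n}
    )


def classify(
    differential: pd.DataFrame,
    correlation: pd.DataFrame,
    alpha_reactive: float = 0.05,
    alpha_corr: float = 1e-4,
) -> pd.DataFrame:
    """Partition the probe universe by set logic over the two tests.

    R = {twin P < alpha_reactive}, C = {correlation P < alpha_corr}:

    * ``causative``                = C \\ R
    * ``correlated_and_reactive``  = C & R
    * ``reactive``                 = R \\ C
    * ``unclassified``             = everything else

    Both inputs must cover the identical (post-filter) probe universe.
    """
    dset = differential.set_index("probe_id")["p_value"]
    cset = correlation.set_index("probe_id")["p_value"]
    if set(dset.index) != set(cset.index):
        only_d = set(dset.index) - set(cset.index)
        only_c = set(cset.index) - set(dset.index)
        raise ValidationError(
            f"probe universes differ: {len(only_d)} only in differential, "
            f"{len(only_c)} only in correlation"
        )
    probes = correlation["probe_id"].tolist()
    in_r = (dset.loc[probes] < alpha_reactive).to_numpy()
    in_c = (cset.loc[probes] < alpha_corr).to_numpy()
    label = np.select(
        [in_c & ~in_r, in_c & in_r, ~in_c & in_r],
        ["causative", "correlated_and_reactive", "reactive"],
        default="unclassified",
    )
    return pd.DataFrame({"probe_id": probes, "label": label})


def collapse_probes_to_genes(
    classification: pd.DataFrame, probe_gene_map
) -> pd.DataFrame:
    """Collapse probe labels to gene symbols, strongest label winning.

    ``probe_gene_map`` is a DataFrame with ``probe_id``/``gene_id`` columns
    (a probe may map to several genes, or to none — unmapped probes drop out)
    or a dict probe -> gene. A gene is causative if *any* of its probes is;
    otherwise the precedence is correlated_and_reactive > reactive >
    unclassified. Gene order follows first appearance in the map.
    """
    if isinstance(probe_gene_map, dict):
        probe_gene_map = pd.DataFrame(
            {"probe_id": list(probe_gene_map), "gene_id": list(probe_gene_map.values())}
        )
    rank = {lab: i for i, lab in enumerate(CLASS_LABELS)}
    merged = probe_gene_map.merge(classification, on="probe_id", how="inner")
    merged["_rank"] = merged["label"].map(rank)
    best = merged.groupby("gene_id", sort=False)["_rank"].min()
    inverse = {i: lab for lab, i in rank.items()}
    return pd.DataFrame(
        {"gene_id": best.index.tolist(), "label": [inverse[i] for i in best]}
    )
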