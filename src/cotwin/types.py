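"""Validated in-memory containers shared by every pipeline stage.

Conventions
-----------
* Genomic coordinates are 0-based half-open everywhere in memory. 1-based
  positions appear only in on-disk formats (VCF, the ``pos_1based`` column of
  dosage TSVs) and are converted on read/write.
* Missing genotype dosages are ``numpy.nan`` — an explicit sentinel distinct
  from 0, so per-SNP sample dropping is possible downstream.
* Expression intensities are non-negative normalized array signals in
  arbitrary units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """An on-disk representation violates its declared layout."""


class ValidationError(ValueError):
    """An in-memory object violates a domain invariant."""


class ParameterizationError(ValueError):
    """A simulation configuration demands an unattainable generative model."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


SEX_VALUES = ("female", "male")
#: column schema for phenotype tables (extra covariate columns may follow)
PHENOTYPE_COLUMNS = ("sample_id", "bmi", "sex", "age", "cohort")
#: column schema for SNP metadata; ``pos`` is 0-based
SNP_COLUMNS = ("snp_id", "chrom", "pos", "ref", "alt")
#: column schema for gene annotation; [start, end) half-open
GENE_COLUMNS = ("gene_id", "chrom", "start", "end", "strand")
STRAND_VALUES = ("+", "-", "unknown")

CLASS_LABELS = ("causative", "correlated_and_reactive", "reactive", "unclassified")


def _require_unique(values, what: str) -> None:
    seen = set()
    for v in values:
        if v in seen:
            raise ValidationError(f"duplicate {what}: {v!r}")
        seen.add(v)


@dataclass
class ExpressionMatrix:
    """Probe x sample matrix of non-negative normalized intensities."""

    probe_ids: list
    sample_ids: list
    values: np.ndarray

    def __post_init__(self):
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"expression matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        _require_unique(self.probe_ids, "probe id")
        _require_unique(self.sample_ids, "sample id")
        if self.values.size and not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite intensity at probe {self.probe_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if self.values.size and self.values.min() < 0:
            i, j = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative intensity at probe {self.probe_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    def select_probes(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask, dtype=bool)
        keep = [p for p, m in zip(self.probe_ids, mask) if m]
        return ExpressionMatrix(keep, list(self.sample_ids), self.values[mask])

    def sample_values(self, sample_ids) -> np.ndarray:
        """Columns for ``sample_ids``, in that order."""
        index = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise ValidationError(f"samples absent from expression matrix: {missing}")
        return self.values[:, [index[s] for s in sample_ids]]


@dataclass
class TwinPairSet:
    """Monozygotic pairs: one obese and one lean co-twin per pair."""

    pair_ids: list
    obese_ids: list
    lean_ids: list

    def __post_init__(self):
        if not (len(self.pair_ids) == len(self.obese_ids) == len(self.lean_ids)):
            raise ValidationError("pair/obese/lean id lists differ in length")
        _require_unique(self.pair_ids, "pair id")
        _require_unique(list(self.obese_ids) + list(self.lean_ids), "twin sample id")

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"pair_id": self.pair_ids, "obese_sample": self.obese_ids, "lean_sample": self.lean_ids}
        )


@dataclass
class GenotypeDosageMatrix:
    """SNP x sample additive alt-allele dosages in [0, 2]; NaN marks missing."""

    snps: pd.DataFrame
    sample_ids: list
    dosages: np.ndarray

    def __post_init__(self):
        self.snps = self.snps.reset_index(drop=True)
        missing_cols = [c for c in SNP_COLUMNS if c not in self.snps.columns]
        if missing_cols:
            raise ValidationError(f"snp table lacks columns {missing_cols}")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.snps), len(self.sample_ids)):
            raise ValidationError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.snps)} SNPs x {len(self.sample_ids)} samples"
            )
        _require_unique(self.snps["snp_id"].tolist(), "snp id")
        _require_unique(self.sample_ids, "sample id")
        if (self.snps["pos"] < 0).any():
            bad = self.snps.loc[self.snps["pos"] < 0, "snp_id"].iloc[0]
            raise ValidationError(f"negative position for SNP {bad!r}")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"dosage {self.dosages[i, j]} outside [0, 2] for SNP "
                f"{self.snps['snp_id'].iloc[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_dosages(self, sample_ids) -> np.ndarray:
        index = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise ValidationError(f"samples absent from genotype matrix: {missing}")
        return self.dosages[:, [index[s] for s in sample_ids]]


@dataclass
class PairRatioMatrix:
    """Probe x pair matrix of obese/lean expression ratios (co-twin normalized).

    Values above 1 mean higher expression in the obese co-twin.
    """

    probe_ids: list
    pair_ids: list
    ratios: np.ndarray

    def __post_init__(self):
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.pair_ids = [str(p) for p in self.pair_ids]
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.ratios.shape != (len(self.probe_ids), len(self.pair_ids)):
            raise ValidationError(
                f"ratio matrix shape {self.ratios.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.pair_ids)} pairs"
            )
        _require_unique(self.probe_ids, "probe id")
        _require_unique(self.pair_ids, "pair id")
        if self.ratios.size and not (
            np.all(np.isfinite(self.ratios)) and self.ratios.min() > 0
        ):
            bad = ~(np.isfinite(self.ratios) & (self.ratios > 0))
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-positive or non-finite ratio at probe {self.probe_ids[i]!r}, "
                f"pair {self.pair_ids[j]!r}"
            )

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)


def validate_phenotype_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-sample phenotype table (sample_id, bmi, sex, age, cohort)."""
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"phenotype table lacks columns {missing}")
    df = df.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    _require_unique(df["sample_id"].tolist(), "sample id")
    for col in ("bmi", "age"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or not np.all(np.isfinite(vals)) or (vals <= 0).any():
            bad = df.loc[~(np.isfinite(vals) & (vals > 0)), "sample_id"].iloc[0]
            raise ValidationError(f"non-positive or non-numeric {col} for sample {bad!r}")
        df[col] = vals.astype(float)
    bad_sex = ~df["sex"].isin(SEX_VALUES)
    if bad_sex.any():
        raise ValidationError(
            f"sex must be one of {SEX_VALUES}; offending sample "
            f"{df.loc[bad_sex, 'sample_id'].iloc[0]!r}"
        )
    df["cohort"] = df["cohort"].astype(str)
    return df


def validate_gene_annotation(df: pd.DataFrame) -> pd.DataFrame:
    """Validate gene records in 0-based half-open coordinates."""
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"gene annotation lacks columns {missing}")
    df = df.copy()
    df["gene_id"] = df["gene_id"].astype(str)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    bad = df["start"] >= df["end"]
    if bad.any():
        raise ValidationError(
            f"start >= end for gene {df.loc[bad, 'gene_id'].iloc[0]!r}"
        )
    bad_strand = ~df["strand"].isin(STRAND_VALUES)
    if bad_strand.any():
        raise ValidationError(
            f"strand must be one of {STRAND_VALUES}; offending gene "
            f"{df.loc[bad_strand, 'gene_id'].iloc[0]!r}"
        )
    return df.reset_index(drop=True)
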