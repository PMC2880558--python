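"""Readers and writers for every external representation the pipeline touches.

Tab-delimited layouts
---------------------
* Expression TSV: first column ``probe_id``, header row of sample ids, numeric
  body. No missing values allowed.
* Dosage TSV: five metadata columns ``snp_id chrom pos_1based ref alt``
  followed by one column per sample; ``.`` marks a missing dosage.
* Twin-pair TSV: columns ``pair_id obese_sample lean_sample``.
* Phenotype TSV: columns ``sample_id bmi sex age cohort`` plus optional
  covariate columns.

VCF is read through cyvcf2; GT fields are converted to alt-allele counts and
DS fields are used verbatim when present. BED is standard 0-based half-open.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    ExpressionMatrix,
    FormatError,
    GenotypeDosageMatrix,
    TwinPairSet,
    ValidationError,
    validate_gene_annotation,
    validate_phenotype_table,
)

FLOAT_FORMAT = "%.10g"
MISSING = "."


def _read_tsv(path) -> pd.DataFrame:
    # pandas silently mangles duplicate header fields, so check them first
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    seen = set()
    for name in header:
        if name in seen:
            raise FormatError(f"{path}: duplicate column {name!r} in header")
        seen.add(name)
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed TSV ({exc})") from exc


def _to_float_block(df: pd.DataFrame, path, allow_missing: bool) -> np.ndarray:
    """Convert a string-valued block to floats with located error messages."""
    block = df.replace(MISSING, "nan") if allow_missing else df
    values = block.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    raw = df.to_numpy(dtype=object)
    bad = np.isnan(values) & (raw != MISSING if allow_missing else True)
    bad &= raw != "nan"
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: non-numeric value {raw[i, j]!r} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    if not allow_missing and np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise FormatError(
            f"{path}: missing value at row {df.index[i]!r}, column {df.columns[j]!r} "
            "(ragged row or empty cell)"
        )
    return values


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a probe x sample expression TSV, preserving row/column order."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected a probe-id column plus sample columns")
    probe_col = df.columns[0]
    probes = df[probe_col].tolist()
    samples = list(df.columns[1:])
    body = df[samples]
    body.index = probes
    values = _to_float_block(body, path, allow_missing=False)
    try:
        return ExpressionMatrix(probes, samples, values)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    frame = matrix.to_frame()
    frame.index.name = "probe_id"
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, lineterminator="\n")


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(path) -> GenotypeDosageMatrix:
    """Read genotypes from a dosage TSV or a VCF, dispatching on extension."""
    name = str(path)
    if name.endswith((".vcf", ".vcf.gz")):
        return read_vcf(path)
    if name.endswith((".tsv", ".txt")):
        return read_dosage_tsv(path)
    raise FormatError(f"{path}: unknown genotype file extension (expect .tsv/.txt/.vcf)")


def read_dosage_tsv(path) -> GenotypeDosageMatrix:
    df = _read_tsv(path)
    meta_cols = ["snp_id", "chrom", "pos_1based", "ref", "alt"]
    if list(df.columns[:5]) != meta_cols:
        raise FormatError(
            f"{path}: first five columns must be {meta_cols}, got {list(df.columns[:5])}"
        )
    samples = list(df.columns[5:])
    body = df[samples]
    body.index = df["snp_id"].tolist()
    dosages = _to_float_block(body, path, allow_missing=True)
    pos1 = pd.to_numeric(df["pos_1based"], errors="coerce")
    if pos1.isna().any() or (pos1 < 1).any():
        bad = df.loc[~(pos1 >= 1), "snp_id"].iloc[0]
        raise FormatError(f"{path}: pos_1based must be >= 1 (SNP {bad!r})")
    snps = pd.DataFrame(
        {
            "snp_id": df["snp_id"],
            "chrom": df["chrom"],
            "pos": pos1.astype(int) - 1,  # to 0-based
            "ref": df["ref"],
            "alt": df["alt"],
        }
    )
    try:
        return GenotypeDosageMatrix(snps, samples, dosages)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_dosage_tsv(genotypes: GenotypeDosageMatrix, path) -> None:
    meta = pd.DataFrame(
        {
            "snp_id": genotypes.snps["snp_id"],
            "chrom": genotypes.snps["chrom"],
            "pos_1based": genotypes.snps["pos"].astype(int) + 1,
            "ref": genotypes.snps["ref"],
            "alt": genotypes.snps["alt"],
        }
    )
    body = pd.DataFrame(genotypes.dosages, columns=genotypes.sample_ids)
    body = body.map(lambda v: MISSING if np.isnan(v) else FLOAT_FORMAT % v)
    pd.concat([meta.reset_index(drop=True), body], axis=1).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_vcf(path) -> GenotypeDosageMatrix:
    """Read a VCF; DS dosages take precedence over GT allele counts."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    meta, rows = [], []
    for var in vcf:
        alt = var.ALT[0] if var.ALT else MISSING
        fmt = var.FORMAT or []
        if "DS" in fmt:
            dosage = np.asarray(var.format("DS"), dtype=float).reshape(-1)
        else:
            dosage = np.empty(len(samples))
            for j, gt in enumerate(var.genotypes):
                alleles = gt[:-1]
                if any(a < 0 for a in alleles):
                    dosage[j] = np.nan
                else:
                    dosage[j] = sum(1 for a in alleles if a > 0)
        meta.append((var.ID or f"{var.CHROM}:{var.POS}", var.CHROM, var.POS - 1, var.REF, alt))
        rows.append(dosage)
    snps = pd.DataFrame(meta, columns=["snp_id", "chrom", "pos", "ref", "alt"])
    dosages = np.vstack(rows) if rows else np.empty((0, len(samples)))
    return GenotypeDosageMatrix(snps, samples, dosages)


def write_vcf(genotypes: GenotypeDosageMatrix, path, encode: str = "auto") -> None:
    """Write a minimal VCF 4.2. ``encode`` is ``GT``, ``DS`` or ``auto``.

    ``auto`` uses GT when all non-missing dosages are integral, else DS.
    """
    dos = genotypes.dosages
    if encode == "auto":
        nonmiss = dos[~np.isnan(dos)]
        encode = "GT" if np.all(nonmiss == np.round(nonmiss)) else "DS"
    if encode not in ("GT", "DS"):
        raise ValueError(f"encode must be GT, DS or auto, got {encode!r}")
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(genotypes.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        if encode == "GT":
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        else:
            fh.write(
                '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt allele dosage">\n'
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.sample_ids)
            + "\n"
        )
        for i, snp in genotypes.snps.iterrows():
            if encode == "GT":
                fields = [
                    "./." if np.isnan(v) else gt_codes[int(round(v))] for v in dos[i]
                ]
            else:
                fields = [MISSING if np.isnan(v) else FLOAT_FORMAT % v for v in dos[i]]
            fh.write(
                f"{snp['chrom']}\t{int(snp['pos']) + 1}\t{snp['snp_id']}\t"
                f"{snp['ref']}\t{snp['alt']}\t.\t.\t.\t{encode}\t" + "\t".join(fields) + "\n"
            )


# ---------------------------------------------------------------------------
# annotation, pairs, phenotypes


def read_gene_annotation(path) -> pd.DataFrame:
    """Read gene spans from BED (>= 4 columns; name required, strand optional)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(
                    f"{path}:{lineno}: BED needs >= 4 columns (chrom start end name)"
                )
            chrom, start, end, name = parts[0], parts[1], parts[2], parts[3]
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "unknown"
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer interval") from exc
            records.append((name, chrom, start_i, end_i, strand))
    df = pd.DataFrame(records, columns=["gene_id", "chrom", "start", "end", "strand"])
    try:
        return validate_gene_annotation(df)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_bed(annotation: pd.DataFrame, path) -> None:
    annotation = validate_gene_annotation(annotation)
    with open(path, "w") as fh:
        for _, rec in annotation.iterrows():
            strand = rec["strand"] if rec["strand"] in ("+", "-") else "."
            fh.write(
                f"{rec['chrom']}\t{rec['start']}\t{rec['end']}\t{rec['gene_id']}\t0\t{strand}\n"
            )


def read_twin_pairs(path) -> TwinPairSet:
    df = _read_tsv(path)
    needed = ["pair_id", "obese_sample", "lean_sample"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: twin-pair TSV lacks columns {missing}")
    return TwinPairSet(
        df["pair_id"].tolist(), df["obese_sample"].tolist(), df["lean_sample"].tolist()
    )


def write_twin_pairs(pairs: TwinPairSet, path) -> None:
    pairs.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_phenotypes(path) -> pd.DataFrame:
    df = _read_tsv(path)
    for col in df.columns:
        if col not in ("sample_id", "sex", "cohort"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
    try:
        return validate_phenotype_table(df)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT, lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# packaged fixture tables


@dataclass
class FixtureTables:
    """The published candidate-gene and SNP-association tables.

    ``table1``: 28 probe-level rows linking adipose expression to BMI
    (correlation in 77 unrelated adults, fold change and intrapair P in 13
    discordant MZ pairs). ``table2``/``table3``: per-SNP meta-analysis
    P-values for the putatively causative (23 rows) and reactive (21 rows)
    gene sets. Values are transcribed digit-for-digit from print, including
    the original's "PRDX8" gene label in table2.
    """

    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame

    def __post_init__(self):
        counts = (len(self.table1), len(self.table2), len(self.table3))
        if counts != (28, 23, 21):
            raise ValidationError(f"fixture tables must have 28/23/21 rows, got {counts}")
        for name, tab in (("table2", self.table2), ("table3", self.table3)):
            for col in ("p_women", "p_men", "p_overall"):
                if not ((tab[col] > 0) & (tab[col] <= 1)).all():
                    raise ValidationError(f"{name}.{col} outside (0, 1]")
            if not ((tab["maf"] > 0) & (tab["maf"] <= 0.5)).all():
                raise ValidationError(f"{name}.maf outside (0, 0.5]")
        if not ((self.table1["p_unrelated"] > 0) & (self.table1["p_unrelated"] <= 1)).all():
            raise ValidationError("table1.p_unrelated outside (0, 1]")


def _fixture_path(name: str):
    return importlib.resources.files("cotwin.data").joinpath(name)


def load_fixture_tables() -> FixtureTables:
    """Load the packaged candidate-gene tables (28/23/21 rows)."""
    with importlib.resources.as_file(_fixture_path("table1.tsv")) as p:
        t1 = pd.read_csv(p, sep="\t")
    with importlib.resources.as_file(_fixture_path("table2.tsv")) as p:
        t2 = pd.read_csv(p, sep="\t")
    with importlib.resources.as_file(_fixture_path("table3.tsv")) as p:
        t3 = pd.read_csv(p, sep="\t")
    return FixtureTables(t1, t2, t3)
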