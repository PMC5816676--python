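"""Readers and writers for the package's tabular formats.

Formats (all plain text):

* genotype matrix TSV — first column ``line``, one column per SNP named
  ``chrom:pos``, cells A/B/H/"-";
* SNP table TSV — chrom, pos (1-based), allele_a, allele_b, cm, plus a
  ``##chrom_length`` header comment per chromosome;
* phenotype CSV — line, location, year, rep, value;
* bin map TSV — bin_id, chrom, start, end (0-based half-open, BED-style),
  mid_bp, n_snps[, cm] then one A/B/H/"-" column per line;
* annotation — 4-column BED (0-based half-open) or minimal GFF3 (1-based
  inclusive, ``ID=`` attribute); both are normalized to a 1-based inclusive
  DataFrame (chrom, start, end, id) at read time, converting exactly once.

Malformed inputs raise :class:`FormatError` naming the file and offence.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .binmap import BinMap
from .codes import from_chars, to_chars
from .sim import RawGenotypeMatrix, SNPSet, TrueGenotypeSet

__all__ = [
    "FormatError",
    "write_snp_table", "read_snp_table",
    "write_genotype_matrix", "read_genotype_matrix",
    "write_phenotypes", "read_phenotypes",
    "write_binmap", "read_binmap",
    "write_genetic_map",
    "read_annotation", "write_annotation_bed",
    "write_truth", "read_truth",
    "bed_to_report", "report_to_bed",
]


class FormatError(ValueError):
    """A file failed validation; the message names the file and problem."""


def _check_nonempty(path: Path) -> None:
    if not path.exists():
        raise FormatError(f"{path}: file does not exist")
    if path.stat().st_size == 0:
        raise FormatError(f"{path}: empty input")


def _check_columns(df: pd.DataFrame, required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing header column(s) {missing}; expected {required}"
        )


def bed_to_report(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


def report_to_bed(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


# -- SNP table --------------------------------------------------------------

def write_snp_table(snps: SNPSet, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for chrom, length in snps.chrom_lengths.items():
            fh.write(f"##chrom_length\t{chrom}\t{length}\n")
        snps.table.to_csv(fh, sep="\t", index=False)


def read_snp_table(path) -> SNPSet:
    path = Path(path)
    _check_nonempty(path)
    chrom_lengths: dict[str, int] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("##chrom_length"):
            _, chrom, length = line.rstrip("\n").split("\t")
            chrom_lengths[chrom] = int(length)
            body_start = i + 1
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t")
    _check_columns(df, ["chrom", "pos", "allele_a", "allele_b", "cm"], path)
    if not chrom_lengths:
        chrom_lengths = {
            str(c): int(df.loc[df["chrom"] == c, "pos"].max())
            for c in df["chrom"].unique()
        }
    return SNPSet(table=df, chrom_lengths=chrom_lengths)


# -- genotype matrix --------------------------------------------------------

def write_genotype_matrix(raw: RawGenotypeMatrix, path) -> None:
    snp_names = [
        f"{c}:{p}" for c, p in zip(raw.snps.table["chrom"], raw.snps.table["pos"])
    ]
    df = pd.DataFrame(to_chars(raw.calls), index=raw.line_ids, columns=snp_names)
    df.index.name = "line"
    df.to_csv(path, sep="\t")


def read_genotype_matrix(path, snps: SNPSet) -> RawGenotypeMatrix:
    path = Path(path)
    _check_nonempty(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged rows ({exc})") from exc
    if df.index.name != "line":
        raise FormatError(f"{path}: first header column must be 'line'")
    expected = [
        f"{c}:{p}" for c, p in zip(snps.table["chrom"], snps.table["pos"])
    ]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: SNP columns do not match the SNP table")
    arr = df.to_numpy()
    try:
        calls = from_chars(arr)
    except ValueError as exc:
        bad = ~np.isin(arr, list("ABH-"))
        r, c = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: invalid genotype code {arr[r, c]!r} at line "
            f"{df.index[r]!r}, SNP {df.columns[c]!r}; valid codes are A, B, H, -"
        ) from exc
    depth = (calls != -1).astype(np.int64)
    return RawGenotypeMatrix(
        snps=snps, line_ids=[str(i) for i in df.index], calls=calls, depth=depth
    )


# -- phenotypes -------------------------------------------------------------

def write_phenotypes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    path = Path(path)
    _check_nonempty(path)
    df = pd.read_csv(path)
    _check_columns(df, ["line", "location", "year", "rep", "value"], path)
    if df["value"].map(lambda v: isinstance(v, str)).any():
        bad = df.index[df["value"].map(lambda v: isinstance(v, str))][0]
        raise FormatError(f"{path}: non-numeric value at data row {bad + 1}")
    return df


# -- bin map ----------------------------------------------------------------

_BIN_META = ["bin_id", "chrom", "start", "end", "mid_bp", "n_snps"]


def write_binmap(binmap: BinMap, path) -> None:
    path = Path(path)
    meta_cols = _BIN_META + (["cm"] if "cm" in binmap.bins.columns else [])
    chars = to_chars(binmap.genotypes)
    df = pd.concat(
        [
            binmap.bins[meta_cols].reset_index(drop=True),
            pd.DataFrame(chars.T, columns=binmap.line_ids),
        ],
        axis=1,
    )
    with open(path, "w") as fh:
        for chrom, length in binmap.chrom_lengths.items():
            fh.write(f"##chrom_length\t{chrom}\t{length}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_binmap(path) -> BinMap:
    path = Path(path)
    _check_nonempty(path)
    chrom_lengths: dict[str, int] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body = 0
    for i, line in enumerate(lines):
        if line.startswith("##chrom_length"):
            _, chrom, length = line.rstrip("\n").split("\t")
            chrom_lengths[chrom] = int(length)
            body = i + 1
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body:])), sep="\t")
    _check_columns(df, _BIN_META, path)
    meta_cols = _BIN_META + (["cm"] if "cm" in df.columns else [])
    line_ids = [c for c in df.columns if c not in meta_cols]
    if not line_ids:
        raise FormatError(f"{path}: no per-line genotype columns")
    try:
        genotypes = from_chars(df[line_ids].to_numpy(dtype=str)).T
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return BinMap(
        bins=df[meta_cols].copy(),
        genotypes=genotypes,
        line_ids=line_ids,
        chrom_lengths=chrom_lengths,
    )


def write_genetic_map(binmap: BinMap, path) -> None:
    if "cm" not in binmap.bins.columns:
        raise ValueError("bin map carries no genetic map")
    binmap.bins[["bin_id", "chrom", "mid_bp", "cm"]].to_csv(path, sep="\t", index=False)


# -- annotations ------------------------------------------------------------

def read_annotation(path) -> pd.DataFrame:
    """BED or minimal GFF3 -> DataFrame (chrom, start, end, id), 1-based
    inclusive coordinates."""
    path = Path(path)
    _check_nonempty(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_gff3(path)
    return _read_bed(path)


def _read_bed(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(
                    f"{path}: line {ln}: BED needs >= 4 columns (chrom, start, end, id)"
                )
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}: line {ln}: non-integer coordinates") from exc
            rstart, rend = bed_to_report(start, end)
            rows.append({"chrom": parts[0], "start": rstart, "end": rend, "id": parts[3]})
    if not rows:
        raise FormatError(f"{path}: no annotation records")
    return pd.DataFrame(rows)


def _read_gff3(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}: line {ln}: GFF3 needs 9 columns")
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID", attrs.get("Name", f"feature{ln}"))
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise FormatError(f"{path}: line {ln}: non-integer coordinates") from exc
            rows.append({"chrom": parts[0], "start": start, "end": end, "id": gene_id})
    if not rows:
        raise FormatError(f"{path}: no annotation records")
    return pd.DataFrame(rows)


def write_annotation_bed(annotation: pd.DataFrame, path) -> None:
    """DataFrame (1-based inclusive) -> 4-column BED (0-based half-open)."""
    with open(path, "w") as fh:
        for _, row in annotation.iterrows():
            start, end = report_to_bed(int(row["start"]), int(row["end"]))
            fh.write(f"{row['chrom']}\t{start}\t{end}\t{row['id']}\n")


# -- truth JSON -------------------------------------------------------------

def write_truth(truth: TrueGenotypeSet, path, extra: dict | None = None) -> None:
    payload = {
        "line_ids": list(truth.line_ids),
        "crossovers": truth.crossovers.to_dict(orient="list"),
        "residual_heterozygosity": truth.residual_heterozygosity(),
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")


def read_truth(path) -> dict:
    path = Path(path)
    _check_nonempty(path)
    with open(path) as fh:
        return json.load(fh)
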