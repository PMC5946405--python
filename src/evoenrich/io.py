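"""Readers and writers for the pipeline's external formats.

Formats: TSV-with-header for GWAS summary statistics and LD pair tables,
BED3/BED4 for interval annotations, two-column text for scored markers,
refFlat for transcript models.  Writers emit what the paired reader accepts
(round-trip identity on valid data); readers never silently coerce — invalid
rows are dropped with a counted reject log or raise a :class:`FormatError`.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .model import (
    AnnotationSet,
    EmptyInputError,
    FormatError,
    GenomicInterval,
    GwasTable,
    LDStore,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

DEFAULT_COLUMN_MAP = {
    "snp_id": "snp_id",
    "chrom": "chrom",
    "pos": "pos",
    "pvalue": "pvalue",
    "maf": "maf",
    "allele1": "allele1",
    "allele2": "allele2",
}


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def _to_float(series: pd.Series) -> pd.Series:
    """Exact (correctly rounded) string-to-float conversion; bad cells -> NaN."""

    def conv(x):
        try:
            return float(x)
        except (TypeError, ValueError):
            return np.nan

    return series.map(conv).astype(float)


def read_gwas_summary(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    trait_name: Optional[str] = None,
    build: str = "hg19",
) -> GwasTable:
    """Read delimited summary statistics into a validated :class:`GwasTable`.

    ``column_map`` maps the table's field names (``snp_id``, ``chrom``,
    ``pos``, ``pvalue``, optionally ``maf``/``allele1``/``allele2``) to the
    file's column headers.  Rows violating the invariants (``pvalue`` outside
    (0,1], ``pos < 1``, duplicate id, unparseable numbers) are dropped and
    counted on the returned table's ``n_rejected``.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = _read_table(path)
    for field in ("snp_id", "chrom", "pos", "pvalue"):
        if cmap[field] not in raw.columns:
            raise FormatError(
                f"{path}: required column {cmap[field]!r} (for {field}) not found; "
                f"columns present: {list(raw.columns)}"
            )
    df = pd.DataFrame({"snp_id": raw[cmap["snp_id"]].astype(str)})
    df["chrom"] = raw[cmap["chrom"]].astype(str)
    df["pos"] = _to_float(raw[cmap["pos"]])
    df["pvalue"] = _to_float(raw[cmap["pvalue"]])
    for opt in ("maf", "allele1", "allele2"):
        col = cmap.get(opt)
        if col is not None and col in raw.columns:
            if opt == "maf":
                df[opt] = _to_float(raw[col])
            else:
                df[opt] = raw[col]
        else:
            df[opt] = np.nan if opt == "maf" else pd.NA

    ok = (
        df["pos"].notna()
        & (df["pos"] >= 1)
        & df["pvalue"].notna()
        & (df["pvalue"] > 0)
        & (df["pvalue"] <= 1)
        & ~df["snp_id"].duplicated(keep="first")
    )
    # out-of-range MAF invalidates the row rather than being clipped
    ok &= df["maf"].isna() | ((df["maf"] >= 0) & (df["maf"] <= 0.5))
    n_rejected = int((~ok).sum())
    if n_rejected:
        bad_rows = list(df.index[~ok][:20] + 2)  # 1-based, after header
        logger.warning(
            "%s: dropped %d invalid rows (file lines incl. header: %s%s)",
            path, n_rejected, bad_rows, "..." if n_rejected > 20 else "",
        )
    df = df[ok]
    if df.empty:
        raise EmptyInputError(f"{path}: no valid GWAS rows")
    name = trait_name if trait_name is not None else Path(str(path)).stem
    return GwasTable(name, df, build=build, n_rejected=n_rejected)


def write_gwas_summary(gwas: GwasTable, path, comment_lines: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in comment_lines:
            fh.write(f"# {line}\n")
        gwas.records.to_csv(fh, sep="\t", index=False, na_rep="")


def read_bed_intervals(path, name: Optional[str] = None) -> AnnotationSet:
    """Read BED3/BED4 lines (0-based half-open) preserving input order."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            label = parts[3] if len(parts) > 3 and parts[3] else ""
            intervals.append(GenomicInterval(chrom, start, end, label))
    if not intervals:
        raise EmptyInputError(f"{path}: no intervals")
    return AnnotationSet(name or Path(str(path)).stem, "interval", intervals=intervals)


def write_bed_intervals(annotation: AnnotationSet, path) -> None:
    if annotation.kind != "interval":
        raise TypeError("write_bed_intervals requires an interval annotation")
    with open(path, "w") as fh:
        for iv in annotation.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


def read_marker_scores(path, name: Optional[str] = None) -> AnnotationSet:
    """Read a two-column (snp_id, score) marker list; score may be missing.

    Duplicate ids keep the first occurrence with a warning.
    """
    markers = []
    seen = set()
    n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            snp_id = parts[0].strip()
            if not snp_id or snp_id.lower() in ("snp_id", "marker", "rsid"):
                continue  # tolerate a header line
            if snp_id in seen:
                n_dup += 1
                continue
            seen.add(snp_id)
            score = None
            if len(parts) > 1 and parts[1].strip() != "":
                try:
                    score = float(parts[1])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric score") from exc
            markers.append((snp_id, score))
    if n_dup:
        logger.warning("%s: %d duplicate marker ids, kept first occurrence", path, n_dup)
    if not markers:
        raise EmptyInputError(f"{path}: no markers")
    return AnnotationSet(name or Path(str(path)).stem, "marker", markers=markers)


def write_marker_scores(annotation: AnnotationSet, path) -> None:
    if annotation.kind != "marker":
        raise TypeError("write_marker_scores requires a marker annotation")
    with open(path, "w") as fh:
        fh.write("snp_id\tscore\n")
        for snp_id, score in annotation.markers:
            fh.write(f"{snp_id}\t{'' if score is None else repr(score)}\n")


def read_ld_table(path) -> LDStore:
    """Read a pairwise LD table (columns snp_a, snp_b, r2) into an LDStore."""
    df = _read_table(path)
    for col in ("snp_a", "snp_b", "r2"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing LD column {col!r}")
    r2 = _to_float(df["r2"])
    if r2.isna().any() or (r2 < 0).any() or (r2 > 1).any():
        raise FormatError(f"{path}: r2 values must be numeric in [0, 1]")
    return LDStore(zip(df["snp_a"].astype(str), df["snp_b"].astype(str), r2))


def write_ld_table(ld: LDStore, path, comment_lines: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in comment_lines:
            fh.write(f"# {line}\n")
        fh.write("snp_a\tsnp_b\tr2\n")
        for a, b, r2 in ld.to_pairs():
            fh.write(f"{a}\t{b}\t{r2!r}\n")


def _parse_block_list(text: str, lineno: int, path) -> list:
    try:
        return [int(x) for x in text.rstrip(",").split(",") if x != ""]
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: malformed exon block list") from exc


def read_refflat(path) -> list:
    """Read refFlat rows (gene, transcript, chrom, strand, txStart, txEnd,
    cdsStart, cdsEnd, exonCount, exonStarts, exonEnds) into TranscriptModels."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 11:
                raise FormatError(f"{path}:{lineno}: expected 11 refFlat columns")
            gene, tx, chrom, strand = parts[0], parts[1], parts[2], parts[3]
            tx_start, tx_end, cds_start, cds_end = map(int, parts[4:8])
            exon_count = int(parts[8])
            exon_starts = _parse_block_list(parts[9], lineno, path)
            exon_ends = _parse_block_list(parts[10], lineno, path)
            if len(exon_starts) != exon_count or len(exon_ends) != exon_count:
                raise FormatError(
                    f"{path}:{lineno}: exonCount={exon_count} does not match "
                    f"block lists ({len(exon_starts)}/{len(exon_ends)})"
                )
            out.append(
                TranscriptModel(
                    gene=gene, transcript=tx, chrom=chrom, strand=strand,
                    tx_start=tx_start, tx_end=tx_end,
                    cds_start=cds_start, cds_end=cds_end,
                    exon_starts=exon_starts, exon_ends=exon_ends,
                )
            )
    if not out:
        raise EmptyInputError(f"{path}: no transcripts")
    return out


def write_refflat(transcripts: Iterable[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(
                "\t".join(
                    [
                        t.gene, t.transcript, t.chrom, t.strand,
                        str(t.tx_start), str(t.tx_end),
                        str(t.cds_start), str(t.cds_end),
                        str(len(t.exon_starts)),
                        ",".join(map(str, t.exon_starts)) + ",",
                        ",".join(map(str, t.exon_ends)) + ",",
                    ]
                )
                + "\n"
            )
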