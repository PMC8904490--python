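"""Readers and writers for the tabular formats the pipeline consumes.

All genomic intervals are normalized on input to a single internal
convention: **0-based half-open** ``[start, end)``, the BED interchange
convention. SEG tables and GFF3 are 1-based inclusive on disk by default;
the ``dialect`` flag of :func:`read_seg` makes the assumption explicit and
overridable. Every writer emits a provenance comment line (``#`` prefixed,
tool version plus an optional context string); every reader skips ``#``
lines.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "Segment",
    "Feature",
    "ExpressionMatrix",
    "Dialect",
    "read_seg",
    "write_seg",
    "segments_by_sample",
    "read_matrix",
    "write_matrix",
    "read_features",
    "write_features",
    "read_tf_table",
    "write_tf_table",
    "provenance_line",
]

TF_CONFIDENCE_GRADES = ("A", "B", "C", "D", "E")


class Dialect(str, enum.Enum):
    """Coordinate convention of an on-disk interval table."""

    one_based_inclusive = "one_based_inclusive"
    zero_based_half_open = "zero_based_half_open"


@dataclass(frozen=True)
class Segment:
    """One copy-number segment of one sample.

    ``log2_ratio`` is the log2 of tumor/normal copy-number ratio; the
    amplification/deletion status rule compares region-averaged values of
    this field against +0.1 / -0.1. Coordinates are internal 0-based
    half-open.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    log2_ratio: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(
                f"segment {self.sample_id} {self.chrom}:{self.start}-{self.end}: "
                "start must be < end (internal 0-based half-open)"
            )
        if not np.isfinite(self.log2_ratio):
            raise ValidationError(
                f"segment {self.sample_id} {self.chrom}:{self.start}-{self.end}: "
                "non-finite log2 ratio"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Feature:
    """A genomic feature (gene or miRNA) with internal 0-based half-open span.

    Strand is stored but only consulted for promoter windows in methylation
    aggregation; ``.`` means unknown.
    """

    feature_id: str
    kind: str  # "gene" | "mirna"
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.kind not in ("gene", "mirna"):
            raise ValidationError(f"feature {self.feature_id}: unknown kind {self.kind!r}")
        if not self.start < self.end:
            raise ValidationError(f"feature {self.feature_id}: start must be < end")
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"feature {self.feature_id}: strand must be +, - or .")

    @property
    def tss(self) -> int:
        """Transcription start site (strand-aware; '+' and '.' use start)."""
        return self.end - 1 if self.strand == "-" else self.start


VALUE_KINDS = ("raw_count", "rpm", "beta", "log2ratio")


class ExpressionMatrix:
    """A features-by-samples value matrix with a declared value kind.

    ``raw_count`` matrices must hold non-negative integers and may not have
    missing entries; ``beta`` values must lie in [0, 1] but may be missing
    (NaN), because methylation platforms differ in gene coverage; ``rpm``
    and ``log2ratio`` are unconstrained finite reals.
    """

    def __init__(self, df: pd.DataFrame, value_kind: str):
        if value_kind not in VALUE_KINDS:
            raise ValidationError(f"unknown value_kind {value_kind!r}")
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate row ids: {dupes[:5]}")
        if df.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        values = df.to_numpy(dtype=float)
        if value_kind == "raw_count":
            if np.any(~np.isfinite(values)):
                raise ValidationError("raw_count matrix may not contain missing values")
            if np.any(values < 0) or np.any(values != np.round(values)):
                raise ValidationError("raw_count values must be non-negative integers")
            df = df.astype(np.int64)
        elif value_kind == "beta":
            finite = values[np.isfinite(values)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValidationError("beta values must lie in [0, 1]")
        else:
            if np.any(~np.isfinite(values)):
                raise ValidationError(f"{value_kind} matrix may not contain missing values")
        self.df = df
        self.value_kind = value_kind

    @property
    def row_ids(self) -> list[str]:
        return [str(i) for i in self.df.index]

    @property
    def col_ids(self) -> list[str]:
        return [str(c) for c in self.df.columns]

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.df.loc[:, list(sample_ids)], self.value_kind)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.value_kind == other.value_kind and self.df.equals(other.df)

    def __repr__(self) -> str:
        r, c = self.df.shape
        return f"ExpressionMatrix({r} features x {c} samples, {self.value_kind})"


def provenance_line(context: str = "") -> str:
    from . import __version__

    tail = f" {context}" if context else ""
    return f"# cnmir {__version__}{tail}"


def _to_internal(start: int, end: int, dialect: Dialect) -> tuple[int, int]:
    if Dialect(dialect) is Dialect.one_based_inclusive:
        return start - 1, end
    return start, end


def _from_internal(start: int, end: int, dialect: Dialect) -> tuple[int, int]:
    if Dialect(dialect) is Dialect.one_based_inclusive:
        return start + 1, end
    return start, end


_SEG_COLUMN_ALIASES = {
    "sample": "sample",
    "sample_id": "sample",
    "chromosome": "chrom",
    "chrom": "chrom",
    "start": "start",
    "end": "end",
    "seg.mean": "log2_ratio",
    "seg_mean": "log2_ratio",
    "segment_mean": "log2_ratio",
    "log2_ratio": "log2_ratio",
}


def read_seg(path, dialect: Dialect = Dialect.one_based_inclusive) -> list[Segment]:
    """Read a SEG-format table into internally normalized segments.

    Requires a header naming sample, chromosome, start, end and segment-mean
    columns (common aliases accepted; extra columns such as Num_Probes are
    ignored). Overlapping segments within one sample are rejected: the
    upstream segmentation contract is a per-sample partition and silently
    averaging overlaps would hide corrupt input.
    """
    df = _read_tsv(path)
    cols = {}
    for c in df.columns:
        key = _SEG_COLUMN_ALIASES.get(str(c).strip().lower())
        if key is not None and key not in cols:
            cols[key] = c
    missing = {"sample", "chrom", "start", "end", "log2_ratio"} - set(cols)
    if missing:
        raise ParseError(f"{path}: missing SEG columns: {sorted(missing)}")

    segments: list[Segment] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        try:
            start = int(rec[cols["start"]])
            end = int(rec[cols["end"]])
            log2 = float(rec[cols["log2_ratio"]])
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: line {i}: malformed row ({exc})") from None
        start, end = _to_internal(start, end, dialect)
        try:
            segments.append(
                Segment(str(rec[cols["sample"]]), str(rec[cols["chrom"]]), start, end, log2)
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {i}: {exc}") from None
    _check_no_overlap(segments, str(path))
    return segments


def _check_no_overlap(segments: Sequence[Segment], source: str) -> None:
    by_key: dict[tuple[str, str], list[Segment]] = {}
    for s in segments:
        by_key.setdefault((s.sample_id, s.chrom), []).append(s)
    for (sample, chrom), segs in by_key.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"{source}: overlapping segments for sample {sample} on {chrom}: "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )


def write_seg(path, segments: Iterable[Segment],
              dialect: Dialect = Dialect.one_based_inclusive,
              context: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(provenance_line(context) + "\n")
        fh.write("Sample\tChromosome\tStart\tEnd\tSegment_Mean\n")
        for s in segments:
            start, end = _from_internal(s.start, s.end, dialect)
            fh.write(f"{s.sample_id}\t{s.chrom}\t{start}\t{end}\t{s.log2_ratio:.17g}\n")


def segments_by_sample(segments: Iterable[Segment]) -> dict[str, list[Segment]]:
    """Group a flat segment list per sample, each sorted by (chrom, start)."""
    out: dict[str, list[Segment]] = {}
    for s in segments:
        out.setdefault(s.sample_id, []).append(s)
    for sample in out:
        out[sample].sort(key=lambda s: (s.chrom, s.start))
    return out


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from None


def read_matrix(path, value_kind: str) -> ExpressionMatrix:
    """Read a rectangular TSV (first column feature ids, rest samples)."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from None
    if df.columns.size == 0:
        raise ParseError(f"{path}: matrix has no sample columns")
    non_numeric = df.columns[
        [not np.issubdtype(dt, np.number) for dt in df.dtypes]
    ].tolist()
    if non_numeric:
        raise ParseError(f"{path}: non-numeric values in columns {non_numeric[:5]}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        return ExpressionMatrix(df, value_kind)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_matrix(path, matrix: ExpressionMatrix, context: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(provenance_line(context) + "\n")
        matrix.df.to_csv(fh, sep="\t", index_label="feature_id")


def read_features(path, format: str = "bed", kind: str | None = None) -> list[Feature]:
    """Read gene/miRNA annotations from BED6(+kind) or GFF3-lite.

    BED is 0-based half-open already; GFF3 is 1-based inclusive and is
    converted. For BED the feature kind comes from an optional 7th column,
    falling back to the ``kind`` argument; for GFF3 the ``type`` column maps
    gene-like types to ``gene`` and miRNA types to ``mirna``.
    """
    if format not in ("bed", "gff3lite"):
        raise ValueError(f"unknown feature format {format!r}")
    features: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if format == "bed":
                features.append(_parse_bed_line(fields, kind, path, lineno))
            else:
                features.append(_parse_gff3_line(fields, path, lineno))
    seen: set[tuple[str, str]] = set()
    for f in features:
        key = (f.kind, f.feature_id)
        if key in seen:
            raise ValidationError(f"{path}: duplicate feature_id {f.feature_id!r} (kind {f.kind})")
        seen.add(key)
    return features


def _parse_bed_line(fields: list[str], kind: str | None, path, lineno: int) -> Feature:
    if len(fields) < 4:
        raise ParseError(f"{path}: line {lineno}: BED needs >= 4 columns")
    chrom, start, end, name = fields[0], fields[1], fields[2], fields[3]
    strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
    row_kind = fields[6] if len(fields) > 6 and fields[6] else kind
    if row_kind is None:
        raise ParseError(
            f"{path}: line {lineno}: no kind column and no default kind given"
        )
    try:
        istart, iend = int(start), int(end)
    except ValueError as exc:
        raise ParseError(f"{path}: line {lineno}: {exc}") from None
    try:
        return Feature(name, row_kind, chrom, istart, iend, strand)
    except ValidationError as exc:
        raise ValidationError(f"{path}: line {lineno}: {exc}") from None


_GFF_TYPE_TO_KIND = {
    "gene": "gene",
    "protein_coding_gene": "gene",
    "mirna": "mirna",
    "mirna_gene": "mirna",
    "mirna_primary_transcript": "mirna",
}


def _parse_gff3_line(fields: list[str], path, lineno: int) -> Feature:
    if len(fields) < 9:
        raise ParseError(f"{path}: line {lineno}: GFF3 needs 9 columns")
    chrom, _source, ftype, start, end, _score, strand, _phase, attrs = fields[:9]
    kind = _GFF_TYPE_TO_KIND.get(ftype.lower())
    if kind is None:
        raise ParseError(f"{path}: line {lineno}: unknown feature type {ftype!r}")
    attr_map = {}
    for chunk in attrs.split(";"):
        if "=" in chunk:
            k, v = chunk.split("=", 1)
            attr_map[k.strip()] = v.strip()
    feature_id = attr_map.get("ID") or attr_map.get("Name")
    if not feature_id:
        raise ParseError(f"{path}: line {lineno}: missing ID attribute")
    istart, iend = _to_internal(int(start), int(end), Dialect.one_based_inclusive)
    try:
        return Feature(feature_id, kind, chrom, istart, iend,
                       strand if strand in ("+", "-") else ".")
    except ValidationError as exc:
        raise ValidationError(f"{path}: line {lineno}: {exc}") from None


def write_features(path, features: Iterable[Feature], context: str = "") -> None:
    """Write features as BED6 plus a 7th kind column (internal coordinates)."""
    with open(path, "w") as fh:
        fh.write(provenance_line(context) + "\n")
        for f in features:
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.end}\t{f.feature_id}\t.\t{f.strand}\t{f.kind}\n"
            )


def read_tf_table(path) -> pd.DataFrame:
    """Read a TF->target table (tf_id, target_id, optional confidence A..E).

    Duplicate (tf_id, target_id) pairs are collapsed keeping the best
    (alphabetically first) confidence grade.
    """
    df = _read_tsv(path)
    cols = {str(c).strip().lower(): c for c in df.columns}
    if "tf_id" not in cols or "target_id" not in cols:
        raise ParseError(f"{path}: TF table needs tf_id and target_id columns")
    out = pd.DataFrame(
        {
            "tf_id": df[cols["tf_id"]].astype(str),
            "target_id": df[cols["target_id"]].astype(str),
        }
    )
    if "confidence" in cols:
        conf = df[cols["confidence"]].astype(str).str.strip().str.upper()
        bad = sorted(set(conf) - set(TF_CONFIDENCE_GRADES) - {"", "NAN"})
        if bad:
            raise ValidationError(
                f"{path}: confidence grades must be one of {TF_CONFIDENCE_GRADES}, got {bad}"
            )
        out["confidence"] = conf.where(~conf.isin(["", "NAN"]), None)
    else:
        out["confidence"] = None
    out = (
        out.sort_values(["tf_id", "target_id", "confidence"], na_position="last")
        .drop_duplicates(["tf_id", "target_id"], keep="first")
        .reset_index(drop=True)
    )
    return out


def write_tf_table(path, table: pd.DataFrame, context: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(provenance_line(context) + "\n")
        table.to_csv(fh, sep="\t", index=False)
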