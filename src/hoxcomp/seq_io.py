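"""Sequence and annotation I/O plus coordinate-safe interval arithmetic.

All coordinates inside the package are 0-based, half-open ``[start, end)``.
GFF3 input (1-based, closed) is converted at the boundary; BED is passed
through unchanged. Sequences are uppercased on input and any character
outside ``{A, C, G, T, N}`` (IUPAC ambiguity codes, gap dashes in unaligned
records, stray symbols) is replaced by ``N`` with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("hoxcomp")

VALID_BASES = frozenset("ACGTN")

FEATURE_KINDS = frozenset(
    {"exon", "gene", "microRNA", "pseudogene", "assembly_gap", "repeat"}
)


class FormatError(ValueError):
    """Raised when an input file does not parse under the expected format."""


class UsageError(ValueError):
    """Raised when an operation is called with incoherent arguments."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval on a named sequence.

    ``start`` is 0-based inclusive, ``end`` exclusive; ``strand`` is one of
    ``+``, ``-`` or ``.`` (unstranded).
    """

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise FormatError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise FormatError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class AnnotatedCluster:
    """One species' cluster sequence plus typed feature intervals."""

    species: str
    cluster_name: str
    sequence: str
    features: list[tuple[GenomicInterval, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        gaps = []
        for iv, kind in self.features:
            if kind not in FEATURE_KINDS:
                raise UsageError(f"unknown feature kind {kind!r}")
            if iv.start < 0 or iv.end > n:
                raise UsageError(
                    f"feature {iv} outside sequence of length {n}"
                )
            if kind == "assembly_gap":
                gaps.append(iv)
        gaps.sort()
        for a, b in zip(gaps, gaps[1:]):
            if a.end > b.start:
                raise UsageError(f"overlapping assembly gaps {a} / {b}")

    def features_of_kind(self, kind: str) -> list[GenomicInterval]:
        return [iv for iv, k in self.features if k == kind]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _sanitize(seq: str, record_id: str) -> str:
    up = seq.upper()
    bad = set(up) - VALID_BASES
    if bad:
        logger.warning(
            "record %s: %d character(s) outside ACGTN (%s) replaced by N",
            record_id,
            sum(up.count(c) for c in bad),
            ",".join(sorted(bad)),
        )
        up = "".join(c if c in VALID_BASES else "N" for c in up)
    return up


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(id, sequence)`` pairs.

    Sequences are uppercased; characters outside ``{A,C,G,T,N}`` become ``N``
    with a logged warning. An empty or malformed file raises
    :class:`FormatError`.
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except (ValueError, FileNotFoundError) as exc:
        raise FormatError(f"cannot parse FASTA {path}: {exc}") from exc
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    out = []
    for rec in records:
        if not rec.id:
            raise FormatError(f"record with empty header in {path}")
        out.append((rec.id, _sanitize(str(rec.seq), rec.id)))
    return out


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    """Write ``(id, sequence)`` pairs as FASTA."""
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_aligned_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read an aligned FASTA file (equal-length gapped records).

    Gap dashes are preserved; residues are uppercased. Unequal record
    lengths raise :class:`FormatError`.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no records in alignment {path}")
    out = [(rec.id, str(rec.seq).upper()) for rec in records]
    lengths = {len(s) for _, s in out}
    if len(lengths) != 1:
        raise FormatError(f"unequal aligned record lengths in {path}")
    return out


write_aligned_fasta = write_fasta


# ---------------------------------------------------------------------------
# Features (BED / GFF3)
# ---------------------------------------------------------------------------

_GFF3_KIND_MAP = {
    "exon": "exon",
    "cds": "exon",
    "gene": "gene",
    "mirna": "microRNA",
    "microrna": "microRNA",
    "pseudogene": "pseudogene",
    "gap": "assembly_gap",
    "assembly_gap": "assembly_gap",
    "repeat": "repeat",
    "repeat_region": "repeat",
    "dispersed_repeat": "repeat",
}


def _coerce_kind(raw: str) -> str:
    kind = _GFF3_KIND_MAP.get(raw.lower(), raw)
    if kind not in FEATURE_KINDS:
        raise FormatError(f"unrecognized feature kind {raw!r}")
    return kind


def read_features(
    path: str | Path, dialect: str
) -> list[tuple[GenomicInterval, str]]:
    """Read typed feature intervals from BED or GFF3.

    dialect : {"BED", "GFF3"}
        BED coordinates (0-based half-open) pass through; GFF3 (1-based
        closed) is converted to the internal convention. The feature kind
        comes from BED column 4 (the name field) or the GFF3 type column.
    """
    path = Path(path)
    dialect = dialect.upper()
    if dialect not in {"BED", "GFF3"}:
        raise UsageError(f"unknown dialect {dialect!r}")
    out: list[tuple[GenomicInterval, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            cols = line.split("\t")
            if dialect == "BED":
                if len(cols) < 3:
                    raise FormatError(f"{path}:{lineno}: <3 BED columns")
                seq_id, start_s, end_s = cols[0], cols[1], cols[2]
                kind = _coerce_kind(cols[3]) if len(cols) > 3 else "gene"
                strand = cols[5] if len(cols) > 5 else "."
                start, end = int(start_s), int(end_s)
            else:
                if len(cols) < 8:
                    raise FormatError(f"{path}:{lineno}: <8 GFF3 columns")
                seq_id, kind_raw = cols[0], cols[2]
                start, end = int(cols[3]) - 1, int(cols[4])
                strand = cols[6] if cols[6] in {"+", "-"} else "."
                kind = _coerce_kind(kind_raw)
            if start > end:
                raise FormatError(
                    f"{path}:{lineno}: start > end after conversion"
                )
            out.append((GenomicInterval(seq_id, start, end, strand), kind))
    return out


def write_bed(
    path: str | Path,
    intervals: Iterable[GenomicInterval | tuple[GenomicInterval, str]],
    scores: Sequence[float] | None = None,
) -> None:
    """Write intervals (optionally ``(interval, name)`` pairs) as BED.

    When ``scores`` is given it fills the BED score column (e.g. percent
    identity of a conserved element).
    """
    rows = []
    for item in intervals:
        if isinstance(item, tuple):
            iv, name = item
        else:
            iv, name = item, "."
        rows.append([iv.seq_id, iv.start, iv.end, name, 0, iv.strand])
    if scores is not None:
        for row, score in zip(rows, scores):
            row[4] = score
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a sorted list of maximal disjoint intervals."""
    if not intervals:
        return []
    seq_ids = {iv.seq_id for iv in intervals}
    if len(seq_ids) > 1:
        raise UsageError(f"mixed seq_ids {sorted(seq_ids)}")
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    merged = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.start <= last.end:
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.seq_id, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.seq_id, iv.start, iv.end))
    return merged


def total_length(intervals: Sequence[GenomicInterval]) -> int:
    """Total base count of the union of intervals."""
    return sum(len(iv) for iv in merge_intervals(intervals))


def subtract_intervals(
    region: GenomicInterval, mask: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Maximal sub-intervals of ``region`` not covered by ``mask``, sorted."""
    for iv in mask:
        if iv.seq_id != region.seq_id:
            raise UsageError(
                f"mask interval on {iv.seq_id} but region on {region.seq_id}"
            )
    clipped = [
        GenomicInterval(
            region.seq_id, max(iv.start, region.start), min(iv.end, region.end)
        )
        for iv in mask
        if iv.start < region.end and iv.end > region.start
    ]
    covered = merge_intervals(clipped) if clipped else []
    out = []
    cursor = region.start
    for iv in covered:
        if iv.start > cursor:
            out.append(GenomicInterval(region.seq_id, cursor, iv.start))
        cursor = max(cursor, iv.end)
    if cursor < region.end:
        out.append(GenomicInterval(region.seq_id, cursor, region.end))
    return out


def clip_intervals(
    intervals: Sequence[GenomicInterval], region: GenomicInterval
) -> list[GenomicInterval]:
    """Intersect each interval with ``region``, dropping empty results."""
    out = []
    for iv in intervals:
        if iv.seq_id != region.seq_id:
            continue
        s, e = max(iv.start, region.start), min(iv.end, region.end)
        if s < e:
            out.append(GenomicInterval(iv.seq_id, s, e, iv.strand))
    return out


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------


def cluster_length_kb(cluster: AnnotatedCluster) -> float:
    """Cluster length in kb, rounded half-up to one decimal."""
    if not cluster.sequence:
        raise UsageError("empty cluster sequence")
    kb = Decimal(len(cluster.sequence)) / Decimal(1000)
    return float(kb.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
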