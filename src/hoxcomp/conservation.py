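"""Conserved noncoding element (CNE) detection and phylogenetic grouping.

A CNE is a noncoding interval of a reference cluster that stays above an
identity cutoff against another species in a global pairwise alignment —
by default >=65 % identity over windows of >=50 bp, the classic cutoff for
vertebrate Hox-cluster screens. Calling proceeds by seeding at fixed-width
windows that pass the cutoff, merging overlapping passing windows, trimming
flanking mismatch/gap columns, and filtering on overall identity and
reference-base length. Gap and N columns count as mismatches.

Each CNE is then assigned the deepest phylogenetic group whose diagnostic
species also carries the element at the same reference position, in the
fixed priority order gnathostome (elephant shark) > osteichthyan (spotted
gar) > sarcopterygian (coelacanth) > tetrapod (fall-through); a CNE counted
in one group is not counted again in a later one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import Align

from .seq_io import (
    FormatError,
    GenomicInterval,
    UsageError,
    subtract_intervals,
)
from .synthetic_data import ConfigError

GROUPS = ("gnathostome", "osteichthyan", "sarcopterygian", "tetrapod")

GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class ConservationThresholds:
    min_identity: float = 65.0
    min_length: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 100:
            raise UsageError("min_identity must be in (0, 100]")
        if self.min_length < 1:
            raise UsageError("min_length must be >= 1")


@dataclass
class PairwiseAlignment:
    """Two aligned sequences plus column->position coordinate maps.

    ``ref_coord_map[c]`` is the reference position written in column ``c``
    or -1 when the reference row carries a gap there (``other_coord_map``
    likewise for the other species).
    """

    ref_species: str
    other_species: str
    ref_aln: str
    other_aln: str
    ref_coord_map: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    other_coord_map: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.ref_aln) != len(self.other_aln):
            raise FormatError("aligned rows differ in length")
        if self.ref_coord_map is None:
            self.ref_coord_map = _coord_map(self.ref_aln)
        if self.other_coord_map is None:
            self.other_coord_map = _coord_map(self.other_aln)

    def __len__(self) -> int:
        return len(self.ref_aln)

    @property
    def ref_sequence(self) -> str:
        return "".join(c for c in self.ref_aln if c not in GAP_CHARS)


def _coord_map(gapped: str) -> np.ndarray:
    arr = np.frombuffer(gapped.encode(), dtype=np.uint8)
    is_base = ~np.isin(arr, np.frombuffer(b"-.", dtype=np.uint8))
    out = np.where(is_base, np.cumsum(is_base) - 1, -1)
    return out.astype(np.int64)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


def global_align(
    ref: str,
    other: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -6.0,
    gap_extend: float = -1.0,
    ref_species: str = "ref",
    other_species: str = "other",
) -> PairwiseAlignment:
    """Optimal affine-gap global alignment of two nucleotide sequences.

    ``gap_open`` is the score of the first gapped column of a run and
    ``gap_extend`` of each further column. The stiff default gap opening
    keeps deeply diverged noncoding sequence on the diagonal instead of
    letting the optimizer inflate column identity with cheap gaps (optimal
    alignment of unrelated DNA under weak gap costs approaches ~55 %
    identity, which would swamp a 65 % conservation cutoff). Intended for
    desk-scale inputs (quadratic time and memory; roughly <=50 kb).
    """
    if not ref or not other:
        raise UsageError("cannot align an empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(ref.upper(), other.upper())[0]
    return PairwiseAlignment(
        ref_species=ref_species,
        other_species=other_species,
        ref_aln=aln[0],
        other_aln=aln[1],
    )


def alignment_from_strings(
    ref_aln: str, other_aln: str, ref_species: str = "ref", other_species: str = "other"
) -> PairwiseAlignment:
    """Wrap two pre-aligned gapped rows (e.g. read from aligned FASTA)."""
    return PairwiseAlignment(ref_species, other_species, ref_aln.upper(), other_aln.upper())


def _match_columns(aln: PairwiseAlignment) -> np.ndarray:
    """Boolean per-column indicator: both rows carry the same non-gap,
    non-N base. Gap and N columns count as mismatches."""
    a = np.frombuffer(aln.ref_aln.encode(), dtype=np.uint8)
    b = np.frombuffer(aln.other_aln.encode(), dtype=np.uint8)
    bad = np.frombuffer(b"-.N", dtype=np.uint8)
    return (a == b) & ~np.isin(a, bad) & ~np.isin(b, bad)


def windowed_identity(aln: PairwiseAlignment, window: int) -> np.ndarray:
    """Percent identity for every window start (length L - window + 1)."""
    if window < 1:
        raise UsageError("window must be >= 1")
    if window > len(aln):
        raise UsageError("window exceeds alignment length")
    m = _match_columns(aln).astype(np.int64)
    csum = np.concatenate(([0], np.cumsum(m)))
    sums = csum[window:] - csum[:-window]
    return 100.0 * sums / window


# ---------------------------------------------------------------------------
# CNE calling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CNERecord:
    interval: GenomicInterval  # reference coordinates
    identity: float
    aln_span: int  # alignment columns covered
    group: str = "unassigned"
    in_intron: bool = False

    def __post_init__(self) -> None:
        if self.group not in GROUPS + ("unassigned",):
            raise ConfigError(f"unknown group {self.group!r}")


def _trim_to_matches(m: np.ndarray, s: int, e: int) -> tuple[int, int]:
    """Shrink [s, e) to the first/last match column; (s, s) if none."""
    idx = np.flatnonzero(m[s:e])
    if idx.size == 0:
        return s, s
    return s + int(idx[0]), s + int(idx[-1]) + 1


def call_cnes(
    aln: PairwiseAlignment,
    thresholds: ConservationThresholds = ConservationThresholds(),
    coding_mask: list[GenomicInterval] | None = None,
) -> list[CNERecord]:
    """Call conserved elements on the reference from a pairwise alignment.

    Windows of ``min_length`` columns with identity >= ``min_identity``
    are merged when overlapping, trimmed to flanking match columns, and
    kept when the whole span still satisfies the identity cutoff and covers
    >= ``min_length`` reference bases. Portions overlapping ``coding_mask``
    (reference coordinates) are cut out; remainders below ``min_length`` or
    the identity cutoff are dropped. Output is sorted and non-overlapping.
    """
    L = len(aln)
    w = thresholds.min_length
    if L < w:
        return []
    m = _match_columns(aln)
    csum = np.concatenate(([0], np.cumsum(m.astype(np.int64))))
    sums = csum[w:] - csum[:-w]
    passing = np.flatnonzero(100.0 * sums >= thresholds.min_identity * w)
    if passing.size == 0:
        return []

    # Merge overlapping passing windows into column runs.
    runs: list[tuple[int, int]] = []
    start = prev = int(passing[0])
    for i in passing[1:]:
        i = int(i)
        if i <= prev + w:  # windows [prev, prev+w) and [i, i+w) overlap/abut
            prev = i
        else:
            runs.append((start, prev + w))
            start = prev = i
    runs.append((start, prev + w))

    ref_id = f"{aln.ref_species}"
    records: list[CNERecord] = []
    for s, e in runs:
        s, e = _trim_to_matches(m, s, e)
        if e <= s:
            continue
        span_ref = aln.ref_coord_map[s:e]
        ref_positions = span_ref[span_ref >= 0]
        if ref_positions.size == 0:
            continue
        ref_iv = GenomicInterval(ref_id, int(ref_positions[0]), int(ref_positions[-1]) + 1)
        identity = 100.0 * float(csum[e] - csum[s]) / (e - s)
        if identity < thresholds.min_identity or len(ref_iv) < thresholds.min_length:
            continue
        pieces = (
            subtract_intervals(ref_iv, [GenomicInterval(ref_id, mi.start, mi.end) for mi in coding_mask])
            if coding_mask
            else [ref_iv]
        )
        for piece in pieces:
            rec = _record_for_ref_span(aln, m, csum, piece, thresholds, ref_id)
            if rec is not None:
                records.append(rec)
    records.sort(key=lambda r: r.interval.start)
    return records


def _record_for_ref_span(
    aln: PairwiseAlignment,
    m: np.ndarray,
    csum: np.ndarray,
    ref_iv: GenomicInterval,
    thresholds: ConservationThresholds,
    ref_id: str,
) -> CNERecord | None:
    cols = np.flatnonzero(
        (aln.ref_coord_map >= ref_iv.start) & (aln.ref_coord_map < ref_iv.end)
    )
    if cols.size == 0:
        return None
    s, e = int(cols[0]), int(cols[-1]) + 1
    s, e = _trim_to_matches(m, s, e)
    if e <= s:
        return None
    span_ref = aln.ref_coord_map[s:e]
    ref_positions = span_ref[span_ref >= 0]
    iv = GenomicInterval(ref_id, int(ref_positions[0]), int(ref_positions[-1]) + 1)
    identity = 100.0 * float(csum[e] - csum[s]) / (e - s)
    if identity < thresholds.min_identity or len(iv) < thresholds.min_length:
        return None
    return CNERecord(interval=iv, identity=identity, aln_span=e - s)


# ---------------------------------------------------------------------------
# Cross-species correspondence and grouping
# ---------------------------------------------------------------------------


def project_to_reference(
    aln: PairwiseAlignment, other_iv: GenomicInterval
) -> GenomicInterval | None:
    """Project an interval on the other species through the alignment onto
    reference coordinates (None when only gap columns are covered)."""
    cols = np.flatnonzero(
        (aln.other_coord_map >= other_iv.start)
        & (aln.other_coord_map < other_iv.end)
    )
    if cols.size == 0:
        return None
    ref_positions = aln.ref_coord_map[cols]
    ref_positions = ref_positions[ref_positions >= 0]
    if ref_positions.size == 0:
        return None
    return GenomicInterval(
        aln.ref_species, int(ref_positions.min()), int(ref_positions.max()) + 1
    )


def match_cnes(
    ref_cnes: list[CNERecord],
    other_cnes: list[CNERecord],
    aln: PairwiseAlignment,
) -> list[tuple[int, list[int]]]:
    """Correspondence between reference CNEs and other-species CNEs.

    A reference CNE corresponds to every other-species CNE whose projected
    interval overlaps it by at least one base; one-to-many matches are
    expected (long elements in one species break into shorter ones in the
    other). Reference CNEs without matches are omitted.
    """
    projected: list[GenomicInterval | None] = [
        project_to_reference(aln, rec.interval) for rec in other_cnes
    ]
    out: list[tuple[int, list[int]]] = []
    for i, rec in enumerate(ref_cnes):
        hits = [
            j
            for j, proj in enumerate(projected)
            if proj is not None and proj.intersection_length(rec.interval) >= 1
        ]
        if hits:
            out.append((i, hits))
    return out


def classify_cne_groups(
    ref_cnes: list[CNERecord],
    presence: dict[str, set[str]],
    per_species_hits: dict[str, list[GenomicInterval]],
) -> list[CNERecord]:
    """Assign each CNE its deepest phylogenetic group.

    ``presence`` maps each group label to its diagnostic species (e.g.
    ``{"gnathostome": {"elephant_shark"}, ...}``); ``per_species_hits``
    holds, per diagnostic species, the reference-coordinate intervals where
    that species shares conservation. The first group in the priority order
    whose diagnostic species overlaps the CNE (>=1 bp) wins; a CNE matching
    no diagnostic species falls through to "tetrapod".
    """
    for label in presence:
        if label not in GROUPS:
            raise ConfigError(f"unknown clade label {label!r}")
    out: list[CNERecord] = []
    for rec in ref_cnes:
        group = "tetrapod"
        for label in GROUPS[:-1]:
            species_set = presence.get(label, set())
            found = any(
                rec.interval.intersection_length(iv) >= 1
                for sp in species_set
                for iv in per_species_hits.get(sp, [])
            )
            if found:
                group = label
                break
        out.append(replace(rec, group=group))
    return out


def flag_intronic(
    cnes: list[CNERecord],
    gene_spans: list[GenomicInterval],
    exons: list[GenomicInterval],
) -> list[CNERecord]:
    """Mark CNEs lying inside a gene span but outside all exons."""
    out = []
    for rec in cnes:
        iv = rec.interval
        inside_gene = any(
            g.start <= iv.start and iv.end <= g.end for g in gene_spans
        )
        touches_exon = any(iv.intersection_length(x) >= 1 for x in exons)
        out.append(replace(rec, in_intron=inside_gene and not touches_exon))
    return out


def cne_summary_table(classified: dict[str, list[CNERecord]]) -> pd.DataFrame:
    """Counts of CNEs by cluster and phylogenetic group, with totals."""
    rows = []
    for cluster, recs in classified.items():
        counts = {g: 0 for g in GROUPS}
        for rec in recs:
            if rec.group in counts:
                counts[rec.group] += 1
        counts["total"] = sum(counts.values())
        rows.append({"cluster": cluster, **counts})
    df = pd.DataFrame(rows, columns=["cluster", *GROUPS, "total"])
    if not df.empty:
        total_row = {"cluster": "total"}
        for col in [*GROUPS, "total"]:
            total_row[col] = int(df[col].sum())
        df.loc[len(df)] = total_row
    return df
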