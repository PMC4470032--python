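"""Direct and inverted repeat discovery by sequence self-comparison.

A direct/inverted repeat is a pair of near-identical sequence copies
("arms") in the same/opposite orientation, separated by a spacer. Arms are
found library-free by exact k-mer seeding between the sequence and itself
(direct) or its reverse complement (inverted), followed by ungapped
extension with an identity-drop stop rule. Density statistics use interval
union semantics: a base covered by several hits counts once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seq_io import (
    GenomicInterval,
    UsageError,
    clip_intervals,
    merge_intervals,
    subtract_intervals,
    total_length,
)

logger = logging.getLogger("hoxcomp")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RepeatPair:
    """Two repeat arms with orientation, identity and spacer geometry.

    ``spacer`` is ``arm2.start - arm1.end`` on the forward strand for both
    orientations; ``arm_length`` is the shorter of the two arms.
    """

    arm1: GenomicInterval
    arm2: GenomicInterval
    orientation: str  # "direct" | "inverted"
    arm_identity: float
    arm_length: int
    spacer: int

    def __post_init__(self) -> None:
        if self.orientation not in {"direct", "inverted"}:
            raise UsageError(f"bad orientation {self.orientation!r}")
        if self.arm1.start >= self.arm2.start:
            raise UsageError("arm1 must start before arm2")
        if self.spacer < 0:
            raise UsageError("negative spacer (overlapping arms)")


@dataclass(frozen=True)
class RepeatSearchParams:
    """Thresholds for the self-comparison repeat search.

    ``min_arm_identity`` mirrors the 70 % minimum identity used for
    self-comparison screens of Hox clusters; ``long_arm_threshold`` is the
    100 bp arm size above which an inverted repeat counts as "long".
    """

    min_arm_identity: float = 70.0
    min_arm_length: int = 50
    long_arm_threshold: int = 100
    seed_length: int = 12
    max_spacer: int = 10_000

    def __post_init__(self) -> None:
        if self.seed_length > self.min_arm_length:
            raise UsageError("seed_length must be <= min_arm_length")
        if not 0 < self.min_arm_identity <= 100:
            raise UsageError("min_arm_identity out of range")


def _low_complexity(kmer: str) -> bool:
    return len(set(kmer)) <= 2


def extend_seed(
    match_at, seed_start: int, seed_len: int, lo: int, hi: int, min_identity: float
) -> tuple[int, int, int]:
    """Maximal-score ungapped extension of an exact seed along one pairing
    line.

    ``match_at(x)`` says whether offset ``x`` (in ``[lo, hi)``) pairs as a
    match; the seed occupies ``[seed_start, seed_start + seed_len)`` and is
    all matches. A match scores +1 and a mismatch -q/(1-q) with
    ``q = min_identity/100``, so stretches above the identity threshold
    raise the score and background lowers it; the span maximizing the
    cumulative score (ties toward the shorter span) is returned as
    ``(start, end, n_matches)``. Extension stops early once the running
    identity of the extension falls below ``q - 0.05`` (an X-drop-style
    bail-out on hopeless background).
    """
    q = min_identity / 100.0
    penalty = q / (1.0 - q) if q < 1.0 else 1e9
    floor = q - 0.05

    # Rightward from the seed end.
    best_end, best_right_score, best_right_matches = (
        seed_start + seed_len,
        float(seed_len),
        seed_len,
    )
    score, matches, length = float(seed_len), seed_len, seed_len
    x = seed_start + seed_len
    while x < hi:
        length += 1
        if match_at(x):
            matches += 1
            score += 1.0
            if score > best_right_score:
                best_right_score, best_end, best_right_matches = score, x + 1, matches
        else:
            score -= penalty
        if matches < floor * length:
            break
        x += 1

    # Leftward from the seed start, right end fixed.
    best_start, best_score, best_matches = (
        seed_start,
        best_right_score,
        best_right_matches,
    )
    score, matches, length = best_right_score, best_right_matches, best_end - seed_start
    x = seed_start - 1
    while x >= lo:
        length += 1
        if match_at(x):
            matches += 1
            score += 1.0
            if score > best_score:
                best_score, best_start, best_matches = score, x, matches
        else:
            score -= penalty
        if matches < floor * length:
            break
        x -= 1
    return best_start, best_end, best_matches


def _index_kmers(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer or _low_complexity(kmer):
            continue
        index.setdefault(kmer, []).append(i)
    return index


def _dedupe_and_merge(candidates: list[RepeatPair]) -> list[RepeatPair]:
    """Drop exact duplicates and merge pairs whose arms both overlap,
    keeping the pair with the longer (then higher-identity) arm."""
    kept: list[RepeatPair] = []
    for cand in sorted(
        candidates,
        key=lambda r: (-r.arm_length, -r.arm_identity, r.arm1.start, r.arm2.start),
    ):
        redundant = False
        for other in kept:
            if (
                cand.orientation == other.orientation
                and cand.arm1.overlaps(other.arm1)
                and cand.arm2.overlaps(other.arm2)
            ):
                redundant = True
                break
        if not redundant:
            kept.append(cand)
    kept.sort(key=lambda r: (r.arm1.start, r.arm2.start))
    return kept


def find_repeat_pairs(
    sequence: str,
    params: RepeatSearchParams = RepeatSearchParams(),
    seq_id: str = "seq",
) -> list[RepeatPair]:
    """Find direct and inverted repeat pairs by self-comparison.

    Direct hits live on a diagonal of the self-comparison: offset ``x``
    pairs with ``x + D``. Inverted hits live on an anti-diagonal: ``x``
    pairs with ``C - x`` (the partner base must be the complement). Exact
    ``seed_length``-mer matches between the sequence and itself (direct)
    or its reverse complement (inverted) locate the pairing line; the seed
    is then extended ungapped along the line and trimmed to the
    maximal-score span (see :func:`extend_seed`), so an arm above the
    identity threshold extends fully while flanking background is cut off.
    Hits are filtered by ``min_arm_length`` / ``min_arm_identity`` /
    ``max_spacer``, deduplicated (mirror seeds of the same pairing line
    collapse) and merged when both arms overlap, keeping the longer arm.
    Seeds whose k-mer has at most two distinct bases are skipped,
    suppressing homopolymer and dinucleotide artifacts.
    """
    n = len(sequence)
    k = params.seed_length
    if n < 2 * params.min_arm_length:
        logger.warning("sequence of %d bp too short for repeat search", n)
        return []
    sequence = sequence.upper()
    comp = sequence.translate(_COMPLEMENT)
    candidates: list[RepeatPair] = []
    index = _index_kmers(sequence, k)

    # Direct: diagonal offset D = j - i, pairing x <-> x + D.
    seen_dir: set[tuple[int, int, int]] = set()
    for positions in index.values():
        for ai in range(len(positions)):
            for bi in range(ai + 1, len(positions)):
                i, j = positions[ai], positions[bi]
                D = j - i
                if D > params.max_spacer + n:  # cannot satisfy spacer cap
                    continue

                def match_d(x: int, D: int = D) -> bool:
                    return (
                        sequence[x] == sequence[x + D] and sequence[x] != "N"
                    )

                x1, x2, matches = extend_seed(
                    match_d, i, k, 0, n - D, params.min_arm_identity
                )
                length = x2 - x1
                spacer = D - length
                key = (D, x1, x2)
                if key in seen_dir:
                    continue
                seen_dir.add(key)
                identity = 100.0 * matches / length
                if (
                    length < params.min_arm_length
                    or identity < params.min_arm_identity
                    or spacer < 0
                    or spacer > params.max_spacer
                ):
                    continue
                candidates.append(
                    RepeatPair(
                        GenomicInterval(seq_id, x1, x2),
                        GenomicInterval(seq_id, x1 + D, x2 + D),
                        "direct",
                        identity,
                        length,
                        spacer,
                    )
                )

    # Inverted: anti-diagonal C, pairing x <-> C - x with complementarity.
    rc = reverse_complement(sequence)
    seen_inv: set[tuple[int, int, int]] = set()
    for p in range(n - k + 1):
        kmer = rc[p : p + k]
        if kmer not in index:
            continue
        for i in index[kmer]:
            C = i + (n - 1 - p)
            lo = max(0, C - n + 1)
            hi = (C - 1) // 2 + 1  # keep x < C - x: arms must not overlap
            if i + k > hi:
                # seed crosses the palindrome centre; its mirror half is
                # redundant and any arm >= k long also has an uncrossed seed
                continue

            def match_i(x: int, C: int = C) -> bool:
                return sequence[x] == comp[C - x] and sequence[x] != "N"

            x1, x2, matches = extend_seed(
                match_i, i, k, lo, hi, params.min_arm_identity
            )
            key = (C, x1, x2)
            if key in seen_inv:
                continue
            seen_inv.add(key)
            length = x2 - x1
            identity = 100.0 * matches / length
            spacer = (C - x2 + 1) - x2
            if (
                length < params.min_arm_length
                or identity < params.min_arm_identity
                or spacer < 0
                or spacer > params.max_spacer
            ):
                continue
            candidates.append(
                RepeatPair(
                    GenomicInterval(seq_id, x1, x2),
                    GenomicInterval(seq_id, C - x2 + 1, C - x1 + 1),
                    "inverted",
                    identity,
                    length,
                    spacer,
                )
            )

    return _dedupe_and_merge(candidates)


def long_inverted_repeats(
    pairs: list[RepeatPair],
    params: RepeatSearchParams = RepeatSearchParams(),
) -> list[RepeatPair]:
    """Inverted pairs with arm length strictly above ``long_arm_threshold``,
    sorted by arm length descending."""
    out = [
        p
        for p in pairs
        if p.orientation == "inverted" and p.arm_length > params.long_arm_threshold
    ]
    out.sort(key=lambda p: -p.arm_length)
    return out


def repeat_density(
    repeat_hits: list[GenomicInterval], region_length: int
) -> float:
    """Percent of a region covered by the union of repeat hits."""
    if region_length <= 0:
        raise UsageError("region_length must be positive")
    return 100.0 * total_length(repeat_hits) / region_length


def restricted_density(
    hits: list[GenomicInterval],
    region: GenomicInterval,
    exclusions: list[GenomicInterval],
) -> float:
    """Repeat density over the region minus excluded intervals.

    Mirrors restricting a cross-species comparison to regions homologous to
    the sequence actually obtained: excluded intervals (e.g. regions
    homologous to unsequenced gaps) contribute to neither numerator nor
    denominator.
    """
    retained = subtract_intervals(region, exclusions)
    denom = sum(len(iv) for iv in retained)
    if denom <= 0:
        raise UsageError("empty retained region")
    clipped: list[GenomicInterval] = []
    for part in retained:
        clipped.extend(clip_intervals(hits, part))
    covered = total_length(clipped) if clipped else 0
    return 100.0 * covered / denom


def hotspot_table(
    hits: list[GenomicInterval],
    intergenic_regions: list[tuple[str, GenomicInterval]],
) -> pd.DataFrame:
    """Per-region repeat hit counts, covered bp and density.

    Regions must be non-overlapping; a hit is counted in every region it
    intersects (hits straddling a boundary are clipped for the bp columns).
    A final ``total`` row sums counts and bp over the named regions.
    """
    for i, (_, a) in enumerate(intergenic_regions):
        for _, b in intergenic_regions[i + 1 :]:
            if a.overlaps(b):
                raise UsageError(f"overlapping regions {a} / {b}")
    rows = []
    for name, region in intergenic_regions:
        clipped = clip_intervals(hits, region)
        covered = total_length(clipped) if clipped else 0
        count = sum(1 for iv in hits if iv.overlaps(region))
        rows.append(
            {
                "region": name,
                "start": region.start,
                "end": region.end,
                "n_hits": count,
                "repeat_bp": covered,
                "density_pct": 100.0 * covered / len(region) if len(region) else 0.0,
            }
        )
    df = pd.DataFrame(
        rows, columns=["region", "start", "end", "n_hits", "repeat_bp", "density_pct"]
    )
    total_len = sum(r["end"] - r["start"] for r in rows)
    total_bp = sum(r["repeat_bp"] for r in rows)
    df.loc[len(df)] = {
        "region": "total",
        "start": 0,
        "end": total_len,
        "n_hits": sum(r["n_hits"] for r in rows),
        "repeat_bp": total_bp,
        "density_pct": 100.0 * total_bp / total_len if total_len else 0.0,
    }
    return df


def repeat_pairs_table(pairs: list[RepeatPair]) -> pd.DataFrame:
    """Repeat pairs as a BEDPE-style table."""
    rows = [
        {
            "seq_id": p.arm1.seq_id,
            "arm1_start": p.arm1.start,
            "arm1_end": p.arm1.end,
            "arm2_start": p.arm2.start,
            "arm2_end": p.arm2.end,
            "orientation": p.orientation,
            "arm_identity": round(p.arm_identity, 2),
            "arm_length": p.arm_length,
            "spacer": p.spacer,
        }
        for p in pairs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "seq_id",
            "arm1_start",
            "arm1_end",
            "arm2_start",
            "arm2_end",
            "orientation",
            "arm_identity",
            "arm_length",
            "spacer",
        ],
    )
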