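"""CNE detection: alignment scores, windowed identity, calling, matching
and phylogenetic grouping."""

from functools import lru_cache

import numpy as np
import pytest

import hoxcomp as h
from hoxcomp.conservation import CNERecord, _match_columns
from hoxcomp.seq_io import UsageError
from hoxcomp.synthetic_data import ConfigError


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def optimal_affine_score(a, b, match=1.0, mismatch=-1.0, open_=-2.0, ext=-1.0):
    """Exhaustive optimal global affine-gap alignment score for tiny
    strings (recursive with memoization over (i, j, state))."""

    @lru_cache(maxsize=None)
    def best(i, j, state):
        # state: 0 = last column was a substitution, 1 = gap in b, 2 = gap in a
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            sub = match if a[i] == b[j] else mismatch
            options.append(sub + best(i + 1, j + 1, 0))
        if i < len(a):
            cost = ext if state == 1 else open_
            options.append(cost + best(i + 1, j, 1))
        if j < len(b):
            cost = ext if state == 2 else open_
            options.append(cost + best(i, j + 1, 2))
        return max(options)

    return best(0, 0, 0)


def score_alignment(aln, match=1.0, mismatch=-1.0, open_=-2.0, ext=-1.0):
    """Score a returned alignment directly from its gapped rows."""
    total, prev = 0.0, None
    for ca, cb in zip(aln.ref_aln, aln.other_aln):
        if ca == "-" or cb == "-":
            which = "a" if ca == "-" else "b"
            total += ext if prev == which else open_
            prev = which
        else:
            total += match if ca == cb else mismatch
            prev = None
    return total


def oracle_call_cnes(aln, thresholds, coding_mask=None):
    """Naive window-scan reimplementation of the CNE-calling definition:
    enumerate every window, merge covered columns with a boolean array,
    trim runs to match columns, then apply identity/length/mask rules."""
    L = len(aln.ref_aln)
    w = thresholds.min_length
    match = [
        aln.ref_aln[i] == aln.other_aln[i]
        and aln.ref_aln[i] not in "-.N"
        and aln.other_aln[i] not in "-.N"
        for i in range(L)
    ]
    covered = [False] * L
    for s in range(L - w + 1):
        ident = 100.0 * sum(match[s : s + w]) / w
        if ident >= thresholds.min_identity:
            for c in range(s, s + w):
                covered[c] = True
    ref_pos = []
    p = 0
    for c in range(L):
        ref_pos.append(p if aln.ref_aln[c] not in "-." else -1)
        if aln.ref_aln[c] not in "-.":
            p += 1

    def span_record(s, e):
        while s < e and not match[s]:
            s += 1
        while e > s and not match[e - 1]:
            e -= 1
        if e <= s:
            return None
        positions = [ref_pos[c] for c in range(s, e) if ref_pos[c] >= 0]
        if not positions:
            return None
        ident = 100.0 * sum(match[s:e]) / (e - s)
        iv = (positions[0], positions[-1] + 1)
        if ident < thresholds.min_identity or iv[1] - iv[0] < thresholds.min_length:
            return None
        return iv, ident

    intervals = []
    c = 0
    while c < L:
        if covered[c]:
            s = c
            while c < L and covered[c]:
                c += 1
            rec = span_record(s, c)
            if rec is None:
                continue
            iv, _ = rec
            pieces = [iv]
            if coding_mask:
                pieces = []
                remaining = [iv]
                for m in sorted(coding_mask, key=lambda x: x.start):
                    nxt = []
                    for (ps, pe) in remaining:
                        if m.end <= ps or m.start >= pe:
                            nxt.append((ps, pe))
                        else:
                            if ps < m.start:
                                nxt.append((ps, m.start))
                            if m.end < pe:
                                nxt.append((m.end, pe))
                    remaining = nxt
                pieces = remaining
            for ps, pe in pieces:
                cols = [
                    ci for ci in range(L) if ps <= ref_pos[ci] < pe
                ]
                rec2 = span_record(cols[0], cols[-1] + 1) if cols else None
                if rec2 is not None:
                    intervals.append(rec2[0])
        else:
            c += 1
    return sorted(intervals)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


class TestGlobalAlign:
    def test_identical_sequences_align_without_gaps(self, rng):
        seq = h.random_sequence(rng, 100)
        aln = h.global_align(seq, seq)
        assert aln.ref_aln == aln.other_aln == seq

    @pytest.mark.parametrize(
        "a, b",
        [
            ("ACGT", "ACT"),
            ("ACGTACG", "TACGT"),
            ("AAAA", "TTTT"),
            ("ACGTA", "A"),
            ("GATTACA", "GCATGCA"),
        ],
    )
    def test_score_matches_exhaustive_enumeration(self, a, b):
        aln = h.global_align(a, b, gap_open=-2.0, gap_extend=-1.0)
        assert score_alignment(aln) == optimal_affine_score(a, b)

    def test_acgt_vs_act_scores_one(self):
        # match 1, mismatch -1, open -2, extend -1: three matches and one
        # opened gap
        assert optimal_affine_score("ACGT", "ACT") == 1.0
        aln = h.global_align("ACGT", "ACT", gap_open=-2.0, gap_extend=-1.0)
        assert score_alignment(aln) == 1.0

    def test_single_mismatch_column(self):
        aln = h.global_align("A", "T")
        assert (aln.ref_aln, aln.other_aln) == ("A", "T")

    def test_empty_sequence_rejected(self):
        with pytest.raises(UsageError):
            h.global_align("", "ACGT")

    def test_coord_map_recovers_reference(self, rng):
        a = h.random_sequence(rng, 200)
        b = h.random_sequence(rng, 180)
        aln = h.global_align(a, b)
        assert aln.ref_sequence == a
        for c, p in enumerate(aln.ref_coord_map):
            if p >= 0:
                assert aln.ref_aln[c] == a[p]


class TestWindowedIdentity:
    def test_identical_rows_are_100(self):
        aln = h.alignment_from_strings("ACGT" * 25, "ACGT" * 25)
        assert (h.windowed_identity(aln, 50) == 100.0).all()

    def test_ten_mismatches_in_fifty_is_80(self):
        ref = "A" * 50
        other = "C" * 10 + "A" * 40
        aln = h.alignment_from_strings(ref, other)
        assert h.windowed_identity(aln, 50)[0] == 80.0

    def test_all_gap_other_row_is_0(self):
        aln = h.alignment_from_strings("ACGTACGT", "--------")
        assert (h.windowed_identity(aln, 4) == 0.0).all()

    def test_window_validation(self):
        aln = h.alignment_from_strings("ACGT", "ACGT")
        with pytest.raises(UsageError):
            h.windowed_identity(aln, 0)
        with pytest.raises(UsageError):
            h.windowed_identity(aln, 5)


# ---------------------------------------------------------------------------
# CNE calling
# ---------------------------------------------------------------------------


def random_alignment_with_blocks(rng, n_cols=1500, n_blocks=2, p_bg=0.45):
    """Gapless random alignment with planted high-identity blocks."""
    ref = list(h.random_sequence(rng, n_cols))
    other = []
    block_cols = np.zeros(n_cols, dtype=bool)
    candidates = np.arange(0, max(1, n_cols - 160), 250)
    n_blocks = min(n_blocks, len(candidates))
    starts = rng.choice(candidates, n_blocks, replace=False)
    for s in starts:
        block_cols[s : s + 150] = True
    for i in range(n_cols):
        p_same = 0.92 if block_cols[i] else p_bg
        if rng.random() < p_same:
            other.append(ref[i])
        else:
            other.append("ACGT"[(("ACGT".index(ref[i])) + int(rng.integers(1, 4))) % 4])
    return h.alignment_from_strings("".join(ref), "".join(other)), block_cols


class TestCallCnes:
    def test_planted_element_recovered(self, rng):
        aln, block_cols = random_alignment_with_blocks(rng, n_blocks=1, p_bg=0.3)
        recs = h.call_cnes(aln)
        assert len(recs) >= 1
        s = int(np.flatnonzero(block_cols)[0])
        best = max(
            recs,
            key=lambda r: min(r.interval.end, s + 150) - max(r.interval.start, s),
        )
        overlap = min(best.interval.end, s + 150) - max(best.interval.start, s)
        # boundary windows legitimately extend a call a little past the
        # planted block, so require high but not exact reciprocal overlap
        assert overlap / 150 >= 0.9
        assert overlap / len(best.interval) >= 0.5

    def test_uniform_half_identity_yields_nothing(self):
        ref = "ACGT" * 100
        other = ("AC" + "TA") * 100  # alternating match/mismatch: 50%
        aln = h.alignment_from_strings(ref, other)
        assert h.call_cnes(aln) == []

    def test_region_inside_coding_mask_dropped(self, rng):
        aln, block_cols = random_alignment_with_blocks(rng, n_blocks=1)
        s = int(np.flatnonzero(block_cols)[0])
        mask = [h.GenomicInterval("ref", max(0, s - 60), s + 210)]
        recs = h.call_cnes(aln, coding_mask=mask)
        for rec in recs:
            assert rec.interval.intersection_length(mask[0]) == 0

    def test_emitted_records_satisfy_thresholds_and_order(self, rng):
        thresholds = h.ConservationThresholds()
        for rep in range(10):
            aln, _ = random_alignment_with_blocks(rng, n_blocks=3, p_bg=0.5)
            recs = h.call_cnes(aln, thresholds)
            for rec in recs:
                assert rec.identity >= thresholds.min_identity
                assert len(rec.interval) >= thresholds.min_length
            starts = [r.interval.start for r in recs]
            assert starts == sorted(starts)
            for r1, r2 in zip(recs, recs[1:]):
                assert r1.interval.end <= r2.interval.start

    def test_matches_window_scan_oracle(self, rng):
        """On small alignments the seed-merge-trim caller must equal the
        naive all-window oracle exactly."""
        thresholds = h.ConservationThresholds()
        for rep in range(25):
            aln, _ = random_alignment_with_blocks(
                rng,
                n_cols=int(rng.integers(300, 2000)),
                n_blocks=int(rng.integers(0, 3)) or 1,
                p_bg=float(rng.uniform(0.3, 0.55)),
            )
            mask = None
            if rep % 3 == 0:
                s = int(rng.integers(0, 1000))
                mask = [h.GenomicInterval("ref", s, s + 200)]
            got = [
                (r.interval.start, r.interval.end)
                for r in h.call_cnes(aln, thresholds, mask)
            ]
            assert got == oracle_call_cnes(aln, thresholds, mask)

    def test_gap_heavy_alignment_uses_reference_length(self):
        """A conserved stretch interrupted by gaps must satisfy the length
        threshold in reference bases, not alignment columns."""
        ref = "ACGTACGTAC" * 6  # 60 bases
        other = ref[:30] + "-" * 5 + ref[30:]
        ref_aln = ref[:30] + "-" * 5 + ref[30:]
        # build a consistent pair: insert gap in ref row against extra bases
        aln = h.alignment_from_strings(ref_aln, other[:30] + "ACGTA" + other[35:])
        recs = h.call_cnes(aln, h.ConservationThresholds(min_identity=65, min_length=50))
        assert all(len(r.interval) >= 50 for r in recs)


# ---------------------------------------------------------------------------
# Matching and grouping
# ---------------------------------------------------------------------------


def make_rec(start, end, seq_id="ref"):
    return CNERecord(
        interval=h.GenomicInterval(seq_id, start, end), identity=80.0, aln_span=end - start
    )


class TestMatchCnes:
    def test_identical_sets_match_one_to_one(self, rng):
        seq = h.random_sequence(rng, 500)
        aln = h.global_align(seq, seq)
        cnes = [make_rec(10, 80), make_rec(200, 290)]
        out = h.match_cnes(cnes, cnes, aln)
        assert out == [(0, [0]), (1, [1])]

    def test_disjoint_sets_do_not_match(self, rng):
        seq = h.random_sequence(rng, 500)
        aln = h.global_align(seq, seq)
        assert h.match_cnes([make_rec(0, 50)], [make_rec(300, 400)], aln) == []

    def test_one_ref_cne_spanning_two_other_cnes(self, rng):
        seq = h.random_sequence(rng, 500)
        aln = h.global_align(seq, seq)
        out = h.match_cnes(
            [make_rec(100, 300)], [make_rec(120, 160), make_rec(220, 260)], aln
        )
        assert out == [(0, [0, 1])]


class TestClassifyGroups:
    hits = {
        "elephant_shark": [h.GenomicInterval("ref", 0, 100)],
        "spotted_gar": [h.GenomicInterval("ref", 0, 100), h.GenomicInterval("ref", 200, 300)],
        "coelacanth": [h.GenomicInterval("ref", 0, 100), h.GenomicInterval("ref", 400, 500)],
    }
    presence = {
        "gnathostome": {"elephant_shark"},
        "osteichthyan": {"spotted_gar"},
        "sarcopterygian": {"coelacanth"},
    }

    def test_deepest_group_wins(self):
        recs = h.classify_cne_groups([make_rec(10, 90)], self.presence, self.hits)
        assert recs[0].group == "gnathostome"

    def test_gar_only_is_osteichthyan(self):
        recs = h.classify_cne_groups([make_rec(210, 280)], self.presence, self.hits)
        assert recs[0].group == "osteichthyan"

    def test_coelacanth_only_is_sarcopterygian(self):
        recs = h.classify_cne_groups([make_rec(410, 480)], self.presence, self.hits)
        assert recs[0].group == "sarcopterygian"

    def test_no_hit_falls_through_to_tetrapod(self):
        recs = h.classify_cne_groups([make_rec(600, 700)], self.presence, self.hits)
        assert recs[0].group == "tetrapod"

    def test_each_cne_gets_exactly_one_group(self):
        recs = h.classify_cne_groups(
            [make_rec(10, 90), make_rec(210, 280), make_rec(600, 700)],
            self.presence,
            self.hits,
        )
        assert [r.group for r in recs] == [
            "gnathostome",
            "osteichthyan",
            "tetrapod",
        ]

    def test_unknown_clade_label_rejected(self):
        with pytest.raises(ConfigError):
            h.classify_cne_groups([], {"mystery_clade": {"x"}}, {})


class TestSummaryAndIntrons:
    def test_empty_input_gives_empty_table(self):
        df = h.cne_summary_table({})
        assert df.empty

    def test_counts_are_additive(self):
        recs = [make_rec(0, 60)] * 3 + [make_rec(100, 160)] * 2
        recs = [
            CNERecord(r.interval, r.identity, r.aln_span, group=g)
            for r, g in zip(recs, ["gnathostome"] * 3 + ["tetrapod"] * 2)
        ]
        df = h.cne_summary_table({"HoxA": recs}).set_index("cluster")
        assert df.loc["HoxA", "gnathostome"] == 3
        assert df.loc["HoxA", "tetrapod"] == 2
        assert df.loc["HoxA", "total"] == 5
        assert df.loc["total", "total"] == 5

    def test_intron_flagging(self):
        genes = [h.GenomicInterval("ref", 0, 1000)]
        exons = [h.GenomicInterval("ref", 0, 100), h.GenomicInterval("ref", 500, 600)]
        recs = h.flag_intronic(
            [make_rec(200, 300), make_rec(550, 650), make_rec(1200, 1300)],
            genes,
            exons,
        )
        assert [r.in_intron for r in recs] == [True, False, False]
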