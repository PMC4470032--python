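"""Synthetic multi-species Hox-like cluster sequences with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume: a root sequence evolved down a fixed species tree under the
Jukes–Cantor model with lineage-specific rate multipliers, low-divergence
conserved noncoding elements (CNEs) with clade-specific retention or loss,
strongly conserved exons, and direct/inverted/interspersed repeats inserted
per species at known coordinates. Every planted element's realized interval
is recorded so detection stages can be scored exactly.

Branch lengths are in expected substitutions per site. A CNE with
``conservation_scaling`` *s* evolves at *s* times the branch length; exons
evolve at 0.1 times the most conserved CNE scaling (or 0.1 if no CNEs are
planted). A species' rate multiplier applies to its terminal branch;
internal branches use multiplier 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .repeats import RepeatPair, reverse_complement
from .seq_io import AnnotatedCluster, GenomicInterval

BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


class ConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


def encode(seq: str) -> np.ndarray:
    arr = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ConfigError("sequence contains characters outside ACGT")
    return arr


def decode(arr: np.ndarray) -> str:
    return _BASE_ARR[arr].tobytes().decode()


def random_sequence(rng: np.random.Generator, n: int) -> str:
    return decode(rng.integers(0, 4, n, dtype=np.uint8))


def jc_expected_diff(d: float) -> float:
    """Expected proportion of differing sites after evolving a total path of
    ``d`` substitutions/site under Jukes–Cantor: (3/4)(1 - e^(-4d/3))."""
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each base to a different base with probability ``rate``."""
    arr = encode(seq)
    hit = rng.random(arr.size) < rate
    shifts = rng.integers(1, 4, arr.size, dtype=np.uint8)
    arr = np.where(hit, (arr + shifts) % 4, arr).astype(np.uint8)
    return decode(arr)


def simulate_triplet_genes(
    n_genes: int,
    n_sites: int,
    branch_a: float,
    branch_b: float,
    branch_out: float = 0.5,
    internal: float = 0.1,
    seed: int = 0,
    species: tuple[str, str, str] = ("A", "B", "O"),
):
    """Simulate gene alignments for relative-rate testing.

    Topology ((A, B), O): a root sequence evolves to the outgroup over
    ``branch_out`` and to an internal node over ``internal``; the ingroups
    A and B diverge from that node over ``branch_a`` / ``branch_b``
    (substitutions/site, Jukes–Cantor). Returns a list of
    :class:`~hoxcomp.rrt.TripletAlignment`, one per gene.
    """
    from .rrt import TripletAlignment

    rng = np.random.default_rng(seed)
    shape = (n_genes, n_sites)
    root = rng.integers(0, 4, shape, dtype=np.uint8)

    def branch(parent: np.ndarray, d: float) -> np.ndarray:
        p_change = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
        hit = rng.random(shape) < p_change
        shifts = rng.integers(1, 4, shape, dtype=np.uint8)
        return np.where(hit, (parent + shifts) % 4, parent).astype(np.uint8)

    out = branch(root, branch_out)
    node = branch(root, internal)
    a = branch(node, branch_a)
    b = branch(node, branch_b)
    sp_a, sp_b, sp_o = species
    return [
        TripletAlignment(
            gene=f"gene{i:04d}",
            ingroup_a=decode(a[i]),
            ingroup_b=decode(b[i]),
            outgroup=decode(out[i]),
            species_a=sp_a,
            species_b=sp_b,
            outgroup_name=sp_o,
        )
        for i in range(n_genes)
    ]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CNESpec:
    """A planted conserved element: ``retained_in`` is the set of species
    that keep it; in all others the interval is re-randomized (loss)."""

    position: int
    length: int
    conservation_scaling: float = 0.05
    retained_in: frozenset[str] | None = None  # None = all species

    def __post_init__(self) -> None:
        if not 0 < self.conservation_scaling <= 1:
            raise ConfigError("conservation_scaling must be in (0, 1]")
        if self.length < 1:
            raise ConfigError("CNE length must be >= 1")


@dataclass(frozen=True)
class RepeatSpec:
    kind: str  # "direct" | "inverted" | "interspersed"
    arm_length: int
    spacer_length: int
    insert_position: int
    per_copy_mutation_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in {"direct", "inverted", "interspersed"}:
            raise ConfigError(f"unknown repeat kind {self.kind!r}")
        if self.arm_length < 1:
            raise ConfigError("arm_length must be >= 1")
        if self.spacer_length < 0 or self.per_copy_mutation_rate < 0:
            raise ConfigError("negative spacer or mutation rate")

    @property
    def footprint(self) -> int:
        if self.kind == "interspersed":
            return self.arm_length
        return 2 * self.arm_length + self.spacer_length


@dataclass(frozen=True)
class ExonSpec:
    position: int
    length: int


@dataclass
class SimulationConfig:
    tree: str  # Newick with branch lengths (substitutions/site)
    rate_multipliers: dict[str, float] = field(default_factory=dict)
    seq_length: int = 20_000
    cne_spec: list[CNESpec] = field(default_factory=list)
    repeat_spec: list[RepeatSpec] = field(default_factory=list)
    exon_spec: list[ExonSpec] = field(default_factory=list)
    cluster_name: str = "HoxA"
    seed: int = 0

    def validate(self, species: list[str]) -> None:
        spans: list[tuple[int, int, str]] = []
        for c in self.cne_spec:
            spans.append((c.position, c.position + c.length, "CNE"))
            if c.retained_in is not None and not set(c.retained_in) <= set(species):
                raise ConfigError(
                    f"retained_in references unknown species {set(c.retained_in) - set(species)}"
                )
        for e in self.exon_spec:
            spans.append((e.position, e.position + e.length, "exon"))
        for r in self.repeat_spec:
            # insertion points are zero-width in ancestral coordinates
            spans.append((r.insert_position, r.insert_position, "repeat"))
        for s, e, kind in spans:
            if s < 0 or e > self.seq_length:
                raise ConfigError(f"{kind} at [{s},{e}) outside sequence")
        spans.sort()
        for (s1, e1, k1), (s2, e2, k2) in zip(spans, spans[1:]):
            if s2 < e1 or (s2 == s1 and e2 == e1):
                raise ConfigError(
                    f"planted {k1} [{s1},{e1}) overlaps {k2} [{s2},{e2})"
                )
        for mult in self.rate_multipliers.values():
            if mult <= 0:
                raise ConfigError("rate multipliers must be positive")


@dataclass
class GroundTruth:
    clusters: dict[str, AnnotatedCluster]
    cne_intervals: dict[str, list[GenomicInterval]]
    exon_intervals: dict[str, list[GenomicInterval]]
    repeat_pairs: dict[str, list[RepeatPair]]
    repeat_hits: dict[str, list[GenomicInterval]]
    substitutions_per_branch: dict[str, int]


# ---------------------------------------------------------------------------
# Planting primitives
# ---------------------------------------------------------------------------


_COMP_ONE = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_GUARD = 12  # bp of enforced mismatch beyond each planted arm


def _base_avoiding(*forbidden: str) -> str:
    for b in BASES:
        if b not in forbidden:
            return b
    raise AssertionError("unreachable: four bases, at most three exclusions")


def _depalindromize(spacer: str) -> str:
    """Break every self-complementary pairing t <-> len-1-t so the planted
    inverted-repeat arms cannot extend through the spacer."""
    s = list(spacer)
    for t in range(len(s) // 2):
        u = len(s) - 1 - t
        if s[t] == _COMP_ONE[s[u]]:
            s[t] = _base_avoiding(_COMP_ONE[s[u]])
    return "".join(s)


def _plant_repeat(
    sequence: str, spec: RepeatSpec, rng: np.random.Generator, seq_id: str
) -> tuple[str, RepeatPair | None, list[GenomicInterval]]:
    """Insert one repeat unit; returns new sequence, optional pair record
    and the hit intervals (arm copies) in post-insertion coordinates.

    Flanking bases are adjusted (guard zone) so the planted arms cannot
    extend by chance into the surrounding background, making the planted
    geometry exactly recoverable for noise-free insertions; planted
    elements should therefore sit at least the guard width apart.
    """
    pos = spec.insert_position
    if pos < 0 or pos > len(sequence):
        raise ConfigError(f"insert position {pos} out of bounds")
    arm = random_sequence(rng, spec.arm_length)
    if spec.kind == "interspersed":
        copy = mutate_sequence(arm, spec.per_copy_mutation_rate, rng)
        new = sequence[:pos] + copy + sequence[pos:]
        iv = GenomicInterval(seq_id, pos, pos + spec.arm_length)
        return new, None, [iv]
    arm2 = arm if spec.kind == "direct" else reverse_complement(arm)
    copy1 = mutate_sequence(arm, spec.per_copy_mutation_rate, rng)
    copy2 = mutate_sequence(arm2, spec.per_copy_mutation_rate, rng)
    spacer = random_sequence(rng, spec.spacer_length)

    background = list(sequence)
    sp = list(spacer)
    S = spec.spacer_length
    if spec.kind == "inverted":
        sp = list(_depalindromize("".join(sp)))
        # Outer guard: the anti-diagonal pairs background before the unit
        # with background after it; force mismatches there.
        for g in range(_GUARD):
            b_pos, a_pos = pos - 1 - g, pos + g
            if b_pos < 0 or a_pos >= len(background):
                break
            partner = _COMP_ONE[background[b_pos]]
            if background[a_pos] == partner:
                background[a_pos] = _base_avoiding(partner)
    else:  # direct
        # Guard within the spacer: on the diagonal, positions just past
        # arm1 pair with background after the unit and positions just
        # before arm2 pair with background before it; force mismatches.
        for idx in range(S):
            avoid = set()
            if idx < _GUARD and pos + idx < len(background):
                avoid.add(background[pos + idx])
            if S - 1 - idx < _GUARD and pos - 1 - (S - 1 - idx) >= 0:
                avoid.add(background[pos - 1 - (S - 1 - idx)])
            if sp[idx] in avoid:
                sp[idx] = _base_avoiding(*avoid)

    unit = copy1 + "".join(sp) + copy2
    new = "".join(background[:pos]) + unit + "".join(background[pos:])
    iv1 = GenomicInterval(seq_id, pos, pos + spec.arm_length)
    iv2 = GenomicInterval(
        seq_id,
        pos + spec.arm_length + spec.spacer_length,
        pos + 2 * spec.arm_length + spec.spacer_length,
    )
    n_same = sum(a == b for a, b in zip(copy1, copy2 if spec.kind == "direct" else reverse_complement(copy2)))
    identity = 100.0 * n_same / spec.arm_length
    pair = RepeatPair(
        iv1, iv2, spec.kind, identity, spec.arm_length, spec.spacer_length
    )
    return new, pair, [iv1, iv2]


def plant_inverted_repeat(
    sequence: str,
    arm_length: int,
    spacer_length: int,
    position: int,
    seed: int,
    seq_id: str = "seq",
) -> tuple[str, RepeatPair]:
    """Insert ``arm + spacer + reverse_complement(arm)`` at ``position``.

    The arm and spacer are freshly randomized from ``seed``; the returned
    :class:`RepeatPair` carries the exact post-insertion coordinates.
    """
    if arm_length < 1:
        raise ConfigError("arm_length must be >= 1")
    if position < 0 or position + 2 * arm_length + spacer_length > len(sequence):
        raise ConfigError("insertion out of bounds")
    spec = RepeatSpec("inverted", arm_length, spacer_length, position)
    rng = np.random.default_rng(seed)
    new, pair, _ = _plant_repeat(sequence, spec, rng, seq_id)
    assert pair is not None
    return new, pair


def plant_direct_repeat(
    sequence: str,
    arm_length: int,
    spacer_length: int,
    position: int,
    seed: int,
    seq_id: str = "seq",
) -> tuple[str, RepeatPair]:
    """Insert ``arm + spacer + arm`` at ``position`` (direct orientation)."""
    if arm_length < 1:
        raise ConfigError("arm_length must be >= 1")
    if position > len(sequence) or position < 0:
        raise ConfigError("insertion out of bounds")
    spec = RepeatSpec("direct", arm_length, spacer_length, position)
    rng = np.random.default_rng(seed)
    new, pair, _ = _plant_repeat(sequence, spec, rng, seq_id)
    assert pair is not None
    return new, pair


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------


def _site_scalings(config: SimulationConfig) -> np.ndarray:
    scaling = np.ones(config.seq_length)
    cne_floor = min(
        (c.conservation_scaling for c in config.cne_spec), default=1.0
    )
    exon_scaling = 0.1 * cne_floor
    for c in config.cne_spec:
        scaling[c.position : c.position + c.length] = c.conservation_scaling
    for e in config.exon_spec:
        scaling[e.position : e.position + e.length] = exon_scaling
    return scaling


def _evolve(
    parent: np.ndarray,
    distance_per_site: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """One Jukes–Cantor branch: per-site change probability
    (3/4)(1 - e^(-4d/3)); changed sites move uniformly to another base."""
    p_change = 0.75 * (1.0 - np.exp(-4.0 * distance_per_site / 3.0))
    hit = rng.random(parent.size) < p_change
    shifts = rng.integers(1, 4, parent.size, dtype=np.uint8)
    child = np.where(hit, (parent + shifts) % 4, parent).astype(np.uint8)
    return child, int(hit.sum())


def simulate_clusters(config: SimulationConfig) -> GroundTruth:
    """Simulate one cluster per tree tip and return it with ground truth.

    The root sequence is uniform over ACGT; each branch applies Jukes–Cantor
    substitutions scaled per site (CNE/exon conservation) and per lineage
    (terminal-branch rate multipliers). CNEs absent from a species'
    ``retained_in`` set are overwritten with fresh random sequence in that
    species, keeping coordinates comparable across species. Repeats are then
    inserted per species; recorded CNE/exon coordinates are shifted past the
    insertions. Deterministic for a fixed seed.
    """
    tree = dendropy.Tree.get(data=config.tree, schema="newick")
    species = sorted(
        leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon
    )
    if not set(config.rate_multipliers) <= set(species):
        raise ConfigError(
            f"rate multipliers for unknown species "
            f"{set(config.rate_multipliers) - set(species)}"
        )
    config.validate(species)

    ss = np.random.SeedSequence(config.seed)
    evo_rng = np.random.default_rng(ss.spawn(1)[0])
    species_rngs = {
        sp: np.random.default_rng(child)
        for sp, child in zip(species, np.random.SeedSequence((config.seed, 1)).spawn(len(species)))
    }

    scaling = _site_scalings(config)
    root_seq = evo_rng.integers(0, 4, config.seq_length, dtype=np.uint8)

    tip_seqs: dict[str, np.ndarray] = {}
    subs_per_branch: dict[str, int] = {}
    node_seq = {id(tree.seed_node): root_seq}
    internal_counter = 0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = node_seq[id(node.parent_node)]
        blen = node.edge.length or 0.0
        is_leaf = node.is_leaf()
        label = (
            node.taxon.label
            if is_leaf and node.taxon
            else f"internal_{internal_counter}"
        )
        if not is_leaf:
            internal_counter += 1
        mult = config.rate_multipliers.get(label, 1.0) if is_leaf else 1.0
        child_seq, n_subs = _evolve(parent_seq, blen * mult * scaling, evo_rng)
        node_seq[id(node)] = child_seq
        subs_per_branch[label] = n_subs
        if is_leaf:
            tip_seqs[label] = child_seq

    clusters: dict[str, AnnotatedCluster] = {}
    cne_intervals: dict[str, list[GenomicInterval]] = {}
    exon_intervals: dict[str, list[GenomicInterval]] = {}
    repeat_pairs: dict[str, list[RepeatPair]] = {}
    repeat_hits: dict[str, list[GenomicInterval]] = {}

    repeat_specs = sorted(
        config.repeat_spec, key=lambda r: r.insert_position, reverse=True
    )

    for sp in species:
        rng = species_rngs[sp]
        arr = tip_seqs[sp].copy()
        retained: list[CNESpec] = []
        for c in config.cne_spec:
            if c.retained_in is None or sp in c.retained_in:
                retained.append(c)
            else:
                arr[c.position : c.position + c.length] = rng.integers(
                    0, 4, c.length, dtype=np.uint8
                )
        seq = decode(arr)

        pairs: list[RepeatPair] = []
        hits: list[GenomicInterval] = []
        # Insert right-to-left so earlier insert positions stay valid.
        for spec in repeat_specs:
            seq, pair, ivs = _plant_repeat(seq, spec, rng, sp)
            if pair is not None:
                pairs.append(pair)
            hits.extend(ivs)
        # Shift records of repeats inserted to the right of earlier inserts.
        offsets = sorted(
            (r.insert_position, r.footprint) for r in config.repeat_spec
        )

        def _shift(point: int, *, at_start: bool = False) -> int:
            # An insertion at exactly an interval's start pushes the
            # interval right; one at its end does not.
            off = 0
            for pos, foot in offsets:
                if pos < point or (at_start and pos == point):
                    off += foot
            return point + off

        def shift_iv(iv: GenomicInterval) -> GenomicInterval:
            return GenomicInterval(
                sp, _shift(iv.start, at_start=True), _shift(iv.end)
            )

        fixed_pairs = []
        fixed_hits = []
        for spec, pair in zip(
            [r for r in repeat_specs if r.kind != "interspersed"], pairs
        ):
            delta = _shift(spec.insert_position) - spec.insert_position
            fixed_pairs.append(
                RepeatPair(
                    GenomicInterval(sp, pair.arm1.start + delta, pair.arm1.end + delta),
                    GenomicInterval(sp, pair.arm2.start + delta, pair.arm2.end + delta),
                    pair.orientation,
                    pair.arm_identity,
                    pair.arm_length,
                    pair.spacer,
                )
            )
        for spec in repeat_specs:
            delta = _shift(spec.insert_position) - spec.insert_position
            base = spec.insert_position + delta
            if spec.kind == "interspersed":
                fixed_hits.append(GenomicInterval(sp, base, base + spec.arm_length))
            else:
                fixed_hits.append(GenomicInterval(sp, base, base + spec.arm_length))
                fixed_hits.append(
                    GenomicInterval(
                        sp,
                        base + spec.arm_length + spec.spacer_length,
                        base + 2 * spec.arm_length + spec.spacer_length,
                    )
                )

        cnes = [
            shift_iv(GenomicInterval(sp, c.position, c.position + c.length))
            for c in retained
        ]
        exons = [
            shift_iv(GenomicInterval(sp, e.position, e.position + e.length))
            for e in config.exon_spec
        ]
        features = [(iv, "exon") for iv in exons] + [
            (iv, "repeat") for iv in fixed_hits
        ]
        clusters[sp] = AnnotatedCluster(sp, config.cluster_name, seq, features)
        cne_intervals[sp] = sorted(cnes)
        exon_intervals[sp] = sorted(exons)
        repeat_pairs[sp] = sorted(fixed_pairs, key=lambda p: p.arm1.start)
        repeat_hits[sp] = sorted(fixed_hits)

    return GroundTruth(
        clusters=clusters,
        cne_intervals=cne_intervals,
        exon_intervals=exon_intervals,
        repeat_pairs=repeat_pairs,
        repeat_hits=repeat_hits,
        substitutions_per_branch=subs_per_branch,
    )
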