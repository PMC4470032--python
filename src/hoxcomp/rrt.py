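"""Tajima's relative rate test (RRT) and rate-order synthesis.

For two ingroup lineages A and B and an outgroup O, Tajima's test counts
the aligned sites where exactly one ingroup differs from the other two:
``m_A`` (A differs, B = O) and ``m_B`` (B differs, A = O). Under rate
constancy E[m_A] = E[m_B]; the statistic (m_A - m_B)^2 / (m_A + m_B) is
compared with chi-square on 1 degree of freedom (no continuity
correction). Sites with gaps or unknown residues in any of the three rows
are excluded beforehand.

Batteries over gene sets produce, per gene, a partial "slower-than" order
over the species drawn as a Hasse diagram: a directed edge runs from the
faster to the slower species for every comparison with p <= 0.05, tiered as
high (p <= 0.01) or significant (0.01 < p <= 0.05), and the edge set is
transitively reduced. Genome-wide runs over three ingroups summarize how
many genes each species is significantly slower/faster than each other.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .seq_io import FormatError, UsageError

logger = logging.getLogger("hoxcomp")

NT_AMBIGUOUS = frozenset("N-.?")
AA_AMBIGUOUS = frozenset("XBZJ-.?*")

TIER_HIGH = "high"  # p <= 0.01
TIER_SIG = "significant"  # 0.01 < p <= 0.05
TIER_NS = "ns"


def significance_tier(p: float) -> str:
    if p <= 0.01:
        return TIER_HIGH
    if p <= 0.05:
        return TIER_SIG
    return TIER_NS


@dataclass(frozen=True)
class TripletAlignment:
    gene: str
    ingroup_a: str
    ingroup_b: str
    outgroup: str
    alphabet: str = "nucleotide"  # "nucleotide" | "protein"
    species_a: str = "A"
    species_b: str = "B"
    outgroup_name: str = "O"

    def __post_init__(self) -> None:
        if self.alphabet not in {"nucleotide", "protein"}:
            raise UsageError(f"unknown alphabet {self.alphabet!r}")
        if not (
            len(self.ingroup_a) == len(self.ingroup_b) == len(self.outgroup)
        ):
            raise FormatError("triplet rows differ in length")


@dataclass(frozen=True)
class RRTResult:
    gene: str
    species_a: str
    species_b: str
    outgroup: str
    n_sites_used: int
    m_a: int
    m_b: int
    chi2: float
    p: float
    significance: str
    cluster: str = ""

    @property
    def slower(self) -> str | None:
        """The significantly slower species, or None when not significant
        (the species with fewer unique substitutions evolves more slowly)."""
        if self.significance == TIER_NS or self.m_a == self.m_b:
            return None
        return self.species_a if self.m_a < self.m_b else self.species_b

    @property
    def faster(self) -> str | None:
        if self.slower is None:
            return None
        return self.species_b if self.slower == self.species_a else self.species_a


def strip_ambiguous_columns(triplet: TripletAlignment) -> TripletAlignment:
    """Remove every column holding a gap or ambiguity symbol in any row
    (complete deletion). Nucleotide ambiguity: N; protein: X/B/Z/J."""
    ambiguous = NT_AMBIGUOUS if triplet.alphabet == "nucleotide" else AA_AMBIGUOUS
    keep = [
        i
        for i in range(len(triplet.ingroup_a))
        if not (
            {triplet.ingroup_a[i], triplet.ingroup_b[i], triplet.outgroup[i]}
            & ambiguous
        )
    ]
    take = lambda s: "".join(s[i] for i in keep)
    return TripletAlignment(
        gene=triplet.gene,
        ingroup_a=take(triplet.ingroup_a),
        ingroup_b=take(triplet.ingroup_b),
        outgroup=take(triplet.outgroup),
        alphabet=triplet.alphabet,
        species_a=triplet.species_a,
        species_b=triplet.species_b,
        outgroup_name=triplet.outgroup_name,
    )


def tajima_rrt(triplet: TripletAlignment, cluster: str = "") -> RRTResult:
    """Tajima's relative rate test on a (stripped) triplet alignment.

    m_a counts sites where only ingroup A differs (B equals O), m_b the
    mirror count. chi2 = (m_a - m_b)^2 / (m_a + m_b) with p from
    chi-square(1); when m_a + m_b = 0 the test is uninformative and p = 1.
    """
    a = np.frombuffer(triplet.ingroup_a.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(triplet.ingroup_b.upper().encode(), dtype=np.uint8)
    o = np.frombuffer(triplet.outgroup.upper().encode(), dtype=np.uint8)
    m_a = int(np.count_nonzero((a != b) & (a != o) & (b == o)))
    m_b = int(np.count_nonzero((b != a) & (b != o) & (a == o)))
    total = m_a + m_b
    if total == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = (m_a - m_b) ** 2 / total
        p = float(stats.chi2.sf(chi2, df=1))
    return RRTResult(
        gene=triplet.gene,
        species_a=triplet.species_a,
        species_b=triplet.species_b,
        outgroup=triplet.outgroup_name,
        n_sites_used=a.size,
        m_a=m_a,
        m_b=m_b,
        chi2=float(chi2),
        p=p,
        significance=significance_tier(p),
        cluster=cluster,
    )


def rrt_battery(
    alignments: dict[str, dict[str, str]],
    ingroups: list[str],
    outgroup: str,
    alphabet: str = "nucleotide",
    cluster_of: dict[str, str] | None = None,
) -> list[RRTResult]:
    """Run the RRT for every gene and every unordered ingroup pair.

    ``alignments`` maps gene -> species -> aligned sequence (equal lengths
    within a gene). Genes missing the outgroup are skipped with a logged
    notice; within a gene, pairs are formed only from the ingroups present.
    Output ordering is deterministic: gene, then lexicographic species pair.
    """
    results: list[RRTResult] = []
    for gene in sorted(alignments):
        seqs = alignments[gene]
        if outgroup not in seqs:
            logger.warning("gene %s: outgroup %s missing; skipped", gene, outgroup)
            continue
        present = sorted(sp for sp in ingroups if sp in seqs)
        missing = sorted(set(ingroups) - set(present))
        if missing:
            logger.info("gene %s: ingroups %s absent", gene, ",".join(missing))
        cluster = (cluster_of or {}).get(gene, "")
        for sp_a, sp_b in itertools.combinations(present, 2):
            triplet = TripletAlignment(
                gene=gene,
                ingroup_a=seqs[sp_a],
                ingroup_b=seqs[sp_b],
                outgroup=seqs[outgroup],
                alphabet=alphabet,
                species_a=sp_a,
                species_b=sp_b,
                outgroup_name=outgroup,
            )
            stripped = strip_ambiguous_columns(triplet)
            if len(stripped.ingroup_a) == 0:
                logger.warning(
                    "gene %s pair %s/%s: no unambiguous columns", gene, sp_a, sp_b
                )
            results.append(tajima_rrt(stripped, cluster=cluster))
    return results


# ---------------------------------------------------------------------------
# Hasse diagrams
# ---------------------------------------------------------------------------


@dataclass
class PartialOrder:
    """Species nodes with significance-tiered "slower-than" edges.

    ``edges`` holds (slower, faster, tier) for every significant pairwise
    result; ``reduced_edges`` is the transitive reduction (the Hasse
    diagram's cover relations), each keeping its original tier.
    """

    nodes: set[str]
    edges: list[tuple[str, str, str]]
    reduced_edges: list[tuple[str, str, str]] = field(default_factory=list)


def build_hasse(results: list[RRTResult]) -> PartialOrder:
    """Combine one gene's pairwise RRTs into a Hasse diagram.

    Each significant result contributes a directed faster -> slower edge.
    Should the significant edges form a directed cycle (mutually
    contradictory evidence across three or more pairs), the edges inside
    each strongly connected component are dropped, leaving those species
    incomparable; the remaining DAG is transitively reduced.
    """
    genes = {r.gene for r in results}
    if len(genes) > 1:
        raise UsageError(f"results span several genes: {sorted(genes)}")
    nodes = {r.species_a for r in results} | {r.species_b for r in results}
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    tier_of: dict[tuple[str, str], str] = {}
    edges: list[tuple[str, str, str]] = []
    for r in results:
        if r.slower is None:
            continue
        g.add_edge(r.faster, r.slower)
        tier_of[(r.faster, r.slower)] = r.significance
        edges.append((r.slower, r.faster, r.significance))
    if not nx.is_directed_acyclic_graph(g):
        logger.warning("contradictory significant RRTs form a cycle; dropped")
        for comp in nx.strongly_connected_components(g):
            if len(comp) > 1:
                for u, v in list(g.edges()):
                    if u in comp and v in comp:
                        g.remove_edge(u, v)
        edges = [(s, f, t) for (s, f, t) in edges if g.has_edge(f, s)]
    reduced = nx.transitive_reduction(g)
    reduced_edges = sorted(
        (v, u, tier_of[(u, v)]) for u, v in reduced.edges()
    )
    return PartialOrder(nodes=nodes, edges=sorted(edges), reduced_edges=reduced_edges)


def hasse_to_dot(order: PartialOrder, gene: str = "") -> str:
    """Hasse diagram as DOT text: solid edges for p <= 0.01, dotted for
    0.01 < p <= 0.05; the arrow points at the slower species."""
    lines = [f'digraph "{gene or "hasse"}" {{', "  rankdir=BT;"]
    for node in sorted(order.nodes):
        lines.append(f'  "{node}";')
    for slower, faster, tier in order.reduced_edges:
        style = "solid" if tier == TIER_HIGH else "dotted"
        lines.append(f'  "{faster}" -> "{slower}" [style={style}];')
    lines.append("}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def summarize_pairwise(results: list[RRTResult]) -> pd.DataFrame:
    """Per cluster and species pair: directional win counts by tier.

    Rows are (cluster, species_a, species_b) with species in lexicographic
    order; counts tally genes where each side is significantly slower at
    each tier, plus non-significant genes and the fraction of genes where
    each side is slower at p <= 0.05.
    """
    buckets: dict[tuple[str, str, str], dict[str, int]] = {}
    for r in results:
        sp1, sp2 = sorted([r.species_a, r.species_b])
        key = (r.cluster, sp1, sp2)
        b = buckets.setdefault(
            key,
            {
                "a_slower_high": 0,
                "a_slower_sig": 0,
                "b_slower_high": 0,
                "b_slower_sig": 0,
                "ns": 0,
                "n_genes": 0,
            },
        )
        b["n_genes"] += 1
        if r.slower is None:
            b["ns"] += 1
        else:
            side = "a" if r.slower == sp1 else "b"
            tier = "high" if r.significance == TIER_HIGH else "sig"
            b[f"{side}_slower_{tier}"] += 1
    rows = []
    for (cluster, sp1, sp2), b in sorted(buckets.items()):
        n = b["n_genes"]
        rows.append(
            {
                "cluster": cluster,
                "species_a": sp1,
                "species_b": sp2,
                **b,
                "frac_a_slower": (b["a_slower_high"] + b["a_slower_sig"]) / n,
                "frac_b_slower": (b["b_slower_high"] + b["b_slower_sig"]) / n,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster",
            "species_a",
            "species_b",
            "a_slower_high",
            "a_slower_sig",
            "b_slower_high",
            "b_slower_sig",
            "ns",
            "n_genes",
            "frac_a_slower",
            "frac_b_slower",
        ],
    )


def genome_matrix(results: list[RRTResult], ingroups: list[str]) -> pd.DataFrame:
    """Genome-wide per-species significance counts for three ingroups.

    For each ingroup species there are six count categories: significantly
    slower than each of the two other species, slower than both, and the
    mirror faster counts — each split by tier (high: p <= 0.01;
    significant: 0.01 < p <= 0.05). Columns are a MultiIndex
    (category, tier); summing across the tier level gives the collapsed
    p <= 0.05 matrix.
    """
    if len(ingroups) != 3:
        raise UsageError("genome matrix requires exactly 3 ingroup species")
    ingroups = sorted(ingroups)
    per_gene: dict[str, dict[tuple[str, str], str]] = {}
    for r in results:
        if r.slower is None:
            continue
        per_gene.setdefault(r.gene, {})[(r.slower, r.faster)] = r.significance

    counts: dict[tuple[str, str, str], int] = {}

    def bump(sp: str, cat: str, tier: str) -> None:
        counts[(sp, cat, tier)] = counts.get((sp, cat, tier), 0) + 1

    for gene, outcomes in per_gene.items():
        for sp in ingroups:
            others = [o for o in ingroups if o != sp]
            slower_tiers = []
            faster_tiers = []
            for o in others:
                if (sp, o) in outcomes:
                    tier = outcomes[(sp, o)]
                    bump(sp, f"slower_than_{o}", tier)
                    slower_tiers.append(tier)
                if (o, sp) in outcomes:
                    tier = outcomes[(o, sp)]
                    bump(sp, f"faster_than_{o}", tier)
                    faster_tiers.append(tier)
            if len(slower_tiers) == 2:
                tier = TIER_HIGH if all(t == TIER_HIGH for t in slower_tiers) else TIER_SIG
                bump(sp, "slower_than_both", tier)
            if len(faster_tiers) == 2:
                tier = TIER_HIGH if all(t == TIER_HIGH for t in faster_tiers) else TIER_SIG
                bump(sp, "faster_than_both", tier)

    cat_names: list[str] = []
    for sp in ingroups:
        others = [o for o in ingroups if o != sp]
        for o in others:
            for name in (f"slower_than_{o}", f"faster_than_{o}"):
                if name not in cat_names:
                    cat_names.append(name)
    for name in ("slower_than_both", "faster_than_both"):
        cat_names.append(name)

    columns = pd.MultiIndex.from_product(
        [cat_names, [TIER_HIGH, TIER_SIG]], names=["category", "tier"]
    )
    df = pd.DataFrame(0, index=pd.Index(ingroups, name="species"), columns=columns)
    for (sp, cat, tier), n in counts.items():
        if (cat, tier) in df.columns:
            df.loc[sp, (cat, tier)] = n
    return df


def genome_fractions(matrix: pd.DataFrame, n_genes: int) -> pd.DataFrame:
    """Genome matrix collapsed over tiers (p <= 0.05) as fractions of the
    gene set: per species, e.g. the fraction of genes significantly slower
    than a given other ingroup or slower than both."""
    collapsed = matrix.T.groupby(level="category").sum().T
    return collapsed / n_genes


def slower_than_any_fraction(
    results: list[RRTResult], species: str, n_genes: int
) -> float:
    """Fraction of genes where ``species`` is significantly slower
    (p <= 0.05) than at least one other ingroup."""
    genes = {r.gene for r in results if r.slower == species}
    return len(genes) / n_genes
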