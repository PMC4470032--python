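# Methods

This note records the models, parameter choices and numerical conventions
behind hoxcomp, and what the synthetic-data tests do and do not
demonstrate about real data.

## Coordinates and I/O

All internal coordinates are 0-based half-open; GFF3's 1-based closed
convention is converted at the parse boundary and BED passes through.
FASTA input is uppercased and any character outside `{A,C,G,T,N}` —
including IUPAC ambiguity codes present in deposited records — becomes
`N` with a logged warning, rather than an error. Cluster lengths in kb
round half-up to one decimal, matching how such figures are usually
printed. Pairwise alignment is backed by Biopython's `PairwiseAligner`
(affine-gap global mode); Newick parsing by dendropy; transitive
reduction by networkx. Each of these sits behind the module function the
rest of the package calls, and each is cross-checked in the test suite
against an independent oracle (exhaustive alignment-score enumeration;
round-trip parsing; bitset reachability).

## Synthetic cluster generator

The generator produces, per species (tree tip), one cluster sequence with
fully known ground truth. Its purpose is calibration and testing: it
emulates the statistical structure the analysis stages assume, not the
full complexity of genomic sequence.

**Substitution model.** Jukes–Cantor only. A branch of length *b*
(expected substitutions/site) changes each site with probability
(3/4)(1 − e^(−4b/3)), moving uniformly to one of the other three bases.
JC was chosen because the downstream statistics consume identities and
substitution counts, not model fits, and it gives closed forms for
calibration (the simulated pairwise difference is checked against the
closed-form expectation to within 3 standard errors).

**Rate multipliers.** A species' rate multiplier scales its *terminal*
branch only; internal branches use 1.0. The multiplier keyed by a tip is
ambiguous for internal branches subtending several tips, and terminal-only
scaling keeps "lineage X evolves *m*-times faster" exactly interpretable
in the relative-rate tests the generator feeds.

**Conserved elements and exons.** A planted CNE with
`conservation_scaling` *s* ∈ (0, 1] evolves at *s*·*b* on every branch;
exons evolve at 0.1 times the most conserved CNE scaling (0.1 if no CNEs
are planted), making coding sequence strictly the most conserved feature.
CNE *loss* in a species is modelled as replacement by fresh random
sequence rather than deletion, so coordinates stay comparable across
species and ground-truth bookkeeping stays exact. This is a deliberate
simplification: no indel evolution occurs along the tree at all, so
alignments of simulated clusters are easier than alignments of real
clusters, where indels and rearrangements dominate deep comparisons.

**Repeats.** Direct, inverted and interspersed (single-copy) repeats are
inserted per species after tree simulation, reflecting the observation
that repeat content is lineage-specific. Insertions are applied
right-to-left and all recorded coordinates (CNEs, exons, arms) are
shifted past them. Two guard mechanisms make planted geometry exactly
recoverable in noise-free insertions: spacers of inverted repeats are
de-palindromized (no position complement-matches its mirror), and a
12 bp zone flanking each unit is adjusted so that the pairing line cannot
extend into background by chance. Planted elements should therefore sit
at least the guard width apart. Arms may additionally be mutated at a
per-copy rate to emulate diverged copies.

**Determinism.** All randomness flows from the config seed through named
`numpy` `SeedSequence` substreams (tree evolution; one stream per
species for loss and insertion), so identical configs give byte-identical
output regardless of dict ordering.

## CNE calling

The caller's normative definition (the exact peak-extension algorithm of
the classic visualization tools is unpublished, so this definition is the
contract here, chosen to be reproducible and oracle-checkable):

1. compute per-column matches on the pairwise alignment — a match needs
   the same base on both rows, neither a gap nor an `N` (gaps and `N`
   count as mismatches, the conservative reading of "no gaps");
2. slide a window of `min_length` columns (default 50) and mark windows
   with identity ≥ `min_identity` (default 65 %);
3. merge overlapping passing windows into runs and trim each run to its
   first/last match column;
4. keep a run if its overall column identity still clears the cutoff and
   it covers ≥ `min_length` *reference bases* (length is measured in
   reference bases, identity over alignment columns);
5. cut out portions overlapping the coding mask; remainders are re-trimmed
   and must again clear both thresholds.

The test suite proves this implementation equal to a naive all-window
oracle on alignments up to 2,000 columns, and measures ≥95 % recovery of
planted elements (≥50 % reciprocal overlap) with ≲0.3 false calls per
100 kb on 100 replicate synthetic cluster pairs.

**Alignment scores.** Defaults are match +1, mismatch −1, gap open −6,
gap extend −1. The stiff opening penalty matters: under weak gap costs,
the optimal global alignment of *unrelated* DNA approaches ~55 % column
identity (the optimizer buys matches with cheap gaps), which would swamp
a 65 % conservation cutoff. With the defaults, deeply diverged background
stays near its raw ~30–45 % identity and false calls are rare. The
synthetic recovery studies use terminal branches of 0.85 (total path
1.7 substitutions/site, raw identity ≈33 %), i.e. saturation-depth
background comparable to a tetrapod–chondrichthyan comparison.

**Cross-species matching and grouping.** A reference CNE corresponds to
every other-species CNE whose alignment-projected interval overlaps it by
≥1 bp; one-to-many matches are expected (long elements break into shorter
ones in a faster-evolving genome). The same ≥1 bp rule decides whether a
diagnostic species (elephant shark / spotted gar / coelacanth) shares an
element; published work does not state a minimum overlap, so the most
permissive rule is declared here. Groups are assigned in fixed priority
order (gnathostome > osteichthyan > sarcopterygian > tetrapod) and each
element gets exactly one group. Intronic elements are flagged as inside a
gene span but overlapping no exon.

## Repeat discovery

Self-comparison hits live on pairing lines: direct pairs on a diagonal
(*x* ↔ *x + D*), inverted pairs on an anti-diagonal (*x* ↔ *C − x*,
partner complemented). Exact k-mer seeds (default k = 12, skipping seeds
with ≤2 distinct bases or `N` — the low-complexity filter standing in for
the usual exclusion of simple repeats) locate the line; ungapped
extension then maximizes a cumulative score with match +1 and mismatch
−q/(1 − q) (q = identity threshold), so spans above the threshold extend
and background trims, with an X-drop-style bail-out when the running
identity falls 5 points below the threshold. The right end is fixed
before the left extension, making trimming deterministic. Seeds crossing
a palindrome centre are skipped (their mirror half is redundant; any arm
at least k long also carries an uncrossed seed). Mirror duplicates
collapse on the shared pairing line; pairs whose arms both overlap merge,
keeping the longer arm.

Explicit `min_arm_length` (50 bp) + `min_arm_identity` (70 %) replace the
e-value filter of database search tools: e-values depend on database size
and are not reproducible in a self-contained reimplementation. Only
ungapped arms are reported, since arm length/identity/spacer are the
quantities of interest and gapped arms would add unconstrained free
parameters. Spacer is `arm2.start − arm1.end` on the forward strand for
both orientations; arms are required not to overlap. Inverted repeats
with arms strictly >100 bp are classed as "long". Equality with a
brute-force scan of every pairing line is verified on ≤2 kb sequences
over 50 seeds.

## Relative rate tests

Tajima's test, computed exactly as defined: after complete deletion of
columns carrying a gap or ambiguity character in any of the three rows
(`N` for nucleotides; `X/B/Z/J` for proteins — the two modes share one
code path and differ only in this alphabet), `m_A` counts sites where
only ingroup A differs and `m_B` the mirror count;
χ² = (m_A − m_B)²/(m_A + m_B) on 1 df, no continuity correction, p = 1
when `m_A + m_B = 0` (short, fully conserved genes must not crash a
battery). No multiple-testing correction is applied across genes; the
two reporting tiers are p ≤ 0.01 (high, solid edge) and
0.01 < p ≤ 0.05 (significant, dotted edge). Calibration: under equal-rate
simulation (1,000 genes × 1,000 sites, moderate divergence) the rejection
rate at α = 0.05 lands in the exact binomial 95 % band [0.037, 0.064],
and power is monotone in the ingroup rate ratio.

**Hasse synthesis.** Each significant pairwise result contributes a
directed faster→slower edge; the Hasse diagram is the transitive
reduction of this edge set. Two-node contradictions cannot occur (each
pair yields one directed result), but three or more pairwise tests *can*
form a directed cycle; edges inside any strongly connected component are
then dropped, leaving those species incomparable — contradictory evidence
should not manufacture an ordering. Reduction correctness is verified
exhaustively against an independent reachability oracle over all 3^10
pairwise-outcome configurations on five species.

**Genome-wide matrix.** For a three-ingroup design, each species has six
count categories — significantly slower than each of the two others,
slower than both, and the mirror faster counts — each split by
significance tier. Summing tiers gives the collapsed p ≤ 0.05 matrix from
which headline fractions (slower-than-both, slower-than-any) derive.

## Branch-length folds

Fold comparisons divide terminal branch lengths and round half-up to the
requested decimals. Terminal branches are the default (the published
per-lineage comparisons read most naturally as tip branches);
root-to-tip path lengths are available via `from_root=True`. Printed
inputs 0.34/0.13 and 0.35/0.12 reproduce 2.6 and 2.9.

## Pipeline

`run_pipeline` executes simulate → align → CNE → classify → repeats → RRT
→ summaries from one config. Stage seeds derive from the single config
seed via SHA-256, outputs carry a header with the config hash and seed,
and reruns are byte-identical. The reference CNE set is taken from the
first comparison species in sorted order; diagnostic hits come from the
remaining comparisons. The orchestrator currently requires a simulation
block; analyses of on-disk FASTA go through the stage functions or the
CLI subcommands directly.

## Problem sizes and limitations

Default study sizes were chosen for desk-scale work: 4 kb clusters ×100
replicates for recovery studies, 1,000 × 1,000 for test calibration, ≤2 kb
for brute-force equivalence — each large enough for the statistics being
checked (binomial bands, 95 % recovery thresholds) to be meaningful.
Quadratic alignment limits single comparisons to roughly ≤50 kb per
sequence.

What the synthetic tests do *not* show: robustness to indels and
rearrangements (none are simulated), to alignment error at real loci, to
base-composition or rate heterogeneity beyond the per-feature scalings
(JC is homogeneous), or to the library-specific behaviour of
repeat-classification tools (the finder is library-free by design;
externally produced repeat annotations can be supplied as BED for the
density and hotspot stages). Published headline figures that depend on
specific genome-database versions (absolute CNE counts, repeat densities
per species) are therefore not reproduced here; the structural facts and
statistical properties above are.
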