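"""Terminal branch-length extraction and fold-difference comparisons.

Trees are consumed as Newick text with branch lengths in substitutions per
site (inferred externally, e.g. by maximum likelihood). The fold
comparison divides one species' terminal branch length by another's —
e.g. a frog terminal branch of 0.34 against a caecilian branch of 0.13 is
a 2.6-fold difference — rounding half-up to the requested precision.
Root-to-tip path lengths are available as an option, but the default uses
terminal branches only.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import dendropy
import pandas as pd

from .seq_io import FormatError, UsageError


@dataclass
class SpeciesTree:
    newick: str
    tips: set[str]
    terminal_branch_length: dict[str, float]
    root_to_tip: dict[str, float]

    def length(self, species: str, *, from_root: bool = False) -> float:
        table = self.root_to_tip if from_root else self.terminal_branch_length
        if species not in self.tips:
            raise UsageError(f"{species!r} is not a tip of the tree")
        if species not in table:
            raise FormatError(f"tip {species!r} has no branch length")
        return table[species]


def parse_newick(text: str) -> SpeciesTree:
    """Parse a Newick tree, extracting tip names and terminal branch
    lengths (plus root-to-tip path lengths for the optional mode).

    Tips without a branch length are recorded but raise
    :class:`FormatError` when queried.
    """
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"cannot parse Newick: {exc}") from exc
    tips: set[str] = set()
    terminal: dict[str, float] = {}
    root_to_tip: dict[str, float] = {}
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None:
            raise FormatError("unnamed tip in tree")
        name = leaf.taxon.label
        tips.add(name)
        if leaf.edge.length is not None:
            length = float(leaf.edge.length)
            if length < 0:
                raise FormatError(f"negative branch length on {name}")
            terminal[name] = length
            dist = 0.0
            node = leaf
            complete = True
            while node.parent_node is not None:
                if node.edge.length is None:
                    complete = False
                    break
                dist += float(node.edge.length)
                node = node.parent_node
            if complete:
                root_to_tip[name] = dist
    if not tips:
        raise FormatError("tree has no named tips")
    return SpeciesTree(
        newick=text.strip(),
        tips=tips,
        terminal_branch_length=terminal,
        root_to_tip=root_to_tip,
    )


def branch_fold(
    tree: SpeciesTree,
    numerator: str,
    denominator: str,
    decimals: int = 1,
    *,
    from_root: bool = False,
) -> float:
    """Ratio of two species' branch lengths, rounded half-up."""
    num = tree.length(numerator, from_root=from_root)
    den = tree.length(denominator, from_root=from_root)
    if den == 0:
        raise UsageError(f"zero branch length for denominator {denominator!r}")
    q = Decimal(str(num)) / Decimal(str(den))
    quantum = Decimal(1).scaleb(-decimals)
    return float(q.quantize(quantum, rounding=ROUND_HALF_UP))


def branch_length_table(
    tree: SpeciesTree, pairs: list[tuple[str, str]], decimals: int = 1
) -> pd.DataFrame:
    """Terminal lengths and folds for a list of (numerator, denominator)
    species pairs."""
    rows = []
    for num, den in pairs:
        rows.append(
            {
                "numerator": num,
                "denominator": den,
                "numerator_length": tree.length(num),
                "denominator_length": tree.length(den),
                "fold": branch_fold(tree, num, den, decimals),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "numerator",
            "denominator",
            "numerator_length",
            "denominator_length",
            "fold",
        ],
    )
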