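"""Distance trees from breakpoint matrices and parsimony ancestral states.

Neighbor joining turns a pairwise breakpoint-distance matrix into an
unrooted tree, giving a rearrangement-based view of relatedness that can be
compared against a sequence-based phylogeny (which is an *input* here, read
from Newick — tree inference from sequences is out of scope).

Fitch parsimony reconstructs ancestral character states on a rooted tree for
a discrete character; here the parasitic lifestyle coding used for chalcid
wasps: 1 = primary parasitoid, 2 = both primary parasitoid and
hyperparasitoid, 3 = undefined.  An undefined tip is treated as fully
ambiguous ({1, 2}) rather than as a third observable state, so missing
biology never inflates the change count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .annotation_io import ValidationError
from .gene_order import BreakpointMatrix

__all__ = [
    "CharacterAssignment",
    "nj_from_matrix",
    "fitch_ancestral",
    "read_newick",
    "write_newick",
    "read_tip_states",
]

#: Observable lifestyle states; 3 codes for "undefined" and expands to the
#: full ambiguity set during reconstruction.
OBSERVABLE_STATES = frozenset({1, 2})
MISSING_STATE = 3


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, BreakpointMatrix):
        return matrix.values.astype(float)
    return pd.DataFrame(matrix).astype(float)


def nj_from_matrix(matrix) -> dendropy.Tree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Accepts a :class:`BreakpointMatrix` or a labelled DataFrame.  Standard
    Saitou–Nei agglomeration; ties in the Q criterion are broken by
    lexicographic taxon-pair label; negative branch lengths are clamped to 0
    with a warning.  Returns an unrooted dendropy tree.
    """
    frame = _as_frame(matrix)
    if list(frame.index) != list(frame.columns):
        raise ValidationError("distance matrix must have matching row/column labels")
    if not np.allclose(frame.values, frame.values.T):
        raise ValidationError("distance matrix is not symmetric")
    if len(frame) < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")

    labels = [str(c) for c in frame.columns]
    dist: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            dist[(a, b)] = dist[(b, a)] = float(frame.loc[a, b])

    newick: dict[str, str] = {lab: lab for lab in labels}
    active = sorted(labels)
    clamped = False
    counter = 0
    while len(active) > 3:
        r = len(active)
        total = {a: sum(dist[(a, b)] for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (r - 2) * dist[(a, b)] - total[a] - total[b]
                key = (q, a, b)  # lexicographic tie-break on the label pair
                if best is None or key < best:
                    best = key
        _, a, b = best
        d_ab = dist[(a, b)]
        la = 0.5 * d_ab + (total[a] - total[b]) / (2 * (r - 2))
        lb = d_ab - la
        if la < 0 or lb < 0:
            clamped = True
            la, lb = max(la, 0.0), max(lb, 0.0)
        node = f"_nj{counter}"
        counter += 1
        newick[node] = f"({newick[a]}:{la:.6g},{newick[b]}:{lb:.6g})"
        for c in active:
            if c in (a, b):
                continue
            dist[(node, c)] = dist[(c, node)] = \
                0.5 * (dist[(a, c)] + dist[(b, c)] - d_ab)
        active = sorted([c for c in active if c not in (a, b)] + [node])

    a, b, c = active
    la = 0.5 * (dist[(a, b)] + dist[(a, c)] - dist[(b, c)])
    lb = 0.5 * (dist[(a, b)] + dist[(b, c)] - dist[(a, c)])
    lc = 0.5 * (dist[(a, c)] + dist[(b, c)] - dist[(a, b)])
    if min(la, lb, lc) < 0:
        clamped = True
        la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    if clamped:
        warnings.warn("negative branch length(s) clamped to 0", stacklevel=2)
    text = (f"({newick[a]}:{la:.6g},{newick[b]}:{lb:.6g},"
            f"{newick[c]}:{lc:.6g});")
    return dendropy.Tree.get(data=text, schema="newick")


@dataclass(frozen=True)
class CharacterAssignment:
    """Tip states plus reconstructed internal state sets and change count.

    ``node_states`` maps dendropy node ids to Fitch state sets (bottom-up
    pass); ``total_changes`` is the parsimony minimum number of state
    changes on the tree.
    """

    tip_states: dict[str, int]
    node_states: dict[int, frozenset[int]]
    root_states: frozenset[int]
    total_changes: int


def fitch_ancestral(tree: dendropy.Tree,
                    tip_states: dict[str, int]) -> CharacterAssignment:
    """Fitch parsimony bottom-up pass on a (rooted) dendropy tree.

    Every leaf must appear in ``tip_states``; state 3 (undefined) enters the
    pass as the full ambiguity set {1, 2}.  Polytomies are combined by
    iterated pairwise intersection/union in child order.
    """
    node_states: dict[int, frozenset[int]] = {}
    changes = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else None
            if label is None or label not in tip_states:
                raise ValidationError(f"unlabeled or unassigned tip: {label!r}")
            state = tip_states[label]
            node_states[id(node)] = (frozenset(OBSERVABLE_STATES)
                                     if state == MISSING_STATE
                                     else frozenset({state}))
            continue
        children = node.child_nodes()
        acc = node_states[id(children[0])]
        for child in children[1:]:
            nxt = node_states[id(child)]
            inter = acc & nxt
            if inter:
                acc = inter
            else:
                acc = acc | nxt
                changes += 1
        node_states[id(node)] = acc
    root = tree.seed_node
    return CharacterAssignment(tip_states=dict(tip_states),
                               node_states=node_states,
                               root_states=node_states[id(root)],
                               total_changes=changes)


def read_newick(source) -> dendropy.Tree:
    """Read a Newick tree from a path or string."""
    if isinstance(source, str) and ("(" in source):
        return dendropy.Tree.get(data=source, schema="newick")
    return dendropy.Tree.get(path=str(source), schema="newick")


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick").strip()


def read_tip_states(text: str) -> dict[str, int]:
    """Parse a two-column TSV ``taxon<TAB>state`` into a tip-state map."""
    states = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("taxon\t"):
            continue
        taxon, _, state = line.partition("\t")
        states[taxon.strip()] = int(state)
    return states
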