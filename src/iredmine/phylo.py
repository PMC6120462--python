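"""Distance-matrix phylogenetics: pairwise distances, neighbour joining,
newick export and donor-type branch annotation.

Distances are in substitutions per site. The default "poisson" model applies
the multiple-hit correction d = -ln(1 - p) to the observed proportion of
differing sites p; the uncorrected p-distance is also available. Gapped
columns are excluded pairwise (only columns where both rows carry a residue
count), not listwise.

Neighbour joining follows the Saitou–Nei agglomeration and is exact on
additive matrices: it recovers both the generating topology and its branch
lengths. Trees are held as :class:`skbio.TreeNode` objects, left unrooted
(trifurcating root).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from io import StringIO

import numpy as np
from skbio import TreeNode

from .align import MultipleAlignment


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise distances with ordered taxon ids."""

    ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("matrix shape does not match taxon count")
        if not np.allclose(self.data, self.data.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.data) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.data < 0) or not np.all(np.isfinite(self.data)):
            raise ValueError("distances must be finite and non-negative")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.ids.index(pair[0]), self.ids.index(pair[1])
        return float(self.data[i, j])

    def to_tsv(self) -> str:
        lines = ["\t" + "\t".join(self.ids)]
        for i, tid in enumerate(self.ids):
            lines.append(tid + "\t" + "\t".join(f"{x:.10g}" for x in self.data[i]))
        return "\n".join(lines) + "\n"

    def to_phylip(self) -> str:
        lines = [f"{len(self.ids)}"]
        for i, tid in enumerate(self.ids):
            lines.append(f"{tid:<10s} " + " ".join(f"{x:.6f}" for x in self.data[i]))
        return "\n".join(lines) + "\n"


def pairwise_distance(msa: MultipleAlignment, model: str = "poisson") -> DistanceMatrix:
    """Pairwise evolutionary distances from a multiple alignment.

    p = mismatches / shared ungapped columns; under "poisson",
    d = -ln(1 - p). A pair sharing no ungapped column, or with p = 1 under
    the poisson model, is an error.
    """
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    if len(msa.ids) < 2:
        raise ValueError("need at least 2 rows")
    n = len(msa.ids)
    arr = np.array([list(row) for row in msa.rows])
    gap = arr == "-"
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~gap[i] & ~gap[j]
            n_shared = int(shared.sum())
            if n_shared == 0:
                raise ValueError(
                    f"{msa.ids[i]} and {msa.ids[j]} share no ungapped column"
                )
            p = float((arr[i][shared] != arr[j][shared]).sum()) / n_shared
            if model == "p":
                d = p
            else:
                if p >= 1.0:
                    raise ValueError(
                        f"saturated pair {msa.ids[i]}/{msa.ids[j]} (p = 1) "
                        "cannot be Poisson-corrected"
                    )
                d = -math.log(1.0 - p)
            D[i, j] = D[j, i] = d
    return DistanceMatrix(list(msa.ids), D)


def neighbor_joining(D: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbour joining.

    Ties in the Q criterion are broken on the lowest index pair; negative
    branch-length estimates are clamped to zero with a warning. The returned
    tree is unrooted (its root is the final trifurcation).
    """
    n = len(D.ids)
    if n < 3:
        raise ValueError("neighbour joining requires at least 3 taxa")
    nodes = [TreeNode(name=tid) for tid in D.ids]
    d = D.data.copy()
    active = list(range(n))

    def clamp(x: float) -> float:
        if x < 0:
            if x < -1e-9:
                warnings.warn(
                    f"negative neighbour-joining branch length {x:.3g} clamped to 0",
                    stacklevel=2,
                )
            return 0.0
        return x

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best_q = math.inf
        best_pair = (active[0], active[1])
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * d[i, j] - sums[i] - sums[j]
                if q < best_q - 1e-12:
                    best_q = q
                    best_pair = (i, j)
        i, j = best_pair
        li = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = clamp(li)
        nodes[j].length = clamp(lj)
        # grow the arrays with the new internal node
        m = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[m, k] = d[k, m] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [m]

    i, j, k = active
    # three-way join: pendant lengths from the three pairwise distances
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    nodes[i].length = clamp(li)
    nodes[j].length = clamp(lj)
    nodes[k].length = clamp(lk)
    return root


def to_newick(tree: TreeNode) -> str:
    """Deterministic newick serialisation.

    Children are ordered lexicographically by the smallest leaf label in
    their subtree, so two structurally identical trees serialise
    byte-identically.
    """

    def min_leaf(node: TreeNode) -> str:
        if node.is_tip():
            return node.name or ""
        return min(min_leaf(c) for c in node.children)

    def fmt(node: TreeNode) -> str:
        if node.is_tip():
            label = node.name or ""
        else:
            kids = sorted(node.children, key=min_leaf)
            label = "(" + ",".join(fmt(c) for c in kids) + ")"
        if node.length is not None:
            label += f":{node.length:.10g}"
        return label

    return fmt(tree) + ";"


def parse_newick(text: str) -> TreeNode:
    return TreeNode.read(StringIO(text))


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions, each normalised to the side that does
    not contain the lexicographically smallest taxon (rooting-invariant)."""
    leaves = frozenset(t.name for t in tree.tips())
    anchor = min(leaves)
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = leaves - side
        if 2 <= len(side) <= len(leaves) - 2:
            parts.add(side)
    return parts


def rf_distance(t1: TreeNode, t2: TreeNode) -> int:
    """Robinson–Foulds distance (symmetric difference of bipartitions)."""
    if {t.name for t in t1.tips()} != {t.name for t in t2.tips()}:
        raise ValueError("trees are over different taxon sets")
    b1, b2 = bipartitions(t1), bipartitions(t2)
    return len(b1 ^ b2)


@dataclass
class BranchTypeSummary:
    """Donor-type partition of the tree's leaves."""

    counts: dict[str, int]
    monophyletic: dict[str, bool]

    @property
    def clean_separation(self) -> bool:
        return all(self.monophyletic.values())


def _clades(tree: TreeNode) -> list[frozenset[str]]:
    clades = []
    for node in tree.postorder():
        if node.is_tip():
            clades.append(frozenset([node.name]))
        else:
            clades.append(frozenset(t.name for t in node.tips()))
    return clades


def assign_branch_types(
    tree: TreeNode, donor_calls: dict[str, str]
) -> tuple[TreeNode, BranchTypeSummary]:
    """Annotate leaves with their donor type and check type monophyly.

    On an unrooted tree a leaf set is monophyletic when some edge separates
    exactly that set from the rest; equivalently, the set or its complement
    appears as a clade of the arbitrarily rooted representation.
    """
    leaves = [t.name for t in tree.tips()]
    missing = [l for l in leaves if l not in donor_calls]
    if missing:
        raise ValueError(f"missing donor call for leaves: {missing}")
    for tip in tree.tips():
        tip.donor_type = donor_calls[tip.name]
    all_leaves = frozenset(leaves)
    clades = _clades(tree)
    types = sorted({donor_calls[l] for l in leaves})
    counts = {t: sum(1 for l in leaves if donor_calls[l] == t) for t in types}
    mono = {}
    for t in types:
        members = frozenset(l for l in leaves if donor_calls[l] == t)
        mono[t] = (
            len(members) <= 1
            or members == all_leaves
            or members in clades
            or (all_leaves - members) in clades
        )
    return tree, BranchTypeSummary(counts=counts, monophyletic=mono)
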