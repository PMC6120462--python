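"""Synthetic protein families with known phylogeny and planted features.

The generator emulates the statistical structure the discovery pipeline
assumes: a family of homologous Rossmann-fold proteins descending from a
common ancestor along a known binary tree, carrying

* a GxGxxG dinucleotide-binding motif near the N-terminus,
* a polar residue (Ser/Thr) at reference position 111,
* apolar flanking residues at positions 137 and 191, and
* clade-specific proton-donor and selectivity residues: one clade gets the
  Asp donor at 187 with (R)-markers (V/T/I at 139, M/L at 194), the other
  the Tyr donor with (S)-markers (P at 139, F at 194).

Sites evolve independently: the number of substitution events per site on a
branch of length t is Poisson(rate * t), each event replacing the residue
with a uniformly chosen different one. Planted sites are hard-protected in
positives, so the selection criteria are deterministic features of every
positive record; negatives violating exactly one criterion each can be
planted on top. Every family is self-audited: the stored truth table is
recomputed from the emitted sequences at generation time.

No indels are generated by default, so reference numbering transfers to
every family member as the identity map; this keeps neighbour-joining
exactness tests sharp and is adequate for exercising the filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .discovery import KEY_POSITIONS, scan_gxgxxg
from .phylo import DistanceMatrix
from .selectivity import INDETERMINATE, KeyResidues, predict_selectivity
from .seqio import SequenceRecord

_AA = "ACDEFGHIKLMNPQRSTVWY"
_NON_G = _AA.replace("G", "")

NEGATIVE_MODES = (
    "ablate_motif",
    "truncate",
    "break_donor",
    "polar_flank",
    "break_111",
    "distant_outgroup",
)

#: Which filter criterion each negative mode is constructed to violate.
MODE_TARGET = {
    "ablate_motif": "rossmann",
    "truncate": "rossmann",
    "break_donor": "donor_residue",
    "polar_flank": "apolar_flank",
    "break_111": "polar_111",
    "distant_outgroup": "evalue",
}


@dataclass
class FamilyConfig:
    """Parameters of a synthetic IRED-like family.

    ``rate`` is the expected number of substitution events per site per
    unit branch length; branch lengths are exponential with mean
    ``branch_length_mean`` (floored at ``branch_length_min``), and the two
    donor clades hang off the root on branches of length
    ``clade_separation`` each.
    """

    n_taxa: int = 20
    scaffold_length: int = 290
    motif_start: int = 15
    key_positions: tuple[int, ...] = KEY_POSITIONS
    rate: float = 0.3
    branch_length_mean: float = 0.15
    branch_length_min: float = 0.02
    clade_separation: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.rate < 0.5):
            raise ValueError("rate must lie in [0, 0.5)")
        if self.n_taxa < 4:
            raise ValueError("need at least 4 taxa (2 per donor clade)")
        motif_span = set(range(self.motif_start, self.motif_start + 6))
        if motif_span & set(self.key_positions):
            raise ValueError("motif window overlaps a key position")
        if max(self.key_positions) > self.scaffold_length:
            raise ValueError("key positions must fit within the scaffold")
        if self.motif_start + 5 > self.scaffold_length:
            raise ValueError("motif must fit within the scaffold")


@dataclass
class TruthRow:
    """Generator-side ground truth for one record."""

    id: str
    is_positive: bool
    has_motif: bool
    key_residues: dict[int, str | None]
    donor_type: str
    expected_pass: bool
    expected_failures: list[str] = field(default_factory=list)
    expected_selectivity: str = INDETERMINATE
    negative_mode: str | None = None


@dataclass
class SyntheticFamily:
    """Sequences, true tree and per-record truth table."""

    config: FamilyConfig
    records: list[SequenceRecord]
    reference: SequenceRecord
    tree: TreeNode
    truth: dict[str, TruthRow]

    @property
    def templates(self) -> list[SequenceRecord]:
        return [self.reference]

    def positives(self) -> list[SequenceRecord]:
        return [r for r in self.records if self.truth[r.id].is_positive]


def _random_subtree(
    names: list[str], rng: np.random.Generator, bl_mean: float, bl_min: float
) -> TreeNode:
    nodes = [TreeNode(name=n) for n in names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        for child in (a, b):
            child.length = float(max(rng.exponential(bl_mean), bl_min))
        parent = TreeNode(children=[a, b])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    return nodes[0]


def _mutate(
    seq: list[str],
    t: float,
    rate: float,
    protected: frozenset[int],
    rng: np.random.Generator,
) -> list[str]:
    """Evolve a sequence along one branch; positions are 1-based."""
    out = list(seq)
    n_events = rng.poisson(rate * t, size=len(seq))
    for idx in np.nonzero(n_events)[0]:
        if (idx + 1) in protected:
            continue
        for _ in range(int(n_events[idx])):
            current = out[idx]
            choices = [a for a in _AA if a != current]
            out[idx] = choices[int(rng.integers(len(choices)))]
    return out


def _scrub_window_motifs(
    seq: list[str], motif_start: int | None, window: int, protected: frozenset[int],
    rng: np.random.Generator,
) -> None:
    """Remove accidental GxGxxG hits starting within the motif window.

    The planted motif (if any) is left alone; any other hit has at least
    one unprotected G, which is mutated away.
    """
    while True:
        rec = SequenceRecord(id="tmp", residues="".join(seq))
        hits = [
            h for h in scan_gxgxxg(rec)
            if h.start <= window and h.start != motif_start
        ]
        if not hits:
            return
        hit = hits[0]
        g_positions = [hit.start, hit.start + 2, hit.start + 5]
        mutable = [p for p in g_positions if p not in protected]
        if not mutable:  # cannot happen with non-G motif interiors
            raise RuntimeError("accidental motif overlaps only protected sites")
        p = mutable[0]
        seq[p - 1] = _NON_G[int(rng.integers(len(_NON_G)))]


def generate_family(cfg: FamilyConfig) -> SyntheticFamily:
    """Sample a family of positive records along a random binary tree.

    The root's two subtrees are the D-type and Y-type clades. Reproducible
    for a fixed config (including its mandatory seed).
    """
    rng = np.random.default_rng(cfg.seed)
    ms = cfg.motif_start
    protected = frozenset(range(ms, ms + 6)) | frozenset(cfg.key_positions)
    window = 60

    scaffold = [_AA[int(rng.integers(20))] for _ in range(cfg.scaffold_length)]
    # plant the dinucleotide-binding motif with non-G interior residues
    interior = [_NON_G[int(rng.integers(len(_NON_G)))] for _ in range(3)]
    motif = ["G", interior[0], "G", interior[1], interior[2], "G"]
    scaffold[ms - 1 : ms + 5] = motif
    scaffold[111 - 1] = "ST"[int(rng.integers(2))]
    scaffold[137 - 1] = "AILMFV"[int(rng.integers(6))]
    scaffold[191 - 1] = "AILMFV"[int(rng.integers(6))]
    # the ancestor itself carries the D-regime residues, so the reference/
    # template sequence is a valid family member in its own right
    d_plants = {139: "VTI"[int(rng.integers(3))], 187: "D", 194: "ML"[int(rng.integers(2))]}
    for pos, res in d_plants.items():
        scaffold[pos - 1] = res
    _scrub_window_motifs(scaffold, ms, window, protected, rng)

    n_d = (cfg.n_taxa + 1) // 2
    d_names = [f"D{i + 1:02d}" for i in range(n_d)]
    y_names = [f"Y{i + 1:02d}" for i in range(cfg.n_taxa - n_d)]
    d_clade = _random_subtree(d_names, rng, cfg.branch_length_mean, cfg.branch_length_min)
    y_clade = _random_subtree(y_names, rng, cfg.branch_length_mean, cfg.branch_length_min)
    d_clade.length = cfg.clade_separation
    y_clade.length = cfg.clade_separation
    tree = TreeNode(children=[d_clade, y_clade])

    clade_plants = {
        id(d_clade): d_plants,
        id(y_clade): {139: "P", 187: "Y", 194: "F"},
    }

    leaf_seqs: dict[str, str] = {}

    def descend(node: TreeNode, seq: list[str]) -> None:
        seq = list(seq)
        plants = clade_plants.get(id(node))
        if plants:
            for pos, res in plants.items():
                seq[pos - 1] = res
        if node.length:
            seq = _mutate(seq, node.length, cfg.rate, protected, rng)
        if node.is_tip():
            _scrub_window_motifs(seq, ms, window, protected, rng)
            leaf_seqs[node.name] = "".join(seq)
        else:
            for child in node.children:
                descend(child, seq)

    for child in tree.children:
        descend(child, scaffold)

    reference = SequenceRecord(id="REF", residues="".join(scaffold),
                               description="family ancestor (reference numbering)")
    records = [
        SequenceRecord(id=name, residues=leaf_seqs[name])
        for name in d_names + y_names
    ]
    truth = {r.id: _audit_record(r, cfg, is_positive=True) for r in records}
    family = SyntheticFamily(
        config=cfg, records=records, reference=reference, tree=tree, truth=truth
    )
    audit_family(family)
    return family


def _audit_record(
    record: SequenceRecord,
    cfg: FamilyConfig,
    is_positive: bool,
    negative_mode: str | None = None,
) -> TruthRow:
    """Derive the truth row by direct inspection of the emitted sequence.

    With no indels, reference numbering is the identity map, so key
    residues are read off literally.
    """
    hits = [h for h in scan_gxgxxg(record) if h.start <= 60]
    has_motif = bool(hits) and len(record) >= 250
    key_res = {
        pos: (record.residues[pos - 1] if pos <= len(record) else None)
        for pos in cfg.key_positions
    }
    donor = key_res.get(187)
    if donor in ("D", "E"):
        dtype = "D-type"
    elif donor == "Y":
        dtype = "Y-type"
    else:
        dtype = "other"
    if all(key_res.get(p) for p in (137, 139, 187, 191, 194)):
        sel = predict_selectivity(
            KeyResidues(
                res_137eq=key_res[137], res_139eq=key_res[139], res_187eq=key_res[187],
                res_191eq=key_res[191], res_194eq=key_res[194],
            ),
            call_id=record.id,
        ).prediction if donor in ("D", "E", "Y") else INDETERMINATE
    else:
        sel = INDETERMINATE
    failures = [] if is_positive else [MODE_TARGET[negative_mode]]
    return TruthRow(
        id=record.id,
        is_positive=is_positive,
        has_motif=has_motif,
        key_residues=key_res,
        donor_type=dtype,
        expected_pass=is_positive,
        expected_failures=failures,
        expected_selectivity=sel,
        negative_mode=negative_mode,
    )


def audit_family(family: SyntheticFamily) -> None:
    """Verify the stored truth table against the emitted sequences."""
    cfg = family.config
    for rec in family.records:
        row = family.truth[rec.id]
        fresh = _audit_record(rec, cfg, row.is_positive, row.negative_mode)
        if (
            fresh.has_motif != row.has_motif
            or fresh.key_residues != row.key_residues
            or fresh.donor_type != row.donor_type
        ):
            raise AssertionError(f"truth table inconsistent for {rec.id}")
        if row.is_positive:
            if not fresh.has_motif:
                raise AssertionError(f"positive {rec.id} lost its motif")
            if fresh.key_residues[111] not in "ST":
                raise AssertionError(f"positive {rec.id} lost the polar 111 residue")


def plant_negatives(
    family: SyntheticFamily,
    modes: tuple[str, ...] = NEGATIVE_MODES,
    per_mode: int = 1,
    truncate_length: int = 230,
    seed: int | None = None,
) -> SyntheticFamily:
    """Append records violating exactly one selection criterion each.

    Donor/flank modes are derived from D-clade members (the flank rule is
    waived for Tyr donors); ``distant_outgroup`` is an unrelated random
    sequence whose targeted criterion is the homology gate.
    """
    rng = np.random.default_rng(family.config.seed + 1 if seed is None else seed)
    cfg = family.config
    ms = cfg.motif_start
    protected = frozenset(range(ms, ms + 6)) | frozenset(cfg.key_positions)
    d_sources = [r for r in family.positives() if family.truth[r.id].donor_type == "D-type"]
    counter = {m: 0 for m in NEGATIVE_MODES}
    for mode in modes:
        if mode not in NEGATIVE_MODES:
            raise ValueError(f"unknown negative mode {mode!r}")
        for _ in range(per_mode):
            counter[mode] += 1
            src = d_sources[counter[mode] % len(d_sources)]
            seq = list(src.residues)
            if mode == "ablate_motif":
                for g in (ms, ms + 2, ms + 5):
                    seq[g - 1] = "A"
                _scrub_window_motifs(seq, None, 60, frozenset(cfg.key_positions), rng)
            elif mode == "truncate":
                seq = seq[:truncate_length]
            elif mode == "break_donor":
                seq[187 - 1] = "K"
            elif mode == "polar_flank":
                seq[191 - 1] = "S"
            elif mode == "break_111":
                seq[111 - 1] = "A"
            elif mode == "distant_outgroup":
                seq = [_AA[int(rng.integers(20))] for _ in range(cfg.scaffold_length)]
            rec = SequenceRecord(
                id=f"NEG_{mode}_{counter[mode]:02d}", residues="".join(seq)
            )
            family.records.append(rec)
            family.truth[rec.id] = _audit_record(
                rec, cfg, is_positive=False, negative_mode=mode
            )
    audit_family(family)
    return family


def additive_matrix_from_tree(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path lengths; additive by construction."""

    dists: dict[tuple[str, str], float] = {}

    def collect(node: TreeNode) -> list[tuple[str, float]]:
        if node.is_tip():
            below = [(node.name, 0.0)]
        else:
            groups = [collect(c) for c in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for name_a, da in groups[gi]:
                        for name_b, db in groups[gj]:
                            key = tuple(sorted((name_a, name_b)))
                            dists[key] = da + db
            below = [t for g in groups for t in g]
        length = node.length or 0.0
        return [(name, d + length) for name, d in below]

    collect(tree)
    ids = sorted({n for pair in dists for n in pair})
    n = len(ids)
    mat = np.zeros((n, n))
    for (a, b), d in dists.items():
        i, j = ids.index(a), ids.index(b)
        mat[i, j] = mat[j, i] = d
    return DistanceMatrix(ids, mat)


def random_tree(
    n_taxa: int, rng: np.random.Generator, bl_mean: float = 0.15, bl_min: float = 0.01
) -> TreeNode:
    """A random binary tree with positive branch lengths (for NJ oracles)."""
    names = [f"T{i + 1:02d}" for i in range(n_taxa)]
    tree = _random_subtree(names, rng, bl_mean, bl_min)
    tree.length = None
    return tree
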