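"""Donor typing and stereoselectivity prediction from active-site residues.

IREDs fall into two phylogenetic branches named after the proton-donor
residue at position 187 (IRED-B numbering): the D-type branch (Asp or Glu)
and the Y-type branch (Tyr). Stereoselectivity correlates better with a
second residue pair: (S)-selective enzymes carry Pro at 139 and Phe at 194,
while (R)-selective ones carry a hydrophobic residue (Val/Thr/Ile) at 139
and Met or Leu at 194. The S-markers are reported as invariant and take
precedence; an enzyme matching neither rule is called indeterminate rather
than defaulted to the donor-type-implied selectivity, because the donor
residue alone is a known-unreliable predictor (the bundled reference panel
contains one D-type enzyme, IRED-G, that is (S)-selective).

The bundled reference panel mirrors the printed partial-alignment segments
of the 14 characterised enzymes (IRED-A .. IRED-N). Segment columns are
pre-aligned to IRED-B coordinates: segment 1 ends at the 139-equivalent
column (so columns 4 and 6 are the 137/139 equivalents) and segment 2
starts at the 185-equivalent column (so columns 3, 7 and 10 are the
187/191/194 equivalents).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from .align import PositionMap
from .discovery import DEFAULT_SETS, ResidueClassSets
from .seqio import AMINO_ACIDS, SequenceRecord

D_TYPE, Y_TYPE, OTHER = "D-type", "Y-type", "other"
S_PRED, R_PRED, INDETERMINATE = "S", "R", "indeterminate"

# 1-based columns of the key residues within the pre-aligned segments
_SEG1_COLS = {"res_137eq": 4, "res_139eq": 6}
_SEG2_COLS = {"res_187eq": 3, "res_191eq": 7, "res_194eq": 10}


@dataclass(frozen=True)
class Table1Segments:
    """One enzyme's pre-aligned partial-sequence segments."""

    id: str
    start1: int
    segment1: str
    end1: int
    start2: int
    segment2: str
    end2: int
    uniprot: str = ""
    literature_selectivity: str = ""

    def __post_init__(self) -> None:
        if len(self.segment1) != 6:
            raise ValueError(f"{self.id}: segment1 must be 6 residues")
        if len(self.segment2) != 12:
            raise ValueError(f"{self.id}: segment2 must be 12 residues")
        for start, seg, end in (
            (self.start1, self.segment1, self.end1),
            (self.start2, self.segment2, self.end2),
        ):
            if end - start + 1 != len(seg):
                raise ValueError(f"{self.id}: printed coordinates do not span segment")


@dataclass(frozen=True)
class KeyResidues:
    """The five key active-site residues in IRED-B-equivalent columns."""

    res_137eq: str
    res_139eq: str
    res_187eq: str
    res_191eq: str
    res_194eq: str


@dataclass
class SelectivityCall:
    """Donor type plus rule-based stereoselectivity prediction."""

    id: str
    donor_type: str
    prediction: str
    matched_rule: str  # "s_rule" | "r_rule" | "none"
    evidence: dict
    donor_selectivity_mismatch: bool = False


def key_residues_from_segments(seg: Table1Segments) -> KeyResidues:
    vals = {name: seg.segment1[col - 1] for name, col in _SEG1_COLS.items()}
    vals |= {name: seg.segment2[col - 1] for name, col in _SEG2_COLS.items()}
    return KeyResidues(**vals)


def donor_type(res_187eq: str) -> str:
    """D or E -> D-type; Y -> Y-type; any other residue -> other."""
    if res_187eq not in AMINO_ACIDS:
        raise ValueError(f"not an amino-acid residue: {res_187eq!r}")
    if res_187eq in "DE":
        return D_TYPE
    if res_187eq == "Y":
        return Y_TYPE
    return OTHER


def predict_selectivity(
    k: KeyResidues, sets: ResidueClassSets = DEFAULT_SETS, call_id: str = ""
) -> SelectivityCall:
    """Apply the (S)- and (R)-marker rules to the 139/194 residue pair.

    S-rule: 139 = Pro and 194 = Phe. R-rule: 139 in {V,T,I} and
    194 in {M,L}. S takes precedence; neither rule -> indeterminate.
    """
    dtype = donor_type(k.res_187eq)
    s_match = k.res_139eq in sets.s_rule_139 and k.res_194eq in sets.s_rule_194
    r_match = k.res_139eq in sets.r_rule_139 and k.res_194eq in sets.r_rule_194
    if s_match:
        prediction, rule = S_PRED, "s_rule"
    elif r_match:
        prediction, rule = R_PRED, "r_rule"
    else:
        prediction, rule = INDETERMINATE, "none"
    mismatch = (dtype == D_TYPE and prediction == S_PRED) or (
        dtype == Y_TYPE and prediction == R_PRED
    )
    return SelectivityCall(
        id=call_id,
        donor_type=dtype,
        prediction=prediction,
        matched_rule=rule,
        evidence={
            "res_139eq": k.res_139eq,
            "res_194eq": k.res_194eq,
            "res_187eq": k.res_187eq,
        },
        donor_selectivity_mismatch=mismatch,
    )


def load_table1() -> list[Table1Segments]:
    """The bundled 14-enzyme reference panel (IRED-A .. IRED-N)."""
    text = (resources.files("iredmine.data") / "table1_segments.tsv").read_text()
    out = []
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        out.append(
            Table1Segments(
                id=row["id"],
                uniprot=row["uniprot"],
                start1=int(row["start1"]),
                segment1=row["seg1"],
                end1=int(row["end1"]),
                start2=int(row["start2"]),
                segment2=row["seg2"],
                end2=int(row["end2"]),
                literature_selectivity=row["literature_selectivity"],
            )
        )
    return out


def classify_table1(
    fixtures: list[Table1Segments] | None = None,
    sets: ResidueClassSets = DEFAULT_SETS,
) -> tuple[list[SelectivityCall], dict]:
    """Classify the reference panel; returns per-enzyme calls and a summary."""
    fixtures = fixtures if fixtures is not None else load_table1()
    calls = [
        predict_selectivity(key_residues_from_segments(seg), sets, call_id=seg.id)
        for seg in fixtures
    ]
    summary = {
        "donor_counts": _count(c.donor_type for c in calls),
        "prediction_counts": _count(c.prediction for c in calls),
        "mismatches": [c.id for c in calls if c.donor_selectivity_mismatch],
        "indeterminate": [c.id for c in calls if c.prediction == INDETERMINATE],
    }
    return calls, summary


def annotate_candidates(
    candidates: list[SequenceRecord],
    posmaps: dict[str, PositionMap],
    sets: ResidueClassSets = DEFAULT_SETS,
) -> list[SelectivityCall]:
    """Selectivity calls for filtered candidates via their position maps.

    A gap at any key position yields an indeterminate call with reason
    "unaligned" in the evidence.
    """
    calls = []
    for cand in candidates:
        posmap = posmaps[cand.id]
        residues = {}
        unaligned = []
        for pos in (137, 139, 187, 191, 194):
            cpos = posmap.mapping.get(pos)
            if cpos is None:
                unaligned.append(pos)
                residues[pos] = None
            else:
                residues[pos] = cand.residues[cpos - 1]
        if unaligned or any(r not in AMINO_ACIDS for r in residues.values()):
            dtype = donor_type(residues[187]) if residues[187] in AMINO_ACIDS else OTHER
            calls.append(
                SelectivityCall(
                    id=cand.id,
                    donor_type=dtype,
                    prediction=INDETERMINATE,
                    matched_rule="none",
                    evidence={
                        "unaligned_positions": unaligned,
                        **{f"res_{p}eq": residues[p] for p in residues},
                    },
                )
            )
            continue
        k = KeyResidues(
            res_137eq=residues[137],
            res_139eq=residues[139],
            res_187eq=residues[187],
            res_191eq=residues[191],
            res_194eq=residues[194],
        )
        calls.append(predict_selectivity(k, sets, call_id=cand.id))
    return calls


def calls_to_tsv(calls: list[SelectivityCall]) -> str:
    lines = ["id\tdonor_type\tprediction\tmatched_rule\tdonor_selectivity_mismatch"]
    for c in calls:
        lines.append(
            f"{c.id}\t{c.donor_type}\t{c.prediction}\t{c.matched_rule}"
            f"\t{c.donor_selectivity_mismatch}"
        )
    return "\n".join(lines) + "\n"


def _count(items) -> dict:
    out: dict[str, int] = {}
    for x in items:
        out[x] = out.get(x, 0) + 1
    return dict(sorted(out.items()))
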