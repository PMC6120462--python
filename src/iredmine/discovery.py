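"""Candidate-selection criteria for sequence-based IRED discovery.

A candidate passes when it

(i)   scores an E-value at or below the homology gate (default 1e-50)
      against at least one of the template IRED sequences,
(ii)  looks like a full-length Rossmann-fold protein: at least ``min_len``
      residues with a complete GxGxxG dinucleotide-binding consensus
      starting within the first ``window`` residues,
(iii) carries a polar residue (Ser/Thr) at the 111-equivalent position, and
(iv)  carries a proton-donor residue at the 187-equivalent position:
      Asp/Glu with apolar residues (Ala/Ile/Leu/Met/Phe/Val) at BOTH
      flanking positions 137 and 191, or a Tyr (flanks not required).

Positions are in reference (IRED-B) numbering and are transferred to each
candidate through a global alignment with the reference. Criterion (iii)
can be toggled off to reproduce the three-criterion reading of the
selection procedure.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

from .align import (
    PositionMap,
    ScoringParams,
    global_align,
    local_align,
    map_positions,
    significance,
)
from .seqio import DedupReport, SequenceRecord, deduplicate

#: Reference-numbering coordinates of the active-site key positions.
KEY_POSITIONS = (111, 137, 139, 187, 191, 194)

_MOTIF_RE = re.compile(r"(?=(G[^X]G[^X][^X]G))")


@dataclass(frozen=True)
class MotifHit:
    """A GxGxxG match; ``start`` is the 1-based position of the first G."""

    start: int
    matched_text: str


@dataclass(frozen=True)
class ResidueClassSets:
    """Residue classes used by the selection criteria."""

    polar_111: frozenset = frozenset("ST")
    acidic_donor: frozenset = frozenset("DE")
    tyr_donor: frozenset = frozenset("Y")
    apolar_flank: frozenset = frozenset("AILMFV")
    s_rule_139: frozenset = frozenset("P")
    s_rule_194: frozenset = frozenset("F")
    r_rule_139: frozenset = frozenset("VTI")
    r_rule_194: frozenset = frozenset("ML")


DEFAULT_SETS = ResidueClassSets()


@dataclass
class CandidateVerdict:
    """Per-candidate record of every criterion with its evidence."""

    id: str
    passed_evalue: bool | None = None
    best_e_value: float | None = None
    best_template: str | None = None
    has_rossmann: bool | None = None
    motif: MotifHit | None = None
    polar_111_ok: bool | None = None
    res_111: str | None = None
    donor_residue: str | None = None
    donor_ok: bool | None = None
    flank_137: str | None = None
    flank_137_apolar: bool | None = None
    flank_191: str | None = None
    flank_191_apolar: bool | None = None
    mapped_positions: dict = field(default_factory=dict)
    failure_reasons: list[str] = field(default_factory=list)

    @property
    def overall_pass(self) -> bool:
        checks = [self.passed_evalue, self.has_rossmann, self.polar_111_ok, self.donor_ok]
        return all(c is not False and c is not None for c in checks if c is not None) and any(
            c is not None for c in checks
        ) and not self.failure_reasons

    def as_dict(self) -> dict:
        return {
            "id": self.id,
            "passed_evalue": self.passed_evalue,
            "best_e_value": self.best_e_value,
            "best_template": self.best_template,
            "has_rossmann": self.has_rossmann,
            "motif_start": self.motif.start if self.motif else None,
            "polar_111_ok": self.polar_111_ok,
            "res_111": self.res_111,
            "donor_residue": self.donor_residue,
            "donor_ok": self.donor_ok,
            "flank_137": self.flank_137,
            "flank_191": self.flank_191,
            "overall_pass": self.overall_pass,
            "failure_reasons": list(self.failure_reasons),
        }


@dataclass
class FilterReport:
    """Stage-by-stage accounting of a discovery filter run."""

    n_input: int
    n_after_dedup: int
    n_pass_evalue: int
    n_pass_all: int
    verdicts: list[CandidateVerdict]
    dedup: DedupReport | None = None

    def verdict(self, candidate_id: str) -> CandidateVerdict:
        for v in self.verdicts:
            if v.id == candidate_id:
                return v
        raise KeyError(candidate_id)

    def passing_ids(self) -> list[str]:
        return [v.id for v in self.verdicts if v.overall_pass]

    def to_tsv(self) -> str:
        header = (
            "id\tpassed_evalue\tbest_e_value\tbest_template\thas_rossmann\tmotif_start"
            "\tres_111\tpolar_111_ok\tdonor_residue\tdonor_ok\tflank_137\tflank_191"
            "\toverall_pass\tfailure_reasons"
        )
        rows = [header]
        for v in self.verdicts:
            d = v.as_dict()
            rows.append(
                "\t".join(
                    "" if d[k] is None else str(d[k])
                    for k in (
                        "id", "passed_evalue", "best_e_value", "best_template",
                        "has_rossmann", "motif_start", "res_111", "polar_111_ok",
                        "donor_residue", "donor_ok", "flank_137", "flank_191",
                        "overall_pass",
                    )
                )
                + "\t"
                + ";".join(v.failure_reasons)
            )
        return "\n".join(rows) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_after_dedup": self.n_after_dedup,
                "n_pass_evalue": self.n_pass_evalue,
                "n_pass_all": self.n_pass_all,
                "verdicts": [v.as_dict() for v in self.verdicts],
            },
            indent=2,
        )


def scan_gxgxxg(record: SequenceRecord) -> list[MotifHit]:
    """All (possibly overlapping) GxGxxG windows, in position order."""
    return [
        MotifHit(start=m.start() + 1, matched_text=m.group(1))
        for m in _MOTIF_RE.finditer(record.residues)
    ]


def check_rossmann(
    record: SequenceRecord, window: int = 60, min_len: int = 250
) -> tuple[bool, MotifHit | None]:
    """Full-length Rossmann-fold check.

    True iff the sequence has at least ``min_len`` residues (excluding
    truncated entries) and a GxGxxG motif starting within the first
    ``window`` residues. The earliest such hit is reported.
    """
    if record.contains_x:
        return False, None
    hits = [h for h in scan_gxgxxg(record) if h.start <= window]
    hit = hits[0] if hits else None
    return (len(record) >= min_len and hit is not None), hit


def evaluate_residue_criteria(
    candidate: SequenceRecord,
    posmap: PositionMap,
    sets: ResidueClassSets = DEFAULT_SETS,
    verdict: CandidateVerdict | None = None,
) -> CandidateVerdict:
    """Evaluate the polar-111 and proton-donor/flank criteria.

    ``posmap`` must map the reference positions 111, 137, 187 and 191 onto
    the candidate. An unaligned key position fails its criterion with reason
    "unaligned" rather than raising, so batch runs complete.
    """
    v = verdict or CandidateVerdict(id=candidate.id)
    for pos in (111, 137, 187, 191):
        if pos not in posmap.mapping:
            raise ValueError(f"position map lacks reference position {pos}")

    def residue_at(refpos: int) -> str | None:
        cpos = posmap.mapping[refpos]
        if cpos is None:
            return None
        return candidate.residues[cpos - 1]

    v.mapped_positions = dict(posmap.mapping)
    if candidate.contains_x:
        v.polar_111_ok = False
        v.donor_ok = False
        v.failure_reasons.append("contains_X")
        return v

    v.res_111 = residue_at(111)
    if v.res_111 is None:
        v.polar_111_ok = False
        v.failure_reasons.append("polar_111:unaligned")
    else:
        v.polar_111_ok = v.res_111 in sets.polar_111
        if not v.polar_111_ok:
            v.failure_reasons.append("polar_111")

    v.donor_residue = residue_at(187)
    v.flank_137 = residue_at(137)
    v.flank_191 = residue_at(191)
    v.flank_137_apolar = v.flank_137 in sets.apolar_flank if v.flank_137 else False
    v.flank_191_apolar = v.flank_191 in sets.apolar_flank if v.flank_191 else False
    if v.donor_residue is None:
        v.donor_ok = False
        v.failure_reasons.append("donor_residue:unaligned")
    elif v.donor_residue in sets.tyr_donor:
        v.donor_ok = True
    elif v.donor_residue in sets.acidic_donor:
        v.donor_ok = v.flank_137_apolar and v.flank_191_apolar
        if not v.donor_ok:
            v.failure_reasons.append("apolar_flank")
    else:
        v.donor_ok = False
        v.failure_reasons.append("donor_residue")
    return v


def run_filter(
    candidates: list[SequenceRecord],
    templates: list[SequenceRecord],
    reference: SequenceRecord,
    key_positions: tuple[int, ...] = KEY_POSITIONS,
    params: ScoringParams | None = None,
    evalue_threshold: float = 1e-50,
    window: int = 60,
    min_len: int = 250,
    enforce_polar_111: bool = True,
    enforce_donor: bool = True,
    effective_db_length: int | None = None,
    sets: ResidueClassSets = DEFAULT_SETS,
) -> tuple[list[SequenceRecord], FilterReport, dict[str, PositionMap]]:
    """Run the full selection pipeline: dedup, E-gate, Rossmann, residues.

    Every criterion is evaluated for every deduplicated candidate so each
    verdict names all violated criteria; ``overall_pass`` is their
    conjunction. Returns the passing records, the report, and the position
    maps (reference numbering -> candidate coordinates) for downstream
    selectivity annotation.
    """
    if not templates:
        raise ValueError("at least one template sequence is required")
    params = params or ScoringParams()
    unique, dedup_report = deduplicate(candidates)
    if effective_db_length is None:
        effective_db_length = sum(len(r) for r in unique) or 1

    posmaps: dict[str, PositionMap] = {}
    verdicts: list[CandidateVerdict] = []
    for cand in unique:
        v = CandidateVerdict(id=cand.id)
        # (i) homology gate: best E-value over the templates
        best_e, best_t = None, None
        for tmpl in templates:
            aln = local_align(tmpl, cand, params)
            _, e = significance(aln.raw_score, len(tmpl), effective_db_length, params)
            if best_e is None or e < best_e:
                best_e, best_t = e, tmpl.id
        v.best_e_value = best_e
        v.best_template = best_t
        v.passed_evalue = best_e is not None and best_e <= evalue_threshold
        if not v.passed_evalue:
            v.failure_reasons.append("evalue")
        # (ii) Rossmann / full length
        v.has_rossmann, v.motif = check_rossmann(cand, window=window, min_len=min_len)
        if not v.has_rossmann:
            v.failure_reasons.append("rossmann")
        # (iii)+(iv) residue criteria in reference numbering
        ref_aln = global_align(reference, cand, params)
        posmap = map_positions(ref_aln, reference.id, key_positions, len(reference))
        posmaps[cand.id] = posmap
        evaluate_residue_criteria(cand, posmap, sets, verdict=v)
        if not enforce_polar_111:
            v.polar_111_ok = None
            v.failure_reasons = [r for r in v.failure_reasons if not r.startswith("polar_111")]
        if not enforce_donor:
            v.donor_ok = None
            v.failure_reasons = [
                r for r in v.failure_reasons
                if r not in ("donor_residue", "donor_residue:unaligned", "apolar_flank")
            ]
        verdicts.append(v)

    passing = [c for c, v in zip(unique, verdicts) if v.overall_pass]
    report = FilterReport(
        n_input=len(candidates),
        n_after_dedup=len(unique),
        n_pass_evalue=sum(1 for v in verdicts if v.passed_evalue),
        n_pass_all=len(passing),
        verdicts=verdicts,
        dedup=dedup_report,
    )
    return passing, report, posmaps
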