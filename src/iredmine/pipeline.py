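"""End-to-end orchestration of the discovery analysis.

``run_discovery`` chains the stages: deduplication, homology gate, Rossmann
check, residue criteria, multiple alignment of the survivors, distance
matrix, neighbour-joining tree, donor typing and selectivity prediction.
Every intermediate is written to the output directory, so each number in
the run report is re-derivable from persisted files, and identical
config + seed reproduce identical outputs byte for byte (wall-clock
information goes only to ``run.log``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .align import ScoringParams, progressive_msa
from .discovery import KEY_POSITIONS, FilterReport, run_filter
from .phylo import assign_branch_types, neighbor_joining, pairwise_distance, to_newick
from .selectivity import annotate_candidates, calls_to_tsv, classify_table1
from .seqio import SequenceRecord, read_fasta, write_fasta

logger = logging.getLogger("iredmine")


@dataclass
class RunConfig:
    """Configuration of one discovery run (flat key-value serialisable)."""

    candidates_fasta: str
    templates_fasta: str
    reference_fasta: str
    outdir: str
    key_positions: tuple[int, ...] = KEY_POSITIONS
    evalue_threshold: float = 1e-50
    min_len: int = 250
    motif_window: int = 60
    criteria_polar_111: bool = True
    criteria_donor: bool = True
    distance_model: str = "poisson"
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "key_positions" in raw:
            raw["key_positions"] = tuple(int(p) for p in raw["key_positions"])
        return cls(**raw)

    def validate(self) -> None:
        for attr in ("candidates_fasta", "templates_fasta", "reference_fasta"):
            if not Path(getattr(self, attr)).exists():
                raise FileNotFoundError(f"{attr}: {getattr(self, attr)} does not exist")
        if self.evalue_threshold < 0 or self.min_len <= 0 or self.motif_window <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class RunReport:
    """Counts and output paths of a completed discovery run."""

    n_input: int
    n_after_dedup: int
    n_pass_evalue: int
    n_pass_all: int
    donor_counts: dict = field(default_factory=dict)
    monophyletic: dict = field(default_factory=dict)
    prediction_counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def run_discovery(cfg: RunConfig) -> RunReport:
    """Execute the full pipeline and persist all intermediates."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir / "run.log")
    logger.info("criteria: evalue<=%.3g, min_len>=%d, motif window<=%d, polar_111=%s, donor=%s",
                cfg.evalue_threshold, cfg.min_len, cfg.motif_window,
                cfg.criteria_polar_111, cfg.criteria_donor)
    (outdir / "config.yaml").write_text(
        yaml.safe_dump({**asdict(cfg), "key_positions": list(cfg.key_positions)},
                       sort_keys=True)
    )

    candidates = read_fasta(cfg.candidates_fasta)
    templates = read_fasta(cfg.templates_fasta)
    reference = read_fasta(cfg.reference_fasta)[0]
    params = ScoringParams()

    if not candidates:
        logger.warning("empty candidate set: writing empty report")
        report = RunReport(0, 0, 0, 0)
        (outdir / "run_report.json").write_text(report.to_json())
        return report

    passing, filt, posmaps = run_filter(
        candidates, templates, reference,
        key_positions=cfg.key_positions, params=params,
        evalue_threshold=cfg.evalue_threshold,
        window=cfg.motif_window, min_len=cfg.min_len,
        enforce_polar_111=cfg.criteria_polar_111,
        enforce_donor=cfg.criteria_donor,
    )
    _write_filter_outputs(outdir, filt)
    write_fasta(passing, outdir / "survivors.fasta")
    logger.info("filter: %d input -> %d dedup -> %d pass E-gate -> %d pass all",
                filt.n_input, filt.n_after_dedup, filt.n_pass_evalue, filt.n_pass_all)

    report = RunReport(
        n_input=filt.n_input,
        n_after_dedup=filt.n_after_dedup,
        n_pass_evalue=filt.n_pass_evalue,
        n_pass_all=filt.n_pass_all,
        outputs={"filter_report": "filter_report.tsv", "survivors": "survivors.fasta"},
    )

    calls = annotate_candidates(passing, posmaps)
    (outdir / "selectivity.tsv").write_text(calls_to_tsv(calls))
    report.outputs["selectivity"] = "selectivity.tsv"
    report.prediction_counts = _count(c.prediction for c in calls)

    if len(passing) >= 3:
        msa = progressive_msa(passing, params)
        (outdir / "msa.fasta").write_text(msa.to_fasta())
        dist = pairwise_distance(msa, model=cfg.distance_model)
        (outdir / "distances.tsv").write_text(dist.to_tsv())
        (outdir / "distances.phy").write_text(dist.to_phylip())
        tree = neighbor_joining(dist)
        donor_calls = {c.id: c.donor_type for c in calls}
        tree, summary = assign_branch_types(tree, donor_calls)
        (outdir / "tree.nwk").write_text(to_newick(tree) + "\n")
        report.outputs.update(
            {"msa": "msa.fasta", "distances": "distances.tsv", "tree": "tree.nwk"}
        )
        report.donor_counts = summary.counts
        report.monophyletic = summary.monophyletic
        logger.info("tree: donor partition %s, monophyletic %s",
                    summary.counts, summary.monophyletic)
    else:
        logger.warning("fewer than 3 survivors: skipping alignment and tree stages")

    (outdir / "run_report.json").write_text(report.to_json())
    return report


def classify_table1_report() -> dict:
    """Donor typing and selectivity calls for the bundled reference panel."""
    calls, summary = classify_table1()
    rows = []
    for c in calls:
        rows.append(
            {
                "id": c.id,
                "donor_type": c.donor_type,
                "prediction": c.prediction,
                "matched_rule": c.matched_rule,
                "donor_selectivity_mismatch": c.donor_selectivity_mismatch,
            }
        )
    return {"calls": rows, "summary": summary}


def _write_filter_outputs(outdir: Path, filt: FilterReport) -> None:
    (outdir / "filter_report.tsv").write_text(filt.to_tsv())
    (outdir / "filter_report.json").write_text(filt.to_json())
    if filt.dedup is not None:
        (outdir / "dedup.json").write_text(filt.dedup.to_json())
        (outdir / "dedup.tsv").write_text(filt.dedup.to_tsv())


def _setup_logging(logfile: Path) -> None:
    logger.setLevel(logging.INFO)
    for h in list(logger.handlers):
        logger.removeHandler(h)
    fh = logging.FileHandler(logfile, mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)


def _count(items) -> dict:
    out: dict[str, int] = {}
    for x in items:
        out[x] = out.get(x, 0) + 1
    return dict(sorted(out.items()))


def simulate_to_dir(outdir: str | Path, n_taxa: int = 20, seed: int = 0,
                    with_negatives: bool = True) -> dict:
    """Generate a synthetic family run directory (FASTA + newick + truth TSV)."""
    from .phylo import to_newick as _nwk
    from .simulate import FamilyConfig, generate_family, plant_negatives

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    family = generate_family(FamilyConfig(n_taxa=n_taxa, seed=seed))
    if with_negatives:
        plant_negatives(family)
    write_fasta(family.records, outdir / "family.fasta")
    write_fasta([family.reference], outdir / "reference.fasta")
    write_fasta(family.templates, outdir / "templates.fasta")
    (outdir / "true_tree.nwk").write_text(_nwk(family.tree) + "\n")
    lines = ["id\tis_positive\tnegative_mode\tdonor_type\texpected_selectivity\texpected_failures"]
    for rec in family.records:
        row = family.truth[rec.id]
        lines.append(
            f"{row.id}\t{row.is_positive}\t{row.negative_mode or ''}\t{row.donor_type}"
            f"\t{row.expected_selectivity}\t{';'.join(row.expected_failures)}"
        )
    (outdir / "truth.tsv").write_text("\n".join(lines) + "\n")
    return {
        "n_records": len(family.records),
        "n_positive": len(family.positives()),
        "outdir": str(outdir),
        "seed": seed,
    }
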