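"""End-to-end pipeline: peptide table -> differential -> protease prediction
-> activity scores -> cross-omics concordance, with a machine-readable run
report of the counts at every stage."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

from . import __version__
from .concordance import concordance, write_concordance
from .differential import (ALPHA_DEFAULT, FC_DOWN_DEFAULT, FC_UP_DEFAULT,
                           select_regulated, write_differential)
from .io import (read_cleavage_db, read_evidence_table, read_fasta,
                 read_groups, read_peptide_table)
from .prediction import (CONTEXT_WINDOW_DEFAULT, derive_cleavage_events,
                         match_proteases, write_associations)
from .scoring import (MIN_PEPTIDES_DEFAULT, association_totals,
                      count_occurrences, filter_min_peptides, score_proteases,
                      write_scores)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    peptide_table: str
    groups: str
    fasta: str
    cleavage_db: str
    evidence: str | None = None
    alpha: float = ALPHA_DEFAULT
    fc_up: float = FC_UP_DEFAULT
    fc_down: float = FC_DOWN_DEFAULT
    min_peptides: int = MIN_PEPTIDES_DEFAULT
    window: int = CONTEXT_WINDOW_DEFAULT
    out_dir: str = "urinpep_run"

    def __post_init__(self) -> None:
        if not (0 < self.fc_down < 1 < self.fc_up):
            raise ValueError("need fc_down < 1 < fc_up")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_peptides < 1:
            raise ValueError("min_peptides must be >= 1")


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages, write outputs under ``config.out_dir``, return the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    for label, path in [("peptide table", config.peptide_table),
                        ("groups", config.groups),
                        ("FASTA", config.fasta),
                        ("cleavage DB", config.cleavage_db)]:
        if not Path(path).exists():
            raise PipelineError(f"stage 'input' failed: missing {label} file: {path}")
    if config.evidence is not None and not Path(config.evidence).exists():
        raise PipelineError(f"stage 'input' failed: missing evidence file: "
                            f"{config.evidence}")

    peptides, sample_ids = _stage("read_peptides")(read_peptide_table,
                                                   config.peptide_table)
    groups = _stage("read_groups")(read_groups, config.groups, sample_ids)
    sequences = _stage("read_fasta")(read_fasta, config.fasta)
    db = _stage("read_cleavage_db")(read_cleavage_db, config.cleavage_db)

    results = _stage("differential")(select_regulated, peptides, groups,
                                     config.alpha, config.fc_up, config.fc_down)
    write_differential(results, out / "differential.tsv")
    regulated_ids = {r.peptide_id for r in results if r.direction != "unchanged"}

    def _events():
        events = []
        for pep in peptides:
            if pep.peptide_id not in regulated_ids:
                continue
            if pep.protein_accession not in sequences:
                logger.warning("no parent sequence for %s; peptide %s skipped",
                               pep.protein_accession, pep.peptide_id)
                continue
            events.extend(derive_cleavage_events(
                pep, len(sequences[pep.protein_accession])))
        return events

    events = _stage("cleavage_events")(_events)
    associations = _stage("protease_matching")(match_proteases, events, db,
                                               sequences, config.window)
    write_associations(associations, out / "associations.tsv")

    scores_final = []
    n_up = n_down = 0
    n_scored = 0
    if associations:
        counts = _stage("occurrence_counts")(count_occurrences, associations, results)
        n_up, n_down = association_totals(counts)
        if n_up >= 1 and n_down >= 1:
            scores = _stage("activity_scores")(score_proteases, counts, n_up, n_down)
            n_scored = len(scores)
            scores_final = filter_min_peptides(scores, config.min_peptides)
        else:
            logger.warning("one-sided regulation (n_up=%d, n_down=%d); "
                           "activity scores undefined", n_up, n_down)
    write_scores(scores_final, out / "scores.tsv", out / "scores.json")

    summary = {}
    if config.evidence is not None:
        evidence = _stage("read_evidence")(read_evidence_table, config.evidence)
        records, summary = _stage("concordance")(concordance, scores_final, evidence)
        write_concordance(records, summary, out / "concordance.tsv",
                          out / "concordance.json")

    report = {
        "version": __version__,
        "config": asdict(config),
        "counts": {
            "peptides_detected": len(peptides),
            "samples_case": len(groups.case_ids),
            "samples_control": len(groups.control_ids),
            "regulated_up": sum(r.direction == "up" for r in results),
            "regulated_down": sum(r.direction == "down" for r in results),
            "cleavage_events": len(events),
            "associations": len(associations),
            "n_up": n_up,
            "n_down": n_down,
            "proteases_scored": n_scored,
            "proteases_reported": len(scores_final),
        },
        "concordance_summary": summary,
        "proteases": [
            {"protease": s.protease, "score": s.score_display,
             "pct_freq": s.pct_freq_display,
             "occ_up": s.occ_up, "occ_down": s.occ_down}
            for s in scores_final
        ],
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
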