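"""Cross-omics concordance of predicted protease activity with external evidence.

Each scored protease's predicted direction (activated if score > 0, else
deactivated) is compared against direction calls from external sources —
kidney tissue transcriptomics and protein expression studies.  A source
agrees when activation meets increase or deactivation meets decrease, and
opposes when they cross; ``no_change`` and ``inconclusive`` evidence passes
through as its own verdict, and absent evidence is ``missing``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from .scoring import ActivityScore

logger = logging.getLogger(__name__)

SOURCES = ("transcriptomics", "protein_expression")
DIRECTIONS = ("increase", "decrease", "no_change", "inconclusive", "missing")
VERDICTS = ("agree", "oppose", "no_change", "inconclusive", "missing")


@dataclass(frozen=True)
class EvidenceRecord:
    protease: str
    source: str
    direction: str

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown evidence source {self.source!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown evidence direction {self.direction!r}")


@dataclass
class ConcordanceRecord:
    protease: str
    predicted: str  # "activated" | "deactivated"
    verdicts: dict[str, str] = field(default_factory=dict)  # source -> verdict


def _verdict(predicted: str, direction: str) -> str:
    if direction in ("no_change", "inconclusive", "missing"):
        return direction
    concordant = (predicted == "activated") == (direction == "increase")
    return "agree" if concordant else "oppose"


def concordance(scores: Iterable[ActivityScore],
                evidence: Iterable[EvidenceRecord],
                ) -> tuple[list[ConcordanceRecord], dict[str, dict[str, int]]]:
    """Annotate scored proteases with per-source verdicts and tally them.

    Returns the per-protease records (in score-table order) and a summary
    ``{source: {verdict: count}}``.  Evidence for proteases absent from the
    score table is flagged with a warning and ignored in the tallies.
    """
    scores = list(scores)
    by_protease: dict[str, dict[str, str]] = {}
    scored_names = {s.protease for s in scores}
    for ev in evidence:
        if ev.protease not in scored_names:
            logger.warning("evidence for unscored protease %s ignored", ev.protease)
            continue
        slot = by_protease.setdefault(ev.protease, {})
        if ev.source in slot:
            raise ValueError(f"duplicate evidence for ({ev.protease}, {ev.source})")
        slot[ev.source] = ev.direction

    records = []
    summary = {source: {v: 0 for v in VERDICTS} for source in SOURCES}
    for s in scores:
        predicted = "activated" if s.score > 0 else "deactivated"
        verdicts = {}
        for source in SOURCES:
            direction = by_protease.get(s.protease, {}).get(source, "missing")
            verdict = _verdict(predicted, direction)
            verdicts[source] = verdict
            summary[source][verdict] += 1
        records.append(ConcordanceRecord(s.protease, predicted, verdicts))
    return records, summary


def write_concordance(records: Iterable[ConcordanceRecord],
                      summary: dict[str, dict[str, int]],
                      tsv_path, json_path=None) -> None:
    import json

    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "protease": r.protease,
                "predicted": r.predicted,
                **{source: r.verdicts.get(source, "missing") for source in SOURCES},
            }
            for r in records
        ],
        columns=["protease", "predicted", *SOURCES],
    )
    df.to_csv(tsv_path, sep="\t", index=False, lineterminator="\n")
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
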