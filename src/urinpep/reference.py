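"""Bundled reference dataset from a published urinary peptidomics study of
diabetic nephropathy.

The study compared urinary CE-MS peptide profiles of 121 macroalbuminuric
diabetic patients against 118 normoalbuminuric diabetic controls, predicted
cleaving proteases for the differentially abundant peptides from observed
cleavage sites, and scored each protease's activity change.  This module
ships the published per-protease regulated-peptide counts (occ_up/occ_down),
the association totals (n_up = 93, n_down = 42, summing to the study's 135
protease-peptide associations), the published rounded scores, and the
study's cross-omics direction calls — enough to re-derive the published
score table from counts and to check any scoring change against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

from .concordance import EvidenceRecord
from .scoring import ActivityScore


@dataclass(frozen=True)
class ReferenceRow:
    protease: str
    occ_up: int
    occ_down: int
    pct_freq: int      # as published (nearest integer)
    score: float       # as published (2 decimals)


def _load() -> dict:
    with resources.files("urinpep.data").joinpath("reference_study.json").open() as fh:
        return json.load(fh)


def reference_totals() -> tuple[int, int]:
    """(n_up, n_down) association totals of the reference study."""
    data = _load()
    return data["n_up"], data["n_down"]


def reference_rows() -> list[ReferenceRow]:
    """Published counts and rounded score values, in published order."""
    return [
        ReferenceRow(r["protease"], r["occ_up"], r["occ_down"],
                     r["pct_freq"], r["score"])
        for r in _load()["proteases"]
    ]


def reference_counts() -> dict[str, tuple[int, int]]:
    """protease -> (occ_up, occ_down) for the 17 reported proteases."""
    return {r.protease: (r.occ_up, r.occ_down) for r in reference_rows()}


def reference_scores() -> list[ActivityScore]:
    """Recompute ActivityScore objects from the reference counts and totals."""
    n_up, n_down = reference_totals()
    return [
        ActivityScore(r.protease, r.occ_up, r.occ_down, n_up, n_down)
        for r in reference_rows()
    ]


def reference_evidence() -> list[EvidenceRecord]:
    """Cross-omics direction evidence; proteases without a call are omitted."""
    records = []
    for r in _load()["proteases"]:
        for source in ("transcriptomics", "protein_expression"):
            if r[source] != "missing":
                records.append(EvidenceRecord(r["protease"], source, r[source]))
    return records


def compare_to_published(counts: dict[str, tuple[int, int]] | None = None,
                         n_up: int | None = None,
                         n_down: int | None = None) -> list[dict]:
    """Re-score counts and diff against the published rounded values.

    Defaults to the bundled counts/totals.  Returns one dict per protease
    with recomputed and published (pct_freq, score) and a ``match`` flag at
    the published rounding.
    """
    published = {r.protease: r for r in reference_rows()}
    if counts is None:
        counts = reference_counts()
    if n_up is None or n_down is None:
        n_up, n_down = reference_totals()
    report = []
    for protease, (occ_up, occ_down) in counts.items():
        s = ActivityScore(protease, occ_up, occ_down, n_up, n_down)
        pub = published.get(protease)
        report.append({
            "protease": protease,
            "occ_up": occ_up,
            "occ_down": occ_down,
            "pct_freq": s.pct_freq_display,
            "score": s.score_display,
            "published_pct_freq": pub.pct_freq if pub else None,
            "published_score": pub.score if pub else None,
            "match": (pub is not None
                      and s.pct_freq_display == pub.pct_freq
                      and s.score_display == pub.score),
        })
    return report
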