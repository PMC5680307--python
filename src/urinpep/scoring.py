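"""Protease activity scoring from regulated-peptide associations.

For each predicted protease, let occ(up) and occ(down) be the numbers of its
associated peptides that are up- and down-regulated, and let n(up), n(down)
be the totals of up-/down-regulated protease-peptide associations summed over
*all* predicted proteases (with multiplicity: a peptide associated with three
proteases contributes three associations).  Then with n(total) = n(up) + n(down):

    weight      = occ(down)/n(down) + occ(up)/n(up)
    freq%(up)   = occ(up)   / n(total) * 100
    freq%(down) = occ(down) / n(total) * 100
    %freq       = (freq%(up) - freq%(down)) / (freq%(up) + freq%(down)) * 100
                = (occ(up) - occ(down)) / (occ(up) + occ(down)) * 100
    Score       = %freq * weight

%freq lies in [-100, 100] and measures the imbalance of a protease's up vs
down associations; the weight scales it by how much of the overall regulated
signal the protease accounts for.  A positive score predicts increased
proteolytic activity in cases, a negative score decreased activity.  A
minimum number of associated peptides (default 3) gates the reported list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from .differential import DifferentialResult
from .prediction import ProteasePeptideAssociation

logger = logging.getLogger(__name__)

MIN_PEPTIDES_DEFAULT = 3


@dataclass
class ActivityScore:
    """Full-precision score components for one protease.

    ``pct_freq_display`` and ``score_display`` carry the reporting precision
    (nearest integer / 2 decimals); all other fields are exact.
    """

    protease: str
    occ_up: int
    occ_down: int
    n_up: int
    n_down: int

    def __post_init__(self) -> None:
        if self.occ_up + self.occ_down < 1:
            raise ValueError(f"{self.protease}: needs at least one associated peptide")
        if self.occ_up < 0 or self.occ_down < 0:
            raise ValueError(f"{self.protease}: negative occurrence count")
        if self.n_up < max(self.occ_up, 1) or self.n_down < max(self.occ_down, 1):
            raise ValueError(
                f"{self.protease}: totals (n_up={self.n_up}, n_down={self.n_down}) "
                f"inconsistent with counts ({self.occ_up}, {self.occ_down})"
            )

    @property
    def n_total(self) -> int:
        return self.n_up + self.n_down

    @property
    def weight(self) -> float:
        return self.occ_down / self.n_down + self.occ_up / self.n_up

    @property
    def freq_up_pct(self) -> float:
        return self.occ_up / self.n_total * 100.0

    @property
    def freq_down_pct(self) -> float:
        return self.occ_down / self.n_total * 100.0

    @property
    def pct_freq(self) -> float:
        up, down = self.freq_up_pct, self.freq_down_pct
        return (up - down) / (up + down) * 100.0

    @property
    def score(self) -> float:
        return self.pct_freq * self.weight

    @property
    def pct_freq_display(self) -> int:
        return round(self.pct_freq)

    @property
    def score_display(self) -> float:
        return round(self.score, 2)

    @property
    def n_peptides(self) -> int:
        return self.occ_up + self.occ_down


def count_occurrences(associations: Iterable[ProteasePeptideAssociation],
                      results: Iterable[DifferentialResult]) -> dict[str, tuple[int, int]]:
    """Per-protease (occ_up, occ_down): unique regulated peptides per direction.

    Every associated peptide must appear in ``results``; associations to
    peptides left "unchanged" are skipped with a warning (the pipeline only
    feeds regulated peptides forward).
    """
    direction = {r.peptide_id: r.direction for r in results}
    counts: dict[str, set[tuple[str, str]]] = {}
    skipped = 0
    for assoc in associations:
        if assoc.peptide_id not in direction:
            raise KeyError(
                f"association {assoc.protease}<->{assoc.peptide_id}: peptide "
                f"missing from differential results"
            )
        d = direction[assoc.peptide_id]
        if d == "unchanged":
            skipped += 1
            continue
        counts.setdefault(assoc.protease, set()).add((assoc.peptide_id, d))
    if skipped:
        logger.warning("skipped %d associations to unregulated peptides", skipped)
    return {
        protease: (
            sum(1 for _, d in pairs if d == "up"),
            sum(1 for _, d in pairs if d == "down"),
        )
        for protease, pairs in counts.items()
    }


def association_totals(counts: Mapping[str, tuple[int, int]]) -> tuple[int, int]:
    """(n_up, n_down): association totals over all predicted proteases.

    Computed before any minimum-peptide filter and with multiplicity across
    proteases, so n_up + n_down equals the total number of protease-peptide
    associations, not the number of unique peptides.
    """
    n_up = sum(u for u, _ in counts.values())
    n_down = sum(d for _, d in counts.values())
    return n_up, n_down


def score_proteases(counts: Mapping[str, tuple[int, int]],
                    n_up: int | None = None,
                    n_down: int | None = None) -> list[ActivityScore]:
    """Score every protease with at least one regulated peptide.

    Totals default to :func:`association_totals` of ``counts``; they can be
    passed explicitly when re-scoring a published count table whose totals
    include proteases not listed.
    """
    if not counts:
        raise ValueError("no protease-peptide associations to score")
    if n_up is None or n_down is None:
        n_up, n_down = association_totals(counts)
    if n_up < 1 or n_down < 1:
        raise ValueError(
            f"association totals must both be >= 1, got n_up={n_up}, n_down={n_down}"
        )
    return [
        ActivityScore(protease, occ_up, occ_down, n_up, n_down)
        for protease, (occ_up, occ_down) in counts.items()
        if occ_up + occ_down >= 1
    ]


def filter_min_peptides(scores: Iterable[ActivityScore],
                        min_peptides: int = MIN_PEPTIDES_DEFAULT) -> list[ActivityScore]:
    """Apply the reliability threshold and rank for reporting.

    Keeps proteases with >= ``min_peptides`` associated regulated peptides;
    orders predicted-activated (score > 0) by descending score, then
    predicted-deactivated by ascending score, ties broken alphabetically.
    """
    kept = [s for s in scores if s.n_peptides >= min_peptides]
    activated = sorted((s for s in kept if s.score > 0),
                       key=lambda s: (-s.score, s.protease))
    neutral = sorted((s for s in kept if s.score == 0), key=lambda s: s.protease)
    deactivated = sorted((s for s in kept if s.score < 0),
                         key=lambda s: (s.score, s.protease))
    return activated + neutral + deactivated


def write_scores(scores: Iterable[ActivityScore], tsv_path, json_path=None) -> None:
    """TSV at reporting precision; optional JSON with full precision and totals."""
    import json

    import pandas as pd

    scores = list(scores)
    df = pd.DataFrame(
        [
            {
                "protease": s.protease,
                "occ_down": s.occ_down,
                "occ_up": s.occ_up,
                "pct_freq": s.pct_freq_display,
                "score": f"{s.score_display:.2f}",
            }
            for s in scores
        ],
        columns=["protease", "occ_down", "occ_up", "pct_freq", "score"],
    )
    df.to_csv(tsv_path, sep="\t", index=False, lineterminator="\n")
    if json_path is not None:
        payload = {
            "n_up": scores[0].n_up if scores else None,
            "n_down": scores[0].n_down if scores else None,
            "proteases": [
                {
                    "protease": s.protease,
                    "occ_up": s.occ_up,
                    "occ_down": s.occ_down,
                    "weight": s.weight,
                    "freq_up_pct": s.freq_up_pct,
                    "freq_down_pct": s.freq_down_pct,
                    "pct_freq": s.pct_freq,
                    "score": s.score,
                }
                for s in scores
            ],
        }
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
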