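"""Assign candidate proteases to peptides from their termini.

A naturally occurring urinary peptide records up to two in vivo cleavage
events: one that generated its N-terminus (the scissile bond sits between
parent residues ``start - 1`` and ``start``, so P1 = start - 1) and one that
generated its C-terminus (P1 = stop).  A terminus flush with the parent
protein's own end is not a cleavage event.

Events are matched against a curated cleavage-site table in two modes:

* ``same_substrate`` — the event's (substrate accession, P1 position) equals
  a table entry exactly;
* ``cross_substrate`` — the event's P4..P4' octamer context equals the
  octamer of a table entry on a *different* substrate, the strict reading of
  "observed in different substrate" evidence.

Matches are deduplicated to unique (protease, peptide) pairs so downstream
occurrence counts are numbers of peptides, not numbers of termini;
``same_substrate`` wins as the recorded mode when both occur.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from .io import CleavageSiteEntry, PeptideRecord

logger = logging.getLogger(__name__)

CONTEXT_WINDOW_DEFAULT = 4
PAD = "-"


@dataclass(frozen=True)
class CleavageEvent:
    """One inferred cleavage: the bond C-terminal to parent residue ``p1_position``."""

    peptide_id: str
    terminus: str  # "N" or "C"
    substrate_accession: str
    p1_position: int


@dataclass(frozen=True)
class ProteasePeptideAssociation:
    protease: str
    peptide_id: str
    terminus: str
    match_mode: str  # "same_substrate" | "cross_substrate"
    site_context: str


def derive_cleavage_events(peptide: PeptideRecord, parent_length: int) -> list[CleavageEvent]:
    """Return the 0-2 cleavage events implied by a peptide's coordinates."""
    if peptide.stop > parent_length:
        raise ValueError(
            f"peptide {peptide.peptide_id!r}: stop={peptide.stop} exceeds "
            f"parent length {parent_length}"
        )
    events = []
    if peptide.start > 1:
        events.append(CleavageEvent(peptide.peptide_id, "N",
                                    peptide.protein_accession, peptide.start - 1))
    if peptide.stop < parent_length:
        events.append(CleavageEvent(peptide.peptide_id, "C",
                                    peptide.protein_accession, peptide.stop))
    return events


def extract_site_context(parent_sequence: str, p1_position: int,
                         window: int = CONTEXT_WINDOW_DEFAULT) -> str:
    """P(window)..P1 | P1'..P(window)' context of a cleavage site.

    1-based ``p1_position``; positions beyond either protein end are padded
    with ``-``.  The default window of 4 gives the standard octamer.
    """
    n = len(parent_sequence)
    if not 1 <= p1_position < n:
        raise ValueError(f"p1_position {p1_position} out of range for length-{n} sequence")
    left = parent_sequence[max(0, p1_position - window):p1_position]
    left = PAD * (window - len(left)) + left
    right = parent_sequence[p1_position:p1_position + window]
    right = right + PAD * (window - len(right))
    return left + right


def match_proteases(events: Iterable[CleavageEvent],
                    db: Iterable[CleavageSiteEntry],
                    sequences: Mapping[str, str],
                    window: int = CONTEXT_WINDOW_DEFAULT) -> list[ProteasePeptideAssociation]:
    """Match cleavage events against the site table.

    Events on accessions absent from ``sequences`` are skipped with a
    warning (their octamer context cannot be computed).  Table entries whose
    substrate sequence is unavailable still participate in same-substrate
    matching but cannot be matched cross-substrate.
    """
    db = list(db)
    by_site: dict[tuple[str, int], list[CleavageSiteEntry]] = {}
    by_octamer: dict[str, list[CleavageSiteEntry]] = {}
    for entry in db:
        by_site.setdefault((entry.substrate_accession, entry.p1_position), []).append(entry)
        seq = sequences.get(entry.substrate_accession)
        if seq is not None and 1 <= entry.p1_position < len(seq):
            octamer = extract_site_context(seq, entry.p1_position, window)
            by_octamer.setdefault(octamer, []).append(entry)

    # (protease, peptide) -> best association; same_substrate preferred,
    # then N-terminus before C for determinism.
    best: dict[tuple[str, str], ProteasePeptideAssociation] = {}

    def _rank(assoc: ProteasePeptideAssociation) -> tuple[int, int]:
        return (assoc.match_mode != "same_substrate", assoc.terminus != "N")

    for event in events:
        seq = sequences.get(event.substrate_accession)
        if seq is None:
            logger.warning("no sequence for accession %s; skipping event on %s",
                           event.substrate_accession, event.peptide_id)
            continue
        if not 1 <= event.p1_position < len(seq):
            logger.warning("event P1=%d outside cleavable range of %s; skipping",
                           event.p1_position, event.substrate_accession)
            continue
        context = extract_site_context(seq, event.p1_position, window)
        candidates: list[ProteasePeptideAssociation] = []
        for entry in by_site.get((event.substrate_accession, event.p1_position), []):
            candidates.append(ProteasePeptideAssociation(
                entry.protease, event.peptide_id, event.terminus,
                "same_substrate", context))
        for entry in by_octamer.get(context, []):
            if entry.substrate_accession != event.substrate_accession:
                candidates.append(ProteasePeptideAssociation(
                    entry.protease, event.peptide_id, event.terminus,
                    "cross_substrate", context))
        for assoc in candidates:
            key = (assoc.protease, assoc.peptide_id)
            if key not in best or _rank(assoc) < _rank(best[key]):
                best[key] = assoc
    return sorted(best.values(), key=lambda a: (a.peptide_id, a.protease))


def write_associations(associations: Iterable[ProteasePeptideAssociation], path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "peptide_id": a.peptide_id,
                "protease": a.protease,
                "terminus": a.terminus,
                "match_mode": a.match_mode,
                "site_context": a.site_context,
            }
            for a in associations
        ],
        columns=["peptide_id", "protease", "terminus", "match_mode", "site_context"],
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_associations(path) -> list[ProteasePeptideAssociation]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        ProteasePeptideAssociation(
            protease=row.protease,
            peptide_id=row.peptide_id,
            terminus=row.terminus,
            match_mode=row.match_mode,
            site_context=row.site_context,
        )
        for row in df.itertuples()
    ]
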