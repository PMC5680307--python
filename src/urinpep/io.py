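"""Readers and writers for the pipeline's four input tables.

All peptide coordinates are 1-based and inclusive on both ends, following the
UniProt convention for naturally occurring peptides; nothing is
converted internally. An absent abundance cell means the peptide was not
detected in that sample and is read as 0.0 (no imputation).

Formats
-------
* Peptide table: TSV/CSV with columns ``peptide_id, sequence, accession,
  start, stop`` followed by one abundance column per sample. An optional
  ``modifications`` column carries PTM annotations as free text; matching and
  length checks always use the plain residue string.
* Sample groups: YAML/JSON mapping with keys ``case`` and ``control``, or a
  two-column delimited file ``sample_id<TAB>group`` with group values
  ``case``/``control``.
* Protein sequences: FASTA; the accession is the first whitespace-delimited
  header token, with the UniProt ``sp|ACC|NAME`` / ``tr|ACC|NAME`` dialect
  unpacked to the bare accession.
* Cleavage-site table: TSV/CSV with columns ``protease, substrate_accession,
  p1_position, evidence``. Only experimentally observed evidence classes are
  retained, mirroring the restriction to observed cleavage sites.
* Evidence-direction table: TSV/CSV with columns ``protease, source,
  direction`` for cross-omics concordance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Evidence classes kept by :func:`read_cleavage_db`.  "observed" means the
#: protease was experimentally shown to cut this substrate at this position;
#: "observed_different_substrate" means the same site sequence was shown to be
#: cut in another protein.
OBSERVED_EVIDENCE = frozenset({"observed", "observed_different_substrate"})

PEPTIDE_META_COLUMNS = ("peptide_id", "sequence", "accession", "start", "stop")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")


class InputError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass
class PeptideRecord:
    """One detected urinary peptide mapped onto its parent protein.

    ``start``/``stop`` are 1-based inclusive residue positions of the fragment
    in the parent; ``abundances`` maps sample id to a non-negative signal
    intensity (arbitrary units), with undetected samples stored as 0.0.
    """

    peptide_id: str
    sequence: str
    protein_accession: str
    start: int
    stop: int
    abundances: dict[str, float] = field(default_factory=dict)
    modifications: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.stop):
            raise InputError(
                f"peptide {self.peptide_id!r}: invalid coordinates "
                f"start={self.start}, stop={self.stop} (need 1 <= start <= stop)"
            )
        if self.sequence and self.stop - self.start + 1 != len(self.sequence):
            raise InputError(
                f"peptide {self.peptide_id!r}: span {self.start}-{self.stop} "
                f"({self.stop - self.start + 1} residues) does not match "
                f"sequence length {len(self.sequence)}"
            )
        for sample, value in self.abundances.items():
            if value < 0:
                raise InputError(
                    f"peptide {self.peptide_id!r}: negative abundance "
                    f"{value} in sample {sample!r}"
                )

    @property
    def length(self) -> int:
        return self.stop - self.start + 1


@dataclass
class SampleGroups:
    """Case (nephropathy) and control sample id lists; disjoint, non-empty."""

    case_ids: list[str]
    control_ids: list[str]

    def __post_init__(self) -> None:
        if not self.case_ids or not self.control_ids:
            raise InputError("both sample groups must be non-empty")
        overlap = set(self.case_ids) & set(self.control_ids)
        if overlap:
            raise InputError(f"samples in both groups: {sorted(overlap)}")

    @property
    def all_ids(self) -> list[str]:
        return list(self.case_ids) + list(self.control_ids)


@dataclass
class CleavageSiteEntry:
    """Curated protease -> (substrate, P1 position) association.

    ``p1_position`` is the 1-based index of the residue immediately N-terminal
    to the scissile bond.
    """

    protease: str
    substrate_accession: str
    p1_position: int
    evidence: str = "observed"

    def __post_init__(self) -> None:
        if self.p1_position < 1:
            raise InputError(
                f"cleavage site {self.protease}/{self.substrate_accession}: "
                f"p1_position must be >= 1, got {self.p1_position}"
            )
        if self.evidence not in OBSERVED_EVIDENCE:
            raise InputError(f"unknown evidence class {self.evidence!r}")


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited text table, inferring comma vs tab from content."""
    return pd.read_csv(path, sep=None, engine="python", dtype=str,
                       keep_default_na=False)


def read_peptide_table(path: str | Path) -> tuple[list[PeptideRecord], list[str]]:
    """Parse a peptide abundance table.

    Returns the validated records and the ordered list of sample columns.
    Blank abundance cells become 0.0.  Duplicate peptide ids, malformed
    coordinates and non-numeric abundances are hard errors naming the row.
    """
    df = _read_table(path)
    missing = [c for c in PEPTIDE_META_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in PEPTIDE_META_COLUMNS]
    has_mods = "modifications" in extra
    if has_mods:
        extra.remove("modifications")
    sample_ids = extra
    if not sample_ids:
        raise InputError(f"{path}: no abundance columns found")

    records: list[PeptideRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        pid = row["peptide_id"]
        if pid in seen:
            raise InputError(f"{path}: duplicate peptide_id {pid!r}")
        seen.add(pid)
        try:
            start, stop = int(row["start"]), int(row["stop"])
        except ValueError as exc:
            raise InputError(f"{path}: peptide {pid!r}: non-integer coordinate") from exc
        abundances = {}
        for sample in sample_ids:
            cell = row[sample].strip()
            try:
                abundances[sample] = float(cell) if cell else 0.0
            except ValueError as exc:
                raise InputError(
                    f"{path}: peptide {pid!r}: bad abundance {cell!r} "
                    f"in sample {sample!r}"
                ) from exc
        records.append(
            PeptideRecord(
                peptide_id=pid,
                sequence=row["sequence"].strip().upper(),
                protein_accession=row["accession"].strip(),
                start=start,
                stop=stop,
                abundances=abundances,
                modifications=row.get("modifications", "").strip() if has_mods else "",
            )
        )
    return records, sample_ids


def write_peptide_table(records: Iterable[PeptideRecord],
                        sample_ids: list[str],
                        path: str | Path) -> None:
    """Write records in the dialect :func:`read_peptide_table` consumes.

    Abundances are written with :func:`repr` precision so that a write/read
    round trip reproduces every value exactly.
    """
    rows = []
    any_mods = False
    for rec in records:
        row = {
            "peptide_id": rec.peptide_id,
            "sequence": rec.sequence,
            "accession": rec.protein_accession,
            "start": rec.start,
            "stop": rec.stop,
        }
        if rec.modifications:
            any_mods = True
        row["modifications"] = rec.modifications
        for sample in sample_ids:
            row[sample] = repr(rec.abundances.get(sample, 0.0))
        rows.append(row)
    columns = list(PEPTIDE_META_COLUMNS)
    if any_mods:
        columns.append("modifications")
    else:
        for row in rows:
            row.pop("modifications")
    df = pd.DataFrame(rows, columns=columns + sample_ids)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_groups(path: str | Path, sample_ids: Iterable[str] | None = None) -> SampleGroups:
    """Read group membership from YAML/JSON (keys case/control) or a
    two-column delimited file.

    When ``sample_ids`` is given, every configured sample must appear in it.
    """
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml", ".json"}:
        with open(path) as fh:
            data = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
        if not isinstance(data, Mapping) or "case" not in data or "control" not in data:
            raise InputError(f"{path}: expected mapping with keys 'case' and 'control'")
        case, control = list(map(str, data["case"])), list(map(str, data["control"]))
    else:
        df = _read_table(path)
        if list(df.columns[:2]) != ["sample_id", "group"]:
            raise InputError(f"{path}: expected columns sample_id, group")
        labels = df["group"].str.strip().str.lower()
        bad = sorted(set(labels) - {"case", "control"})
        if bad:
            raise InputError(f"{path}: unknown group labels {bad}")
        case = list(df.loc[labels == "case", "sample_id"])
        control = list(df.loc[labels == "control", "sample_id"])
    groups = SampleGroups(case_ids=case, control_ids=control)
    if sample_ids is not None:
        unknown = sorted(set(groups.all_ids) - set(sample_ids))
        if unknown:
            raise InputError(
                f"{path}: samples in group config but not in peptide table: {unknown}"
            )
    return groups


def write_groups(groups: SampleGroups, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"case": list(groups.case_ids), "control": list(groups.control_ids)},
            fh, sort_keys=False,
        )


def _accession_from_header(token: str) -> str:
    # UniProt dialect: sp|P01009|A1AT_HUMAN or tr|Q12345|NAME
    parts = token.split("|")
    if len(parts) >= 3 and parts[0].lower() in {"sp", "tr"}:
        return parts[1]
    return token


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences; returns accession -> uppercase sequence.

    Duplicate accessions and empty files are hard errors; residues outside
    the 20 standard amino acids plus X are rejected.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        acc = _accession_from_header(record.id)
        if acc in sequences:
            raise InputError(f"{path}: duplicate accession {acc!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise InputError(f"{path}: empty sequence for {acc!r}")
        bad = set(seq) - _VALID_RESIDUES
        if bad:
            raise InputError(f"{path}: invalid residues {sorted(bad)} in {acc!r}")
        sequences[acc] = seq
    if not sequences:
        raise InputError(f"{path}: no FASTA records found")
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for acc in sequences:
            fh.write(f">{acc}\n")
            seq = sequences[acc]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _normalize_evidence(token: str) -> str:
    return token.strip().lower().replace(" ", "_").replace("observed_in_different_substrate",
                                                           "observed_different_substrate")


def read_cleavage_db(path: str | Path) -> list[CleavageSiteEntry]:
    """Read a cleavage-site association table, keeping only observed sites.

    Rows whose evidence label is not one of the observed classes (e.g. the
    probability-based prediction tiers) are dropped with a logged count, not
    an error — the analysis is deliberately restricted to experimentally
    observed cleavage sites.
    """
    df = _read_table(path)
    required = ["protease", "substrate_accession", "p1_position", "evidence"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")
    entries: list[CleavageSiteEntry] = []
    dropped = 0
    for _, row in df.iterrows():
        evidence = _normalize_evidence(row["evidence"])
        if evidence not in OBSERVED_EVIDENCE:
            dropped += 1
            continue
        entries.append(
            CleavageSiteEntry(
                protease=row["protease"].strip(),
                substrate_accession=row["substrate_accession"].strip(),
                p1_position=int(row["p1_position"]),
                evidence=evidence,
            )
        )
    if dropped:
        logger.warning("%s: dropped %d non-observed cleavage-site rows", path, dropped)
    if not entries:
        logger.warning("%s: cleavage-site table is empty after filtering", path)
    return entries


def write_cleavage_db(entries: Iterable[CleavageSiteEntry], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "protease": e.protease,
                "substrate_accession": e.substrate_accession,
                "p1_position": e.p1_position,
                "evidence": e.evidence,
            }
            for e in entries
        ],
        columns=["protease", "substrate_accession", "p1_position", "evidence"],
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_evidence_table(path: str | Path) -> "list":
    """Read cross-omics direction evidence (protease, source, direction)."""
    from .concordance import EvidenceRecord  # avoid import cycle

    df = _read_table(path)
    required = ["protease", "source", "direction"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")
    return [
        EvidenceRecord(
            protease=row["protease"].strip(),
            source=row["source"].strip().lower(),
            direction=row["direction"].strip().lower().replace(" ", "_"),
        )
        for _, row in df.iterrows()
    ]
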