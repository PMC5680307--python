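"""Synthetic urinary-peptidomics cohorts with planted protease activity.

The generator emulates the structure of a two-group CE-MS peptidomics study
at desk scale: random parent proteins, a curated cleavage-site table, and
naturally occurring peptide fragments whose termini abut the planted sites.
Peptide abundances are log-normal (positive, right-skewed, as CE-MS signal
intensities are) with a multiplicative case/control fold applied according
to the generating protease's planted direction — up for ``activated``, down
for ``deactivated``, none for ``null``.  Every peptide is anchored to its
site on exactly one terminus; the free terminus is kept clear of all other
planted sites so that the planted associations are exactly the ones a
correct matcher recovers.

Background peptides live on dedicated proteins with no cleavage-site entries
(one third up-shifted, one third down-shifted, one third null) and exercise
the pipeline's ability to ignore regulated peptides with no protease link.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .concordance import EvidenceRecord
from .io import (AMINO_ACIDS, CleavageSiteEntry, PeptideRecord, SampleGroups,
                 write_cleavage_db, write_fasta, write_groups,
                 write_peptide_table)

DIRECTIONS = ("activated", "deactivated", "null")


def default_proteases() -> list[tuple[str, str, int]]:
    """6 activated, 6 deactivated and 5 null proteases, 2 sites each."""
    spec = []
    for i in range(6):
        spec.append((f"PRTA{i + 1}", "activated", 2))
    for i in range(6):
        spec.append((f"PRTD{i + 1}", "deactivated", 2))
    for i in range(5):
        spec.append((f"PRTN{i + 1}", "null", 2))
    return spec


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    ``effect_size`` is the multiplicative case/control fold applied to the
    peptides of non-null proteases (upward for activated, downward for
    deactivated); ``noise_sigma`` is the standard deviation of the
    natural-log abundance.
    """

    seed: int = 0
    n_case: int = 30
    n_control: int = 30
    n_proteins: int = 25
    protein_length_range: tuple[int, int] = (200, 400)
    proteases: list[tuple[str, str, int]] = field(default_factory=default_proteases)
    peptides_per_site: int = 5
    effect_size: float = 4.0
    noise_sigma: float = 1.0
    background_peptides: int = 48

    def __post_init__(self) -> None:
        if self.effect_size <= 1:
            raise ValueError("effect_size must be > 1")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be > 0")
        for name, direction, n_sites in self.proteases:
            if direction not in DIRECTIONS:
                raise ValueError(f"protease {name}: unknown direction {direction!r}")
            if n_sites < 0:
                raise ValueError(f"protease {name}: negative site count")
        if self.n_proteins < len(self.proteases) + 1:
            raise ValueError(
                "need at least one protein per protease plus one background protein"
            )


@dataclass
class TruthTable:
    protease_direction: dict[str, str]
    # peptide_id -> (protease or None for background, regulation in {up, down, none})
    peptide_truth: dict[str, tuple[str | None, str]]


@dataclass
class SyntheticCohort:
    peptides: list[PeptideRecord]
    sample_ids: list[str]
    groups: SampleGroups
    sequences: dict[str, str]
    cleavage_db: list[CleavageSiteEntry]
    evidence: list[EvidenceRecord]
    truth: TruthTable


# planted sites are kept this far apart, and free termini this far from any
# site, so no accidental same-substrate match can arise
_SITE_SPACING = 40
_MIN_LEN, _MAX_LEN = 8, 25


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one cohort; byte-reproducible given the seed."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.protein_length_range

    n_prot = config.n_proteins
    accessions = [f"SYN{i + 1:05d}" for i in range(n_prot)]
    sequences = {acc: _random_protein(rng, int(rng.integers(lo, hi + 1)))
                 for acc in accessions}

    sample_ids = ([f"case{i + 1:03d}" for i in range(config.n_case)]
                  + [f"ctrl{i + 1:03d}" for i in range(config.n_control)])
    groups = SampleGroups(case_ids=sample_ids[:config.n_case],
                          control_ids=sample_ids[config.n_case:])

    cleavage_db: list[CleavageSiteEntry] = []
    peptides: list[PeptideRecord] = []
    peptide_truth: dict[str, tuple[str | None, str]] = {}
    pep_counter = 0

    def _abundances(regulation: str) -> dict[str, float]:
        base = rng.uniform(np.log(500.0), np.log(5000.0))
        values = np.exp(base + config.noise_sigma
                        * rng.standard_normal(len(sample_ids)))
        if regulation == "up":
            values[:config.n_case] *= config.effect_size
        elif regulation == "down":
            values[:config.n_case] /= config.effect_size
        return {s: round(float(v), 4) for s, v in zip(sample_ids, values)}

    for idx, (name, direction, n_sites) in enumerate(config.proteases):
        acc = accessions[idx]
        seq = sequences[acc]
        length = len(seq)
        usable = length - 2 * _SITE_SPACING
        if n_sites * _SITE_SPACING > usable:
            raise ValueError(
                f"protease {name}: {n_sites} sites do not fit in a "
                f"{length}-residue protein with {_SITE_SPACING}-residue spacing"
            )
        # evenly spaced P1 positions, jittered within a safe margin
        sites = []
        for k in range(n_sites):
            p1 = _SITE_SPACING + (k * usable) // max(n_sites, 1) \
                + int(rng.integers(0, 10))
            sites.append(p1)
            cleavage_db.append(CleavageSiteEntry(name, acc, p1, "observed"))

        regulation = {"activated": "up", "deactivated": "down", "null": "none"}[direction]
        for p1 in sites:
            for j in range(config.peptides_per_site):
                pep_counter += 1
                pid = f"pep{pep_counter:05d}"
                plen = int(rng.integers(_MIN_LEN, min(_MAX_LEN, _SITE_SPACING - 2) + 1))
                if j % 2 == 0:  # N-terminus anchored: cut at p1 generated the start
                    start, stop = p1 + 1, p1 + plen
                else:  # C-terminus anchored: cut at p1 generated the stop
                    start, stop = p1 - plen + 1, p1
                peptides.append(PeptideRecord(
                    peptide_id=pid,
                    sequence=seq[start - 1:stop],
                    protein_accession=acc,
                    start=start,
                    stop=stop,
                    abundances=_abundances(regulation),
                ))
                peptide_truth[pid] = (name, regulation)

    background_accs = accessions[len(config.proteases):]
    for b in range(config.background_peptides):
        pep_counter += 1
        pid = f"pep{pep_counter:05d}"
        acc = background_accs[b % len(background_accs)]
        seq = sequences[acc]
        plen = int(rng.integers(_MIN_LEN, _MAX_LEN + 1))
        start = int(rng.integers(2, len(seq) - plen))
        regulation = ("up", "down", "none")[b % 3]
        peptides.append(PeptideRecord(
            peptide_id=pid,
            sequence=seq[start - 1:start + plen - 1],
            protein_accession=acc,
            start=start,
            stop=start + plen - 1,
            abundances=_abundances(regulation),
        ))
        peptide_truth[pid] = (None, regulation)

    evidence = [
        EvidenceRecord(name, "transcriptomics",
                       "increase" if direction == "activated" else "decrease")
        for name, direction, _ in config.proteases
        if direction != "null"
    ]
    truth = TruthTable(
        protease_direction={name: d for name, d, _ in config.proteases},
        peptide_truth=peptide_truth,
    )
    return SyntheticCohort(peptides, sample_ids, groups, sequences,
                           cleavage_db, evidence, truth)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Emit the cohort in exactly the dialects the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "peptides": out / "peptides.tsv",
        "groups": out / "groups.yaml",
        "fasta": out / "proteins.fasta",
        "cleavage_db": out / "cleavage_sites.tsv",
        "evidence": out / "evidence.tsv",
        "truth": out / "truth.json",
    }
    write_peptide_table(cohort.peptides, cohort.sample_ids, paths["peptides"])
    write_groups(cohort.groups, paths["groups"])
    write_fasta(cohort.sequences, paths["fasta"])
    write_cleavage_db(cohort.cleavage_db, paths["cleavage_db"])
    with open(paths["evidence"], "w") as fh:
        fh.write("protease\tsource\tdirection\n")
        for ev in cohort.evidence:
            fh.write(f"{ev.protease}\t{ev.source}\t{ev.direction}\n")
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "protease_direction": cohort.truth.protease_direction,
                "peptide_truth": {
                    pid: {"protease": p, "regulation": r}
                    for pid, (p, r) in cohort.truth.peptide_truth.items()
                },
            },
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")
    return paths


@dataclass
class RecoveryReport:
    """Outcome of running the full pipeline on a generated cohort."""

    per_protease: dict[str, dict]     # name -> {true, predicted, score}
    n_non_null: int
    n_correct: int
    n_null_reported: int
    n_regulated_peptides: int
    n_scored: int

    @property
    def recovery_rate(self) -> float:
        return self.n_correct / self.n_non_null if self.n_non_null else float("nan")


def recover_and_check(config: SimulationConfig,
                      alpha: float = 0.05,
                      fc_up: float = 1.5,
                      fc_down: float = 0.66,
                      min_peptides: int = 3) -> RecoveryReport:
    """Generate a cohort, run every stage in memory, compare signs to truth."""
    from .differential import select_regulated
    from .prediction import derive_cleavage_events, match_proteases
    from .scoring import (association_totals, count_occurrences,
                          filter_min_peptides, score_proteases)

    cohort = generate_cohort(config)
    results = select_regulated(cohort.peptides, cohort.groups,
                               alpha=alpha, fc_up=fc_up, fc_down=fc_down)
    regulated_ids = {r.peptide_id for r in results if r.direction != "unchanged"}
    events = []
    for pep in cohort.peptides:
        if pep.peptide_id in regulated_ids:
            events.extend(derive_cleavage_events(
                pep, len(cohort.sequences[pep.protein_accession])))
    associations = match_proteases(events, cohort.cleavage_db, cohort.sequences)
    final = []
    if associations:
        counts = count_occurrences(associations, results)
        n_up, n_down = association_totals(counts)
        if n_up >= 1 and n_down >= 1:
            final = filter_min_peptides(score_proteases(counts, n_up, n_down),
                                        min_peptides)

    predicted = {s.protease: ("activated" if s.score > 0 else "deactivated", s.score)
                 for s in final}
    per_protease = {}
    n_non_null = n_correct = n_null_reported = 0
    for name, true_dir in cohort.truth.protease_direction.items():
        pred_dir, score = predicted.get(name, (None, None))
        per_protease[name] = {"true": true_dir, "predicted": pred_dir, "score": score}
        if true_dir == "null":
            n_null_reported += pred_dir is not None
        else:
            n_non_null += 1
            n_correct += pred_dir == true_dir
    return RecoveryReport(
        per_protease=per_protease,
        n_non_null=n_non_null,
        n_correct=n_correct,
        n_null_reported=n_null_reported,
        n_regulated_peptides=len(regulated_ids),
        n_scored=len(final),
    )
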