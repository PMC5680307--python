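"""Cleavage-event derivation, site context extraction, protease matching."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from urinpep.io import CleavageSiteEntry, PeptideRecord
from urinpep.prediction import (derive_cleavage_events, extract_site_context,
                                match_proteases)


def _pep(pid, acc, start, stop):
    return PeptideRecord(peptide_id=pid, sequence="", protein_accession=acc,
                         start=start, stop=stop)


# ------------------------------------------------------------- events

def test_whole_protein_fragment_has_no_cleavage_events():
    assert derive_cleavage_events(_pep("p", "A", 1, 100), 100) == []


def test_internal_fragment_yields_both_termini():
    events = derive_cleavage_events(_pep("p", "A", 10, 20), 100)
    assert [(e.terminus, e.p1_position) for e in events] == [("N", 9), ("C", 20)]


def test_protein_start_fragment_yields_only_c_event():
    events = derive_cleavage_events(_pep("p", "A", 1, 20), 100)
    assert [(e.terminus, e.p1_position) for e in events] == [("C", 20)]


def test_stop_beyond_parent_is_an_error():
    with pytest.raises(ValueError, match="exceeds"):
        derive_cleavage_events(_pep("p", "A", 10, 120), 100)


# ------------------------------------------------------------- context

@pytest.mark.parametrize(
    "p1, expected",
    [(5, "BCDEFGHI"), (2, "--ABCDEF"), (9, "FGHIJ---")],
)
def test_octamer_context_with_padding(p1, expected):
    assert extract_site_context("ABCDEFGHIJ", p1) == expected


def test_context_p1_out_of_range():
    with pytest.raises(ValueError):
        extract_site_context("ABCDEFGHIJ", 10)  # p1 must be < length
    with pytest.raises(ValueError):
        extract_site_context("ABCDEFGHIJ", 0)


# ------------------------------------------------------------- matching

def test_same_substrate_match(toy_sequences, toy_db):
    events = derive_cleavage_events(
        _pep("p1", "P00002", 10, 20), len(toy_sequences["P00002"]))
    assocs = match_proteases(events, toy_db, toy_sequences)
    assert [(a.protease, a.match_mode) for a in assocs] == [("MMP9", "same_substrate")]


def test_cross_substrate_match_requires_octamer_identity():
    # same octamer around the cut in two different proteins
    seq_x = "AAAA" + "LVFFAEDV" + "AAAA"
    seq_y = "CCCCCC" + "LVFFAEDV" + "CCCCCC"
    sequences = {"X": seq_x, "Y": seq_y}
    db = [CleavageSiteEntry("BACE1", "X", 8, "observed")]  # cut LVFF|AEDV in X
    events = derive_cleavage_events(_pep("p1", "Y", 11, 18), len(seq_y))
    # N-terminal event at p1=10 in Y has octamer LVFFAEDV
    assocs = match_proteases(events, db, sequences)
    assert [(a.protease, a.match_mode) for a in assocs] == [("BACE1", "cross_substrate")]
    assert assocs[0].site_context == "LVFFAEDV"


def test_both_termini_matching_same_protease_dedup(toy_sequences):
    db = [
        CleavageSiteEntry("CTSD", "P00001", 9, "observed"),
        CleavageSiteEntry("CTSD", "P00001", 20, "observed"),
    ]
    events = derive_cleavage_events(
        _pep("p1", "P00001", 10, 20), len(toy_sequences["P00001"]))
    assocs = match_proteases(events, db, toy_sequences)
    assert len(assocs) == 1
    assert assocs[0].match_mode == "same_substrate"


def test_event_on_unknown_accession_is_skipped(toy_db, toy_sequences):
    events = derive_cleavage_events(_pep("p1", "GHOST", 10, 20), 100)
    assert match_proteases(events, toy_db, toy_sequences) == []


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.data())
def test_matcher_equals_brute_force_on_random_fixtures(data):
    """Indexed matcher == nested-loop matcher over events x entries."""
    import numpy as np

    seed = data.draw(st.integers(0, 10_000))
    rng = np.random.default_rng(seed)
    alphabet = list("ACDG")  # tiny alphabet to force octamer collisions
    accs = ["A1", "A2", "A3"]
    sequences = {a: "".join(rng.choice(alphabet, size=40)) for a in accs}
    db = [
        CleavageSiteEntry(f"PR{rng.integers(3)}", accs[rng.integers(3)],
                          int(rng.integers(1, 40)), "observed")
        for _ in range(8)
    ]
    peptides = []
    for i in range(6):
        acc = accs[rng.integers(3)]
        start = int(rng.integers(1, 30))
        stop = int(rng.integers(start, min(start + 15, len(sequences[acc]))))
        peptides.append(_pep(f"p{i}", acc, start, stop))
    events = [e for p in peptides
              for e in derive_cleavage_events(p, len(sequences[p.protein_accession]))]

    from urinpep.prediction import extract_site_context as ctx
    expected = {}
    for e in events:
        seq = sequences[e.substrate_accession]
        if not 1 <= e.p1_position < len(seq):
            continue
        context = ctx(seq, e.p1_position)
        for entry in db:
            sseq = sequences[entry.substrate_accession]
            same = (entry.substrate_accession == e.substrate_accession
                    and entry.p1_position == e.p1_position)
            cross = (entry.substrate_accession != e.substrate_accession
                     and 1 <= entry.p1_position < len(sseq)
                     and ctx(sseq, entry.p1_position) == context)
            if same or cross:
                key = (entry.protease, e.peptide_id)
                mode = "same_substrate" if same else "cross_substrate"
                if key not in expected or mode == "same_substrate":
                    expected[key] = mode if mode == "same_substrate" \
                        else expected.get(key, mode)
    got = match_proteases(events, db, sequences)
    assert {(a.protease, a.peptide_id) for a in got} == set(expected)
    for a in got:
        if expected[(a.protease, a.peptide_id)] == "same_substrate":
            assert a.match_mode == "same_substrate"


def test_restricting_db_restricts_output_monotonically(toy_sequences, toy_db):
    peptides = [_pep("p1", "P00002", 10, 20), _pep("p2", "P00001", 19, 30)]
    events = [e for p in peptides
              for e in derive_cleavage_events(p, len(toy_sequences[p.protein_accession]))]
    full = match_proteases(events, toy_db, toy_sequences)
    reduced = match_proteases(events, toy_db[:1], toy_sequences)
    full_pairs = {(a.protease, a.peptide_id) for a in full}
    reduced_pairs = {(a.protease, a.peptide_id) for a in reduced}
    assert reduced_pairs <= full_pairs
    assert all(a.protease == "MMP9" for a in reduced)
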