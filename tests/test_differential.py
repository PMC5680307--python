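"""Differential analysis: exact/approximate rank test, BH adjustment, gates.

The rank-test and FDR oracles here are independent brute-force
implementations (full labeling enumeration; literal step-up arithmetic) and
are compared against the library path.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from urinpep.differential import (benjamini_hochberg, fold_change,
                                  mann_whitney_p, select_regulated)
from urinpep.io import SampleGroups

from conftest import make_peptide


# ---------------------------------------------------------------- oracles

def mw_exact_oracle(case, control):
    """Two-sided exact Mann-Whitney p by enumerating all labelings."""
    pooled = list(case) + list(control)
    k = len(case)

    def u_stat(case_vals, control_vals):
        return sum(c > d for c in case_vals for d in control_vals)

    u_obs = u_stat(case, control)
    us = []
    for idx in itertools.combinations(range(len(pooled)), k):
        sel = set(idx)
        cv = [pooled[i] for i in idx]
        dv = [pooled[i] for i in range(len(pooled)) if i not in sel]
        us.append(u_stat(cv, dv))
    us = np.array(us)
    p_low = np.mean(us <= u_obs)
    p_high = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_low, p_high))


def bh_oracle(p_values):
    """Literal step-up arithmetic: sort, q_i = p_i*m/i, cummin from the top."""
    p = list(p_values)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adjusted[i] = running
    return adjusted


# ------------------------------------------------------- Mann-Whitney test

def test_exact_p_for_fully_separated_three_vs_three():
    # U = 0 is one labeling of C(6,3) = 20; doubled -> 0.1
    assert mann_whitney_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)


def test_identical_groups_give_p_one():
    assert mann_whitney_p([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0
    assert mann_whitney_p([5.0, 5.0], [5.0, 5.0]) == 1.0


def test_exact_p_for_fully_separated_four_vs_four_matches_enumeration():
    case, control = [10, 11, 12, 13], [1, 2, 3, 4]
    assert mann_whitney_p(case, control) == pytest.approx(
        mw_exact_oracle(case, control))  # = 2/C(8,4)


def test_empty_group_is_an_error():
    with pytest.raises(ValueError):
        mann_whitney_p([], [1.0])


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.data())
def test_exact_branch_equals_full_enumeration_for_small_tie_free_inputs(data):
    n1 = data.draw(st.integers(1, 6))
    n2 = data.draw(st.integers(1, min(6, 12 - n1)))
    values = data.draw(st.lists(
        st.integers(-1000, 1000), min_size=n1 + n2, max_size=n1 + n2,
        unique=True))
    case, control = values[:n1], values[n1:]
    assert mann_whitney_p(case, control) == pytest.approx(
        mw_exact_oracle(case, control), abs=1e-12)


def test_large_sample_approximation_tracks_enumeration():
    # n just above the exact-branch cutoff: normal approximation should be
    # within a couple of percent of the enumerated p for moderate p
    rng = np.random.default_rng(7)
    case = list(rng.normal(0.8, 1, 7))
    control = list(rng.normal(0, 1, 7))
    approx = mann_whitney_p(case, control)
    exact = mw_exact_oracle(case, control)
    assert approx == pytest.approx(exact, abs=0.05)


# -------------------------------------------------------------------- BH

def test_bh_hand_checked_triplet():
    np.testing.assert_allclose(benjamini_hochberg([0.01, 0.02, 0.03]),
                               [0.03, 0.03, 0.03])


def test_bh_single_p_is_identity():
    np.testing.assert_allclose(benjamini_hochberg([0.5]), [0.5])


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        benjamini_hochberg([0.1, 1.2])
    with pytest.raises(ValueError):
        benjamini_hochberg([-0.1])


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
def test_bh_equals_brute_force_and_dominates_input(p_values):
    adjusted = benjamini_hochberg(p_values)
    np.testing.assert_allclose(adjusted, bh_oracle(p_values), atol=1e-12)
    assert np.all(adjusted >= np.asarray(p_values) - 1e-15)
    assert np.all(adjusted <= 1.0)


# ------------------------------------------------------------ fold change

@pytest.mark.parametrize(
    "case, control, expected",
    [
        ([3.0, 3.0], [2.0, 2.0], 1.5),
        ([5.0, 5.0], [0.0, 0.0], math.inf),
    ],
)
def test_fold_change_conventions(case, control, expected):
    assert fold_change(case, control) == expected


def test_fold_change_undefined_when_both_groups_silent():
    assert math.isnan(fold_change([0.0, 0.0], [0.0, 0.0]))


# -------------------------------------------------------- select_regulated

def test_planted_upshifts_recovered(rng):
    """50 two-fold up-shifted peptides among 150, n=30/30: >= 45 called up."""
    n = 30
    case_ids = [f"c{i}" for i in range(n)]
    control_ids = [f"d{i}" for i in range(n)]
    groups = SampleGroups(case_ids, control_ids)
    peptides = []
    for i in range(150):
        shift = 2.0 if i < 50 else 1.0
        control_vals = np.exp(rng.standard_normal(n) * 0.5 + 5)
        case_vals = np.exp(rng.standard_normal(n) * 0.5 + 5) * shift
        peptides.append(make_peptide(f"p{i}", "P00001", 2, 6, "ACDEF",
                                     case_vals, control_vals,
                                     case_ids, control_ids))
    results = select_regulated(peptides, groups)
    up_ids = {r.peptide_id for r in results if r.direction == "up"}
    assert sum(f"p{i}" in up_ids for i in range(50)) >= 45
    # unshifted peptides essentially never called
    assert sum(f"p{i}" in up_ids for i in range(50, 150)) <= 2


def test_null_cohort_false_discovery_fraction_small(rng):
    """No shift anywhere: BH keeps the discovery fraction near zero."""
    n = 15
    case_ids = [f"c{i}" for i in range(n)]
    control_ids = [f"d{i}" for i in range(n)]
    groups = SampleGroups(case_ids, control_ids)
    total_called = 0
    total = 0
    for _ in range(3):
        peptides = [
            make_peptide(f"p{i}", "P00001", 2, 6, "ACDEF",
                         np.exp(rng.standard_normal(n)),
                         np.exp(rng.standard_normal(n)),
                         case_ids, control_ids)
            for i in range(1000)
        ]
        results = select_regulated(peptides, groups)
        total_called += sum(r.adjusted_p < 0.05 for r in results)
        total += len(results)
    assert total_called / total <= 0.02


def test_small_cohort_exact_floor_blocks_any_call(toy_groups):
    """n=3/3: the exact test cannot go below p=0.1, so nothing is regulated."""
    pep = make_peptide("p1", "P00001", 2, 6, "ACDEF",
                       [1000.0, 1100.0, 1200.0], [1.0, 1.1, 1.2])
    results = select_regulated([pep], toy_groups)
    assert results[0].p_value == pytest.approx(0.1)
    assert results[0].direction == "unchanged"


def test_gates_use_adjusted_p_not_raw(rng):
    """A peptide significant on raw p but not after adjustment stays unchanged."""
    n = 10
    case_ids = [f"c{i}" for i in range(n)]
    control_ids = [f"d{i}" for i in range(n)]
    groups = SampleGroups(case_ids, control_ids)
    # one modest shift drowned among many null peptides
    peptides = [make_peptide("shifted", "P00001", 2, 6, "ACDEF",
                             np.exp(rng.standard_normal(n) * 0.8 + 0.9),
                             np.exp(rng.standard_normal(n) * 0.8),
                             case_ids, control_ids)]
    peptides += [
        make_peptide(f"null{i}", "P00001", 2, 6, "ACDEF",
                     np.exp(rng.standard_normal(n)),
                     np.exp(rng.standard_normal(n)),
                     case_ids, control_ids)
        for i in range(400)
    ]
    results = select_regulated(peptides, groups)
    target = results[0]
    if target.p_value < 0.05 and target.adjusted_p >= 0.05:
        assert target.direction == "unchanged"
    for r in results:
        if r.direction != "unchanged":
            assert r.adjusted_p < 0.05
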