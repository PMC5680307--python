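"""Differential peptide abundance between case and control urine samples.

Peptide intensities from CE-MS profiles are compared group-wise with the
two-sided Mann-Whitney rank-sum test; p-values are adjusted for multiple
testing with the Benjamini-Hochberg step-up procedure; peptides are called
regulated when the adjusted p-value clears ``alpha`` *and* the case/control
fold change clears the asymmetric gates (> ``fc_up`` for up-regulation,
< ``fc_down`` for down-regulation).  The gates are applied to the adjusted
p-value only, never the raw one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import PeptideRecord, SampleGroups

logger = logging.getLogger(__name__)

#: Combined sample size at or below which the exact null distribution of U is
#: enumerated (tie-free data only); beyond it, or with ties, the tie-corrected
#: normal approximation is used.
EXACT_MAX_N = 12

ALPHA_DEFAULT = 0.05
FC_UP_DEFAULT = 1.5
FC_DOWN_DEFAULT = 0.66


@dataclass
class DifferentialResult:
    """Per-peptide test outcome.

    ``fold_change`` is mean(case)/mean(control) on the raw abundance scale;
    +inf when only the case group has signal, NaN (undefined) when neither
    group does.  ``direction`` is ``up``/``down``/``unchanged``.
    """

    peptide_id: str
    p_value: float
    adjusted_p: float
    fold_change: float
    direction: str = "unchanged"


def mann_whitney_p(case_values: Sequence[float], control_values: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U test p-value.

    Exact enumeration of the U null distribution when the combined sample
    size is <= 12 and the data are tie-free; otherwise the normal
    approximation with midranks and the tie correction to the variance
    (no continuity correction, so identical groups give p = 1 exactly).
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([case, control])
    tie_free = np.unique(pooled).size == pooled.size
    if pooled.size <= EXACT_MAX_N and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    if np.ptp(pooled) == 0:
        return 1.0  # all observations identical: no evidence either way
    res = stats.mannwhitneyu(case, control, alternative="two-sided",
                             method=method, use_continuity=False)
    return float(min(res.pvalue, 1.0))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sorted ascending, q_i = p_i * m / i, monotonized by a cumulative minimum
    from the largest rank down, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(case_values: Sequence[float], control_values: Sequence[float]) -> float:
    """Ratio of group means on the raw abundance scale.

    Returns +inf when the control mean is 0 and the case mean positive, and
    NaN (undefined; never called regulated) when both means are 0.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("both groups must be non-empty")
    mc, mn = case.mean(), control.mean()
    if mn == 0:
        return math.inf if mc > 0 else math.nan
    return float(mc / mn)


def _direction(adjusted_p: float, fc: float, alpha: float,
               fc_up: float, fc_down: float) -> str:
    if math.isnan(fc) or adjusted_p >= alpha:
        return "unchanged"
    if fc > fc_up:
        return "up"
    if fc < fc_down:
        return "down"
    return "unchanged"


def select_regulated(records: Iterable[PeptideRecord], groups: SampleGroups,
                     alpha: float = ALPHA_DEFAULT,
                     fc_up: float = FC_UP_DEFAULT,
                     fc_down: float = FC_DOWN_DEFAULT) -> list[DifferentialResult]:
    """Score every peptide and assign regulation directions.

    All peptides are tested (no detection-frequency pre-filter); the BH
    adjustment spans the full peptide list.
    """
    records = list(records)
    if min(len(groups.case_ids), len(groups.control_ids)) < 3:
        logger.warning("fewer than 3 samples in a group; rank tests will have "
                       "little power and the exact-test p-value floor applies")
    results = []
    p_values = []
    for rec in records:
        case = [rec.abundances.get(s, 0.0) for s in groups.case_ids]
        control = [rec.abundances.get(s, 0.0) for s in groups.control_ids]
        p = mann_whitney_p(case, control)
        fc = fold_change(case, control)
        p_values.append(p)
        results.append(DifferentialResult(rec.peptide_id, p, math.nan, fc))
    adjusted = benjamini_hochberg(p_values)
    for res, q in zip(results, adjusted):
        res.adjusted_p = float(q)
        res.direction = _direction(res.adjusted_p, res.fold_change,
                                   alpha, fc_up, fc_down)
    n_up = sum(r.direction == "up" for r in results)
    n_down = sum(r.direction == "down" for r in results)
    logger.info("differential analysis: %d peptides, %d up, %d down",
                len(results), n_up, n_down)
    return results


def write_differential(results: Iterable[DifferentialResult], path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "peptide_id": r.peptide_id,
                "p_value": repr(r.p_value),
                "adjusted_p": repr(r.adjusted_p),
                "fold_change": repr(r.fold_change),
                "direction": r.direction,
            }
            for r in results
        ],
        columns=["peptide_id", "p_value", "adjusted_p", "fold_change", "direction"],
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_differential(path) -> list[DifferentialResult]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [
        DifferentialResult(
            peptide_id=str(row.peptide_id),
            p_value=float(row.p_value),
            adjusted_p=float(row.adjusted_p),
            fold_change=float(row.fold_change),
            direction=str(row.direction),
        )
        for row in df.itertuples()
    ]
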