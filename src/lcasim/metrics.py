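"""Outcome metrics: parameter-recovery bias, boundary prevalence, effect sizes.

Parameter recovery is summarized as absolute relative bias,
|estimate - truth| / |truth|. CRP bias is averaged over a fixed pair of
high-value and a fixed pair of low-value CRPs per replication so that cells
with different numbers of indicators are compared fairly. Factor effects
over the design are summarized as eta-squared (SS_effect / SS_total, from
the balanced fixed-effects decomposition) for continuous outcomes and as
odds ratios from a logistic regression with ordinal [0,1]-rescaled factors
for binary outcomes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .design import PopulationSpec
from .estimator import ParameterSet


def relative_bias(est: float, truth: float) -> float:
    """Absolute relative bias |est - truth| / |truth|; undefined for truth 0."""
    if truth == 0:
        raise ValueError("relative bias is undefined for a true value of 0")
    return abs(est - truth) / abs(truth)


def _fixed_crp_positions(true_crp: np.ndarray, value: float, k: int = 2) -> list[tuple[int, int]]:
    """First ``k`` positions (class-major order) whose population CRP is ``value``."""
    pos = [(c, j) for c in range(true_crp.shape[0]) for j in range(true_crp.shape[1])
           if true_crp[c, j] == value]
    return pos[:k]


def crp_bias(est_crp: np.ndarray, true_crp: np.ndarray) -> tuple[float, float]:
    """Mean absolute relative bias over two high-value and two low-value CRPs.

    The pairs are the first two CRPs in class-major order whose population
    value equals the high (resp. low) level; boundary estimates are included.
    """
    est_crp = np.asarray(est_crp, dtype=float)
    true_crp = np.asarray(true_crp, dtype=float)
    high, low = true_crp.max(), true_crp.min()
    hb = float(np.mean([relative_bias(est_crp[c, j], true_crp[c, j])
                        for c, j in _fixed_crp_positions(true_crp, high)]))
    lb = float(np.mean([relative_bias(est_crp[c, j], true_crp[c, j])
                        for c, j in _fixed_crp_positions(true_crp, low)]))
    return hb, lb


def structural_bias(est: ParameterSet, spec: PopulationSpec) -> dict:
    """Bias of the structural (class-membership) parameters.

    Without a covariate: relative bias of each estimated class proportion.
    With one: relative bias of each non-reference logistic intercept (the
    class-proportion role at the covariate mean) and of the slope — for
    3-class models the two equal slopes' biases are averaged.
    """
    out: dict = {}
    if not spec.has_covariate:
        out["class_proportion"] = np.array(
            [relative_bias(e, t) for e, t in zip(est.gamma, spec.gamma)]
        )
        out["slope"] = None
        return out
    C = spec.n_classes
    out["class_proportion"] = np.array(
        [relative_bias(est.beta0[c], spec.beta0[c]) for c in range(C - 1)]
    )
    out["slope"] = float(
        np.mean([relative_bias(est.beta1[c], spec.beta1[c]) for c in range(C - 1)])
    )
    return out


def boundary_prevalence(records: Iterable) -> float:
    """Mean fraction of the C*J CRPs flagged at the boundary, over usable fits."""
    fracs = []
    for rec in records:
        if rec.status != "ok":
            continue
        C, J = rec.fit.estimate.crp.shape if rec.fit is not None else (None, None)
        if C is None:
            C, J = rec.cell.n_classes, rec.cell.n_indicators
        fracs.append(rec.boundary_count / (C * J))
    if not fracs:
        return float("nan")
    return float(np.mean(fracs))


def _check_balanced(data: pd.DataFrame, factors: Sequence[str]) -> None:
    counts = data.groupby(list(factors), observed=True).size()
    full = int(np.prod([data[f].nunique() for f in factors]))
    if len(counts) != full or counts.nunique() != 1:
        raise ValueError("eta_squared requires a balanced, fully crossed factorial layout")


def eta_squared(
    data: pd.DataFrame,
    outcome: str,
    factors: Sequence[str],
    term: str | Sequence[str],
) -> float:
    """Proportion of outcome variance attributable to a design term.

    SS_term / SS_total from the balanced fixed-effects decomposition: the
    term's per-observation effect is built from marginal cell means by
    inclusion-exclusion, so main effects and interactions of any order are
    orthogonal and their SS (plus residual) add up to SS_total. A constant
    outcome returns 0 by convention.
    """
    term_factors = (term,) if isinstance(term, str) else tuple(term)
    for f in term_factors:
        if f not in factors:
            raise ValueError(f"term factor {f!r} not among design factors {list(factors)}")
    _check_balanced(data, factors)

    y = data[outcome].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    if ss_total == 0:
        return 0.0

    k = len(term_factors)
    effect = np.zeros(len(data))
    for r in range(k + 1):
        for subset in itertools.combinations(term_factors, r):
            sign = (-1) ** (k - r)
            if r == 0:
                effect += sign * grand
            else:
                m = data.groupby(list(subset), observed=True)[outcome].transform("mean")
                effect += sign * m.to_numpy(dtype=float)
    return float((effect ** 2).sum() / ss_total)


@dataclass
class OrEffect:
    """Odds-ratio effect size of one design factor on a binary outcome."""

    odds_ratio: float
    separated: bool = False


def or_effect(
    data: pd.DataFrame,
    outcome: str,
    factor_levels: dict[str, Sequence],
    term: str,
) -> OrEffect:
    """Odds ratio of ``term`` from a logistic regression of a binary outcome.

    Each factor enters as a single ordinal predictor with its ordered levels
    rescaled to [0, 1], so one coefficient (hence one odds ratio) summarizes
    the factor. Complete separation is reported as an infinite odds ratio
    with a flag rather than raised.
    """
    y = data[outcome].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    X = pd.DataFrame(index=data.index)
    for f, levels in factor_levels.items():
        levels = list(levels)
        ranks = data[f].map({lv: i for i, lv in enumerate(levels)})
        if ranks.isna().any():
            raise ValueError(f"unknown level in factor {f!r}")
        X[f] = ranks / max(len(levels) - 1, 1)
    X = sm.add_constant(X.astype(float))
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        coef = float(res.params[term])
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return OrEffect(odds_ratio=float("inf"), separated=True)
    if not np.isfinite(coef) or abs(coef) > 30:
        return OrEffect(odds_ratio=float("inf"), separated=True)
    return OrEffect(odds_ratio=float(np.exp(coef)))
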