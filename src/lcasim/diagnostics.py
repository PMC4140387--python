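"""Per-replication classification: label alignment and exclusion statuses.

Class labels in a mixture model are arbitrary, so a fitted replication must
be checked against the generating labels before its estimates can be
aggregated. The check is based on the class assignment matrix (true class by
modal posterior class). Replications are classified into a mutually
exclusive status: usable (``ok``), ``nonconverged``, ``label_switched``,
``incorrigible`` (assignment too inaccurate to determine any labeling), or
``zero_variance`` (a constant observed item). Label-switched replications
are excluded rather than relabeled.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .datagen import Dataset, zero_variance_check
from .design import DesignCell
from .estimator import FitResult

STATUSES = ("ok", "nonconverged", "label_switched", "incorrigible", "zero_variance")

#: minimum per-class assignment accuracy (diagonal of the permuted
#: assignment matrix) below which a replication is incorrigible
DEFAULT_ACCURACY_FLOOR = 0.7


@dataclass
class LabelResult:
    status: str                      # "correct" | "switched" | "incorrigible"
    permutation: tuple[int, ...]     # 0-based; new class k was estimated class perm[k]


@dataclass
class ReplicationRecord:
    """Outcome of a single replication: status, alignment, and (if usable) bias."""

    cell: Optional[DesignCell]
    replication_index: int
    seed: int
    status: str
    permutation: tuple[int, ...]
    loglik: float = np.nan
    n_iterations: int = 0
    boundary_count: int = 0
    bias: dict | None = None
    fit: FitResult | None = None

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if (self.bias is not None) != (self.status == "ok"):
            raise ValueError("bias must be present exactly for ok replications")


def assignment_matrix(fit: FitResult, d: Dataset) -> np.ndarray:
    """Class assignment matrix A with A[t, e] = P(modal class e | true class t).

    Rows index true classes, columns the estimated classes under modal
    (highest-posterior) assignment; ties break toward the lower class index.
    Rows are proportions and sum to 1 (a true class absent from the sample
    yields a NaN row, treated downstream as incorrigible).
    """
    C = fit.posterior.shape[1]
    modal = np.argmax(fit.posterior, axis=1)
    A = np.zeros((C, C))
    for t in range(C):
        sel = d.true_class == t + 1
        n_t = int(sel.sum())
        if n_t == 0:
            A[t] = np.nan
            continue
        A[t] = np.bincount(modal[sel], minlength=C) / n_t
    return A


def classify_labels(A: np.ndarray, accuracy_floor: float = DEFAULT_ACCURACY_FLOOR) -> LabelResult:
    """Determine the labeling of an estimated solution from its assignment matrix.

    Searches all permutations of the estimated classes for the one maximizing
    the matched assignment rate (trace of the column-permuted matrix). The
    result is incorrigible when no permutation achieves the per-class
    accuracy floor on every diagonal entry, or when the best permutation is
    not unique; otherwise the solution is correct (identity) or switched.
    """
    C = A.shape[0]
    if not np.all(np.isfinite(A)):
        return LabelResult("incorrigible", tuple(range(C)))
    perms = list(itertools.permutations(range(C)))
    scores = np.array([sum(A[t, p[t]] for t in range(C)) for p in perms])
    best = int(np.argmax(scores))
    if np.sum(scores == scores[best]) > 1:
        return LabelResult("incorrigible", tuple(range(C)))
    perm = perms[best]
    diag = np.array([A[t, perm[t]] for t in range(C)])
    if diag.min() < accuracy_floor:
        return LabelResult("incorrigible", tuple(range(C)))
    if perm == tuple(range(C)):
        return LabelResult("correct", perm)
    return LabelResult("switched", perm)


def classify_replication(
    fit: FitResult | None,
    d: Dataset,
    accuracy_floor: float = DEFAULT_ACCURACY_FLOOR,
) -> tuple[str, tuple[int, ...]]:
    """Apply the exclusion cascade to one replication.

    Precedence: zero variance of an observed item, then non-convergence,
    then the label classification (incorrigible / label_switched / ok).
    Returns (status, permutation); the permutation is the identity except
    for label-switched solutions.
    """
    _, any_constant = zero_variance_check(d)
    C = d.true_class.max() if fit is None else fit.posterior.shape[1]
    identity = tuple(range(int(C)))
    if any_constant:
        return "zero_variance", identity
    if fit is None or not fit.converged:
        return "nonconverged", identity
    res = classify_labels(assignment_matrix(fit, d), accuracy_floor)
    if res.status == "incorrigible":
        return "incorrigible", identity
    if res.status == "switched":
        return "label_switched", res.permutation
    return "ok", identity
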