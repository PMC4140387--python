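"""Synthetic replication datasets and a brute-force likelihood oracle.

Data generation follows the latent class model exactly: an optional
standard-normal covariate drives class membership through a multinomial
logistic model, and items are conditionally independent Bernoulli draws
given the class. ``pattern_probabilities`` enumerates the exact probability
of every response pattern and serves as an independent oracle for the
likelihood code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import softmax

from .design import PopulationSpec


@dataclass
class Dataset:
    """One generated sample.

    ``true_class`` (1-based labels) is retained for diagnostics only and
    never enters estimation.
    """

    responses: np.ndarray            # (n, J) of 0/1
    covariate: np.ndarray | None     # (n,) or None
    true_class: np.ndarray           # (n,) in 1..C
    seed: int | None = None

    @property
    def n(self) -> int:
        return self.responses.shape[0]

    @property
    def n_indicators(self) -> int:
        return self.responses.shape[1]

    def to_frame(self, include_true_class: bool = False) -> pd.DataFrame:
        """Tabular view with columns y1..yJ, optional x and true_class."""
        df = pd.DataFrame(
            self.responses, columns=[f"y{j}" for j in range(1, self.n_indicators + 1)]
        )
        if self.covariate is not None:
            df["x"] = self.covariate
        if include_true_class:
            df["true_class"] = self.true_class
        return df


def class_membership_probs(spec: PopulationSpec, x: np.ndarray | None) -> np.ndarray:
    """Class membership probabilities, (n, C), given covariate values.

    Without a covariate this is the unconditional ``gamma`` broadcast over
    observations; with one it is softmax(beta0 + beta1 * x) row-wise.
    """
    if not spec.has_covariate or x is None:
        if x is None and spec.has_covariate:
            raise ValueError("spec has a covariate; covariate values are required")
        n = 1 if x is None else len(x)
        return np.broadcast_to(spec.gamma, (n, spec.n_classes))
    eta = spec.beta0[None, :] + np.outer(np.asarray(x, dtype=float), spec.beta1)
    return softmax(eta, axis=1)


def generate_dataset(spec: PopulationSpec, n: int, seed) -> Dataset:
    """Draw one replication dataset of size ``n`` from the population.

    The covariate (if any) is drawn first, then class labels, then item
    responses, so a given seed yields a bit-identical dataset.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    C, J = spec.n_classes, spec.n_indicators

    if spec.has_covariate:
        x = rng.standard_normal(n)
        probs = class_membership_probs(spec, x)
        u = rng.random(n)
        labels = 1 + (u[:, None] >= np.cumsum(probs, axis=1)).sum(axis=1)
        labels = np.minimum(labels, C)
    else:
        x = None
        labels = 1 + rng.choice(C, size=n, p=spec.gamma)

    responses = (rng.random((n, J)) < spec.crp[labels - 1]).astype(np.int8)
    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    return Dataset(responses=responses, covariate=x, true_class=labels,
                   seed=int(seed_int) if seed_int is not None else None)


def pattern_probabilities(spec: PopulationSpec, x: float | None = None) -> dict[tuple[int, ...], float]:
    """Exact probability of each of the 2^J response patterns.

    Brute-force enumeration of the finite mixture of Bernoulli products;
    intended as a testing oracle, limited to J <= 20. For a covariate model,
    probabilities are conditional on the supplied covariate value ``x``.
    """
    J = spec.n_indicators
    if J > 20:
        raise ValueError(f"pattern enumeration requires J <= 20, got {J}")
    if spec.has_covariate and x is None:
        raise ValueError("covariate model: supply the covariate value x to condition on")
    if spec.has_covariate:
        prior = class_membership_probs(spec, np.array([float(x)]))[0]
    else:
        prior = spec.gamma

    patterns = ((np.arange(2 ** J)[:, None] >> np.arange(J - 1, -1, -1)) & 1).astype(float)
    # per-class product of Bernoulli pmfs over items, then mix over classes
    per_class = np.prod(
        patterns[:, None, :] * spec.crp[None, :, :]
        + (1 - patterns[:, None, :]) * (1 - spec.crp[None, :, :]),
        axis=2,
    )
    probs = per_class @ prior
    return {tuple(int(v) for v in row): float(p) for row, p in zip(patterns, probs)}


def zero_variance_check(d: Dataset) -> tuple[np.ndarray, bool]:
    """Flag items whose responses are constant over the whole sample.

    Returns (per-item flags, overall flag). A replication with any constant
    item is unusable: the item's CRPs are not estimable.
    """
    y = d.responses
    flags = np.all(y == y[0], axis=0)
    return flags, bool(flags.any())
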