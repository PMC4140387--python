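"""Factorial design cells and the true generating populations.

The study design crosses five factors: number of latent classes (2 or 3),
sample size, number of binary indicators, indicator quality (how close the
conditional response probabilities, CRPs, sit to 0/1), and the strength of a
covariate effect on class membership. Each cell maps to one generating
population: a vector of class proportions, a C x J matrix of CRPs, and a
multinomial-logistic structural model for class membership given a
standard-normal covariate.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

SAMPLE_SIZES = (70, 100, 200, 300, 500, 1000, 2000)
N_INDICATORS = tuple(range(4, 13))
QUALITY_LEVELS = ("low", "moderate", "high")
COVARIATE_LEVELS = ("none", "small", "moderate", "large")

#: high/low CRP pair per indicator-quality level
QUALITY_CRP = {"high": (0.9, 0.1), "moderate": (0.8, 0.2), "low": (0.7, 0.3)}

#: odds ratio of class membership per unit covariate, per effect-size level
COVARIATE_OR = {"none": 1.0, "small": 1.5, "moderate": 2.5, "large": 4.0}

#: 1-based indicators on which the mixed-profile class (Class 2) endorses at
#: the high CRP; the remaining indicators use the low CRP.
CLASS2_HIGH_ITEMS = frozenset({1, 2, 5, 7, 9, 11})

CLASS_PROPORTIONS = {2: (0.67, 0.33), 3: (0.4, 0.4, 0.2)}


@dataclass(frozen=True, order=True)
class DesignCell:
    """One condition of the factorial design.

    3-class models with 4 indicators are excluded as generally
    underidentified and cannot be constructed.
    """

    n_classes: int
    sample_size: int
    n_indicators: int
    quality: str
    covariate: str

    def __post_init__(self) -> None:
        if self.n_classes not in (2, 3):
            raise ValueError(f"n_classes must be 2 or 3, got {self.n_classes}")
        if self.sample_size not in SAMPLE_SIZES:
            raise ValueError(f"sample_size must be one of {SAMPLE_SIZES}, got {self.sample_size}")
        if self.n_indicators not in N_INDICATORS:
            raise ValueError(f"n_indicators must be in {N_INDICATORS}, got {self.n_indicators}")
        if self.quality not in QUALITY_LEVELS:
            raise ValueError(f"quality must be one of {QUALITY_LEVELS}, got {self.quality!r}")
        if self.covariate not in COVARIATE_LEVELS:
            raise ValueError(f"covariate must be one of {COVARIATE_LEVELS}, got {self.covariate!r}")
        if self.n_classes == 3 and self.n_indicators == 4:
            raise ValueError("3-class models with 4 indicators are underidentified")

    def seed_key(self) -> int:
        """Deterministic integer identity used to derive per-replication seeds.

        Depends only on the cell's factor levels, so results are independent
        of cell ordering or parallel scheduling.
        """
        digits = (
            self.n_classes - 2,
            SAMPLE_SIZES.index(self.sample_size),
            self.n_indicators - 4,
            QUALITY_LEVELS.index(self.quality),
            COVARIATE_LEVELS.index(self.covariate),
        )
        radices = (2, len(SAMPLE_SIZES), len(N_INDICATORS), len(QUALITY_LEVELS), len(COVARIATE_LEVELS))
        key = 0
        for d, r in zip(digits, radices):
            key = key * r + d
        return key


@dataclass
class PopulationSpec:
    """True generating parameters for one design cell.

    ``gamma`` are the unconditional class proportions; ``crp[c, j]`` is the
    probability of endorsing item j (coded 1) given membership in class c+1.
    With a covariate, class membership follows a multinomial logistic model
    with intercepts ``beta0`` and slopes ``beta1`` (last class is the
    reference, fixed at zero); softmax(beta0) equals ``gamma`` so that class
    proportions at the covariate mean match the unconditional design.
    """

    gamma: np.ndarray
    crp: np.ndarray
    beta0: np.ndarray
    beta1: np.ndarray
    has_covariate: bool

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.crp = np.atleast_2d(np.asarray(self.crp, dtype=float))
        self.beta0 = np.asarray(self.beta0, dtype=float)
        self.beta1 = np.asarray(self.beta1, dtype=float)
        C = self.gamma.size
        if self.crp.shape[0] != C:
            raise ValueError("crp must have one row per class")
        if not math.isclose(self.gamma.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("class proportions must sum to 1")
        if np.any(self.gamma <= 0):
            raise ValueError("class proportions must be strictly positive")
        if np.any((self.crp <= 0) | (self.crp >= 1)):
            raise ValueError("population CRPs must lie strictly in (0, 1)")
        if self.beta0.size != C or self.beta1.size != C:
            raise ValueError("beta0 and beta1 must have one entry per class")
        if self.beta0[-1] != 0 or self.beta1[-1] != 0:
            raise ValueError("reference (last) class must have zero intercept and slope")
        if not self.has_covariate and np.any(self.beta1 != 0):
            raise ValueError("slopes must be zero when there is no covariate")

    @property
    def n_classes(self) -> int:
        return self.gamma.size

    @property
    def n_indicators(self) -> int:
        return self.crp.shape[1]

    def to_json(self) -> str:
        return json.dumps(
            {
                "gamma": self.gamma.tolist(),
                "crp": self.crp.tolist(),
                "beta0": self.beta0.tolist(),
                "beta1": self.beta1.tolist(),
                "has_covariate": self.has_covariate,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "PopulationSpec":
        d = json.loads(s)
        return cls(
            gamma=np.array(d["gamma"]),
            crp=np.array(d["crp"]),
            beta0=np.array(d["beta0"]),
            beta1=np.array(d["beta1"]),
            has_covariate=bool(d["has_covariate"]),
        )


def or_to_slope(level: str) -> float:
    """Logistic slope beta1 = log(OR) for a covariate effect-size level."""
    if level not in COVARIATE_OR:
        raise ValueError(f"unknown covariate level {level!r}; expected one of {COVARIATE_LEVELS}")
    return math.log(COVARIATE_OR[level])


def proportions_to_intercepts(gamma) -> np.ndarray:
    """Multinomial-logit intercepts whose softmax reproduces ``gamma``.

    beta0_c = log(gamma_c / gamma_C) with the last class as reference, so the
    final entry is exactly zero.
    """
    gamma = np.asarray(gamma, dtype=float)
    if np.any(gamma <= 0):
        raise ValueError("all class proportions must be strictly positive")
    if not math.isclose(gamma.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("class proportions must sum to 1")
    beta0 = np.log(gamma / gamma[-1])
    beta0[-1] = 0.0
    return beta0


def class_profile_crps(n_classes: int, n_indicators: int, quality: str) -> np.ndarray:
    """CRP matrix for the study's class profiles.

    Class 1 endorses every item at the high CRP; Class 2 endorses items
    1,2,5,7,9,11 (1-based, truncated to J) at the high CRP and the rest at
    the low CRP; Class 3 (3-class models only) endorses every item at the
    low CRP.
    """
    high, low = QUALITY_CRP[quality]
    J = n_indicators
    class2 = np.array([high if j in CLASS2_HIGH_ITEMS else low for j in range(1, J + 1)])
    rows = [np.full(J, high), class2]
    if n_classes == 3:
        rows.append(np.full(J, low))
    return np.vstack(rows)


def build_population_spec(cell: DesignCell) -> PopulationSpec:
    """Generating population for a design cell."""
    gamma = np.array(CLASS_PROPORTIONS[cell.n_classes])
    crp = class_profile_crps(cell.n_classes, cell.n_indicators, cell.quality)
    beta0 = proportions_to_intercepts(gamma)
    slope = or_to_slope(cell.covariate)
    beta1 = np.full(cell.n_classes, slope)
    beta1[-1] = 0.0
    return PopulationSpec(
        gamma=gamma,
        crp=crp,
        beta0=beta0,
        beta1=beta1,
        has_covariate=cell.covariate != "none",
    )


def enumerate_design() -> list[DesignCell]:
    """All conditions of the fully crossed design, minus 3-class/4-indicator.

    756 two-class cells plus 672 three-class cells (1428 total), in a stable
    order sorted by (n_classes, sample_size, n_indicators, quality level,
    covariate level).
    """
    cells = []
    for C in (2, 3):
        for n, J, q, cov in itertools.product(SAMPLE_SIZES, N_INDICATORS, QUALITY_LEVELS, COVARIATE_LEVELS):
            if C == 3 and J == 4:
                continue
            cells.append(DesignCell(C, n, J, q, cov))
    cells.sort(
        key=lambda c: (
            c.n_classes,
            c.sample_size,
            c.n_indicators,
            QUALITY_LEVELS.index(c.quality),
            COVARIATE_LEVELS.index(c.covariate),
        )
    )
    return cells


def design_to_frame(cells: list[DesignCell]) -> pd.DataFrame:
    """Design grid as a DataFrame, one row per cell (exportable to CSV)."""
    return pd.DataFrame([asdict(c) for c in cells])
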