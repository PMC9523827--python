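"""Rank estimators for the Mann-Whitney parameter on accumulating two-arm data.

This module houses the midrank machinery and the per-stage estimators that
the three group sequential tests share:

* the relative effect ``p = P(X1 < X2) + 1/2 P(X1 = X2)`` estimated from
  mean midranks,
* the pooled rank variance and information of the Wilcoxon-Mann-Whitney
  (WMW) statistic,
* the Brunner-Munzel (BM) variance components, information and
  Satterthwaite-Welch degrees of freedom,
* the log win odds (LWO) effect ``psi = logit(p)`` and its delta-method
  information,
* the standardized statistic ``Z = (effect - null) * sqrt(information)``.

All estimators operate on midranks only, so they are invariant under any
strictly increasing transformation of the pooled data; ordinal categories
enter as integer codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .errors import BoundaryEffectError, DegenerateVarianceError, InvalidInputError

__all__ = [
    "TwoArmStageData",
    "RankSummary",
    "EffectEstimate",
    "midranks",
    "relative_effect",
    "rank_summary",
    "wmw_variance",
    "wmw_information",
    "bm_variance_components",
    "bm_information",
    "bm_degrees_of_freedom",
    "lwo_effect_and_information",
    "z_statistic",
    "effect_estimate",
]


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class TwoArmStageData:
    """Accumulating observations from a parallel two-arm trial.

    Each observation carries the first analysis (stage, 1-based) at which
    it is available; the sample analysed at stage ``k`` is the cumulative
    set of observations with ``stage_of_arrival <= k``.
    """

    values_arm1: np.ndarray
    values_arm2: np.ndarray
    stages_arm1: np.ndarray
    stages_arm2: np.ndarray
    K: int

    def __post_init__(self) -> None:
        self.values_arm1 = np.asarray(self.values_arm1, dtype=float)
        self.values_arm2 = np.asarray(self.values_arm2, dtype=float)
        self.stages_arm1 = np.asarray(self.stages_arm1, dtype=int)
        self.stages_arm2 = np.asarray(self.stages_arm2, dtype=int)
        if self.K < 1:
            raise InvalidInputError("K must be at least 1")
        for g, (v, s) in enumerate(
            [(self.values_arm1, self.stages_arm1), (self.values_arm2, self.stages_arm2)], 1
        ):
            if v.shape != s.shape or v.ndim != 1:
                raise InvalidInputError(f"arm {g}: values and stages must be 1-d and aligned")
            if s.size and (s.min() < 1 or s.max() > self.K):
                raise InvalidInputError(f"arm {g}: stage labels must lie in 1..K={self.K}")

    @classmethod
    def from_single_stage(cls, values_arm1, values_arm2) -> "TwoArmStageData":
        v1 = np.asarray(values_arm1, dtype=float)
        v2 = np.asarray(values_arm2, dtype=float)
        return cls(v1, v2, np.ones(v1.size, int), np.ones(v2.size, int), K=1)

    def cumulative(self, stage: int) -> tuple[np.ndarray, np.ndarray]:
        """Observations of both arms available at analysis ``stage``."""
        if not 1 <= stage <= self.K:
            raise InvalidInputError(f"stage must lie in 1..K={self.K}")
        return (
            self.values_arm1[self.stages_arm1 <= stage],
            self.values_arm2[self.stages_arm2 <= stage],
        )

    def sizes(self, stage: int) -> tuple[int, int]:
        x1, x2 = self.cumulative(stage)
        return x1.size, x2.size


@dataclass
class RankSummary:
    """Pooled and within-group midranks of the cumulative stage-``k`` sample."""

    pooled_arm1: np.ndarray   # R_{1i}^{(k)}
    pooled_arm2: np.ndarray   # R_{2j}^{(k)}
    within_arm1: np.ndarray   # R_{1i}^{(1k)}
    within_arm2: np.ndarray   # R_{2j}^{(2k)}
    mean_arm1: float = field(init=False)
    mean_arm2: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_arm1 = float(np.mean(self.pooled_arm1))
        self.mean_arm2 = float(np.mean(self.pooled_arm2))

    @property
    def n1(self) -> int:
        return self.pooled_arm1.size

    @property
    def n2(self) -> int:
        return self.pooled_arm2.size

    @property
    def N(self) -> int:
        return self.n1 + self.n2


@dataclass
class EffectEstimate:
    """Every per-stage quantity the three tests need, computed once.

    ``psi_hat``, ``info_lwo`` and ``z_lwo`` are NaN when the relative
    effect sits on the boundary {0, 1} (flagged by ``boundary_effect``);
    information fields are NaN under a zero variance estimate (flagged by
    ``degenerate_wmw`` / ``degenerate_bm``).  Downstream policy decides
    how to treat the flags.
    """

    stage: int
    n1: int
    n2: int
    p_hat: float
    psi_hat: float
    sigmaR2_hat: float
    sigma1sq_hat: float
    sigma2sq_hat: float
    info_wmw: float
    info_bm: float
    info_lwo: float
    df_hat: float
    z_wmw: float
    z_bm: float
    z_lwo: float
    boundary_effect: bool = False
    degenerate_wmw: bool = False
    degenerate_bm: bool = False

    def z(self, method: str) -> float:
        return {"wmw": self.z_wmw, "bm": self.z_bm, "bm_t": self.z_bm, "lwo": self.z_lwo}[method]

    def info(self, method: str) -> float:
        return {
            "wmw": self.info_wmw,
            "bm": self.info_bm,
            "bm_t": self.info_bm,
            "lwo": self.info_lwo,
        }[method]


# ---------------------------------------------------------------------------
# midranks and the relative effect
# ---------------------------------------------------------------------------

def midranks(values) -> np.ndarray:
    """Midranks ``R_i = 1/2 + sum_j c(x_i, x_j)`` of a sample.

    ``c`` is the normalised count kernel (0, 1/2, 1 for less / tied /
    greater), so tied values share the average of their ordinary ranks and
    the output sums to ``n(n+1)/2``.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InvalidInputError("midranks of an empty sample are undefined")
    return rankdata(v, method="average")


def relative_effect(data: TwoArmStageData, stage: int) -> float:
    """Estimate ``p = P(X1 < X2) + 1/2 P(X1 = X2)`` at an analysis.

    Uses the mean-midrank identity
    ``p_hat = (Rbar_2 - Rbar_1) / N + 1/2``, identical to the pairwise
    double sum ``(1/(n1 n2)) sum_ij c(X2j, X1i)``.
    """
    rs = rank_summary(data, stage)
    return float((rs.mean_arm2 - rs.mean_arm1) / rs.N + 0.5)


def rank_summary(data: TwoArmStageData, stage: int) -> RankSummary:
    x1, x2 = data.cumulative(stage)
    if x1.size == 0 or x2.size == 0:
        raise InvalidInputError(f"both arms must be nonempty at stage {stage}")
    pooled = midranks(np.concatenate([x1, x2]))
    return RankSummary(
        pooled_arm1=pooled[: x1.size],
        pooled_arm2=pooled[x1.size:],
        within_arm1=midranks(x1),
        within_arm2=midranks(x2),
    )


# ---------------------------------------------------------------------------
# Wilcoxon-Mann-Whitney variance and information
# ---------------------------------------------------------------------------

def wmw_variance(ranks: RankSummary, Nk: int | None = None) -> float:
    """Pooled rank variance ``sigmaR2 = sum (R - (N+1)/2)^2 / (N-1)``.

    Equals ``N(N+1)/12`` when all pooled values are distinct; zero when
    they are all tied.
    """
    N = ranks.N if Nk is None else Nk
    if N < 2:
        raise InvalidInputError("need at least two pooled observations")
    centre = (N + 1) / 2
    ss = float(np.sum((ranks.pooled_arm1 - centre) ** 2) + np.sum((ranks.pooled_arm2 - centre) ** 2))
    return ss / (N - 1)


def wmw_information(n1: int, n2: int, sigmaR2: float) -> float:
    """WMW information ``I = N n1 n2 / sigmaR2``; ``12 n1 n2 / (N+1)`` for tie-free data."""
    if n1 < 2 or n2 < 2:
        raise InvalidInputError("need at least two observations per arm")
    if sigmaR2 <= 0:
        raise DegenerateVarianceError("pooled rank variance is zero")
    N = n1 + n2
    return N * n1 * n2 / sigmaR2


# ---------------------------------------------------------------------------
# Brunner-Munzel components
# ---------------------------------------------------------------------------

def bm_variance_components(data: TwoArmStageData, stage: int) -> tuple[float, float]:
    """Brunner-Munzel variance estimators ``(sigma1sq_hat, sigma2sq_hat)``.

    ``sigma_g^2`` estimates ``V{F_h(X_g)}`` (the variance of the other
    arm's normalised CDF evaluated at arm ``g``) from the difference of
    pooled and within-group midranks.
    """
    rs = rank_summary(data, stage)
    return _bm_components_from_ranks(rs)


def _bm_components_from_ranks(rs: RankSummary) -> tuple[float, float]:
    n1, n2 = rs.n1, rs.n2
    if n1 < 2 or n2 < 2:
        raise InvalidInputError("need at least two observations per arm")
    d1 = rs.pooled_arm1 - rs.within_arm1 - rs.mean_arm1 + (n1 + 1) / 2
    d2 = rs.pooled_arm2 - rs.within_arm2 - rs.mean_arm2 + (n2 + 1) / 2
    s1 = float(np.sum(d1 ** 2)) / (n2 ** 2 * (n1 - 1))
    s2 = float(np.sum(d2 ** 2)) / (n1 ** 2 * (n2 - 1))
    return s1, s2


def bm_information(n1: int, n2: int, s1sq: float, s2sq: float) -> float:
    """BM information ``I = (sigma1sq/n1 + sigma2sq/n2)^-1``."""
    if n1 < 1 or n2 < 1:
        raise InvalidInputError("arm sizes must be positive")
    denom = s1sq / n1 + s2sq / n2
    if denom <= 0:
        raise DegenerateVarianceError("both Brunner-Munzel variance components are zero")
    return 1.0 / denom


def bm_degrees_of_freedom(n1: int, n2: int, s1sq: float, s2sq: float) -> float:
    """Satterthwaite-Welch degrees of freedom for the BM t-approximation.

    ``nu = (s1/n1 + s2/n2)^2 / [s1^2/(n1^2 (n1-1)) + s2^2/(n2^2 (n2-1))]``;
    collapses to ``2(n-1)`` for equal sizes and equal components.
    """
    num = (s1sq / n1 + s2sq / n2) ** 2
    den = s1sq ** 2 / (n1 ** 2 * (n1 - 1)) + s2sq ** 2 / (n2 ** 2 * (n2 - 1))
    if den <= 0:
        raise DegenerateVarianceError("degrees-of-freedom denominator is zero")
    return num / den


# ---------------------------------------------------------------------------
# log win odds
# ---------------------------------------------------------------------------

def lwo_effect_and_information(p_hat: float, info_bm: float) -> tuple[float, float]:
    """Delta-method log win odds: ``psi = logit(p)``, ``I = {p(1-p)}^2 I_BM``."""
    if not 0.0 < p_hat < 1.0:
        raise BoundaryEffectError(f"relative effect {p_hat} on the boundary; log win odds undefined")
    if info_bm <= 0:
        raise InvalidInputError("Brunner-Munzel information must be positive")
    psi = float(np.log(p_hat / (1.0 - p_hat)))
    return psi, (p_hat * (1.0 - p_hat)) ** 2 * info_bm


def z_statistic(effect: float, null_value: float, info: float) -> float:
    """Standardized statistic ``Z = (effect - null) sqrt(I)``."""
    if info <= 0:
        raise InvalidInputError("information must be positive")
    return (effect - null_value) * float(np.sqrt(info))


# ---------------------------------------------------------------------------
# one-stop per-stage estimate
# ---------------------------------------------------------------------------

def effect_estimate(data: TwoArmStageData, stage: int) -> EffectEstimate:
    """Compute every statistic of one analysis in a single rank pass.

    Degenerate conditions do not raise here; they set NaN fields and
    flags so that monitoring and simulation can apply their policies.
    """
    rs = rank_summary(data, stage)
    n1, n2, N = rs.n1, rs.n2, rs.N
    if n1 < 2 or n2 < 2:
        raise InvalidInputError("need at least two observations per arm at an analysed stage")
    p_hat = float((rs.mean_arm2 - rs.mean_arm1) / N + 0.5)
    sigmaR2 = wmw_variance(rs)
    s1, s2 = _bm_components_from_ranks(rs)

    degenerate_wmw = sigmaR2 <= 0
    degenerate_bm = (s1 / n1 + s2 / n2) <= 0
    boundary = not (0.0 < p_hat < 1.0)

    info_wmw = np.nan if degenerate_wmw else N * n1 * n2 / sigmaR2
    info_bm = np.nan if degenerate_bm else 1.0 / (s1 / n1 + s2 / n2)
    df_hat = np.nan if degenerate_bm else bm_degrees_of_freedom(n1, n2, s1, s2)
    z_wmw = np.nan if degenerate_wmw else (p_hat - 0.5) * np.sqrt(info_wmw)
    z_bm = np.nan if degenerate_bm else (p_hat - 0.5) * np.sqrt(info_bm)

    if boundary or degenerate_bm:
        psi = np.nan
        info_lwo = np.nan
        z_lwo = np.nan
    else:
        psi, info_lwo = lwo_effect_and_information(p_hat, info_bm)
        z_lwo = psi * np.sqrt(info_lwo)

    return EffectEstimate(
        stage=stage, n1=n1, n2=n2,
        p_hat=p_hat, psi_hat=float(psi),
        sigmaR2_hat=float(sigmaR2), sigma1sq_hat=float(s1), sigma2sq_hat=float(s2),
        info_wmw=float(info_wmw), info_bm=float(info_bm), info_lwo=float(info_lwo),
        df_hat=float(df_hat),
        z_wmw=float(z_wmw), z_bm=float(z_bm), z_lwo=float(z_lwo),
        boundary_effect=boundary, degenerate_wmw=degenerate_wmw, degenerate_bm=degenerate_bm,
    )
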