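"""Error spending, sequential boundaries, monitoring and repeated CIs.

The three rank statistics asymptotically follow the canonical joint
distribution: ``(Z_1, ..., Z_K)`` multivariate normal with
``E(Z_k) = theta sqrt(I_k)`` and ``Corr(Z_i, Z_j) = sqrt(I_i / I_j)``
for ``i <= j``.  That Markov structure lets every boundary-crossing
probability be computed by a one-dimensional recursive integration over
the score process ``S_k = Z_k sqrt(I_k)`` (independent increments), which
is what :func:`canonical_probabilities` implements — deterministic
Gauss-Legendre quadrature, no Monte Carlo.

Stage levels come from Lan-DeMets error spending: a nondecreasing
function ``f`` with ``f(0) = 0`` and ``f(t >= 1) = alpha`` prescribes the
cumulative type-I error spent at information fraction ``t``; the final
analysis always spends the full remainder ``alpha - f(tau_{K-1})``.

Repeated confidence intervals invert the same boundaries: with the
symmetric two-sided construction, a 95% repeated CI accompanies the
one-sided 2.5% test using the identical per-tail critical values ``c_k``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import InvalidInputError, MonotonicityError, NumericError
from .rank_core import EffectEstimate, TwoArmStageData, effect_estimate

__all__ = [
    "SequentialDesign",
    "BoundarySet",
    "StageDecision",
    "spending_value",
    "spend_increments",
    "canonical_probabilities",
    "boundaries",
    "repeated_p_value",
    "monitor",
    "repeated_ci",
]

logger = logging.getLogger("gsrank")

METHODS = ("wmw", "bm", "bm_t", "lwo")

#: grid half-width in standard deviations and node count of the
#: Gauss-Legendre recursion; 512 nodes give crossing probabilities well
#: below 1e-8 absolute error for K <= 4.
_GRID_SD = 8.5
_GRID_NODES = 512
_TAU_EPS = 1e-8


@dataclass
class SequentialDesign:
    """Prespecified design of a group sequential trial.

    ``alpha`` is the overall one-sided significance level (two-sided
    designs spend ``alpha/2`` per tail); ``Imax`` the prespecified
    maximum information used as the denominator of information fractions.
    """

    K: int
    alpha: float = 0.025
    sided: str = "one_sided"
    spending: str = "obrien_fleming"
    Imax: float | None = None

    def __post_init__(self) -> None:
        if self.K < 1:
            raise InvalidInputError("K must be at least 1")
        if not 0.0 < self.alpha < 1.0:
            raise InvalidInputError("alpha must lie in (0, 1)")
        if self.sided not in ("one_sided", "two_sided"):
            raise InvalidInputError(f"unknown sidedness {self.sided!r}")
        if self.spending not in ("obrien_fleming", "pocock"):
            raise InvalidInputError(f"unknown spending function {self.spending!r}")
        if self.Imax is not None and self.Imax <= 0:
            raise InvalidInputError("Imax must be positive")

    @property
    def tail_alpha(self) -> float:
        """Error spent per tail (equals alpha for one-sided designs)."""
        return self.alpha if self.sided == "one_sided" else self.alpha / 2


@dataclass
class BoundarySet:
    """Stage levels and critical values of one spending design."""

    info_fractions: np.ndarray   # tau_k, capped at 1
    increments: np.ndarray       # pi_k, sum to the per-tail alpha
    stage_levels: np.ndarray     # alpha_k = P(Z >= c_k) under N(0,1)
    crit_values: np.ndarray      # c_k

    @property
    def correlation(self) -> np.ndarray:
        t = self.info_fractions
        return np.sqrt(np.minimum.outer(t, t) / np.maximum.outer(t, t))


@dataclass
class StageDecision:
    """Outcome of one interim (or final) analysis."""

    stage: int
    n1: int
    n2: int
    p_hat: float
    effect: float
    z: float
    p_value: float
    stage_level: float
    crit_value: float
    reject: bool
    info: float
    info_fraction: float
    ci_lo: float | None = None
    ci_hi: float | None = None
    events: tuple = ()


# ---------------------------------------------------------------------------
# spending functions
# ---------------------------------------------------------------------------

def spending_value(kind: str, alpha: float, t) -> float | np.ndarray:
    """Cumulative error spent at information fraction ``t``.

    O'Brien-Fleming type: ``min{2 - 2 Phi(z_{1-alpha/2}/sqrt(t)), alpha}``;
    Pocock type: ``min[alpha ln{1 + (e-1) t}, alpha]``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise InvalidInputError("information fraction must be nonnegative")
    tc = np.minimum(t_arr, 1.0)
    if kind == "pocock":
        out = np.minimum(alpha * np.log1p((np.e - 1.0) * tc), alpha)
    elif kind == "obrien_fleming":
        z = stats.norm.isf(alpha / 2)
        with np.errstate(divide="ignore"):
            arg = z / np.sqrt(np.where(tc > 0, tc, np.inf))
        out = np.where(tc > 0, np.minimum(2.0 * stats.norm.sf(arg), alpha), 0.0)
    else:
        raise InvalidInputError(f"unknown spending function {kind!r}")
    return float(out) if np.isscalar(t) else out


def spend_increments(design: SequentialDesign, observed_info) -> np.ndarray:
    """Per-stage error increments ``pi_k`` from observed information.

    ``pi_1 = f(tau_1)``, ``pi_k = f(tau_k) - f(tau_{k-1})`` for interior
    stages, and the final stage spends the full remainder
    ``alpha - f(tau_{K-1})`` regardless of whether the last observed
    information reached Imax.
    """
    info = np.asarray(observed_info, dtype=float)
    if info.size != design.K:
        raise InvalidInputError(f"expected {design.K} information values, got {info.size}")
    if np.any(np.diff(info) <= 0):
        raise MonotonicityError("observed information must be strictly increasing")
    alpha = design.tail_alpha
    if design.K == 1:
        return np.array([alpha])
    Imax = design.Imax if design.Imax is not None else info[-1]
    tau = np.minimum(info / Imax, 1.0)
    f = spending_value(design.spending, alpha, tau)
    pi = np.empty(design.K)
    pi[0] = f[0]
    pi[1:-1] = np.diff(f)[:-1]
    pi[-1] = alpha - f[-2]
    return np.maximum(pi, 0.0)


# ---------------------------------------------------------------------------
# canonical-distribution probabilities (recursive integration)
# ---------------------------------------------------------------------------

_GL_X, _GL_W = np.polynomial.legendre.leggauss(_GRID_NODES)


def _gl_nodes(lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
    half = (hi - lo) / 2
    return lo + half * (_GL_X + 1), _GL_W * half


class _ScoreRecursion:
    """Sub-density of the score process on its non-crossing region.

    The canonical statistics correspond to a score process
    ``S_k = Z_k sqrt(tau_k)`` with independent mean-zero normal
    increments of variance ``tau_k - tau_{k-1}``.  The object carries
    the quadrature-weighted sub-density of ``S_{k}`` restricted to
    ``{S_j < u_j sqrt(tau_j), j <= k}``; :meth:`exit_prob` evaluates the
    stage-``k+1`` crossing probability for a candidate limit (cheap, no
    kernel rebuild) and :meth:`advance` integrates one stage forward.
    """

    def __init__(self, taus: np.ndarray) -> None:
        self.tau = np.asarray(taus, dtype=float)
        if self.tau.size == 0 or self.tau[0] <= 0 or np.any(np.diff(self.tau) <= 0):
            raise MonotonicityError("information fractions must be positive and increasing")
        self.k = -1
        self.psi: np.ndarray | None = None   # density x quadrature weight
        self.grid: np.ndarray | None = None

    def exit_prob(self, u: float) -> float:
        """P(no crossing before, Z_{k+2} >= u) for the next stage."""
        k = self.k + 1
        if k == 0:
            return float(stats.norm.sf(u))
        dk = np.sqrt(self.tau[k] - self.tau[k - 1])
        return float(self.psi @ stats.norm.sf((u * np.sqrt(self.tau[k]) - self.grid) / dk))

    def advance(self, u: float) -> None:
        """Restrict the next stage to ``Z < u`` and absorb it."""
        k = self.k + 1
        sk = np.sqrt(self.tau[k])
        hi = min(u, _GRID_SD) * sk
        if k == 0:
            lo = min(-_GRID_SD * sk, hi - _GRID_SD * sk)
            grid, w = _gl_nodes(lo, hi)
            self.psi = stats.norm.pdf(grid / sk) / sk * w
        else:
            dk = np.sqrt(self.tau[k] - self.tau[k - 1])
            lo = min(-_GRID_SD * sk, hi - _GRID_SD * dk)
            grid, w = _gl_nodes(lo, hi)
            kernel = stats.norm.pdf((grid[:, None] - self.grid[None, :]) / dk) / dk
            self.psi = (kernel @ self.psi) * w
        self.grid = grid
        self.k = k


def canonical_probabilities(times, upper) -> tuple[np.ndarray, float]:
    """Stagewise first-crossing probabilities under the canonical law.

    For mean-zero ``(Z_1, ..., Z_K)`` with ``Corr(Z_i, Z_j) =
    sqrt(t_i/t_j)``, returns ``(exit, noncross)`` where ``exit[k-1] =
    P(Z_1 < u_1, ..., Z_{k-1} < u_{k-1}, Z_k >= u_k)`` and ``noncross =
    P(Z_k < u_k for all k)``.  ``times`` must be strictly increasing and
    positive; ``upper`` may contain ``+inf`` (stage cannot reject).
    """
    t = np.asarray(times, dtype=float)
    u = np.asarray(upper, dtype=float)
    if t.size != u.size or t.size == 0:
        raise InvalidInputError("times and upper limits must align and be nonempty")
    rec = _ScoreRecursion(t / t[-1])
    exit_probs = np.empty(t.size)
    for k in range(t.size):
        exit_probs[k] = rec.exit_prob(u[k])
        if k < t.size - 1:
            rec.advance(u[k])
    noncross = 1.0 - float(np.sum(exit_probs))
    return exit_probs, max(noncross, 0.0)


def _solve_boundaries(taus: np.ndarray, pis: np.ndarray) -> np.ndarray:
    """Critical values with stagewise exit probabilities ``pis``."""
    rec = _ScoreRecursion(taus)
    c = np.empty(taus.size)
    for k in range(taus.size):
        if pis[k] <= 1e-15:
            c[k] = np.inf
        elif k == 0:
            c[k] = stats.norm.isf(pis[0])
        else:
            try:
                c[k] = optimize.brentq(
                    lambda ck: rec.exit_prob(ck) - pis[k], -10.0, 12.0,
                    xtol=1e-10, rtol=1e-12,
                )
            except ValueError as err:  # pragma: no cover - diagnostic path
                raise NumericError(
                    f"boundary solver failed at stage {k + 1}: pi={pis[k]:.3e}, tau={taus[:k+1]}"
                ) from err
        if k < taus.size - 1:
            rec.advance(c[k])
    return c


def boundaries(design: SequentialDesign, observed_info) -> BoundarySet:
    """Solve the stage levels ``alpha_k`` and critical values ``c_k``.

    ``c_k`` satisfies ``P(Z_1 < c_1, ..., Z_{k-1} < c_{k-1}, Z_k >= c_k)
    = pi_k`` recursively under the canonical correlation
    ``sqrt(tau_i/tau_j)``; for ``K = 1`` this is the plain normal
    quantile ``z_{1-alpha}``.
    """
    info = np.asarray(observed_info, dtype=float)
    pi = spend_increments(design, info)
    Imax = design.Imax if design.Imax is not None else info[-1]
    tau = np.minimum(info / Imax, 1.0)
    # guard against ties introduced by the cap at 1
    for k in range(1, tau.size):
        if tau[k] <= tau[k - 1]:
            tau[k] = tau[k - 1] + _TAU_EPS
    c = _solve_boundaries(tau, pi)
    levels = stats.norm.sf(c)
    return BoundarySet(info_fractions=tau, increments=pi, stage_levels=levels, crit_values=c)


def repeated_p_value(z: float, df: float | None = None) -> float:
    """Repeated p-value ``1 - Phi(z)``, or ``1 - F_nu(z)`` for the
    Brunner-Munzel t-approximation."""
    if df is not None:
        if df <= 0:
            raise InvalidInputError("degrees of freedom must be positive")
        return float(stats.t.sf(z, df))
    return float(stats.norm.sf(z))


# ---------------------------------------------------------------------------
# monitoring
# ---------------------------------------------------------------------------

def _effect_and_null(est: EffectEstimate, method: str) -> tuple[float, float]:
    if method == "lwo":
        return est.psi_hat, 0.0
    return est.p_hat, 0.5


def monitor(
    data: TwoArmStageData,
    design: SequentialDesign,
    method: str = "bm",
    on_degenerate: str = "raise",
) -> list[StageDecision]:
    """Run the group sequential test over the observed stages.

    Information is frozen at the stage where it is first estimated; the
    trial stops at the first rejection (no futility stopping).  A
    decreasing information estimate is clamped (for spending purposes
    only) to just above the previous stage's value and logged.

    ``on_degenerate``: ``"raise"`` propagates degenerate-variance /
    boundary-effect conditions as typed errors; ``"skip"`` records the
    stage as non-rejecting, carrying the information forward — the
    default simulation policy.
    """
    if method not in METHODS:
        raise InvalidInputError(f"unknown method {method!r}; choose from {METHODS}")
    if on_degenerate not in ("raise", "skip"):
        raise InvalidInputError("on_degenerate must be 'raise' or 'skip'")
    if design.Imax is None:
        raise InvalidInputError("monitoring requires a prespecified Imax in the design")

    decisions: list[StageDecision] = []
    frozen_info: list[float] = []
    pis: list[float] = []
    alpha = design.tail_alpha
    f_prev = 0.0
    for k in range(1, design.K + 1):
        est = effect_estimate(data, k)
        events = []
        degenerate = est.degenerate_wmw if method == "wmw" else est.degenerate_bm
        boundary = method == "lwo" and est.boundary_effect
        if degenerate or boundary:
            event = "zero_variance" if degenerate else "boundary_effect"
            if on_degenerate == "raise":
                from .errors import BoundaryEffectError, DegenerateVarianceError

                exc = DegenerateVarianceError if degenerate else BoundaryEffectError
                raise exc(f"stage {k}: {event}")
            events.append(event)
            info_k = frozen_info[-1] if frozen_info else _TAU_EPS * design.Imax
        else:
            info_k = est.info(method)
        if frozen_info and info_k <= frozen_info[-1]:
            if "zero_variance" not in events and "boundary_effect" not in events:
                events.append("decreasing_information")
                logger.warning("stage %d: information decreased (%.4g <= %.4g); clamped for spending",
                               k, info_k, frozen_info[-1])
            info_for_spending = frozen_info[-1] * (1 + _TAU_EPS) + _TAU_EPS
        else:
            info_for_spending = info_k
        frozen_info.append(info_for_spending)

        tau_k = min(info_for_spending / design.Imax, 1.0)
        if len(frozen_info) > 1:
            tau_prev = min(frozen_info[-2] / design.Imax, 1.0)
            tau_k = max(tau_k, tau_prev + _TAU_EPS)
        if k < design.K:
            f_k = max(spending_value(design.spending, alpha, tau_k), f_prev)
            pi_k = f_k - f_prev
        else:
            f_k = alpha
            pi_k = alpha - f_prev

        taus = np.minimum(np.asarray(frozen_info) / design.Imax, 1.0)
        for j in range(1, taus.size):
            if taus[j] <= taus[j - 1]:
                taus[j] = taus[j - 1] + _TAU_EPS
        pis.append(pi_k)
        c_k = float(_solve_boundaries(taus, np.asarray(pis))[-1])
        alpha_k = float(stats.norm.sf(c_k))
        f_prev = f_k

        if events and (degenerate or boundary):
            z = np.nan
            p_val = np.nan
            reject = False
        else:
            z = est.z(method)
            if method == "lwo" and est.boundary_effect and not est.degenerate_bm:
                # fall back to the BM repeated p-value (policy)
                z = est.z_bm
                events.append("boundary_effect")
            p_val = repeated_p_value(z, est.df_hat if method == "bm_t" else None)
            reject = bool(p_val <= alpha_k)

        ci_lo = ci_hi = None
        if method in ("bm", "bm_t", "lwo") and not (degenerate or boundary):
            ci_lo, ci_hi = repeated_ci(est, c_k, method)
        decisions.append(
            StageDecision(
                stage=k, n1=est.n1, n2=est.n2, p_hat=est.p_hat,
                effect=_effect_and_null(est, method)[0] if not boundary else np.nan,
                z=float(z), p_value=float(p_val), stage_level=alpha_k,
                crit_value=float(c_k), reject=reject, info=float(info_k),
                info_fraction=float(tau_k), ci_lo=ci_lo, ci_hi=ci_hi,
                events=tuple(events),
            )
        )
        if reject:
            break
    return decisions


def repeated_ci(
    estimate: EffectEstimate, crit_value: float, method: str = "bm"
) -> tuple[float, float]:
    """Two-sided repeated confidence interval for ``p`` at one stage.

    Inverts the symmetric two-sided boundary with per-tail critical value
    ``c_k`` (the same values as the one-sided test at per-tail level
    alpha, giving 95% repeated CIs alongside a 2.5% one-sided test):

    * ``bm``: ``p_hat +- c_k / sqrt(I_BM)``, truncated to [0, 1];
    * ``bm_t``: the normal quantile is mapped through the t distribution
      with the estimated degrees of freedom;
    * ``lwo``: ``psi_hat +- c_k / sqrt(I_LWO)``, inverse-logit back to
      the p scale (always inside (0, 1)).
    """
    if method not in ("bm", "bm_t", "lwo"):
        raise InvalidInputError(f"repeated CIs are available for bm, bm_t, lwo; not {method!r}")
    if not np.isfinite(crit_value):
        return (0.0, 1.0) if method != "lwo" else (0.0, 1.0)
    if method in ("bm", "bm_t"):
        if estimate.degenerate_bm:
            raise InvalidInputError("degenerate variance: no CI")
        mult = crit_value
        if method == "bm_t":
            mult = float(stats.t.ppf(stats.norm.cdf(crit_value), estimate.df_hat))
        half = mult / np.sqrt(estimate.info_bm)
        return (max(estimate.p_hat - half, 0.0), min(estimate.p_hat + half, 1.0))
    if estimate.boundary_effect:
        from .errors import BoundaryEffectError

        raise BoundaryEffectError("relative effect on the boundary; log win odds CI undefined")
    half = crit_value / np.sqrt(estimate.info_lwo)
    lo, hi = estimate.psi_hat - half, estimate.psi_hat + half
    expit = lambda x: 1.0 / (1.0 + np.exp(-x))
    return (float(expit(lo)), float(expit(hi)))
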