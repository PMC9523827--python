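"""Approximate power and sample size for the group sequential rank tests.

With the two arm distributions and a constant allocation ``t = n_1k/N_k``
specified, every true information level is available analytically, and
the power of the one-sided level-``alpha`` group sequential test of
``H0: p <= 1/2`` against ``H1: p > 1/2`` has a closed multivariate-normal
form:

* critical values ``c_k`` are solved from the chosen spending function
  under the canonical correlation of the respective statistic's true
  information sequence (WMW uses its own information, BM/LWO information
  is proportional to ``N_k`` under constant allocation);
* the power is ``1 - Phi_R(a_1, ..., a_K)`` where ``Phi_R`` is the
  K-variate normal CDF with correlation ``sqrt(N_i/N_j)`` and

  - WMW:  ``a_k = sqrt(I_k^BM / I_k^WMW) c_k - sqrt(I_k^BM) (p - 1/2)``
  - BM:   ``a_k = c_k - sqrt(I_k^BM) (p - 1/2)``
  - LWO:  ``a_k = c_k - sqrt(I_k^LWO) psi``,  ``psi = logit(p)``.

The shift of the WMW statistic involves the BM information because under
the alternative the variance of ``p_hat`` is the Brunner-Munzel one; the
WMW information (a pure ``H0`` quantity) only standardizes the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .errors import InvalidInputError, SearchBoundError
from .sequential_design import SequentialDesign, boundaries, canonical_probabilities
from .true_effects import (
    DistributionModel,
    true_bm_variances,
    true_relative_effect,
    true_wmw_variance,
)

__all__ = ["PowerSpec", "power", "sample_size", "true_stage_informations"]


@dataclass
class PowerSpec:
    """Planning inputs: model, method, allocation and stage totals."""

    model: DistributionModel
    method: str
    t: float
    stage_Ns: tuple
    design: SequentialDesign = field(default_factory=lambda: SequentialDesign(K=2, spending="pocock"))

    def __post_init__(self) -> None:
        Ns = np.asarray(self.stage_Ns, dtype=float)
        if np.any(np.diff(Ns) <= 0) or Ns.size != self.design.K:
            raise InvalidInputError("stage totals must be strictly increasing with length K")
        if not 0.0 < self.t < 1.0:
            raise InvalidInputError("allocation t must lie in (0, 1)")
        if self.method not in ("wmw", "bm", "lwo"):
            raise InvalidInputError("method must be one of wmw, bm, lwo")


def true_stage_informations(model: DistributionModel, t: float, stage_Ns) -> dict:
    """True WMW/BM/LWO information at each stage total ``N_k``.

    Arm sizes enter as ``n_1k = t N_k`` and ``n_2k = (1 - t) N_k``
    (real-valued; planning does not round).
    """
    Ns = np.asarray(stage_Ns, dtype=float)
    n1, n2 = t * Ns, (1 - t) * Ns
    p = true_relative_effect(model)
    s1, s2 = true_bm_variances(model)
    if s1 + s2 <= 0:
        raise InvalidInputError("degenerate model: zero Brunner-Munzel variance")
    info_bm = 1.0 / (s1 / n1 + s2 / n2)
    info_wmw = np.array(
        [N * a * b / true_wmw_variance(model, t, int(round(N))) for N, a, b in zip(Ns, n1, n2)]
    )
    info_lwo = (p * (1 - p)) ** 2 * info_bm
    return {"p": p, "psi": float(np.log(p / (1 - p))), "wmw": info_wmw, "bm": info_bm, "lwo": info_lwo}


def power(spec: PowerSpec) -> float:
    """Approximate power of the group sequential test for ``H1: p > 1/2``."""
    info = true_stage_informations(spec.model, spec.t, spec.stage_Ns)
    p, psi = info["p"], info["psi"]
    if p <= 0.5:
        raise InvalidInputError("one-sided power requires true p > 1/2")
    times = info["wmw"] if spec.method == "wmw" else info["bm"]
    design = SequentialDesign(
        K=spec.design.K, alpha=spec.design.alpha, sided=spec.design.sided,
        spending=spec.design.spending, Imax=float(times[-1]),
    )
    c = boundaries(design, times).crit_values
    if spec.method == "wmw":
        args = np.sqrt(info["bm"] / info["wmw"]) * c - np.sqrt(info["bm"]) * (p - 0.5)
    elif spec.method == "bm":
        args = c - np.sqrt(info["bm"]) * (p - 0.5)
    else:
        args = c - np.sqrt(info["lwo"]) * psi
    Ns = np.asarray(spec.stage_Ns, dtype=float)
    _, noncross = canonical_probabilities(Ns, args)
    return float(1.0 - noncross)


def _stage_step(t: float, fractions: np.ndarray) -> int:
    """Smallest N_K making every ``f_k N_K``, ``t f_k N_K`` integral."""
    denoms = []
    for fk in fractions:
        fr = Fraction(fk).limit_denominator(10**6)
        denoms.append(fr.denominator)
        denoms.append((fr * Fraction(t).limit_denominator(10**6)).denominator)
    return math.lcm(*denoms)


def sample_size(
    model: DistributionModel,
    method: str,
    t: float,
    design: SequentialDesign,
    target_power: float,
    stage_fractions=None,
    max_total: int = 1_000_000,
) -> dict:
    """Smallest admissible maximum sample size reaching ``target_power``.

    Stage totals follow ``N_k = f_k N_K`` with equally spaced fractions
    by default; ``N_K`` is searched over multiples of the smallest step
    that keeps every per-stage arm size integral (e.g. 4 for two equal
    stages at 1:1, 6 at 2:1 allocation).  Returns the stage totals, arm
    sizes and achieved power.
    """
    if not design.tail_alpha < target_power < 1.0:
        raise InvalidInputError("target power must lie in (alpha, 1)")
    fractions = (
        np.arange(1, design.K + 1) / design.K
        if stage_fractions is None
        else np.asarray(stage_fractions, dtype=float)
    )
    if fractions.size != design.K or fractions[-1] != 1.0 or np.any(np.diff(fractions) <= 0):
        raise InvalidInputError("stage fractions must be increasing and end at 1")
    step = _stage_step(t, fractions)

    def power_at(NK: int) -> float:
        Ns = tuple(np.round(fractions * NK).astype(int))
        return power(PowerSpec(model, method, t, Ns, design))

    # the smallest admissible size with >= 2 per arm at stage 1
    lo_mult = 1
    while fractions[0] * lo_mult * step * min(t, 1 - t) < 2:
        lo_mult += 1
    hi_mult = max(lo_mult, 1)
    while power_at(hi_mult * step) < target_power:
        hi_mult *= 2
        if hi_mult * step > max_total:
            raise SearchBoundError(
                f"target power {target_power} unreachable below N_K = {max_total}"
            )
    lo, hi = lo_mult, hi_mult  # power_at(hi*step) >= target
    while lo < hi:
        mid = (lo + hi) // 2
        if power_at(mid * step) >= target_power:
            hi = mid
        else:
            lo = mid + 1
    NK = hi * step
    Ns = np.round(fractions * NK).astype(int)
    return {
        "stage_totals": [int(N) for N in Ns],
        "arm1_sizes": [int(round(t * N)) for N in Ns],
        "arm2_sizes": [int(N - round(t * N)) for N in Ns],
        "achieved_power": power_at(NK),
        "target_power": target_power,
        "step": step,
    }
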