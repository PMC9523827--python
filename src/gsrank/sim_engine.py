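"""Monte-Carlo engine for the group sequential rank tests.

Replicates full trials under an analytic :class:`DistributionModel`,
reveals each replicate's data cumulatively by stage, evaluates all
requested tests on the same data, and reports overall and per-stage
cumulative rejection rates with Monte-Carlo standard errors.

Everything is vectorized across replicates: midranks of all replicates
of one stage are computed in a single axis-wise ``rankdata`` call, and
for designs with one or two analyses the stage levels are solved per
replicate with a vectorized bivariate-normal CDF (arcsine-form
Gauss-Legendre quadrature).  Designs with three or more analyses fall
back to a per-replicate loop over the scalar boundary machinery.

Finite-sample breakdowns are never fatal here; they are resolved by
:func:`exception_policy` and counted in the result:

* ``zero_variance`` — the stage is treated as non-rejecting and its
  information is carried forward unchanged;
* ``decreasing_information`` — the information fraction is clamped to
  just above the previous stage's for spending purposes while the
  statistic keeps the raw estimate;
* ``boundary_effect`` — an estimated relative effect on {0, 1} makes the
  log win odds undefined; the Brunner-Munzel repeated p-value is used
  instead (on {0, 1} the BM variance is itself zero, so in practice the
  stage resolves as ``zero_variance``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.stats import rankdata

from .errors import InvalidInputError
from .sequential_design import (
    METHODS,
    SequentialDesign,
    boundaries,
    spending_value,
)
from .true_effects import DistributionModel, sample, true_information

__all__ = [
    "SimScenario",
    "SimResult",
    "simulate_stage_statistics",
    "run_scenario",
    "exception_policy",
    "scenario_grid",
    "repeated_ci_coverage",
    "bvn_cdf",
]

_TAU_FLOOR = 1e-10
_TAU_EPS = 1e-8
_CHUNK_ELEMS = 4_000_000  # target elements per (replicate x subject) block


# ---------------------------------------------------------------------------
# scenario containers
# ---------------------------------------------------------------------------

@dataclass
class SimScenario:
    """One simulation condition of the study grid."""

    model: DistributionModel
    NK: int
    allocation: str = "1:1"          # "1:1" or "2:1" (arm 1 gets the larger share)
    K: int = 2
    spending: str = "pocock"
    methods: tuple = METHODS
    replications: int = 100_000
    base_seed: int = 0
    alpha: float = 0.025
    scenario_index: int = 0
    stage_fractions: tuple | None = None

    @property
    def t(self) -> float:
        if self.allocation == "1:1":
            return 0.5
        if self.allocation == "2:1":
            return 2.0 / 3.0
        raise InvalidInputError(f"unknown allocation {self.allocation!r}")

    def stage_sizes(self) -> tuple[np.ndarray, np.ndarray]:
        """Cumulative per-arm sizes (n1k, n2k) at each analysis."""
        fr = (
            np.arange(1, self.K + 1) / self.K
            if self.stage_fractions is None
            else np.asarray(self.stage_fractions, dtype=float)
        )
        Nk = np.rint(fr * self.NK).astype(int)
        n1 = np.rint(self.t * Nk).astype(int)
        return n1, Nk - n1


@dataclass
class SimResult:
    """Rejection rates of one scenario, per test."""

    scenario: SimScenario
    overall: dict = field(default_factory=dict)          # method -> rate
    stage_cumulative: dict = field(default_factory=dict)  # method -> array of K rates
    se: dict = field(default_factory=dict)               # method -> Monte-Carlo SE
    exceptions: dict = field(default_factory=dict)       # method -> {event: count}
    replications: int = 0


# ---------------------------------------------------------------------------
# vectorized bivariate normal CDF (arcsine form)
# ---------------------------------------------------------------------------

_BVN_X, _BVN_W = np.polynomial.legendre.leggauss(48)


def bvn_cdf(h, k, rho):
    """``P(Z1 <= h, Z2 <= k)`` for standard bivariate normal, vectorized.

    Uses the single-integral arcsine representation
    ``Phi(h)Phi(k) + (1/2pi) int_0^{asin rho} exp(-(h^2+k^2-2hk sin u)
    / (2 cos^2 u)) du`` with fixed Gauss-Legendre nodes; absolute error
    below 1e-10 for ``|rho| <= 1 - 1e-9``.
    """
    h = np.asarray(h, float)
    k = np.asarray(k, float)
    rho = np.clip(np.asarray(rho, float), -1 + 1e-12, 1 - 1e-12)
    hb, kb, rb = np.broadcast_arrays(h, k, rho)
    up = np.arcsin(rb)
    theta = 0.5 * up[..., None] * (_BVN_X + 1.0)
    cos2 = np.cos(theta) ** 2
    hk = (hb * kb)[..., None]
    expo = -(hb[..., None] ** 2 + kb[..., None] ** 2 - 2.0 * hk * np.sin(theta)) / (2.0 * cos2)
    integral = 0.5 * up * np.sum(_BVN_W * np.exp(expo), axis=-1)
    out = stats.norm.cdf(hb) * stats.norm.cdf(kb) + integral / (2.0 * np.pi)
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# vectorized per-stage rank statistics
# ---------------------------------------------------------------------------

def _sample_block(model: DistributionModel, arm: int, reps: int, n: int,
                  rng: np.random.Generator) -> np.ndarray:
    return sample(model, arm, reps * n, rng).reshape(reps, n)


def _stage_stats_block(x1: np.ndarray, x2: np.ndarray) -> dict:
    """All per-replicate statistics of one analysis from raw data blocks."""
    n1, n2 = x1.shape[1], x2.shape[1]
    N = n1 + n2
    pooled = rankdata(np.concatenate([x1, x2], axis=1), method="average", axis=1)
    R1, R2 = pooled[:, :n1], pooled[:, n1:]
    m1 = R1.mean(axis=1)
    m2 = R2.mean(axis=1)
    p_hat = (m2 - m1) / N + 0.5

    centre = (N + 1) / 2
    sigmaR2 = (((R1 - centre) ** 2).sum(axis=1) + ((R2 - centre) ** 2).sum(axis=1)) / (N - 1)

    W1 = rankdata(x1, method="average", axis=1)
    W2 = rankdata(x2, method="average", axis=1)
    d1 = R1 - W1 - m1[:, None] + (n1 + 1) / 2
    d2 = R2 - W2 - m2[:, None] + (n2 + 1) / 2
    s1 = (d1 ** 2).sum(axis=1) / (n2 ** 2 * (n1 - 1))
    s2 = (d2 ** 2).sum(axis=1) / (n1 ** 2 * (n2 - 1))

    deg_wmw = sigmaR2 <= 0
    bm_denom = s1 / n1 + s2 / n2
    deg_bm = bm_denom <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        info_wmw = np.where(deg_wmw, np.nan, N * n1 * n2 / sigmaR2)
        info_bm = np.where(deg_bm, np.nan, 1.0 / bm_denom)
        df = np.where(
            deg_bm, np.nan,
            bm_denom ** 2 / (s1 ** 2 / (n1 ** 2 * (n1 - 1)) + s2 ** 2 / (n2 ** 2 * (n2 - 1))),
        )
        z_wmw = (p_hat - 0.5) * np.sqrt(info_wmw)
        z_bm = (p_hat - 0.5) * np.sqrt(info_bm)
        boundary = (p_hat <= 0.0) | (p_hat >= 1.0)
        pq = np.clip(p_hat, 1e-12, 1 - 1e-12)
        psi = np.log(pq / (1 - pq))
        info_lwo = np.where(boundary, np.nan, (pq * (1 - pq)) ** 2 * info_bm)
        z_lwo = np.where(boundary, np.nan, psi * np.sqrt(info_lwo))
    return dict(
        p_hat=p_hat, sigmaR2=sigmaR2, s1=s1, s2=s2, df=df,
        info_wmw=info_wmw, info_bm=info_bm, info_lwo=info_lwo,
        z_wmw=z_wmw, z_bm=z_bm, z_lwo=z_lwo,
        deg_wmw=deg_wmw, deg_bm=deg_bm, boundary=boundary,
    )


def simulate_stage_statistics(
    model: DistributionModel,
    n1_stages,
    n2_stages,
    reps: int,
    base_seed: int = 0,
    scenario_index: int = 0,
) -> dict:
    """Per-replicate, per-stage statistics of simulated trials.

    Each replicate draws its full-trial data once; the stage-``k``
    statistics use the first ``n1_stages[k]``/``n2_stages[k]``
    observations of each arm (cumulative reveal).  Returns a dict of
    ``(reps, K)`` arrays keyed like the output of the rank estimators.
    Seeding is counter-based: block ``b`` starting at replicate ``r``
    uses ``default_rng([base_seed, scenario_index, r])``.
    """
    n1s = np.asarray(n1_stages, int)
    n2s = np.asarray(n2_stages, int)
    K = n1s.size
    if np.any(n1s < 2) or np.any(n2s < 2):
        raise InvalidInputError("need at least two observations per arm per stage")
    chunk = max(1, _CHUNK_ELEMS // int(n1s[-1] + n2s[-1]))
    keys = ["p_hat", "sigmaR2", "s1", "s2", "df", "info_wmw", "info_bm", "info_lwo",
            "z_wmw", "z_bm", "z_lwo", "deg_wmw", "deg_bm", "boundary"]
    out = {key: np.empty((reps, K), dtype=bool if key.startswith(("deg", "bound")) else float)
           for key in keys}
    for start in range(0, reps, chunk):
        stop = min(start + chunk, reps)
        rng = np.random.default_rng([base_seed, scenario_index, start])
        x1 = _sample_block(model, 1, stop - start, int(n1s[-1]), rng)
        x2 = _sample_block(model, 2, stop - start, int(n2s[-1]), rng)
        for k in range(K):
            blk = _stage_stats_block(x1[:, : n1s[k]], x2[:, : n2s[k]])
            for key in keys:
                out[key][start:stop, k] = blk[key]
    return out


# ---------------------------------------------------------------------------
# exception policy
# ---------------------------------------------------------------------------

def exception_policy(event: str, state: dict) -> dict:
    """Default resolution of a finite-sample breakdown at one stage.

    ``state`` carries ``info_prev`` (frozen information of the previous
    stage, or None at the first) and for ``decreasing_information`` the
    raw estimate ``info_raw``.  Returns the resolved stage directives:
    ``info_for_spending``, ``rejectable`` and ``p_value_source``.
    """
    if event == "zero_variance":
        prev = state.get("info_prev")
        return {"info_for_spending": prev if prev is not None else 0.0,
                "rejectable": False, "p_value_source": None}
    if event == "decreasing_information":
        prev = state["info_prev"]
        return {"info_for_spending": prev * (1 + _TAU_EPS) + _TAU_EPS,
                "rejectable": True, "p_value_source": "own"}
    if event == "boundary_effect":
        return {"info_for_spending": state.get("info_prev") or 0.0,
                "rejectable": True, "p_value_source": "bm"}
    raise InvalidInputError(f"unknown exception event {event!r}")


# ---------------------------------------------------------------------------
# per-method decisions
# ---------------------------------------------------------------------------

def _method_arrays(st: dict, method: str):
    if method == "wmw":
        return st["info_wmw"], st["z_wmw"], st["deg_wmw"]
    if method in ("bm", "bm_t"):
        return st["info_bm"], st["z_bm"], st["deg_bm"]
    if method == "lwo":
        return st["info_lwo"], st["z_lwo"], st["deg_bm"] | st["boundary"]
    raise InvalidInputError(f"unknown method {method!r}")


def _apply_info_policy(info: np.ndarray, deg: np.ndarray, Imax: float):
    """Frozen, policy-clamped information fractions, plus event counts."""
    reps, K = info.shape
    tau = np.empty_like(info)
    events = {"zero_variance": 0, "decreasing_information": 0}
    tau_raw = info / Imax
    prev = np.full(reps, 0.0)
    for k in range(K):
        cur = np.where(deg[:, k], prev, tau_raw[:, k])
        events["zero_variance"] += int(deg[:, k].sum())
        cur = np.minimum(cur, 1.0)
        dec = (~deg[:, k]) & (cur <= prev) & (k > 0)
        events["decreasing_information"] += int(dec.sum())
        cur = np.where(cur <= prev, prev * (1 + _TAU_EPS) + _TAU_EPS, cur)
        tau[:, k] = np.maximum(cur, _TAU_FLOOR)
        prev = tau[:, k]
    return tau, events


def _t_reject(z, df, level):
    """Rejection of the BM t-approximation at nominal stage level."""
    with np.errstate(invalid="ignore"):
        pv = stats.t.sf(z, np.where(np.isnan(df), 1.0, df))
    return np.where(np.isnan(z) | np.isnan(df), False, pv <= level)


def _first_rejection_k2(st: dict, method: str, spending: str, alpha: float,
                        Imax: float) -> tuple[np.ndarray, dict]:
    """First-rejection stage (0 = none) for K in {1, 2}, fully vectorized."""
    info, z, deg = _method_arrays(st, method)
    reps, K = info.shape
    tau, events = _apply_info_policy(info, deg, Imax)
    if method == "lwo":
        events["boundary_effect"] = int(st["boundary"].sum())

    a1 = np.asarray(spending_value(spending, alpha, tau[:, 0]))
    if K == 1:
        a1 = np.full(reps, alpha)
    with np.errstate(invalid="ignore"):
        if method == "bm_t":
            rej1 = _t_reject(z[:, 0], st["df"][:, 0], a1)
        else:
            rej1 = np.where(np.isnan(z[:, 0]), False, stats.norm.sf(np.nan_to_num(z[:, 0])) <= a1)
    rej1 &= ~deg[:, 0]
    if K == 1:
        return np.where(rej1, 1, 0), events

    c1 = np.minimum(stats.norm.isf(np.maximum(a1, 1e-300)), 38.0)
    pi2 = np.maximum(alpha - a1, 0.0)
    rho = np.sqrt(tau[:, 0] / tau[:, 1])
    phi_c1 = stats.norm.cdf(c1)
    if method == "bm_t":
        # need the explicit critical value to map through the t quantile
        lo = np.full(reps, -2.0)
        hi = np.full(reps, 12.0)
        for _ in range(50):
            mid = 0.5 * (lo + hi)
            excess = phi_c1 - bvn_cdf(c1, mid, rho)
            hi = np.where(excess <= pi2, mid, hi)
            lo = np.where(excess > pi2, mid, lo)
        c2 = 0.5 * (lo + hi)
        c2 = np.where(pi2 <= 1e-15, np.inf, c2)
        a2 = stats.norm.sf(c2)
        rej2 = _t_reject(z[:, 1], st["df"][:, 1], a2)
    else:
        z2 = np.nan_to_num(z[:, 1], nan=-50.0)
        exceed = phi_c1 - bvn_cdf(c1, z2, rho)
        rej2 = (exceed <= pi2) & (pi2 > 1e-15)
    rej2 &= ~deg[:, 1] & ~np.isnan(z[:, 1])
    first = np.where(rej1, 1, np.where(rej2, 2, 0))
    return first, events


def _first_rejection_loop(st: dict, method: str, spending: str, alpha: float,
                          Imax: float) -> tuple[np.ndarray, dict]:
    """Per-replicate fallback for K >= 3 (scalar boundary machinery)."""
    info, z, deg = _method_arrays(st, method)
    reps, K = info.shape
    tau, events = _apply_info_policy(info, deg, Imax)
    if method == "lwo":
        events["boundary_effect"] = int(st["boundary"].sum())
    design = SequentialDesign(K=K, alpha=alpha, spending=spending, Imax=1.0)
    first = np.zeros(reps, dtype=int)
    for r in range(reps):
        bset = boundaries(design, tau[r])
        for k in range(K):
            if deg[r, k] or np.isnan(z[r, k]):
                continue
            if method == "bm_t":
                pv = stats.t.sf(z[r, k], st["df"][r, k])
            else:
                pv = stats.norm.sf(z[r, k])
            if pv <= bset.stage_levels[k]:
                first[r] = k + 1
                break
    return first, events


# ---------------------------------------------------------------------------
# the engine
# ---------------------------------------------------------------------------

def run_scenario(scn: SimScenario) -> SimResult:
    """Simulate one scenario and return rejection rates per test.

    Deterministic given ``base_seed`` and ``scenario_index``; all
    requested methods are evaluated on the same replicate data; Imax is
    the true information at the maximum sample size computed from the
    known generating model.
    """
    n1s, n2s = scn.stage_sizes()
    st = simulate_stage_statistics(
        scn.model, n1s, n2s, scn.replications, scn.base_seed, scn.scenario_index
    )
    imax = {
        m: true_information(scn.model, m, int(n1s[-1]), int(n2s[-1])) for m in set(scn.methods)
    }
    result = SimResult(scenario=scn, replications=scn.replications)
    solver = _first_rejection_k2 if scn.K <= 2 else _first_rejection_loop
    for method in scn.methods:
        first, events = solver(st, method, scn.spending, scn.alpha, imax[method])
        cum = np.array([np.mean((first > 0) & (first <= k + 1)) for k in range(scn.K)])
        rate = float(cum[-1])
        result.overall[method] = rate
        result.stage_cumulative[method] = cum
        result.se[method] = float(np.sqrt(rate * (1 - rate) / scn.replications))
        result.exceptions[method] = events
    return result


def scenario_grid(config: dict) -> list[SimScenario]:
    """Cartesian expansion of a scenario configuration.

    ``config`` holds the model plus lists under ``NK``, ``allocation``,
    ``K`` and ``spending`` (the study grid: 5 x 2 x 3 x 2 = 60 scenarios
    per distribution setting), with optional ``methods``,
    ``replications``, ``alpha`` and ``base_seed``.  Per-scenario seeds
    derive from the base seed and the scenario index.
    """
    model = config["model"]
    dims = [config[key] for key in ("NK", "allocation", "K", "spending")]
    if any(len(d) == 0 for d in dims):
        raise InvalidInputError("every grid dimension must be nonempty")
    scenarios = []
    for idx, (NK, alloc, K, spend) in enumerate(itertools.product(*dims)):
        scenarios.append(
            SimScenario(
                model=model, NK=int(NK), allocation=alloc, K=int(K), spending=spend,
                methods=tuple(config.get("methods", METHODS)),
                replications=int(config.get("replications", 100_000)),
                base_seed=int(config.get("base_seed", 0)),
                alpha=float(config.get("alpha", 0.025)),
                scenario_index=idx,
            )
        )
    return scenarios


# ---------------------------------------------------------------------------
# repeated-CI coverage (two-stage designs)
# ---------------------------------------------------------------------------

def repeated_ci_coverage(
    model: DistributionModel,
    true_p: float,
    NK: int,
    t: float = 0.5,
    spending: str = "obrien_fleming",
    alpha: float = 0.025,
    reps: int = 10_000,
    base_seed: int = 0,
    method: str = "bm_t",
) -> dict:
    """Simultaneous coverage of the two-stage repeated CI for ``p``.

    A trial is covered when the repeated interval contains the true
    relative effect at *every* stage.  The two-sided 95% intervals use
    the same per-tail critical values as the one-sided level-``alpha``
    test (see :func:`gsrank.sequential_design.repeated_ci`).
    """
    if method not in ("bm", "bm_t", "lwo"):
        raise InvalidInputError("coverage is defined for bm, bm_t, lwo")
    N1 = NK // 2
    n1s = np.array([round(t * N1), round(t * NK)], int)
    n2s = np.array([N1 - n1s[0], NK - n1s[1]], int)
    st = simulate_stage_statistics(model, n1s, n2s, reps, base_seed)
    imax = true_information(model, "bm" if method == "bm_t" else method,
                            int(n1s[-1]), int(n2s[-1]))
    info, _, deg = _method_arrays(st, "bm" if method == "bm_t" else method)
    tau, _ = _apply_info_policy(info, deg, imax)

    a1 = np.asarray(spending_value(spending, alpha, tau[:, 0]))
    c1 = np.minimum(stats.norm.isf(np.maximum(a1, 1e-300)), 38.0)
    pi2 = np.maximum(alpha - a1, 0.0)
    rho = np.sqrt(tau[:, 0] / tau[:, 1])
    phi_c1 = stats.norm.cdf(c1)
    lo = np.full(reps, -2.0)
    hi = np.full(reps, 12.0)
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        excess = phi_c1 - bvn_cdf(c1, mid, rho)
        hi = np.where(excess <= pi2, mid, hi)
        lo = np.where(excess > pi2, mid, lo)
    c2 = np.where(pi2 <= 1e-15, np.inf, 0.5 * (lo + hi))

    covered = np.ones(reps, dtype=bool)
    for k, ck in enumerate((c1, c2)):
        if method in ("bm", "bm_t"):
            mult = ck
            if method == "bm_t":
                mult = stats.t.ppf(stats.norm.cdf(ck), st["df"][:, k])
            half = mult / np.sqrt(st["info_bm"][:, k])
            lo_k = st["p_hat"][:, k] - half
            hi_k = st["p_hat"][:, k] + half
        else:
            pq = np.clip(st["p_hat"][:, k], 1e-12, 1 - 1e-12)
            psi = np.log(pq / (1 - pq))
            half = ck / np.sqrt(st["info_lwo"][:, k])
            lo_k = 1 / (1 + np.exp(-(psi - half)))
            hi_k = 1 / (1 + np.exp(-(psi + half)))
        covered &= (np.clip(lo_k, 0, 1) <= true_p) & (true_p <= np.clip(hi_k, 0, 1))
    cov = float(np.mean(covered))
    return {"coverage": cov, "se": float(np.sqrt(cov * (1 - cov) / reps)), "reps": reps}
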