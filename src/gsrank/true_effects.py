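"""Analytic two-arm distribution models and their true effect quantities.

Planning the group sequential rank tests requires the population values
of everything the estimators in :mod:`gsrank.rank_core` target:

* the relative effect ``p = int F1 dF2`` and log win odds ``psi``,
* the Brunner-Munzel variance components ``sigma1^2 = V{F2(X1)}`` and
  ``sigma2^2 = V{F1(X2)}`` (normalised CDFs),
* the pooled rank variance ``sigmaR^2(N, t)`` of the mixture
  ``F = t F1 + (1-t) F2`` that drives the WMW information,
* the per-method information at given arm sizes.

Three model families are supported: normal arms, ordinal 5-category arms
obtained by cutting a latent Beta variable at the 0.2 grid, and raw
category probability tables.  Discrete quantities are finite sums
(exact); the normal-model variance components use adaptive quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats

from .errors import InvalidInputError

__all__ = [
    "DistributionModel",
    "TrueEffectReport",
    "normal_model",
    "latent_beta_ordinal_model",
    "pmf_model",
    "ordinal_from_latent_beta",
    "true_relative_effect",
    "true_bm_variances",
    "true_wmw_variance",
    "true_information",
    "true_effect_report",
    "sample",
]

_QUAD_KW = dict(epsabs=1e-12, epsrel=1e-10, limit=200)


@dataclass
class DistributionModel:
    """Analytic specification of the two arms.

    ``family`` is one of ``normal`` (params: mu1, sd1, mu2, sd2),
    ``latent_beta_ordinal`` (params: a1, b1, a2, b2; categories coded
    1..5) or ``empirical_pmf`` (params: two pmf arrays over shared
    support values).
    """

    family: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in ("normal", "latent_beta_ordinal", "empirical_pmf"):
            raise InvalidInputError(f"unknown family {self.family!r}")
        if self.family == "normal":
            if self.params["sd1"] <= 0 or self.params["sd2"] <= 0:
                raise InvalidInputError("normal sds must be positive")
        elif self.family == "latent_beta_ordinal":
            for key in ("a1", "b1", "a2", "b2"):
                if self.params[key] <= 0:
                    raise InvalidInputError("Beta shape parameters must be positive")
        else:
            p1 = np.asarray(self.params["pmf1"], float)
            p2 = np.asarray(self.params["pmf2"], float)
            if p1.shape != p2.shape or p1.ndim != 1:
                raise InvalidInputError("pmf arrays must be 1-d and aligned")
            if np.any(p1 < 0) or np.any(p2 < 0):
                raise InvalidInputError("pmf entries must be nonnegative")
            if abs(p1.sum() - 1) > 1e-9 or abs(p2.sum() - 1) > 1e-9:
                raise InvalidInputError("pmf arrays must sum to 1")
            if np.max(p1) >= 1 - 1e-12 or np.max(p2) >= 1 - 1e-12:
                raise InvalidInputError("one-point distributions are excluded")

    # -- discrete helpers ---------------------------------------------------
    @property
    def is_discrete(self) -> bool:
        return self.family != "normal"

    def pmfs(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(support values, pmf arm 1, pmf arm 2) for discrete families."""
        if self.family == "latent_beta_ordinal":
            p1 = ordinal_from_latent_beta(self.params["a1"], self.params["b1"])
            p2 = ordinal_from_latent_beta(self.params["a2"], self.params["b2"])
            return np.arange(1.0, 6.0), p1, p2
        if self.family == "empirical_pmf":
            p1 = np.asarray(self.params["pmf1"], float)
            p2 = np.asarray(self.params["pmf2"], float)
            values = np.asarray(self.params.get("values", np.arange(1, p1.size + 1)), float)
            return values, p1, p2
        raise InvalidInputError("normal model has no pmf")


def normal_model(mu1: float, sd1: float, mu2: float, sd2: float) -> DistributionModel:
    return DistributionModel("normal", dict(mu1=mu1, sd1=sd1, mu2=mu2, sd2=sd2))


def latent_beta_ordinal_model(a1: float, b1: float, a2: float, b2: float) -> DistributionModel:
    return DistributionModel("latent_beta_ordinal", dict(a1=a1, b1=b1, a2=a2, b2=b2))


def pmf_model(pmf1, pmf2, values=None) -> DistributionModel:
    params = dict(pmf1=np.asarray(pmf1, float), pmf2=np.asarray(pmf2, float))
    if values is not None:
        params["values"] = np.asarray(values, float)
    return DistributionModel("empirical_pmf", params)


# ---------------------------------------------------------------------------
# latent Beta ordinal construction
# ---------------------------------------------------------------------------

def ordinal_from_latent_beta(alpha: float, beta: float) -> np.ndarray:
    """Category probabilities of a 5-level ordinal variable.

    A latent ``Beta(alpha, beta)`` variable is cut at the equidistant grid
    ``0.2 k``: ``P(C_k) = B(0.2 k) - B(0.2 (k-1))`` for ``k = 1..5``.
    """
    if alpha <= 0 or beta <= 0:
        raise InvalidInputError("Beta shape parameters must be positive")
    grid = 0.2 * np.arange(6)
    return np.diff(stats.beta.cdf(grid, alpha, beta))


def _normalised_cdf(pmf: np.ndarray) -> np.ndarray:
    """Normalised CDF ``F = (F- + F+)/2`` at the support atoms."""
    return np.cumsum(pmf) - pmf / 2


# ---------------------------------------------------------------------------
# true effect quantities
# ---------------------------------------------------------------------------

def true_relative_effect(model: DistributionModel) -> float:
    """True ``p = P(X1 < X2) + 1/2 P(X1 = X2) = int F1 dF2``.

    Exact finite sum for discrete models;
    ``Phi((mu2 - mu1)/sqrt(sd1^2 + sd2^2))`` for normal arms.
    """
    if model.family == "normal":
        pr = model.params
        return float(
            stats.norm.cdf((pr["mu2"] - pr["mu1"]) / np.hypot(pr["sd1"], pr["sd2"]))
        )
    _, p1, p2 = model.pmfs()
    p = float(np.sum(p2 * _normalised_cdf(p1)))
    if not 0.0 < p < 1.0:
        raise InvalidInputError("degenerate model: relative effect on the boundary")
    return p


def true_bm_variances(model: DistributionModel) -> tuple[float, float]:
    """True Brunner-Munzel components ``(V{F2(X1)}, V{F1(X2)})``.

    Both lie in [0, 1/4]; both equal 1/12 when the arms share one
    continuous distribution; both vanish under complete separation.
    """
    p = true_relative_effect(model)
    if model.is_discrete:
        _, p1, p2 = model.pmfs()
        F1, F2 = _normalised_cdf(p1), _normalised_cdf(p2)
        s1 = float(np.sum(p1 * F2 ** 2) - (1 - p) ** 2)
        s2 = float(np.sum(p2 * F1 ** 2) - p ** 2)
        return max(s1, 0.0), max(s2, 0.0)
    pr = model.params
    d1 = stats.norm(pr["mu1"], pr["sd1"])
    d2 = stats.norm(pr["mu2"], pr["sd2"])

    def second_moment(da, db):
        # E{ Fb(Xa)^2 } by quadrature over the standardized variable
        f = lambda z: db.cdf(da.ppf(stats.norm.cdf(z))) ** 2 * stats.norm.pdf(z)
        val, _ = integrate.quad(f, -10, 10, **_QUAD_KW)
        return val

    s1 = second_moment(d1, d2) - (1 - p) ** 2
    s2 = second_moment(d2, d1) - p ** 2
    return max(float(s1), 0.0), max(float(s2), 0.0)


def true_wmw_variance(model: DistributionModel, t: float, N: int) -> float:
    """Population pooled-rank variance of the mixture ``F = t F1 + (1-t) F2``.

    ``sigmaR^2 = N{(N-2) int F^2 dF - (N-3)/4} - (N/4) int (F+ - F-) dF``
    with ``F`` the normalised mixture CDF; reduces to ``N(N+1)/12`` for
    continuous mixtures.
    """
    if not 0.0 < t < 1.0:
        raise InvalidInputError("allocation t must lie strictly between 0 and 1")
    if N < 2:
        raise InvalidInputError("N must be at least 2")
    if model.is_discrete:
        _, p1, p2 = model.pmfs()
        m = t * p1 + (1 - t) * p2
        Fm = _normalised_cdf(m)
        int_F2_dF = float(np.sum(m * Fm ** 2))
        jump = float(np.sum(m ** 2))  # int (F+ - F-) dF = sum of squared atom masses
        return N * ((N - 2) * int_F2_dF - (N - 3) / 4) - N / 4 * jump
    # continuous mixture: int F^2 dF = 1/3 and no atoms
    return N * (N + 1) / 12.0


def true_information(model: DistributionModel, method: str, n1: int, n2: int) -> float:
    """True information of one analysis with cumulative arm sizes (n1, n2).

    WMW: ``N n1 n2 / sigmaR^2(N, t)`` with ``t = n1/N``;
    BM: ``(sigma1^2/n1 + sigma2^2/n2)^-1``;
    LWO: ``{p(1-p)}^2`` times the BM information.
    """
    if n1 < 1 or n2 < 1:
        raise InvalidInputError("arm sizes must be positive")
    if method == "wmw":
        N = n1 + n2
        return N * n1 * n2 / true_wmw_variance(model, n1 / N, N)
    if method in ("bm", "bm_t"):
        s1, s2 = true_bm_variances(model)
        denom = s1 / n1 + s2 / n2
        if denom <= 0:
            raise InvalidInputError("degenerate model: zero Brunner-Munzel variance")
        return 1.0 / denom
    if method == "lwo":
        p = true_relative_effect(model)
        return (p * (1 - p)) ** 2 * true_information(model, "bm", n1, n2)
    raise InvalidInputError(f"unknown method {method!r}")


@dataclass
class TrueEffectReport:
    """Bundle of all population quantities of a model at allocation t."""

    p: float
    psi: float
    sigma1sq: float
    sigma2sq: float
    t: float

    def sigmaR2(self, N: int) -> float:
        return true_wmw_variance(self._model, self.t, N)

    _model: DistributionModel = None  # type: ignore[assignment]


def true_effect_report(model: DistributionModel, t: float = 0.5) -> TrueEffectReport:
    p = true_relative_effect(model)
    s1, s2 = true_bm_variances(model)
    rep = TrueEffectReport(p=p, psi=float(np.log(p / (1 - p))), sigma1sq=s1, sigma2sq=s2, t=t)
    rep._model = model
    return rep


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample(model: DistributionModel, arm: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` iid observations for one arm (1 or 2).

    Ordinal draws come from binning latent Beta variables at the 0.2 grid
    and take integer codes 1..5.
    """
    if arm not in (1, 2):
        raise InvalidInputError("arm must be 1 or 2")
    if n < 0:
        raise InvalidInputError("n must be nonnegative")
    if n == 0:
        return np.empty(0)
    pr = model.params
    if model.family == "normal":
        mu, sd = (pr["mu1"], pr["sd1"]) if arm == 1 else (pr["mu2"], pr["sd2"])
        return rng.normal(mu, sd, size=n)
    if model.family == "latent_beta_ordinal":
        a, b = (pr["a1"], pr["b1"]) if arm == 1 else (pr["a2"], pr["b2"])
        latent = rng.beta(a, b, size=n)
        return np.minimum(np.floor(latent / 0.2).astype(int) + 1, 5).astype(float)
    values, p1, p2 = model.pmfs()
    return rng.choice(values, size=n, p=p1 if arm == 1 else p2)
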