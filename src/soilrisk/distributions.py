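"""Parametric distribution fitting and the exposure-factor distributions
used by the probabilistic assessment.

Concentration data are positively skewed, so the candidate families for
fitting are lognormal, gamma and Weibull, each fitted by maximum
likelihood with the location pinned at zero. Candidates are ranked by the
Anderson–Darling statistic, which weights the tails — the part of the
distribution that drives risk.

Two exposure factors get purpose-built constructors: the population soil
ingestion rate (lognormal with median 50 mg/day and 95th percentile
200 mg/day) and the body weight of the Turkish population (a beta
distribution scaled to [0, 111.15] kg with shape parameters
α = 12.76, β = 8.15).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors, normal_ad

from soilrisk.errors import DomainError, FittingError

logger = logging.getLogger(__name__)

POSITIVE_FAMILIES = frozenset({"lognormal", "gamma", "weibull"})
FAMILIES = frozenset(
    {"lognormal", "gamma", "weibull", "beta_scaled", "normal", "point"}
)
DEFAULT_CANDIDATES = frozenset({"lognormal", "gamma", "weibull"})


@dataclass(frozen=True)
class FittedDistribution:
    """A named parametric family with parameters and a sampling contract.

    Attributes
    ----------
    family : str
        One of ``lognormal`` (params ``mu``, ``sigma`` of log-values),
        ``gamma`` (``shape``, ``scale``), ``weibull`` (``shape``,
        ``scale``), ``beta_scaled`` (``alpha``, ``beta``, ``min``,
        ``max``), ``normal`` (``loc``, ``scale``) or ``point``
        (``value``, a degenerate constant).
    params : dict
        Family-specific parameters as above.
    gof : tuple (statistic family, value) or None
        Goodness-of-fit record, e.g. ``("AD", 0.31)``.
    support : (low, high)
        Bounds every sample must respect.
    """

    family: str
    params: dict = field(default_factory=dict)
    gof: tuple[str, float] | None = None
    support: tuple[float, float] = (0.0, math.inf)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise DomainError(f"unknown family {self.family!r}")
        p = self.params
        try:
            if self.family == "lognormal":
                assert p["sigma"] > 0
            elif self.family in ("gamma", "weibull"):
                assert p["shape"] > 0 and p["scale"] > 0
            elif self.family == "beta_scaled":
                assert p["alpha"] > 0 and p["beta"] > 0 and p["max"] > p["min"]
            elif self.family == "normal":
                assert p["scale"] > 0
            elif self.family == "point":
                assert math.isfinite(p["value"])
        except (KeyError, AssertionError) as exc:
            raise DomainError(
                f"invalid parameters for family {self.family!r}: {p}"
            ) from exc

    @property
    def frozen(self):
        """The scipy frozen distribution behind this object (None for point)."""
        p = self.params
        if self.family == "lognormal":
            return stats.lognorm(s=p["sigma"], scale=math.exp(p["mu"]))
        if self.family == "gamma":
            return stats.gamma(a=p["shape"], scale=p["scale"])
        if self.family == "weibull":
            return stats.weibull_min(c=p["shape"], scale=p["scale"])
        if self.family == "beta_scaled":
            return stats.beta(
                a=p["alpha"], b=p["beta"],
                loc=p["min"], scale=p["max"] - p["min"],
            )
        if self.family == "normal":
            return stats.norm(loc=p["loc"], scale=p["scale"])
        return None

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` values; every draw lies inside ``support``."""
        if self.family == "point":
            return np.full(n, self.params["value"], dtype=float)
        return np.asarray(self.frozen.rvs(size=n, random_state=rng), dtype=float)

    def mean(self) -> float:
        if self.family == "point":
            return float(self.params["value"])
        return float(self.frozen.mean())

    def median(self) -> float:
        if self.family == "point":
            return float(self.params["value"])
        return float(self.frozen.ppf(0.5))

    def ppf(self, q: float) -> float:
        if self.family == "point":
            return float(self.params["value"])
        return float(self.frozen.ppf(q))

    def to_dict(self) -> dict:
        """Serializable form (family + params + support + gof)."""
        return {
            "family": self.family,
            "params": dict(self.params),
            "support": list(self.support),
            "gof": list(self.gof) if self.gof else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedDistribution":
        gof = tuple(d["gof"]) if d.get("gof") else None
        return cls(
            family=d["family"],
            params=dict(d["params"]),
            gof=gof,
            support=tuple(d.get("support", (0.0, math.inf))),
        )


def point_mass(value: float) -> FittedDistribution:
    """Degenerate distribution concentrated at one value."""
    return FittedDistribution(
        family="point", params={"value": float(value)},
        support=(float(value), float(value)),
    )


def anderson_darling_statistic(values: np.ndarray, cdf) -> float:
    """Anderson–Darling statistic of a sample against a fitted CDF.

    A² = −n − (1/n) Σ (2i−1)[ln F(x₍ᵢ₎) + ln(1 − F(x₍ₙ₊₁₋ᵢ₎))]
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    u = np.clip(cdf(x), 1e-12, 1 - 1e-12)
    i = np.arange(1, n + 1)
    return float(-n - np.mean((2 * i - 1) * (np.log(u) + np.log1p(-u[::-1]))))


def _fit_family(family: str, x: np.ndarray) -> FittedDistribution:
    """MLE fit of one family with location pinned at zero."""
    if family == "lognormal":
        sigma, _, scale = stats.lognorm.fit(x, floc=0)
        params = {"mu": math.log(scale), "sigma": sigma}
    elif family == "gamma":
        shape, _, scale = stats.gamma.fit(x, floc=0)
        params = {"shape": shape, "scale": scale}
    elif family == "weibull":
        shape, _, scale = stats.weibull_min.fit(x, floc=0)
        params = {"shape": shape, "scale": scale}
    elif family == "normal":
        loc, scale = stats.norm.fit(x)
        return FittedDistribution(
            family="normal", params={"loc": loc, "scale": scale},
            support=(-math.inf, math.inf),
        )
    else:
        raise DomainError(f"family {family!r} is not fittable here")
    return FittedDistribution(family=family, params=params, support=(0.0, math.inf))


def fit_best(
    values: Iterable[float],
    candidates: Sequence[str] | frozenset = DEFAULT_CANDIDATES,
) -> FittedDistribution:
    """Fit candidate families by MLE and return the best by Anderson–Darling.

    Parameters
    ----------
    values : at least 10 finite reals
    candidates : subset of {lognormal, gamma, weibull, normal}
        Positive-support families are silently excluded (with a warning)
        when the data contain nonpositive values.

    Returns
    -------
    FittedDistribution
        The candidate with the smallest AD statistic; ``gof`` records
        ``("AD", value)``.

    Raises
    ------
    FittingError
        Fewer than 10 values, all-identical values, or no usable candidate.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 10:
        raise FittingError(f"need at least 10 values to fit, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise FittingError("values must be finite")
    if np.ptp(x) == 0:
        raise FittingError("degenerate data: all values identical")

    usable = set(candidates) & FAMILIES - {"beta_scaled", "point"}
    if not usable:
        raise DomainError(f"no fittable candidate among {set(candidates)}")
    if np.any(x <= 0):
        dropped = usable & POSITIVE_FAMILIES
        if dropped:
            logger.warning(
                "nonpositive values present; excluding %s from candidacy",
                sorted(dropped),
            )
        usable -= POSITIVE_FAMILIES
        if not usable:
            raise FittingError(
                "data contain nonpositive values and no unbounded candidate "
                "family was offered"
            )

    best: FittedDistribution | None = None
    best_ad = math.inf
    for family in sorted(usable):
        try:
            fitted = _fit_family(family, x)
        except Exception as exc:  # scipy MLE non-convergence
            logger.warning("MLE fit failed for %s: %s", family, exc)
            continue
        ad = anderson_darling_statistic(x, fitted.frozen.cdf)
        if ad < best_ad:
            best_ad = ad
            best = fitted
    if best is None:
        raise FittingError("every candidate fit failed")
    return FittedDistribution(
        family=best.family, params=best.params,
        gof=("AD", best_ad), support=best.support,
    )


def ingestion_rate_distribution(
    central: float = 50.0,
    upper: float = 200.0,
    upper_percentile: float = 0.95,
) -> FittedDistribution:
    """Lognormal soil ingestion-rate distribution from two quantiles.

    The population soil ingestion rate has central tendency (median)
    ``central`` mg/day and ``upper_percentile`` quantile ``upper`` mg/day,
    with minimum 0. Solving the lognormal quantile equations gives
    μ = ln(central) and σ = ln(upper/central) / z(upper_percentile).

    With the defaults (50, 200, 0.95): μ = 3.912, σ = 0.8428.
    """
    if not 0 < central < upper:
        raise DomainError(
            f"need 0 < central < upper, got central={central}, upper={upper}"
        )
    if not 0.5 < upper_percentile < 1:
        raise DomainError(
            f"upper_percentile must be in (0.5, 1), got {upper_percentile}"
        )
    z = stats.norm.ppf(upper_percentile)
    sigma = math.log(upper / central) / z
    return FittedDistribution(
        family="lognormal",
        params={"mu": math.log(central), "sigma": sigma},
        support=(0.0, math.inf),
    )


def body_weight_distribution(
    minimum: float = 0.0,
    maximum: float = 111.15,
    alpha: float = 12.76,
    beta: float = 8.15,
) -> FittedDistribution:
    """Scaled-beta body-weight distribution of the target population.

    Samples are ``min + (max − min)·B`` with ``B ~ Beta(alpha, beta)``;
    the analytic mean is ``min + (max − min)·α/(α+β)`` (≈ 67.8 kg with
    the default Turkish-population parameters).
    """
    if maximum <= minimum:
        raise DomainError(f"need max > min, got [{minimum}, {maximum}]")
    if alpha <= 0 or beta <= 0:
        raise DomainError(f"shape parameters must be > 0, got α={alpha}, β={beta}")
    return FittedDistribution(
        family="beta_scaled",
        params={"alpha": alpha, "beta": beta, "min": minimum, "max": maximum},
        support=(minimum, maximum),
    )


def normality_tests(values: Iterable[float], alpha: float = 0.05) -> dict:
    """Anderson–Darling and Kolmogorov–Smirnov (Lilliefors) normality tests.

    Both tests use the composite normal null with estimated mean and
    variance. Returns a dict with keys ``anderson_darling`` and
    ``kolmogorov_smirnov``, each holding ``statistic``, ``p_value`` and a
    ``reject`` flag at the given significance level.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 8:
        raise FittingError(f"need at least 8 values, got {x.size}")
    if np.ptp(x) == 0:
        raise FittingError("zero-variance data: normality tests undefined")
    ad_stat, ad_p = normal_ad(x)
    ks_stat, ks_p = lilliefors(x, dist="norm")
    return {
        "anderson_darling": {
            "statistic": float(ad_stat),
            "p_value": float(ad_p),
            "reject": bool(ad_p < alpha),
        },
        "kolmogorov_smirnov": {
            "statistic": float(ks_stat),
            "p_value": float(ks_p),
            "reject": bool(ks_p < alpha),
        },
    }
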