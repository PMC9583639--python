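"""Monte Carlo population risk and bootstrap uncertainty.

Each trial draws an independent triple (concentration C, ingestion rate
IR, body weight BW) from their distributions and pushes it through the
dose equations: the chronic toxic risk (CTR, a hazard quotient) divides
the average daily dose by the oral reference dose, the carcinogenic risk
(CR) multiplies the lifetime average daily dose by the oral slope factor.
Fixed factors follow the probabilistic design: EF 350 day/yr, ED 75 yr,
AT 27,375 days (75 × 365), CF 1e-6.

Bootstrap uncertainty re-runs the whole simulation (1000 trials, 200
repetitions by default) on independent substreams of one master seed and
reports the spread of the per-repetition mean and median — the sampling
noise of the Monte Carlo procedure itself, not population variability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from soilrisk.distributions import FittedDistribution
from soilrisk.errors import CapabilityError, DomainError, SoilRiskError
from soilrisk.exposure import (
    CRZone,
    HQZone,
    ToxicityParams,
    classify_cr,
    classify_hq,
)

_MAX_REDRAW_ROUNDS = 100


@dataclass(frozen=True)
class SimulationSpec:
    """Inputs of one Monte Carlo risk simulation.

    ``at_days`` is the averaging time in days (default 27,375 = 75 × 365);
    ``lt_years`` the lifetime used for the carcinogenic dose.
    """

    concentration_dist: FittedDistribution
    ir_dist: FittedDistribution
    bw_dist: FittedDistribution
    toxicity: ToxicityParams
    n_trials: int = 10_000
    ef: float = 350.0
    ed_years: float = 75.0
    at_days: float = 27_375.0
    lt_years: float = 75.0
    cf: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise DomainError("n_trials must be >= 1")
        for name in ("ef", "ed_years", "at_days", "lt_years", "cf"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0")


@dataclass(frozen=True)
class RiskSummary:
    """Summary statistics of a simulated risk distribution.

    ``p95`` is the upper-bound risk; ``cv`` is sd/mean of the trials.
    ``se`` holds per-statistic bootstrap standard errors when available.
    """

    mean: float
    median: float
    p25: float
    p75: float
    p95: float
    maximum: float
    cv: float
    n_trials: int
    se: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.p25 <= self.median <= self.p75 <= self.p95 <= self.maximum):
            raise DomainError("summary percentiles must be monotone")
        if self.cv < 0:
            raise DomainError("cv must be >= 0")


@dataclass(frozen=True)
class BootstrapResult:
    """Spread of one summary statistic across simulation repetitions."""

    statistic: str
    se: float
    iqr: float
    repetitions: int
    trials_per_repetition: int

    def __post_init__(self) -> None:
        if self.se < 0 or self.iqr < 0:
            raise DomainError("se and iqr must be >= 0")


def _draw(dist: FittedDistribution, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n finite in-support values, re-drawing rejects a bounded number
    of rounds; a shortened vector is never returned."""
    low, high = dist.support
    x = dist.sample(n, rng)
    for _ in range(_MAX_REDRAW_ROUNDS):
        bad = ~np.isfinite(x) | (x < low) | (x > high)
        if dist.family != "point":
            bad |= x <= 0  # zero BW or IR would make the dose blow up
        n_bad = int(bad.sum())
        if n_bad == 0:
            return x
        x[bad] = dist.sample(n_bad, rng)
    raise SoilRiskError(
        f"could not draw {n} valid samples from {dist.family} after "
        f"{_MAX_REDRAW_ROUNDS} redraw rounds"
    )


def _trial_doses(spec: SimulationSpec, rng: np.random.Generator,
                 risk_kind: str) -> np.ndarray:
    c = _draw(spec.concentration_dist, spec.n_trials, rng)
    ir = _draw(spec.ir_dist, spec.n_trials, rng)
    bw = _draw(spec.bw_dist, spec.n_trials, rng)
    numer = c * ir * spec.ef * spec.ed_years * spec.cf
    if risk_kind == "ctr":
        return numer / (bw * spec.at_days)
    return numer / (bw * spec.lt_years * 365.0)


def summarize_trials(trials: np.ndarray, se: dict | None = None) -> RiskSummary:
    """RiskSummary of a trial vector."""
    trials = np.asarray(trials, dtype=float)
    mean = float(trials.mean())
    p25, median, p75, p95 = (
        float(v) for v in np.percentile(trials, [25, 50, 75, 95])
    )
    sd = float(trials.std(ddof=1)) if trials.size > 1 else 0.0
    cv = sd / mean if mean > 0 else 0.0
    return RiskSummary(
        mean=mean, median=median, p25=p25, p75=p75, p95=p95,
        maximum=float(trials.max()), cv=cv, n_trials=int(trials.size),
        se=dict(se or {}),
    )


def simulate_risk(
    spec: SimulationSpec,
    risk_kind: str = "ctr",
    seed: int | np.random.SeedSequence | None = 0,
) -> tuple[np.ndarray, RiskSummary]:
    """Monte Carlo simulation of population risk.

    Parameters
    ----------
    spec : SimulationSpec
    risk_kind : {"ctr", "cr"}
        ``ctr`` needs an oral reference dose, ``cr`` an oral slope factor.
    seed : int or numpy SeedSequence
        Fully determines the output: identical (spec, seed) give identical
        trials.

    Returns
    -------
    (trials, summary)
        The raw trial vector (length ``spec.n_trials``) and its
        :class:`RiskSummary`.
    """
    if risk_kind not in ("ctr", "cr"):
        raise DomainError(f"risk_kind must be 'ctr' or 'cr', got {risk_kind!r}")
    tox = spec.toxicity
    if risk_kind == "ctr" and tox.rfd is None:
        raise CapabilityError(
            f"chronic risk needs an RfD for {tox.element_form}"
        )
    if risk_kind == "cr" and tox.sf is None:
        raise CapabilityError(
            f"carcinogenic risk needs a slope factor for {tox.element_form}"
        )
    rng = np.random.default_rng(seed)
    doses = _trial_doses(spec, rng, risk_kind)
    trials = doses / tox.rfd if risk_kind == "ctr" else doses * tox.sf
    return trials, summarize_trials(trials)


def bootstrap_uncertainty(
    spec: SimulationSpec,
    risk_kind: str = "ctr",
    repetitions: int = 200,
    trials_per_repetition: int = 1000,
    seed: int | np.random.SeedSequence | None = 0,
) -> dict[str, BootstrapResult]:
    """Uncertainty of Monte Carlo summaries by re-running the simulation.

    The simulation is repeated ``repetitions`` times with
    ``trials_per_repetition`` trials each, on independent substreams
    spawned from one master seed. Reported are the standard error and
    interquartile range, across repetitions, of the mean and of the
    median of the simulated risk.

    Returns
    -------
    dict with keys ``"mean"`` and ``"median"``, each a
    :class:`BootstrapResult`.
    """
    if repetitions < 2:
        raise DomainError("repetitions must be >= 2")
    base = (
        seed if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    rep_spec = SimulationSpec(
        concentration_dist=spec.concentration_dist,
        ir_dist=spec.ir_dist,
        bw_dist=spec.bw_dist,
        toxicity=spec.toxicity,
        n_trials=trials_per_repetition,
        ef=spec.ef,
        ed_years=spec.ed_years,
        at_days=spec.at_days,
        lt_years=spec.lt_years,
        cf=spec.cf,
    )
    means = np.empty(repetitions)
    medians = np.empty(repetitions)
    for i, child in enumerate(base.spawn(repetitions)):
        trials, _ = simulate_risk(rep_spec, risk_kind, seed=child)
        means[i] = trials.mean()
        medians[i] = np.median(trials)

    def _result(label: str, values: np.ndarray) -> BootstrapResult:
        if np.ptp(values) == 0:
            # identical repetition statistics: spread is exactly zero
            # (np.std would report the rounding noise of its internal mean)
            se = iqr = 0.0
        else:
            q75, q25 = np.percentile(values, [75, 25])
            se = float(values.std(ddof=1))
            iqr = float(q75 - q25)
        return BootstrapResult(
            statistic=label,
            se=se,
            iqr=iqr,
            repetitions=repetitions,
            trials_per_repetition=trials_per_repetition,
        )

    return {"mean": _result("mean", means), "median": _result("median", medians)}


def upper_bound(
    summary: RiskSummary, risk_kind: str = "cr"
) -> tuple[float, CRZone | HQZone]:
    """The 95th-percentile (upper-bound) risk with its zone label."""
    if risk_kind == "cr":
        return summary.p95, classify_cr(summary.p95)
    if risk_kind == "ctr":
        return summary.p95, classify_hq(summary.p95)
    raise DomainError(f"risk_kind must be 'ctr' or 'cr', got {risk_kind!r}")
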