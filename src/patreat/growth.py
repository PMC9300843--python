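"""Gompertz tumor-growth modeling and derived kinetic features.

The volume trajectory of each animal is fit with the Gompertz law

    V(t) = alpha * exp[(beta/kappa) * (1 - e^(-kappa t))]

where ``alpha`` (mm^3) is the volume at implantation time t=0, ``beta``
(day^-1) the initial specific growth rate V'(0)/V(0), and ``kappa``
(day^-1) the exponential decay rate of the specific growth rate; the
curve is non-decreasing and plateaus at ``alpha * e^(beta/kappa)``.

From a converged fit the module derives the kinetic features used for
treatment-response analysis: areas under the fitted volume-time curve
over the pretreatment / on-treatment / posttreatment windows, the days
at which the fitted volume reaches 2x / 5x / 10x its pretreatment
reference, and Kaplan-Meier survival summaries of size-limit events.

The modeling interface follows the Model/Results convention:
``GompertzModel(days, volumes).fit()`` returns a
:class:`GompertzResults` carrying estimates, covariance, diagnostics and
a ``summary()`` table, with prediction, quadrature and fold-time methods
hanging off the results object.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize

from lifelines import KaplanMeierFitter

from .errors import InsufficientDataError, NumericDomainError, ValidationError
from .synth import gompertz_volume

__all__ = [
    "TumorTimeSeries",
    "GompertzModel",
    "GompertzResults",
    "GrowthMetrics",
    "fit_gompertz",
    "gompertz_value",
    "interval_auc",
    "fold_time",
    "growth_metrics",
    "fit_cohort",
    "km_estimate",
    "KMEstimate",
    "AUC_PRESETS",
]

#: AUC window presets (days): pretreatment / on-treatment / posttreatment.
#: "standard" (default) splits at the dosing start (D11) and dosing end
#: (D26); "alternate" splits at D10 and D21.
AUC_PRESETS: dict[str, dict[str, tuple[float, float]]] = {
    "standard": {"early": (5.0, 10.0), "treat": (11.0, 26.0), "late": (26.0, 40.0)},
    "alternate": {"early": (5.0, 10.0), "treat": (10.0, 21.0), "late": (21.0, 40.0)},
}


@dataclass(frozen=True)
class TumorTimeSeries:
    """One animal's longitudinal volume record."""

    animal_id: str
    days: tuple[float, ...]
    volumes: tuple[float, ...]
    group: int = 0

    def __post_init__(self) -> None:
        d = np.asarray(self.days, dtype=float)
        v = np.asarray(self.volumes, dtype=float)
        if d.shape != v.shape:
            raise ValidationError("days and volumes must have equal length")
        if not np.all(np.diff(d) > 0):
            raise ValidationError("days must be strictly increasing")
        if np.any(v < 0):
            raise ValidationError("volumes must be >= 0")


class GompertzModel:
    """Nonlinear least-squares Gompertz model for one volume trajectory.

    Parameters
    ----------
    days, volumes : array-like
        Observation times (days post-implantation) and volumes (mm^3);
        at least 4 points, not all volumes equal.
    log_residuals : bool
        Fit in log-volume space (multiplicative error model) instead of
        untransformed volumes.
    """

    def __init__(self, days, volumes, log_residuals: bool = False):
        self.days = np.asarray(days, dtype=float)
        self.volumes = np.asarray(volumes, dtype=float)
        self.log_residuals = bool(log_residuals)
        if self.days.shape != self.volumes.shape or self.days.ndim != 1:
            raise ValidationError("days and volumes must be equal-length 1D arrays")
        if self.days.size < 4:
            raise InsufficientDataError("Gompertz fit needs >= 4 (day, volume) points")
        if not np.all(np.diff(self.days) > 0):
            raise ValidationError("days must be strictly increasing")
        if np.ptp(self.volumes) == 0:
            raise InsufficientDataError(
                "volumes are constant; the growth rate is unidentifiable"
            )
        if self.log_residuals and np.any(self.volumes <= 0):
            raise ValidationError("log-residual fitting requires positive volumes")

    @classmethod
    def from_series(cls, series: TumorTimeSeries, **kwargs) -> "GompertzModel":
        return cls(series.days, series.volumes, **kwargs)

    def default_init(self) -> tuple[float, float, float]:
        """alpha0 = first volume; beta0 = log-slope of the first two points;
        kappa0 = 0.05 / day."""
        v = np.maximum(self.volumes, 1e-6)
        alpha0 = float(v[0])
        dt = self.days[1] - self.days[0]
        beta0 = float(np.log(v[1] / v[0]) / dt)
        if not np.isfinite(beta0) or beta0 <= 0:
            beta0 = 0.1
        return alpha0, beta0, 0.05

    def fit(
        self,
        init: tuple[float, float, float] | None = None,
        bounds: tuple | None = None,
        tol: float = 1e-12,
        n_starts: int = 3,
    ) -> "GompertzResults":
        """Fit (alpha, beta, kappa) with positivity bounds.

        On non-convergence, up to ``n_starts`` perturbed restarts are
        tried; a still-failing fit is returned with ``converged=False``
        and NaN parameters (never a silent bad fit).
        """
        if bounds is None:
            bounds = ([1e-9, 1e-9, 1e-9], [np.inf, np.inf, np.inf])
        p0 = np.asarray(init if init is not None else self.default_init(), dtype=float)
        p0 = np.clip(p0, bounds[0], bounds[1])

        y = np.log(self.volumes) if self.log_residuals else self.volumes

        def f(t, a, b, k):
            v = gompertz_volume(t, a, b, k)
            return np.log(v) if self.log_residuals else v

        rng = np.random.default_rng(0)
        last_err: Exception | None = None
        for attempt in range(max(1, n_starts)):
            start = p0 if attempt == 0 else p0 * rng.lognormal(0.0, 0.5, size=3)
            start = np.clip(start, bounds[0], bounds[1])
            try:
                popt, pcov = optimize.curve_fit(
                    f,
                    self.days,
                    y,
                    p0=start,
                    bounds=bounds,
                    xtol=tol,
                    ftol=tol,
                    maxfev=20000,
                )
            except (RuntimeError, optimize.OptimizeWarning, ValueError) as err:
                last_err = err
                continue
            resid = self.volumes - gompertz_volume(self.days, *popt)
            return GompertzResults(
                model=self,
                alpha=float(popt[0]),
                beta=float(popt[1]),
                kappa=float(popt[2]),
                sse=float(resid @ resid),
                converged=True,
                cov=pcov,
                n_starts_used=attempt + 1,
            )
        return GompertzResults(
            model=self,
            alpha=float("nan"),
            beta=float("nan"),
            kappa=float("nan"),
            sse=float("nan"),
            converged=False,
            cov=np.full((3, 3), np.nan),
            n_starts_used=max(1, n_starts),
            failure=str(last_err),
        )


@dataclass
class GompertzResults:
    """Fitted Gompertz parameters with diagnostics.

    ``fold_time`` returns ``math.inf`` when the target volume lies beyond
    the fitted plateau (a censored, not erroneous, outcome).
    """

    model: GompertzModel
    alpha: float
    beta: float
    kappa: float
    sse: float
    converged: bool
    cov: np.ndarray
    n_starts_used: int = 1
    failure: str | None = field(default=None)

    @property
    def params(self) -> tuple[float, float, float]:
        return self.alpha, self.beta, self.kappa

    @property
    def plateau(self) -> float:
        """Asymptotic volume alpha * e^(beta/kappa), mm^3 (inf on overflow)."""
        try:
            return self.alpha * math.exp(self.beta / self.kappa)
        except OverflowError:
            return math.inf

    def predict(self, t) -> np.ndarray:
        """Fitted V(t) in mm^3 for t >= 0 days."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise NumericDomainError("t must be >= 0")
        return gompertz_volume(t, *self.params)

    def interval_auc(self, interval: tuple[float, float], tol: float = 1e-9) -> float:
        """Area under the fitted curve over [a, b], mm^3 * day."""
        a, b = float(interval[0]), float(interval[1])
        if a < 0 or a >= b:
            raise ValidationError("interval must satisfy 0 <= a < b")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", integrate.IntegrationWarning)
            val, _ = integrate.quad(
                lambda t: gompertz_volume(t, *self.params), a, b,
                epsabs=tol, epsrel=tol, limit=200,
            )
        return float(val)

    def fold_time(self, factor: float, reference_day: float = 5.0) -> float:
        """Smallest t >= reference_day with V(t) = factor * V(reference_day).

        Found by root bracketing on the monotone fitted curve; returns
        ``math.inf`` (censored) when the target exceeds the plateau.
        """
        if factor <= 1:
            raise ValidationError("factor must be > 1")
        if reference_day < 0:
            raise ValidationError("reference_day must be >= 0")
        target = factor * float(self.predict(reference_day))
        if target >= self.plateau:
            return math.inf

        def g(t):
            return gompertz_volume(t, *self.params) - target

        hi = reference_day + 1.0
        while g(hi) < 0:
            hi = reference_day + 2 * (hi - reference_day)
            if hi - reference_day > 1e6:  # pragma: no cover - plateau guard above
                return math.inf
        return float(optimize.brentq(g, reference_day, hi, xtol=1e-10, rtol=1e-12))

    def summary(self) -> str:
        se = np.sqrt(np.diag(self.cov))
        lines = [
            "Gompertz growth fit",
            "=" * 46,
            f"{'n obs':<22}{self.model.days.size:>10d}",
            f"{'converged':<22}{str(self.converged):>10}",
            f"{'residual SSE':<22}{self.sse:>10.4g}",
            f"{'plateau (mm^3)':<22}"
            f"{self.plateau if self.converged else float('nan'):>10.4g}",
            "-" * 46,
            f"{'param':<10}{'estimate':>12}{'std err':>12}",
            f"{'alpha':<10}{self.alpha:>12.5g}{se[0]:>12.3g}",
            f"{'beta':<10}{self.beta:>12.5g}{se[1]:>12.3g}",
            f"{'kappa':<10}{self.kappa:>12.5g}{se[2]:>12.3g}",
            "=" * 46,
        ]
        return "\n".join(lines)


# --------------------------------------------------------------------------
# functional wrappers (one call per pipeline operation)


def fit_gompertz(
    series: TumorTimeSeries, init=None, bounds=None, tol: float = 1e-12, **kwargs
) -> GompertzResults:
    """Fit the Gompertz model to one animal's time series."""
    return GompertzModel.from_series(series, **kwargs).fit(
        init=init, bounds=bounds, tol=tol
    )


def gompertz_value(fit: GompertzResults, t) -> np.ndarray:
    return fit.predict(t)


def interval_auc(fit: GompertzResults, interval) -> float:
    return fit.interval_auc(interval)


def fold_time(fit: GompertzResults, factor, reference_day: float = 5.0) -> float:
    return fit.fold_time(factor, reference_day)


@dataclass(frozen=True)
class GrowthMetrics:
    """Kinetic features of one fitted trajectory."""

    auc_early: float
    auc_treat: float
    auc_late: float
    t2x: float
    t5x: float
    t10x: float
    intervals: dict[str, tuple[float, float]]
    reference_day: float


def growth_metrics(
    fit: GompertzResults, preset: str = "standard", reference_day: float = 5.0
) -> GrowthMetrics:
    """Interval AUCs and fold-times from one converged fit.

    ``preset`` selects the AUC window delimitation ("standard" or "alternate");
    fold-times are referenced to the pretreatment volume on
    ``reference_day``.
    """
    if preset not in AUC_PRESETS:
        raise ValidationError(f"preset must be one of {sorted(AUC_PRESETS)}")
    iv = AUC_PRESETS[preset]
    return GrowthMetrics(
        auc_early=fit.interval_auc(iv["early"]),
        auc_treat=fit.interval_auc(iv["treat"]),
        auc_late=fit.interval_auc(iv["late"]),
        t2x=fit.fold_time(2, reference_day),
        t5x=fit.fold_time(5, reference_day),
        t10x=fit.fold_time(10, reference_day),
        intervals=dict(iv),
        reference_day=reference_day,
    )


def fit_cohort(
    table: pd.DataFrame, preset: str = "standard", reference_day: float = 5.0, **fit_kwargs
) -> pd.DataFrame:
    """Per-animal Gompertz fits and growth metrics for a tidy cohort table.

    Expects columns ``animal_id``, ``group``, ``day``, ``volume_mm3``.
    Returns one row per animal; animals whose fit fails are kept with
    ``converged=False`` and NaN features.
    """
    rows = []
    for aid, sub in table.groupby("animal_id", sort=True):
        sub = sub.sort_values("day")
        series = TumorTimeSeries(
            animal_id=str(aid),
            days=tuple(sub["day"]),
            volumes=tuple(sub["volume_mm3"]),
            group=int(sub["group"].iloc[0]),
        )
        try:
            res = fit_gompertz(series, **fit_kwargs)
        except (InsufficientDataError, ValidationError):
            res = None
        row = dict(animal_id=str(aid), group=series.group)
        if res is not None and res.converged:
            gm = growth_metrics(res, preset=preset, reference_day=reference_day)
            row.update(
                alpha=res.alpha, beta=res.beta, kappa=res.kappa, sse=res.sse,
                converged=True, auc_early=gm.auc_early, auc_treat=gm.auc_treat,
                auc_late=gm.auc_late, t2x=gm.t2x, t5x=gm.t5x, t10x=gm.t10x,
            )
        else:
            row.update(
                alpha=np.nan, beta=np.nan, kappa=np.nan, sse=np.nan,
                converged=False, auc_early=np.nan, auc_treat=np.nan,
                auc_late=np.nan, t2x=np.nan, t5x=np.nan, t10x=np.nan,
            )
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# survival


@dataclass
class KMEstimate:
    """Kaplan-Meier product-limit estimate of one group's survival."""

    timeline: np.ndarray
    survival: np.ndarray
    median_days: float
    n: int

    @property
    def median_defined(self) -> bool:
        return math.isfinite(self.median_days)


def km_estimate(events: Sequence[tuple[float, bool]] | pd.DataFrame) -> KMEstimate:
    """Product-limit survival curve and median survival.

    Parameters
    ----------
    events : sequence of (event_day, censored) or DataFrame
        One entry per animal; ``censored`` True means the animal left the
        study without the event.  A DataFrame must have columns
        ``event_day`` and ``censored``.

    Notes
    -----
    The median is the first day at which the estimated survival drops to
    <= 0.5 (the conventional definition); it is ``inf`` (flagged via
    ``median_defined``) when the curve never reaches 0.5, e.g. when all
    animals are censored.
    """
    if isinstance(events, pd.DataFrame):
        durations = events["event_day"].to_numpy(dtype=float)
        censored = events["censored"].to_numpy(dtype=bool)
    else:
        durations = np.asarray([e[0] for e in events], dtype=float)
        censored = np.asarray([bool(e[1]) for e in events])
    if durations.size == 0:
        raise InsufficientDataError("need >= 1 animal for a survival estimate")

    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=~censored)
    surv = kmf.survival_function_["KM_estimate"]
    return KMEstimate(
        timeline=surv.index.to_numpy(dtype=float),
        survival=surv.to_numpy(dtype=float),
        median_days=float(kmf.median_survival_time_),
        n=int(durations.size),
    )
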