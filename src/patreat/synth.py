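"""Synthetic data generation with known ground truth.

The animal and phantom data this pipeline is designed for are not
publicly deposited, so every input can be generated here instead:

* tube phantoms (oxygenated / deoxygenated hemoglobin at 5-18 mm depth
  in water or 0.5% intralipid),
* vascularized ellipsoidal tumor scenes at 8-10 mm depth,
* longitudinal two-group cohorts with Gompertz growth, a treated-group
  StO2 dip 24-72 h after the start of dosing with weekend recovery, and
  size-limit survival events,
* regression cohorts drawn from the three-predictor linear growth-rate
  model.

All generators consume a ``numpy`` integer seed and are bit-reproducible.
The forward model for scenes is

    a(lambda) = Gamma * Phi(lambda, z) * [eps_HbO2(lambda) * cHbO2
                                          + eps_Hb(lambda) * cHb] + noise

with Gamma a single proportionality constant folding the Grueneisen
parameter and system gain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .errors import GeometryError, ValidationError
from .extinction import ExtinctionTable, load_default_extinction
from .fluence import FluenceModel
from .volumes import PAVolumePair, depth_coordinates

__all__ = [
    "Scene",
    "PhantomSpec",
    "TumorSpec",
    "CohortSpec",
    "CohortTable",
    "simulate_phantom_scene",
    "simulate_tumor_scene",
    "simulate_growth_cohort",
    "simulate_regression_cohort",
    "gompertz_volume",
    "DEFAULT_IMAGING_DAYS",
]

#: three-times-a-week imaging schedule from day 5 post-implantation, with
#: the extra 24 h scan after the first dose (day 12).
DEFAULT_IMAGING_DAYS: tuple[int, ...] = (
    5, 7, 10, 12, 14, 17, 19, 21, 24, 26, 28, 31, 33, 35, 38, 40,
)


def gompertz_volume(t, alpha: float, beta: float, kappa: float):
    """Gompertz growth curve V(t) = alpha*exp[(beta/kappa)(1 - e^(-kappa t))].

    alpha is the volume at t=0 (mm^3), beta the initial specific growth
    rate (day^-1) and kappa the exponential decay rate of that specific
    growth rate (day^-1); the curve plateaus at alpha*e^(beta/kappa).
    """
    t = np.asarray(t, dtype=float)
    return alpha * np.exp((beta / kappa) * (1.0 - np.exp(-kappa * t)))


# --------------------------------------------------------------------------
# scenes


@dataclass
class Scene:
    """A synthetic dual-wavelength acquisition plus its ground truth.

    ``truth_sto2`` is NaN on voxels without hemoglobin signal; elsewhere it
    equals 100*cHbO2/(cHbO2+cHb) exactly.
    """

    volumes: PAVolumePair
    truth_chbo2: np.ndarray
    truth_chb: np.ndarray
    roi_mask: np.ndarray
    gamma: float = 1.0

    @property
    def truth_hbt(self) -> np.ndarray:
        return self.truth_chbo2 + self.truth_chb

    @property
    def truth_sto2(self) -> np.ndarray:
        hbt = self.truth_hbt
        out = np.full(hbt.shape, np.nan)
        np.divide(
            100.0 * self.truth_chbo2, hbt, out=out, where=hbt > 0
        )
        return out


def _forward_amplitudes(
    chbo2: np.ndarray,
    chb: np.ndarray,
    ext: ExtinctionTable,
    fluence: FluenceModel,
    voxel_spacing,
    depth_axis: int,
    gamma: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless amplitude volumes from concentration maps."""
    z = depth_coordinates(chbo2.shape, voxel_spacing, depth_axis, broadcast=True)
    out = []
    for wl in ext.wavelengths:
        eo, eh = ext.epsilon(wl)
        phi = fluence.at(wl, z)
        out.append(gamma * phi * (eo * chbo2 + eh * chb))
    return out[0], out[1]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and optics of a blood-filled tube phantom.

    A polyethylene tube of ``tube_diameter`` mm runs laterally at
    ``tube_depth`` mm below the transducer, filled with a hemoglobin
    solution of ``hb_concentration`` mM at ``true_sto2`` percent oxygen
    saturation.  ``pulse_energy_jitter`` is the relative SD of the
    per-frame laser pulse energy (default 5/45, from a 45 +/- 5 mJ pulse
    energy), applied multiplicatively and identically to both wavelengths
    within a frame.
    """

    tube_diameter: float = 2.0
    tube_depth: float = 10.0
    true_sto2: float = 100.0
    hb_concentration: float = 2.5
    voxel_spacing: tuple[float, float, float] = (0.15, 0.1, 0.1)
    shape: tuple[int, int, int] = (8, 200, 48)
    noise_sd: float = 0.02
    pulse_energy_jitter: float = 5.0 / 45.0
    depth_axis: int = 1

    def __post_init__(self) -> None:
        if self.tube_diameter <= 0 or self.hb_concentration < 0:
            raise ValidationError("tube_diameter and hb_concentration must be positive")
        if not 0.0 <= self.true_sto2 <= 100.0:
            raise ValidationError("true_sto2 must lie in [0, 100]")
        if self.noise_sd < 0 or self.pulse_energy_jitter < 0:
            raise ValidationError("noise SDs must be >= 0")
        r = self.tube_diameter / 2.0
        depth_extent = self.shape[self.depth_axis] * self.voxel_spacing[self.depth_axis]
        if self.tube_depth - r < 0 or self.tube_depth + r > depth_extent:
            raise GeometryError(
                f"tube at {self.tube_depth} mm (radius {r} mm) does not fit in a "
                f"{depth_extent:.1f} mm deep volume"
            )


def simulate_phantom_scene(
    spec: PhantomSpec,
    fluence: FluenceModel | None = None,
    seed: int = 0,
    ext: ExtinctionTable | None = None,
    gamma: float = 1.0,
) -> Scene:
    """Simulate a dual-wavelength acquisition of a tube phantom.

    Voxels inside the tube carry the forward-model amplitude; voxels
    outside carry background noise only.  Truth maps are populated from
    the specified hemoglobin concentration split by ``true_sto2``.
    """
    if fluence is None:
        fluence = FluenceModel.for_medium("water")
    if ext is None:
        ext = load_default_extinction()
    rng = np.random.default_rng(seed)

    da, la = spec.depth_axis, 2 if spec.depth_axis != 2 else 1
    # tube axis = lateral axis (2); cross-section in (frame, depth) plane is a
    # disc around (mid-frame, tube_depth)
    idx = np.indices(spec.shape).astype(float)
    z = idx[da] * spec.voxel_spacing[da]
    frame_axis = next(a for a in range(3) if a not in (da, 2))
    y = (idx[frame_axis] - (spec.shape[frame_axis] - 1) / 2.0) * spec.voxel_spacing[
        frame_axis
    ]
    tube = (z - spec.tube_depth) ** 2 + y**2 <= (spec.tube_diameter / 2.0) ** 2
    if not tube.any():
        raise GeometryError("tube cross-section covers no voxel")

    chbo2 = np.where(tube, spec.hb_concentration * spec.true_sto2 / 100.0, 0.0)
    chb = np.where(tube, spec.hb_concentration * (1.0 - spec.true_sto2 / 100.0), 0.0)

    a_lo, a_hi = _forward_amplitudes(
        chbo2, chb, ext, fluence, spec.voxel_spacing, da, gamma
    )
    scale = a_lo[tube].mean() if tube.any() else 1.0
    if spec.pulse_energy_jitter > 0:
        shp = [1, 1, 1]
        shp[frame_axis] = spec.shape[frame_axis]
        jitter = rng.normal(1.0, spec.pulse_energy_jitter, size=tuple(shp))
        a_lo = a_lo * jitter
        a_hi = a_hi * jitter
    if spec.noise_sd > 0:
        a_lo = a_lo + rng.normal(0.0, spec.noise_sd * scale, size=spec.shape)
        a_hi = a_hi + rng.normal(0.0, spec.noise_sd * scale, size=spec.shape)

    pair = PAVolumePair(
        a_lo,
        a_hi,
        wavelengths=ext.wavelengths,
        voxel_spacing=spec.voxel_spacing,
        depth_axis=da,
        meta={
            "scene": "phantom",
            "seed": int(seed),
            "medium": fluence.medium,
            "tube_depth_mm": spec.tube_depth,
            "true_sto2_pct": spec.true_sto2,
        },
    )
    return Scene(pair, chbo2, chb, roi_mask=tube, gamma=gamma)


@dataclass(frozen=True)
class TumorSpec:
    """An ellipsoidal, partially vascularized tumor scene.

    A fraction ``vascular_fraction`` of ROI voxels carries hemoglobin
    signal; the rest are signal-free (they matter for the distinction
    between the "average" and "total" StO2 biomarkers).  True StO2 varies
    linearly from ``sto2_core`` at the ellipsoid center to
    ``sto2_periphery`` at its surface (equal values give a uniform field).
    The tumor top sits ``depth_offset`` mm below the transducer, matching
    a typical 8-10 mm subcutaneous placement.
    """

    semi_axes: tuple[float, float, float] = (2.5, 2.0, 2.5)
    vascular_fraction: float = 0.5
    sto2_core: float = 55.0
    sto2_periphery: float = 70.0
    depth_offset: float = 9.0
    hb_concentration: float = 0.15
    voxel_spacing: tuple[float, float, float] = (0.15, 0.1, 0.1)
    shape: tuple[int, int, int] | None = None
    noise_sd: float = 0.02
    pulse_energy_jitter: float = 5.0 / 45.0
    depth_axis: int = 1

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValidationError("semi-axes must be positive")
        if not 0.0 < self.vascular_fraction <= 1.0:
            raise ValidationError("vascular_fraction must lie in (0, 1]")
        for s in (self.sto2_core, self.sto2_periphery):
            if not 0.0 <= s <= 100.0:
                raise ValidationError("StO2 field values must lie in [0, 100]")
        if self.noise_sd < 0 or self.pulse_energy_jitter < 0:
            raise ValidationError("noise SDs must be >= 0")
        if self.depth_offset < 0:
            raise ValidationError("depth_offset must be >= 0")

    def resolved_shape(self) -> tuple[int, int, int]:
        if self.shape is not None:
            return self.shape
        # tight box: ellipsoid extent + 1 mm margin, depth axis also fits the
        # standoff between transducer and tumor top
        axes_mm = [2 * a + 2.0 for a in self.semi_axes]
        axes_mm[self.depth_axis] += self.depth_offset
        return tuple(
            int(math.ceil(mm / sp)) for mm, sp in zip(axes_mm, self.voxel_spacing)
        )


def simulate_tumor_scene(
    spec: TumorSpec,
    fluence: FluenceModel | None = None,
    seed: int = 0,
    ext: ExtinctionTable | None = None,
    gamma: float = 1.0,
) -> Scene:
    """Simulate a dual-wavelength acquisition of a vascularized tumor."""
    if fluence is None:
        fluence = FluenceModel.for_medium("tissue")
    if ext is None:
        ext = load_default_extinction()
    rng = np.random.default_rng(seed)

    shape = spec.resolved_shape()
    da = spec.depth_axis
    idx = np.indices(shape).astype(float)
    center = [(n - 1) / 2.0 for n in shape]
    # center the ellipsoid; along depth, hang its top at depth_offset
    center[da] = (spec.depth_offset + spec.semi_axes[da]) / spec.voxel_spacing[da]
    r2 = np.zeros(shape)
    for ax in range(3):
        r2 += (
            (idx[ax] - center[ax]) * spec.voxel_spacing[ax] / spec.semi_axes[ax]
        ) ** 2
    roi = r2 <= 1.0
    if not roi.any():
        raise GeometryError("ellipsoid covers no voxel")
    depth_extent = shape[da] * spec.voxel_spacing[da]
    if (spec.depth_offset + 2 * spec.semi_axes[da]) > depth_extent:
        raise GeometryError("tumor does not fit within the volume depth extent")

    n_roi = int(roi.sum())
    n_vasc = max(1, int(round(spec.vascular_fraction * n_roi)))
    roi_flat = np.flatnonzero(roi)
    vasc_flat = rng.choice(roi_flat, size=n_vasc, replace=False)
    vascular = np.zeros(shape, dtype=bool)
    vascular.ravel()[vasc_flat] = True

    rad = np.sqrt(np.clip(r2, 0.0, 1.0))
    sto2_field = spec.sto2_core + (spec.sto2_periphery - spec.sto2_core) * rad
    chbo2 = np.where(vascular, spec.hb_concentration * sto2_field / 100.0, 0.0)
    chb = np.where(vascular, spec.hb_concentration * (1.0 - sto2_field / 100.0), 0.0)

    a_lo, a_hi = _forward_amplitudes(
        chbo2, chb, ext, fluence, spec.voxel_spacing, da, gamma
    )
    scale = a_lo[vascular].mean()
    frame_axis = next(a for a in range(3) if a != da and a != 2)
    if spec.pulse_energy_jitter > 0:
        shp = [1, 1, 1]
        shp[frame_axis] = shape[frame_axis]
        jitter = rng.normal(1.0, spec.pulse_energy_jitter, size=tuple(shp))
        a_lo = a_lo * jitter
        a_hi = a_hi * jitter
    if spec.noise_sd > 0:
        a_lo = a_lo + rng.normal(0.0, spec.noise_sd * scale, size=shape)
        a_hi = a_hi + rng.normal(0.0, spec.noise_sd * scale, size=shape)

    pair = PAVolumePair(
        a_lo,
        a_hi,
        wavelengths=ext.wavelengths,
        voxel_spacing=spec.voxel_spacing,
        depth_axis=da,
        meta={"scene": "tumor", "seed": int(seed), "medium": fluence.medium},
    )
    return Scene(pair, chbo2, chb, roi_mask=roi, gamma=gamma)


# --------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Study design of a two-group longitudinal cohort.

    Per-animal Gompertz parameters are drawn from group priors; the
    treated group's beta and kappa are multiplied by ``treatment_effect``
    (a ``(beta_factor, kappa_factor)`` pair, or one scalar for both; the
    defaults encode a 4-fold beta and 8-fold kappa reduction).  Treated
    animals' StO2 dips by ``sto2_dip`` percentage points over the first
    72 h of dosing (days 12-14 for an day-11 treatment start) and, when
    ``weekend_recovery`` is on, returns linearly to baseline over the
    following non-dosing days.  An animal leaves the study (survival
    event) on the day its noiseless tumor length first reaches
    ``size_limit`` mm.
    """

    n_control: int = 8
    n_treated: int = 8
    alpha_mean: float = 8.0
    alpha_sd: float = 1.5
    beta_mean: float = 0.25
    beta_sd: float = 0.025
    kappa_mean: float = 0.030
    kappa_sd: float = 0.003
    treatment_start_day: float = 11.0
    treatment_effect: tuple[float, float] | float = (0.25, 0.125)
    sto2_baseline: float = 62.0
    sto2_animal_sd: float = 3.0
    sto2_dip: float = 15.0
    weekend_recovery: bool = True
    recovery_day: float = 17.0
    vascular_fraction: float = 0.5
    volume_noise_cv: float = 0.05
    sto2_noise_sd: float = math.sqrt(4.8)
    sto2_tot_noise_sd: float = math.sqrt(7.40)
    hbt_avg_baseline: float = 2500.0
    hbt_avg_noise_sd: float = math.sqrt(3006.0)
    hbt_tot_baseline: float = 1250.0
    hbt_tot_noise_sd: float = 90.0
    size_limit: float = 20.0
    study_end_day: float = 80.0
    imaging_days: tuple[float, ...] = DEFAULT_IMAGING_DAYS

    def __post_init__(self) -> None:
        if self.n_control < 0 or self.n_treated < 0:
            raise ValidationError("group sizes must be >= 0")
        sds = (
            self.alpha_sd, self.beta_sd, self.kappa_sd, self.volume_noise_cv,
            self.sto2_noise_sd, self.sto2_tot_noise_sd, self.hbt_avg_noise_sd,
            self.hbt_tot_noise_sd, self.sto2_animal_sd,
        )
        if any(s < 0 for s in sds):
            raise ValidationError("all SDs must be >= 0")
        eb, ek = self.effect_factors()
        if not (0 < eb <= 1 and 0 < ek <= 1):
            raise ValidationError("treatment_effect factors must lie in (0, 1]")
        if len(self.imaging_days) == 0:
            raise ValidationError("imaging schedule must not be empty")
        days = np.asarray(self.imaging_days, dtype=float)
        if not np.all(np.diff(days) > 0):
            raise ValidationError("imaging_days must be strictly increasing")

    def effect_factors(self) -> tuple[float, float]:
        e = self.treatment_effect
        if np.isscalar(e):
            return float(e), float(e)
        return float(e[0]), float(e[1])


@dataclass
class CohortTable:
    """A simulated cohort: tidy measurement table plus generating truth.

    ``table`` columns: animal_id, group (0 control / 1 treated), day,
    volume_mm3, sto2_avg_pct, sto2_tot_pct, hbt_avg, hbt_tot, event_day,
    censored.  ``truth`` holds one row per animal with the generating
    (alpha, beta, kappa) and noiseless event day.
    """

    table: pd.DataFrame
    truth: pd.DataFrame
    spec: CohortSpec

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _length_from_volume(volume_mm3: float) -> float:
    """Longest caliper dimension, sphere-equivalent: L = (6V/pi)^(1/3)."""
    return (6.0 * volume_mm3 / math.pi) ** (1.0 / 3.0)


def _event_day(alpha, beta, kappa, size_limit, horizon) -> tuple[float, bool]:
    """First day the noiseless length reaches size_limit; censored at horizon."""
    v_limit = math.pi / 6.0 * size_limit**3
    plateau = alpha * math.exp(beta / kappa)
    if v_limit >= plateau or v_limit <= alpha:
        if v_limit <= alpha:
            return 0.0, False
        return float(horizon), True
    # invert V(t) = v_limit analytically
    t = -math.log(1.0 - (kappa / beta) * math.log(v_limit / alpha)) / kappa
    if t > horizon:
        return float(horizon), True
    return float(t), False


def _treated_sto2_offset(day: float, spec: CohortSpec) -> float:
    """StO2 offset (pp, <= 0) of a treated animal on a given day."""
    t0 = spec.treatment_start_day
    nadir = t0 + 3.0  # 72 h after the first dose
    if day <= t0:
        return 0.0
    if day <= nadir:
        return -spec.sto2_dip * (day - t0) / (nadir - t0)
    if spec.weekend_recovery:
        if day >= spec.recovery_day:
            return 0.0
        return -spec.sto2_dip * (spec.recovery_day - day) / (spec.recovery_day - nadir)
    return -spec.sto2_dip


def simulate_growth_cohort(spec: CohortSpec, seed: int = 0) -> CohortTable:
    """Simulate a two-group longitudinal cohort (see :class:`CohortSpec`).

    Each animal contributes one row per imaging day up to (and including
    the day of) its survival event; no measurements exist after the event
    day, so the table has sum(animals x surviving days) rows.
    """
    rng = np.random.default_rng(seed)
    eb, ek = spec.effect_factors()

    truth_rows = []
    rows = []
    days = np.asarray(spec.imaging_days, dtype=float)
    animal = 0
    for group, n in ((0, spec.n_control), (1, spec.n_treated)):
        for _ in range(n):
            aid = f"M{animal:03d}"
            animal += 1
            alpha = max(rng.normal(spec.alpha_mean, spec.alpha_sd), 0.5)
            beta = max(rng.normal(spec.beta_mean, spec.beta_sd), 1e-3)
            kappa = max(rng.normal(spec.kappa_mean, spec.kappa_sd), 1e-4)
            if group == 1:
                beta *= eb
                kappa *= ek
            ev, cens = _event_day(
                alpha, beta, kappa, spec.size_limit, spec.study_end_day
            )
            sto2_base = rng.normal(spec.sto2_baseline, spec.sto2_animal_sd)
            truth_rows.append(
                dict(
                    animal_id=aid, group=group, alpha=alpha, beta=beta,
                    kappa=kappa, event_day=ev, censored=cens,
                    sto2_baseline=sto2_base,
                )
            )
            for day in days:
                if day > ev:
                    break
                v = float(gompertz_volume(day, alpha, beta, kappa))
                v_obs = v * (1.0 + rng.normal(0.0, spec.volume_noise_cv))
                s = sto2_base
                if group == 1:
                    s += _treated_sto2_offset(day, spec)
                s_avg = np.clip(s + rng.normal(0.0, spec.sto2_noise_sd), 0, 100)
                s_tot = np.clip(
                    s * spec.vascular_fraction
                    + rng.normal(0.0, spec.sto2_tot_noise_sd),
                    0,
                    100,
                )
                rows.append(
                    dict(
                        animal_id=aid,
                        group=group,
                        day=float(day),
                        volume_mm3=max(v_obs, 0.0),
                        sto2_avg_pct=float(s_avg),
                        sto2_tot_pct=float(s_tot),
                        hbt_avg=spec.hbt_avg_baseline
                        + rng.normal(0.0, spec.hbt_avg_noise_sd),
                        hbt_tot=spec.hbt_tot_baseline
                        + rng.normal(0.0, spec.hbt_tot_noise_sd),
                        event_day=ev,
                        censored=bool(cens),
                    )
                )
    table = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    return CohortTable(table=table, truth=truth, spec=spec)


# --------------------------------------------------------------------------
# regression cohorts

#: predictor ranges matching the study regime: pretreatment volumes of
#: ~45-85 mm^3 and StO2 changes of a few to ~15 percentage points.
DEFAULT_PREDICTOR_RANGES: tuple[tuple[float, float], ...] = (
    (45.0, 85.0),
    (-15.0, 15.0),
    (-15.0, 15.0),
)

REGRESSION_PREDICTORS = ("pretreat_volume_mm3", "dsto2_d7_d10", "dsto2_d10_d14")


def simulate_regression_cohort(
    coefficients: Sequence[float],
    n: int = 29,
    predictor_ranges: Sequence[tuple[float, float]] = DEFAULT_PREDICTOR_RANGES,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a cohort from the linear growth-rate model.

    The response is

        beta = b0 + b1*pretreat_volume + b2*dStO2(D7-D10)
                  + b3*dStO2(D10-D14) + eps,   eps ~ N(0, noise_sd^2)

    with predictors uniform on ``predictor_ranges``.  The generating
    coefficients are echoed in ``df.attrs`` for recovery studies.
    """
    b = np.asarray(coefficients, dtype=float)
    if b.shape != (4,):
        raise ValidationError("coefficients must be a 4-vector (b0..b3)")
    if n < 5:
        raise ValidationError("n must be >= 5")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    ranges = [tuple(map(float, r)) for r in predictor_ranges]
    if len(ranges) != 3 or any(hi <= lo for lo, hi in ranges):
        raise ValidationError("predictor_ranges must be three non-degenerate intervals")

    rng = np.random.default_rng(seed)
    x = np.column_stack([rng.uniform(lo, hi, size=n) for lo, hi in ranges])
    beta = b[0] + x @ b[1:]
    if noise_sd > 0:
        beta = beta + rng.normal(0.0, noise_sd, size=n)
    df = pd.DataFrame(x, columns=list(REGRESSION_PREDICTORS))
    df["beta"] = beta
    df.attrs["coefficients"] = b.tolist()
    df.attrs["noise_sd"] = float(noise_sd)
    df.attrs["seed"] = int(seed)
    return df
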