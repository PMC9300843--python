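"""Dual-wavelength spectral unmixing to hemoglobin and StO2 maps.

Per voxel, the photoacoustic amplitudes at the two wavelengths are an
absorption-weighted mix of oxy- and deoxyhemoglobin:

    a(lambda_i) = eps_HbO2(lambda_i) * cHbO2 + eps_Hb(lambda_i) * cHb

(up to a common proportionality constant absorbed into the relative
concentrations).  Inverting this 2x2 system gives relative cHbO2 and
cHb, from which StO2 = 100 * cHbO2 / (cHbO2 + cHb) and HbT =
cHbO2 + cHb.  Depth-dependent, wavelength-dependent fluence decay
("spectral coloring") biases the solve; :func:`compensate_fluence`
provides the optional correction and :func:`depth_bias_profile`
quantifies the residual bias on tube-phantom scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyROIError, NumericDomainError, ValidationError
from .extinction import ExtinctionTable, load_default_extinction
from .fluence import FluenceModel
from .volumes import PAVolumePair

__all__ = [
    "ChromophoreMaps",
    "unmix_pair",
    "compensate_fluence",
    "depth_bias_profile",
    "estimate_noise_floor",
]

CLAMP_POLICIES = ("flag", "range", "none")


@dataclass
class ChromophoreMaps:
    """Per-voxel chromophore concentrations and derived oximetry maps.

    ``valid_mask`` marks voxels whose StO2 is trustworthy: amplitude above
    the noise floor, HbT > 0, and (under the "flag" policy) both
    concentrations non-negative.  Under "flag", out-of-range voxels are
    never altered — they are only excluded from the mask.
    """

    chbo2: np.ndarray
    chb: np.ndarray
    sto2: np.ndarray
    hbt: np.ndarray
    valid_mask: np.ndarray
    clamp: str = "flag"
    voxel_spacing: tuple[float, float, float] = (0.15, 0.1, 0.1)
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.sto2.shape


def estimate_noise_floor(
    pair: PAVolumePair, background_mask: np.ndarray, k: float = 3.0
) -> float:
    """Noise floor as ``k`` times the background amplitude SD.

    The background region is user-specified; the SD is pooled over both
    wavelength volumes.
    """
    if background_mask.shape != pair.shape:
        raise ValidationError("background mask shape must match the volumes")
    if not background_mask.any():
        raise EmptyROIError("background mask selects no voxels")
    vals = np.concatenate(
        [pair.vol_lo[background_mask].ravel(), pair.vol_hi[background_mask].ravel()]
    )
    return float(k * vals.std(ddof=1))


def unmix_pair(
    volumes: PAVolumePair,
    ext: ExtinctionTable | None = None,
    noise_floor: float = 0.0,
    clamp: str = "flag",
    background_mask: np.ndarray | None = None,
) -> ChromophoreMaps:
    """Solve the per-voxel 2x2 system for cHbO2/cHb and derive StO2, HbT.

    Parameters
    ----------
    volumes : PAVolumePair
        Co-registered amplitude volumes at the table's two wavelengths.
    ext : ExtinctionTable, optional
        Defaults to the packaged 750/850 nm hemoglobin table.
    noise_floor : float
        Voxels with both amplitudes <= this are zero-filled and marked
        invalid.  Ignored if ``background_mask`` is given, in which case
        the floor is 3x the background SD (:func:`estimate_noise_floor`).
    clamp : {"flag", "range", "none"}
        Policy for out-of-range solutions.  "flag" (default) leaves values
        untouched but excludes them from ``valid_mask``; "range" clips
        negative concentrations to zero (so StO2 lands in [0, 100]);
        "none" keeps raw values and only requires HbT > 0 for validity.
    """
    if ext is None:
        ext = load_default_extinction()
    if clamp not in CLAMP_POLICIES:
        raise ConfigurationError(f"clamp must be one of {CLAMP_POLICIES}")
    if background_mask is not None:
        noise_floor = estimate_noise_floor(volumes, background_mask)

    e = ext.matrix
    det = e[0, 0] * e[1, 1] - e[0, 1] * e[1, 0]
    a_lo, a_hi = volumes.vol_lo, volumes.vol_hi
    # analytic 2x2 inverse, vectorized over voxels
    chbo2 = (e[1, 1] * a_lo - e[0, 1] * a_hi) / det
    chb = (-e[1, 0] * a_lo + e[0, 0] * a_hi) / det

    signal = (a_lo > noise_floor) | (a_hi > noise_floor)
    chbo2 = np.where(signal, chbo2, 0.0)
    chb = np.where(signal, chb, 0.0)

    if clamp == "range":
        chbo2 = np.maximum(chbo2, 0.0)
        chb = np.maximum(chb, 0.0)

    hbt = chbo2 + chb
    sto2 = np.zeros_like(hbt)
    with np.errstate(invalid="ignore", divide="ignore"):
        np.divide(100.0 * chbo2, hbt, out=sto2, where=hbt > 0)

    valid = signal & (hbt > 0)
    if clamp == "flag":
        valid &= (chbo2 >= 0) & (chb >= 0)

    return ChromophoreMaps(
        chbo2=chbo2,
        chb=chb,
        sto2=sto2,
        hbt=hbt,
        valid_mask=valid,
        clamp=clamp,
        voxel_spacing=volumes.voxel_spacing,
        meta={**volumes.meta, "noise_floor": float(noise_floor), "clamp": clamp},
    )


def compensate_fluence(volumes: PAVolumePair, fluence: FluenceModel) -> PAVolumePair:
    """Divide each voxel amplitude by the model fluence at its depth.

    Not idempotent: calling twice divides twice.  The returned pair's
    metadata records the compensation (model medium and mu_eff values).
    """
    z = volumes.depth_map()
    out = volumes.copy()
    for attr, wl in (("vol_lo", volumes.wavelengths[0]), ("vol_hi", volumes.wavelengths[1])):
        phi = fluence.at(wl, z)
        if np.any(phi <= 0):
            raise NumericDomainError("fluence must be positive at every depth")
        setattr(out, attr, getattr(volumes, attr) / phi)
    out.meta["fluence_compensated"] = out.meta.get("fluence_compensated", 0) + 1
    out.meta["fluence_medium"] = fluence.medium
    out.meta["fluence_mu_eff"] = {
        float(k): float(v) for k, v in fluence.mu_eff.items()
    }
    return out


def depth_bias_profile(
    scenes: Iterable,
    ext: ExtinctionTable | None = None,
    noise_floor: float = 0.0,
    fluence: FluenceModel | None = None,
) -> pd.DataFrame:
    """Estimated-vs-true StO2 over tube voxels for phantom scenes at depths.

    Parameters
    ----------
    scenes : iterable of Scene
        Phantom scenes (each carries its truth and tube mask); at least
        two depths are required for a profile.
    fluence : FluenceModel, optional
        When given, amplitudes are fluence-compensated with this model
        before unmixing.

    Returns
    -------
    DataFrame
        Columns ``depth_mm``, ``mean_sto2``, ``sd_sto2``, ``truth_sto2``,
        ``bias`` (mean - truth), one row per scene, sorted by depth.
    """
    rows = []
    for scene in scenes:
        mask = scene.roi_mask
        if not mask.any():
            raise EmptyROIError("phantom scene has no tube voxels")
        pair = scene.volumes
        if fluence is not None:
            pair = compensate_fluence(pair, fluence)
        # raw (unclamped) estimates: bias beyond [0, 100] must stay visible
        maps = unmix_pair(pair, ext=ext, noise_floor=noise_floor, clamp="none")
        est = maps.sto2[mask & maps.valid_mask]
        truth = np.nanmean(scene.truth_sto2[mask])
        rows.append(
            dict(
                depth_mm=float(pair.meta.get("tube_depth_mm", np.nan)),
                mean_sto2=float(est.mean()),
                sd_sto2=float(est.std(ddof=1)) if est.size > 1 else 0.0,
                truth_sto2=float(truth),
                bias=float(est.mean() - truth),
            )
        )
    if len(rows) < 2:
        raise ValidationError("need phantom scenes at >= 2 depths")
    return pd.DataFrame(rows).sort_values("depth_mm", ignore_index=True)
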