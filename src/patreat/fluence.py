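"""Single-exponential optical fluence model.

Light delivered at the tissue (or water-tank) surface decays with depth;
in the diffusive regime the decay is well approximated by Beer-Lambert
attenuation with an effective coefficient mu_eff per wavelength,

    Phi(lambda, z) = Phi0 * exp(-mu_eff(lambda) * z).

Wavelength-dependent mu_eff is what biases uncorrected two-wavelength
StO2 estimates with depth ("spectral coloring"); a wavelength-independent
mu_eff cancels in the concentration ratio and produces no bias.

Default media:

``water``
    Essentially non-scattering; attenuation is the water absorption
    coefficient itself (~0.0026 / 0.0043 mm^-1 at 750 / 850 nm).
``intralipid_0.5pct``
    0.5% intralipid emulsion mimicking soft-tissue scattering; effective
    attenuation from mu_eff = sqrt(3 mu_a (mu_a + mu_s')) with the usual
    intralipid reduced-scattering spectrum scaled to 0.5% (~0.052 /
    0.058 mm^-1 at 750 / 850 nm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import NumericDomainError, ValidationError

__all__ = ["FluenceModel"]

#: mu_eff (mm^-1) per medium at (750 nm, 850 nm); see module docstring.
_MEDIUM_MU_EFF: dict[str, tuple[float, float]] = {
    "water": (0.0026, 0.0043),
    "intralipid_0.5pct": (0.052, 0.058),
    "tissue": (0.11, 0.12),
}


@dataclass(frozen=True)
class FluenceModel:
    """Beer-Lambert fluence decay, one attenuation coefficient per wavelength.

    Parameters
    ----------
    surface_fluence : float
        Fluence at depth 0 (arbitrary energy/area units; it folds into the
        overall system constant, so only its depth profile matters).
    mu_eff : dict
        Effective attenuation coefficient (mm^-1) keyed by wavelength (nm).
    medium : str
        Label of the propagation medium (bookkeeping only).
    """

    surface_fluence: float = 1.0
    mu_eff: dict[float, float] = field(default_factory=dict)
    medium: str = "water"

    def __post_init__(self) -> None:
        if self.surface_fluence <= 0:
            raise ValidationError("surface_fluence must be positive")
        for wl, mu in self.mu_eff.items():
            if mu < 0:
                raise ValidationError(f"mu_eff({wl} nm) = {mu} must be >= 0")

    @classmethod
    def for_medium(
        cls,
        medium: str,
        wavelengths: tuple[float, float] = (750.0, 850.0),
        surface_fluence: float = 1.0,
    ) -> "FluenceModel":
        """Build the documented default model for a named medium."""
        try:
            mus = _MEDIUM_MU_EFF[medium]
        except KeyError:
            raise ValidationError(
                f"unknown medium {medium!r}; choose from {sorted(_MEDIUM_MU_EFF)}"
            ) from None
        return cls(
            surface_fluence=surface_fluence,
            mu_eff=dict(zip(wavelengths, mus)),
            medium=medium,
        )

    def attenuation(self, wavelength: float) -> float:
        """mu_eff (mm^-1) at ``wavelength``; 0 if the wavelength is unset."""
        for wl, mu in self.mu_eff.items():
            if np.isclose(wl, wavelength):
                return float(mu)
        return 0.0

    def at(self, wavelength: float, depth_mm) -> np.ndarray:
        """Fluence Phi(lambda, z) at depth(s) ``depth_mm`` (mm).

        Strictly positive and non-increasing in depth.
        """
        z = np.asarray(depth_mm, dtype=float)
        if np.any(z < 0):
            raise NumericDomainError("depth must be non-negative")
        return self.surface_fluence * np.exp(-self.attenuation(wavelength) * z)
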