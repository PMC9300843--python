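"""Hemoglobin molar extinction coefficients for spectral unmixing.

Dual-wavelength photoacoustic oximetry solves, per voxel, a 2x2 linear
system whose matrix rows are the molar extinction coefficients of
oxy- and deoxyhemoglobin at the two interrogation wavelengths.  This
module ships a literature-derived table (Prahl compilation) for the
750/850 nm pair that straddles the ~800 nm isosbestic point, and a small
container class that validates the matrix and reports its conditioning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = ["ExtinctionTable", "load_default_extinction"]


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction coefficients of HbO2 and Hb at two wavelengths.

    Parameters
    ----------
    wavelengths : tuple of float
        Interrogation wavelengths in nm, shortest first.
    eps_hbo2, eps_hb : tuple of float
        Molar extinction coefficients (cm^-1 M^-1) of oxyhemoglobin and
        deoxyhemoglobin at ``wavelengths``.

    Notes
    -----
    The unmixing matrix is ``[[eps_hbo2[0], eps_hb[0]],
    [eps_hbo2[1], eps_hb[1]]]``; it must be non-singular for the
    two-wavelength inversion to be defined, and its condition number is
    exposed because it controls noise amplification in the solve.
    """

    wavelengths: tuple[float, float]
    eps_hbo2: tuple[float, float]
    eps_hb: tuple[float, float]
    #: populated in __post_init__
    condition_number: float = field(init=False, default=np.nan)

    def __post_init__(self) -> None:
        if len(self.wavelengths) != 2:
            raise ConfigurationError("exactly two wavelengths are required")
        coeffs = np.array([*self.eps_hbo2, *self.eps_hb], dtype=float)
        if not np.all(coeffs > 0):
            raise ConfigurationError("extinction coefficients must be positive")
        m = self.matrix
        det = np.linalg.det(m)
        if not np.isfinite(det) or abs(det) < 1e-12 * np.abs(m).max() ** 2:
            raise ConfigurationError(
                "extinction matrix is singular; the two wavelengths do not "
                "separate HbO2 from Hb"
            )
        object.__setattr__(self, "condition_number", float(np.linalg.cond(m)))

    @property
    def matrix(self) -> np.ndarray:
        """2x2 unmixing matrix, rows = wavelengths, cols = (HbO2, Hb)."""
        return np.array(
            [
                [self.eps_hbo2[0], self.eps_hb[0]],
                [self.eps_hbo2[1], self.eps_hb[1]],
            ],
            dtype=float,
        )

    def epsilon(self, wavelength: float) -> tuple[float, float]:
        """Return ``(eps_hbo2, eps_hb)`` at one of the table's wavelengths."""
        for i, wl in enumerate(self.wavelengths):
            if np.isclose(wl, wavelength):
                return self.eps_hbo2[i], self.eps_hb[i]
        raise ConfigurationError(f"wavelength {wavelength} nm not in table")

    @classmethod
    def from_csv(cls, path) -> "ExtinctionTable":
        """Load a two-row table with columns wavelength_nm, eps_hbo2, eps_hb."""
        df = pd.read_csv(path, comment="#")
        if len(df) != 2:
            raise ConfigurationError("extinction CSV must have exactly two rows")
        df = df.sort_values("wavelength_nm")
        return cls(
            wavelengths=tuple(df["wavelength_nm"].astype(float)),
            eps_hbo2=tuple(df["eps_hbo2"].astype(float)),
            eps_hb=tuple(df["eps_hb"].astype(float)),
        )


def load_default_extinction() -> ExtinctionTable:
    """The packaged Prahl-compilation 750/850 nm hemoglobin table."""
    ref = resources.files("patreat.data").joinpath("hb_extinction.csv")
    with resources.as_file(ref) as path:
        return ExtinctionTable.from_csv(path)
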