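"""Chromophore absorption spectra for tissue optical-property composition.

Each :class:`ChromophoreSpectrum` holds specific absorption (per cm at unit
volume/concentration fraction) on a strictly increasing wavelength grid and
interpolates linearly inside it; extrapolation is a hard error, because the
shipped tables are approximate literature digitisations whose shape outside
the tabulated 450–1100 nm band is unknown.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["ChromophoreSpectrum", "load_default_library", "CHROMOPHORE_NAMES"]

CHROMOPHORE_NAMES = (
    "melanin",
    "hb_oxy",
    "hb_deoxy",
    "water",
    "cco_oxidised",
    "cco_reduced",
)


@dataclass(frozen=True)
class ChromophoreSpectrum:
    name: str
    wavelengths: np.ndarray   # nm, strictly increasing
    absorption: np.ndarray    # per cm at unit fraction

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorption, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorption", ab)
        if len(wl) != len(ab):
            raise ValueError("wavelength and absorption arrays differ in length")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(ab < 0):
            raise ValueError("absorption must be nonnegative")

    def __call__(self, wavelength: float) -> float:
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        if not (lo <= wavelength <= hi):
            raise ValueError(
                f"{self.name}: wavelength {wavelength} nm outside tabulated "
                f"range [{lo:g}, {hi:g}] nm (no extrapolation)"
            )
        return float(np.interp(wavelength, self.wavelengths, self.absorption))

    @property
    def range(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])


def load_default_library(path=None) -> dict[str, ChromophoreSpectrum]:
    """Load the packaged (or a user-supplied) chromophore CSV.

    The CSV has a ``wavelength_nm`` column plus one column per chromophore;
    ``#`` lines are comments.
    """
    if path is None:
        source = resources.files("mtmrs.photon_transport").joinpath(
            "data/chromophores.csv"
        )
        with resources.as_file(source) as p:
            table = pd.read_csv(p, comment="#")
    else:
        table = pd.read_csv(path, comment="#")
    if "wavelength_nm" not in table.columns:
        raise ValueError("chromophore table must have a wavelength_nm column")
    wl = table["wavelength_nm"].to_numpy(dtype=float)
    return {
        col: ChromophoreSpectrum(col, wl, table[col].to_numpy(dtype=float))
        for col in table.columns
        if col != "wavelength_nm"
    }
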