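"""Dosimetry sweeps: wavelength spectra and melanin-fraction series.

The quantity of interest for photobiomodulation dosimetry is the fraction
of light entering the head that is (a) reaching and (b) absorbed in the
cortical grey matter, and (c) the share of that absorption attributable to
the cytochrome c / cytochrome c oxidase chromophore, obtained by
multiplying the grey-matter absorption by the chromophore's share of the
grey-matter μa at that wavelength.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from mtmrs.photon_transport.chromophores import load_default_library
from mtmrs.photon_transport.layers import (
    GM_LAYER_NAME,
    LayerSpec,
    build_head_model,
    default_head_specs,
    with_melanin,
)
from mtmrs.photon_transport.mc import run_mc

__all__ = ["sweep_wavelengths", "melanin_sweep", "MelaninSweepResult"]


def _dosimetry_row(
    specs, library, wavelength, n_photons, seed,
    target_layer=GM_LAYER_NAME, chromophore="cco_oxidised",
) -> dict:
    layers = build_head_model(specs, library, wavelength)
    tallies = run_mc(layers, n_photons=n_photons, seed=seed, wavelength=wavelength)
    target = layers[[l.name for l in layers].index(target_layer)]
    chrom_share = target.chromophore_mua_fraction(chromophore)
    entering = tallies.entering_fraction
    gm_abs = tallies.absorbed_in(target_layer) / entering
    idx = tallies.layer_names.index(target_layer)
    row = {
        "wavelength": wavelength,
        "n_photons": n_photons,
        "specular_reflectance": tallies.specular_reflectance,
        "diffuse_reflectance": tallies.diffuse_reflectance,
        "transmittance": tallies.transmittance,
        "gm_reaching": tallies.reaching_last_relative(),
        "gm_absorbed": gm_abs,
        "chromophore_mua_share": chrom_share,
        "chromophore_absorbed": gm_abs * chrom_share,
        "gm_reaching_se": tallies.se["reached_last"] / entering,
        "gm_absorbed_se": float(tallies.se["absorbed"][idx]) / entering,
        "conservation_error": tallies.conservation_error,
    }
    for name, frac in zip(tallies.layer_names, tallies.absorbed):
        row[f"absorbed_{name}"] = float(frac)
    return row


def sweep_wavelengths(
    layer_specs: list[LayerSpec] | None = None,
    wavelengths=None,
    n_photons: int = 100_000,
    seed: int = 0,
    chromophore: str = "cco_oxidised",
    chromophore_library=None,
) -> pd.DataFrame:
    """Per-wavelength dosimetry table over (default) 450–1100 nm.

    All fractions except the raw reflectance/transmittance/absorbed columns
    are relative to light entering the head (incident minus specular).
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    if layer_specs is None:
        layer_specs = default_head_specs()
    if wavelengths is None:
        wavelengths = np.arange(450.0, 1101.0, 25.0)
    wavelengths = np.asarray(wavelengths, dtype=float)
    library = chromophore_library or load_default_library()
    rng = np.random.default_rng(seed)
    rows = [
        _dosimetry_row(
            layer_specs, library, wl, n_photons,
            seed=int(rng.integers(0, 2**31 - 1)), chromophore=chromophore,
        )
        for wl in wavelengths
    ]
    return pd.DataFrame(rows)


class MelaninSweepResult:
    """Melanin series plus the relative drop between its extremes."""

    def __init__(self, table: pd.DataFrame):
        self.table = table

    @property
    def drop_ratio(self) -> float:
        """1 − chromophore absorption at the highest melanin fraction
        relative to the lowest."""
        t = self.table.sort_values("melanin_fraction")
        low = t["chromophore_absorbed"].iloc[0]
        high = t["chromophore_absorbed"].iloc[-1]
        return 1.0 - high / low

    @property
    def gm_drop_ratio(self) -> float:
        t = self.table.sort_values("melanin_fraction")
        return 1.0 - t["gm_absorbed"].iloc[-1] / t["gm_absorbed"].iloc[0]


def melanin_sweep(
    layer_specs: list[LayerSpec] | None = None,
    wavelength: float = 670.0,
    melanin_fractions=(0.04, 0.1, 0.2, 0.3, 0.43),
    n_photons: int = 100_000,
    seed: int = 0,
    chromophore: str = "cco_oxidised",
    chromophore_library=None,
) -> MelaninSweepResult:
    """Grey-matter and chromophore absorption versus skin melanin fraction."""
    fractions = np.asarray(melanin_fractions, dtype=float)
    if np.any((fractions < 0) | (fractions > 1)):
        raise ValueError("melanin fractions must lie in [0, 1]")
    if layer_specs is None:
        layer_specs = default_head_specs()
    library = chromophore_library or load_default_library()
    rng = np.random.default_rng(seed)
    rows = []
    for frac in fractions:
        specs = with_melanin(layer_specs, float(frac))
        row = _dosimetry_row(
            specs, library, wavelength, n_photons,
            seed=int(rng.integers(0, 2**31 - 1)), chromophore=chromophore,
        )
        row["melanin_fraction"] = float(frac)
        rows.append(row)
    return MelaninSweepResult(pd.DataFrame(rows))
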