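"""Reflectance spectra: containers, solar weighting and mainland-island
band comparisons.

The atomic measurement is a reflectance spectrum on a fixed 1-nm wavelength
grid (default 350-2500 nm, the spectroradiometer's range).  Spectra are
summarised as *solar-weighted* reflectance, i.e. reflectance averaged with a
solar irradiance spectrum as weight, which approximates the fraction of
incident sunlight an animal's surface actually reflects.  Mainland-island
cohorts are compared per 100-nm bin with Welch t-tests under a
Holm-Bonferroni correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "WavelengthGrid",
    "ReflectanceSpectrum",
    "IrradianceSpectrum",
    "SpectralBand",
    "BANDS",
    "average_patches",
    "solar_weighted_reflectance",
    "solar_correct_spectrum",
    "divergence_percent",
    "binned_band_tests",
    "holm_adjust",
]

#: upper reflectance bound treated as a calibration artefact (clip + warn);
#: anything above is rejected outright.
_CLIP_MAX = 1.05


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform integer wavelength grid in nanometres (inclusive of both ends)."""

    start_nm: int = 350
    stop_nm: int = 2500
    step_nm: int = 1

    def __post_init__(self) -> None:
        if self.start_nm >= self.stop_nm:
            raise ValueError("grid start must be below stop")
        if self.step_nm < 1:
            raise ValueError("grid step must be >= 1 nm")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.arange(self.start_nm, self.stop_nm + 1, self.step_nm, dtype=float)

    def __len__(self) -> int:
        return len(self.wavelengths)


@dataclass(frozen=True)
class SpectralBand:
    """A named wavelength band: UV 350-400, VIS 400-700, NIR 700-2500, FULL 350-2500."""

    name: str
    lo_nm: int
    hi_nm: int

    def mask(self, wavelengths: np.ndarray) -> np.ndarray:
        return (wavelengths >= self.lo_nm) & (wavelengths <= self.hi_nm)


BANDS: dict[str, SpectralBand] = {
    "UV": SpectralBand("UV", 350, 400),
    "VIS": SpectralBand("VIS", 400, 700),
    "NIR": SpectralBand("NIR", 700, 2500),
    "FULL": SpectralBand("FULL", 350, 2500),
}


def _as_band(band: SpectralBand | str) -> SpectralBand:
    if isinstance(band, SpectralBand):
        return band
    try:
        return BANDS[band.upper()]
    except KeyError:
        raise ValueError(f"unknown band {band!r}; expected one of {sorted(BANDS)}") from None


def _validate_reflectance(values: np.ndarray, kind: str = "reflectance") -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("reflectance values must be finite")
    if np.any(values < 0):
        raise ValueError("reflectance values must be >= 0")
    if kind == "weighted":
        # irradiance-weighted values are not bounded by 1
        return values
    if np.any(values > _CLIP_MAX):
        raise ValueError(
            f"reflectance values above {_CLIP_MAX} look like a failed calibration"
        )
    if np.any(values > 1.0):
        warnings.warn(
            "reflectance values in (1.0, 1.05] clipped to 1.0 (calibration artefact)",
            stacklevel=3,
        )
        values = np.minimum(values, 1.0)
    return values


@dataclass
class ReflectanceSpectrum:
    """One reflectance measurement (fractions per wavelength) with specimen metadata."""

    grid: WavelengthGrid
    values: np.ndarray
    specimen_id: str = ""
    taxon: str = ""
    population: str = ""  # "mainland" | "island"
    surface: str = ""  # "dorsal" | "ventral"
    patch: str = ""
    kind: str = "reflectance"  # "weighted" marks irradiance-weighted values (may exceed 1)

    def __post_init__(self) -> None:
        self.values = _validate_reflectance(self.values, self.kind)
        if len(self.values) != len(self.grid):
            raise ValueError(
                f"values length {len(self.values)} does not match grid length {len(self.grid)}"
            )
        if self.population not in ("", "mainland", "island"):
            raise ValueError(f"population must be mainland/island, got {self.population!r}")
        if self.surface not in ("", "dorsal", "ventral"):
            raise ValueError(f"surface must be dorsal/ventral, got {self.surface!r}")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths


@dataclass
class IrradianceSpectrum:
    """Spectral irradiance on a wavelength grid; only ratios are ever used."""

    grid: WavelengthGrid
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.intensity) != len(self.grid):
            raise ValueError("intensity length does not match grid")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValueError("irradiance must be finite and >= 0")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths

    def on_grid(self, grid: WavelengthGrid) -> np.ndarray:
        """Linear-interpolate intensity onto ``grid`` (no extrapolation)."""
        return resample(self.wavelengths, self.intensity, grid.wavelengths)


def resample(x_src: np.ndarray, y_src: np.ndarray, x_new: np.ndarray) -> np.ndarray:
    """Linear interpolation; raises instead of extrapolating."""
    x_src = np.asarray(x_src, dtype=float)
    x_new = np.asarray(x_new, dtype=float)
    if x_new.min() < x_src.min() or x_new.max() > x_src.max():
        raise ValueError(
            f"target grid [{x_new.min()}, {x_new.max()}] extends outside the "
            f"source range [{x_src.min()}, {x_src.max()}]"
        )
    return np.interp(x_new, x_src, np.asarray(y_src, dtype=float))


def average_patches(spectra: Sequence[ReflectanceSpectrum]) -> ReflectanceSpectrum:
    """Pointwise mean over feather-patch measurements of one specimen surface.

    All inputs must share specimen, surface and grid; the result keeps the
    specimen metadata with ``patch="mean"``.
    """
    if not spectra:
        raise ValueError("need at least one patch measurement")
    first = spectra[0]
    for s in spectra[1:]:
        if s.grid != first.grid:
            raise ValueError("patch measurements on different wavelength grids")
        if (s.specimen_id, s.surface) != (first.specimen_id, first.surface):
            raise ValueError(
                "patch measurements mix specimens or surfaces: "
                f"{(s.specimen_id, s.surface)} vs {(first.specimen_id, first.surface)}"
            )
    mean = np.mean([s.values for s in spectra], axis=0)
    return replace(first, values=mean, patch="mean")


def solar_weighted_reflectance(
    r: ReflectanceSpectrum,
    sun: IrradianceSpectrum,
    band: SpectralBand | str = "FULL",
) -> float:
    """Irradiance-weighted mean reflectance over ``band``.

    Computes trapz(R * I) / trapz(I) on the spectrum's grid, i.e. the fraction
    of band solar energy reflected.  The irradiance is resampled onto the
    reflectance grid first.
    """
    band = _as_band(band)
    wl = r.wavelengths
    mask = band.mask(wl)
    if mask.sum() < 2:
        raise ValueError(f"band {band.name} covers fewer than 2 grid points")
    intensity = sun.on_grid(r.grid)
    denom = np.trapezoid(intensity[mask], wl[mask])
    if denom <= 0:
        raise ValueError(f"zero total irradiance on band {band.name}")
    num = np.trapezoid(r.values[mask] * intensity[mask], wl[mask])
    return float(num / denom)


def solar_correct_spectrum(
    r: ReflectanceSpectrum,
    sun: IrradianceSpectrum,
    mode: str = "weighted",
) -> ReflectanceSpectrum:
    """Per-wavelength solar-weighted reflectance r(lambda) * I(lambda) / mean(I).

    Normalising by the mean irradiance keeps the output on the reflectance
    scale and makes it invariant to rescaling the irradiance.  With
    ``mode="raw"`` the input is passed through unchanged (for analyses that
    want uncorrected per-wavelength values).
    """
    if mode == "raw":
        return replace(r, values=r.values.copy())
    if mode != "weighted":
        raise ValueError("mode must be 'weighted' or 'raw'")
    intensity = sun.on_grid(r.grid)
    mean_i = intensity.mean()
    if mean_i <= 0:
        raise ValueError("irradiance is zero everywhere on the spectrum grid")
    return replace(r, values=r.values * intensity / mean_i, kind="weighted")


def divergence_percent(island_mean: float, mainland_mean: float) -> float:
    """Signed divergence (island - mainland) / island * 100.

    Positive values mean island birds reflect more than mainland birds.
    """
    if island_mean == 0:
        raise ValueError("island mean reflectance is zero; divergence undefined")
    return (island_mean - mainland_mean) / island_mean * 100.0


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values."""
    return multipletests(np.asarray(p_values, dtype=float), method="holm")[1]


def make_bins(
    lo: int = 350, hi: int = 2500, width: int = 100
) -> list[tuple[int, int]]:
    """100-nm bin edges [350,450), ... ; a trailing partial bin is kept."""
    edges = list(range(lo, hi, width))
    return [(e, min(e + width, hi)) for e in edges]


def binned_weighted_means(
    values: np.ndarray,
    wavelengths: np.ndarray,
    intensity: np.ndarray,
    bins: Sequence[tuple[int, int]],
) -> np.ndarray:
    """Solar-weighted mean reflectance per bin for a stack of spectra.

    ``values`` is (n_spectra, n_wavelengths); returns (n_spectra, n_bins).
    Each bin is integrated from its left edge up to and including its right
    edge, so adjacent bins share one grid point as integration endpoint.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    out = np.empty((values.shape[0], len(bins)))
    for j, (lo, hi) in enumerate(bins):
        m = (wavelengths >= lo) & (wavelengths <= hi)
        denom = np.trapezoid(intensity[m], wavelengths[m])
        if denom <= 0:
            raise ValueError(f"zero irradiance in bin [{lo}, {hi}]")
        out[:, j] = np.trapezoid(values[:, m] * intensity[m], wavelengths[m], axis=1) / denom
    return out


def binned_band_tests(
    island: Sequence[ReflectanceSpectrum],
    mainland: Sequence[ReflectanceSpectrum],
    sun: IrradianceSpectrum,
    bin_width: int = 100,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mainland-island comparison of solar-weighted reflectance per 100-nm bin.

    For each bin the per-specimen solar-weighted bin mean is computed, groups
    are compared with a Welch two-sample t-test, and p-values are adjusted
    across bins with Holm-Bonferroni.  ``significant_for`` codes which group
    reflects significantly more ("island", "mainland" or "none"), the sign
    convention of the divergence statistic.
    """
    if len(island) < 2 or len(mainland) < 2:
        raise ValueError("need at least 2 specimens per cohort")
    grid = island[0].grid
    for s in (*island, *mainland):
        if s.grid != grid:
            raise ValueError("all spectra must share one wavelength grid")
    wl = grid.wavelengths
    intensity = sun.on_grid(grid)
    bins = make_bins(grid.start_nm, grid.stop_nm, bin_width)

    isl = binned_weighted_means(np.vstack([s.values for s in island]), wl, intensity, bins)
    mai = binned_weighted_means(np.vstack([s.values for s in mainland]), wl, intensity, bins)

    isl_mean = isl.mean(axis=0)
    mai_mean = mai.mean(axis=0)
    div = np.array(
        [divergence_percent(i, m) for i, m in zip(isl_mean, mai_mean)]
    )
    t, p_raw = stats.ttest_ind(isl, mai, axis=0, equal_var=False)
    p_holm = holm_adjust(p_raw)
    sig = np.where(
        p_holm < alpha, np.where(div > 0, "island", "mainland"), "none"
    )
    return pd.DataFrame(
        {
            "bin_lo_nm": [b[0] for b in bins],
            "bin_hi_nm": [b[1] for b in bins],
            "partial_bin": [(b[1] - b[0]) != bin_width for b in bins],
            "island_mean": isl_mean,
            "mainland_mean": mai_mean,
            "divergence_pct": div,
            "t": t,
            "p_raw": p_raw,
            "p_holm": p_holm,
            "significant_for": sig,
        }
    )
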