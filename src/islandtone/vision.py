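"""Receptor-noise modelling of visual contrast between birds and backgrounds.

Implements the Vorobyev-Osorio receptor-noise-limited model: photoreceptor
quantum catches are integrals of reflectance x illuminant x sensitivity, von
Kries-normalised to the adapting background, and discriminability (Delta S
for chromatic, Delta L for achromatic) is the receptor-signal distance
weighted by receptor noise, in "just noticeable distance" units.  Receptor
sensitivities are generated from the Govardovskii A1 visual-pigment template.

Receptor curves, cone ratios and Weber fractions for raptor-like viewers are
not measured here; the presets follow common practice for violet-sensitive
(peafowl-like) and ultraviolet-sensitive (blue-tit-like) systems and every
parameter can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "govardovskii_a1",
    "ReceptorSet",
    "build_receptor_set",
    "ViewingScene",
    "quantum_catches",
    "chromatic_contrast",
    "achromatic_contrast",
    "contrast_comparison",
    "RECEPTOR_PRESETS",
]

#: discrimination thresholds (noise-weighted Euclidean distances) commonly
#: assumed for birds; 2.0 standard, 1.0 under favourable conditions.
DISCRIMINATION_THRESHOLD = 2.0
DISCRIMINATION_THRESHOLD_LOW = 1.0


def govardovskii_a1(wavelengths_nm: np.ndarray, lambda_max: float) -> np.ndarray:
    """Govardovskii et al. A1 visual-pigment absorbance template.

    Alpha band plus beta band, normalised to unit peak on the supplied grid.
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    if not 300 <= lambda_max <= 700:
        raise ValueError("lambda_max outside 300-700 nm")
    x = lambda_max / wl
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    lam_beta = 189.0 + 0.315 * lambda_max
    b_beta = -40.5 + 0.195 * lambda_max
    beta = 0.26 * np.exp(-(((wl - lam_beta) / b_beta) ** 2))
    s = alpha + beta
    return s / s.max()


@dataclass
class ReceptorSet:
    """Photoreceptor sensitivities, relative densities and Weber fractions."""

    wavelengths: np.ndarray
    sensitivities: np.ndarray  # (n_receptors, n_wavelengths), unit peak each
    densities: np.ndarray  # relative cone densities
    weber: float  # Weber fraction of the most abundant single cone
    double_cone: np.ndarray  # achromatic channel sensitivity
    weber_achromatic: float = 0.1
    label: str = "custom"

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.sensitivities = np.atleast_2d(np.asarray(self.sensitivities, dtype=float))
        self.densities = np.asarray(self.densities, dtype=float)
        self.double_cone = np.asarray(self.double_cone, dtype=float)
        if np.any(self.sensitivities < 0) or np.any(self.double_cone < 0):
            raise ValueError("sensitivities must be >= 0")
        if np.any(self.densities <= 0):
            raise ValueError("densities must be > 0")
        if self.sensitivities.shape[0] != len(self.densities):
            raise ValueError("one density per receptor required")

    @property
    def n_receptors(self) -> int:
        return self.sensitivities.shape[0]

    def noise(self) -> np.ndarray:
        """Per-receptor noise e_i = omega * sqrt(eta_max / eta_i)."""
        return self.weber * np.sqrt(self.densities.max() / self.densities)


#: peak sensitivities (nm) and relative densities for the packaged viewers.
RECEPTOR_PRESETS: dict[str, dict] = {
    "violet_sensitive": {
        "lambda_max": (424.0, 477.0, 537.0, 605.0),
        "densities": (1.0, 1.9, 2.2, 2.1),
        "double_cone_lambda_max": 567.0,
    },
    "uv_sensitive": {
        "lambda_max": (371.0, 448.0, 503.0, 563.0),
        "densities": (1.0, 1.78, 2.21, 1.96),
        "double_cone_lambda_max": 563.0,
    },
}


def build_receptor_set(
    label: str | None = None,
    lambda_max: Sequence[float] | None = None,
    densities: Sequence[float] | None = None,
    weber: float = 0.1,
    weber_achromatic: float = 0.1,
    double_cone_lambda_max: float | None = None,
    wavelengths: np.ndarray | None = None,
) -> ReceptorSet:
    """Build a viewer from a preset label or explicit pigment peaks.

    ``weber`` applies to the most abundant single cone; other receptors'
    noise scales with the inverse square root of relative density.
    """
    if wavelengths is None:
        wavelengths = np.arange(350.0, 701.0)
    if label is not None:
        preset = RECEPTOR_PRESETS.get(label)
        if preset is None:
            raise ValueError(f"unknown preset {label!r}; options {sorted(RECEPTOR_PRESETS)}")
        lambda_max = preset["lambda_max"]
        densities = preset["densities"]
        double_cone_lambda_max = preset["double_cone_lambda_max"]
    else:
        label = "custom"
    if lambda_max is None or densities is None:
        raise ValueError("provide a preset label or lambda_max + densities")
    lam = list(lambda_max)
    if lam != sorted(lam):
        raise ValueError("lambda_max values must be ascending")
    sens = np.vstack([govardovskii_a1(wavelengths, lm) for lm in lam])
    if double_cone_lambda_max is None:
        double_cone_lambda_max = lam[-1]
    double = govardovskii_a1(wavelengths, double_cone_lambda_max)
    return ReceptorSet(
        wavelengths=wavelengths,
        sensitivities=sens,
        densities=np.asarray(densities, dtype=float),
        weber=weber,
        double_cone=double,
        weber_achromatic=weber_achromatic,
        label=label,
    )


@dataclass
class ViewingScene:
    """Illuminant plus viewing-condition label for contrast calculations."""

    wavelengths: np.ndarray
    illuminant: np.ndarray
    condition: str = "custom"  # island_fog | mainland_clear | custom

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.illuminant = np.asarray(self.illuminant, dtype=float)
        if np.any(self.illuminant < 0):
            raise ValueError("illuminant must be >= 0")


def _align(scene: ViewingScene, receptors: ReceptorSet, reflectance, wavelengths):
    """Interpolate reflectance and illuminant onto the receptor grid."""
    wl = receptors.wavelengths
    if wavelengths is not None:
        refl = np.interp(wl, np.asarray(wavelengths, dtype=float), reflectance)
    else:
        refl = np.asarray(reflectance, dtype=float)
        if len(refl) != len(wl):
            raise ValueError("reflectance not on the receptor grid; pass wavelengths")
    illum = np.interp(wl, scene.wavelengths, scene.illuminant)
    return refl, illum


def _raw_catches(refl: np.ndarray, illum: np.ndarray, S: np.ndarray, wl: np.ndarray) -> np.ndarray:
    return np.trapezoid(refl * illum * S, wl, axis=-1)


def quantum_catches(
    reflectance: np.ndarray,
    scene: ViewingScene,
    receptors: ReceptorSet,
    background: np.ndarray | None = None,
    wavelengths: np.ndarray | None = None,
) -> np.ndarray:
    """Per-receptor quantum catches, von Kries normalised if a background is given.

    Q_i = integral R(l) I(l) S_i(l) dl; with a background, catches are divided
    by the background catches (chromatic adaptation), which makes downstream
    contrasts invariant to the illuminant's overall intensity.
    """
    refl, illum = _align(scene, receptors, reflectance, wavelengths)
    q = _raw_catches(refl, illum, receptors.sensitivities, receptors.wavelengths)
    if background is None:
        return q
    bg, _ = _align(scene, receptors, background, wavelengths)
    qb = _raw_catches(bg, illum, receptors.sensitivities, receptors.wavelengths)
    if np.any(qb <= 0):
        raise ValueError("zero background catch in at least one receptor")
    return q / qb


def _delta_f(target, background, scene, receptors, wavelengths):
    qt = quantum_catches(target, scene, receptors, wavelengths=wavelengths)
    qb = quantum_catches(background, scene, receptors, wavelengths=wavelengths)
    if np.any(qt <= 0) or np.any(qb <= 0):
        raise ValueError("non-positive quantum catch; check spectra and illuminant")
    return np.log(qt / qb)


def chromatic_contrast(
    target: np.ndarray,
    background: np.ndarray,
    scene: ViewingScene,
    receptors: ReceptorSet,
    wavelengths: np.ndarray | None = None,
) -> float:
    """Noise-weighted chromatic distance Delta S between target and background.

    Uses the log-linear receptor signal f_i = ln Q_i and the general
    n-receptor noise-limited formula

        Delta S^2 = sum_{i<j} (prod_{k != i,j} e_k^2) (df_i - df_j)^2
                    / sum_i prod_{k != i} e_k^2,

    which reduces to |df_1 - df_2| / sqrt(e_1^2 + e_2^2) for a dichromat.
    """
    if receptors.n_receptors < 2:
        raise ValueError("chromatic contrast needs >= 2 receptor classes")
    df = _delta_f(target, background, scene, receptors, wavelengths)
    e = receptors.noise()
    e2 = e**2
    n = len(e)
    prod_all = np.prod(e2)
    denom = np.sum(prod_all / e2)  # sum_i prod_{k != i} e_k^2
    num = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            num += (prod_all / (e2[i] * e2[j])) * (df[i] - df[j]) ** 2
    return float(np.sqrt(num / denom))


def achromatic_contrast(
    target: np.ndarray,
    background: np.ndarray,
    scene: ViewingScene,
    receptors: ReceptorSet,
    wavelengths: np.ndarray | None = None,
) -> float:
    """Double-cone luminance contrast Delta L = |ln(Q_t / Q_b)| / omega_D."""
    wl = receptors.wavelengths
    t_refl, illum = _align(scene, receptors, target, wavelengths)
    b_refl, _ = _align(scene, receptors, background, wavelengths)
    qt = _raw_catches(t_refl, illum, receptors.double_cone, wl)
    qb = _raw_catches(b_refl, illum, receptors.double_cone, wl)
    if qt <= 0 or qb <= 0:
        raise ValueError("zero double-cone catch")
    return float(abs(np.log(qt / qb)) / receptors.weber_achromatic)


def _per_specimen_contrasts(cohort, backgrounds, scene, receptors, wavelengths):
    """Mean contrast of each specimen over all background samples."""
    rows = []
    for spec in cohort:
        ds = [chromatic_contrast(spec, bg, scene, receptors, wavelengths) for bg in backgrounds]
        dl = [achromatic_contrast(spec, bg, scene, receptors, wavelengths) for bg in backgrounds]
        rows.append((float(np.mean(ds)), float(np.mean(dl))))
    return np.array(rows)  # (n, 2): Delta S, Delta L


def contrast_comparison(
    island: Sequence[np.ndarray],
    mainland: Sequence[np.ndarray],
    backgrounds: Sequence[np.ndarray],
    scene: ViewingScene,
    receptors: ReceptorSet,
    n_boot: int = 2000,
    seed: int | None = None,
    wavelengths: np.ndarray | None = None,
) -> pd.DataFrame:
    """Island vs mainland visual contrast with bootstrap CIs and a linear-model p.

    Per-specimen contrasts (averaged over background samples) are summarised
    per group with percentile bootstrap 95% confidence intervals, and the
    mainland-island difference is tested with a two-group linear model (OLS
    on a group indicator).  One row per channel (chromatic, achromatic).
    """
    if len(island) < 2 or len(mainland) < 2:
        raise ValueError("need >= 2 specimens per cohort")
    if len(backgrounds) == 0:
        raise ValueError("empty background set")
    if n_boot < 100:
        raise ValueError("n_boot too small for a 95% bootstrap CI (need >= 100)")
    rng = np.random.default_rng(seed)
    isl = _per_specimen_contrasts(island, backgrounds, scene, receptors, wavelengths)
    mai = _per_specimen_contrasts(mainland, backgrounds, scene, receptors, wavelengths)

    rows = []
    for ch, name in ((0, "chromatic"), (1, "achromatic")):
        xi, xm = isl[:, ch], mai[:, ch]
        boots_i = rng.choice(xi, size=(n_boot, len(xi))).mean(axis=1)
        boots_m = rng.choice(xm, size=(n_boot, len(xm))).mean(axis=1)
        y = np.concatenate([xm, xi])
        g = np.concatenate([np.zeros(len(xm)), np.ones(len(xi))])
        fit = sm.OLS(y, sm.add_constant(g)).fit()
        rows.append(
            {
                "channel": name,
                "island_mean": xi.mean(),
                "island_ci_lo": np.percentile(boots_i, 2.5),
                "island_ci_hi": np.percentile(boots_i, 97.5),
                "mainland_mean": xm.mean(),
                "mainland_ci_lo": np.percentile(boots_m, 2.5),
                "mainland_ci_hi": np.percentile(boots_m, 97.5),
                "difference": xm.mean() - xi.mean(),
                "diff_ci_lo": np.percentile(boots_m - boots_i, 2.5),
                "diff_ci_hi": np.percentile(boots_m - boots_i, 97.5),
                "p_value": float(fit.pvalues[1]),
            }
        )
    return pd.DataFrame(rows)
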