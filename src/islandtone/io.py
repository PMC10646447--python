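"""Readers, writers, run configuration and the end-to-end pipeline.

CSV dialects
------------
* Spectra (wide): column 1 ``wavelength_nm``, one column per measurement id;
  companion metadata CSV with columns ``measurement_id, specimen_id, taxon,
  population, surface, patch``.
* Irradiance: ``wavelength_nm, irradiance``.
* Climate: ``timestamp, air_temperature_c, wind_m_s, direct_w_m2,
  diffuse_w_m2, albedo, zenith_deg``.

All files written here start with comment headers recording the tool
version, the config hash and the seed, so every output is traceable to the
run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import __version__
from .heatflux import Microclimate
from .spectra import IrradianceSpectrum, ReflectanceSpectrum, WavelengthGrid

__all__ = [
    "read_spectra",
    "write_spectra",
    "read_irradiance",
    "write_irradiance",
    "read_climate",
    "write_climate",
    "read_tree",
    "RunConfig",
    "run_pipeline",
]


def _header_lines(seed: int | None = None, config_hash: str = "") -> str:
    lines = [f"# islandtone {__version__}"]
    if config_hash:
        lines.append(f"# config_hash: {config_hash}")
    if seed is not None:
        lines.append(f"# seed: {seed}")
    return "\n".join(lines) + "\n"


def write_csv(df: pd.DataFrame, path: Path | str, seed: int | None = None, config_hash: str = "") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_lines(seed, config_hash))
        df.to_csv(fh, index=False)


def read_csv(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_spectra(
    spectra: list[ReflectanceSpectrum],
    path: Path | str,
    meta_path: Path | str,
    seed: int | None = None,
) -> None:
    grid = spectra[0].grid
    wide = {"wavelength_nm": grid.wavelengths.astype(int)}
    meta_rows = []
    for i, s in enumerate(spectra):
        mid = f"m{i:04d}"
        wide[mid] = s.values
        meta_rows.append(
            {
                "measurement_id": mid,
                "specimen_id": s.specimen_id,
                "taxon": s.taxon,
                "population": s.population,
                "surface": s.surface,
                "patch": s.patch,
            }
        )
    write_csv(pd.DataFrame(wide), path, seed=seed)
    write_csv(pd.DataFrame(meta_rows), meta_path, seed=seed)


def read_spectra(path: Path | str, meta_path: Path | str) -> list[ReflectanceSpectrum]:
    """Load a wide spectra CSV joined to its metadata table.

    Rows may come in any wavelength order; the grid must be uniform and
    monotone after sorting.  Metadata referencing unknown measurement ids,
    duplicate ids, or measurements without metadata are rejected by name.
    """
    wide = read_csv(path)
    if "wavelength_nm" not in wide.columns:
        raise ValueError(f"{path}: missing 'wavelength_nm' column")
    wide = wide.sort_values("wavelength_nm").reset_index(drop=True)
    wl = wide["wavelength_nm"].to_numpy()
    steps = np.diff(wl)
    if len(steps) == 0 or np.any(steps <= 0) or len(set(steps.tolist())) != 1:
        raise ValueError(f"{path}: wavelength grid is not uniform and monotone")
    grid = WavelengthGrid(int(wl[0]), int(wl[-1]), int(steps[0]))

    meta = read_csv(meta_path)
    if meta["measurement_id"].duplicated().any():
        dup = meta.loc[meta["measurement_id"].duplicated(), "measurement_id"].iloc[0]
        raise ValueError(f"{meta_path}: duplicate measurement_id {dup!r}")
    measurement_cols = [c for c in wide.columns if c != "wavelength_nm"]
    unknown = set(meta["measurement_id"]) - set(measurement_cols)
    if unknown:
        raise ValueError(f"{meta_path}: metadata for unknown measurement id(s) {sorted(unknown)}")
    missing = set(measurement_cols) - set(meta["measurement_id"])
    if missing:
        raise ValueError(f"{path}: measurement(s) without metadata: {sorted(missing)}")

    meta = meta.set_index("measurement_id")
    out = []
    for mid in measurement_cols:
        row = meta.loc[mid]
        out.append(
            ReflectanceSpectrum(
                grid=grid,
                values=wide[mid].to_numpy(dtype=float),
                specimen_id=str(row["specimen_id"]),
                taxon=str(row["taxon"]),
                population=str(row["population"]),
                surface=str(row["surface"]),
                patch=str(row["patch"]),
            )
        )
    return out


def write_irradiance(sun: IrradianceSpectrum, path: Path | str, seed: int | None = None) -> None:
    write_csv(
        pd.DataFrame({"wavelength_nm": sun.wavelengths, "irradiance": sun.intensity}),
        path,
        seed=seed,
    )


def read_irradiance(path: Path | str) -> IrradianceSpectrum:
    df = read_csv(path).sort_values("wavelength_nm")
    wl = df["wavelength_nm"].to_numpy()
    step = int(np.diff(wl)[0]) if len(wl) > 1 else 1
    grid = WavelengthGrid(int(wl[0]), int(wl[-1]), step)
    return IrradianceSpectrum(grid=grid, intensity=df["irradiance"].to_numpy(dtype=float))


_CLIMATE_COLS = {
    "air_temperature_c": "air_temperature_c",
    "wind_m_s": "wind_m_s",
    "direct_w_m2": "direct_w_m2",
    "diffuse_w_m2": "diffuse_w_m2",
    "albedo": "albedo",
    "zenith_deg": "zenith_deg",
}


def write_climate(climate: Microclimate, path: Path | str, seed: int | None = None) -> None:
    df = pd.DataFrame({k: getattr(climate, k) for k in _CLIMATE_COLS})
    df.insert(0, "timestamp", climate.timestamp if climate.timestamp is not None else np.arange(len(climate)))
    write_csv(df, path, seed=seed)


def read_climate(path: Path | str) -> Microclimate:
    df = read_csv(path)
    return Microclimate(
        timestamp=df["timestamp"].to_numpy(),
        **{k: df[k].to_numpy(dtype=float) for k in _CLIMATE_COLS},
    )


def read_tree(path: Path | str) -> dendropy.Tree:
    """Parse a newick tree; duplicate tips are rejected, polytomies reported."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"{path}: malformed newick ({exc})") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError(f"{path}: duplicate tip labels")
    return tree


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class RunConfig:
    """End-to-end run settings; every stage seed derives from ``seed``."""

    out_dir: Path = Path("islandtone_results")
    seed: int = 1
    band: str = "VIS"
    n_perm: int = 199
    n_boot: int = 500
    n_hours: int = 8760
    viewer: str = "violet_sensitive"
    exclude_taxa: tuple[str, ...] = ()

    def config_hash(self) -> str:
        # hash the analysis settings only, not where results are written
        payload = json.dumps(
            {k: str(v) for k, v in self.__dict__.items() if k != "out_dir"},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    # one root SeedSequence split per stage keeps stages independent
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def run_pipeline(config: RunConfig) -> dict:
    """Simulate fixtures and run every analysis stage; write a JSON summary.

    Stages: cohort generation -> solar correction + 100-nm bin tests ->
    trajectory statistics -> visual contrast -> heat-flux year ->
    phylogenetic signal.  A failure in any stage aborts with the stage name.
    """
    from . import heatflux, phylosignal, spectra, synthetic, trajectory, vision

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    seeds = _stage_seeds(config.seed)
    summary: dict = {"seed": config.seed, "config_hash": chash, "version": __version__}

    stage = "synthetic_data"
    try:
        cohorts = synthetic.gen_all_cohorts(seed=seeds[0])
        sun = synthetic.gen_solar_spectrum()
        scene_data = synthetic.gen_scene(seed=seeds[1])

        stage = "spectra_core"
        band = spectra.BANDS[config.band]
        div = {}
        for taxon, c in cohorts.items():
            isl = np.mean([spectra.solar_weighted_reflectance(s, sun, band) for s in c["island"]])
            mai = np.mean([spectra.solar_weighted_reflectance(s, sun, band) for s in c["mainland"]])
            div[taxon] = spectra.divergence_percent(float(isl), float(mai))
        first = next(iter(cohorts.values()))
        bins = spectra.binned_band_tests(first["island"], first["mainland"], sun)
        write_csv(bins, out / "bin_tests.csv", seed=config.seed, config_hash=chash)
        summary["spectra"] = {
            "divergence_pct": div,
            "significant_bins": int((bins["significant_for"] != "none").sum()),
        }

        stage = "trajectory"
        keep = [t for t in cohorts if t not in config.exclude_taxa]
        mask = band.mask(first["island"][0].wavelengths)
        ts = trajectory.TrajectorySet(
            {
                t: (
                    np.vstack([s.values[mask] for s in cohorts[t]["mainland"]]),
                    np.vstack([s.values[mask] for s in cohorts[t]["island"]]),
                )
                for t in keep
            },
            band=config.band,
        )
        perm = trajectory.permutation_pairwise(ts, n_perm=config.n_perm, seed=seeds[2])
        write_csv(perm["lengths"], out / "trajectory_lengths.csv", seed=config.seed, config_hash=chash)
        write_csv(perm["pairs"], out / "trajectory_pairs.csv", seed=config.seed, config_hash=chash)
        summary["trajectory"] = {
            "mean_pairwise_correlation": float(perm["pairs"]["correlation"].mean()),
            "mean_pairwise_angle_deg": float(perm["pairs"]["angle_deg"].mean()),
            "disparity_island": trajectory.disparity_by_side(ts, "island"),
            "disparity_mainland": trajectory.disparity_by_side(ts, "mainland"),
        }

        stage = "vision"
        receptors = vision.build_receptor_set(config.viewer)
        scene = vision.ViewingScene(
            wavelengths=scene_data["illuminant_wavelengths"],
            illuminant=scene_data["illuminant_fog"],
            condition="island_fog",
        )
        from .srgb2spec import extend_to_pipeline_grid, reconstruct_spectrum

        soils = []
        for _, row in scene_data["island_soils"].iterrows():
            refl, _info = reconstruct_spectrum(np.array([row.r, row.g, row.b]))
            soils.append(extend_to_pipeline_grid(refl).values)
        grid_wl = first["island"][0].wavelengths
        comp = vision.contrast_comparison(
            [s.values for s in first["island"]],
            [s.values for s in first["mainland"]],
            soils,
            scene,
            receptors,
            n_boot=config.n_boot,
            seed=seeds[3],
            wavelengths=grid_wl,
        )
        write_csv(comp, out / "visual_contrast.csv", seed=config.seed, config_hash=chash)
        summary["vision"] = {
            r["channel"]: {"difference": float(r["difference"]), "p": float(r["p_value"])}
            for _, r in comp.iterrows()
        }

        stage = "heatflux"
        climate = synthetic.gen_climate(preset="island", n_hours=config.n_hours, seed=seeds[4])
        spec0 = synthetic.DEFAULT_COHORTS[0]
        r_isl = float(np.mean([spectra.solar_weighted_reflectance(s, sun, "FULL") for s in first["island"]]))
        r_mai = float(np.mean([spectra.solar_weighted_reflectance(s, sun, "FULL") for s in first["mainland"]]))
        morph_i = heatflux.allometric_morph(spec0.mass_g, r_isl)
        morph_m = heatflux.allometric_morph(spec0.mass_g, r_mai)
        annual = heatflux.annual_simulation(morph_i, morph_m, climate)
        summary["heatflux"] = {
            "annual_mean_differential_pct_bmr": annual["annual_mean_differential"],
            "midday_mean_differential_pct_bmr": annual["midday_mean_differential"],
            "fraction_daylight_heating": annual["fraction_daylight_heating"],
        }

        stage = "phylosignal"
        tree, trait = synthetic.gen_tree_and_trait(seed=seeds[5])
        d_res = phylosignal.estimate_D(tree, trait, n_perm=config.n_perm, seed=seeds[6])
        summary["phylosignal"] = {"D": d_res["D"], "p_random": d_res["p_random"]}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
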