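"""End-to-end orchestration: simulate → render → quantify → fit → friction.

A :class:`RunConfig` (loadable from a single YAML file) selects stages and
carries every tunable; one global seed fans out deterministically to
per-stage child seeds through ``numpy.random.SeedSequence(seed, stage_key)``
so stages can be re-run independently without perturbing each other.  Every
run writes a JSON metadata file echoing the full effective configuration,
package version, derived seeds and per-stage wall times: metadata plus
config fully determine every output byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .frictionlaws import (
    JKRParams,
    MaterialSpec,
    figure_material_curves,
    fit_amonton_extended,
    growth_rate_C,
    rigid_mu,
    shear_stress_series,
)
from .imquant import quantify_image
from .padmech import UM2_PER_MM2, FibrilBed, PadGeometry, sweep_loads
from .scalestats import (
    add_real_contact_area,
    fit_all_responses,
    real_contact_area,
    summarize_by_load,
)
from .synthgen import (
    SynthParams,
    make_population,
    render_contact_image,
    synth_friction,
)
from .padmech import solve_indentation

logger = logging.getLogger("frictionpad")

ALL_STAGES = ("simulate", "render", "quantify", "fit", "friction")

#: Canonical observation-table schema (CSV).
OBS_SCHEMA = ("individual_id", "load_mN", "A_A_mm2", "N_A_per_um2",
              "A_Ac_um2", "A_R_um2", "friction_mN")

_STAGE_KEYS = {name: i for i, name in enumerate(ALL_STAGES)}


@dataclass
class RunConfig:
    """Full configuration of one pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    synth: SynthParams = field(default_factory=SynthParams)
    bed_overrides: dict = field(default_factory=dict)
    pad: PadGeometry = field(default_factory=PadGeometry)
    pixel_scale: float = 0.05
    connectivity: int = 8
    sample_fraction: float = 1.0
    render_window_um: float = 30.0
    render_load_mN: float = 2.0
    render_noise_sd: float = 0.02
    n_boot: int = 2000
    ci_level: float = 0.95
    observations_csv: str | None = None  # stats-only runs on existing data

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        synth = SynthParams(**raw.pop("synth", {}))
        pad = PadGeometry(**raw.pop("pad", {}))
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(synth=synth, pad=pad, **raw)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage child seed derived from the global seed."""
        ss = np.random.SeedSequence([self.seed, _STAGE_KEYS[stage]])
        return int(ss.generate_state(1)[0] % (2**31))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pad"] = dataclasses.asdict(self.pad)
        d["synth"] = dataclasses.asdict(self.synth)
        return d


# ---------------------------------------------------------------------------
# observation-table I/O and validation
# ---------------------------------------------------------------------------
def write_observations(obs: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in OBS_SCHEMA if c in obs.columns]
    obs.to_csv(path, index=False, columns=cols)


def read_observations(path: str | Path) -> pd.DataFrame:
    obs = pd.read_csv(path)
    report = validate_observations(obs)
    if report["violations"]:
        v = report["violations"][0]
        raise ValueError(
            f"invalid observations file {path}: row {v['row']}, column "
            f"{v['column']}: {v['message']} "
            f"({len(report['violations'])} violation(s) total)")
    return obs


def validate_observations(obs: pd.DataFrame | str | Path) -> dict:
    """Schema and invariant check of an observation table.

    Returns ``{"n_rows": ..., "violations": [{"row", "column", "message"},
    ...]}``; an empty violation list means the table is valid.  Checks:
    required columns, strictly positive loads, non-negative areas and
    densities, and consistency of any A_R column with the decomposition
    A_A·N_A·A_Ac to 1e-6 relative.
    """
    if not isinstance(obs, pd.DataFrame):
        obs = pd.read_csv(obs)
    violations: list[dict] = []
    required = ("individual_id", "load_mN", "A_A_mm2", "N_A_per_um2",
                "A_Ac_um2")
    for col in required:
        if col not in obs.columns:
            violations.append({"row": -1, "column": col,
                               "message": "required column missing"})
    if violations:
        return {"n_rows": len(obs), "violations": violations}

    for idx, row in obs.iterrows():
        if not row["load_mN"] > 0:
            violations.append({"row": int(idx), "column": "load_mN",
                               "message": f"load {row['load_mN']} not > 0"})
        for col in ("A_A_mm2", "N_A_per_um2", "A_Ac_um2"):
            if row[col] < 0:
                violations.append({"row": int(idx), "column": col,
                                   "message": f"negative value {row[col]}"})
    if "A_R_um2" in obs.columns:
        expected = real_contact_area(
            obs["A_A_mm2"].clip(lower=0), obs["N_A_per_um2"].clip(lower=0),
            obs["A_Ac_um2"].clip(lower=0))
        rel = np.abs(obs["A_R_um2"].to_numpy() - expected) / np.maximum(
            np.abs(expected), 1e-300)
        for idx in np.nonzero(rel > 1e-6)[0]:
            violations.append({
                "row": int(obs.index[idx]), "column": "A_R_um2",
                "message": "inconsistent with A_A·N_A·A_Ac beyond 1e-6 "
                           f"relative (rel err {rel[idx]:.2e})"})
    return {"n_rows": len(obs), "violations": violations}


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------
def _simulate(config: RunConfig) -> pd.DataFrame:
    params = dataclasses.replace(config.synth,
                                 seed=config.stage_seed("simulate"))
    items, _records = make_population(params, pad=config.pad)
    if config.bed_overrides:
        items = [(dataclasses.replace(bed, **config.bed_overrides), pad)
                 for bed, pad in items]
    frames = []
    for i, (bed, pad) in enumerate(items):
        frames.append(sweep_loads(bed, pad, list(params.loads),
                                  individual_id=f"ind{i:02d}"))
    obs = pd.concat(frames, ignore_index=True)
    obs = add_real_contact_area(obs)
    obs["friction_mN"] = synth_friction(
        obs["A_R_um2"].to_numpy(), tau=params.tau_true,
        noise_sd=params.friction_noise_sd, seed=config.stage_seed("simulate"))
    return obs


def run(config: RunConfig) -> Path:
    """Execute the selected stages; returns the run directory.

    Partial stage selection is supported: ``fit``/``friction`` without
    ``simulate`` read ``observations_csv`` (or a previous run's
    observations.csv in the same directory).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta: dict = {"package_version": __version__,
                  "config": config.to_dict(),
                  "stage_seeds": {s: config.stage_seed(s)
                                  for s in config.stages},
                  "timings_s": {}}
    obs: pd.DataFrame | None = None

    def _load_obs() -> pd.DataFrame:
        nonlocal obs
        if obs is None:
            src = config.observations_csv or out / "observations.csv"
            logger.info("loading observations from %s", src)
            obs = read_observations(src)
        if "A_R_um2" not in obs.columns:
            obs = add_real_contact_area(obs)
        return obs

    for stage in config.stages:
        t0 = time.perf_counter()
        logger.info("stage %s", stage)
        if stage == "simulate":
            obs = _simulate(config)
            write_observations(obs, out / "observations.csv")
        elif stage == "render":
            params = dataclasses.replace(
                config.synth, seed=config.stage_seed("simulate"))
            items, _ = make_population(params, pad=config.pad)
            bed, pad = items[0]
            if config.bed_overrides:
                bed = dataclasses.replace(bed, **config.bed_overrides)
            state = solve_indentation(bed, pad, config.render_load_mN)
            h = config.render_window_um / 2
            img = render_contact_image(
                state, pixel_scale=config.pixel_scale,
                noise_sd=config.render_noise_sd,
                seed=config.stage_seed("render"),
                region=(-h, -h, h, h))
            img.save(out / "contact_image.tif")
        elif stage == "quantify":
            from .imquant import ContactImage

            img = ContactImage.load(out / "contact_image.tif")
            table, summary = quantify_image(
                img, connectivity=config.connectivity,
                sample_fraction=config.sample_fraction,
                seed=config.stage_seed("quantify"))
            table.to_csv(out / "particles.csv", index=False)
            pd.DataFrame([summary]).to_csv(out / "image_summary.csv",
                                           index=False)
        elif stage == "fit":
            data = _load_obs()
            summarize_by_load(data).to_csv(out / "load_summary.csv",
                                           index=False)
            fits = fit_all_responses(data)
            fits.to_csv(out / "powerlaw_fits.csv", index=False)
        elif stage == "friction":
            data = _load_obs()
            if "friction_mN" not in data.columns:
                raise ValueError("friction stage needs a friction_mN column")
            med = data.groupby("load_mN")["friction_mN"].median()
            ffit = fit_amonton_extended(med.index.to_numpy(),
                                        med.to_numpy())
            tau_rep = shear_stress_series(
                data["friction_mN"].to_numpy(), data["A_R_um2"].to_numpy(),
                obs=data)
            C = growth_rate_C(data["load_mN"],
                              data["A_R_um2"] / UM2_PER_MM2)
            pd.DataFrame([{
                "mu": ffit.mu, "F0_mN": ffit.F0, "F_adh_mN": ffit.F_adh,
                "tau_median_MPa": tau_rep.median, "tau_mad_MPa": tau_rep.mad,
                "tau_friedman_chi2": (tau_rep.friedman.statistic
                                      if tau_rep.friedman else np.nan),
                "tau_friedman_p": (tau_rep.friedman.pvalue
                                   if tau_rep.friedman else np.nan),
                "C_mm2_per_mN": C,
                "mu_tauC": rigid_mu(tau_rep.median, C),
            }]).to_csv(out / "friction_fit.csv", index=False)

            pad_fit = fit_all_responses(data)
            arow = pad_fit[pad_fit.parameter == "A_R_um2"].iloc[0]
            materials = [
                MaterialSpec(name="pad_power_law", law="power_law",
                             tau_MPa=tau_rep.median,
                             prefactor_mm2=10**arow.intercept / UM2_PER_MM2,
                             exponent=arow.slope),
                MaterialSpec(name="steel", law="linear_C", tau_MPa=800.0,
                             C_mm2_per_mN=1.0e-6),
                MaterialSpec(name="soft_sphere_jkr", law="jkr",
                             jkr=JKRParams()),
            ]
            grid = np.linspace(0.0, 4.0, 81)
            figure_material_curves(materials, grid).to_csv(
                out / "material_curves.csv", index=False)
        meta["timings_s"][stage] = round(time.perf_counter() - t0, 3)

    (out / "run_metadata.json").write_text(
        json.dumps(meta, indent=2, default=str))
    return out
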