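"""End-to-end driver: simulate -> downscale -> fit -> project -> bioecon -> summarize.

``run_pipeline`` executes every stage in order from a single
:class:`~fishcast.config.PipelineConfig`, writes all artefacts under the
configured output directory, and returns a manifest recording each output
with its SHA-256 checksum, the producing stage, the config hash and the
seed. Re-running with an identical config reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import abundance, bioeconomics, downscale, gridio, summaries, synthetic
from .config import PRESENT_PERIOD, PipelineConfig

log = logging.getLogger("fishcast")


def config_hash(config: PipelineConfig) -> str:
    from .config import _as_plain

    blob = json.dumps(_as_plain(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return the output manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    manifest: dict = {
        "config_hash": chash,
        "seed": config.seed,
        "switches": asdict(config.switches),
        "outputs": [],
    }
    log.info("run %s: switch values %s", chash, manifest["switches"])

    def record(stage: str, path: Path) -> None:
        manifest["outputs"].append(
            {
                "stage": stage,
                "path": str(path.relative_to(out)),
                "sha256": gridio.file_checksum(path),
            }
        )

    syn = config.synthetic
    syn.seed = config.seed

    stage = "simulate"
    try:
        clim = synthetic.generate_environment(syn)
        niches = synthetic.default_niches(syn)
        surveys = synthetic.sample_surveys(clim.fine, niches, syn)
        params = synthetic.generate_reference_params(syn.n_species, seed=config.seed)
        geo = synthetic.generate_geography(syn, clim.marine_mask)

        gridio.write_grid(clim.fine, out / "env_present.nc")
        record(stage, out / "env_present.nc")
        surveys.to_csv(out / "surveys.csv", index=False)
        record(stage, out / "surveys.csv")
        synthetic.write_reference_params(params, out / "params.csv")
        record(stage, out / "params.csv")
        gridio.write_ports_geojson(geo.ports, out / "ports.geojson")
        record(stage, out / "ports.geojson")
        gridio.write_eez_geojson(geo.eez, out / "eez.geojson")
        record(stage, out / "eez.geojson")
        gridio.write_grid(geo.effort, out / "effort.nc")
        record(stage, out / "effort.nc")
    except Exception as e:  # noqa: BLE001 - abort with the failing stage named
        raise PipelineError(stage, e) from e

    stage = "downscale"
    try:
        env_stacks = {("", PRESENT_PERIOD): clim.fine}
        for scen in config.scenario_names:
            for period in config.periods:
                env_stacks[(scen, period)] = downscale.downscale_stack(
                    clim.coarse_hist,
                    clim.coarse_future,
                    clim.fine,
                    scen,
                    period,
                    method=config.switches.resampling,
                )
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    stage = "fit"
    try:
        models = {}
        for niche in niches:
            sub = surveys[surveys["species"] == niche.species]
            train, test = abundance.split_train_test(sub, seed=config.seed)
            rf_spec = abundance.TunedModelSpec(
                "rf", {"n_trees": 300, "max_features": 3, "min_node_size": 5}
            )
            brt_spec = abundance.TunedModelSpec(
                "brt",
                {"n_trees": 300, "learning_rate": 0.05, "interaction_depth": 3},
            )
            models[niche.species] = abundance.fit_ensemble(
                train,
                test,
                rf_spec,
                brt_spec,
                seed=config.seed,
                species=niche.species,
                log1p_response=config.switches.log1p_response,
            )
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    stage = "project"
    try:
        surfaces = {}
        for (scen, period), env in env_stacks.items():
            for sp, model in models.items():
                surfaces[(sp, period, scen)] = abundance.predict_surface(model, env)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    stage = "bioecon"
    try:
        species_df, fleet = bioeconomics.bioecon_table(
            surfaces,
            params,
            region_mask=geo.eez["east"],
            sensitivities=config.sensitivities,
            msy_exponent_sign=config.switches.msy_exponent_sign,
        )
        species_df.to_csv(out / "bioecon_species.csv", index=False)
        record(stage, out / "bioecon_species.csv")
        fleet.to_csv(out / "bioecon_fleet.csv", index=False)
        record(stage, out / "bioecon_fleet.csv")
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    stage = "summarize"
    try:
        tracks = summaries.cog_tracks(surfaces)
        tracks.to_csv(out / "cog_tracks.csv", index=False)
        record(stage, out / "cog_tracks.csv")

        pct = summaries.percent_change_table(fleet)
        pct.to_csv(out / "percent_changes.csv", index=False)
        record(stage, out / "percent_changes.csv")

        grounds = summaries.fishing_ground_compare(
            geo.effort,
            config.switches.effort_threshold_hours,
            surfaces,
            geo.eez,
            params,
            msy_exponent_sign=config.switches.msy_exponent_sign,
        )
        grounds.to_csv(out / "fishing_grounds.csv", index=False)
        record(stage, out / "fishing_grounds.csv")

        profiles = []
        for port in geo.ports.itertuples():
            for (scen, period), _env in env_stacks.items():
                total_mcp = None
                for sp, model in models.items():
                    u = params.set_index("species").loc[sp, "u_msy"]
                    surf = surfaces[(sp, period, scen)] * float(u)
                    total_mcp = surf if total_mcp is None else total_mcp + surf
                prof = summaries.port_buffer_profile(
                    total_mcp,
                    port.lon,
                    port.lat,
                    jurisdiction_mask=geo.eez["east"],
                )
                prof["port"] = port.port
                prof["period"] = period
                prof["scenario"] = scen
                profiles.append(prof)
        pd.concat(profiles, ignore_index=True).to_csv(
            out / "buffer_profiles.csv", index=False
        )
        record(stage, out / "buffer_profiles.csv")
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
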