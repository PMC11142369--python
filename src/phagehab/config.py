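"""Run configuration, validation and the end-to-end pipeline.

A run config is a small JSON or YAML document with optional sections
``geometry``, ``transport``, ``mutation``, ``eco`` and ``run``; every field
left out falls back to the device preset (feed titer 2×10⁹ virions/ml,
D = 8×10⁻⁸ cm²/s, Θ_D = 2×10⁻⁹ per division, 10⁴-cell inoculum, 20 h
gradient pre-run).  Unknown keys are rejected with an aggregated report, so
typos cannot silently revert a parameter to its default.

``pipeline_run`` chains the stages the experiment chains: gradient pre-run →
spatial eco-evolutionary run → hot-spot detection → mutation-rate estimates,
writing field.csv, record.csv, estimates.json and run.log with a provenance
block (config hash, seeds, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .geometry import DeviceLayout, build_hex_array, inoculum_count, medium_volume, reference_layout
from .kinetics import GrowthContext, MutationParams, estimate_theta_L, generations_elapsed
from .transport import TransportParams, simulate_gradient
from .ecoevo import EcoParams, detect_hotspots, run_experiment

__all__ = ["GeometryConfig", "RunSettings", "RunConfig", "load_config", "pipeline_run"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GeometryConfig:
    preset: str = "reference"          # or "custom"
    layout_path: str | None = None
    rows: int = 6
    cols: int = 75
    target_area_mm2: float = 40.0

    def build(self) -> DeviceLayout:
        if self.layout_path:
            return DeviceLayout.from_json(Path(self.layout_path).read_text())
        if self.preset == "reference":
            return reference_layout()
        return build_hex_array(self.rows, self.cols, target_area_mm2=self.target_area_mm2)


@dataclass(frozen=True)
class RunSettings:
    duration_h: float = 24.0
    pre_run_h: float = 20.0
    seed: int = 0
    initial_cells: int = 10_000
    dt_h: float = 0.001
    record_every: int = 100
    hotspot_threshold: int = 100


@dataclass
class RunConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    transport: TransportParams = field(default_factory=TransportParams)
    mutation: MutationParams = field(default_factory=MutationParams)
    eco: EcoParams = field(default_factory=EcoParams)
    run: RunSettings = field(default_factory=RunSettings)

    def validate(self) -> None:
        errors = []
        try:
            self.transport.validate()
        except ValueError as e:
            errors.append(f"transport: {e}")
        try:
            self.mutation.validate()
        except ValueError as e:
            errors.append(f"mutation: {e}")
        try:
            self.eco.validate()
        except ValueError as e:
            errors.append(f"eco: {e}")
        if self.run.duration_h < 0:
            errors.append("run: duration_h must be non-negative")
        if self.run.dt_h <= 0:
            errors.append("run: dt_h must be positive")
        if self.geometry.layout_path and not Path(self.geometry.layout_path).exists():
            errors.append(f"geometry: layout file not found: {self.geometry.layout_path}")
        if errors:
            raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))

    def to_dict(self) -> dict:
        return {
            "geometry": dataclasses.asdict(self.geometry),
            "transport": dataclasses.asdict(self.transport),
            "mutation": dataclasses.asdict(self.mutation),
            "eco": dataclasses.asdict(self.eco),
            "run": dataclasses.asdict(self.run),
        }

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


_SECTIONS = {
    "geometry": GeometryConfig,
    "transport": TransportParams,
    "mutation": MutationParams,
    "eco": EcoParams,
    "run": RunSettings,
}


def _build_section(cls, payload: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - known
    if unknown:
        raise ConfigError(f"unknown keys in section '{section}': {sorted(unknown)}")
    return cls(**payload)


def load_config(source: str | Path | dict | None = None) -> RunConfig:
    """Load and validate a run configuration.

    ``source`` may be a path to a JSON/YAML file, an already-parsed mapping,
    or None/empty for the full device preset.  Unknown sections or keys are
    reported by name.
    """
    if source is None:
        doc: dict = {}
    elif isinstance(source, dict):
        doc = source
    else:
        text = Path(source).read_text()
        doc = yaml.safe_load(text) or {}
        if not isinstance(doc, dict):
            raise ConfigError("config document must be a mapping")
    unknown = set(doc) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    kwargs = {
        name: _build_section(cls, doc.get(name, {}) or {}, name) for name, cls in _SECTIONS.items()
    }
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg


def dump_config(cfg: RunConfig) -> str:
    return yaml.safe_dump(cfg.to_dict(), sort_keys=True)


def pipeline_run(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Execute pre-run → experiment → estimation; returns the output dir."""
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"phagehab {__version__}",
        f"config sha256[:16] {cfg.digest()}",
        f"seed {cfg.run.seed}",
    ]

    def _stage(name):
        log_lines.append(f"stage: {name}")

    try:
        _stage("geometry")
        layout = cfg.geometry.build()
        log_lines.append(
            f"  chambers={layout.n_chambers} area={layout.total_area_mm2():.2f} mm2 "
            f"volume={medium_volume(layout):.3f} ul"
        )

        _stage("transport pre-run")
        total_h = cfg.run.pre_run_h + cfg.run.duration_h
        params = cfg.transport
        field_full = simulate_gradient(layout, params, duration_h=max(total_h, params.time_step_s / 3600.0),
                                       store_every=max(1, int(round(360.0 / params.time_step_s))))
        field = field_full.after(cfg.run.pre_run_h * 3600.0)
        fdf = field.to_frame()
        field_csv = out / "field.csv"
        with open(field_csv, "w") as fh:
            fh.write("# time_s [s], chamber_id, concentration [virions/ml]\n")
            fdf.to_csv(fh, index=False)

        estimates: dict = {}
        record_csv = out / "record.csv"
        if cfg.run.duration_h > 0:
            _stage("eco-evo experiment")
            record = run_experiment(
                layout,
                field,
                cfg.eco,
                cfg.mutation,
                duration_h=cfg.run.duration_h,
                seed=cfg.run.seed,
                dt_h=cfg.run.dt_h,
                record_every=cfg.run.record_every,
                initial_cells=cfg.run.initial_cells,
            )
            rdf = record.to_frame()
            with open(record_csv, "w") as fh:
                fh.write("# time_h [h], chamber_id, S/I/R/P [cells or virions], nutrient [divisions]\n")
                rdf.to_csv(fh, index=False)

            _stage("estimation")
            hotspots = detect_hotspots(record, threshold=cfg.run.hotspot_threshold)
            estimates["hotspots"] = [
                {"chamber_id": cid, "first_crossing_h": t} for cid, t in hotspots[:10]
            ]
            if hotspots:
                t_detect = hotspots[0][1]
                G, G_round = generations_elapsed(t_detect, cfg.mutation)
                g = max(1, int(round(G)))
                est = estimate_theta_L(GrowthContext(N_o=cfg.run.initial_cells, g=g, k=1))
                estimates["first_detection_h"] = t_detect
                estimates["first_detection_generations"] = g
                estimates["theta_L_estimate"] = est.value
                estimates["theta_L_order_of_magnitude"] = est.order_of_magnitude
        else:
            with open(record_csv, "w") as fh:
                fh.write("# time_h [h], chamber_id, S/I/R/P [cells or virions], nutrient [divisions]\n")
                fh.write("time_h,chamber_id,S,I,R,P,nutrient\n")

        count, rounded = inoculum_count(2e8, layout.inlet.well_volume_ul)
        estimates["inoculum_expected_cells"] = count
        estimates["inoculum_power_of_ten"] = rounded
        estimates["provenance"] = {
            "version": __version__,
            "config_digest": cfg.digest(),
            "seed": cfg.run.seed,
        }
        (out / "estimates.json").write_text(json.dumps(estimates, indent=1, sort_keys=True))
    except Exception as e:  # noqa: BLE001 - stage-tagged abort
        log_lines.append(f"FAILED: {e}")
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        raise
    log_lines.append("done")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
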