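"""Synthetic datasets with known ground truth for estimator validation.

Three scenarios are emulated, mirroring the experiment's operating point
(N₀ = 10⁴ founders, ~30 generations of exposure, stress-induced rates of
order 10⁻⁵ per division):

fluctuation_assay   parallel-culture resistant counts (the classic
                    well-mixed-flask design) from the branching simulator;
first_detection     per-replicate generation at which the first resistant
                    lineage arises in a constant exposed pool — the record
                    type from which the Θ_L estimator is inverted;
spatial_record      a miniature spatial run with a planted resistant
                    hot-spot chamber, for detector unit tests.

Every generated table is written next to a JSON ground-truth sidecar holding
the true parameters and seeds; recovery tests read truth only from the
sidecar, never from the table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .branching import run_fluctuation_assay
from .kinetics import MutationParams
from .ecoevo import EcoParams, SimulationRecord, run_experiment
from .geometry import build_hex_array
from .transport import ConcentrationField

__all__ = [
    "SyntheticSpec",
    "make_fluctuation_dataset",
    "make_detection_dataset",
    "make_spatial_fixture",
]

SCENARIOS = ("fluctuation_assay", "first_detection", "spatial_record")


@dataclass
class SyntheticSpec:
    """Ground-truth description of one synthetic dataset."""

    scenario: str
    mutation: MutationParams = field(default_factory=MutationParams)
    eco: EcoParams = field(default_factory=EcoParams)
    n_replicates: int = 200
    N_o: int = 10_000
    generations: int = 30
    exposed: bool = False
    root_seed: int = 0

    def validate(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; pick one of {SCENARIOS}")
        if self.n_replicates < 1:
            raise ValueError("replicate count must be >= 1")
        self.mutation.validate()


def _write_sidecar(out_dir: Path, spec: SyntheticSpec, extra: dict) -> None:
    doc = {
        "scenario": spec.scenario,
        "truth": {
            "theta_D": spec.mutation.theta_D,
            "theta_L": spec.mutation.theta_L,
            "target_size": spec.mutation.target_size,
            "N_o": spec.N_o,
            "generations": spec.generations,
            "exposed": spec.exposed,
        },
        "root_seed": spec.root_seed,
        **extra,
    }
    (out_dir / "truth.json").write_text(json.dumps(doc, indent=1))


def make_fluctuation_dataset(spec: SyntheticSpec, out_dir: str | Path | None = None) -> pd.DataFrame:
    """Replicate fluctuation-assay outcomes with a ground-truth sidecar."""
    spec.validate()
    if spec.scenario != "fluctuation_assay":
        raise ValueError("spec.scenario must be 'fluctuation_assay'")
    schedule = [spec.exposed] * spec.generations
    _, outcomes = run_fluctuation_assay(
        max(spec.n_replicates, 2),
        spec.N_o,
        spec.generations,
        spec.mutation,
        exposure_schedule=schedule,
        base_seed=spec.root_seed,
    )
    outcomes = outcomes[: spec.n_replicates]
    df = pd.DataFrame(
        {
            "replicate_id": np.arange(len(outcomes)),
            "seed": [o.seed for o in outcomes],
            "total_cells": [o.total_cells for o in outcomes],
            "resistant_cells": [o.resistant_cells for o in outcomes],
            "first_resistant_generation": [o.first_resistant_generation for o in outcomes],
        }
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "fluctuation.csv", index=False)
        _write_sidecar(out, spec, {"table": "fluctuation.csv"})
    return df


def make_detection_dataset(spec: SyntheticSpec, out_dir: str | Path | None = None) -> pd.DataFrame:
    """First-detection generations for a constant exposed pool of N₀ cells.

    Each generation every cell divides (the pool is held at N₀ by the phage
    pressure) and a first resistant lineage appears with per-generation
    probability 1 − (1 − p)^N₀, p = m·Θ_D + Θ_L·[exposed] — a geometric
    waiting time.  Replicates that never detect within ``generations`` get a
    missing value.
    """
    spec.validate()
    if spec.scenario != "first_detection":
        raise ValueError("spec.scenario must be 'first_detection'")
    p = spec.mutation.target_size * spec.mutation.theta_D + (
        spec.mutation.theta_L if spec.exposed else 0.0
    )
    rng = np.random.default_rng(np.random.SeedSequence(spec.root_seed))
    detected: list[float] = []
    for _ in range(spec.n_replicates):
        gen = None
        if p > 0:
            mutants = rng.binomial(spec.N_o, p, size=spec.generations)
            hits = np.nonzero(mutants > 0)[0]
            if hits.size:
                gen = int(hits[0]) + 1
        else:
            rng.binomial(spec.N_o, 0.0, size=spec.generations)  # keep stream aligned
        detected.append(np.nan if gen is None else gen)
    df = pd.DataFrame(
        {"replicate_id": np.arange(spec.n_replicates), "first_detection_generation": detected}
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "detection.csv", index=False)
        _write_sidecar(out, spec, {"table": "detection.csv"})
    return df


def make_spatial_fixture(
    spec: SyntheticSpec,
    planted_resistant: int = 50,
    out_dir: str | Path | None = None,
) -> tuple[SimulationRecord, int]:
    """Miniature 3×3-chamber record with a resistant clone planted in one
    chamber; returns (record, planted_chamber_id).

    The planted clone grows under phage-free conditions, so the planted
    chamber is the first (or only) hot spot a detector should report.
    """
    spec.validate()
    if spec.scenario != "spatial_record":
        raise ValueError("spec.scenario must be 'spatial_record'")
    layout = build_hex_array(rows=3, cols=3, target_area_mm2=0.9)
    zero_field = ConcentrationField(
        times_s=np.array([0.0]),
        values=np.zeros((1, layout.n_chambers)),
        chamber_ids=[c.id for c in layout.chambers],
    )
    eco = spec.eco
    record = run_experiment(
        layout,
        zero_field,
        eco,
        spec.mutation,
        duration_h=3.0,
        seed=spec.root_seed,
        dt_h=0.02,
        record_every=5,
        initial_cells=200,
    )
    planted_id = layout.inlet.chamber
    if planted_resistant > 0:
        # plant the clone post hoc in the inlet chamber: R grows at the same
        # division probability as the recorded S population did
        j = record.chamber_ids.index(planted_id)
        rng = np.random.default_rng(np.random.SeedSequence((spec.root_seed, 1)))
        r = int(planted_resistant)
        for t in range(record.R.shape[0]):
            record.R[t, j] += r
            if t + 1 < record.R.shape[0]:
                dt = record.times_h[t + 1] - record.times_h[t]
                n_loc = record.nutrient[t, j]
                p_div = min(eco.mu_max_per_h * n_loc / (eco.K_s + n_loc) * dt, 1.0)
                r += int(rng.binomial(r, p_div))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        record.to_frame().to_csv(out / "spatial.csv", index=False)
        _write_sidecar(out, spec, {"table": "spatial.csv", "planted_chamber": planted_id})
    return record, planted_id
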