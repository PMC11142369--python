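"""Stochastic branching simulator of growth with resistance mutation.

Every generation, every cell divides.  A dividing *sensitive* cell yields,
with probability p = m·Θ_D + Θ_L·[exposed], one resistant and one sensitive
daughter (otherwise two sensitive daughters); resistant cells breed true and
are never lost.  Mutant production per generation is therefore
Binomial(S, p) with S the sensitive pool — the stochastic twin of the
deterministic expected-count arithmetic in :mod:`phagehab.kinetics` — and the
whole update works on aggregated counts, so populations up to ~10¹² cost the
same as ten cells.

The fluctuation-assay driver reproduces the classic well-mixed-flask design:
many parallel cultures, each grown from N₀ founders for G generations, with
the across-replicate distribution of resistant counts (mean, variance, Fano
factor, fraction p₀ of cultures with no mutants) summarizing the mutation
mechanism.  Spontaneous mutation produces the heavy-tailed jackpot
distribution (Fano ≫ 1); induction at the final generation produces a plain
binomial (Fano ≈ 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .kinetics import MutationParams

__all__ = [
    "LineageOutcome",
    "FluctuationSummary",
    "simulate_lineage",
    "run_fluctuation_assay",
    "first_detection_generation",
    "replicate_seeds",
]


@dataclass
class LineageOutcome:
    """Result of one growth-with-mutation realization."""

    total_cells: int
    resistant_cells: int
    first_resistant_generation: int | None
    seed: int
    resistant_trajectory: np.ndarray | None = None  # per-generation R, len G+1


@dataclass
class FluctuationSummary:
    n_replicates: int
    mean: float
    variance: float
    fano: float | None          # None when the mean is zero
    p0: float
    p0_rate_estimate: float | None  # None (flagged) when p0 == 0
    base_seed: int


def _mutation_probability(params: MutationParams, exposed: bool) -> float:
    p = params.target_size * params.theta_D + (params.theta_L if exposed else 0.0)
    if p > 1.0:
        raise ValueError("combined per-division mutation probability exceeds 1")
    return p


def simulate_lineage(
    N_o: int,
    G: int,
    params: MutationParams,
    exposure_schedule: Sequence[bool] | None = None,
    seed: int = 0,
    track_trajectory: bool = False,
) -> LineageOutcome:
    """Grow one culture from ``N_o`` founders for ``G`` generations.

    ``exposure_schedule[g]`` flags whether generation g+1 happens under
    phage exposure (stress-induced rate active); default: never exposed.
    """
    if N_o < 1:
        raise ValueError("N_o must be >= 1")
    if G < 0:
        raise ValueError("G must be >= 0")
    params.validate()
    if exposure_schedule is None:
        exposure_schedule = [False] * G
    if len(exposure_schedule) != G:
        raise ValueError("exposure schedule length must equal G")

    rng = np.random.default_rng(seed)
    S = int(N_o)
    R = 0
    first = None
    traj = [0] if track_trajectory else None
    for g in range(G):
        p = _mutation_probability(params, bool(exposure_schedule[g]))
        mutants = int(rng.binomial(S, p)) if (S > 0 and p > 0.0) else 0
        S = 2 * S - mutants
        R = 2 * R + mutants
        if first is None and R > 0:
            first = g + 1
        if traj is not None:
            traj.append(R)
    return LineageOutcome(
        total_cells=S + R,
        resistant_cells=R,
        first_resistant_generation=first,
        seed=seed,
        resistant_trajectory=np.array(traj) if traj is not None else None,
    )


def replicate_seeds(base_seed: int, n: int) -> np.ndarray:
    """Deterministic per-replicate 32-bit seeds derived from a root seed."""
    return np.random.SeedSequence(base_seed).generate_state(n)


def run_fluctuation_assay(
    n_replicates: int,
    N_o: int,
    G: int,
    params: MutationParams,
    exposure_schedule: Sequence[bool] | None = None,
    base_seed: int = 0,
    track_trajectory: bool = False,
) -> tuple[FluctuationSummary, list[LineageOutcome]]:
    """Run parallel cultures and summarize the resistant-count distribution.

    The p₀ rate estimate uses the zero-culture fraction: with D cell
    divisions per culture (D = N₀·(2^G − 1)), p₀ = e^(−θD) under the
    spontaneous model, so θ̂ = −ln(p₀)/D.  Flagged ``None`` when p₀ = 0.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    seeds = replicate_seeds(base_seed, n_replicates)
    outcomes = [
        simulate_lineage(N_o, G, params, exposure_schedule, seed=int(s), track_trajectory=track_trajectory)
        for s in seeds
    ]
    counts = np.array([o.resistant_cells for o in outcomes], dtype=float)
    mean = float(counts.mean())
    var = float(counts.var(ddof=1))
    fano = var / mean if mean > 0 else None
    p0 = float(np.mean(counts == 0))
    divisions = N_o * (2.0 ** G - 1.0)
    p0_rate = -math.log(p0) / divisions if p0 > 0 else None
    summary = FluctuationSummary(
        n_replicates=n_replicates,
        mean=mean,
        variance=var,
        fano=fano,
        p0=p0,
        p0_rate_estimate=p0_rate,
        base_seed=base_seed,
    )
    return summary, outcomes


def first_detection_generation(
    outcomes: Sequence[LineageOutcome], detection_threshold: int = 1
) -> list[int | None]:
    """Earliest generation at which each replicate's resistant count reaches
    the detection threshold (``None`` if it never does).

    Thresholds above 1 require outcomes recorded with trajectories.
    """
    if detection_threshold < 1:
        raise ValueError("detection threshold must be >= 1")
    result: list[int | None] = []
    for o in outcomes:
        if detection_threshold == 1 and o.resistant_trajectory is None:
            result.append(o.first_resistant_generation)
            continue
        if o.resistant_trajectory is None:
            raise ValueError("threshold > 1 requires trajectories (track_trajectory=True)")
        hits = np.nonzero(o.resistant_trajectory >= detection_threshold)[0]
        result.append(int(hits[0]) if hits.size else None)
    return result
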