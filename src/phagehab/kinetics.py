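"""Deterministic mutation-accumulation arithmetic.

Implements the expected-value bookkeeping for resistance mutations in an
exponentially doubling population:

* spontaneous ("Darwinian") accumulation — starting from N₀ sensitive cells,
  each division produces a resistant daughter with probability m·Θ_D, and
  mutants breed true, so after G generations the expected resistant count is

      N_r ≈ m · G · Θ_D · N₀ · 2^(G−1)

  valid while the sensitive pool is essentially undepleted (m·G·Θ_D ≪ 1);

* the corresponding resistant fraction F ≈ m·G·Θ_D, whose product with N₀
  gives the expected number of pre-existing resistant cells in an inoculum
  drawn after G generations of unstressed growth;

* a back-of-envelope stress-induced ("Lamarckian") rate estimator: observing
  k resistant lineages after g generations of exposure of a roughly constant
  pool of N₀ cells gives Θ_L ≈ k/(g·N₀), quoted together with its nearest
  order of magnitude;

* a Composite expectation combining both mechanisms, which reduces to the
  spontaneous formula when Θ_L = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "MutationParams",
    "GrowthContext",
    "ExpectedResistant",
    "RateEstimate",
    "CompositeExpectation",
    "expected_resistant_darwinian",
    "resistant_fraction",
    "estimate_theta_L",
    "generations_elapsed",
    "composite_expected",
    "order_of_magnitude",
]

#: Eq.-1 regime check: flag when m·G·Θ_D exceeds this.
APPROX_REGIME_LIMIT = 0.01


@dataclass(frozen=True)
class MutationParams:
    """Resistance-mutation parameters.

    theta_D          : spontaneous rate per cell division (default 2.0×10⁻⁹,
                       the unstressed E. coli single-bp substitution rate)
    theta_L          : stress-induced rate per division under phage exposure
    target_size      : number m of distinct single-bp changes conferring
                       resistance (the worst-case assumption is m = 1)
    generation_time_h: doubling time (default 0.5 h)
    """

    theta_D: float = 2.0e-9
    theta_L: float = 0.0
    target_size: int = 1
    generation_time_h: float = 0.5

    def validate(self) -> None:
        if not (0.0 <= self.theta_D <= 1.0 and 0.0 <= self.theta_L <= 1.0):
            raise ValueError("mutation rates must lie in [0, 1]")
        if self.target_size < 1:
            raise ValueError("target size must be >= 1")
        if self.generation_time_h <= 0:
            raise ValueError("generation time must be positive")

    def with_round_rate(self) -> "MutationParams":
        """Preset variant using the round-number spontaneous rate 10⁻⁹."""
        return replace(self, theta_D=1e-9)


@dataclass(frozen=True)
class GrowthContext:
    """One growth episode: N₀ founders, G total generations, g generations of
    phage exposure before the first resistant lineage was observed, and k
    observed resistant lineages."""

    N_o: float
    G: int = 0
    g: int = 0
    k: int = 0

    def validate(self) -> None:
        if self.N_o < 1:
            raise ValueError("founder count must be >= 1")
        if self.G < 0 or self.g < 0 or self.k < 0:
            raise ValueError("G, g, k must be non-negative")


@dataclass(frozen=True)
class ExpectedResistant:
    value: float
    approximation_ok: bool


@dataclass(frozen=True)
class RateEstimate:
    value: float
    order_of_magnitude: float
    is_upper_bound: bool = False


@dataclass(frozen=True)
class CompositeExpectation:
    spontaneous: float
    induced: float

    @property
    def total(self) -> float:
        return self.spontaneous + self.induced


def order_of_magnitude(x: float) -> float:
    """Nearest power of ten (round the exponent half away from zero).

    3.33×10⁻⁶ → 10⁻⁵ and 7.14×10⁻⁷ → 10⁻⁶.
    """
    if x <= 0:
        raise ValueError("order_of_magnitude requires x > 0")
    e = math.log10(x)
    k = math.floor(e + 0.5) if e >= 0 else math.ceil(e - 0.5)
    return 10.0 ** k


def expected_resistant_darwinian(ctx: GrowthContext, params: MutationParams) -> ExpectedResistant:
    """Expected resistant cells after G generations of unstressed doubling.

    N_r = m·G·Θ_D·N₀·2^(G−1).  The ``approximation_ok`` flag is False when
    m·G·Θ_D exceeds the regime limit (the sensitive pool is then no longer
    approximately undepleted and the linear sum over-counts).
    """
    ctx.validate()
    params.validate()
    if ctx.G < 1:
        raise ValueError("expected_resistant_darwinian requires G >= 1")
    m = params.target_size
    value = m * ctx.G * params.theta_D * ctx.N_o * 2.0 ** (ctx.G - 1)
    ok = m * ctx.G * params.theta_D <= APPROX_REGIME_LIMIT
    return ExpectedResistant(value=value, approximation_ok=ok)


def resistant_fraction(G: int, params: MutationParams, N_o: float | None = None):
    """Fraction F = m·G·Θ_D of a grown culture expected to carry resistance.

    This is the expected-count formula normalized by N₀·2^(G−1), matching the
    accumulation arithmetic above.  If ``N_o`` is given, also returns the
    expected number of pre-existing resistant cells F·N₀ in an inoculum of
    that size (a number that is ≪ 1 for the device's operating point).
    """
    params.validate()
    if G < 0:
        raise ValueError("G must be non-negative")
    F = params.target_size * G * params.theta_D
    if N_o is None:
        return F
    return F, F * N_o


def estimate_theta_L(ctx: GrowthContext) -> RateEstimate:
    """Order-of-magnitude stress-induced mutation rate from k resistant
    lineages observed after g generations of exposure of ~N₀ cells.

    Θ_L ≈ k / (g·N₀).  With k = 0 no resistance was seen and the same
    expression at k = 1 is returned as an upper bound, flagged as such.
    """
    ctx.validate()
    if ctx.g < 1:
        raise ValueError("estimate_theta_L requires g >= 1")
    if ctx.k == 0:
        bound = 1.0 / (ctx.g * ctx.N_o)
        return RateEstimate(value=bound, order_of_magnitude=order_of_magnitude(bound), is_upper_bound=True)
    value = ctx.k / (ctx.g * ctx.N_o)
    return RateEstimate(value=value, order_of_magnitude=order_of_magnitude(value))


def generations_elapsed(duration_h: float, params: MutationParams) -> tuple[float, float]:
    """Generations in ``duration_h`` hours, plus the value rounded to the
    nearest multiple of ten (15 h → 30; 72 h → 144, "roughly 140")."""
    params.validate()
    if duration_h < 0:
        raise ValueError("duration must be non-negative")
    G = duration_h / params.generation_time_h
    return G, round(G / 10.0) * 10.0


def composite_expected(
    ctx: GrowthContext,
    params: MutationParams,
    exposure_schedule: Sequence[bool],
    population: Sequence[float] | None = None,
) -> CompositeExpectation:
    """Expected resistant count under both mutation mechanisms.

    With ``population=None`` the population doubles every generation from N₀
    and mutant lineages expand with it: the spontaneous part is Eq.-1-style
    m·G·Θ_D·N₀·2^(G−1) and each exposed generation contributes
    Θ_L·N₀·2^(G−1) resistant descendants.  Passing an explicit per-generation
    ``population`` trajectory instead counts mutation *events* on that
    trajectory without descendant expansion — the constant-N₀ case is the
    algebraic inverse of :func:`estimate_theta_L` (Θ_L = k/(g·N₀) gives an
    expected count of exactly k).
    """
    ctx.validate()
    params.validate()
    schedule = np.asarray(exposure_schedule, dtype=bool)
    if schedule.shape != (ctx.G,):
        raise ValueError("exposure schedule length must equal G")
    m = params.target_size
    if population is None:
        G = ctx.G
        if G < 1:
            return CompositeExpectation(0.0, 0.0)
        spont = m * G * params.theta_D * ctx.N_o * 2.0 ** (G - 1)
        induced = params.theta_L * int(schedule.sum()) * ctx.N_o * 2.0 ** (G - 1)
        return CompositeExpectation(spontaneous=spont, induced=induced)
    pop = np.asarray(population, dtype=float)
    if pop.shape != (ctx.G,):
        raise ValueError("population trajectory length must equal G")
    spont = m * params.theta_D * float(pop.sum())
    induced = params.theta_L * float(pop[schedule].sum())
    return CompositeExpectation(spontaneous=spont, induced=induced)
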