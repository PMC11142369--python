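"""Compartmental virion transport over the chamber network.

Each chamber is treated as well mixed; corridors and nanoslits are diffusive
conduits with conductance g = D·A/L (volume flow of concentration per unit
concentration difference, ml/s), where A is the conduit cross-section and L
its length.  The two flow channels are Dirichlet reservoirs: the continuous
medium flow holds the phage-feed channel at the feed titer c₀ and the plain
channel at zero.  The resulting ODE system

    Vᵢ dcᵢ/dt = Σⱼ gᵢⱼ (cⱼ − cᵢ)

is integrated with an unconditionally stable implicit (backward-Euler)
scheme, which preserves positivity, the discrete maximum principle, and —
for a closed system — total virion number exactly.

This replaces the published full-3D finite-element gradient computation with
a network model; the per-chamber concentrations are what the downstream
eco-evolutionary simulation consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import DeviceLayout, PHAGE_FEED

__all__ = [
    "TransportParams",
    "ConcentrationField",
    "TransportSystem",
    "conductance_matrix",
    "simulate_gradient",
    "steady_state_field",
]


class TransportError(ValueError):
    pass


@dataclass(frozen=True)
class TransportParams:
    """Virion transport parameters.

    diffusion_coefficient_cm2_s : phage diffusivity (default 8×10⁻⁸ cm²/s)
    feed_concentration_per_ml   : phage titer in the loaded channel
                                  (default 2×10⁹ virions/ml)
    pre_run_duration_h          : gradient pre-establishment time (default 20 h)
    time_step_s                 : integrator step (default 10 s)
    """

    diffusion_coefficient_cm2_s: float = 8e-8
    feed_concentration_per_ml: float = 2e9
    pre_run_duration_h: float = 20.0
    time_step_s: float = 10.0

    def validate(self) -> None:
        if self.diffusion_coefficient_cm2_s <= 0:
            raise TransportError("diffusion coefficient must be positive")
        if self.feed_concentration_per_ml <= 0:
            raise TransportError("feed concentration must be positive")
        if self.pre_run_duration_h <= 0:
            raise TransportError("pre-run duration must be positive")
        if self.time_step_s <= 0:
            raise TransportError("time step must be positive")


@dataclass
class ConcentrationField:
    """Per-chamber virion concentration trajectory (virions/ml)."""

    times_s: np.ndarray          # shape (T,)
    values: np.ndarray           # shape (T, n_chambers)
    chamber_ids: list[int]

    def at(self, t_s: float) -> np.ndarray:
        """Nearest-frame concentration vector; clamped outside the range."""
        idx = int(np.argmin(np.abs(self.times_s - t_s)))
        return self.values[idx]

    @property
    def final(self) -> np.ndarray:
        return self.values[-1]

    def after(self, t0_s: float) -> "ConcentrationField":
        """Sub-field starting at ``t0_s`` with times re-zeroed (e.g. to treat
        the end of the pre-run as experiment time zero)."""
        keep = self.times_s >= t0_s - 1e-9
        if not keep.any():
            raise TransportError("after(): t0 beyond the simulated range")
        return ConcentrationField(
            times_s=self.times_s[keep] - t0_s,
            values=self.values[keep],
            chamber_ids=self.chamber_ids,
        )

    def to_frame(self):
        import pandas as pd

        t = np.repeat(self.times_s, len(self.chamber_ids))
        cid = np.tile(self.chamber_ids, len(self.times_s))
        return pd.DataFrame(
            {"time_s": t, "chamber_id": cid, "concentration_virions_per_ml": self.values.ravel()}
        )


def _conduit_conductance_ml_s(D_cm2_s: float, width_um: float, depth_um: float, length_um: float) -> float:
    area_cm2 = (width_um * 1e-4) * (depth_um * 1e-4)
    length_cm = length_um * 1e-4
    return D_cm2_s * area_cm2 / length_cm


@dataclass
class TransportSystem:
    """Assembled exchange operator over chambers plus the two channel nodes.

    ``laplacian`` is the symmetric (n+2)×(n+2) graph Laplacian of pairwise
    conductances (ml/s), chambers first, channel nodes last; every row sums
    to zero.  ``volumes_ml`` holds chamber volumes.
    """

    laplacian: sp.csr_matrix
    volumes_ml: np.ndarray
    chamber_ids: list[int]
    channel_index: dict[str, int]          # channel id -> node index
    channel_roles: dict[str, str] = field(default_factory=dict)

    @property
    def n_chambers(self) -> int:
        return len(self.chamber_ids)

    def interior_operator(self) -> tuple[sp.csr_matrix, sp.csr_matrix]:
        """Split L into (chamber-chamber block, chamber-channel block)."""
        n = self.n_chambers
        L = self.laplacian.tocsr()
        return L[:n, :n].tocsr(), L[:n, n:].tocsr()

    def default_boundary_values(self, c0: float) -> dict[str, float]:
        vals = {}
        for cid, role in self.channel_roles.items():
            vals[cid] = c0 if role == PHAGE_FEED else 0.0
        return vals


def conductance_matrix(
    layout: DeviceLayout, params: TransportParams, include_slits: bool = True
) -> TransportSystem:
    """Build the diffusive exchange operator for a layout.

    Corridor conductance uses the 10 μm etch depth; nanoslit conductance the
    100 nm slit depth, making a slit ~100× less conductive per unit width.
    ``include_slits=False`` detaches the channels (closed chamber network).
    Raises if the chamber graph is disconnected.
    """
    params.validate()
    layout.validate()
    D = params.diffusion_coefficient_cm2_s
    n = layout.n_chambers
    id2idx = {c.id: i for i, c in enumerate(layout.chambers)}
    ch2idx = {ch.id: n + k for k, ch in enumerate(layout.channels)}

    rows, cols, vals = [], [], []

    def add_edge(i: int, j: int, g: float) -> None:
        rows.extend([i, j, i, j])
        cols.extend([j, i, i, j])
        vals.extend([g, g, -g, -g])

    for cor in layout.corridors:
        g = _conduit_conductance_ml_s(D, cor.width_um, cor.depth_um, cor.length_um)
        add_edge(id2idx[cor.a], id2idx[cor.b], g)
    if include_slits:
        for slit in layout.nanoslits:
            g = _conduit_conductance_ml_s(D, slit.width_um, slit.depth_nm * 1e-3, slit.length_um)
            add_edge(id2idx[slit.chamber], ch2idx[slit.channel], g)

    ntot = n + len(layout.channels)
    W = sp.coo_matrix((vals, (rows, cols)), shape=(ntot, ntot)).tocsr()
    # chamber volume: area [mm²] × depth [μm] = 1e-3 mm³, and 1 mm³ = 1e-3 ml
    volumes = np.array([c.area_mm2 * c.depth_um * 1e-6 for c in layout.chambers])
    return TransportSystem(
        laplacian=W,
        volumes_ml=volumes,
        chamber_ids=[c.id for c in layout.chambers],
        channel_index=ch2idx,
        channel_roles={ch.id: ch.role for ch in layout.channels},
    )


def _boundary_vector(system: TransportSystem, boundary_values: dict[str, float]) -> np.ndarray:
    vec = np.zeros(len(system.channel_index))
    for cid, idx in system.channel_index.items():
        vec[idx - system.n_chambers] = boundary_values.get(cid, 0.0)
    return vec


def simulate_gradient(
    layout: DeviceLayout,
    params: TransportParams,
    duration_h: float | None = None,
    boundary_values: dict[str, float] | None = None,
    initial: np.ndarray | None = None,
    closed: bool = False,
    store_every: int = 1,
) -> ConcentrationField:
    """Integrate the chamber concentrations under Dirichlet channel boundaries.

    By default the phage-feed channel is held at the feed titer and the plain
    channel at 0, starting from an empty device, for the pre-run duration.
    ``closed=True`` detaches both channels (no boundary exchange; used for
    conservation checks).  ``store_every`` thins the stored trajectory.
    """
    params.validate()
    if duration_h is None:
        duration_h = params.pre_run_duration_h
    if duration_h <= 0:
        raise TransportError("duration must be positive")
    dt = params.time_step_s
    system = conductance_matrix(layout, params, include_slits=not closed)
    n = system.n_chambers
    L_ii, L_ib = system.interior_operator()

    if boundary_values is None:
        boundary_values = system.default_boundary_values(params.feed_concentration_per_ml)
    b_vec = _boundary_vector(system, boundary_values)

    c = np.zeros(n) if initial is None else np.asarray(initial, dtype=float).copy()
    if c.shape != (n,):
        raise TransportError("initial condition has wrong shape")

    V = system.volumes_ml
    # Backward Euler: (V/dt - L_ii) c_{k+1} = (V/dt) c_k + L_ib c_b
    A = sp.diags(V) / dt - L_ii
    forcing = np.zeros(n) if closed else np.asarray(L_ib @ b_vec)
    lu = spla.splu(A.tocsc())

    n_steps = max(1, int(round(duration_h * 3600.0 / dt)))
    times = [0.0]
    frames = [c.copy()]
    for k in range(1, n_steps + 1):
        c = lu.solve(V / dt * c + forcing)
        if k % store_every == 0 or k == n_steps:
            times.append(k * dt)
            frames.append(c.copy())
    return ConcentrationField(
        times_s=np.array(times), values=np.array(frames), chamber_ids=system.chamber_ids
    )


def steady_state_field(
    layout: DeviceLayout,
    params: TransportParams,
    boundary_values: dict[str, float] | None = None,
) -> np.ndarray:
    """Asymptotic per-chamber concentration with fixed channel boundaries.

    Solves the linear balance L_ii c = −L_ib c_b.  Raises if the layout has
    no nanoslit attachment to any channel (singular system — no boundary
    condition reaches the interior).
    """
    params.validate()
    system = conductance_matrix(layout, params)
    if not layout.nanoslits:
        raise TransportError("no nanoslits: steady state is undetermined")
    L_ii, L_ib = system.interior_operator()
    if boundary_values is None:
        boundary_values = system.default_boundary_values(params.feed_concentration_per_ml)
    b_vec = _boundary_vector(system, boundary_values)
    # balance: L_ii c + L_ib c_b = 0  =>  (-L_ii) c = L_ib c_b
    rhs = np.asarray(L_ib @ b_vec)
    c = spla.spsolve((-L_ii).tocsc(), rhs)
    return np.asarray(c)


def row_profile(layout: DeviceLayout, values: np.ndarray) -> np.ndarray:
    """Mean concentration per chamber row (row 0 = phage-feed side)."""
    rows = np.array([c.row for c in layout.chambers])
    vals = np.asarray(values)
    return np.array([vals[rows == r].mean() for r in range(layout.rows)])
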