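"""Explicit finite-difference Euler-Maruyama integrator for the HH cable.

The membrane voltage obeys a reaction-diffusion equation

    C_m dV/dt = (a / 2 R_i) V_xx - I_ion(V, n, m, h) + I_drive(x, t)

with sealed (zero-flux) ends, coupled to the three gating ODEs per node.
Additive space-time white noise enters the voltage equation on the noise
window only, with the standard finite-difference scaling: the stochastic
increment per node and step is ``sigma * sqrt(dt/dx) * z`` with ``z``
i.i.d. standard normal.  In conductance mode the applied current is
replaced by OU-driven synaptic conductances times driving forces and the
voltage equation itself carries no noise.

Two code paths compute identical trajectories: :func:`step` (vectorised
numpy, one step at a time — the readable reference) and a compiled
kernel used by :func:`integrate` for long runs.  Both consume the same
normal-variate stream, so results agree to rounding regardless of path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .membrane import BLOWUP_MV, BlowUpError, GatingState, MembraneParams, \
    gating_steady_state, ionic_current, rate_coefficients
from .stimulation import DriveSpec, signal_profile, synaptic_current, window_nodes

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f

        return wrap


__all__ = [
    "CableGrid",
    "FieldState",
    "SolutionRecord",
    "laplacian",
    "step",
    "integrate",
    "StabilityError",
]


class StabilityError(ValueError):
    """Raised when the explicit scheme's stability bound is violated."""


@dataclass(frozen=True)
class CableGrid:
    """Spatial/temporal discretization of the nerve cylinder.

    Attributes
    ----------
    L : float
        Cable length, cm.
    nx : int
        Number of spatial nodes (>= 3); ``dx = L / (nx - 1)``.
    dt : float
        Time step, ms.
    t_end : float
        Final (evaluation) time, ms.
    """

    L: float = 4.5
    nx: int = 451
    dt: float = 0.01
    t_end: float = 100.0

    def __post_init__(self) -> None:
        if self.nx < 3:
            raise ValueError("CableGrid.nx must be >= 3")
        if min(self.L, self.dt, self.t_end) <= 0:
            raise ValueError("CableGrid lengths and times must be positive")

    @property
    def dx(self) -> float:
        return self.L / (self.nx - 1)

    @property
    def x(self) -> np.ndarray:
        """Node positions in cm."""
        return np.linspace(0.0, self.L, self.nx)

    @property
    def nsteps(self) -> int:
        return int(round(self.t_end / self.dt))

    def stability_ratio(self, p: MembraneParams) -> float:
        """``r = D dt / dx^2`` for the voltage diffusion coefficient of ``p``."""
        return p.diffusion * self.dt / self.dx**2

    def validate(self, p: MembraneParams) -> None:
        """Enforce ``r <= 1/2`` (error) and warn above ``1/4``."""
        r = self.stability_ratio(p)
        if r > 0.5:
            raise StabilityError(
                f"stability ratio r = D*dt/dx^2 = {r:.3f} exceeds 1/2; "
                "reduce dt or increase dx"
            )
        if r > 0.25:
            warnings.warn(
                f"stability ratio r = {r:.3f} > 1/4; the explicit scheme is "
                "formally stable but accuracy may suffer",
                stacklevel=2,
            )

    @classmethod
    def from_spacing(cls, L: float, dx: float, dt: float, t_end: float) -> "CableGrid":
        """Build a grid from a target node spacing (L must be a multiple of dx)."""
        nx = int(round(L / dx)) + 1
        if abs((nx - 1) * dx - L) > 1e-9:
            raise ValueError(f"L={L} is not a multiple of dx={dx}")
        return cls(L=L, nx=nx, dt=dt, t_end=t_end)


@dataclass
class FieldState:
    """The cable's state at one instant: V plus gating (and conductance) fields."""

    V: np.ndarray
    gating: GatingState
    t: float = 0.0
    g_e: np.ndarray | None = None
    g_i: np.ndarray | None = None

    def copy(self) -> "FieldState":
        return FieldState(
            V=self.V.copy(),
            gating=GatingState(
                np.array(self.gating.n), np.array(self.gating.m), np.array(self.gating.h)
            ),
            t=self.t,
            g_e=None if self.g_e is None else self.g_e.copy(),
            g_i=None if self.g_i is None else self.g_i.copy(),
        )


def resting_field(grid: CableGrid, spec: DriveSpec | None = None) -> FieldState:
    """Uniform resting initial condition (V=0, gating at its V=0 equilibrium).

    In conductance mode the conductance fields start at their local
    equilibrium values (``ge_bar`` on the signal window, zero outside).
    """
    g0 = gating_steady_state(0.0)
    ones = np.ones(grid.nx)
    st = FieldState(
        V=np.zeros(grid.nx),
        gating=GatingState(float(g0.n) * ones, float(g0.m) * ones, float(g0.h) * ones),
        t=0.0,
    )
    if spec is not None and spec.noise_kind == "conductance":
        ge = np.zeros(grid.nx)
        ge[window_nodes(grid.x, spec.signal_window)] = spec.synaptic.ge_bar
        gi = np.zeros(grid.nx)
        gi[window_nodes(grid.x, spec.signal_window)] = spec.synaptic.gi_bar
        st.g_e, st.g_i = ge, gi
    return st


def laplacian(V: np.ndarray, dx: float) -> np.ndarray:
    """Second spatial difference with zero-flux (mirror ghost node) ends.

    Interior node i gets ``(V[i+1] - 2 V[i] + V[i-1]) / dx^2``; the end
    nodes use a reflected ghost node, so a spatially constant field maps
    exactly to zero and no flux crosses the sealed ends.
    """
    if V.shape[0] < 3:
        raise ValueError("laplacian needs at least 3 nodes")
    out = np.empty_like(V)
    out[1:-1] = V[2:] - 2.0 * V[1:-1] + V[:-2]
    out[0] = 2.0 * (V[1] - V[0])
    out[-1] = 2.0 * (V[-2] - V[-1])
    out /= dx * dx
    return out


# ---------------------------------------------------------------------------
# Reference (numpy) single step
# ---------------------------------------------------------------------------

def step(
    state: FieldState,
    grid: CableGrid,
    p: MembraneParams,
    drive: DriveSpec,
    rng: np.random.Generator | None = None,
) -> FieldState:
    """Advance the full cable state by one time step (reference path).

    All right-hand-side terms are evaluated at the current time level
    (fully explicit).  The stochastic increment touches only nodes inside
    the noise window; with ``noise_kind="none"`` or ``sigma=0`` no random
    numbers are drawn at all.
    """
    x = grid.x
    dt, dx = grid.dt, grid.dx
    V, g = state.V, state.gating
    I_sig = signal_profile(x, drive)

    if drive.noise_kind == "conductance":
        I_drive = synaptic_current(V, state.g_e, state.g_i, drive)
    else:
        I_drive = I_sig

    I_ion = ionic_current(V, g, p)
    V_new = V + dt * (p.diffusion * laplacian(V, dx) + (I_drive - I_ion) / p.C_m)

    noise_idx = window_nodes(x, drive.noise_window)
    if drive.noise_kind == "additive" and drive.sigma > 0 and noise_idx.size:
        z = rng.standard_normal(noise_idx.size)
        V_new[noise_idx] += (drive.sigma / p.C_m) * np.sqrt(dt / dx) * z

    an, bn, am, bm, ah, bh = rate_coefficients(V)
    g_new = GatingState(
        n=np.clip(g.n + dt * (an * (1 - g.n) - bn * g.n), 0.0, 1.0),
        m=np.clip(g.m + dt * (am * (1 - g.m) - bm * g.m), 0.0, 1.0),
        h=np.clip(g.h + dt * (ah * (1 - g.h) - bh * g.h), 0.0, 1.0),
    )

    ge_new = gi_new = None
    if drive.noise_kind == "conductance":
        syn = drive.synaptic
        sig_idx = window_nodes(x, drive.signal_window)
        ge_bar_f = np.zeros(grid.nx)
        ge_bar_f[sig_idx] = syn.ge_bar
        gi_bar_f = np.zeros(grid.nx)
        gi_bar_f[sig_idx] = syn.gi_bar
        ge_new = state.g_e + dt * (ge_bar_f - state.g_e) / syn.tau_e
        gi_new = state.g_i + dt * (gi_bar_f - state.g_i) / syn.tau_i
        if noise_idx.size:
            amp = np.sqrt(dt / dx)
            ge_new[noise_idx] += syn.sigma_e * amp * rng.standard_normal(noise_idx.size)
            gi_new[noise_idx] += syn.sigma_i * amp * rng.standard_normal(noise_idx.size)
        ge_new = np.maximum(ge_new, 0.0)
        gi_new = np.maximum(gi_new, 0.0)

    bad = ~np.isfinite(V_new) | (np.abs(V_new) > BLOWUP_MV)
    if np.any(bad):
        i = int(np.argmax(bad))
        raise BlowUpError(
            f"cable integration unstable at node {i} (x={x[i]:.3f} cm), "
            f"t={state.t + dt:.3f} ms: V={V_new[i]!r}"
        )

    return FieldState(V=V_new, gating=g_new, t=state.t + dt, g_e=ge_new, g_i=gi_new)


# ---------------------------------------------------------------------------
# Compiled kernel (many steps per call, pre-drawn normals)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _run_chunk(
    V, n, m, h, ge, gi,
    I_sig, ge_bar_f, gi_bar_f, noise_idx, Ze, Zi,
    nsteps, dt, dx, D, Cm, gK, gNa, gL, VK, VNa, VL,
    cond_mode, sigma, tau_e, tau_i, sigma_e, sigma_i, VE, VI,
    probe_idx, probe_out,
):  # pragma: no cover - exercised via integrate()
    nx = V.shape[0]
    nw = noise_idx.shape[0]
    dx2 = dx * dx
    amp_v = sigma / Cm * np.sqrt(dt / dx)
    amp_e = sigma_e * np.sqrt(dt / dx)
    amp_i = sigma_i * np.sqrt(dt / dx)
    Vn = np.empty(nx)
    for k in range(nsteps):
        for j in range(probe_idx.shape[0]):
            probe_out[k, j] = V[probe_idx[j]]
        for i in range(nx):
            if i == 0:
                lap = 2.0 * (V[1] - V[0]) / dx2
            elif i == nx - 1:
                lap = 2.0 * (V[nx - 2] - V[nx - 1]) / dx2
            else:
                lap = (V[i + 1] - 2.0 * V[i] + V[i - 1]) / dx2
            v = V[i]
            I_ion = (
                gK * n[i] ** 4 * (v - VK)
                + gNa * m[i] ** 3 * h[i] * (v - VNa)
                + gL * (v - VL)
            )
            if cond_mode:
                I_drive = ge[i] * (VE - v) + gi[i] * (VI - v)
            else:
                I_drive = I_sig[i]
            Vn[i] = v + dt * (D * lap + (I_drive - I_ion) / Cm)
        if not cond_mode and sigma > 0.0:
            for j in range(nw):
                Vn[noise_idx[j]] += amp_v * Ze[k, j]
        # gating update from the pre-step voltage
        for i in range(nx):
            v = V[i]
            dv = 10.0 - v
            if dv > 1e-6 or dv < -1e-6:
                an = 0.01 * dv / (np.expm1(dv / 10.0))
            else:
                an = 0.01 * (10.0 - dv / 2.0)
            bn = 0.125 * np.exp(-v / 80.0)
            dv = 25.0 - v
            if dv > 1e-6 or dv < -1e-6:
                am = 0.1 * dv / (np.expm1(dv / 10.0))
            else:
                am = 0.1 * (10.0 - dv / 2.0)
            bm = 4.0 * np.exp(-v / 18.0)
            ah = 0.07 * np.exp(-v / 20.0)
            bh = 1.0 / (np.exp((30.0 - v) / 10.0) + 1.0)
            n[i] = min(1.0, max(0.0, n[i] + dt * (an * (1.0 - n[i]) - bn * n[i])))
            m[i] = min(1.0, max(0.0, m[i] + dt * (am * (1.0 - m[i]) - bm * m[i])))
            h[i] = min(1.0, max(0.0, h[i] + dt * (ah * (1.0 - h[i]) - bh * h[i])))
        if cond_mode:
            for i in range(nx):
                ge[i] += dt * (ge_bar_f[i] - ge[i]) / tau_e
                gi[i] += dt * (gi_bar_f[i] - gi[i]) / tau_i
            for j in range(nw):
                ge[noise_idx[j]] += amp_e * Ze[k, j]
                gi[noise_idx[j]] += amp_i * Zi[k, j]
            for i in range(nx):
                if ge[i] < 0.0:
                    ge[i] = 0.0
                if gi[i] < 0.0:
                    gi[i] = 0.0
        for i in range(nx):
            if not np.isfinite(Vn[i]) or abs(Vn[i]) > BLOWUP_MV:
                return k, i
            V[i] = Vn[i]
    return -1, -1


@dataclass
class SolutionRecord:
    """Output of :func:`integrate`.

    ``snapshots`` maps requested times to voltage fields; ``probes`` is a
    (nsteps, n_probe) array of V time series at the probe nodes (empty if
    none requested).  ``final`` is the full state at ``t_end``, ready for
    spatial spike counting.
    """

    grid: CableGrid
    final: FieldState
    snapshot_times: np.ndarray
    snapshots: list[FieldState] = field(default_factory=list)
    probe_positions: np.ndarray = field(default_factory=lambda: np.empty(0))
    probes: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    probe_t: np.ndarray = field(default_factory=lambda: np.empty(0))

    def snapshot_V(self) -> np.ndarray:
        """Stack of snapshot voltage fields, shape (n_snapshots, nx)."""
        return np.array([s.V for s in self.snapshots])


def _noise_block(rng, nsteps, nw, drive):
    """Draw the normal variates one chunk of steps consumes, in the same
    order the step-by-step reference path would draw them."""
    if nw == 0:
        return np.empty((nsteps, 0)), np.empty((nsteps, 0))
    if drive.noise_kind == "additive":
        if drive.sigma == 0.0:
            return np.empty((nsteps, 0)), np.empty((nsteps, 0))
        return rng.standard_normal((nsteps, nw)), np.empty((nsteps, 0))
    if drive.noise_kind == "conductance":
        Z = rng.standard_normal((nsteps, 2, nw))
        return np.ascontiguousarray(Z[:, 0, :]), np.ascontiguousarray(Z[:, 1, :])
    return np.empty((nsteps, 0)), np.empty((nsteps, 0))


def integrate(
    initial: FieldState,
    grid: CableGrid,
    p: MembraneParams,
    drive: DriveSpec,
    rng: np.random.Generator | None = None,
    snapshot_times=(),
    probe_positions=(),
    chunk_steps: int = 2000,
) -> SolutionRecord:
    """Run the explicit scheme from ``initial`` to ``grid.t_end``.

    Parameters
    ----------
    initial : FieldState
        Starting state (see :func:`resting_field`).
    rng : numpy Generator, optional
        Required whenever the drive has a stochastic component; the same
        generator state always yields the identical trajectory.
    snapshot_times : sequence of float
        Times (ms) at which to record the full field; rounded to steps.
    probe_positions : sequence of float
        Positions (cm) whose voltage is recorded every step.
    chunk_steps : int
        Steps per kernel call (controls the size of pre-drawn noise
        blocks; no effect on results).

    Raises
    ------
    BlowUpError
        Naming the node and time at which the field left [-500, 500] mV.
    StabilityError
        If ``r = D dt/dx^2 > 1/2``.
    """
    grid.validate(p)
    snapshot_times = np.asarray(sorted(snapshot_times), dtype=float)
    if snapshot_times.size and (
        snapshot_times[0] < 0 or snapshot_times[-1] > grid.t_end + 1e-9
    ):
        raise ValueError("snapshot_times must lie in [0, t_end]")
    needs_rng = (drive.noise_kind == "additive" and drive.sigma > 0) or (
        drive.noise_kind == "conductance"
        and (drive.synaptic.sigma_e > 0 or drive.synaptic.sigma_i > 0)
    )
    if needs_rng and rng is None:
        raise ValueError("a seeded numpy Generator is required for stochastic drive")
    if rng is None:
        rng = np.random.default_rng(0)

    x = grid.x
    state = initial.copy()
    cond = drive.noise_kind == "conductance"
    if cond and state.g_e is None:
        init = resting_field(grid, drive)
        state.g_e, state.g_i = init.g_e, init.g_i

    I_sig = signal_profile(x, drive)
    sig_idx = window_nodes(x, drive.signal_window)
    ge_bar_f = np.zeros(grid.nx)
    gi_bar_f = np.zeros(grid.nx)
    ge_bar_f[sig_idx] = drive.synaptic.ge_bar
    gi_bar_f[sig_idx] = drive.synaptic.gi_bar
    noise_idx = window_nodes(x, drive.noise_window).astype(np.int64)
    if not needs_rng:
        noise_idx = np.empty(0, dtype=np.int64)

    probe_positions = np.asarray(probe_positions, dtype=float)
    probe_idx = np.array(
        [int(round(q / grid.dx)) for q in probe_positions], dtype=np.int64
    )
    nsteps = grid.nsteps
    probes = np.empty((nsteps, probe_idx.size))

    snap_steps = [int(round(ts / grid.dt)) for ts in snapshot_times]
    record = SolutionRecord(
        grid=grid,
        final=state,  # replaced below
        snapshot_times=snapshot_times,
        probe_positions=probe_positions,
        probe_t=np.arange(nsteps) * grid.dt,
    )

    V = state.V.astype(float).copy()
    n = np.asarray(state.gating.n, dtype=float).copy()
    m = np.asarray(state.gating.m, dtype=float).copy()
    h = np.asarray(state.gating.h, dtype=float).copy()
    ge = state.g_e.astype(float).copy() if cond else np.zeros(0)
    gi = state.g_i.astype(float).copy() if cond else np.zeros(0)
    if cond:
        ge_full, gi_full = ge, gi
    else:
        ge_full = gi_full = np.zeros(grid.nx)

    done = 0
    snap_ptr = 0

    def take_snapshots():
        nonlocal snap_ptr
        while snap_ptr < len(snap_steps) and snap_steps[snap_ptr] == done:
            record.snapshots.append(
                FieldState(
                    V=V.copy(),
                    gating=GatingState(n.copy(), m.copy(), h.copy()),
                    t=done * grid.dt,
                    g_e=ge_full.copy() if cond else None,
                    g_i=gi_full.copy() if cond else None,
                )
            )
            snap_ptr += 1

    take_snapshots()
    while done < nsteps:
        todo = min(chunk_steps, nsteps - done)
        # stop a chunk at the next snapshot boundary
        for s in snap_steps:
            if done < s < done + todo:
                todo = s - done
                break
        Ze, Zi = _noise_block(rng, todo, noise_idx.size, drive)
        if Ze.shape[1] == 0:
            Ze = np.empty((todo, 0))
        kf, inode = _run_chunk(
            V, n, m, h, ge_full, gi_full,
            I_sig, ge_bar_f, gi_bar_f, noise_idx, Ze, Zi,
            todo, grid.dt, grid.dx, p.diffusion, p.C_m,
            p.gK_bar, p.gNa_bar, p.gL, p.V_K, p.V_Na, p.V_L,
            cond, drive.sigma if drive.noise_kind == "additive" else 0.0,
            drive.synaptic.tau_e, drive.synaptic.tau_i,
            drive.synaptic.sigma_e, drive.synaptic.sigma_i,
            drive.synaptic.V_E, drive.synaptic.V_I,
            probe_idx, probes[done : done + todo],
        )
        if kf >= 0:
            t_bad = (done + kf + 1) * grid.dt
            raise BlowUpError(
                f"cable integration unstable at node {inode} "
                f"(x={x[inode]:.3f} cm), t={t_bad:.3f} ms"
            )
        done += todo
        take_snapshots()

    record.final = FieldState(
        V=V,
        gating=GatingState(n, m, h),
        t=nsteps * grid.dt,
        g_e=ge_full if cond else None,
        g_i=gi_full if cond else None,
    )
    record.probes = probes
    return record
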