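"""Spatial windows and amplitudes for signal and noise.

The deterministic drive is a constant current density ``mu`` applied
indefinitely on a small end segment (the "signal window", a stand-in for
the soma-dendritic input region).  The stochastic drive lives on an
independent "noise window" that may overlap the signal window fully,
partially, or not at all, and comes in two flavours:

* ``additive`` — two-parameter (space-time) white noise added to the
  voltage equation with amplitude ``sigma``;
* ``conductance`` — excitatory/inhibitory synaptic conductances driven
  by per-node Ornstein-Uhlenbeck processes (the diffusion approximation
  of shot-noise synaptic input) multiplying driving-force terms.

Windows are intervals in cm snapped to grid nodes.  A node at position
``x`` belongs to window ``[x0, x1)`` (half-open), so abutting windows
share no node and "disjoint" means exactly that at the grid level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SynapticParams",
    "DriveSpec",
    "signal_profile",
    "noise_mask",
    "window_nodes",
    "overlap_fraction",
    "conductance_step",
    "synaptic_current",
]


@dataclass(frozen=True)
class SynapticParams:
    """Conductance-based (synaptic) input parameters.

    ``ge_bar``/``gi_bar`` are equilibrium conductance densities in
    mS/cm^2, ``V_E``/``V_I`` reversal potentials in mV relative to rest,
    ``tau_e``/``tau_i`` OU decay time constants in ms, and
    ``sigma_e``/``sigma_i`` the conductance noise amplitudes (mS/cm^2
    per sqrt(cm*ms)).
    """

    ge_bar: float = 0.0
    gi_bar: float = 0.0
    V_E: float = 80.0
    V_I: float = -10.0
    tau_e: float = 2.0
    tau_i: float = 6.0
    sigma_e: float = 0.0
    sigma_i: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_e <= 0 or self.tau_i <= 0:
            raise ValueError("synaptic time constants must be positive")
        if self.ge_bar < 0 or self.gi_bar < 0:
            raise ValueError("equilibrium conductances must be nonnegative")


@dataclass(frozen=True)
class DriveSpec:
    """Deterministic signal plus stochastic input specification.

    Attributes
    ----------
    mu : float
        Signal current density on the signal window, uA/cm^2.
    signal_window : (float, float)
        Interval in cm carrying the constant current (default the end
        segment ``[0, 0.1)``).
    noise_kind : str
        ``"additive"``, ``"conductance"`` or ``"none"``.
    sigma : float
        Additive white-noise amplitude, uA/cm^2 per sqrt(cm*ms).
    noise_window : (float, float)
        Interval in cm receiving stochastic input.
    synaptic : SynapticParams
        Conductance-mode parameters (ignored for additive noise).
    """

    mu: float = 0.0
    signal_window: tuple[float, float] = (0.0, 0.1)
    noise_kind: str = "none"
    sigma: float = 0.0
    noise_window: tuple[float, float] = (0.0, 0.0)
    synaptic: SynapticParams = field(default_factory=SynapticParams)

    def __post_init__(self) -> None:
        if self.noise_kind not in ("additive", "conductance", "none"):
            raise ValueError(f"unknown noise_kind {self.noise_kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.mu < 0:
            raise ValueError("mu must be nonnegative")
        for w in (self.signal_window, self.noise_window):
            if w[1] < w[0]:
                raise ValueError(f"window {w} has negative length")


def window_nodes(x: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Indices of grid nodes inside the half-open window ``[x0, x1)``.

    A small tolerance absorbs floating-point jitter in node positions so
    that endpoints stated in cm snap to the intended nodes.
    """
    x0, x1 = window
    eps = 1e-9
    return np.nonzero((x >= x0 - eps) & (x < x1 - eps))[0]


def signal_profile(x: np.ndarray, spec: DriveSpec) -> np.ndarray:
    """Constant-in-time current-density field: ``mu`` on the signal window."""
    out = np.zeros_like(np.asarray(x, dtype=float))
    out[window_nodes(x, spec.signal_window)] = spec.mu
    return out


def noise_mask(x: np.ndarray, spec: DriveSpec) -> np.ndarray:
    """Per-node additive noise amplitude: ``sigma`` on the noise window."""
    out = np.zeros_like(np.asarray(x, dtype=float))
    if spec.noise_kind != "none":
        out[window_nodes(x, spec.noise_window)] = (
            spec.sigma if spec.noise_kind == "additive" else spec.synaptic.sigma_e
        )
    return out


def overlap_fraction(
    signal_window: tuple[float, float], noise_window: tuple[float, float]
) -> float:
    """Fraction of the signal window covered by the noise window.

    ``|signal ∩ noise| / |signal|`` by interval arithmetic, in [0, 1].
    """
    s0, s1 = signal_window
    n0, n1 = noise_window
    if s1 <= s0:
        raise ValueError("signal window has zero length")
    inter = max(0.0, min(s1, n1) - max(s0, n0))
    return inter / (s1 - s0)


def conductance_step(
    g_e: np.ndarray,
    g_i: np.ndarray,
    spec: DriveSpec,
    x: np.ndarray,
    dt: float,
    dx: float,
    rng: np.random.Generator,
    ge_bar_field: np.ndarray | None = None,
    gi_bar_field: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance the synaptic conductance fields by one Euler-Maruyama step.

    Each node carries an independent OU process relaxing to its local
    equilibrium (``ge_bar`` inside the signal window, 0 outside, unless
    explicit equilibrium fields are given).  White-in-space forcing of
    amplitude ``sigma_e`` (resp. ``sigma_i``) acts only on nodes inside
    the noise window, scaled by ``sqrt(dt/dx)`` per step.  Negative
    conductances are clamped to zero (the diffusion approximation is not
    sign-constrained; physical conductances are).
    """
    syn = spec.synaptic
    if ge_bar_field is None:
        ge_bar_field = np.zeros_like(g_e)
        ge_bar_field[window_nodes(x, spec.signal_window)] = syn.ge_bar
    if gi_bar_field is None:
        gi_bar_field = np.zeros_like(g_i)
        gi_bar_field[window_nodes(x, spec.signal_window)] = syn.gi_bar

    idx = window_nodes(x, spec.noise_window)
    amp = np.sqrt(dt / dx)
    g_e = g_e + dt * (ge_bar_field - g_e) / syn.tau_e
    g_i = g_i + dt * (gi_bar_field - g_i) / syn.tau_i
    if idx.size:
        g_e[idx] += syn.sigma_e * amp * rng.standard_normal(idx.size)
        g_i[idx] += syn.sigma_i * amp * rng.standard_normal(idx.size)
    return np.maximum(g_e, 0.0), np.maximum(g_i, 0.0)


def synaptic_current(
    V: np.ndarray, g_e: np.ndarray, g_i: np.ndarray, spec: DriveSpec
) -> np.ndarray:
    """Synaptic current density ``g_e (V_E - V) + g_i (V_I - V)``, uA/cm^2."""
    syn = spec.synaptic
    return g_e * (syn.V_E - V) + g_i * (syn.V_I - V)
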