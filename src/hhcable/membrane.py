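"""Pointwise Hodgkin-Huxley membrane kinetics.

Voltage-dependent rate coefficients, gating steady states, the ionic
current density, and a space-clamped (zero-gradient) forward-Euler
integrator.  Everything uses the depolarization convention: ``V`` is the
deviation of the membrane potential from rest, in mV, so the resting
state is ``V = 0``.

The space-clamped integrator applies exactly the same update rule as the
cable scheme with the diffusion term removed, so that a spatially uniform
cable run and a space-clamped run agree to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MembraneParams",
    "GatingState",
    "rate_coefficients",
    "gating_steady_state",
    "ionic_current",
    "integrate_space_clamped",
    "BlowUpError",
]

#: Voltage magnitude (mV) above which a trajectory is declared numerically
#: unstable.  Physical HH excursions stay below ~120 mV.
BLOWUP_MV = 500.0


class BlowUpError(RuntimeError):
    """Raised when a trajectory exceeds the blow-up guard voltage."""


@dataclass(frozen=True)
class MembraneParams:
    """Squid-axon membrane constants (depolarization convention).

    Attributes
    ----------
    C_m : float
        Membrane capacitance, uF/cm^2.
    gK_bar, gNa_bar, gL : float
        Maximal potassium, sodium and leak conductances, mS/cm^2.
    V_K, V_Na, V_L : float
        Reversal potentials relative to rest, mV.  The default leak
        reversal equilibrates the resting state: the total ionic current
        at ``V = 0`` with gating at steady state is ~0.
    R_i : float
        Intracellular (axial) resistivity, Ohm*cm.
    radius : float
        Fiber radius, cm.  Together with ``R_i`` and ``C_m`` it sets the
        voltage diffusion coefficient ``D = radius / (2 R_i C_m)``.
    """

    C_m: float = 1.0
    gK_bar: float = 36.0
    gNa_bar: float = 120.0
    gL: float = 0.3
    V_K: float = -12.0
    V_Na: float = 115.0
    V_L: float = 10.613
    R_i: float = 34.5
    radius: float = 3.0e-5

    def __post_init__(self) -> None:
        for name in ("C_m", "R_i", "radius"):
            if not getattr(self, name) > 0:
                raise ValueError(f"MembraneParams.{name} must be strictly positive")
        # conductances may be zeroed to reduce the model to a passive or
        # purely diffusive cable (used by the linear-cable oracles)
        for name in ("gK_bar", "gNa_bar", "gL"):
            if getattr(self, name) < 0:
                raise ValueError(f"MembraneParams.{name} must be nonnegative")

    @property
    def diffusion(self) -> float:
        """Voltage diffusion coefficient ``radius / (2 R_i C_m)`` in cm^2/ms."""
        # C_m is in uF/cm^2; Ohm*uF = us, hence the factor 1000 to get ms.
        return 1000.0 * self.radius / (2.0 * self.R_i * self.C_m)


@dataclass
class GatingState:
    """Dimensionless gating variables, each in [0, 1].

    ``n`` is potassium activation, ``m`` sodium activation and ``h``
    sodium inactivation.  Components may be scalars or equal-length
    arrays (one value per cable node).
    """

    n: np.ndarray | float
    m: np.ndarray | float
    h: np.ndarray | float

    def clamp(self) -> "GatingState":
        """Return a copy with every component clipped to [0, 1]."""
        return GatingState(
            n=np.clip(self.n, 0.0, 1.0),
            m=np.clip(self.m, 0.0, 1.0),
            h=np.clip(self.h, 0.0, 1.0),
        )


def _vtrap(x, scale):
    """Evaluate ``x / (exp(x/scale) - 1)`` with the removable singularity
    at ``x = 0`` filled by its series limit ``scale - x/2``."""
    x = np.asarray(x, dtype=float)
    near = np.abs(x) < 1e-6
    # expm1 keeps the quotient accurate for small but non-tiny x
    safe = np.where(near, 1.0, x)
    out = np.where(near, scale - x / 2.0, safe / np.expm1(safe / scale))
    return out


def rate_coefficients(V):
    """HH-1952 voltage-dependent rate coefficients, 1/ms.

    Parameters
    ----------
    V : float or ndarray
        Membrane depolarization in mV.

    Returns
    -------
    tuple of ndarray
        ``(alpha_n, beta_n, alpha_m, beta_m, alpha_h, beta_h)``, all
        nonnegative and continuous in ``V`` (the removable singularities
        of ``alpha_n`` at V=10 and ``alpha_m`` at V=25 are filled by
        their limits).

    Raises
    ------
    ValueError
        If any entry of ``V`` is not finite (this normally signals a
        numerical blow-up upstream).
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("non-finite membrane voltage passed to rate_coefficients")
    alpha_n = 0.01 * _vtrap(10.0 - V, 10.0)
    beta_n = 0.125 * np.exp(-V / 80.0)
    alpha_m = 0.1 * _vtrap(25.0 - V, 10.0)
    beta_m = 4.0 * np.exp(-V / 18.0)
    alpha_h = 0.07 * np.exp(-V / 20.0)
    beta_h = 1.0 / (np.exp((30.0 - V) / 10.0) + 1.0)
    return alpha_n, beta_n, alpha_m, beta_m, alpha_h, beta_h


def gating_steady_state(V) -> GatingState:
    """Equilibrium gating state ``x_inf = alpha_x / (alpha_x + beta_x)``."""
    an, bn, am, bm, ah, bh = rate_coefficients(V)
    return GatingState(n=an / (an + bn), m=am / (am + bm), h=ah / (ah + bh))


def ionic_current(V, gating: GatingState, p: MembraneParams):
    """Total ionic membrane current density, uA/cm^2 (outward positive).

    ``gK_bar n^4 (V - V_K) + gNa_bar m^3 h (V - V_Na) + gL (V - V_L)``.
    """
    V = np.asarray(V, dtype=float)
    return (
        p.gK_bar * gating.n**4 * (V - p.V_K)
        + p.gNa_bar * gating.m**3 * gating.h * (V - p.V_Na)
        + p.gL * (V - p.V_L)
    )


def resting_state(p: MembraneParams) -> tuple[float, GatingState]:
    """The resting point ``(V=0, gating at its V=0 steady state)``."""
    return 0.0, gating_steady_state(0.0)


def integrate_space_clamped(
    p: MembraneParams,
    applied_current,
    t_end: float,
    dt: float = 0.01,
    initial: tuple[float, GatingState] | None = None,
):
    """Forward-Euler integration of the space-clamped (point) HH system.

    Parameters
    ----------
    p : MembraneParams
    applied_current : float or callable
        Applied current density I(t) in uA/cm^2; a scalar means constant
        drive switched on at t=0.
    t_end : float
        Duration in ms.
    dt : float
        Time step in ms; must be <= 0.025 for the accuracy contract.
    initial : optional
        ``(V0, GatingState)``; defaults to rest.

    Returns
    -------
    dict with keys ``t, V, n, m, h`` (1-D arrays of length nsteps+1).

    Raises
    ------
    BlowUpError
        If |V| exceeds 500 mV (numerical instability).
    """
    if dt > 0.025:
        raise ValueError(f"dt={dt} exceeds the accuracy contract (dt <= 0.025 ms)")
    if callable(applied_current):
        I_of_t = applied_current
    else:
        I_const = float(applied_current)
        I_of_t = lambda t: I_const  # noqa: E731

    nsteps = int(round(t_end / dt))
    if initial is None:
        V0, g0 = resting_state(p)
    else:
        V0, g0 = initial
    V = float(V0)
    n, m, h = float(np.asarray(g0.n)), float(np.asarray(g0.m)), float(np.asarray(g0.h))

    out_t = np.empty(nsteps + 1)
    out_V = np.empty(nsteps + 1)
    out_n = np.empty(nsteps + 1)
    out_m = np.empty(nsteps + 1)
    out_h = np.empty(nsteps + 1)
    out_t[0], out_V[0], out_n[0], out_m[0], out_h[0] = 0.0, V, n, m, h

    for k in range(nsteps):
        t = k * dt
        an, bn, am, bm, ah, bh = rate_coefficients(V)
        I_ion = ionic_current(V, GatingState(n, m, h), p)
        V = V + dt * (I_of_t(t) - float(I_ion)) / p.C_m
        n = min(1.0, max(0.0, n + dt * (float(an) * (1 - n) - float(bn) * n)))
        m = min(1.0, max(0.0, m + dt * (float(am) * (1 - m) - float(bm) * m)))
        h = min(1.0, max(0.0, h + dt * (float(ah) * (1 - h) - float(bh) * h)))
        if abs(V) > BLOWUP_MV:
            raise BlowUpError(
                f"space-clamped trajectory blew up at t={t + dt:.3f} ms (V={V:.1f} mV)"
            )
        out_t[k + 1] = (k + 1) * dt
        out_V[k + 1] = V
        out_n[k + 1] = n
        out_m[k + 1] = m
        out_h[k + 1] = h

    return {"t": out_t, "V": out_V, "n": out_n, "m": out_m, "h": out_h}
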