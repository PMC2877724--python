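"""Monte-Carlo experiment designs for noise and spiking on the HH cable.

Every experiment in this module answers one question about how spatially
restricted noise shapes repetitive firing:

* deterministic sweeps locate the bifurcation-like onset of repetitive
  spiking in the drive amplitude (``mu_sweep``, ``find_critical_mu``,
  ``doublet_onset``, ``find_critical_ge``);
* ``isr_curve`` traces mean spike count against noise amplitude and
  exhibits inverse stochastic resonance (an interior minimum) near the
  critical drive;
* ``noise_extent_experiment`` and ``overlap_experiment`` vary where the
  noise lives relative to the signal window, separating the effect of
  noise on spike *generation* (overlapping) from spike *propagation*
  (disjoint);
* ``interior_excitation_control`` repeats the overlap/disjoint contrast
  with the stimulus in mid-cable to rule out boundary artifacts.

All stochastic experiments run 50 independent trials per design point
and summarize them with a normal-approximation 95% confidence interval.
Trial seeds are derived deterministically from a base seed, the
experiment label and the sweep value, so every number is reproducible
and sweep points are statistically independent.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cable import CableGrid, integrate, resting_field
from .membrane import MembraneParams, integrate_space_clamped
from .spikes import count_spikes_spatial, detect_spike_times
from .stimulation import DriveSpec, SynapticParams

__all__ = [
    "TrialSummary",
    "SweepResult",
    "REPETITIVE_MIN_SPIKES",
    "DEFAULT_SIGMA_GRID",
    "run_trials",
    "noise_free_count",
    "mu_sweep",
    "find_critical_mu",
    "doublet_onset",
    "isr_curve",
    "overlap_experiment",
    "noise_extent_experiment",
    "conductance_isr",
    "find_critical_ge",
    "interior_excitation_control",
    "trial_rng",
]

#: Final-time spatial spike count at or above which a run counts as
#: repetitive firing (the noise-free count jumps abruptly from <= 2 to a
#: plateau at the onset, so any cut between the branches is equivalent).
REPETITIVE_MIN_SPIKES = 5

#: Noise amplitudes scanned by default, covering the weak-noise range.
DEFAULT_SIGMA_GRID = (0.0, 0.02, 0.05, 0.1, 0.15, 0.2, 0.3)

N_TRIALS = 50


@dataclass
class TrialSummary:
    """Spike-count statistics over repeated seeded trials."""

    n_trials: int
    counts: np.ndarray
    mean: float
    ci95: float
    noise_free_count: int
    interference_fraction: float

    @classmethod
    def from_counts(cls, counts, noise_free: int) -> "TrialSummary":
        counts = np.asarray(counts, dtype=int)
        n = counts.size
        mean = float(counts.mean())
        sd = float(counts.std(ddof=1)) if n > 1 else 0.0
        return cls(
            n_trials=n,
            counts=counts,
            mean=mean,
            ci95=1.96 * sd / np.sqrt(n) if n > 1 else 0.0,
            noise_free_count=int(noise_free),
            interference_fraction=float(np.mean(counts < noise_free)),
        )


@dataclass
class SweepResult:
    """One ``TrialSummary`` per value of the swept variable."""

    variable: str
    values: np.ndarray
    summaries: list[TrialSummary] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.summaries) != self.values.size:
            raise ValueError("one summary per sweep value required")

    @property
    def means(self) -> np.ndarray:
        return np.array([s.mean for s in self.summaries])

    @property
    def ci95(self) -> np.ndarray:
        return np.array([s.ci95 for s in self.summaries])

    @property
    def interference(self) -> np.ndarray:
        return np.array([s.interference_fraction for s in self.summaries])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                self.variable: self.values,
                "mean_spikes": self.means,
                "ci95": self.ci95,
                "interference_fraction": self.interference,
                "noise_free_count": [s.noise_free_count for s in self.summaries],
                "n_trials": [s.n_trials for s in self.summaries],
            }
        )

    def trials_frame(self) -> pd.DataFrame:
        rows = []
        for v, s in zip(self.values, self.summaries):
            for i, c in enumerate(s.counts):
                rows.append({self.variable: v, "trial": i, "n_spikes": int(c)})
        return pd.DataFrame(rows)


def trial_rng(base_seed: int, experiment: str, sweep_value: float, trial: int):
    """Deterministic, collision-resistant per-trial generator.

    The stream is keyed on (base seed, experiment label, sweep value,
    trial index) so that repeating a run reproduces it exactly while
    different sweep points and experiments stay independent.
    """
    tag = zlib.crc32(experiment.encode()) & 0x7FFFFFFF
    vkey = int(round(sweep_value * 1e6)) & 0x7FFFFFFF
    return np.random.default_rng(
        np.random.SeedSequence([int(base_seed) & 0x7FFFFFFF, tag, vkey, trial])
    )


def _final_count(grid, p, drive, rng=None):
    rec = integrate(resting_field(grid, drive), grid, p, drive, rng=rng)
    return count_spikes_spatial(rec.final.V, grid.dx, t_eval=grid.t_end).n_spikes


def noise_free_count(grid: CableGrid, p: MembraneParams, drive: DriveSpec) -> int:
    """Spatial spike count at the final time with all noise switched off."""
    quiet = replace(
        drive,
        noise_kind="conductance" if drive.noise_kind == "conductance" else "none",
        sigma=0.0,
        synaptic=replace(drive.synaptic, sigma_e=0.0, sigma_i=0.0),
    )
    return _final_count(grid, p, quiet)


def run_trials(
    grid: CableGrid,
    p: MembraneParams,
    drive: DriveSpec,
    n_trials: int = N_TRIALS,
    base_seed: int = 0,
    experiment: str = "trials",
    sweep_value: float = 0.0,
    reference_count: int | None = None,
) -> TrialSummary:
    """Run ``n_trials`` independent integrations and summarize the counts.

    The interference fraction is the fraction of trials whose final-time
    count falls below the noise-free count of the same configuration
    (computed here unless supplied).
    """
    if reference_count is None:
        reference_count = noise_free_count(grid, p, drive)
    counts = np.empty(n_trials, dtype=int)
    for i in range(n_trials):
        rng = trial_rng(base_seed, experiment, sweep_value, i)
        counts[i] = _final_count(grid, p, drive, rng=rng)
    return TrialSummary.from_counts(counts, reference_count)


# ---------------------------------------------------------------------------
# Deterministic characterization
# ---------------------------------------------------------------------------

def mu_sweep(
    grid: CableGrid,
    p: MembraneParams,
    x_sig: float,
    mu_values,
) -> pd.DataFrame:
    """Noise-free spike count at the final time versus drive amplitude.

    Produces the step curve whose abrupt jump marks the onset of
    repetitive firing: 0 spikes at small ``mu``, then a solitary spike,
    a doublet, and finally a plateau of repetitive counts.
    """
    rows = []
    for mu in mu_values:
        drive = DriveSpec(mu=float(mu), signal_window=(0.0, x_sig))
        rows.append({"mu": float(mu), "n_spikes": _final_count(grid, p, drive)})
    return pd.DataFrame(rows)


def find_critical_mu(
    grid: CableGrid,
    p: MembraneParams,
    x_sig: float,
    resolution: float = 0.1,
    mu_lo: float = 4.0,
    mu_hi: float = 10.0,
) -> float:
    """Smallest drive (on the resolution grid) giving repetitive firing.

    A coarse upward scan in steps of 0.5 brackets the onset; the
    bracketing interval is then rescanned at ``resolution``.  The
    repetitive-firing criterion is a final-time spatial count of at
    least ``REPETITIVE_MIN_SPIKES``.
    """
    def repetitive(mu: float) -> bool:
        drive = DriveSpec(mu=mu, signal_window=(0.0, x_sig))
        return _final_count(grid, p, drive) >= REPETITIVE_MIN_SPIKES

    coarse = 0.5
    prev = mu_lo
    mu = mu_lo
    hit = None
    while mu <= mu_hi + 1e-9:
        if repetitive(mu):
            hit = mu
            break
        prev = mu
        mu += coarse
    if hit is None:
        raise ValueError(f"no repetitive firing found for mu <= {mu_hi}")
    mu = prev
    while mu <= hit + 1e-9:
        if repetitive(mu):
            return round(round(mu / resolution) * resolution, 9)
        mu += resolution
    return hit


def find_critical_mu_space_clamped(
    p: MembraneParams,
    resolution: float = 0.1,
    mu_lo: float = 4.0,
    mu_hi: float = 10.0,
    duration: float = 100.0,
    dt: float = 0.01,
) -> float:
    """Critical constant current for sustained firing in the point model.

    Scans the applied current upward and returns the smallest value (at
    the given resolution) for which the space-clamped system emits at
    least ``REPETITIVE_MIN_SPIKES`` spikes during ``duration`` ms of
    sustained drive from rest.
    """
    def repetitive(I: float) -> bool:
        sol = integrate_space_clamped(p, I, duration, dt)
        return detect_spike_times(sol["V"], sol["t"]).size >= REPETITIVE_MIN_SPIKES

    prev = mu_lo
    I = mu_lo
    hit = None
    while I <= mu_hi + 1e-9:
        if repetitive(I):
            hit = I
            break
        prev = I
        I += 0.5
    if hit is None:
        raise ValueError(f"no repetitive firing found for I <= {mu_hi}")
    I = prev
    while I <= hit + 1e-9:
        if repetitive(I):
            return round(round(I / resolution) * resolution, 9)
        I += resolution
    return hit


def doublet_onset(
    grid: CableGrid,
    p: MembraneParams,
    x_sig: float,
    mu_values=None,
) -> float:
    """Smallest drive on the scan grid producing exactly two spikes.

    The doublet is the last sub-repetitive response before the abrupt
    jump to a full train; by default the scan runs over {4.0, 4.5, ...,
    7.0}.
    """
    if mu_values is None:
        mu_values = np.arange(4.0, 7.0 + 1e-9, 0.5)
    for mu in mu_values:
        drive = DriveSpec(mu=float(mu), signal_window=(0.0, x_sig))
        if _final_count(grid, p, drive) == 2:
            return float(mu)
    raise ValueError("no doublet found on the scanned grid")


# ---------------------------------------------------------------------------
# Stochastic experiments
# ---------------------------------------------------------------------------

def isr_curve(
    grid: CableGrid,
    p: MembraneParams,
    mu: float,
    x_sig: float,
    sigmas=DEFAULT_SIGMA_GRID,
    noise_window: tuple[float, float] | None = None,
    n_trials: int = N_TRIALS,
    base_seed: int = 0,
) -> SweepResult:
    """Mean spike count versus additive-noise amplitude.

    With ``mu`` at the critical value the curve dips to an interior
    minimum before recovering (inverse stochastic resonance); well below
    the critical value it increases monotonically.  Noise covers the
    whole cable unless a window is given.
    """
    if noise_window is None:
        noise_window = (0.0, grid.L)
    base = DriveSpec(
        mu=mu, signal_window=(0.0, x_sig), noise_kind="additive",
        sigma=0.0, noise_window=noise_window,
    )
    ref = noise_free_count(grid, p, base)
    summaries = []
    for s in sigmas:
        if s == 0.0:
            summaries.append(TrialSummary.from_counts(np.full(n_trials, ref), ref))
            continue
        drive = replace(base, sigma=float(s))
        summaries.append(
            run_trials(
                grid, p, drive, n_trials, base_seed,
                experiment=f"isr:{x_sig}:{mu}", sweep_value=float(s),
                reference_count=ref,
            )
        )
    return SweepResult("sigma", np.asarray(sigmas, dtype=float), summaries)


def overlap_experiment(
    grid: CableGrid,
    p: MembraneParams,
    x_sig: float = 0.2,
    window_length: float = 0.2,
    offsets=(0.0, 0.04, 0.08, 0.12, 0.16, 0.2),
    mu: float | None = None,
    sigma: float = 0.1,
    n_trials: int = N_TRIALS,
    base_seed: int = 0,
) -> SweepResult:
    """Interference versus signal/noise overlap.

    A noise window of fixed length slides rightward from exact overlap
    with the signal window (offset 0) to complete disjointness.  The
    sweep variable reported is the overlap fraction of the signal window
    covered by noise; interference is the fraction of trials with fewer
    final-time spikes than the noise-free run.
    """
    if mu is None:
        mu = find_critical_mu(grid, p, x_sig)
    base = DriveSpec(mu=mu, signal_window=(0.0, x_sig), noise_kind="additive", sigma=sigma)
    ref = noise_free_count(grid, p, base)
    overlaps = []
    summaries = []
    from .stimulation import overlap_fraction

    for c in offsets:
        win = (float(c), float(c) + window_length)
        drive = replace(base, noise_window=win)
        overlaps.append(overlap_fraction(base.signal_window, win))
        summaries.append(
            run_trials(
                grid, p, drive, n_trials, base_seed,
                experiment=f"overlap:{x_sig}:{mu}:{sigma}", sweep_value=float(c),
                reference_count=ref,
            )
        )
    order = np.argsort(overlaps)
    return SweepResult(
        "overlap", np.asarray(overlaps)[order], [summaries[i] for i in order]
    )


def noise_extent_experiment(
    grid: CableGrid,
    p: MembraneParams,
    x_sig: float,
    mu: float | None = None,
    sigma: float = 0.1,
    b_values=None,
    n_trials: int = N_TRIALS,
    base_seed: int = 0,
) -> SweepResult:
    """Mean count with noise on ``[0, b]`` as the extent ``b`` grows.

    ``b`` runs from near zero to beyond the signal width and includes
    the whole cable; the headline comparison is that whole-cable noise
    silences no more effectively than noise covering just the signal
    region.  ``b = 0`` reproduces the noise-free count exactly.
    """
    if mu is None:
        mu = find_critical_mu(grid, p, x_sig)
    if b_values is None:
        b_values = [0.0, x_sig / 2, x_sig, 2 * x_sig, 4 * x_sig, grid.L]
    base = DriveSpec(mu=mu, signal_window=(0.0, x_sig), noise_kind="additive", sigma=sigma)
    ref = noise_free_count(grid, p, base)
    summaries = []
    for b in b_values:
        if b == 0.0:
            summaries.append(TrialSummary.from_counts(np.full(n_trials, ref), ref))
            continue
        drive = replace(base, noise_window=(0.0, float(b)))
        summaries.append(
            run_trials(
                grid, p, drive, n_trials, base_seed,
                experiment=f"extent:{x_sig}:{mu}:{sigma}", sweep_value=float(b),
                reference_count=ref,
            )
        )
    return SweepResult("b", np.asarray(b_values, dtype=float), summaries)


# ---------------------------------------------------------------------------
# Conductance-based (synaptic) input
# ---------------------------------------------------------------------------

def _conductance_drive(ge_bar: float, sigma_e: float, x_sig: float, syn: SynapticParams):
    return DriveSpec(
        mu=0.0,
        signal_window=(0.0, x_sig),
        noise_kind="conductance",
        noise_window=(0.0, x_sig),
        synaptic=replace(syn, ge_bar=ge_bar, sigma_e=sigma_e),
    )


def find_critical_ge(
    grid: CableGrid,
    p: MembraneParams,
    x_sig: float = 0.1,
    resolution: float = 0.001,
    ge_lo: float = 0.05,
    ge_hi: float = 0.2,
    synaptic: SynapticParams = SynapticParams(),
) -> float:
    """Repetitive-firing threshold in the equilibrium conductance.

    Noise-free bisection over ``ge_bar`` (excitatory-only synaptic drive
    co-located with the signal window) down to ``resolution`` mS/cm^2,
    using the same final-time count criterion as the current-drive case.
    """
    def repetitive(ge: float) -> bool:
        drive = _conductance_drive(ge, 0.0, x_sig, synaptic)
        return _final_count(grid, p, drive) >= REPETITIVE_MIN_SPIKES

    lo, hi = ge_lo, ge_hi
    if repetitive(lo):
        raise ValueError("ge_lo already repetitive; lower the bracket")
    if not repetitive(hi):
        raise ValueError("ge_hi not repetitive; raise the bracket")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if repetitive(mid):
            hi = mid
        else:
            lo = mid
    return hi


def conductance_isr(
    grid: CableGrid,
    p: MembraneParams,
    ge_bars,
    sigma_es=(0.0, 0.0005, 0.001, 0.002, 0.003, 0.005),
    x_sig: float = 0.1,
    synaptic: SynapticParams = SynapticParams(),
    n_trials: int = N_TRIALS,
    base_seed: int = 0,
) -> dict[float, SweepResult]:
    """Mean count versus conductance-noise amplitude for several ``ge_bar``.

    Reproduces the three regimes of the synaptic-input variant: a steep
    drop just above the firing threshold, an interior minimum well above
    it, and a monotone increase below it.
    """
    out: dict[float, SweepResult] = {}
    for ge in ge_bars:
        ref = _final_count(grid, p, _conductance_drive(float(ge), 0.0, x_sig, synaptic))
        summaries = []
        for se in sigma_es:
            if se == 0.0:
                summaries.append(TrialSummary.from_counts(np.full(n_trials, ref), ref))
                continue
            drive = _conductance_drive(float(ge), float(se), x_sig, synaptic)
            summaries.append(
                run_trials(
                    grid, p, drive, n_trials, base_seed,
                    experiment=f"cond-isr:{x_sig}:{ge}", sweep_value=float(se),
                    reference_count=ref,
                )
            )
        out[float(ge)] = SweepResult("sigma_e", np.asarray(sigma_es, dtype=float), summaries)
    return out


# ---------------------------------------------------------------------------
# Interior-excitation control
# ---------------------------------------------------------------------------

def interior_excitation_control(
    grid: CableGrid,
    p: MembraneParams,
    mu: float = 8.2,
    x_sig: float = 0.1,
    sigma: float = 0.1,
    t_eval: float | None = None,
    n_trials: int = N_TRIALS,
    base_seed: int = 0,
) -> dict:
    """Overlap/disjoint contrast with the stimulus in mid-cable.

    The signal window sits at the cable's center so spikes propagate
    symmetrically in both directions; the evaluation time is shortened
    (default ``t_end / 2``) so no spike reaches either sealed end.
    Feeding waves both ways doubles the axial load, so the interior
    repetitive-firing onset sits higher than at the sealed end (~8.0 vs
    6.7 for the default geometry); the default ``mu`` is just above it.
    Returns the noise-free left/right counts plus trial summaries for
    exactly-overlapping and for disjoint noise.
    """
    if t_eval is None:
        t_eval = grid.t_end / 2
    g = CableGrid(L=grid.L, nx=grid.nx, dt=grid.dt, t_end=t_eval)
    mid = grid.L / 2
    sig_win = (mid - x_sig / 2, mid + x_sig / 2)
    base = DriveSpec(mu=mu, signal_window=sig_win, noise_kind="additive", sigma=sigma)

    rec = integrate(resting_field(g), g, p, replace(base, noise_kind="none"))
    sc = count_spikes_spatial(rec.final.V, g.dx, t_eval=t_eval)
    left = int(np.sum(sc.positions < mid))
    right = int(np.sum(sc.positions > mid))
    ref = sc.n_spikes

    overlap = run_trials(
        g, p, replace(base, noise_window=sig_win), n_trials, base_seed,
        experiment="interior:overlap", reference_count=ref,
    )
    disj_win = (mid + x_sig / 2 + 0.05, mid + x_sig / 2 + 0.05 + 2 * x_sig)
    disjoint = run_trials(
        g, p, replace(base, noise_window=disj_win), n_trials, base_seed,
        experiment="interior:disjoint", reference_count=ref,
    )
    return {
        "noise_free_left": left,
        "noise_free_right": right,
        "noise_free_total": ref,
        "overlap": overlap,
        "disjoint": disjoint,
    }
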