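"""Synthetic metastable walker.

This module generates walking data with the statistical structure the rest of
the package assumes: a discrete bank of start-of-step states, horizontal
impulsive perturbations on a uniform velocity grid, an absorbing failure
region, and per-step multi-channel trajectories resampled to 100 points.

The walker is deliberately simple.  Its step-to-step dynamics are a 1-D
affine-plus-saturation return map

    x+ = x* + c * tanh((a (x - x*) + b s) / c)

where ``x`` is the start-of-step state (a velocity-like deviation from the
periodic gait), ``s`` the horizontal impulse perturbation in m/s, ``a`` the
contraction rate, ``b`` a timing-dependent input gain, ``x*`` the fixed point
and ``c`` a mild saturation scale.  A step fails (the walker falls) when the
post-step state leaves the band ``|x+| <= failure_boundary``.  This is the
cheapest dynamical system with genuine metastability and a tunable basin of
attraction: under Gaussian perturbations the mean first passage time to the
failure region spans many orders of magnitude as ``a`` and the boundary vary.

Within-step trajectories are synthesized from a bank of 100-sample template
waveforms (joint angles, hip position, velocities, ground reaction force,
ankle force/torque, foot geometry), each linearly modulated by the start-state
deviation and the perturbation.  The kinetic channels are template-based and
mutually consistent only where the downstream metrics require it (the vertical
ankle force balances the normal ground reaction force and the foot is treated
as massless, so the foot rotation index behaves like a center of pressure);
they are not the output of a rigid-body simulation.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from .exceptions import ConfigurationError, OutOfDomainError

__all__ = [
    "CHANNELS",
    "CH",
    "N_SAMPLES",
    "TIMINGS",
    "FAIL",
    "WalkerConfig",
    "StepTrajectory",
    "StepSequence",
    "DeterministicMesh",
    "simulate_step",
    "build_deterministic_mesh",
    "simulate_brute",
    "load_preset",
    "preset_names",
]

N_SAMPLES = 100

#: Trajectory channels, in storage order.  q1..q6 are joint angles (rad),
#: q7/q8 the horizontal/vertical hip position (m), dq* the corresponding
#: velocities, xst/yst the stance contact point (m), Fn the normal ground
#: reaction force (N), Fax/Fay the stance ankle force (N), tau_a the stance
#: ankle torque (N m), G the foot mass center, A the ankle point and Fg the
#: gravitational force on the foot (zero: the foot is treated as massless).
CHANNELS = [
    "q1", "q2", "q3", "q4", "q5", "q6", "q7", "q8",
    "dq1", "dq2", "dq3", "dq4", "dq5", "dq6", "dq7", "dq8",
    "xst", "yst", "Fn", "Fax", "Fay", "tau_a",
    "Gx", "Gy", "Ax", "Ay", "Fgx", "Fgy",
]
CH = {name: i for i, name in enumerate(CHANNELS)}
N_CHANNELS = len(CHANNELS)

TIMINGS = ("DS0", "SS0", "SS0.5")
#: Effect of perturbation timing on the step-to-step input gain: a push at the
#: start of double support acts on the full step, later pushes act on less of
#: it.
_TIMING_GAIN = {"DS0": 1.0, "SS0": 0.92, "SS0.5": 0.82}
#: Phase shift of the perturbation-driven waveform deformation: later pushes
#: deform later portions of the step.
_TIMING_PHASE = {"DS0": 0.0, "SS0": 0.5, "SS0.5": 1.5}


class _FailType:
    """Singleton sentinel for a failed (absorbed) step."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "FAIL"

    def __bool__(self) -> bool:
        return False


FAIL = _FailType()

# Joint-angle templates: channel -> (offset rad, amplitude rad, phase rad).
_ANGLE_TEMPLATES = {
    "q1": (0.00, 0.05, 0.0),
    "q2": (0.30, 0.25, 0.6),
    "q3": (-0.10, 0.15, 1.2),
    "q4": (-0.20, 0.40, 1.8),
    "q5": (0.10, 0.08, 2.4),
    "q6": (-0.05, 0.12, 3.0),
}

# Deformation sensitivities: channel -> (state gain, perturbation gain,
# modulation phase).  Units: channel units per (m/s) of state deviation or
# perturbation.  Channels not listed are never deformed directly.
_DEFORM_GAINS = {
    "q1": (0.60, 0.40, 0.0),
    "q2": (0.90, 0.50, 0.7),
    "q3": (0.70, 0.60, 1.4),
    "q4": (1.10, 0.50, 2.1),
    "q5": (0.50, 0.70, 2.8),
    "q6": (0.80, 0.45, 3.5),
    "q8": (0.30, 0.20, 0.9),
    "dq1": (2.50, 1.50, 0.3),
    "dq2": (3.50, 1.80, 1.0),
    "dq3": (2.80, 2.00, 1.7),
    "dq4": (4.00, 1.60, 2.4),
    "dq5": (2.20, 2.40, 3.1),
    "dq6": (3.00, 1.70, 3.8),
    "dq7": (1.00, 0.50, 0.5),
    "dq8": (1.00, 0.80, 1.2),
    "Fn": (600.0, 350.0, 0.4),
    "Fax": (150.0, 90.0, 1.1),
    "tau_a": (30.0, 18.0, 1.8),
    "Gx": (0.05, 0.03, 2.5),
    "Gy": (0.02, 0.015, 3.2),
    "Ax": (0.05, 0.04, 0.2),
    "Ay": (0.02, 0.01, 0.9),
}


@dataclass(frozen=True)
class WalkerConfig:
    """Full specification of a synthetic walker.

    The default perturbation grid spans -0.200..+0.200 m/s at 0.002 m/s
    spacing (201 points) and perturbations are drawn from N(0, 0.013^2) m/s,
    applied under one of three timing conditions.
    """

    # Step-to-step return map.
    contraction: float = 0.80          # a, dimensionless
    input_gain: float = 1.0            # b, (m/s state) per (m/s impulse)
    fixed_point: float = 0.0           # x*, m/s
    failure_boundary: float = 0.08     # fall iff |x+| exceeds this, m/s
    saturation: float = 0.25           # c, m/s; softcap of the map increment
    # State discretization (mesh construction).
    state_dim: int = 1
    grid_halfwidth: float = 0.08       # m/s
    grid_spacing: float = 0.004        # m/s
    # Perturbations.
    perturbation_min: float = -0.200   # m/s
    perturbation_max: float = 0.200    # m/s
    perturbation_spacing: float = 0.002  # m/s
    noise_sd: float = 0.013            # m/s
    timing: str = "DS0"
    # Physical scale.
    g: float = 9.81                    # m/s^2
    mass: float = 86.7                 # kg
    leg_length: float = 1.16           # m
    nominal_step_duration: float = 1.0  # T0, s
    nominal_step_length: float = 1.0    # L0, m
    # Spatiotemporal sensitivities (per m/s of state deviation/perturbation).
    duration_state_gain: float = 0.5
    duration_pert_gain: float = 0.2
    length_state_gain: float = 0.3
    length_pert_gain: float = 0.1
    # Global multiplier on all per-channel deformation gains.
    deformation_scale: float = 1.0
    # Walker identity: per-channel template-amplitude and gain multipliers
    # drawn deterministically from the seed, scaled by this factor (0
    # disables them).  Distinct walkers thus have distinct waveforms, the
    # way distinct gaits do.
    style_scale: float = 0.72
    seed: int = 0
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.state_dim != 1:
            raise ConfigurationError(
                "only 1-D walker states are implemented (state_dim=1)")
        if self.timing not in TIMINGS:
            raise ConfigurationError(
                f"timing must be one of {TIMINGS}, got {self.timing!r}")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.nominal_step_duration <= 0:
            raise ConfigurationError("nominal_step_duration must be positive")
        span = self.perturbation_max - self.perturbation_min
        if span <= 0 or self.perturbation_spacing <= 0:
            raise ConfigurationError("empty perturbation grid")
        ratio = span / self.perturbation_spacing
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigurationError(
                "perturbation spacing must divide (max - min) exactly")
        if self.grid_halfwidth < 0 or self.grid_spacing <= 0:
            raise ConfigurationError("invalid state grid")
        if self.grid_halfwidth > 0:
            gratio = 2.0 * self.grid_halfwidth / self.grid_spacing
            if abs(gratio - round(gratio)) > 1e-9:
                raise ConfigurationError(
                    "grid spacing must divide the grid span exactly")
        if abs(self.fixed_point) > self.grid_halfwidth + 1e-12:
            raise ConfigurationError("fixed point lies outside the state grid")

    # -- derived quantities -------------------------------------------------

    @property
    def nominal_speed(self) -> float:
        """Mean forward speed of the periodic gait (m/s)."""
        return self.nominal_step_length / self.nominal_step_duration

    @property
    def perturbation_grid(self) -> np.ndarray:
        n = int(round((self.perturbation_max - self.perturbation_min)
                      / self.perturbation_spacing)) + 1
        return np.linspace(self.perturbation_min, self.perturbation_max, n)

    @property
    def timing_gain(self) -> float:
        return self.input_gain * _TIMING_GAIN[self.timing]

    def replace(self, **kwargs) -> "WalkerConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name)
                for f in self.__dataclass_fields__.values()}  # type: ignore[attr-defined]

    @classmethod
    def from_dict(cls, d: dict) -> "WalkerConfig":
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "WalkerConfig":
        return cls.from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# Trajectory synthesis
# ---------------------------------------------------------------------------

_PHASE = (np.arange(N_SAMPLES) + 0.5) / N_SAMPLES  # step phase, (100,)
_TWO_PI_U = 2.0 * math.pi * _PHASE


@lru_cache(maxsize=128)
def _style(seed: int, scale: float):
    """Per-walker waveform identity: multipliers on the joint-angle
    template amplitudes and on the deformation gains, deterministic in the
    seed."""
    rng = np.random.default_rng(np.uint32(seed) ^ np.uint32(0x5EED))
    amp = {name: 1.0 + 0.08 * scale * rng.uniform(-1, 1)
           for name in _ANGLE_TEMPLATES}
    gains = {name: (1.0 + 0.25 * scale * rng.uniform(-1, 1),
                    1.0 + 0.25 * scale * rng.uniform(-1, 1))
             for name in _DEFORM_GAINS}
    return amp, gains


def _return_map(config: WalkerConfig, x: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Raw (un-snapped) post-step state for start states ``x`` and
    perturbations ``s``."""
    c = config.saturation
    u = (config.contraction * (x - config.fixed_point)
         + config.timing_gain * s)
    return config.fixed_point + c * np.tanh(u / c)


def _scalars(config: WalkerConfig, x: np.ndarray, s: np.ndarray):
    """Per-step duration, length and mean speed for start states ``x`` and
    perturbations ``s`` (vectorized)."""
    # the absolute state drives the waveforms, so walkers with an offset
    # periodic gait (fixed_point != 0) have genuinely shifted mean metrics
    drv = np.asarray(x, dtype=float)
    se = _TIMING_GAIN[config.timing] * np.asarray(s, dtype=float)
    T = config.nominal_step_duration * (
        1.0 + config.duration_state_gain * drv + config.duration_pert_gain * se)
    L = config.nominal_step_length * (
        1.0 + config.length_state_gain * drv + config.length_pert_gain * se)
    T = np.maximum(T, 0.2 * config.nominal_step_duration)
    L = np.maximum(L, 0.2 * config.nominal_step_length)
    return T, L, L / T


def synthesize_steps(config: WalkerConfig, x: np.ndarray, s: np.ndarray):
    """Synthesize trajectories for ``n`` steps.

    Parameters
    ----------
    x, s : arrays of shape (n,)
        Start-of-step states and perturbations.

    Returns
    -------
    samples : (n, 100, n_channels) array
    T, L, v : (n,) arrays of step duration, length and mean speed.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    s = np.atleast_1d(np.asarray(s, dtype=float))
    n = x.shape[0]
    dev = x  # absolute state; see _scalars
    se = _TIMING_GAIN[config.timing] * s
    T, L, v = _scalars(config, x, s)

    out = np.zeros((n, N_SAMPLES, N_CHANNELS))
    leg = config.leg_length
    amp_mult, gain_mult = _style(config.seed, config.style_scale)

    for name, (off, amp, ph) in _ANGLE_TEMPLATES.items():
        amp = amp * amp_mult[name]
        out[:, :, CH[name]] = off + amp * np.sin(_TWO_PI_U + ph)
        out[:, :, CH["d" + name]] = (
            (2.0 * math.pi / T)[:, None] * amp * np.cos(_TWO_PI_U + ph))
    out[:, :, CH["q7"]] = L[:, None] * (_PHASE - 0.5)
    out[:, :, CH["q8"]] = leg * (0.97 + 0.015 * np.cos(2.0 * _TWO_PI_U))
    out[:, :, CH["dq7"]] = v[:, None] * (1.0 + 0.1 * np.sin(_TWO_PI_U))
    out[:, :, CH["dq8"]] = (
        -(0.06 * math.pi * leg / T)[:, None] * np.sin(2.0 * _TWO_PI_U))
    # Stance contact at the local origin; xst/yst stay zero.
    w = config.mass * config.g
    out[:, :, CH["Fn"]] = w * (1.0 + 0.15 * np.sin(_TWO_PI_U + 0.5))
    out[:, :, CH["Fax"]] = -0.15 * w * np.sin(_TWO_PI_U)
    out[:, :, CH["tau_a"]] = 15.0 * np.sin(_TWO_PI_U + 0.8)
    out[:, :, CH["Gx"]] = 0.03
    out[:, :, CH["Gy"]] = 0.04
    out[:, :, CH["Ax"]] = -0.01 + 0.01 * np.sin(_TWO_PI_U)
    out[:, :, CH["Ay"]] = 0.08

    tphase = _TIMING_PHASE[config.timing]
    scale = config.deformation_scale
    for name, (gx, gs, psi) in _DEFORM_GAINS.items():
        mx, ms = gain_mult[name]
        mod_x = 0.6 + 0.4 * np.sin(_TWO_PI_U + psi)
        mod_s = 0.6 + 0.4 * np.sin(_TWO_PI_U + psi + tphase)
        out[:, :, CH[name]] += scale * (
            (gx * mx * dev)[:, None] * mod_x
            + (gs * ms * se)[:, None] * mod_s)

    # Kinetic consistency for the foot: massless foot, ankle carries the load.
    np.maximum(out[:, :, CH["Fn"]], 50.0, out=out[:, :, CH["Fn"]])
    out[:, :, CH["Fay"]] = -out[:, :, CH["Fn"]]
    return out, T, L, v


@dataclass
class StepTrajectory:
    """One step: a (100, n_channels) sample array plus spatiotemporal
    scalars."""

    samples: np.ndarray        # (100, n_channels)
    T: float                   # step duration, s
    L: float                   # step length, m
    v: float                   # mean speed, m/s
    failed: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape != (N_SAMPLES, N_CHANNELS):
            raise ValueError(
                f"samples must have shape ({N_SAMPLES}, {N_CHANNELS})")
        if self.T <= 0:
            raise ValueError("step duration must be positive")
        if self.L < 0:
            raise ValueError("step length must be non-negative")

    def channel(self, name: str) -> np.ndarray:
        return self.samples[:, CH[name]]


@dataclass
class StepSequence:
    """A sequence of completed steps, stored compactly.

    Only the start states and perturbations are stored; the 100-sample
    trajectories are synthesized on demand (they are a deterministic function
    of ``(x0, s)`` given the config), which keeps thousand-step trials cheap.
    ``failed`` records whether the step after the last completed one was a
    fall.
    """

    config: WalkerConfig
    x0: np.ndarray             # (n,) start-of-step states
    s: np.ndarray              # (n,) perturbations
    failed: bool = False

    def __post_init__(self) -> None:
        self.x0 = np.atleast_1d(np.asarray(self.x0, dtype=float))
        self.s = np.atleast_1d(np.asarray(self.s, dtype=float))
        if self.x0.shape != self.s.shape:
            raise ValueError("x0 and s must have equal length")

    def __len__(self) -> int:
        return self.x0.shape[0]

    def __getitem__(self, key) -> "StepSequence":
        if not isinstance(key, slice):
            raise TypeError("use .step(i) for single steps")
        # A slice never spans the fall unless it includes the final step.
        tail = key.indices(len(self))[1] >= len(self)
        return StepSequence(self.config, self.x0[key], self.s[key],
                            failed=self.failed and tail)

    def samples(self) -> np.ndarray:
        """Synthesize the (n, 100, n_channels) trajectory stack."""
        out, _, _, _ = synthesize_steps(self.config, self.x0, self.s)
        return out

    def scalars(self):
        """Per-step (T, L, v) arrays without synthesizing full trajectories."""
        return _scalars(self.config, self.x0, self.s)

    def step(self, i: int) -> StepTrajectory:
        out, T, L, v = synthesize_steps(
            self.config, self.x0[i:i + 1], self.s[i:i + 1])
        return StepTrajectory(out[0], float(T[0]), float(L[0]), float(v[0]))

    def steps(self):
        out, T, L, v = synthesize_steps(self.config, self.x0, self.s)
        return [StepTrajectory(out[i], float(T[i]), float(L[i]), float(v[i]))
                for i in range(len(self))]


# ---------------------------------------------------------------------------
# Single-step simulation and mesh construction
# ---------------------------------------------------------------------------

def simulate_step(config: WalkerConfig, state: float, perturbation: float):
    """Simulate one step from ``state`` under ``perturbation``.

    Returns ``(next_state, StepTrajectory)`` for a successful step or
    ``(FAIL, StepTrajectory)`` when the post-step state crosses the failure
    boundary.  The returned next state is continuous (not snapped to the
    mesh grid).
    """
    if abs(perturbation) > config.perturbation_max + 1e-12:
        raise OutOfDomainError(
            f"perturbation {perturbation} outside "
            f"[{config.perturbation_min}, {config.perturbation_max}]")
    if abs(state) > config.grid_halfwidth + 0.5 * config.grid_spacing + 1e-12:
        raise OutOfDomainError(f"state {state} outside the state grid")
    out, T, L, v = synthesize_steps(
        config, np.array([state]), np.array([perturbation]))
    nxt = float(_return_map(config, np.array([state]),
                            np.array([perturbation]))[0])
    failed = abs(nxt) > config.failure_boundary
    traj = StepTrajectory(out[0], float(T[0]), float(L[0]), float(v[0]),
                          failed=failed)
    return (FAIL if failed else nxt), traj


@dataclass
class DeterministicMesh:
    """One-step response catalog: (start state, perturbation) -> outcome.

    ``states`` holds the discretized start-of-step states with the nominal
    periodic state first (index 0).  ``transitions[i, k]`` is the end-state
    index for perturbation ``perturbation_grid[k]`` applied in state ``i``, or
    ``-1`` for a fall.  Trajectories are synthesized on demand; for a given
    (i, j) pair the stored trajectory is by convention the one for the median
    of all perturbations realizing that transition.
    """

    config: WalkerConfig
    states: np.ndarray          # (t,)
    transitions: np.ndarray     # (t, n_perturbations), int
    perturbation_grid: np.ndarray

    FAIL_INDEX = -1

    @property
    def n_states(self) -> int:
        return self.states.shape[0]

    def successors(self, i: int) -> np.ndarray:
        """Distinct surviving end-state indices reachable from state ``i``."""
        row = self.transitions[i]
        return np.unique(row[row >= 0])

    def median_perturbation(self, i: int, j: int) -> float:
        """Median of the grid perturbations sending state ``i`` to ``j``
        (``j = -1`` selects the failing perturbations).  For an even count the
        lower middle value is taken."""
        svals = self.perturbation_grid[self.transitions[i] == j]
        if svals.size == 0:
            raise KeyError(f"no transition {i} -> {j}")
        svals = np.sort(svals)
        return float(svals[(svals.size - 1) // 2])

    def trajectory(self, i: int, j: int) -> StepTrajectory:
        """The stored (median-perturbation) trajectory for transition
        ``i -> j``."""
        s = self.median_perturbation(i, j)
        _, traj = simulate_step(self.config, float(self.states[i]), s)
        return traj

    def unique_transitions(self):
        """All surviving (i, j) pairs with their median perturbations.

        Returns ``(i_idx, j_idx, s_med)`` arrays of equal length, ordered by
        (i, j)."""
        ii, jj, ss = [], [], []
        for i in range(self.n_states):
            for j in self.successors(i):
                ii.append(i)
                jj.append(int(j))
                ss.append(self.median_perturbation(i, int(j)))
        return (np.asarray(ii, dtype=int), np.asarray(jj, dtype=int),
                np.asarray(ss, dtype=float))


def _state_grid(config: WalkerConfig):
    """Sorted state grid and the permutation placing the nominal state
    first."""
    if config.grid_halfwidth == 0:
        grid = np.array([0.0])
    else:
        m = int(round(2 * config.grid_halfwidth / config.grid_spacing)) + 1
        grid = np.linspace(-config.grid_halfwidth, config.grid_halfwidth, m)
    i_nom = int(np.argmin(np.abs(grid - config.fixed_point)))
    order = np.concatenate(([i_nom],
                            np.delete(np.arange(grid.size), i_nom)))
    return grid, order


def build_deterministic_mesh(config: WalkerConfig) -> DeterministicMesh:
    """Enumerate one step for every (grid state, grid perturbation) pair.

    End states are snapped to the nearest grid state (ties to the lower
    index); non-failed states beyond the grid edge snap to the boundary
    state.  State 1 (index 0) is the nominal periodic state.
    """
    grid, order = _state_grid(config)
    if grid.size == 0:
        raise ConfigurationError("empty state grid")
    pert = config.perturbation_grid
    states = grid[order]
    # inverse permutation: sorted index -> mesh index
    inv = np.empty(grid.size, dtype=int)
    inv[order] = np.arange(grid.size)

    nxt = _return_map(config, states[:, None], pert[None, :])
    fail = np.abs(nxt) > config.failure_boundary
    if grid.size == 1:
        snapped = np.zeros_like(nxt, dtype=int)
    else:
        dx = config.grid_spacing
        pos = (nxt + config.grid_halfwidth) / dx
        # round half down so midpoint ties go to the lower sorted index
        idx_sorted = np.floor(pos + 0.5 - 1e-12).astype(int)
        np.clip(idx_sorted, 0, grid.size - 1, out=idx_sorted)
        snapped = inv[idx_sorted]
    trans = np.where(fail, DeterministicMesh.FAIL_INDEX, snapped).astype(int)
    return DeterministicMesh(config, states, trans, pert)


# ---------------------------------------------------------------------------
# Brute-force simulation
# ---------------------------------------------------------------------------

def simulate_brute(
    config: WalkerConfig,
    perturbation_vectors: Optional[Sequence[np.ndarray]] = None,
    n_steps: int = 1000,
    rng: Union[np.random.Generator, int, None] = None,
    ensure_segments: Optional[tuple] = None,
) -> list:
    """Simulate perturbed walking trials with a perturbation every step.

    Parameters
    ----------
    perturbation_vectors
        Sequences of per-step perturbations (m/s).  When omitted, 10 vectors
        of length ``n_steps`` are drawn from N(0, noise_sd^2) using ``rng``.
        The same vectors can be reused across configs so that different
        walkers experience identical perturbation histories.
    n_steps
        Steps per trial; a trial ends early at the first fall.
    ensure_segments
        Optional ``(count, seg_len)``: keep drawing additional random trials
        until the completed steps can be divided into ``count`` disjoint
        segments of ``seg_len`` steps (e.g. ``(200, 50)``).

    Returns
    -------
    list of StepSequence (completed steps only; ``failed`` marks early falls).
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    if perturbation_vectors is None:
        perturbation_vectors = [rng.normal(0.0, config.noise_sd, n_steps)
                                for _ in range(10)]
    vectors = [np.asarray(vec, dtype=float) for vec in perturbation_vectors]
    for vec in vectors:
        if vec.shape[0] < n_steps:
            raise ConfigurationError(
                "perturbation vector shorter than n_steps")

    def run(vec: np.ndarray) -> StepSequence:
        xs = np.empty(n_steps)
        x = config.fixed_point
        failed = False
        k = 0
        for k in range(n_steps):
            xs[k] = x
            nxt = _return_map(config, np.array([x]), vec[k:k + 1])[0]
            if abs(nxt) > config.failure_boundary:
                failed = True
                break
            x = float(nxt)
        n_done = k + 1 if not failed else k
        return StepSequence(config, xs[:n_done], vec[:n_done], failed=failed)

    trials = [run(vec) for vec in vectors]
    if ensure_segments is not None:
        count, seg_len = ensure_segments
        def total(ts):
            return sum(len(t) // seg_len for t in ts)
        guard = 0
        while total(trials) < count:
            trials.append(run(rng.normal(0.0, config.noise_sd, n_steps)))
            guard += 1
            if guard > 10000:
                raise ConfigurationError(
                    "walker too fragile to accumulate the requested segments")
    return trials


# ---------------------------------------------------------------------------
# Preset bank
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def _preset_table() -> dict:
    text = (importlib.resources.files("gaitrisk") / "presets.yaml").read_text()
    return yaml.safe_load(text)


def preset_names(role: Optional[str] = None) -> list:
    """Names of shipped walker presets; ``role`` filters on 'train', 'val' or
    'extra'."""
    table = _preset_table()
    if role is None:
        return list(table)
    return [k for k, v in table.items() if v.get("role") == role]


def load_preset(name: str, timing: str = "DS0", **overrides) -> WalkerConfig:
    """Load a shipped preset by name, optionally overriding fields."""
    table = _preset_table()
    if name not in table:
        raise KeyError(f"unknown preset {name!r}; have {sorted(table)}")
    params = {k: v for k, v in table[name].items() if k != "role"}
    params.update(timing=timing, name=name)
    params.update(overrides)
    return WalkerConfig(**params)
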