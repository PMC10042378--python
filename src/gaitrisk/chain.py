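"""Absorbing Markov chain built from a deterministic step-transition mesh.

A metastable gait is modelled as a discrete-time absorbing Markov chain over
start-of-step states.  The full transition matrix has the block form

    Ts = [[Q, R],
          [0, 1]]

with ``Q`` the t x t substochastic matrix among transient (walking) states and
``R`` the per-state probability of falling.  Transition probabilities follow
from integrating a Gaussian perturbation law N(0, noise_sd^2) over the
half-open grid cells of the perturbation grid, with the two boundary cells
absorbing the tails so the masses sum to exactly one.

The mean first passage time (MFPT) to the fall state is reported two ways:

* ``mfpt_eigen = -1 / log(lambda_2)`` with ``lambda_2`` the largest-modulus
  eigenvalue of ``Q`` (the second-largest eigenvalue of ``Ts``), and
* ``mfpt_exact``, the row sum of the first row of the fundamental matrix
  ``N = (I - Q)^-1`` (expected visits to each transient state starting from
  the nominal step).

The two agree in the metastable limit; both are always computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import linalg, stats

from .exceptions import NonAbsorbingChainError, StructuralError
from .walker import DeterministicMesh, StepSequence

__all__ = [
    "AbsorbingChain",
    "ChainStatistics",
    "gaussian_cell_masses",
    "build_chain",
    "chain_statistics",
    "sample_chain_trajectory",
    "sample_absorption_steps",
]


def gaussian_cell_masses(grid: np.ndarray, noise_sd: float) -> np.ndarray:
    """Probability mass of N(0, noise_sd^2) on each grid cell.

    Cells are the half-open intervals between midpoints of consecutive grid
    values; the first and last cells extend to -inf / +inf so the masses sum
    to exactly one.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("perturbation grid must be a non-empty 1-D array")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    edges = np.empty(grid.size + 1)
    edges[1:-1] = 0.5 * (grid[1:] + grid[:-1])
    edges[0] = -np.inf
    edges[-1] = np.inf
    cdf = stats.norm.cdf(edges, scale=noise_sd)
    masses = np.diff(cdf)
    # guard against tiny negative round-off
    np.clip(masses, 0.0, None, out=masses)
    masses /= masses.sum()
    return masses


@dataclass
class AbsorbingChain:
    """Transient block ``Q``, failure column ``R`` and bookkeeping."""

    Q: np.ndarray               # (t, t)
    R: np.ndarray               # (t,)
    state_labels: np.ndarray    # (t,) state values (m/s)
    mesh: Optional[DeterministicMesh] = None
    noise_sd: Optional[float] = None

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        t = self.Q.shape[0]
        if self.Q.shape != (t, t) or self.R.shape != (t,):
            raise ValueError("Q must be square and R a matching vector")
        if np.any(self.Q < 0) or np.any(self.R < -1e-15):
            raise ValueError("transition probabilities must be non-negative")
        rows = self.Q.sum(axis=1) + self.R
        if np.max(np.abs(rows - 1.0)) > 1e-12:
            raise ValueError("rows of [Q | R] must sum to 1 within 1e-12")

    @property
    def n_states(self) -> int:
        return self.Q.shape[0]


@dataclass
class ChainStatistics:
    """Fundamental-matrix and spectral summaries of an absorbing chain."""

    N: np.ndarray              # fundamental matrix (I - Q)^-1
    n1: np.ndarray             # expected visits from the nominal state (row 1)
    lambda2: float             # largest-modulus eigenvalue of Q
    mfpt_eigen: float          # -1 / log(lambda2); NaN when undefined
    mfpt_exact: float          # sum of n1

    @property
    def mfpt(self) -> float:
        """The "true MFPT" used downstream: the eigenvalue form by default,
        falling back to the fundamental-matrix value when the eigenvalue
        estimate is numerically undefined."""
        return self.mfpt_eigen if np.isfinite(self.mfpt_eigen) \
            else self.mfpt_exact

    def to_dict(self) -> dict:
        return {
            "lambda2": float(self.lambda2),
            "mfpt_eigen": float(self.mfpt_eigen),
            "mfpt_exact": float(self.mfpt_exact),
            "n1": [float(x) for x in self.n1],
        }


def build_chain(mesh: DeterministicMesh,
                noise_sd: Optional[float] = None) -> AbsorbingChain:
    """Weight the deterministic mesh by the Gaussian perturbation law.

    ``Q[i, j]`` collects the Gaussian cell masses of all grid perturbations
    sending state ``i`` to state ``j``; ``R[i]`` collects the failing ones.
    """
    if noise_sd is None:
        noise_sd = mesh.config.noise_sd
    t = mesh.n_states
    if t == 0:
        raise StructuralError("mesh has no states")
    w = gaussian_cell_masses(mesh.perturbation_grid, noise_sd)
    Q = np.zeros((t, t))
    R = np.zeros(t)
    for i in range(t):
        row = mesh.transitions[i]
        ok = row >= 0
        if not ok.any() and not (~ok).any():
            raise StructuralError(f"state {i} has no transitions")
        np.add.at(Q[i], row[ok], w[ok])
        R[i] = w[~ok].sum()
    # renormalize rows exactly (cell masses already sum to 1; this removes
    # accumulation round-off only)
    rows = Q.sum(axis=1) + R
    Q /= rows[:, None]
    R /= rows
    return AbsorbingChain(Q, R, mesh.states.copy(), mesh=mesh,
                          noise_sd=noise_sd)


def chain_statistics(chain: AbsorbingChain) -> ChainStatistics:
    """Fundamental matrix, visit expectations and both MFPT estimates.

    Raises
    ------
    NonAbsorbingChainError
        When the spectral radius of ``Q`` is >= 1 (absorption not certain).
    """
    Q = chain.Q
    t = chain.n_states
    eigvals = np.linalg.eigvals(Q)
    lam2 = float(np.max(np.abs(eigvals))) if t else 0.0
    if lam2 >= 1.0:
        # For extremely metastable chains the true lambda2 is 1 - O(1e-13)
        # and eigensolver round-off can push the estimate to >= 1 even
        # though absorption is certain; fall back to NaN for the eigenvalue
        # estimate in that case instead of refusing the chain.
        if lam2 > 1.0 + 1e-8 or chain.R.sum() <= 0:
            raise NonAbsorbingChainError(
                f"spectral radius {lam2} >= 1; chain is not absorbing")
        lam2 = float("nan")
    if not np.isfinite(lam2):
        mfpt_eigen = float("nan")
    elif lam2 <= 0.0:
        warnings.warn("lambda2 <= 0: eigenvalue MFPT estimate undefined",
                      stacklevel=2)
        mfpt_eigen = float("nan")
    else:
        mfpt_eigen = -1.0 / np.log(lam2)
    # dense solve, not explicit inversion; (I - Q) is intrinsically
    # near-singular for very metastable chains, so the conditioning warning
    # carries no information here
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", linalg.LinAlgWarning)
        N = linalg.solve(np.eye(t) - Q, np.eye(t))
    n1 = N[0].copy()
    return ChainStatistics(N=N, n1=n1, lambda2=lam2,
                           mfpt_eigen=mfpt_eigen,
                           mfpt_exact=float(n1.sum()))


def sample_chain_trajectory(
    chain: AbsorbingChain,
    mesh: Optional[DeterministicMesh] = None,
    start_state: int = 0,
    n_steps: int = 50,
    rng: Union[np.random.Generator, int, None] = None,
):
    """Sample a random walk through the chain, collecting stored step
    trajectories.

    At each step a perturbation cell is drawn from the same Gaussian masses
    used by :func:`build_chain` and the mesh transition for that cell is
    followed.  The trajectory stored for the realized (i, j) transition (the
    median-perturbation one) is appended, mirroring how the mesh catalogs
    steps.  The walk stops early when the fall state is reached.

    Returns
    -------
    seq : StepSequence
        Completed steps (start states are the snapped grid states, the
        per-step perturbation is the median perturbation of the realized
        transition).
    visited : ndarray
        Indices of the visited transient states, length ``len(seq) + 1``
        unless absorbed at the first step.
    """
    if mesh is None:
        mesh = chain.mesh
    if mesh is None:
        raise ValueError("a mesh is required to recover step trajectories")
    if not (0 <= start_state < chain.n_states):
        raise ValueError(f"start state {start_state} is not transient")
    rng = np.random.default_rng(rng)
    w = gaussian_cell_masses(mesh.perturbation_grid,
                             chain.noise_sd or mesh.config.noise_sd)
    cells = rng.choice(w.size, size=n_steps, p=w)
    xs, ss, visited = [], [], [start_state]
    i = start_state
    failed = False
    for k in range(n_steps):
        j = int(mesh.transitions[i, cells[k]])
        if j == DeterministicMesh.FAIL_INDEX:
            failed = True
            break
        xs.append(float(mesh.states[i]))
        ss.append(mesh.median_perturbation(i, j))
        visited.append(j)
        i = j
    seq = StepSequence(mesh.config, np.asarray(xs), np.asarray(ss),
                       failed=failed)
    return seq, np.asarray(visited, dtype=int)


def sample_absorption_steps(
    chain: AbsorbingChain,
    n_walks: int,
    start_state: int = 0,
    rng: Union[np.random.Generator, int, None] = None,
    max_steps: int = 10_000_000,
) -> np.ndarray:
    """Monte-Carlo absorption times (number of completed steps before the
    fall) for ``n_walks`` independent walks; the oracle counterpart of
    ``mfpt_exact``."""
    rng = np.random.default_rng(rng)
    t = chain.n_states
    # full transition law including the absorbing state t
    P = np.hstack([chain.Q, chain.R[:, None]])
    cum = np.cumsum(P, axis=1)
    cum[:, -1] = 1.0
    out = np.empty(n_walks, dtype=np.int64)
    state = np.full(n_walks, start_state, dtype=np.int64)
    alive = np.arange(n_walks)
    steps = np.zeros(n_walks, dtype=np.int64)
    for _ in range(max_steps):
        if alive.size == 0:
            break
        u = rng.random(alive.size)
        nxt = (u[:, None] > cum[state[alive]]).sum(axis=1)
        # the absorbing transition itself counts as a step, matching the
        # fundamental-matrix convention E[tau] = sum_j N[1, j]
        steps[alive] += 1
        absorbed = nxt == t
        state[alive[~absorbed]] = nxt[~absorbed]
        alive = alive[~absorbed]
    else:  # pragma: no cover - only for pathologically long walks
        raise RuntimeError("walks did not absorb within max_steps")
    out[:] = steps
    return out
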