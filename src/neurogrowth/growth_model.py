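"""Agent-based model of activity-dependent network development.

Neurons live on a 2-D torus.  Each neuron i carries a circular neurite field
of radius R_i standing in for its (undifferentiated) axonal + dendritic
arbor; directed connectivity is the field-overlap area normalized by the
presynaptic field,

    W_ki = s * |A_i ∩ A_k| / |A_k|,

so W_ki is the weight from presynaptic k onto postsynaptic i.  A slow state
variable x_i in [0, 1] (a proxy for intracellular calcium accumulated over
minutes) integrates synaptic drive,

    dx_i/dt = -x_i/tau + (1 - x_i) * sum_k W_ki f(x_k),
    f(x)    = 1 / (1 + exp((theta - x)/a)),

integrated per step either exactly (default: the linear-in-x ODE is solved
over dt with the input held constant, which preserves the stable fixed
point x* = I/(1+I)) or by a plain Euler step, and homeostatic outgrowth
moves the firing rate toward a set-point epsilon:

    dR_i/dt = (1 - 2/(1 + exp((epsilon - f(x_i))/beta))) * rho_growth.

Fields grow while activity is below target and are pruned above it.  Somata
additionally migrate toward their presynaptic inputs with an impulse
exp(mu * f) * rho_migration that shuts off as activity approaches target
(mu < 0), plus a positional jitter of at most the cell-body radius scaled by
the same exponential factor.  Moves that would violate the minimal
inter-soma distance are discarded.

The simulation clock advances in dt = tau = 1 min steps; rates given per
day (rho_growth, rho_migration) are converted to per-minute increments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import (
    hard_core_pattern,
    min_pairwise_distance,
    pairwise_wrapped_distances,
    wrap_positions,
)

__all__ = [
    "ModelParams",
    "NetworkState",
    "Trajectory",
    "MINUTES_PER_DAY",
    "wrapped_distance",
    "circle_overlap_area",
    "compute_connectivity",
    "transfer_rate",
    "integrate_state",
    "growth_step",
    "migration_impulse",
    "direction_vector",
    "migration_step",
    "simulation_step",
    "init_network",
    "run_simulation",
]

MINUTES_PER_DAY = 1440.0

# re-exported here because torus geometry is part of the model contract
from .geometry import wrapped_distance  # noqa: E402  (intentional re-export)


# ---------------------------------------------------------------------------
# parameters and state
# ---------------------------------------------------------------------------

@dataclass
class ModelParams:
    """All model constants.

    Lengths in µm, times in minutes unless the name says otherwise;
    ``rho_growth`` and ``rho_migration`` are µm/day and are divided by 1440
    internally.  ``duration_days`` is the simulated developmental span.
    """

    n_neurons: int = 500
    domain_side: float = 1000.0          # torus side, 1 mm^2 surface
    d_min: float = 12.0                  # minimal inter-soma distance (cell body)
    r0: float = 12.0                     # initial neurite-field radius
    s: float = 0.1                       # synaptic gain
    theta: float = 0.5                   # firing threshold
    a: float = 0.12                      # transfer-function steepness
    tau: float = 1.0                     # integration time constant = dt, min
    epsilon: float = 0.6                 # homeostatic target rate
    beta: float = 0.1                    # growth-function steepness
    rho_growth: float = 4.0              # µm/day
    mu: float = -15.0                    # migration attenuation exponent
    rho_migration: float = 0.0           # µm/day, in vitro range 0-300
    p_rand: float = 0.9                  # weight of the random direction component
    jitter_radius: float = 6.0           # half the cell body diameter, µm
    rand_update_interval: float = 10.0   # min between random-direction refreshes
    duration_days: float = 56.0          # development span to maturation
    seed: Optional[int] = None
    # modeling-choice switches (defaults follow the documented decisions)
    allow_autapses: bool = False         # keep W diagonal at zero
    migrate_toward_input: bool = True    # attraction (default) or repulsion
    p_weights_random: bool = True        # p multiplies the random component
    integration_scheme: str = "exact"    # "exact" (stable) or "euler" (literal)

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if self.domain_side <= 2.0 * self.d_min:
            raise ValueError("domain_side must exceed 2*d_min")
        if self.a <= 0 or self.beta <= 0:
            raise ValueError("transfer/growth steepness must be positive")
        if not (0.0 <= self.s <= 1.0):
            raise ValueError("synaptic gain s must lie in [0, 1]")
        if not (0.0 <= self.p_rand <= 1.0):
            raise ValueError("p_rand must lie in [0, 1]")
        if self.rho_growth < 0 or self.rho_migration < 0:
            raise ValueError("growth/migration rates must be non-negative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.integration_scheme not in ("exact", "euler"):
            raise ValueError("integration_scheme must be 'exact' or 'euler'")

    @property
    def dt(self) -> float:
        """Euler step, identical to the integration time constant (minutes)."""
        return self.tau

    @property
    def rho_growth_per_min(self) -> float:
        return self.rho_growth / MINUTES_PER_DAY

    @property
    def rho_migration_per_min(self) -> float:
        return self.rho_migration / MINUTES_PER_DAY

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)


@dataclass
class NetworkState:
    """Mutable simulation state.

    positions: (n, 2) soma coordinates in [0, L); radii: neurite-field radii;
    x: state variables in [0, 1]; rand_dirs: (n, 2) unit vectors of the
    random movement component; t: simulation clock in minutes.
    """

    positions: np.ndarray
    radii: np.ndarray
    x: np.ndarray
    rand_dirs: np.ndarray
    t: float = 0.0
    step_index: int = 0

    def copy(self) -> "NetworkState":
        return NetworkState(
            positions=self.positions.copy(),
            radii=self.radii.copy(),
            x=self.x.copy(),
            rand_dirs=self.rand_dirs.copy(),
            t=self.t,
            step_index=self.step_index,
        )

    @property
    def n(self) -> int:
        return len(self.positions)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def circle_overlap_area(d, r1, r2):
    """Area of the lens-shaped intersection of two circles.

    ``d`` is the center distance.  Zero for disjoint circles; the area of
    the smaller circle when one contains the other.  Vectorized.
    """
    d = np.asarray(d, dtype=float)
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if np.any(r1 < 0) or np.any(r2 < 0):
        raise ValueError("radii must be non-negative")
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    rmin = np.minimum(r1, r2)
    contained = d <= np.abs(r1 - r2)
    disjoint = d >= r1 + r2
    lens = ~contained & ~disjoint
    out = np.where(contained, np.pi * rmin * rmin, 0.0)
    if np.any(lens):
        dl = np.where(lens, d, 1.0)  # placeholder avoids 0/0 warnings
        a1 = np.where(lens, r1, 1.0)
        a2 = np.where(lens, r2, 1.0)
        cos1 = np.clip((dl * dl + a1 * a1 - a2 * a2) / (2.0 * dl * a1), -1.0, 1.0)
        cos2 = np.clip((dl * dl + a2 * a2 - a1 * a1) / (2.0 * dl * a2), -1.0, 1.0)
        tri = (
            (-dl + a1 + a2) * (dl + a1 - a2) * (dl - a1 + a2) * (dl + a1 + a2)
        )
        lens_area = (
            a1 * a1 * np.arccos(cos1)
            + a2 * a2 * np.arccos(cos2)
            - 0.5 * np.sqrt(np.maximum(tri, 0.0))
        )
        out = np.where(lens, lens_area, out)
    if out.ndim == 0:
        return float(out)
    return out


def compute_connectivity(
    state: NetworkState, params: ModelParams, distances: Optional[np.ndarray] = None
) -> np.ndarray:
    """Directed weight matrix W with W[k, i] the weight from presynaptic k
    onto postsynaptic i: overlap area normalized by the presynaptic field
    area, times the gain s.

    Zero-radius presynaptic neurons contribute an all-zero row; the diagonal
    is zeroed unless ``allow_autapses``.
    """
    if distances is None:
        distances = pairwise_wrapped_distances(state.positions, params.domain_side)
    r = state.radii
    overlap = circle_overlap_area(distances, r[:, None], r[None, :])
    area_pre = np.pi * r * r  # area of the presynaptic (row) neuron
    with np.errstate(divide="ignore", invalid="ignore"):
        w = params.s * overlap / area_pre[:, None]
    w[area_pre == 0.0, :] = 0.0
    if not params.allow_autapses:
        np.fill_diagonal(w, 0.0)
    return w


def transfer_rate(x, theta: float, a: float):
    """Sigmoidal rate f(x) = 1 / (1 + exp((theta - x)/a)), in (0, 1)."""
    if a <= 0:
        raise ValueError("steepness a must be positive")
    return 1.0 / (1.0 + np.exp((theta - np.asarray(x, dtype=float)) / a))


def integrate_state(
    state: NetworkState,
    w: np.ndarray,
    params: ModelParams,
    rates: Optional[np.ndarray] = None,
) -> np.ndarray:
    """One dt-step of the leaky activity integrator
    dx_i/dt = -x_i/tau + (1 - x_i) * I_i with I_i = sum_k W_ki f(x_k).

    Default scheme ("exact"): the ODE is linear in x for input held fixed
    over the step, so it is solved in closed form,
    x' = x_inf + (x - x_inf) * exp(-lambda*dt) with lambda = 1/tau + I and
    x_inf = I/lambda.  This keeps the stable fixed point x* = I/(1+I) of
    the continuous dynamics at any input strength.

    Scheme "euler": plain explicit Euler at dt = tau, which reduces to
    x' = (1 - x) * I, clamped to [0, 1] against overshoot.  At the inputs
    the homeostatic target requires (I > 1) this map is unstable and
    oscillates; it is kept for comparison with the exact scheme.
    """
    if rates is None:
        rates = transfer_rate(state.x, params.theta, params.a)
    total_input = rates @ w  # sum over presynaptic k of W[k, i] f_k
    dt = params.dt
    if params.integration_scheme == "euler":
        x_new = state.x + dt * (
            -state.x / params.tau + (1.0 - state.x) * total_input
        )
        return np.clip(x_new, 0.0, 1.0)
    lam = 1.0 / params.tau + total_input
    x_inf = total_input / lam
    return x_inf + (state.x - x_inf) * np.exp(-lam * dt)


def growth_step(state: NetworkState, rates: np.ndarray, params: ModelParams) -> np.ndarray:
    """Homeostatic neurite-field update; radii floored at zero.

    dR/dt = (1 - 2/(1 + exp((epsilon - f)/beta))) * rho_growth: positive
    below the set-point (outgrowth), negative above it (pruning), zero at
    f = epsilon.
    """
    factor = 1.0 - 2.0 / (1.0 + np.exp((params.epsilon - rates) / params.beta))
    radii = state.radii + params.dt * factor * params.rho_growth_per_min
    return np.maximum(radii, 0.0)


def migration_impulse(rates, params: ModelParams):
    """Per-step migration distance exp(mu*f) * rho_migration * dt (µm).

    With mu < 0 the impulse decays with activity and is negligible at the
    homeostatic target, so neurons stop migrating as they wire up.
    """
    return np.exp(params.mu * np.asarray(rates, dtype=float)) * (
        params.rho_migration_per_min * params.dt
    )


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def direction_vector(
    state: NetworkState,
    w: np.ndarray,
    rates: np.ndarray,
    i: int,
    params: ModelParams,
) -> np.ndarray:
    """Final unit movement direction for neuron i.

    The directed component is the input-weighted vector sum over presynaptic
    neurons (minimal-image bearings, pointing toward the inputs by default);
    it is mixed with the neuron's cached random unit vector, each component
    normalized, weighted (random weight p by default) and the sum
    renormalized.  With no presynaptic drive the random component alone is
    used.
    """
    delta = state.positions - state.positions[i]  # vectors i -> k
    delta -= params.domain_side * np.round(delta / params.domain_side)
    dist = np.sqrt(np.einsum("kj,kj->k", delta, delta))
    with np.errstate(divide="ignore", invalid="ignore"):
        unit_ik = np.where(dist[:, None] > 0, delta / dist[:, None], 0.0)
    weights = w[:, i] * rates  # W_ki f(x_k)
    v_dir = weights @ unit_ik
    if not params.migrate_toward_input:
        v_dir = -v_dir
    norm_dir = np.linalg.norm(v_dir)
    rand = state.rand_dirs[i]
    if norm_dir == 0.0:
        return rand
    p = params.p_rand if params.p_weights_random else 1.0 - params.p_rand
    mixed = (v_dir / norm_dir) * (1.0 - p) + rand * p
    norm_mixed = np.linalg.norm(mixed)
    if norm_mixed == 0.0:
        return rand
    return mixed / norm_mixed


def _rand_unit_vectors(n: int, rng: np.random.Generator) -> np.ndarray:
    ang = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return np.column_stack([np.cos(ang), np.sin(ang)])


def migration_step(
    state: NetworkState,
    w: np.ndarray,
    rates: np.ndarray,
    params: ModelParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Move somata: directed migration plus jitter under hard-core rejection.

    Neurons are processed in a freshly shuffled order; each proposes
    position + V*impulse + jitter (jitter uniform in a disc of radius
    jitter_radius * exp(mu*f), reset every step), wrapped onto the torus.
    A proposal closer than d_min to any other soma is discarded.  Returns
    the (n, 2) realized move vectors (µm; zero rows for discarded moves),
    wrap-free since per-step moves are far below half the domain.

    Draw protocol (all position-independent, drawn before the sequential
    acceptance loop so the stream is reproducible and translation
    invariant): optional rand_dirs refresh, order shuffle, jitter angles,
    jitter radial quantiles.  A fully motionless configuration
    (rho_migration == 0 and jitter_radius == 0) consumes no randomness.
    """
    n = state.n
    L = params.domain_side
    motionless = params.rho_migration == 0.0 and params.jitter_radius == 0.0
    if motionless:
        return np.zeros((n, 2))

    interval_steps = max(1, int(round(params.rand_update_interval / params.dt)))
    if state.step_index > 0 and state.step_index % interval_steps == 0:
        state.rand_dirs = _rand_unit_vectors(n, rng)
    order = rng.permutation(n)
    jit_ang = rng.uniform(0.0, 2.0 * np.pi, size=n)
    jit_quant = rng.uniform(0.0, 1.0, size=n)

    impulses = migration_impulse(rates, params)
    decay = np.exp(params.mu * rates)
    jit_r = params.jitter_radius * decay * np.sqrt(jit_quant)
    jitter = jit_r[:, None] * np.column_stack([np.cos(jit_ang), np.sin(jit_ang)])

    moves = np.zeros((n, 2))
    pos = state.positions
    d_min2 = params.d_min * params.d_min
    for i in order:
        move = jitter[i].copy()
        if impulses[i] > 0.0:
            move += direction_vector(state, w, rates, i, params) * impulses[i]
        proposal = np.mod(pos[i] + move, L)
        if n > 1:
            delta = pos - proposal
            delta -= L * np.round(delta / L)
            d2 = np.einsum("kj,kj->k", delta, delta)
            d2[i] = np.inf
            if d2.min() < d_min2:
                continue  # move violates the hard core: discarded
        pos[i] = proposal
        moves[i] = move
    return moves


def simulation_step(
    state: NetworkState, params: ModelParams, rng: np.random.Generator
) -> np.ndarray:
    """Advance the network by one Euler step dt = tau.

    Order: (1) connectivity from current geometry, (2) rates f(x),
    (3) activity integration, (4) neurite growth, (5) migration — growth and
    migration both use the pre-update rates (synchronous update).  Mutates
    ``state`` in place and returns the per-neuron realized move vectors.
    """
    w = compute_connectivity(state, params)
    rates = transfer_rate(state.x, params.theta, params.a)
    x_new = integrate_state(state, w, params, rates=rates)
    radii_new = growth_step(state, rates, params)
    moves = migration_step(state, w, rates, params, rng)
    state.x = x_new
    state.radii = radii_new
    state.t += params.dt
    state.step_index += 1
    return moves


def init_network(params: ModelParams, rng: np.random.Generator) -> NetworkState:
    """Seed n_neurons somata uniformly on the torus with hard-core rejection
    sampling at d_min; radii start at r0, state variables at zero."""
    positions = hard_core_pattern(
        params.n_neurons, params.domain_side, params.d_min, rng
    )
    return NetworkState(
        positions=wrap_positions(positions, params.domain_side),
        radii=np.full(params.n_neurons, float(params.r0)),
        x=np.zeros(params.n_neurons),
        rand_dirs=_rand_unit_vectors(params.n_neurons, rng),
    )


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Recorded development run: time series plus periodic state snapshots.

    ``series`` maps column name -> array aligned with ``times`` (minutes):
    mean_radius, mean_connectivity (mean off-diagonal weight), mean_input,
    mean_rate, mean_migration_dist (cumulative realized path length),
    mean_net_displacement (wrap-free distance from the seeding position),
    and ci (when enabled).  ``min_distance_per_step`` holds the global minimum
    pairwise soma distance after every step when tracking is on.
    """

    params: ModelParams
    times: np.ndarray
    series: dict
    snapshots: list = field(default_factory=list)  # (t_min, NetworkState copies)
    min_distance_per_step: Optional[np.ndarray] = None


def run_simulation(
    params: ModelParams,
    rng: Optional[np.random.Generator] = None,
    record_every_min: float = 60.0,
    snapshot_every_min: Optional[float] = None,
    record_ci: bool = True,
    ci_null_reps: int = 50,
    track_min_distance: bool = False,
) -> Trajectory:
    """Simulate ``params.duration_days`` of development and record read-outs.

    The clustering index is evaluated against a Monte-Carlo null computed
    once per run (same m, domain and hard core at every record time).
    """
    from .network_metrics import PointPattern, clustering_index, null_nn_distance

    if rng is None:
        rng = np.random.default_rng(params.seed)
    state = init_network(params, rng)
    n_steps = int(round(params.duration_days * MINUTES_PER_DAY / params.dt))

    ci_null = None
    if record_ci and params.n_neurons >= 2:
        ci_null = null_nn_distance(
            params.n_neurons,
            params.domain_side,
            params.d_min,
            reps=ci_null_reps,
            rng=np.random.default_rng(rng.integers(2**31)),
        )

    cum_disp = np.zeros(params.n_neurons)       # realized path length
    net_disp = np.zeros((params.n_neurons, 2))  # wrap-free offset from seeding
    times: list[float] = []
    cols = ["mean_radius", "mean_connectivity", "mean_input", "mean_rate",
            "mean_migration_dist", "mean_net_displacement"]
    if ci_null is not None:
        cols.append("ci")
    series: dict[str, list] = {c: [] for c in cols}
    snapshots: list = []
    min_dists: list[float] = []

    record_stride = max(1, int(round(record_every_min / params.dt)))
    snap_stride = (
        None if snapshot_every_min is None
        else max(1, int(round(snapshot_every_min / params.dt)))
    )

    def record() -> None:
        w = compute_connectivity(state, params)
        rates = transfer_rate(state.x, params.theta, params.a)
        n = state.n
        times.append(state.t)
        series["mean_radius"].append(float(state.radii.mean()))
        off = w.sum() / (n * (n - 1)) if n > 1 else 0.0
        series["mean_connectivity"].append(float(off))
        series["mean_input"].append(float((rates @ w).mean()))
        series["mean_rate"].append(float(rates.mean()))
        series["mean_migration_dist"].append(float(cum_disp.mean()))
        series["mean_net_displacement"].append(
            float(np.linalg.norm(net_disp, axis=1).mean())
        )
        if ci_null is not None:
            pat = PointPattern(state.positions.copy(), params.domain_side, params.d_min)
            series["ci"].append(clustering_index(pat, null_mean=ci_null))

    record()
    snapshots.append((state.t, state.copy()))
    for step in range(1, n_steps + 1):
        moves = simulation_step(state, params, rng)
        cum_disp += np.linalg.norm(moves, axis=1)
        net_disp += moves
        if track_min_distance:
            min_dists.append(min_pairwise_distance(state.positions, params.domain_side))
        if step % record_stride == 0 or step == n_steps:
            record()
        if snap_stride is not None and (step % snap_stride == 0 or step == n_steps):
            snapshots.append((state.t, state.copy()))
    if snap_stride is None and n_steps > 0:
        snapshots.append((state.t, state.copy()))

    return Trajectory(
        params=params,
        times=np.asarray(times),
        series={k: np.asarray(v) for k, v in series.items()},
        snapshots=snapshots,
        min_distance_per_step=np.asarray(min_dists) if track_min_distance else None,
    )
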