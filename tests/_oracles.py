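"""Independent reference implementations used only by the test suite.

Each oracle re-derives a result by the most transparent route available —
straight-line scalar arithmetic, dense time-grid scanning, or exhaustive
enumeration — and deliberately shares no code with the library paths it
checks (only the random-draw protocol of the simulator, which is part of
the documented step contract).
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np


# ---------------------------------------------------------------------------
# scalar simulation step
# ---------------------------------------------------------------------------

def _wrap_delta_scalar(a, b, L):
    """Minimal-image displacement from a to b, componentwise."""
    out = []
    for da, db in zip(a, b):
        d = db - da
        d -= L * round(d / L)
        out.append(d)
    return out


def _dist_scalar(a, b, L):
    dx, dy = _wrap_delta_scalar(a, b, L)
    return math.hypot(dx, dy)


def _lens_scalar(d, r1, r2):
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return math.pi * r * r
    c1 = max(-1.0, min(1.0, (d * d + r1 * r1 - r2 * r2) / (2 * d * r1)))
    c2 = max(-1.0, min(1.0, (d * d + r2 * r2 - r1 * r1) / (2 * d * r2)))
    tri = (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2)
    return (
        r1 * r1 * math.acos(c1)
        + r2 * r2 * math.acos(c2)
        - 0.5 * math.sqrt(max(tri, 0.0))
    )


def scalar_simulation_step(positions, radii, x, rand_dirs, step_index, params, rng):
    """One full model step computed with explicit per-neuron loops.

    Consumes the same random draws, in the same order, as the library step
    (refresh / shuffle / jitter, all before the sequential move loop).
    Returns (positions, radii, x, rand_dirs) as plain lists.
    """
    n = len(positions)
    L = params.domain_side
    dt = params.tau
    positions = [list(p) for p in positions]
    radii = list(radii)
    x = list(x)
    rand_dirs = [list(v) for v in rand_dirs]

    # connectivity W[k][i] = s * overlap(i,k) / area(k)
    w = [[0.0] * n for _ in range(n)]
    for k in range(n):
        area_k = math.pi * radii[k] ** 2
        for i in range(n):
            if i == k or area_k == 0.0:
                continue
            d = _dist_scalar(positions[i], positions[k], L)
            w[k][i] = params.s * _lens_scalar(d, radii[i], radii[k]) / area_k

    rates = [1.0 / (1.0 + math.exp((params.theta - xi) / params.a)) for xi in x]

    x_new = []
    for i in range(n):
        total_input = sum(w[k][i] * rates[k] for k in range(n))
        if params.integration_scheme == "euler":
            xi = x[i] + dt * (-x[i] / params.tau + (1.0 - x[i]) * total_input)
            xi = min(max(xi, 0.0), 1.0)
        else:
            lam = 1.0 / params.tau + total_input
            x_inf = total_input / lam
            xi = x_inf + (x[i] - x_inf) * math.exp(-lam * dt)
        x_new.append(xi)

    rho_g = params.rho_growth / 1440.0
    radii_new = [
        max(
            0.0,
            radii[i]
            + dt
            * (1.0 - 2.0 / (1.0 + math.exp((params.epsilon - rates[i]) / params.beta)))
            * rho_g,
        )
        for i in range(n)
    ]

    motionless = params.rho_migration == 0.0 and params.jitter_radius == 0.0
    if not motionless:
        interval = max(1, round(params.rand_update_interval / params.tau))
        if step_index > 0 and step_index % interval == 0:
            ang = rng.uniform(0.0, 2.0 * math.pi, size=n)
            rand_dirs = [[math.cos(a), math.sin(a)] for a in ang]
        order = list(rng.permutation(n))
        jit_ang = list(rng.uniform(0.0, 2.0 * math.pi, size=n))
        jit_u = list(rng.uniform(0.0, 1.0, size=n))

        rho_m = params.rho_migration / 1440.0
        for i in order:
            decay = math.exp(params.mu * rates[i])
            jr = params.jitter_radius * decay * math.sqrt(jit_u[i])
            mx = jr * math.cos(jit_ang[i])
            my = jr * math.sin(jit_ang[i])
            impulse = decay * rho_m * dt
            if impulse > 0.0:
                vx = vy = 0.0
                for k in range(n):
                    if k == i:
                        continue
                    dxk, dyk = _wrap_delta_scalar(positions[i], positions[k], L)
                    dist = math.hypot(dxk, dyk)
                    if dist == 0.0:
                        continue
                    wt = w[k][i] * rates[k]
                    vx += wt * dxk / dist
                    vy += wt * dyk / dist
                if not params.migrate_toward_input:
                    vx, vy = -vx, -vy
                norm = math.hypot(vx, vy)
                if norm == 0.0:
                    ux, uy = rand_dirs[i]
                else:
                    p = params.p_rand if params.p_weights_random else 1.0 - params.p_rand
                    ux = vx / norm * (1.0 - p) + rand_dirs[i][0] * p
                    uy = vy / norm * (1.0 - p) + rand_dirs[i][1] * p
                    un = math.hypot(ux, uy)
                    if un == 0.0:
                        ux, uy = rand_dirs[i]
                    else:
                        ux, uy = ux / un, uy / un
                mx += ux * impulse
                my += uy * impulse
            px = (positions[i][0] + mx) % L
            py = (positions[i][1] + my) % L
            ok = True
            for j in range(n):
                if j != i and _dist_scalar([px, py], positions[j], L) < params.d_min:
                    ok = False
                    break
            if ok:
                positions[i] = [px, py]

    return positions, radii_new, x_new, rand_dirs


# ---------------------------------------------------------------------------
# brute-force SBE detection (dense time scan)
# ---------------------------------------------------------------------------

def brute_force_sbes(rec, isi_max=0.1, fraction=0.10, min_sites=3,
                     max_sites=20, pad=0.025, dt=0.001):
    """Grid-scan SBE detector: count electrodes with an ongoing burst at
    each grid time, threshold, pad, merge.  Returns a list of
    (core_start, core_end, ext_start, ext_end) tuples.

    Exact when burst boundaries (spike times) lie on the grid.
    """
    active = [el for el, t in rec.spikes.items() if len(t) > 0]
    if not active:
        return []
    thr = min(max(math.ceil(fraction * len(active)), min_sites), max_sites)

    intervals = []  # per-electrode burst [start, end]
    for el in active:
        t = list(rec.spikes[el])
        run = [t[0]] if t else []
        for prev, cur in zip(t, t[1:]):
            if cur - prev < isi_max:
                run.append(cur)
            else:
                if len(run) >= 2:
                    intervals.append((run[0], run[-1]))
                run = [cur]
        if len(run) >= 2:
            intervals.append((run[0], run[-1]))
    if not intervals:
        return []

    n_grid = int(round(rec.duration / dt)) + 1
    above = np.zeros(n_grid, dtype=bool)
    grid = np.arange(n_grid) * dt
    counts = np.zeros(n_grid, dtype=int)
    for s, e in intervals:
        i0 = int(math.ceil(round(s / dt, 9)))
        i1 = int(math.floor(round(e / dt, 9)))
        counts[i0 : i1 + 1] += 1
    above = counts >= thr

    cores = []
    in_run = False
    for i, flag in enumerate(above):
        if flag and not in_run:
            start = grid[i]
            in_run = True
        elif not flag and in_run:
            cores.append((start, grid[i - 1]))
            in_run = False
    if in_run:
        cores.append((start, grid[-1]))

    merged = []
    for cs, ce in cores:
        es, ee = cs - pad, ce + pad
        if merged and es <= merged[-1][3]:
            prev = merged[-1]
            merged[-1] = (prev[0], ce, prev[2], ee)
        else:
            merged.append((cs, ce, es, ee))
    return merged


# ---------------------------------------------------------------------------
# exhaustive modularity maximization
# ---------------------------------------------------------------------------

def _set_partitions(items):
    """All partitions of a list into non-empty unlabeled blocks."""
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def brute_force_best_modularity(w, gamma=1.0):
    """Maximum weighted modularity over all partitions (n <= ~9)."""
    w = np.asarray(w, dtype=float)
    sym = 0.5 * (w + w.T)
    np.fill_diagonal(sym, 0.0)
    g = nx.from_numpy_array(sym)
    nodes = list(g.nodes)
    best = -math.inf
    for part in _set_partitions(nodes):
        q = nx.community.modularity(
            g, [set(b) for b in part], weight="weight", resolution=gamma
        )
        best = max(best, q)
    return best


# ---------------------------------------------------------------------------
# misc helpers
# ---------------------------------------------------------------------------

def lattice_spike_times(rng, duration, n, step=0.01):
    """Sorted unique spike times restricted to a 10 ms lattice."""
    n_slots = int(duration / step)
    k = min(n, n_slots)
    slots = rng.choice(n_slots, size=k, replace=False)
    return np.sort(slots) * step
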