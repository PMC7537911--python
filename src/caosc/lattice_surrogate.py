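"""Desk-scale lattice of coupled calcium release units.

A deliberately minimal, qualitative surrogate for the wave phenomenology
of a spatially resolved cell: a 1-D (or ragged 2-D, N×1) chain of
fast-RyR units with per-step stochastic RyR noise, coupled by diffusive
exchange of cytosolic (and optionally SR) calcium between neighbours.

Each unit keeps the single-unit mathematics intact: its cytosolic
calcium is slaved to its *local* total calcium load through the
conservation closure, and the local load evolves only through pairwise,
antisymmetric exchange fluxes — so the lattice total is conserved
exactly while units remain bona fide single-CaRU models.

This module makes no quantitative claims about wave speeds or regime
boundaries of a spatially detailed cell model; it exists to show the
three qualitative regimes (quiescent / recurring propagated events /
persistently open) and to provide a measurable event rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import ndimage

from .params_buffers import CONTROL, DomainError, ModelParams

__all__ = [
    "LatticeState",
    "LatticeTrace",
    "WaveEvent",
    "step_lattice",
    "simulate_lattice",
    "wave_events",
]


@dataclass
class LatticeState:
    """Per-unit state arrays plus the per-unit total calcium load (μM)."""

    c_d: np.ndarray
    c_sr_tot: np.ndarray
    cT_local: np.ndarray

    @property
    def n_units(self) -> int:
        return len(self.c_d)

    def total_calcium(self) -> float:
        """Lattice-summed load; conserved by the exchange scheme."""
        return float(np.sum(self.cT_local))


@dataclass
class LatticeTrace:
    """Line-scan style record: per-unit c_i (and SR content) over time."""

    t_ms: np.ndarray
    c_i: np.ndarray        # (n_units, n_times)
    c_sr_tot: np.ndarray   # (n_units, n_times)
    cT_local: np.ndarray   # (n_units, n_times)
    params: ModelParams
    meta: dict = field(default_factory=dict)


def _ci_vec(cd, csrtot, cT, p):
    budget = np.maximum(p.v * cT - p.v_d * cd - p.v_sr * csrtot, 0.0)
    b = budget / p.v_i
    q = p.K_b + p.B_b - b
    return np.maximum(0.5 * (-q + np.sqrt(q * q + 4.0 * p.K_b * b)), 0.0)


def _check_dt(dt, d_i, d_sr, p):
    coef = max(d_i * p.v_i / p.v, d_sr * max(1.0, p.v_sr / p.v + 1.0))
    if coef > 0 and dt * 2.0 * coef > 0.9:
        raise ValueError(
            f"dt={dt} ms violates the exchange stability bound; "
            f"use dt <= {0.45 / coef:.4g} ms")


def step_lattice(state: LatticeState, p: ModelParams = CONTROL, *,
                 dt: float = 0.01, sigma: float = 0.0,
                 rng: np.random.Generator | None = None,
                 d_i: float = 4.0, d_sr: float = 0.0) -> LatticeState:
    """One explicit step of the coupled lattice (reference implementation).

    Unit dynamics are the fast-RyR model with optional per-step noise on
    P_o; coupling is a discrete Laplacian built from pairwise
    antisymmetric exchange fluxes with no-flux boundaries.  Refuses a
    step violating the diffusive stability bound, suggesting one that
    does not.
    """
    _check_dt(dt, d_i, d_sr, p)
    cd, csrtot, cT = (state.c_d.copy(), state.c_sr_tot.copy(),
                      state.cT_local.copy())
    ci = _ci_vec(cd, csrtot, cT, p)
    po = cd * cd / (p.K_o**2 + cd * cd)
    if sigma > 0.0:
        if rng is None:
            raise ValueError("sigma > 0 requires an rng")
        po = np.clip(po + sigma * (rng.random(len(cd)) - 0.5), 0.0, 1.0)
    from .params_buffers import free_sr_calcium
    csr = np.asarray(free_sr_calcium(csrtot, p))
    j_rel = p.g * po * (csr - cd)
    j_d = (cd - ci) / p.tau_i
    j_up = p.g_up * ci * ci / (p.K_s**2 + ci * ci)
    cd_new = np.maximum(cd + dt * (j_rel - j_d), 0.0)
    csr_new = np.maximum(
        csrtot + dt * ((p.v_i / p.v_sr) * j_up - (p.v_d / p.v_sr) * j_rel), 0.0)
    cT_new = cT.copy()
    # pairwise exchange, explicitly antisymmetric
    q_i = d_i * np.diff(ci)                      # flux from unit k+1 into k
    cT_new[:-1] += dt * (p.v_i / p.v) * q_i
    cT_new[1:] -= dt * (p.v_i / p.v) * q_i
    if d_sr > 0.0:
        q_s = d_sr * np.diff(csr)
        csr_new[:-1] += dt * q_s
        csr_new[1:] -= dt * q_s
        cT_new[:-1] += dt * (p.v_sr / p.v) * q_s
        cT_new[1:] -= dt * (p.v_sr / p.v) * q_s
    return LatticeState(cd_new, csr_new, cT_new)


@njit(cache=True)
def _lattice_kernel(cd, csrtot, cT, g, tau_i, g_up, K_s, K_o, B_b, K_b,
                    B_SQ, K_SQ, v_i, v_sr, v_d, v, d_i, d_sr, sigma, dt,
                    n_chunk, global_offset, sample_every, U,
                    out_t, out_ci, out_csrtot, out_cT):
    n = cd.shape[0]
    ci = np.empty(n)
    csr = np.empty(n)
    po = np.empty(n)
    for i in range(n_chunk):
        for k in range(n):
            budget = v * cT[k] - v_d * cd[k] - v_sr * csrtot[k]
            if budget < 0.0:
                budget = 0.0
            b = budget / v_i
            q = K_b + B_b - b
            ci[k] = 0.5 * (-q + math.sqrt(q * q + 4.0 * K_b * b))
            if B_SQ == 0.0:
                csr[k] = csrtot[k]
            else:
                s = csrtot[k] - K_SQ - B_SQ
                csr[k] = 0.5 * (s + math.sqrt(s * s + 4.0 * csrtot[k] * K_SQ))
            pk = cd[k] * cd[k] / (K_o * K_o + cd[k] * cd[k])
            if sigma > 0.0:
                pk += sigma * (U[i, k] - 0.5)
                if pk < 0.0:
                    pk = 0.0
                elif pk > 1.0:
                    pk = 1.0
            po[k] = pk
        gi = global_offset + i
        if gi % sample_every == 0:
            j = gi // sample_every
            if j < out_t.shape[0]:
                out_t[j] = gi * dt
                for k in range(n):
                    out_ci[k, j] = ci[k]
                    out_csrtot[k, j] = csrtot[k]
                    out_cT[k, j] = cT[k]
        for k in range(n):
            j_rel = g * po[k] * (csr[k] - cd[k])
            j_d = (cd[k] - ci[k]) / tau_i
            j_up = g_up * ci[k] * ci[k] / (K_s * K_s + ci[k] * ci[k])
            cd[k] += dt * (j_rel - j_d)
            csrtot[k] += dt * ((v_i / v_sr) * j_up - (v_d / v_sr) * j_rel)
            if cd[k] < 0.0:
                cd[k] = 0.0
            if csrtot[k] < 0.0:
                csrtot[k] = 0.0
        for k in range(n - 1):
            q_i = d_i * (ci[k + 1] - ci[k])
            cT[k] += dt * (v_i / v) * q_i
            cT[k + 1] -= dt * (v_i / v) * q_i
            if d_sr > 0.0:
                q_s = d_sr * (csr[k + 1] - csr[k])
                csrtot[k] += dt * q_s
                csrtot[k + 1] -= dt * q_s
                cT[k] += dt * (v_sr / v) * q_s
                cT[k + 1] -= dt * (v_sr / v) * q_s


def simulate_lattice(cT_bar: float, p: ModelParams = CONTROL, *,
                     n_units: int = 50, t_end_ms: float, seed: int | None = None,
                     sigma: float = 2e-3, d_i: float = 4.0, d_sr: float = 0.0,
                     dt_ms: float = 0.01, sample_ms: float = 1.0,
                     kick_unit: int | None = None,
                     kick: float = 0.0) -> LatticeTrace:
    """Integrate the coupled lattice and return a line-scan trace.

    Units start at rest (all calcium in the SR at the common load);
    ``kick_unit`` seeds one unit with ``kick`` μM of dyadic calcium to
    probe propagation of a single release.
    """
    _check_dt(dt_ms, d_i, d_sr, p)
    if cT_bar < 0:
        raise DomainError("cT_bar must be >= 0")
    cd = np.zeros(n_units)
    cT = np.full(n_units, float(cT_bar))
    csrtot = np.full(n_units, p.v * cT_bar / p.v_sr)
    if kick_unit is not None:
        cd[kick_unit] = kick
        csrtot[kick_unit] = (p.v * cT_bar - p.v_d * kick) / p.v_sr
    n_steps = int(round(t_end_ms / dt_ms))
    sample_every = max(1, int(round(sample_ms / dt_ms)))
    n_out = (n_steps + sample_every - 1) // sample_every
    out_t = np.empty(n_out)
    out_ci = np.empty((n_units, n_out))
    out_csr = np.empty((n_units, n_out))
    out_cT = np.empty((n_units, n_out))
    rng = np.random.default_rng(seed)
    chunk = max(1, 8_000_000 // max(1, n_units))
    done = 0
    while done < n_steps:
        m = min(chunk, n_steps - done)
        U = rng.random((m, n_units)) if sigma > 0.0 else np.empty((1, n_units))
        _lattice_kernel(cd, csrtot, cT, p.g, p.tau_i, p.g_up, p.K_s, p.K_o,
                        p.B_b, p.K_b, p.B_SQ, p.K_SQ, p.v_i, p.v_sr, p.v_d,
                        p.v, d_i, d_sr, sigma, dt_ms, m, done, sample_every,
                        U, out_t, out_ci, out_csr, out_cT)
        done += m
    meta = {"cT_bar": cT_bar, "n_units": n_units, "sigma": sigma,
            "d_i": d_i, "d_sr": d_sr, "dt_ms": dt_ms, "seed": seed,
            "sample_ms": sample_ms, "t_end_ms": t_end_ms,
            "kick_unit": kick_unit, "kick": kick}
    return LatticeTrace(out_t, out_ci, out_csr, out_cT, p, meta)


@dataclass(frozen=True)
class WaveEvent:
    """One connected supra-threshold space-time component."""

    start_unit: int
    start_ms: float
    extent_units: int
    speed_units_per_ms: float
    duration_ms: float


def wave_events(trace: LatticeTrace, threshold: float | None = None,
                min_units: int = 1) -> list[WaveEvent]:
    """Detect propagated release events in a lattice line-scan.

    Thresholds c_i at the midpoint between the resting baseline and the
    trace maximum, labels 8-connected supra-threshold components in the
    (unit, time) array, and fits the activation front of each component
    to estimate a speed (infinite for simultaneous, lattice-wide
    activation).
    """
    ci = trace.c_i
    if threshold is None:
        base = float(np.median(ci))
        threshold = 0.5 * (base + float(ci.max()))
        if ci.max() < 0.02:        # quiescent trace: nothing to detect
            return []
    active = ci > threshold
    labels, n_lab = ndimage.label(active, structure=np.ones((3, 3), dtype=int))
    events = []
    dt = float(trace.t_ms[1] - trace.t_ms[0]) if len(trace.t_ms) > 1 else 1.0
    for lab in range(1, n_lab + 1):
        units, times = np.where(labels == lab)
        uniq = np.unique(units)
        if len(uniq) < min_units:
            continue
        t0_idx = times.min()
        start_unit = int(units[times == t0_idx].min())
        # activation front: first supra-threshold time per unit
        front = np.array([times[units == u].min() for u in uniq]) * dt
        dist = np.abs(uniq - start_unit)
        if len(uniq) > 1 and np.ptp(front) > 0:
            slope = np.polyfit(dist, front - front.min(), 1)[0]  # ms per unit
            speed = math.inf if slope <= 0 else 1.0 / slope
        else:
            speed = math.inf if len(uniq) > 1 else 0.0
        events.append(WaveEvent(start_unit, float(trace.t_ms[t0_idx]),
                                int(len(uniq)), float(speed),
                                float((times.max() - t0_idx) * dt)))
    events.sort(key=lambda e: e.start_ms)
    return events
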