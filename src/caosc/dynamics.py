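"""Right-hand sides and trajectory integration for the minimal
calcium-release-unit model, deterministic and stochastic.

Three variants of the model are provided:

``three_var``
    The full minimal model: dyadic calcium ``c_d``, total SR calcium
    ``c_sr_tot`` and RyR open fraction ``P_o`` are dynamical.
``fast_ryr``
    RyR gating is assumed fast, ``P_o = c_d²/(K_o² + c_d²)``, leaving a
    two-variable system in (c_d, c_sr_tot).  This is the baseline model
    of the analysis and the only variant with a stochastic mode.
``fast_dyadic``
    Dyadic diffusion is assumed fast instead, slaving
    ``c_d = (τ_i·g·P_o·c_sr + c_i)/(1 + τ_i·g·P_o)`` and leaving
    (c_sr_tot, P_o) dynamical.  Restricted to ``B_SQ = 0``.

Cytosolic calcium is never integrated: it is recovered at every
evaluation from the total-calcium conservation law
(:func:`caosc.params_buffers.solve_cytosolic`), so mass is conserved
exactly along every trajectory.

The stochastic mode perturbs the open probability once per time step,
``P_o = c_d²/(K_o²+c_d²) + σ·(U − ½)`` with U uniform on (0,1), clamped
to [0,1].  Per-step bounded noise has no step-size-independent continuum
limit, so the step ``dt`` is part of the model definition and is recorded
in the trace metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .params_buffers import (CONTROL, DomainError, ModelParams,
                             free_sr_calcium, reconstruct_load,
                             solve_cytosolic)

__all__ = [
    "VARIANTS",
    "CaruState",
    "Trace",
    "ryr_open_probability",
    "stochastic_po",
    "rhs_three_var",
    "rhs_fast_ryr",
    "rhs_fast_dyadic",
    "slaved_dyadic_calcium",
    "initial_state",
    "integrate",
]

VARIANTS = ("three_var", "fast_ryr", "fast_dyadic")

#: Default fixed step (ms) for stochastic runs; part of the model definition.
DEFAULT_DT_MS = 0.01

#: Default sampling interval (ms) for stored traces.
DEFAULT_SAMPLE_MS = 1.0


@dataclass(frozen=True)
class CaruState:
    """Instantaneous state of one calcium release unit (concentrations μM)."""

    c_d: float
    c_sr_tot: float
    P_o: float
    c_i: float

    def __post_init__(self):
        if min(self.c_d, self.c_sr_tot, self.c_i) < 0:
            raise DomainError("concentrations must be >= 0")
        if not 0.0 <= self.P_o <= 1.0:
            raise DomainError("P_o must lie in [0, 1]")


@dataclass
class Trace:
    """A sampled trajectory with its provenance.

    All concentration columns are μM; ``t_ms`` is strictly increasing.
    ``meta`` records variant, load, B_SQ, noise strength, seed and the
    integrator settings needed to reproduce the run.
    """

    t_ms: np.ndarray
    c_d: np.ndarray
    c_sr_tot: np.ndarray
    c_sr: np.ndarray
    c_i: np.ndarray
    P_o: np.ndarray
    params: ModelParams
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.t_ms)

    def window(self, t0: float, t1: float = math.inf) -> "Trace":
        """Sub-trace with ``t0 <= t_ms < t1``."""
        m = (self.t_ms >= t0) & (self.t_ms < t1)
        return Trace(self.t_ms[m], self.c_d[m], self.c_sr_tot[m],
                     self.c_sr[m], self.c_i[m], self.P_o[m],
                     self.params, dict(self.meta))

    def mass_drift(self) -> float:
        """Max relative deviation of the reconstructed load from c̄_T."""
        cT = self.meta["cT_bar"]
        rec = reconstruct_load(self.c_i, self.c_d, self.c_sr_tot, self.params)
        return float(np.max(np.abs(rec - cT)) / max(cT, 1e-12))


# --------------------------------------------------------------------------
# Fluxes and right-hand sides
# --------------------------------------------------------------------------

def ryr_open_probability(c_d, p: ModelParams = CONTROL):
    """Quasi-steady RyR open fraction ``c_d²/(K_o² + c_d²)``."""
    cd2 = np.square(c_d)
    return cd2 / (p.K_o**2 + cd2)


def stochastic_po(c_d, sigma: float, rng: np.random.Generator,
                  p: ModelParams = CONTROL):
    """Noisy open probability: quasi-steady value plus ``σ·(U − ½)``.

    Uniform symmetric noise, redrawn independently per call; the result
    is clamped to [0, 1].  ``sigma=0`` reproduces the deterministic value
    exactly (no draw is consumed in that case).
    """
    if sigma < 0:
        raise DomainError("sigma must be >= 0")
    po = ryr_open_probability(c_d, p)
    if sigma == 0.0:
        return po
    u = rng.random() if np.isscalar(c_d) else rng.random(np.shape(c_d))
    return np.clip(po + sigma * (u - 0.5), 0.0, 1.0)


def _fluxes(c_d, c_sr, c_i, P_o, p: ModelParams):
    j_rel = p.g * P_o * (c_sr - c_d)
    j_d = (c_d - c_i) / p.tau_i
    j_up = p.g_up * c_i * c_i / (p.K_s**2 + c_i * c_i)
    return j_rel, j_d, j_up


def rhs_three_var(state, cT_bar: float, p: ModelParams = CONTROL):
    """Time derivatives of (c_d, c_sr_tot, P_o) for the full minimal model."""
    c_d, c_sr_tot, P_o = state
    P_o = min(max(P_o, 0.0), 1.0)
    c_i = solve_cytosolic(cT_bar, c_d, c_sr_tot, p, budget_tol=math.inf)
    c_sr = free_sr_calcium(max(c_sr_tot, 0.0), p)
    j_rel, j_d, j_up = _fluxes(c_d, c_sr, c_i, P_o, p)
    return (j_rel - j_d,
            (p.v_i / p.v_sr) * j_up - (p.v_d / p.v_sr) * j_rel,
            p.k_p * c_d * c_d * (1.0 - P_o) - p.k_m * P_o)


def rhs_fast_ryr(state, cT_bar: float, p: ModelParams = CONTROL):
    """Time derivatives of (c_d, c_sr_tot) with RyR gating slaved."""
    c_d, c_sr_tot = state
    c_i = solve_cytosolic(cT_bar, c_d, c_sr_tot, p, budget_tol=math.inf)
    c_sr = free_sr_calcium(max(c_sr_tot, 0.0), p)
    P_o = c_d * c_d / (p.K_o**2 + c_d * c_d)
    j_rel, j_d, j_up = _fluxes(c_d, c_sr, c_i, P_o, p)
    return (j_rel - j_d,
            (p.v_i / p.v_sr) * j_up - (p.v_d / p.v_sr) * j_rel)


def slaved_dyadic_calcium(P_o: float, c_sr_tot: float, cT_bar: float,
                          p: ModelParams = CONTROL,
                          tol: float = 1e-12, max_iter: int = 200):
    """Self-consistent (c_d, c_i) of the fast-dyadic variant.

    Solves ``c_d = (τ_i·g·P_o·c_sr + c_i)/(1 + τ_i·g·P_o)`` jointly with
    the conservation closure for ``c_i`` by fixed-point iteration; the
    conservation feedback on c_d is O(v_d/v_i), so the iteration is a
    strong contraction.
    """
    a = p.tau_i * p.g * min(max(P_o, 0.0), 1.0)
    c_sr = free_sr_calcium(c_sr_tot, p)
    c_d = 0.0
    for _ in range(max_iter):
        c_i = solve_cytosolic(cT_bar, c_d, c_sr_tot, p, budget_tol=math.inf)
        c_d_new = (a * c_sr + c_i) / (1.0 + a)
        if abs(c_d_new - c_d) <= tol * (1.0 + abs(c_d_new)):
            return c_d_new, solve_cytosolic(cT_bar, c_d_new, c_sr_tot, p,
                                            budget_tol=math.inf)
        c_d = c_d_new
    raise RuntimeError(
        f"fast-dyadic inner solve did not converge at P_o={P_o}, "
        f"c_sr_tot={c_sr_tot}, cT_bar={cT_bar}")


def rhs_fast_dyadic(state, cT_bar: float, p: ModelParams = CONTROL):
    """Time derivatives of (c_sr_tot, P_o) with dyadic calcium slaved.

    Only defined for ``B_SQ = 0``.
    """
    if p.B_SQ != 0.0:
        raise DomainError("fast_dyadic variant requires B_SQ = 0")
    c_sr_tot, P_o = state
    P_o = min(max(P_o, 0.0), 1.0)
    c_d, c_i = slaved_dyadic_calcium(P_o, c_sr_tot, cT_bar, p)
    c_sr = c_sr_tot
    j_rel, _, j_up = _fluxes(c_d, c_sr, c_i, P_o, p)
    return ((p.v_i / p.v_sr) * j_up - (p.v_d / p.v_sr) * j_rel,
            p.k_p * c_d * c_d * (1.0 - P_o) - p.k_m * P_o)


# --------------------------------------------------------------------------
# Initial conditions
# --------------------------------------------------------------------------

def initial_state(variant: str, cT_bar: float, p: ModelParams = CONTROL,
                  kick: float = 0.0):
    """Resting initial condition: all calcium in the SR, plus a dyadic kick.

    ``kick`` (μM) is placed in the dyad, the SR holding the remainder, so
    the state is mass-consistent with c̄_T.  The rest state coexists with
    the oscillatory attractor over part of the load range, so basins
    matter: a kick of a few μM is needed to leave the excitable rest
    state deterministically.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    c_sr_tot = (p.v * cT_bar - p.v_d * kick) / p.v_sr
    if c_sr_tot < 0:
        raise DomainError("kick exceeds the total calcium content")
    po = float(ryr_open_probability(kick, p))
    if variant == "three_var":
        return (kick, c_sr_tot, po)
    if variant == "fast_ryr":
        return (kick, c_sr_tot)
    return (c_sr_tot, po)


# --------------------------------------------------------------------------
# Fixed-step (Euler) kernel, used for stochastic runs
# --------------------------------------------------------------------------

@njit(cache=True)
def _euler_fast_ryr_kernel(cd, csrtot, cT, g, tau_i, g_up, K_s, K_o,
                           B_b, K_b, B_SQ, K_SQ, v_i, v_sr, v_d, v,
                           sigma, dt, n_chunk, global_offset, sample_every,
                           U, out_t, out_cd, out_csrtot, out_ci, out_po):
    for i in range(n_chunk):
        budget = v * cT - v_d * cd - v_sr * csrtot
        if budget < 0.0:
            budget = 0.0
        b = budget / v_i
        q = K_b + B_b - b
        ci = 0.5 * (-q + math.sqrt(q * q + 4.0 * K_b * b))
        if B_SQ == 0.0:
            csr = csrtot
        else:
            s = csrtot - K_SQ - B_SQ
            csr = 0.5 * (s + math.sqrt(s * s + 4.0 * csrtot * K_SQ))
        po = cd * cd / (K_o * K_o + cd * cd)
        if sigma > 0.0:
            po += sigma * (U[i] - 0.5)
            if po < 0.0:
                po = 0.0
            elif po > 1.0:
                po = 1.0
        gi = global_offset + i
        if gi % sample_every == 0:
            k = gi // sample_every
            if k < out_t.shape[0]:
                out_t[k] = gi * dt
                out_cd[k] = cd
                out_csrtot[k] = csrtot
                out_ci[k] = ci
                out_po[k] = po
        j_rel = g * po * (csr - cd)
        j_d = (cd - ci) / tau_i
        j_up = g_up * ci * ci / (K_s * K_s + ci * ci)
        cd += dt * (j_rel - j_d)
        csrtot += dt * ((v_i / v_sr) * j_up - (v_d / v_sr) * j_rel)
        if cd < 0.0:
            cd = 0.0
        if csrtot < 0.0:
            csrtot = 0.0
    return cd, csrtot


def _integrate_euler(cT_bar, p, t_end_ms, y0, sigma, seed, dt_ms, sample_ms):
    n_steps = int(round(t_end_ms / dt_ms))
    sample_every = max(1, int(round(sample_ms / dt_ms)))
    n_out = (n_steps + sample_every - 1) // sample_every
    out = {k: np.empty(n_out) for k in ("t", "cd", "csrtot", "ci", "po")}
    rng = np.random.default_rng(seed)
    cd, csrtot = float(y0[0]), float(y0[1])
    chunk = 2_000_000
    done = 0
    while done < n_steps:
        m = min(chunk, n_steps - done)
        U = rng.random(m) if sigma > 0.0 else np.empty(m)
        cd, csrtot = _euler_fast_ryr_kernel(
            cd, csrtot, cT_bar, p.g, p.tau_i, p.g_up, p.K_s, p.K_o,
            p.B_b, p.K_b, p.B_SQ, p.K_SQ, p.v_i, p.v_sr, p.v_d, p.v,
            sigma, dt_ms, m, done, sample_every, U,
            out["t"], out["cd"], out["csrtot"], out["ci"], out["po"])
        done += m
    return out


# --------------------------------------------------------------------------
# Public integrator
# --------------------------------------------------------------------------

def integrate(variant: str, cT_bar: float, p: ModelParams = CONTROL, *,
              t_end_ms: float, y0=None, kick: float = 0.0,
              sigma: float = 0.0, seed: int | None = None,
              method: str | None = None, dt_ms: float = DEFAULT_DT_MS,
              sample_ms: float = DEFAULT_SAMPLE_MS,
              rtol: float = 1e-8, atol: float = 1e-10,
              max_step_ms: float = 5.0) -> Trace:
    """Integrate one variant of the model and return a sampled Trace.

    Parameters
    ----------
    variant : {"three_var", "fast_ryr", "fast_dyadic"}
    cT_bar : float
        Total calcium load (μM), conserved along the trajectory.
    t_end_ms : float
        Model time to integrate.
    y0 : tuple, optional
        Initial state in the variant's coordinates; defaults to
        :func:`initial_state` with the given ``kick``.
    sigma : float
        Noise strength on P_o (fast_ryr only).  ``sigma > 0`` forces the
        fixed-step scheme.
    method : {"adaptive", "euler"}, optional
        Defaults to "euler" when ``sigma > 0`` and "adaptive" otherwise.
        The fixed-step scheme is only implemented for ``fast_ryr``.
    dt_ms : float
        Fixed step for the Euler scheme; recorded in metadata because the
        per-step noise model depends on it.

    Raises
    ------
    RuntimeError
        If the adaptive integrator fails; the message carries the last
        valid time reached.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if sigma < 0:
        raise DomainError("sigma must be >= 0")
    if sigma > 0 and variant != "fast_ryr":
        raise ValueError("stochastic gating is defined for the fast_ryr variant")
    if method is None:
        method = "euler" if sigma > 0 else "adaptive"
    if y0 is None:
        y0 = initial_state(variant, cT_bar, p, kick=kick)

    meta = {"variant": variant, "cT_bar": cT_bar, "B_SQ": p.B_SQ,
            "sigma": sigma, "seed": seed, "method": method,
            "sample_ms": sample_ms, "t_end_ms": t_end_ms}

    if method == "euler":
        if variant != "fast_ryr":
            raise ValueError("fixed-step scheme is implemented for fast_ryr only")
        meta["dt_ms"] = dt_ms
        out = _integrate_euler(cT_bar, p, t_end_ms, y0, sigma, seed,
                               dt_ms, sample_ms)
        c_sr = free_sr_calcium(out["csrtot"], p)
        return Trace(out["t"], out["cd"], out["csrtot"], np.asarray(c_sr),
                     out["ci"], out["po"], p, meta)

    if method != "adaptive":
        raise ValueError(f"unknown method {method!r}")

    from scipy.integrate import solve_ivp

    rhs = {"three_var": rhs_three_var, "fast_ryr": rhs_fast_ryr,
           "fast_dyadic": rhs_fast_dyadic}[variant]
    t_eval = np.arange(0.0, t_end_ms, sample_ms)
    sol = solve_ivp(lambda t, y: rhs(y, cT_bar, p), (0.0, t_end_ms),
                    np.asarray(y0, dtype=float), method="LSODA",
                    rtol=rtol, atol=atol, max_step=max_step_ms,
                    t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(
            f"integration failed at t={sol.t[-1] if len(sol.t) else 0.0} ms "
            f"(last state {sol.y[:, -1] if sol.y.size else y0}): {sol.message}")
    meta.update({"rtol": rtol, "atol": atol, "max_step_ms": max_step_ms})

    if variant == "three_var":
        cd, csrtot, po = sol.y
        po = np.clip(po, 0.0, 1.0)
    elif variant == "fast_ryr":
        cd, csrtot = sol.y
        po = np.asarray(ryr_open_probability(cd, p))
    else:
        csrtot, po = sol.y
        po = np.clip(po, 0.0, 1.0)
        cd = np.array([slaved_dyadic_calcium(pp, cc, cT_bar, p)[0]
                       for pp, cc in zip(po, csrtot)])
    ci = np.array([solve_cytosolic(cT_bar, a, b, p, budget_tol=math.inf)
                   for a, b in zip(cd, csrtot)])
    c_sr = np.asarray(free_sr_calcium(csrtot, p))
    return Trace(sol.t, cd, csrtot, c_sr, ci, po, p, meta)
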