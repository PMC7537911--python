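"""Fixed points, linear stability, and bifurcation diagrams of the
minimal calcium-release-unit model as functions of the total load c̄_T.

At a fixed point the release, diffusion and uptake fluxes balance, which
reduces the model (any variant — the slaving relations are exactly the
fixed-point conditions, so all variants share their equilibria) to a
single scalar equation ``f(c_i; c̄_T) = 0``:

* ``c_d = c_i + (v_i/v_d)·τ_i·J_up(c_i)``
* ``c_sr_tot`` follows from total-calcium conservation,
* the residual is the dyadic balance
  ``g·P_o(c_d)·(c_sr − c_d) − (c_d − c_i)/τ_i``.

``c_i = 0`` (all calcium in the SR, RyRs closed) is a root at every
load.  As the load grows a pair of nontrivial roots appears at a fold;
with calsequestrin present a window with five fixed points can occur.
Stability is classified from the eigenvalues of the variant-specific
Jacobian, evaluated by central finite differences.

The bifurcation structure in load is resolved by
:func:`find_fold` (root-count bisection), :func:`find_hopf` (leading
eigenvalue crossing on the upper branch) and :func:`find_homoclinic`
(bisection on a sustained-oscillation classifier applied to simulated
trajectories; the limit cycle is found by direct integration rather than
periodic-orbit continuation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.signal import find_peaks

from .dynamics import (Trace, initial_state, integrate, rhs_fast_dyadic,
                       rhs_fast_ryr, rhs_three_var, ryr_open_probability)
from .params_buffers import (CONTROL, DomainError, ModelParams,
                             buffered_cytosolic, free_sr_calcium,
                             solve_cytosolic)

__all__ = [
    "FixedPoint",
    "BifurcationDiagram",
    "equilibrium_residual",
    "find_fixed_points",
    "find_fold",
    "find_hopf",
    "find_homoclinic",
    "estimate_period",
    "classify_sustained",
    "sweep_diagram",
    "cycle_extent",
]

#: Default transient discarded before classifying a deterministic run (ms).
DET_TRANSIENT_MS = 2000.0
#: Default transient for stochastic runs (ms); noise-driven cycles are slow.
STOCH_TRANSIENT_MS = 20000.0

_RT_GRID = 2000        # log-spaced points when bracketing f(c_i) roots
_MERGE_TOL = 1e-6      # roots closer than this (μM) are merged


# --------------------------------------------------------------------------
# The scalar equilibrium problem
# --------------------------------------------------------------------------

def _equilibrium_closure(c_i, cT_bar, p):
    """(c_d, c_sr_tot) implied by c_i at equilibrium (arrays ok)."""
    ci = np.asarray(c_i, dtype=float)
    j_up = p.g_up * ci * ci / (p.K_s**2 + ci * ci)
    c_d = ci + (p.v_i / p.v_d) * p.tau_i * j_up
    c_sr_tot = (p.v * cT_bar - p.v_d * c_d
                - p.v_i * buffered_cytosolic(ci, p)) / p.v_sr
    return c_d, c_sr_tot


def equilibrium_residual(c_i, cT_bar: float, p: ModelParams = CONTROL):
    """Scalar residual ``f(c_i; c̄_T)`` whose roots are the fixed points.

    Returns NaN where the implied SR content would be negative (c_i not
    feasible at this load).  Accepts scalars or arrays; units μM/ms.
    """
    scalar = np.isscalar(c_i)
    ci = np.atleast_1d(np.asarray(c_i, dtype=float))
    if np.any(ci < 0):
        raise DomainError("c_i must be >= 0")
    c_d, c_sr_tot = _equilibrium_closure(ci, cT_bar, p)
    res = np.full_like(ci, np.nan)
    ok = c_sr_tot >= 0.0
    if np.any(ok):
        c_sr = free_sr_calcium(c_sr_tot[ok], p)
        po = ryr_open_probability(c_d[ok], p)
        res[ok] = p.g * po * (c_sr - c_d[ok]) - (c_d[ok] - ci[ok]) / p.tau_i
    return float(res[0]) if scalar else res


def _ci_max(cT_bar, p):
    """Largest feasible c_i at this load (where the SR would be empty)."""
    if cT_bar <= 0:
        return 0.0

    def budget(ci):
        _, c_sr_tot = _equilibrium_closure(ci, cT_bar, p)
        return float(c_sr_tot)

    hi = p.v * cT_bar / p.v_i + 1.0
    while budget(hi) > 0:
        hi *= 2.0
    return brentq(budget, 0.0, hi, xtol=1e-12)


def _nontrivial_roots(cT_bar, p):
    cmax = _ci_max(cT_bar, p)
    if cmax <= 1e-4:
        return []
    grid = np.logspace(-4, math.log10(cmax * (1.0 - 1e-9)), _RT_GRID)
    vals = equilibrium_residual(grid, cT_bar, p)
    roots = []
    f = lambda x: equilibrium_residual(float(x), cT_bar, p)
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if not (np.isfinite(a) and np.isfinite(b)):
            continue
        if a == 0.0:
            roots.append(grid[i])
        elif a * b < 0.0:
            roots.append(brentq(f, grid[i], grid[i + 1],
                                xtol=1e-14, rtol=8.9e-16))
    merged = []
    for r in roots:
        if not merged or abs(r - merged[-1]) > _MERGE_TOL:
            merged.append(r)
    return merged


# --------------------------------------------------------------------------
# Stability
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FixedPoint:
    """One equilibrium with its linearisation.

    ``jacobian`` is expressed in the variant's own coordinates
    ((c_d, c_sr_tot), (c_sr_tot, P_o) or (c_d, c_sr_tot, P_o)); for the
    two-variable variants its entries are the (f1, f2; g1, g2) used in
    the nullcline-slope stability argument.
    """

    c_i: float
    c_d: float
    c_sr_tot: float
    c_sr: float
    variant: str
    jacobian: np.ndarray
    eigenvalues: np.ndarray
    stability: str
    branch: str
    residual: float

    @property
    def is_stable(self) -> bool:
        return self.stability.startswith("stable")


def _variant_state(variant, c_i, c_d, c_sr_tot, p):
    po = float(ryr_open_probability(c_d, p))
    if variant == "fast_ryr":
        return np.array([c_d, c_sr_tot])
    if variant == "fast_dyadic":
        return np.array([c_sr_tot, po])
    return np.array([c_d, c_sr_tot, po])


def _variant_rhs(variant):
    return {"fast_ryr": rhs_fast_ryr, "fast_dyadic": rhs_fast_dyadic,
            "three_var": rhs_three_var}[variant]


def _jacobian(variant, y0, cT_bar, p, rel_step=1e-6):
    rhs = _variant_rhs(variant)
    n = len(y0)
    jac = np.zeros((n, n))
    f0 = None
    for j in range(n):
        h = rel_step * max(1.0, abs(y0[j]))
        yp, ym = y0.copy(), y0.copy()
        yp[j] += h
        ym[j] -= h
        try:
            fp = np.asarray(rhs(yp, cT_bar, p))
        except DomainError:
            fp = None     # stepped outside the feasible domain (rest state)
        try:
            fm = np.asarray(rhs(ym, cT_bar, p))
        except DomainError:
            fm = None
        if fp is not None and fm is not None:
            jac[:, j] = (fp - fm) / (2.0 * h)
        else:
            if f0 is None:
                f0 = np.asarray(rhs(y0, cT_bar, p))
            if fm is not None:
                jac[:, j] = (f0 - fm) / h
            elif fp is not None:
                jac[:, j] = (fp - f0) / h
            else:
                raise RuntimeError("Jacobian step infeasible on both sides")
    return jac


def _classify(eigvals):
    re = eigvals.real
    has_complex = np.any(np.abs(eigvals.imag) > 1e-9 * np.maximum(1.0, np.abs(eigvals)))
    if np.all(re < 0):
        return "stable_spiral" if has_complex else "stable_node"
    if np.all(re > 0):
        return "unstable_spiral" if has_complex else "unstable_node"
    return "unstable_spiral" if has_complex else "saddle"


def find_fixed_points(cT_bar: float, p: ModelParams = CONTROL,
                      variant: str = "fast_ryr") -> list[FixedPoint]:
    """All equilibria at this load, sorted by c_i, with stability classes.

    The trivial rest state (c_i = c_d = 0, all calcium in the SR) is
    always included and labelled ``lower``; the largest nontrivial root
    is ``upper`` and any in between ``intermediate``.
    """
    if cT_bar < 0:
        raise DomainError("cT_bar must be >= 0")
    roots = [0.0] + _nontrivial_roots(cT_bar, p)
    out = []
    for k, ci in enumerate(roots):
        c_d, c_sr_tot = (x if np.isscalar(x) else float(x)
                         for x in _equilibrium_closure(ci, cT_bar, p))
        c_d, c_sr_tot = float(c_d), float(c_sr_tot)
        y0 = _variant_state(variant, ci, c_d, c_sr_tot, p)
        jac = _jacobian(variant, y0, cT_bar, p)
        ev = np.linalg.eigvals(jac)
        branch = ("lower" if k == 0
                  else "upper" if k == len(roots) - 1 else "intermediate")
        res = 0.0 if ci == 0.0 else float(equilibrium_residual(ci, cT_bar, p))
        out.append(FixedPoint(ci, c_d, c_sr_tot,
                              float(free_sr_calcium(c_sr_tot, p)),
                              variant, jac, ev, _classify(ev), branch, res))
    return out


# --------------------------------------------------------------------------
# Loci in load: fold, Hopf
# --------------------------------------------------------------------------

def find_fold(p: ModelParams = CONTROL, lo: float = 5.0, hi: float = 400.0,
              tol: float = 0.05) -> float | None:
    """Smallest load with nontrivial fixed points (bisection on root count)."""
    n_hi = len(_nontrivial_roots(hi, p))
    if n_hi < 2:
        return None
    if len(_nontrivial_roots(lo, p)) >= 2:
        return lo
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if len(_nontrivial_roots(mid, p)) >= 2:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def _upper_leading_real(cT_bar, p, variant):
    fps = find_fixed_points(cT_bar, p, variant)
    if fps[-1].branch != "upper":
        return None
    return float(fps[-1].eigenvalues.real.max())


def find_hopf(p: ModelParams = CONTROL, variant: str = "fast_ryr",
              lo: float | None = None, hi: float = 140.0,
              tol: float = 0.05) -> float | None:
    """Load at which the upper branch's leading eigenvalue crosses zero.

    Returns None when there is no crossing — e.g. at high calsequestrin
    levels the upper branch is already stable when it is born at the
    fold, and stabilisation happens in a saddle-node instead of a Hopf.

    Raises
    ------
    RuntimeError
        If the upper branch cannot be tracked over the bracket.
    """
    if lo is None:
        fold = find_fold(p)
        if fold is None:
            return None
        lo = fold + 0.25
    f_lo = _upper_leading_real(lo, p, variant)
    f_hi = _upper_leading_real(hi, p, variant)
    if f_lo is None or f_hi is None:
        raise RuntimeError("upper branch lost while bracketing the Hopf point")
    if f_lo < 0 or f_hi > 0:   # no crossing: born stable, or still unstable
        return None
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        f_mid = _upper_leading_real(mid, p, variant)
        if f_mid is None:
            raise RuntimeError(f"upper branch lost at cT_bar={mid}")
        if f_mid > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# --------------------------------------------------------------------------
# Period estimation and the sustained-oscillation classifier
# --------------------------------------------------------------------------

def _default_transient(trace: Trace) -> float:
    return (STOCH_TRANSIENT_MS if trace.meta.get("sigma", 0.0) > 0
            else DET_TRANSIENT_MS)


def estimate_period(trace: Trace, *, transient_ms: float | None = None,
                    amp_threshold: float | None = None,
                    prominence_frac: float = 0.3,
                    min_peaks: int = 3) -> float | None:
    """Mean inter-peak interval of c_i after the transient, or None.

    None means "no oscillation": peak-to-peak amplitude below the
    threshold (default ``max(0.02 μM, 5% of the trace's c_i maximum)``)
    or fewer than ``min_peaks`` peaks found.

    Raises
    ------
    ValueError
        If the trace does not extend beyond the transient.
    """
    if transient_ms is None:
        transient_ms = _default_transient(trace)
    w = trace.window(transient_ms)
    if len(w) < 2 * (min_peaks + 1):
        raise ValueError(
            f"trace too short: {len(w)} samples beyond the {transient_ms} ms "
            "transient")
    x = w.c_i
    amp = float(x.max() - x.min())
    if amp_threshold is None:
        amp_threshold = max(0.02, 0.05 * float(x.max()))
    if amp < amp_threshold:
        return None
    peaks, _ = find_peaks(x, prominence=prominence_frac * amp)
    if len(peaks) < min_peaks:
        return None
    return float(np.diff(w.t_ms[peaks]).mean())


def classify_sustained(trace: Trace, *, transient_ms: float | None = None,
                       amp_threshold: float | None = None,
                       min_cycles: int = 5,
                       cv_max: float | None = None) -> bool:
    """True if the trace shows a sustained oscillation after the transient.

    Requires at least ``min_cycles`` consecutive cycles whose inter-peak
    intervals have a coefficient of variation below ``cv_max`` (default
    0.2 for deterministic runs, 0.6 for stochastic ones — noise makes
    near-homoclinic cycles slow and irregular), on top of the amplitude
    rule of :func:`estimate_period`.
    """
    if cv_max is None:
        cv_max = 0.6 if trace.meta.get("sigma", 0.0) > 0 else 0.2
    if transient_ms is None:
        transient_ms = _default_transient(trace)
    w = trace.window(transient_ms)
    if len(w) < 2 * (min_cycles + 2):
        return False
    x = w.c_i
    amp = float(x.max() - x.min())
    if amp_threshold is None:
        amp_threshold = max(0.02, 0.05 * float(x.max()))
    if amp < amp_threshold:
        return False
    peaks, _ = find_peaks(x, prominence=0.3 * amp)
    if len(peaks) < min_cycles + 1:
        return False
    ipi = np.diff(w.t_ms[peaks])
    return float(ipi.std() / ipi.mean()) < cv_max


# --------------------------------------------------------------------------
# Limit cycles by direct integration
# --------------------------------------------------------------------------

def _near_upper_ic(cT_bar, p, variant):
    """Initial condition just off the upper fixed point (its basin holds
    the limit cycle when one exists)."""
    fps = find_fixed_points(cT_bar, p, variant)
    if len(fps) < 3:
        return None
    up = fps[-1]
    if variant == "fast_dyadic":
        po = float(ryr_open_probability(up.c_d, p))
        return (up.c_sr_tot * 0.98, min(1.0, po * 1.1 + 0.005))
    if variant == "fast_ryr":
        return (up.c_d * 1.05 + 0.5, up.c_sr_tot * 0.999)
    po = float(ryr_open_probability(up.c_d, p))
    return (up.c_d * 1.05 + 0.5, up.c_sr_tot * 0.999, po)


def cycle_extent(cT_bar: float, p: ModelParams = CONTROL,
                 variant: str = "fast_ryr", *, t_end_ms: float = 4000.0,
                 transient_ms: float = DET_TRANSIENT_MS,
                 sample_ms: float = 0.25,
                 amp_threshold: float | None = None):
    """(oscillating?, c_i min, c_i max, period) of the attractor reached
    from just off the upper fixed point.

    Returns ``(False, nan, nan, None)`` when fewer than three fixed
    points exist (no upper state to oscillate around).
    """
    y0 = _near_upper_ic(cT_bar, p, variant)
    if y0 is None:
        return False, float("nan"), float("nan"), None
    tr = integrate(variant, cT_bar, p, t_end_ms=t_end_ms, y0=y0,
                   sample_ms=sample_ms)
    osc = classify_sustained(tr, transient_ms=transient_ms,
                             amp_threshold=amp_threshold)
    w = tr.window(transient_ms)
    per = estimate_period(tr, transient_ms=transient_ms,
                          amp_threshold=amp_threshold) if osc else None
    return osc, float(w.c_i.min()), float(w.c_i.max()), per


def find_homoclinic(p: ModelParams = CONTROL, variant: str = "fast_ryr", *,
                    lo: float | None = None, hi: float | None = None,
                    tol: float = 0.1, t_end_ms: float = 4000.0,
                    transient_ms: float = DET_TRANSIENT_MS) -> float | None:
    """Smallest load with a sustained deterministic limit cycle.

    Sweeps downward from just below the Hopf point until oscillation is
    found, then bisects the sustained-oscillation classifier.  The cycle
    period grows on approach to the returned locus (the global
    bifurcation has zero frequency).  Returns None if no oscillation is
    found anywhere in the bracket.
    """
    def oscillates(load):
        return cycle_extent(load, p, variant, t_end_ms=t_end_ms,
                            transient_ms=transient_ms)[0]

    if lo is None:
        fold = find_fold(p)
        if fold is None:
            return None
        lo = fold + 0.05
    if hi is None:
        hopf = find_hopf(p, variant)
        hi = (hopf - 0.5) if hopf is not None else lo + 40.0
    osc_hi = None
    for load in np.linspace(hi, lo, 8):
        if oscillates(load):
            osc_hi = load
            break
    if osc_hi is None:
        return None
    if oscillates(lo):
        return lo
    a, b = lo, osc_hi
    while b - a > tol:
        mid = 0.5 * (a + b)
        if oscillates(mid):
            b = mid
        else:
            a = mid
    return 0.5 * (a + b)


# --------------------------------------------------------------------------
# Diagrams
# --------------------------------------------------------------------------

@dataclass
class BifurcationDiagram:
    """Per-load fixed points and limit-cycle extent over a load grid.

    ``fixed_points`` has one row per (load, branch); ``cycles`` one row
    per load with the attractor reached from near the upper state;
    ``loci`` holds the refined fold / homoclinic / Hopf loads (None when
    absent) and the bisection tolerances used.
    """

    ct_values: np.ndarray
    fixed_points: pd.DataFrame
    cycles: pd.DataFrame
    loci: dict
    meta: dict = field(default_factory=dict)


def sweep_diagram(ct_values, p: ModelParams = CONTROL,
                  variant: str = "fast_ryr", *, classify_cycles: bool = True,
                  refine_loci: bool = True, t_end_ms: float = 4000.0,
                  transient_ms: float = DET_TRANSIENT_MS,
                  loci_tol: float = 0.1) -> BifurcationDiagram:
    """Bifurcation diagram over a monotone grid of loads."""
    ct = np.asarray(ct_values, dtype=float)
    if len(ct) > 1 and np.any(np.diff(ct) <= 0):
        raise ValueError("load grid must be strictly increasing")

    fp_rows, cyc_rows = [], []
    for load in ct:
        fps = find_fixed_points(load, p, variant)
        for fp in fps:
            fp_rows.append({"load": load, "branch": fp.branch, "c_i": fp.c_i,
                            "c_d": fp.c_d, "c_sr_tot": fp.c_sr_tot,
                            "stability": fp.stability})
        if classify_cycles:
            osc, lo_i, hi_i, per = cycle_extent(
                load, p, variant, t_end_ms=t_end_ms,
                transient_ms=transient_ms)
            cyc_rows.append({"load": load, "oscillating": bool(osc),
                             "cycle_min": lo_i if osc else np.nan,
                             "cycle_max": hi_i if osc else np.nan,
                             "period_ms": per if osc else np.nan})
    fp_df = pd.DataFrame(fp_rows)
    cyc_df = pd.DataFrame(cyc_rows)

    loci = {"fold": None, "homoclinic": None, "hopf": None,
            "tol_fold": 0.05, "tol_homoclinic": loci_tol, "tol_hopf": 0.05}
    if refine_loci:
        loci["fold"] = find_fold(p, lo=max(ct[0] - 20, 0.5), hi=ct[-1])
        try:
            loci["hopf"] = find_hopf(p, variant)
        except RuntimeError:
            loci["hopf"] = None
        loci["homoclinic"] = find_homoclinic(
            p, variant, tol=loci_tol, t_end_ms=t_end_ms,
            transient_ms=transient_ms)
    return BifurcationDiagram(ct, fp_df, cyc_df, loci,
                              {"variant": variant, "B_SQ": p.B_SQ,
                               "t_end_ms": t_end_ms,
                               "transient_ms": transient_ms})
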