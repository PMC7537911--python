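"""Nullcline geometry, pinch-off detection and the closed-form
onset-of-oscillation results.

For the fast-RyR variant the phase plane is (c_d, c_sr) with cytosolic
calcium slaved to total-calcium conservation.  The ``ċ_d = 0`` nullcline
(α-curve) is S-shaped in c_d: scanning c_sr, each line carries one or
three roots.  Below a critical load the S is connected; above it an
interior band of c_sr appears in which the two low-c_d roots are lost
("pinch-off") and the curve splits into two disconnected branches.  The
split removes the path along which trajectories could settle, so a
sustained oscillation around the upper (unstable) fixed point appears —
the pinch-off is the geometric criterion for oscillation onset.

Under the approximations ``c_d ≪ K_o`` and ``c_d ≪ c_sr`` and with
bound cytosolic buffer dominating free calcium, the pinch-off admits a
closed form.  With ``g̃ = g·τ_i/K_o²`` the critical load is

    ``c̄_T* = √(v_sr·v_i·B_b / (v²·g̃·K_b)) − v_sr/(4·g̃·K_b·v)``

and the diastolic free SR calcium at onset is

    ``c_sr* = v·c̄_T*/(2·v_sr) − 1/(8·g̃·K_b)``,

to be compared with the pre-onset lower-state value ``(v/v_sr)·c̄_T*``.
Note neither expression contains the SERCA strength: the onset load is
independent of ``g_up``, which the numeric pinch-off reproduces exactly
(uptake does not enter the dyadic balance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .dynamics import ryr_open_probability, slaved_dyadic_calcium
from .equilibria import FixedPoint, find_fixed_points
from .params_buffers import (CONTROL, DomainError, ModelParams,
                             total_sr_calcium)

__all__ = [
    "NullclineSet",
    "OnsetResult",
    "SignReport",
    "alpha_residual",
    "beta_residual",
    "compute_nullclines",
    "cd_nullcline_branch_count",
    "po_nullcline_branch_count",
    "pinch_off_load",
    "onset_analytic",
    "onset_vs_buffers",
    "jacobian_sign_report",
]


# --------------------------------------------------------------------------
# Residuals on coordinate lines (vectorised over c_d)
# --------------------------------------------------------------------------

def _ci_of(cd, c_sr_tot, cT_bar, p):
    """Conservation closure, vectorised; NaN where infeasible."""
    cd = np.asarray(cd, dtype=float)
    budget = p.v * cT_bar - p.v_d * cd - p.v_sr * c_sr_tot
    b = budget / p.v_i
    q = p.K_b + p.B_b - b
    with np.errstate(invalid="ignore"):
        ci = 0.5 * (-q + np.sqrt(q * q + 4.0 * p.K_b * b))
    ci = np.where(budget < 0, np.nan, np.maximum(ci, 0.0))
    return ci


def alpha_residual(c_d, c_sr, cT_bar: float, p: ModelParams = CONTROL):
    """``ċ_d`` on the (c_d, c_sr) plane; NaN where infeasible."""
    cd = np.asarray(c_d, dtype=float)
    c_sr_tot = total_sr_calcium(float(c_sr), p)
    ci = _ci_of(cd, c_sr_tot, cT_bar, p)
    po = ryr_open_probability(cd, p)
    return p.g * po * (c_sr - cd) - (cd - ci) / p.tau_i


def beta_residual(c_d, c_sr, cT_bar: float, p: ModelParams = CONTROL):
    """``ċ_sr_tot`` on the (c_d, c_sr) plane; NaN where infeasible."""
    cd = np.asarray(c_d, dtype=float)
    c_sr_tot = total_sr_calcium(float(c_sr), p)
    ci = _ci_of(cd, c_sr_tot, cT_bar, p)
    po = ryr_open_probability(cd, p)
    j_up = p.g_up * ci * ci / (p.K_s**2 + ci * ci)
    return (p.v_i / p.v_sr) * j_up - (p.v_d / p.v_sr) * p.g * po * (c_sr - cd)


def _line_roots(resfun, c_sr, cT_bar, p, n_cd):
    """Roots in c_d of a residual along one c_sr line (log grid)."""
    c_sr_tot = total_sr_calcium(float(c_sr), p)
    cd_max = (p.v * cT_bar - p.v_sr * c_sr_tot) / p.v_d
    if cd_max <= 1e-4:
        return []
    grid = np.logspace(-4, math.log10(cd_max * (1.0 - 1e-9)), n_cd)
    vals = resfun(grid, c_sr, cT_bar, p)
    roots = []
    f = lambda x: float(resfun(float(x), c_sr, cT_bar, p))
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if np.isfinite(a) and np.isfinite(b) and a * b < 0:
            roots.append(brentq(f, grid[i], grid[i + 1], xtol=1e-12))
    return roots


# --------------------------------------------------------------------------
# Branch counting and pinch-off
# --------------------------------------------------------------------------

def _csr_grid(cT_bar, p, n_csr):
    csr_max = float(np.asarray(
        total_sr_calcium(0.0, p) * 0 + (p.v * cT_bar / p.v_sr)))
    # grid over free SR calcium; with CSQ the free value at full SR load
    from .params_buffers import free_sr_calcium
    csr_top = float(free_sr_calcium(csr_max, p))
    return np.linspace(max(0.5, 1e-3 * csr_top), csr_top * 0.999, n_csr)


def cd_nullcline_branch_count(cT_bar: float, p: ModelParams = CONTROL,
                              n_csr: int = 400, n_cd: int = 600) -> int:
    """1 if the ċ_d = 0 curve is connected, 2 if it has pinched off.

    Scans c_sr lines and counts α-roots in c_d.  The split is declared
    when an interior run of lines carrying a single root (the low-c_d
    pair lost) is flanked on both sides by lines carrying three.
    """
    counts = np.array([len(_line_roots(alpha_residual, s, cT_bar, p, n_cd))
                       for s in _csr_grid(cT_bar, p, n_csr)])
    return 2 if _has_interior_gap(counts >= 3) else 1


def _has_interior_gap(ind: np.ndarray) -> bool:
    """True if a False-run lies strictly between two True-runs."""
    idx = np.where(ind)[0]
    if len(idx) < 2:
        return False
    return bool(np.any(~ind[idx[0]:idx[-1] + 1]))


def po_nullcline_branch_count(cT_bar: float, p: ModelParams = CONTROL,
                              n_csr: int = 400, n_po: int = 600) -> int:
    """Branch count of the Ṗ_o = 0 curve of the fast-dyadic variant,
    scanned in the (c_sr, P_o) plane (requires B_SQ = 0)."""
    if p.B_SQ != 0.0:
        raise DomainError("fast-dyadic nullclines require B_SQ = 0")

    def line_count(c_sr):
        # log grid: the low-P_o roots sit orders of magnitude below 1
        po_grid = np.logspace(-8, 0, n_po)
        po_grid[-1] = 1.0 - 1e-12
        vals = np.empty_like(po_grid)
        for i, po in enumerate(po_grid):
            try:
                cd, _ = slaved_dyadic_calcium(po, c_sr, cT_bar, p)
            except Exception:
                vals[i] = np.nan
                continue
            vals[i] = p.k_p * cd * cd * (1.0 - po) - p.k_m * po
        n = 0
        for i in range(len(po_grid) - 1):
            if (np.isfinite(vals[i]) and np.isfinite(vals[i + 1])
                    and vals[i] * vals[i + 1] < 0):
                n += 1
        return n

    counts = np.array([line_count(s) for s in _csr_grid(cT_bar, p, n_csr)])
    return 2 if _has_interior_gap(counts >= 3) else 1


def pinch_off_load(p: ModelParams = CONTROL, *, variant: str = "fast_ryr",
                   lo: float = 35.0, hi: float = 60.0, tol: float = 0.05,
                   n_csr: int = 400, n_cd: int = 600) -> float | None:
    """Critical load at which the fast nullcline pinches off (bisection).

    Returns None when no 1 → 2 transition of the branch count lies in
    [lo, hi].  The result is invariant to the SERCA strength ``g_up``
    because uptake does not enter the pinched nullcline's equation.
    """
    count = {"fast_ryr": cd_nullcline_branch_count,
             "fast_dyadic": po_nullcline_branch_count}[variant]
    f_lo = count(lo, p, n_csr, n_cd)
    f_hi = count(hi, p, n_csr, n_cd)
    if f_lo != 1 or f_hi != 2:
        return None
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if count(mid, p, n_csr, n_cd) >= 2:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


# --------------------------------------------------------------------------
# Full nullcline sets
# --------------------------------------------------------------------------

@dataclass
class NullclineSet:
    """Point sets of both nullclines at one load, in the (c_d, c_sr) plane.

    ``alpha_points`` / ``beta_points`` are (n, 2) arrays of (c_d, c_sr)
    pairs satisfying their defining equation to root-solver tolerance.
    ``alpha_branch_count`` is 1 (connected) or 2 (pinched off).
    ``intersections`` are (c_d, c_sr) pairs where both residuals vanish;
    they coincide with the fixed points of the model.
    """

    cT_bar: float
    alpha_points: np.ndarray
    beta_points: np.ndarray
    alpha_branch_count: int
    intersections: list
    meta: dict = field(default_factory=dict)


def compute_nullclines(cT_bar: float, p: ModelParams = CONTROL,
                       n_csr: int = 400, n_cd: int = 600) -> NullclineSet:
    """Extract both nullclines by per-line root enumeration.

    The α-curve is enumerated in c_d per c_sr line; the β-curve in both
    sweep directions (its folded regions are multivalued either way).
    Intersections are refined by tracking the sign of β along the
    α-curve and polishing each crossing.
    """
    csr_lines = _csr_grid(cT_bar, p, n_csr)
    a_pts, b_pts = [], []
    a_roots_per_line = []
    for s in csr_lines:
        ra = _line_roots(alpha_residual, s, cT_bar, p, n_cd)
        a_roots_per_line.append(ra)
        a_pts.extend((cd, s) for cd in ra)
        b_pts.extend((cd, s) for cd in
                     _line_roots(beta_residual, s, cT_bar, p, n_cd))
    # second sweep direction for the β-curve: roots in c_sr per c_d line
    cd_lines = np.logspace(-3, math.log10(max(10.0, csr_lines[-1])), n_cd // 2)
    for cd in cd_lines:
        f = lambda s: float(beta_residual(float(cd), s, cT_bar, p))
        vals = [f(s) for s in csr_lines[::4]]
        sub = csr_lines[::4]
        for i in range(len(sub) - 1):
            if (np.isfinite(vals[i]) and np.isfinite(vals[i + 1])
                    and vals[i] * vals[i + 1] < 0):
                b_pts.append((cd, brentq(f, sub[i], sub[i + 1], xtol=1e-12)))

    counts = np.array([len(r) for r in a_roots_per_line])
    branch_count = 2 if _has_interior_gap(counts >= 3) else 1

    inter = _intersections(csr_lines, a_roots_per_line, cT_bar, p)
    return NullclineSet(cT_bar, np.array(a_pts), np.array(b_pts),
                        branch_count, inter,
                        {"n_csr": n_csr, "n_cd": n_cd, "B_SQ": p.B_SQ})


def _intersections(csr_lines, a_roots_per_line, cT_bar, p):
    """β-sign changes along the α-curve, polished to machine precision."""
    found = []
    for k in range(len(csr_lines) - 1):
        for cd1 in a_roots_per_line[k]:
            nxt = a_roots_per_line[k + 1]
            if not nxt:
                continue
            cd2 = min(nxt, key=lambda c: abs(math.log10(c / cd1)))
            if abs(math.log10(cd2 / cd1)) > 0.5:
                continue
            b1 = float(beta_residual(cd1, csr_lines[k], cT_bar, p))
            b2 = float(beta_residual(cd2, csr_lines[k + 1], cT_bar, p))
            if not (np.isfinite(b1) and np.isfinite(b2)) or b1 * b2 >= 0:
                continue

            def beta_on_alpha(s, cd1=cd1, cd2=cd2, k=k):
                csr = (1 - s) * csr_lines[k] + s * csr_lines[k + 1]
                cd0 = (1 - s) * cd1 + s * cd2
                f = lambda x: float(alpha_residual(float(x), csr, cT_bar, p))
                lo, hi = cd0 * 0.5, cd0 * 2.0
                try:
                    cd = brentq(f, lo, hi, xtol=1e-13)
                except ValueError:
                    cd = cd0
                return float(beta_residual(cd, csr, cT_bar, p)), cd, csr

            s_star = brentq(lambda s: beta_on_alpha(s)[0], 0.0, 1.0,
                            xtol=1e-12)
            _, cd, csr = beta_on_alpha(s_star)
            if not any(abs(cd - c0) < 1e-4 * (1 + c0) and abs(csr - s0) < 1e-3 * (1 + s0)
                       for c0, s0 in found):
                found.append((cd, csr))
    return found


# --------------------------------------------------------------------------
# Closed-form onset
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OnsetResult:
    """Analytic onset of oscillations (no-calsequestrin regime).

    ``ct_star`` — critical load (μM); ``csr_star`` — diastolic free SR
    calcium at onset (μM); ``csr_lower_at_onset`` — SR calcium of the
    resting state just before onset, ``(v/v_sr)·c̄_T*`` (μM);
    ``g_tilde`` — the lumped gain ``g·τ_i/K_o²`` (μM⁻²).
    """

    ct_star: float | None
    csr_star: float | None
    csr_lower_at_onset: float | None
    g_tilde: float
    has_onset: bool


def onset_analytic(p: ModelParams = CONTROL) -> OnsetResult:
    """Evaluate the closed-form onset load and SR levels.

    Requires ``B_SQ = 0`` (the derivation regime) and ``B_b > 0`` (the
    bound cytosolic buffer must dominate).  Reports no onset when the
    closed form lands at a nonpositive load or SR content.
    """
    if p.B_SQ != 0.0:
        raise DomainError("analytic onset is derived for B_SQ = 0")
    if p.B_b <= 0.0:
        raise DomainError("analytic onset requires B_b > 0")
    gt = p.g_tilde
    v = p.v
    ct_star = (math.sqrt(p.v_sr * p.v_i * p.B_b / (v * v * gt * p.K_b))
               - p.v_sr / (4.0 * gt * p.K_b * v))
    csr_star = v * ct_star / (2.0 * p.v_sr) - 1.0 / (8.0 * gt * p.K_b)
    if ct_star <= 0.0 or csr_star <= 0.0:
        return OnsetResult(None, None, None, gt, False)
    return OnsetResult(ct_star, csr_star, (v / p.v_sr) * ct_star, gt, True)


def onset_vs_buffers(p: ModelParams = CONTROL,
                     bb_values=None, kb_values=None) -> pd.DataFrame:
    """Closed-form onset load over ranges of the cytosolic buffer.

    One scan per parameter, the other held at its value in ``p``.
    Returns a tidy frame with columns ``parameter``, ``value``,
    ``ct_star`` (NaN where the closed form reports no onset).
    """
    rows = []
    for name, values in (("B_b", bb_values), ("K_b", kb_values)):
        if values is None:
            continue
        for val in np.asarray(values, dtype=float):
            if val <= 0:
                raise DomainError(f"{name} scan values must be > 0")
            res = onset_analytic(p.replace(**{name: val}))
            rows.append({"parameter": name, "value": val,
                         "ct_star": res.ct_star if res.has_onset else np.nan})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Nullcline-slope stability argument
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SignReport:
    """Signs of the diagonal Jacobian entries and the verdict they allow."""

    f1: float
    g2: float
    det: float
    verdict: str   # "stable" | "unstable" | "saddle" | "indeterminate"


def jacobian_sign_report(fp: FixedPoint, p: ModelParams = CONTROL) -> SignReport:
    """Stability verdict from the signs of f1 = ∂ċ_d/∂c_d, g2 = ∂ċ_sr/∂c_sr.

    Both diagonal entries negative (with positive determinant) force
    stability via the trace criterion; both positive force instability;
    a negative determinant is a saddle.  Mixed signs — the situation at
    intermediate loads where the α-nullcline slope has turned — leave
    the verdict to the eigenvalues ("indeterminate").
    """
    if fp.jacobian.shape != (2, 2):
        raise ValueError("sign report is defined for two-variable variants")
    f1 = float(fp.jacobian[0, 0])
    g2 = float(fp.jacobian[1, 1])
    det = float(np.linalg.det(fp.jacobian))
    if det < 0:
        verdict = "saddle"
    elif f1 < 0 and g2 < 0:
        verdict = "stable"
    elif f1 > 0 and g2 > 0:
        verdict = "unstable"
    else:
        verdict = "indeterminate"
    return SignReport(f1, g2, det, verdict)
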