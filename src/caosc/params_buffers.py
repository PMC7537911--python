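"""Model parameters, calsequestrin rapid-buffer algebra and the
total-calcium conservation closure.

Units are fixed package-wide: concentrations in μM, time in ms, and
compartment volumes as dimensionless fractions of the unit volume
``v = v_i + v_sr + v_d``.  The control parameter of the whole analysis is
the average total calcium content of the cell (or of one calcium release
unit), ``c̄_T`` in μM, conserved because membrane fluxes are absent.

Two algebraic closures live here and are used by every other module:

* the rapid-buffering approximation for calsequestrin (CSQ), which maps
  total SR calcium to free SR calcium through the positive root of a
  quadratic and conserves mass exactly, and
* the conservation closure that recovers cytosolic free calcium ``c_i``
  from ``c̄_T`` and the instantaneous dyadic / SR contents, again a
  quadratic because of a single saturable cytosolic buffer
  (``B_b``, ``K_b``).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger("caosc")

__all__ = [
    "DomainError",
    "InfeasibleStateError",
    "ModelParams",
    "LoadSpec",
    "CONTROL",
    "free_sr_calcium",
    "total_sr_calcium",
    "solve_cytosolic",
    "buffered_cytosolic",
    "reconstruct_load",
    "load_params",
]


class DomainError(ValueError):
    """Input outside the physical domain (negative concentration, ...)."""


class InfeasibleStateError(DomainError):
    """State whose cytosolic calcium budget is negative.

    Raised when ``v·c̄_T − v_d·c_d − v_sr·c_sr_tot < 0``: more calcium is
    claimed by the dyad and the SR than the cell holds in total.  Such a
    state can only be produced by integrator misuse (or a wild trial step)
    and is reported rather than silently clamped.
    """


# --------------------------------------------------------------------------
# Control parameter set.
#
# Volume fractions, the lumped release gain g̃ = g·τ_i/K_o² and the
# remaining rate constants were calibrated once against the printed
# behaviour of the model (fixed-point fold at ≈39 μM, Hopf at ≈66 μM,
# oscillation onset near 50 μM, SR content 2.28 mM / 0.86 mM around onset,
# upper-branch stabilisation of the slow-RyR variants near 54 μM, and a
# ≈1 s noise-driven period at c̄_T = 35 μM with σ = 2e-3).  Provenance of
# each value is tagged in data/control.toml.
# --------------------------------------------------------------------------

_V_SR = 1.0 / 45.6          # SR fraction of the unit volume
_V_D = 0.001                # dyadic cleft fraction (tiny by construction)
_V_I = 1.0 - _V_SR - _V_D   # cytosolic fraction
_G_TILDE = 2.0 / 2240.0     # g·τ_i/K_o², μM⁻²
_TAU_I = 0.008              # dyad → cytosol diffusion time, ms
_K_O = 15.0                 # RyR half-activation of P_o, μM
_G = _G_TILDE * _K_O**2 / _TAU_I          # RyR release conductance, ms⁻¹
_G_UP = 2.0 * _V_D / (_V_I * _TAU_I)      # SERCA maximal rate, μM/ms
_K_M = 0.086                # RyR closing rate, ms⁻¹


@dataclass(frozen=True)
class ModelParams:
    """All constants of the minimal calcium-release-unit model.

    Attributes
    ----------
    g : float
        RyR release conductance (ms⁻¹); the release flux is
        ``J_rel = g·P_o·(c_sr − c_d)``.
    tau_i : float
        Diffusion time from the dyadic cleft to the bulk cytosol (ms).
    g_up : float
        SERCA maximal pump rate (μM/ms), Hill coefficient 2.
    K_s : float
        SERCA half-saturation (μM).
    K_o : float
        Dyadic calcium at which the RyR open probability is 1/2 (μM);
        ``K_o² = k_m/k_p``.
    k_p, k_m : float
        RyR opening coefficient (μM⁻²·ms⁻¹) and closing rate (ms⁻¹).
    v_i, v_sr, v_d : float
        Cytosolic, SR and dyadic volume fractions (dimensionless; they
        need not sum to one, ``v = v_i + v_sr + v_d`` is used throughout).
    B_b, K_b : float
        Concentration and dissociation constant of the generic cytosolic
        buffer (μM).
    B_SQ, K_SQ : float
        Calsequestrin concentration and dissociation constant in the SR
        (μM).  ``B_SQ = 0`` disables the SR buffer.
    """

    g: float = _G
    tau_i: float = _TAU_I
    g_up: float = _G_UP
    K_s: float = 0.187
    K_o: float = _K_O
    k_p: float = _K_M / _K_O**2
    k_m: float = _K_M
    v_i: float = _V_I
    v_sr: float = _V_SR
    v_d: float = _V_D
    B_b: float = 80.0
    K_b: float = 0.5
    B_SQ: float = 0.0
    K_SQ: float = 650.0

    @property
    def v(self) -> float:
        """Unit volume ``v_i + v_sr + v_d``."""
        return self.v_i + self.v_sr + self.v_d

    @property
    def g_tilde(self) -> float:
        """Lumped release gain ``g·τ_i/K_o²`` (μM⁻²)."""
        return self.g * self.tau_i / self.K_o**2

    def validate(self) -> "ModelParams":
        """Check positivity/unit invariants, returning self for chaining."""
        nonneg = ("g", "tau_i", "g_up", "k_p", "k_m", "v_i", "v_sr", "v_d",
                  "B_b", "B_SQ")
        for name in nonneg:
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("K_o", "K_b", "K_s", "K_SQ"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.v <= 0:
            raise DomainError("total volume fraction must be positive")
        return self

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (and validated)."""
        return dataclasses.replace(self, **changes).validate()


#: Control parameter set used by every default.
CONTROL = ModelParams().validate()


@dataclass(frozen=True)
class LoadSpec:
    """Average total cell calcium c̄_T (μM) and the total content it implies.

    The absolute content is ``Q_T = c̄_T·(v_i + v_sr)``; c̄_T is the
    bifurcation parameter used everywhere else.
    """

    cT_bar: float

    def __post_init__(self):
        if self.cT_bar < 0:
            raise DomainError(f"cT_bar must be >= 0, got {self.cT_bar}")

    def q_total(self, p: ModelParams = CONTROL) -> float:
        return self.cT_bar * (p.v_i + p.v_sr)


# --------------------------------------------------------------------------
# Calsequestrin rapid-buffer algebra
# --------------------------------------------------------------------------

def free_sr_calcium(c_sr_tot, p: ModelParams = CONTROL):
    """Free SR calcium from total SR calcium under rapid CSQ buffering.

    Solves ``c_sr_tot = c_sr + B_SQ·c_sr/(K_SQ + c_sr)`` for the
    nonnegative root,

    ``c_sr = ½·[c_sr_tot − K_SQ − B_SQ + √((c_sr_tot − K_SQ − B_SQ)² + 4·c_sr_tot·K_SQ)]``.

    Accepts scalars or arrays.  This formulation conserves mass exactly:
    the forward map :func:`total_sr_calcium` is its algebraic inverse.
    """
    tot = np.asarray(c_sr_tot, dtype=float)
    if np.any(tot < 0):
        raise DomainError("total SR calcium must be >= 0")
    if p.B_SQ == 0.0:
        return c_sr_tot if np.isscalar(c_sr_tot) else tot.copy()
    b = tot - p.K_SQ - p.B_SQ
    out = 0.5 * (b + np.sqrt(b * b + 4.0 * tot * p.K_SQ))
    # guard the tot -> 0 limit against roundoff producing -0.0
    out = np.maximum(out, 0.0)
    return float(out) if np.isscalar(c_sr_tot) else out


def total_sr_calcium(c_sr, p: ModelParams = CONTROL):
    """Total SR calcium (free + CSQ-bound) from free SR calcium."""
    free = np.asarray(c_sr, dtype=float)
    if np.any(free < 0):
        raise DomainError("free SR calcium must be >= 0")
    out = free + p.B_SQ * free / (p.K_SQ + free)
    return float(out) if np.isscalar(c_sr) else out


# --------------------------------------------------------------------------
# Total-calcium conservation closure
# --------------------------------------------------------------------------

def buffered_cytosolic(c_i, p: ModelParams = CONTROL):
    """Free plus buffer-bound cytosolic calcium, ``c_i + B_b·c_i/(K_b+c_i)``."""
    ci = np.asarray(c_i, dtype=float)
    out = ci + p.B_b * ci / (p.K_b + ci)
    return float(out) if np.isscalar(c_i) else out


def solve_cytosolic(cT_bar: float, c_d: float, c_sr_tot: float,
                    p: ModelParams = CONTROL, *, budget_tol: float = 1e-9) -> float:
    """Cytosolic free calcium from the total-calcium conservation law.

    Given the load c̄_T and the instantaneous dyadic and (total) SR
    contents, the cytosolic budget is

    ``b = (v·c̄_T − v_d·c_d − v_sr·c_sr_tot)/v_i``

    and ``c_i`` is the nonnegative root of
    ``c_i² + (K_b + B_b − b)·c_i − K_b·b = 0``.

    Raises
    ------
    InfeasibleStateError
        If the budget is negative beyond ``budget_tol`` (relative to c̄_T);
        a tiny negative budget from roundoff is clamped to zero.
    """
    budget = p.v * cT_bar - p.v_d * c_d - p.v_sr * c_sr_tot
    if budget < 0.0:
        if budget < -budget_tol * max(1.0, p.v * cT_bar):
            raise InfeasibleStateError(
                f"negative cytosolic calcium budget {budget:.3e} uM at "
                f"cT_bar={cT_bar}, c_d={c_d}, c_sr_tot={c_sr_tot}")
        budget = 0.0
    b = budget / p.v_i
    q = p.K_b + p.B_b - b
    c_i = 0.5 * (-q + math.sqrt(q * q + 4.0 * p.K_b * b))
    # the "+" branch is the nonnegative root; verify rather than trust it
    if c_i < 0.0:
        c_i = 0.0
    return c_i


def reconstruct_load(c_i: float, c_d: float, c_sr_tot: float,
                     p: ModelParams = CONTROL) -> float:
    """Recompute c̄_T from a full state (the mass-conservation identity)."""
    return (p.v_i * buffered_cytosolic(c_i, p) + p.v_d * c_d
            + p.v_sr * c_sr_tot) / p.v


# --------------------------------------------------------------------------
# Parameter files
# --------------------------------------------------------------------------

def load_params(path: str | Path | None = None) -> tuple[ModelParams, dict]:
    """Load a parameter file, validating units/positivity.

    The file is TOML with a ``[params]`` table (field names as in
    :class:`ModelParams`) and an optional ``[provenance]`` table tagging
    each value as PAPER or DERIVED; tags are logged so that analysis runs
    are auditable.  With ``path=None`` the packaged control file is read.

    Returns ``(params, provenance)``.
    """
    import tomllib

    if path is None:
        from importlib import resources
        text = (resources.files("caosc") / "data" / "control.toml").read_text()
        doc = tomllib.loads(text)
        origin = "caosc/data/control.toml"
    else:
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        origin = str(path)

    fields = {f.name for f in dataclasses.fields(ModelParams)}
    values = doc.get("params", {})
    unknown = set(values) - fields
    if unknown:
        raise DomainError(f"unknown parameter(s) in {origin}: {sorted(unknown)}")
    params = ModelParams(**{k: float(v) for k, v in values.items()}).validate()
    provenance = dict(doc.get("provenance", {}))
    for name in sorted(values):
        logger.info("param %s = %g [%s] (%s)", name, values[name],
                    provenance.get(name, "UNTAGGED"), origin)
    return params, provenance
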