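"""Kinetic ODE models of XlnR-regulon transcription.

Two antagonistic Hill factors drive transcription of each target gene
``i`` of the xylanolytic transactivator XlnR in *Aspergillus niger*:

* activation by the XlnR·D-xylose complex ``X`` through
  ``psi_xyl = X^h1 / (K_i1^h1 + X^h1)``, and
* repression by the carbon-catabolite repressor CreA through
  ``psi_crea = K_i2^h2 / (K_i2^h2 + x_CreA^h2)``.

The state equations of the antagonistic-Hill model are

    dX/dt      = K_on * x_xlnR * u(t) - K_off * X
    dx_CreA/dt = k1 * u(t) - k2 * x_CreA
    dx_i/dt    = k_is * psi_xyl(X) * psi_crea(x_CreA) - k_id * x_i

with ``u(t)`` the extracellular D-xylose concentration (mM) and
``x_xlnR`` treated as a constant input because *xlnR* itself is
constitutively transcribed (normalized levels stay near 1–2 units).
A legacy single-Hill-per-factor model with a dynamic *xlnR* state is
kept for comparison.

Time is in hours; expression is in reference-gene-normalized arbitrary
units; ``X`` and ``x_CreA`` are in arbitrary concentration units whose
scale is absorbed by the half-saturation thresholds ``K_i1``/``K_i2``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "KineticParameters",
    "LegacyParameters",
    "ModelState",
    "InputSignal",
    "IntegrationError",
    "psi_xyl",
    "psi_crea",
    "rhs_new",
    "rhs_legacy",
    "simulate",
    "steady_state",
]

#: shared-parameter block (K_on, K_off, k1, k2) averages printed for the
#: wild-type fits; used throughout as a realistic default scale.
THETA1_DEFAULT = {"K_on": 14.957, "K_off": 75.541, "k1": 21.455, "k2": 20.065}


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the offending parameters."""

    def __init__(self, message: str, params=None):
        super().__init__(message)
        self.params = params


def _require_positive(name: str, value: float) -> None:
    if not (value > 0) or not math.isfinite(value):
        raise ValueError(f"parameter {name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class KineticParameters:
    """Full parameter vector theta for one target gene.

    ``k_is`` and ``K_i2`` are strain-specific (wild type Wt vs. the CreA
    partial loss-of-function mutant Mt); the remaining entries are shared.
    ``x_xlnR_const`` is the constant normalized *xlnR* level entering the
    complex-formation term.
    """

    K_on: float = THETA1_DEFAULT["K_on"]
    K_off: float = THETA1_DEFAULT["K_off"]
    k1: float = THETA1_DEFAULT["k1"]
    k2: float = THETA1_DEFAULT["k2"]
    k_is_Wt: float = 10.0
    k_is_Mt: float = 10.0
    K_i1: float = 0.1
    K_i2_Wt: float = 25.0
    K_i2_Mt: float = 25.0
    k_id: float = 1.0
    h1: float = 2
    h2: float = 4
    x_xlnR_const: float = 1.0

    def __post_init__(self):
        for f in fields(self):
            _require_positive(f.name, getattr(self, f.name))
        if self.h1 < 1 or self.h2 < 1:
            raise ValueError("Hill coefficients h1, h2 must be >= 1")

    def for_strain(self, strain: str) -> tuple[float, float]:
        """Return the strain-specific pair ``(k_is, K_i2)``."""
        if strain == "Wt":
            return self.k_is_Wt, self.K_i2_Wt
        if strain == "Mt":
            return self.k_is_Mt, self.K_i2_Mt
        raise ValueError(f"unknown strain {strain!r}; expected 'Wt' or 'Mt'")

    def replace(self, **updates) -> "KineticParameters":
        return replace(self, **updates)

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParameters":
        return cls(**{k: float(v) for k, v in d.items()})

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "KineticParameters":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class LegacyParameters:
    """Parameters of the earlier regulon model with a dynamic xlnR state.

    dx_xlnR/dt = b*u - k_d*x_xlnR;
    dx_i/dt = k_is * (k_i1*x_xlnR)^h1/(1+(k_i1*x_xlnR)^h1)
                   * 1/(1+(k_i2*u)^h2) - k_id*x_i.
    ``k_i1`` and ``k_i2`` are inverse Hill constants; repression is driven
    directly by the stimulus u. The original formulation used h1 = h2 = 1.
    """

    b: float = 1.0
    k_d: float = 1.0
    k_is: float = 10.0
    k_i1: float = 1.0
    k_i2: float = 1.0
    k_id: float = 1.0
    h1: float = 1
    h2: float = 1

    def __post_init__(self):
        for f in fields(self):
            if f.name in ("k_i2",):  # k_i2 = 0 switches repression off
                v = getattr(self, f.name)
                if v < 0 or not math.isfinite(v):
                    raise ValueError(f"{f.name} must be >= 0")
            else:
                _require_positive(f.name, getattr(self, f.name))

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}


class ModelState(NamedTuple):
    """State of the antagonistic-Hill model.

    ``X`` — XlnR·xylose complex; ``x_CreA`` — repressor level; ``x_i`` —
    target transcript. The constant xlnR input lives on the parameter set.
    """

    X: float
    x_CreA: float
    x_i: float


@dataclass(frozen=True)
class InputSignal:
    """D-xylose concentration u(t), in mM, over time in hours.

    kinds
    -----
    ``constant``
        u(t) = u0.
    ``exp``
        u(t) = u0 * exp(-decay_rate * t); mimics consumption in the
        bioreactor (1 mM is nearly exhausted within 5 h; 50 mM only
        drops to about 38 mM).
    ``interp``
        piecewise-linear through measured (time, concentration) knots,
        held constant beyond the last knot.
    """

    kind: str = "constant"
    u0: float = 1.0
    knots: tuple[tuple[float, float], ...] | None = None
    decay_rate: float = 0.0

    def __post_init__(self):
        if self.kind not in ("constant", "exp", "interp"):
            raise ValueError(f"unknown InputSignal kind {self.kind!r}")
        if self.u0 < 0 or not math.isfinite(self.u0):
            raise ValueError("u0 must be finite and >= 0")
        if self.kind == "exp" and self.decay_rate < 0:
            raise ValueError("decay_rate must be >= 0")
        if self.kind == "interp":
            if not self.knots or len(self.knots) < 2:
                raise ValueError("interp signal needs at least two knots")
            t, c = zip(*self.knots)
            if any(b <= a for a, b in zip(t, t[1:])):
                raise ValueError("knot times must be strictly increasing")
            if t[0] != 0:
                raise ValueError("first knot must be at t = 0")
            if any(ci < 0 or ci > self.u0 for ci in c):
                raise ValueError("knot concentrations must lie in [0, u0]")
            if any(b > a for a, b in zip(c, c[1:])):
                raise ValueError("depletion knots must be nonincreasing")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("InputSignal evaluated at negative time")
        if self.kind == "constant":
            out = np.full_like(t, self.u0)
        elif self.kind == "exp":
            out = self.u0 * np.exp(-self.decay_rate * t)
        else:
            kt, kc = map(np.asarray, zip(*self.knots))
            out = np.interp(t, kt, kc)
        return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Hill factors
# ---------------------------------------------------------------------------

def psi_xyl(X, K_i1: float, h1: float):
    """Activation Hill factor X^h1 / (K_i1^h1 + X^h1), in [0, 1].

    Half-saturates at ``X = K_i1``; tends to 1 as the XlnR·xylose complex
    accumulates.
    """
    if K_i1 <= 0:
        raise ValueError("K_i1 must be > 0")
    if h1 < 1:
        raise ValueError("h1 must be >= 1")
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("complex concentration X must be >= 0")
    r = (X / K_i1) ** h1
    out = r / (1.0 + r)
    return out if out.ndim else float(out)


def psi_crea(x_crea, K_i2: float, h2: float):
    """Repression Hill factor K_i2^h2 / (K_i2^h2 + x_CreA^h2), in [0, 1].

    Equals 1/2 at the switching level ``x_CreA = K_i2`` and approaches 1
    when CreA is absent (the full loss-of-function limit).
    """
    if K_i2 <= 0:
        raise ValueError("K_i2 must be > 0")
    if h2 < 1:
        raise ValueError("h2 must be >= 1")
    x = np.asarray(x_crea, dtype=float)
    if np.any(x < 0):
        raise ValueError("repressor concentration must be >= 0")
    r = (x / K_i2) ** h2
    out = 1.0 / (1.0 + r)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Right-hand sides
# ---------------------------------------------------------------------------

def rhs_new(
    state: Sequence[float],
    t: float,
    params: KineticParameters,
    u: InputSignal,
    strain: str = "Wt",
    knockout: bool = False,
) -> tuple[float, float, float]:
    """Time derivative (dX, dx_CreA, dx_i) of the antagonistic-Hill model.

    ``knockout=True`` forces x_CreA to 0 (full CreA loss of function), so
    the repression factor is identically 1.
    """
    X, x_crea, x_i = state
    if X < 0 or x_crea < 0 or x_i < 0:
        raise ValueError("state components must be nonnegative")
    k_is, K_i2 = params.for_strain(strain)
    ut = float(u(t))
    dX = params.K_on * params.x_xlnR_const * ut - params.K_off * X
    if knockout:
        dcrea = 0.0
        rep = 1.0
    else:
        dcrea = params.k1 * ut - params.k2 * x_crea
        rep = psi_crea(x_crea, K_i2, params.h2)
    dx_i = k_is * psi_xyl(X, params.K_i1, params.h1) * rep - params.k_id * x_i
    return dX, dcrea, dx_i


def rhs_legacy(
    state: Sequence[float],
    t: float,
    params: LegacyParameters,
    u: InputSignal,
) -> tuple[float, float]:
    """Time derivative (dx_xlnR, dx_i) of the legacy model."""
    x_xlnr, x_i = state
    if x_xlnr < 0 or x_i < 0:
        raise ValueError("state components must be nonnegative")
    ut = float(u(t))
    dx_xlnr = params.b * ut - params.k_d * x_xlnr
    a = (params.k_i1 * x_xlnr) ** params.h1
    act = a / (1.0 + a)
    rep = 1.0 / (1.0 + (params.k_i2 * ut) ** params.h2)
    dx_i = params.k_is * act * rep - params.k_id * x_i
    return dx_xlnr, dx_i


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate(
    params,
    u: InputSignal,
    t_grid: Iterable[float],
    init: Sequence[float] | None = None,
    model: str = "new",
    strain: str = "Wt",
    knockout: bool = False,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> pd.DataFrame:
    """Integrate a model over ``t_grid`` and return a tidy trajectory table.

    Columns are ``time_h, X, x_CreA, x_i, u`` for the antagonistic-Hill
    model and ``time_h, x_xlnR, x_i, u`` for the legacy one. Values within
    ``atol`` of zero are clipped to exactly 0 so nonnegativity survives
    solver round-off.
    """
    t = np.asarray(list(t_grid), dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0) or t[0] != 0:
        raise ValueError("t_grid must be strictly increasing and start at 0")

    if model == "new":
        if not isinstance(params, KineticParameters):
            raise TypeError("new model requires KineticParameters")
        y0 = np.zeros(3) if init is None else np.asarray(init, dtype=float)

        def f(ti, y):
            return rhs_new(np.maximum(y, 0.0), ti, params, u, strain, knockout)

        columns = ["X", "x_CreA", "x_i"]
    elif model == "legacy":
        if not isinstance(params, LegacyParameters):
            raise TypeError("legacy model requires LegacyParameters")
        y0 = np.zeros(2) if init is None else np.asarray(init, dtype=float)

        def f(ti, y):
            return rhs_legacy(np.maximum(y, 0.0), ti, params, u)

        columns = ["x_xlnR", "x_i"]
    else:
        raise ValueError(f"unknown model {model!r}")

    if np.any(y0 < 0):
        raise ValueError("initial condition must be nonnegative")

    sol = solve_ivp(
        f, (t[0], t[-1]), y0, t_eval=t, method="LSODA", rtol=rtol, atol=atol
    )
    if not sol.success:
        raise IntegrationError(
            f"ODE integration failed: {sol.message}", params=params
        )
    y = sol.y.T.copy()
    y[np.abs(y) < atol] = 0.0
    if np.any(y < -atol):
        raise IntegrationError("trajectory went negative beyond tolerance", params)
    y = np.maximum(y, 0.0)
    out = pd.DataFrame(y, columns=columns)
    out.insert(0, "time_h", t)
    out["u"] = np.asarray(u(t), dtype=float)
    return out


def steady_state(
    params: KineticParameters,
    u_const: float,
    strain: str = "Wt",
    knockout: bool = False,
) -> ModelState:
    """Closed-form fixed point of the antagonistic-Hill model at constant u.

    X* = K_on*x_xlnR*u/K_off, x_CreA* = k1*u/k2 and
    x_i* = k_is*psi_xyl(X*)*psi_crea(x_CreA*)/k_id.
    """
    if u_const < 0:
        raise ValueError("u_const must be >= 0")
    k_is, K_i2 = params.for_strain(strain)
    X = params.K_on * params.x_xlnR_const * u_const / params.K_off
    x_crea = 0.0 if knockout else params.k1 * u_const / params.k2
    if u_const == 0:
        return ModelState(0.0, 0.0, 0.0)
    x_i = (
        k_is
        * psi_xyl(X, params.K_i1, params.h1)
        * psi_crea(x_crea, K_i2, params.h2)
        / params.k_id
    )
    return ModelState(X, x_crea, x_i)
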