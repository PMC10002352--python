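"""Discretized Lotka-Volterra estimation for a coupled index pair.

The continuous model couples a pollution-control effectiveness series I(t)
and an HDI national-share series H(t):

    dI/dt = R_I I (1 - I/K_I + alpha H/K_I)
    dH/dt = R_H H (1 - H/K_H + beta  I/K_H)

In general form (per equation):  dX/dt = a X + b X^2 + c X Y, which is
discretized on annual data with midpoint values

    X(t+1) - X(t) = a m + b m^2 + c m n,
    m = [X(t)+X(t+1)]/2,  n = [Y(t)+Y(t+1)]/2,

and estimated per equation by ordinary least squares.  The carrying
capacities and competition coefficients are recovered from (a, b, c); two
conventions for that back-map are supported (see ``derive_lv_coefficients``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .errors import (
    AlignmentError,
    DegenerateDynamicsError,
    SingularFitError,
    UnderdeterminedSystemError,
)

Convention = Literal["consistent", "published-literal"]

#: Condition number above which a 3-column design is declared unidentifiable.
CONDITION_LIMIT = 1e10
#: Denominator magnitude below which derived dynamics are declared degenerate.
DENOM_TOL = 1e-12


@dataclass(frozen=True)
class CoupledSeries:
    """One entity-window pair of aligned annual series."""

    entity: str
    window: tuple[int, int]
    pollution: tuple[float, ...]
    hdi_share: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.pollution) != len(self.hdi_share):
            raise AlignmentError(
                f"{self.entity}: series lengths differ "
                f"({len(self.pollution)} vs {len(self.hdi_share)})"
            )
        if len(self.pollution) < 4:
            raise UnderdeterminedSystemError(
                f"{self.entity} {self.window}: need >= 4 points "
                f"(3 increments), got {len(self.pollution)}"
            )
        if min(self.pollution) <= 0 or min(self.hdi_share) <= 0:
            raise DegenerateDynamicsError(
                f"{self.entity} {self.window}: series must be strictly positive"
            )


@dataclass(frozen=True)
class DesignSystem:
    """First-difference response and (m, m^2, m*n) midpoint predictors."""

    response: np.ndarray  # shape (T-1,)
    predictors: np.ndarray  # shape (T-1, 3)


@dataclass(frozen=True)
class LVFit:
    """Estimated general-form coefficients and derived LV quantities."""

    a_i: float
    b_i: float
    c_i: float
    a_h: float
    b_h: float
    c_h: float
    r_i: float
    r_h: float
    k_i: float
    k_h: float
    alpha: float
    beta: float
    convention: Convention
    residual_norms: tuple[float, float] = (float("nan"), float("nan"))


def build_lv_design(target: Sequence[float], partner: Sequence[float]) -> DesignSystem:
    """Assemble the discretized least-squares system for one equation.

    ``target`` plays X (the equation being fit), ``partner`` plays Y.
    """
    x = np.asarray(target, dtype=float)
    y = np.asarray(partner, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AlignmentError(
            f"target and partner must be equal-length 1-d series, "
            f"got {x.shape} vs {y.shape}"
        )
    if len(x) < 2:
        raise AlignmentError("need at least two time points to difference")
    m = (x[:-1] + x[1:]) / 2.0
    n = (y[:-1] + y[1:]) / 2.0
    response = np.diff(x)
    predictors = np.column_stack([m, m**2, m * n])
    return DesignSystem(response=response, predictors=predictors)


def fit_lv_equation(d: DesignSystem, label: str = "") -> tuple[float, float, float]:
    """Ordinary least squares for (a, b, c) in one discretized equation.

    Equivalent to the normal-equations solve (B'B)^{-1} B'Y, but computed
    through an SVD-based least-squares routine for numerical stability.
    """
    B, Y = d.predictors, d.response
    if B.shape[0] < 3:
        raise UnderdeterminedSystemError(
            f"{label or 'system'}: {B.shape[0]} increments for 3 coefficients"
        )
    cond = np.linalg.cond(B)
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        raise SingularFitError(
            f"{label or 'system'}: design condition number {cond:.3g} exceeds "
            f"{CONDITION_LIMIT:.0e} (collinear midpoint predictors)"
        )
    coef, *_ = np.linalg.lstsq(B, Y, rcond=None)
    return float(coef[0]), float(coef[1]), float(coef[2])


def derive_lv_coefficients(
    i_coeffs: tuple[float, float, float],
    h_coeffs: tuple[float, float, float],
    convention: Convention = "consistent",
    residual_norms: tuple[float, float] = (float("nan"), float("nan")),
) -> LVFit:
    """Back out (R, K, alpha, beta) from general-form coefficients.

    ``consistent`` inverts the expansion of the logistic form exactly for
    both equations: K = -a/b and cross-coefficient = -c/b.  The
    ``published-literal`` mode instead uses K_H = -a_H/c_H and beta = -b_H/c_H
    for the H equation, a published variant kept for comparison; the two
    agree only when b_H = c_H.
    """
    a_i, b_i, c_i = i_coeffs
    a_h, b_h, c_h = h_coeffs
    if abs(b_i) < DENOM_TOL:
        raise DegenerateDynamicsError(f"b_I={b_i}: carrying capacity undefined")
    k_i = -a_i / b_i
    alpha = -c_i / b_i
    if convention == "consistent":
        if abs(b_h) < DENOM_TOL:
            raise DegenerateDynamicsError(f"b_H={b_h}: carrying capacity undefined")
        k_h = -a_h / b_h
        beta = -c_h / b_h
    elif convention == "published-literal":
        if abs(c_h) < DENOM_TOL:
            raise DegenerateDynamicsError(f"c_H={c_h}: carrying capacity undefined")
        k_h = -a_h / c_h
        beta = -b_h / c_h
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return LVFit(
        a_i=a_i, b_i=b_i, c_i=c_i, a_h=a_h, b_h=b_h, c_h=c_h,
        r_i=a_i, r_h=a_h, k_i=k_i, k_h=k_h, alpha=alpha, beta=beta,
        convention=convention, residual_norms=residual_norms,
    )


def fit_lv_system(s: CoupledSeries, convention: Convention = "consistent") -> LVFit:
    """Fit both coupled equations for one entity-window pair.

    The pollution equation takes the effectiveness series as target and the
    HDI share as partner; the HDI equation swaps the roles.  Each equation
    is estimated separately by least squares, then the LV quantities are
    derived under the requested convention.
    """
    tag_i = f"{s.entity} {s.window} I-equation"
    tag_h = f"{s.entity} {s.window} H-equation"
    d_i = build_lv_design(s.pollution, s.hdi_share)
    d_h = build_lv_design(s.hdi_share, s.pollution)
    ci = fit_lv_equation(d_i, label=tag_i)
    ch = fit_lv_equation(d_h, label=tag_h)
    res_i = float(np.linalg.norm(d_i.response - d_i.predictors @ np.array(ci)))
    res_h = float(np.linalg.norm(d_h.response - d_h.predictors @ np.array(ch)))
    return derive_lv_coefficients(ci, ch, convention, (res_i, res_h))


def general_form_coefficients(fit: LVFit) -> tuple[tuple[float, float, float],
                                                   tuple[float, float, float]]:
    """Re-expand (r, k, alpha/beta) to the general-form (a, b, c) pairs.

    Under the ``consistent`` convention this is the exact inverse of
    :func:`derive_lv_coefficients`; useful for round-trip checks.
    """
    if fit.convention != "consistent":
        raise ValueError("re-expansion is defined for the consistent convention")
    b_i = -fit.r_i / fit.k_i
    b_h = -fit.r_h / fit.k_h
    return (
        (fit.r_i, b_i, -fit.alpha * b_i),
        (fit.r_h, b_h, -fit.beta * b_h),
    )
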