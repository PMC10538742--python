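"""Grey forecasting models for short positive count series.

Grey models tame very short series (n >= 4) by first applying the
accumulated generating operation (AGO), ``x1(k) = sum_{p<=k} x0(p)``, which
turns a fluctuating positive series into a smooth, near-exponential one,
and then fitting a first-order linear differential equation to the
accumulated series.  Fitted and forecast values on the original scale are
recovered by first differences (inverse AGO).

Three models are provided:

``GM11``
    the classical single-series grey model ``dx1/dt + a x1 = b``.

``MGM``
    the multivariate grey model used for incidence-plus-factors panels: a
    single structural (whitening) equation for the dependent series driven
    by the accumulated factor series,
    ``x1^(0)(k) + a z1(k) = sum_i b_i xi^(1)(k)``,
    with ``z1`` the adjacent-mean background of the dependent AGO.  Fitted
    values come from the classical approximate time response, so the model
    genuinely smooths the data rather than interpolating it.

``MGMSystem``
    the fully coupled form ``dX1/dt = A X1 + B`` in which every series gets
    its own equation; its continuous solution is evaluated through an
    augmented matrix exponential, never an explicit matrix inverse.

All estimations use a rank-revealing least-squares solve (SVD); on a
rank-deficient design the minimum-norm solution is used and a warning is
emitted, because with very short panels and many factors the normal
equations can be singular.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm, lstsq

from .panel import SeriesPanel

__all__ = [
    "DegenerateModelError",
    "EstimationWarning",
    "AccumulatedSequences",
    "ago",
    "inverse_ago",
    "round_counts",
    "affine_ode_solution",
    "GM11",
    "GM11Results",
    "MGM",
    "MGMResults",
    "MGMSystem",
    "MGMSystemResults",
    "fit_gm11",
    "fit_mgm",
]


class DegenerateModelError(ValueError):
    """The grey model collapses (e.g. development coefficient ~ 0)."""


class EstimationWarning(UserWarning):
    """Emitted when the least-squares design is rank deficient."""


def round_counts(values: np.ndarray | Sequence[float]) -> np.ndarray:
    """Round to whole counts, halves away from zero (not banker's)."""
    arr = np.asarray(values, dtype=float)
    return np.sign(arr) * np.floor(np.abs(arr) + 0.5)


@dataclass(frozen=True)
class AccumulatedSequences:
    """Original series, its AGO, and the adjacent-mean background.

    ``background[j]`` corresponds to time index ``k = j + 2`` (the mean of
    consecutive AGO values is defined from the second point on).
    """

    original: np.ndarray
    ago: np.ndarray
    background: np.ndarray


def ago(seq: Sequence[float]) -> AccumulatedSequences:
    """First-order accumulated generation with its background sequence."""
    x0 = np.asarray(seq, dtype=float)
    if x0.size == 0:
        raise ValueError("cannot accumulate an empty sequence")
    x1 = np.cumsum(x0)
    z = 0.5 * (x1[1:] + x1[:-1])
    return AccumulatedSequences(original=x0, ago=x1, background=z)


def inverse_ago(x1: np.ndarray) -> np.ndarray:
    """First differences with the first element kept (exact AGO inverse)."""
    x1 = np.asarray(x1, dtype=float)
    return np.concatenate([x1[:1], np.diff(x1)])


def affine_ode_solution(
    A: np.ndarray, t: float, v: np.ndarray, B: np.ndarray
) -> np.ndarray:
    """State of ``dx/dt = A x + B`` at time ``t`` from ``x(0) = v``.

    Uses the augmented matrix exponential ``expm([[A, B], [0, 0]] t)`` so a
    singular ``A`` needs no special-casing; for invertible ``A`` the result
    equals ``e^{At} v + A^{-1}(e^{At} - I) B``.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    v = np.asarray(v, dtype=float).ravel()
    B = np.asarray(B, dtype=float).ravel()
    m = A.shape[0]
    if A.shape != (m, m) or v.size != m or B.size != m:
        raise ValueError(
            f"dimension mismatch: A {A.shape}, v {v.shape}, B {B.shape}"
        )
    M = np.zeros((m + 1, m + 1))
    M[:m, :m] = A
    M[:m, m] = B
    aug = expm(M * float(t)) @ np.append(v, 1.0)
    return aug[:m]


def _lstsq_checked(P: np.ndarray, q: np.ndarray, what: str) -> np.ndarray:
    sol, _, rank, _ = lstsq(P, q)
    if rank < P.shape[1]:
        warnings.warn(
            f"{what}: design matrix is rank deficient "
            f"(rank {rank} < {P.shape[1]} parameters); "
            "using the minimum-norm least-squares solution",
            EstimationWarning,
            stacklevel=3,
        )
    return sol


# ---------------------------------------------------------------------------
# GM(1,1)
# ---------------------------------------------------------------------------


class GM11:
    """Classical single-series grey model GM(1,1).

    The whitening equation ``dx1/dt + a x1 = b`` is estimated by least
    squares on ``x0(k) = -a z(k) + b`` over ``k = 2..n`` and solved in
    closed form; the first fitted value is anchored to the first actual.
    """

    def __init__(self, endog: Sequence[float]) -> None:
        x0 = np.asarray(endog, dtype=float)
        if x0.size < 4:
            raise ValueError(f"GM(1,1) needs at least 4 points, got {x0.size}")
        if np.any(x0 <= 0):
            raise ValueError("GM(1,1) requires a strictly positive series")
        self.endog = x0

    def fit(self) -> "GM11Results":
        acc = ago(self.endog)
        P = np.column_stack([-acc.background, np.ones(acc.background.size)])
        a, b = _lstsq_checked(P, self.endog[1:], "GM(1,1)")
        if abs(a) < 1e-12:
            raise DegenerateModelError(
                "development coefficient a is numerically zero "
                "(constant-trend input); GM(1,1) is degenerate"
            )
        return GM11Results(model=self, a=float(a), b=float(b))


@dataclass(frozen=True)
class GM11Results:
    """Estimated GM(1,1) with fitted values and forecasts."""

    model: GM11
    a: float
    b: float

    @property
    def n(self) -> int:
        return self.model.endog.size

    def _ago_at(self, t: np.ndarray) -> np.ndarray:
        x0 = self.model.endog
        return (x0[0] - self.b / self.a) * np.exp(-self.a * (t - 1.0)) + self.b / self.a

    @property
    def fittedvalues(self) -> np.ndarray:
        """Original-scale fitted series; first value equals the first actual."""
        return inverse_ago(self._ago_at(np.arange(1, self.n + 1, dtype=float)))

    @property
    def fitted_counts(self) -> np.ndarray:
        return round_counts(self.fittedvalues)

    def forecast(self, horizon: int) -> np.ndarray:
        """Original-scale forecasts for ``t = n+1 .. n+horizon``."""
        if horizon < 1:
            raise ValueError(f"horizon must be >= 1, got {horizon}")
        t = np.arange(self.n, self.n + horizon + 1, dtype=float)
        return np.diff(self._ago_at(t + 0.0))

    def summary(self) -> str:
        return (
            "GM(1,1) grey model\n"
            f"  development coefficient a = {self.a:.6g}\n"
            f"  grey input b = {self.b:.6g}\n"
            f"  n = {self.n}, fitted = {np.array2string(self.fittedvalues, precision=1)}"
        )


def fit_gm11(seq: Sequence[float]) -> GM11Results:
    return GM11(seq).fit()


# ---------------------------------------------------------------------------
# MGM(1,n): multivariate grey model with factor drivers
# ---------------------------------------------------------------------------


class MGM:
    """Multivariate grey model MGM(1,n) for a dependent series with factors.

    ``n`` counts the factor series.  The dependent AGO obeys the whitening
    equation ``dx1^(1)/dt + a x1^(1) = sum_i b_i xi^(1)(t)``; the parameters
    ``(a, b_1..b_n)`` are estimated by least squares on

        ``x1^(0)(k) = -a z1(k) + sum_i b_i xi^(1)(k)``, k = 2..n_obs,

    and fitted values use the classical approximate time response

        ``x1hat^(1)(k) = (x1^(0)(1) - D(k)/a) e^{-a(k-1)} + D(k)/a``

    with drive ``D(k) = sum_i b_i xi^(1)(k)``.  Out-of-sample forecasts
    extend each factor's AGO with its own GM(1,1).
    """

    def __init__(
        self,
        endog: Sequence[float],
        exog: np.ndarray | Sequence[Sequence[float]],
        factor_ids: Sequence[str] | None = None,
        label: str | None = None,
    ) -> None:
        self.endog = np.asarray(endog, dtype=float)
        exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if exog.shape[1] != self.endog.size and exog.shape[0] == self.endog.size:
            exog = exog.T  # accept (n_obs, n_factors) layout too
        if exog.shape[1] != self.endog.size:
            raise ValueError(
                f"factor series length {exog.shape[1]} != dependent length "
                f"{self.endog.size}"
            )
        if self.endog.size < 4:
            raise ValueError(f"MGM needs at least 4 points, got {self.endog.size}")
        if np.any(self.endog <= 0):
            raise ValueError("MGM requires a strictly positive dependent series")
        self.exog = exog
        self.factor_ids = (
            tuple(factor_ids)
            if factor_ids is not None
            else tuple(f"F{i + 1}" for i in range(exog.shape[0]))
        )
        if len(self.factor_ids) != exog.shape[0]:
            raise ValueError("factor_ids length does not match exog rows")
        self.label = label or f"MGM(1,{exog.shape[0]})"

    @classmethod
    def from_panel(
        cls, panel: SeriesPanel, factor_ids: Sequence[str]
    ) -> "MGM":
        exog = np.vstack([panel.factor_array(f) for f in factor_ids])
        return cls(panel.dependent_array, exog, factor_ids=tuple(factor_ids))

    def fit(self) -> "MGMResults":
        acc = ago(self.endog)
        factor_ago = np.cumsum(self.exog, axis=1)
        P = np.column_stack([-acc.background, factor_ago[:, 1:].T])
        coef = _lstsq_checked(P, self.endog[1:], self.label)
        a = float(coef[0])
        if abs(a) < 1e-12:
            raise DegenerateModelError(
                f"{self.label}: development coefficient a is numerically zero"
            )
        return MGMResults(
            model=self, a=a, b=np.asarray(coef[1:], dtype=float),
            _factor_ago=factor_ago,
        )


@dataclass(frozen=True)
class MGMResults:
    """Estimated MGM(1,n) with fitted values and factor-driven forecasts."""

    model: MGM
    a: float
    b: np.ndarray
    _factor_ago: np.ndarray

    @property
    def label(self) -> str:
        return self.model.label

    @property
    def n(self) -> int:
        return self.model.endog.size

    @property
    def params(self) -> pd.Series:
        names = ["a"] + [f"b[{f}]" for f in self.model.factor_ids]
        return pd.Series(np.concatenate([[self.a], self.b]), index=names)

    def _response(self, drive: np.ndarray, t: np.ndarray) -> np.ndarray:
        x0 = self.model.endog
        return (x0[0] - drive / self.a) * np.exp(-self.a * (t - 1.0)) + drive / self.a

    @property
    def fittedvalues(self) -> np.ndarray:
        drive = self.b @ self._factor_ago
        t = np.arange(1, self.n + 1, dtype=float)
        return inverse_ago(self._response(drive, t))

    @property
    def fitted_counts(self) -> np.ndarray:
        """Fitted series rounded to whole counts (half away from zero)."""
        return round_counts(self.fittedvalues)

    def forecast(self, horizon: int) -> np.ndarray:
        """Dependent-series forecasts for ``t = n+1 .. n+horizon``.

        Each factor's original series is extended with its own GM(1,1) so
        the accumulated drivers are defined beyond the sample.
        """
        if horizon < 1:
            raise ValueError(f"horizon must be >= 1, got {horizon}")
        ext = []
        for row in self.model.exog:
            fc = GM11(row).fit().forecast(horizon)
            ext.append(np.concatenate([row, fc]))
        factor_ago = np.cumsum(np.vstack(ext), axis=1)
        drive = self.b @ factor_ago
        t = np.arange(1, self.n + horizon + 1, dtype=float)
        full = self._response(drive, t)
        return np.diff(full)[self.n - 1 :]

    def summary(self) -> str:
        par = self.params.map(lambda v: f"{v:.6g}")
        return (
            f"{self.label} multivariate grey model "
            f"(factors: {', '.join(self.model.factor_ids)})\n"
            + par.to_string()
            + f"\n  fitted = {np.array2string(self.fittedvalues, precision=1)}"
        )


def fit_mgm(panel: SeriesPanel, factor_ids: Sequence[str]) -> MGMResults:
    """Fit the multivariate grey model on a panel with the given factors."""
    return MGM.from_panel(panel, factor_ids).fit()


# ---------------------------------------------------------------------------
# Coupled first-order system dX1/dt = A X1 + B
# ---------------------------------------------------------------------------


class MGMSystem:
    """Coupled multivariate grey system: one equation per series.

    Every variable (dependent first, then factors) receives its own
    structural equation; row ``i`` of ``[A | B]`` is estimated by least
    squares of ``xi^(0)(k)`` on the background values of *all* AGO series
    plus a constant.  The continuous solution is evaluated with the
    time-shifted augmented exponential ``exp([[A, B],[0, 0]] (t-1))`` so the
    initial condition ``X1hat(1) = X1(1)`` holds exactly.

    Note: on a panel with ``n_obs - 1 <= m`` estimating equations the system
    interpolates the data (or is underdetermined); it is intended for
    panels appreciably longer than the number of modelled series.
    """

    def __init__(
        self,
        series: np.ndarray | Sequence[Sequence[float]],
        variable_ids: Sequence[str] | None = None,
    ) -> None:
        X0 = np.atleast_2d(np.asarray(series, dtype=float))
        if X0.shape[1] < 4:
            raise ValueError(f"need at least 4 points, got {X0.shape[1]}")
        self.X0 = X0
        m = X0.shape[0]
        self.variable_ids = (
            tuple(variable_ids)
            if variable_ids is not None
            else tuple(f"V{i + 1}" for i in range(m))
        )
        if len(self.variable_ids) != m:
            raise ValueError("variable_ids length does not match series count")

    @classmethod
    def from_panel(
        cls, panel: SeriesPanel, factor_ids: Sequence[str]
    ) -> "MGMSystem":
        rows = [panel.dependent_array] + [panel.factor_array(f) for f in factor_ids]
        return cls(np.vstack(rows), (panel.dependent_name, *factor_ids))

    def fit(self) -> "MGMSystemResults":
        m, n = self.X0.shape
        X1 = np.cumsum(self.X0, axis=1)
        Z = 0.5 * (X1[:, 1:] + X1[:, :-1])
        P = np.hstack([Z.T, np.ones((n - 1, 1))])
        rows = [
            _lstsq_checked(P, self.X0[i, 1:], f"MGM system row {i + 1}")
            for i in range(m)
        ]
        AB = np.vstack(rows)
        return MGMSystemResults(
            model=self, A=AB[:, :m], B=AB[:, m], _X1=X1
        )


@dataclass(frozen=True)
class MGMSystemResults:
    """Estimated coupled grey system (A, B) with its continuous solution."""

    model: MGMSystem
    A: np.ndarray
    B: np.ndarray
    _X1: np.ndarray

    @property
    def n(self) -> int:
        return self.model.X0.shape[1]

    @property
    def m(self) -> int:
        return self.model.X0.shape[0]

    def ago_solution(self, t: float) -> np.ndarray:
        """Continuous AGO-scale solution at (possibly fractional) time t."""
        return affine_ode_solution(self.A, t - 1.0, self._X1[:, 0], self.B)

    @property
    def fittedvalues(self) -> np.ndarray:
        """Per-variable original-scale fitted series (m x n)."""
        X1 = np.column_stack([self.ago_solution(t) for t in range(1, self.n + 1)])
        return np.hstack([X1[:, :1], np.diff(X1, axis=1)])

    @property
    def fitted_counts(self) -> np.ndarray:
        return round_counts(self.fittedvalues)

    def forecast(self, horizon: int) -> np.ndarray:
        """Per-variable forecasts (m x horizon) for ``t = n+1 .. n+horizon``."""
        if horizon < 1:
            raise ValueError(f"horizon must be >= 1, got {horizon}")
        ts = range(self.n, self.n + horizon + 1)
        X1 = np.column_stack([self.ago_solution(t) for t in ts])
        return np.diff(X1, axis=1)

    def summary(self) -> str:
        ids = self.model.variable_ids
        frame = pd.DataFrame(self.A, index=ids, columns=ids)
        frame["B"] = self.B
        return (
            f"Coupled grey system over ({', '.join(ids)})\n"
            "  dX1/dt = A X1 + B, rows of [A|B]:\n"
            + frame.to_string(float_format=lambda v: f"{v:.5g}")
        )
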