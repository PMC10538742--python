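"""Markov-chain correction of grey-model residuals.

A grey model captures the trend of a short series but not its fluctuation.
The correction step classifies each relative fitting error into one of
``s`` equal-width states spanning ``[min delta, max delta]``, estimates a
one-step transition matrix from the observed state sequence, and replaces
each fitted value ``xhat`` by ``xhat * (1 + midpoint of its state)``.  A
one-step-ahead forecast applies the midpoint of the modal future state —
found by summing, over lookback steps ``k``, the row of the k-step matrix
indexed by the state observed ``k`` steps before the target — to a base
value (by default the last observed actual).

Transition probabilities are kept as exact rationals (counts over counts)
alongside their float form, and k-step matrices are exact matrix powers
(Chapman–Kolmogorov).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from collections.abc import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ZeroWidthError",
    "residuals",
    "StatePartition",
    "partition_states",
    "assign_states",
    "TransitionModel",
    "estimate_transitions",
    "kstep",
    "future_state_distribution",
    "correct_fitted",
    "forecast_corrected",
    "MarkovCorrection",
]

FracMatrix = tuple[tuple[Fraction, ...], ...]


class ZeroWidthError(ValueError):
    """All residuals identical: no states to partition (model is exact)."""


def residuals(
    actual: Sequence[float],
    fitted: Sequence[float],
    denominator: str = "actual",
) -> np.ndarray:
    """Relative errors ``(actual - fitted) / denominator``.

    ``denominator="actual"`` is the default (it reproduces tabulated
    relative errors of count data); ``"fitted"`` is the literal grey-theory
    form.
    """
    act = np.asarray(actual, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if act.shape != fit.shape:
        raise ValueError("actual and fitted must have equal length")
    if denominator == "actual":
        den = act
    elif denominator == "fitted":
        den = fit
    else:
        raise ValueError(f"denominator must be 'actual' or 'fitted', got {denominator!r}")
    if np.any(den == 0):
        raise ZeroDivisionError(f"zero {denominator} value in residual denominator")
    return (act - fit) / den


@dataclass(frozen=True)
class StatePartition:
    """``s`` equal-width intervals spanning the residual range.

    Intervals are half-open ``[L_j, U_j)`` except the last, which is closed
    so the maximum residual is assigned.
    """

    edges: np.ndarray  # length s + 1

    @property
    def s(self) -> int:
        return self.edges.size - 1

    @property
    def bounds(self) -> tuple[tuple[float, float], ...]:
        return tuple(
            (float(self.edges[j]), float(self.edges[j + 1])) for j in range(self.s)
        )

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def state_labels(self) -> tuple[str, ...]:
        return tuple(f"S{j + 1}" for j in range(self.s))


def partition_states(resid: Sequence[float], s: int = 3) -> StatePartition:
    """Equal-width partition of ``[min resid, max resid]`` into s states."""
    if s < 2:
        raise ValueError(f"need at least 2 states, got {s}")
    arr = np.asarray(resid, dtype=float)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        raise ZeroWidthError(
            "all residuals identical: zero-width states (model already exact; "
            "Markov correction is a no-op)"
        )
    return StatePartition(edges=np.linspace(lo, hi, s + 1))


def assign_states(resid: Sequence[float], partition: StatePartition) -> np.ndarray:
    """0-based state index per residual (boundary points go to the upper state)."""
    arr = np.asarray(resid, dtype=float)
    lo, hi = partition.edges[0], partition.edges[-1]
    if np.any(arr < lo) or np.any(arr > hi):
        raise ValueError("residual outside the partitioned range")
    idx = np.searchsorted(partition.edges[1:-1], arr, side="right")
    return idx.astype(int)


@dataclass(frozen=True)
class TransitionModel:
    """Transition counts and the one-step probability matrix.

    ``P_frac`` holds the exact rationals ``Q_ij / Q_i``; ``P`` is the float
    view.  Source states never visited get a uniform row (with a warning at
    estimation time).
    """

    counts: np.ndarray  # s x s integer Q_ij
    row_counts: np.ndarray  # length s integer Q_i
    P_frac: FracMatrix

    @property
    def s(self) -> int:
        return self.counts.shape[0]

    @property
    def P(self) -> np.ndarray:
        return np.array([[float(p) for p in row] for row in self.P_frac])

    def to_frame(self, k: int = 1) -> pd.DataFrame:
        labels = [f"S{j + 1}" for j in range(self.s)]
        mat = kstep(self.P_frac, k)
        return pd.DataFrame(
            [[str(p) for p in row] for row in mat], index=labels, columns=labels
        )


def estimate_transitions(states: Sequence[int], s: int | None = None) -> TransitionModel:
    """One-step transition matrix from an observed state sequence.

    The terminal state contributes no source count.  ``s`` defaults to
    ``max(states) + 1``.
    """
    seq = np.asarray(states, dtype=int)
    if seq.size < 2:
        raise ValueError("need at least two observations to estimate transitions")
    ns = int(seq.max()) + 1 if s is None else int(s)
    counts = np.zeros((ns, ns), dtype=int)
    for i, j in zip(seq[:-1], seq[1:]):
        counts[i, j] += 1
    row_counts = counts.sum(axis=1)
    rows: list[tuple[Fraction, ...]] = []
    for i in range(ns):
        if row_counts[i] == 0:
            warnings.warn(
                f"state S{i + 1} never observed as a source; using a uniform row",
                UserWarning,
                stacklevel=2,
            )
            rows.append(tuple(Fraction(1, ns) for _ in range(ns)))
        else:
            rows.append(
                tuple(Fraction(int(counts[i, j]), int(row_counts[i])) for j in range(ns))
            )
    return TransitionModel(counts=counts, row_counts=row_counts, P_frac=tuple(rows))


def _as_frac_matrix(P: FracMatrix | np.ndarray) -> FracMatrix:
    if isinstance(P, np.ndarray):
        return tuple(tuple(Fraction(v).limit_denominator(10**9) for v in row) for row in P)
    return tuple(tuple(Fraction(v) for v in row) for row in P)


def _frac_matmul(X: FracMatrix, Y: FracMatrix) -> FracMatrix:
    s = len(X)
    return tuple(
        tuple(sum((X[i][l] * Y[l][j] for l in range(s)), Fraction(0)) for j in range(s))
        for i in range(s)
    )


def kstep(P1: FracMatrix | np.ndarray, k: int) -> FracMatrix:
    """Exact k-step transition matrix ``P1^k`` (Chapman–Kolmogorov)."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    P = _as_frac_matrix(P1)
    out = P
    for _ in range(k - 1):
        out = _frac_matmul(out, P)
    return out


def future_state_distribution(
    states: Sequence[int],
    trans: TransitionModel,
    lookback: int = 3,
) -> tuple[tuple[Fraction, ...], int]:
    """Summed k-step rows for the next time point and the modal state.

    For each step ``k = 1..lookback`` take the row of ``P1^k`` indexed by
    the state observed ``k`` steps before the forecast target, and sum the
    rows columnwise.  Ties in the modal state break toward the lower index.
    """
    seq = np.asarray(states, dtype=int)
    if lookback < 1:
        raise ValueError(f"lookback must be >= 1, got {lookback}")
    if lookback > seq.size:
        raise ValueError(f"lookback {lookback} exceeds chain length {seq.size}")
    s = trans.s
    weights = [Fraction(0)] * s
    for k in range(1, lookback + 1):
        row = kstep(trans.P_frac, k)[seq[-k]]
        weights = [w + r for w, r in zip(weights, row)]
    best = max(weights)
    modal = min(j for j, w in enumerate(weights) if w == best)
    if sum(1 for w in weights if w == best) > 1:
        warnings.warn(
            "modal future state is tied; breaking toward the lower state index",
            UserWarning,
            stacklevel=2,
        )
    return tuple(weights), modal


def correct_fitted(
    fitted: Sequence[float],
    states: Sequence[int],
    partition: StatePartition,
) -> np.ndarray:
    """Markov-corrected series: ``fitted * (1 + state midpoint)`` per point."""
    fit = np.asarray(fitted, dtype=float)
    seq = np.asarray(states, dtype=int)
    if fit.shape != seq.shape:
        raise ValueError("fitted and states must have equal length")
    mids = partition.midpoints
    return fit * (1.0 + mids[seq])


def forecast_corrected(base_value: float, state_bounds: tuple[float, float]) -> float:
    """One-step corrected forecast: base times one plus the state midpoint."""
    lo, hi = state_bounds
    return float(base_value) * (1.0 + 0.5 * (lo + hi))


@dataclass(frozen=True)
class MarkovCorrection:
    """Bundle of the whole residual-chain analysis for one fitted series."""

    actual: np.ndarray
    fitted: np.ndarray
    residual: np.ndarray
    partition: StatePartition
    states: np.ndarray
    transitions: TransitionModel
    corrected: np.ndarray
    lookback: int
    future_weights: tuple[Fraction, ...]
    modal_state: int

    @classmethod
    def from_series(
        cls,
        actual: Sequence[float],
        fitted: Sequence[float],
        n_states: int = 3,
        denominator: str = "actual",
        lookback: int = 3,
    ) -> "MarkovCorrection":
        act = np.asarray(actual, dtype=float)
        fit = np.asarray(fitted, dtype=float)
        delta = residuals(act, fit, denominator)
        part = partition_states(delta, n_states)
        states = assign_states(delta, part)
        trans = estimate_transitions(states, n_states)
        corrected = correct_fitted(fit, states, part)
        lb = min(lookback, len(states))
        weights, modal = future_state_distribution(states, trans, lb)
        return cls(
            actual=act,
            fitted=fit,
            residual=delta,
            partition=part,
            states=states,
            transitions=trans,
            corrected=corrected,
            lookback=lb,
            future_weights=weights,
            modal_state=modal,
        )

    def forecast(self, base_value: float) -> float:
        """Corrected one-step forecast from the given base value."""
        return forecast_corrected(
            base_value, self.partition.bounds[self.modal_state]
        )

    def state_table(self, years: Sequence[int] | None = None) -> pd.DataFrame:
        labels = self.partition.state_labels()
        frame = pd.DataFrame(
            {
                "actual": self.actual,
                "fitted": self.fitted,
                "relative_error": self.residual,
                "state": [labels[j] for j in self.states],
                "corrected": self.corrected,
            }
        )
        if years is not None:
            frame.insert(0, "year", list(years))
        return frame

    def summary(self) -> str:
        bounds = ", ".join(
            f"S{j + 1}=[{lo:.4f}, {hi:.4f}{']' if j == self.partition.s - 1 else ')'}"
            for j, (lo, hi) in enumerate(self.partition.bounds)
        )
        weights = ", ".join(str(w) for w in self.future_weights)
        return (
            "Markov residual correction\n"
            f"  states: {bounds}\n"
            f"  one-step transitions:\n{self.transitions.to_frame().to_string()}\n"
            f"  future-state weights (lookback {self.lookback}): ({weights})"
            f" -> modal S{self.modal_state + 1}\n"
            + self.state_table().to_string(index=False)
        )
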