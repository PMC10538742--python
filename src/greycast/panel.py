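"""Multivariate count panels and analysis configuration.

A :class:`SeriesPanel` holds one short annual time series of a dependent
incidence count together with a set of named candidate factor series, all
observed over the same, uniformly spaced calendar years.  Grey-system methods
only need four or more time points, so validation enforces ``n >= 4`` rather
than the much larger samples classical time-series models require.

All model mathematics works on the 1-based discrete time index ``k = 1..n``;
the years are metadata used for labelling and alignment only.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PanelError",
    "MissingColumnError",
    "NonNumericError",
    "UnequalLengthError",
    "TooFewPointsError",
    "NonPositiveDependentError",
    "MissingValueError",
    "YearSpacingError",
    "SeriesPanel",
    "AnalysisConfig",
    "read_panel",
    "write_panel",
]

#: grey-theory minimum number of time points
MIN_POINTS = 4


class PanelError(ValueError):
    """Base class for panel validation failures."""


class MissingColumnError(PanelError):
    """A required column is absent from the input file."""


class NonNumericError(PanelError):
    """A cell could not be parsed as a number."""


class UnequalLengthError(PanelError):
    """Series in the panel have different lengths."""


class TooFewPointsError(PanelError):
    """Fewer than the grey-theory minimum of four time points."""


class NonPositiveDependentError(PanelError):
    """The dependent series contains a zero or negative value."""


class MissingValueError(PanelError):
    """The panel contains a missing (NaN) entry."""


class YearSpacingError(PanelError):
    """Years are not strictly increasing with a constant step."""


def _as_float_tuple(values: Sequence[float], what: str) -> tuple[float, ...]:
    out = []
    for v in values:
        try:
            f = float(v)
        except (TypeError, ValueError) as exc:
            raise NonNumericError(f"non-numeric value {v!r} in {what}") from exc
        if math.isnan(f):
            raise MissingValueError(f"missing entry in {what}")
        out.append(f)
    return tuple(out)


@dataclass(frozen=True)
class SeriesPanel:
    """A validated multivariate count panel.

    Parameters
    ----------
    years
        Calendar years, strictly increasing with constant step.
    dependent
        Strictly positive incidence counts, one per year.
    factors
        Ordered mapping of factor id -> non-negative count series.
    labels
        Optional factor id -> human-readable description.
    dependent_name
        Column name used for the dependent series on CSV round trips.
    """

    years: tuple[int, ...]
    dependent: tuple[float, ...]
    factors: Mapping[str, tuple[float, ...]]
    labels: Mapping[str, str] = field(default_factory=dict)
    dependent_name: str = "total"

    def __post_init__(self) -> None:
        years = tuple(int(y) for y in self.years)
        dependent = _as_float_tuple(self.dependent, "dependent series")
        factors = {
            str(k): _as_float_tuple(v, f"factor {k!r}") for k, v in self.factors.items()
        }
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "dependent", dependent)
        object.__setattr__(self, "factors", factors)
        object.__setattr__(self, "labels", dict(self.labels))

        n = len(years)
        if n < MIN_POINTS:
            raise TooFewPointsError(
                f"too few time points: need at least {MIN_POINTS}, got {n}"
            )
        if len(dependent) != n:
            raise UnequalLengthError(
                f"dependent series has length {len(dependent)}, expected {n}"
            )
        for fid, seq in factors.items():
            if len(seq) != n:
                raise UnequalLengthError(
                    f"factor {fid!r} has length {len(seq)}, expected {n}"
                )
        steps = {b - a for a, b in zip(years, years[1:])}
        if len(steps) != 1 or min(steps) <= 0:
            raise YearSpacingError(
                f"years must be strictly increasing with constant step, got {years}"
            )
        if any(v <= 0 for v in dependent):
            raise NonPositiveDependentError(
                "dependent series must be strictly positive "
                "(it is the residual and MAPE denominator)"
            )
        for fid, seq in factors.items():
            if any(v < 0 for v in seq):
                raise PanelError(f"factor {fid!r} contains a negative value")

    # -- derived quantities -------------------------------------------------

    @property
    def n(self) -> int:
        """Number of time points."""
        return len(self.years)

    @property
    def m(self) -> int:
        """Number of series in the system (dependent + factors)."""
        return 1 + len(self.factors)

    @property
    def factor_ids(self) -> tuple[str, ...]:
        return tuple(self.factors)

    def factor_array(self, fid: str) -> np.ndarray:
        try:
            return np.asarray(self.factors[fid], dtype=float)
        except KeyError as exc:
            raise MissingColumnError(f"unknown factor {fid!r}") from exc

    @property
    def dependent_array(self) -> np.ndarray:
        return np.asarray(self.dependent, dtype=float)

    def subset(self, factor_ids: Sequence[str]) -> "SeriesPanel":
        """Panel restricted to the given factors (order preserved as given)."""
        return SeriesPanel(
            years=self.years,
            dependent=self.dependent,
            factors={fid: tuple(self.factor_array(fid)) for fid in factor_ids},
            labels={k: v for k, v in self.labels.items() if k in set(factor_ids)},
            dependent_name=self.dependent_name,
        )

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, Any] = {"year": list(self.years)}
        data[self.dependent_name] = list(self.dependent)
        for fid, seq in self.factors.items():
            data[fid] = list(seq)
        return pd.DataFrame(data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SeriesPanel):
            return NotImplemented
        return (
            self.years == other.years
            and self.dependent == other.dependent
            and list(self.factors) == list(other.factors)
            and all(self.factors[k] == other.factors[k] for k in self.factors)
            and self.dependent_name == other.dependent_name
        )

    __hash__ = None  # type: ignore[assignment]


def read_panel(path: str | Path, dependent_column: str = "total") -> SeriesPanel:
    """Read a wide CSV (``year`` column + named count columns) into a panel.

    Factor column order is preserved.  Each malformed input raises a distinct
    :class:`PanelError` subclass.
    """
    # round_trip: the default C float parser is not correctly rounded,
    # which would break the lossless round-trip contract
    frame = pd.read_csv(path, float_precision="round_trip")
    cols = list(frame.columns)
    if "year" not in cols:
        raise MissingColumnError(f"no 'year' column in {path} (found {cols})")
    if dependent_column not in cols:
        raise MissingColumnError(
            f"dependent column {dependent_column!r} not found in {path} (found {cols})"
        )
    factor_cols = [c for c in cols if c not in ("year", dependent_column)]
    try:
        years = [int(y) for y in frame["year"]]
    except (TypeError, ValueError) as exc:
        raise NonNumericError(f"non-numeric year in {path}") from exc
    return SeriesPanel(
        years=tuple(years),
        dependent=tuple(frame[dependent_column]),
        factors={c: tuple(frame[c]) for c in factor_cols},
        dependent_name=dependent_column,
    )


def write_panel(panel: SeriesPanel, path: str | Path) -> None:
    """Write a panel to wide CSV so that :func:`read_panel` round-trips it."""
    panel.to_frame().to_csv(path, index=False)


def _check_choice(name: str, value: str, choices: tuple[str, ...]) -> None:
    if value not in choices:
        raise ValueError(f"{name} must be one of {choices}, got {value!r}")


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable knobs of the grey–Markov pipeline.

    ``rho`` is Deng's distinguishing coefficient in the relational
    coefficient; ``screen_threshold`` drops weakly related factors;
    ``n_states`` is the number of equal-width residual states for the Markov
    correction.  ``round_fitted`` reports grey fitted values as whole counts
    before the residual/Markov/metric stages (counts are integers; this is
    the convention the reference analysis of the Michigan data follows).
    """

    rho: float = 0.5
    screen_threshold: float = 0.7
    n_states: int = 3
    residual_denominator: str = "actual"  # or "fitted" (literal grey form)
    forecast_base: str = "last_actual"  # or "model_forecast"
    normalization: str = "initial"  # or "mean"
    dimension_range: tuple[int, int] = (2, 6)
    markov_lookback: int = 3
    round_fitted: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must lie in [0, 1], got {self.rho}")
        if self.n_states < 2:
            raise ValueError(f"n_states must be >= 2, got {self.n_states}")
        _check_choice(
            "residual_denominator", self.residual_denominator, ("actual", "fitted")
        )
        _check_choice(
            "forecast_base", self.forecast_base, ("last_actual", "model_forecast")
        )
        _check_choice("normalization", self.normalization, ("initial", "mean"))
        lo, hi = self.dimension_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid dimension_range {self.dimension_range}")
        if self.markov_lookback < 1:
            raise ValueError("markov_lookback must be >= 1")

    def replace(self, **kwargs: Any) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "AnalysisConfig":
        """Load a config from YAML; keyword overrides win over file values."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "dimension_range" in raw and raw["dimension_range"] is not None:
            raw["dimension_range"] = tuple(raw["dimension_range"])
        return cls(**raw)
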