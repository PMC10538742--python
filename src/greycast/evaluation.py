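"""Error metrics, grey-model dimension selection and model comparison.

MAPE is reported on the percentage scale (4.47 means 4.47%); MAE and RMSE
are in the units of the series (counts).  All metrics run over every time
point including the first, whose grey fitted value equals the actual by
construction (the initial-condition anchor) and therefore contributes zero
error — this is the convention under which the tabulated reference values
for the Michigan panel are reproduced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .gra import RelationalResult
from .grey import GM11, MGM, DegenerateModelError, round_counts
from .markov import MarkovCorrection
from .panel import AnalysisConfig, SeriesPanel

__all__ = [
    "mape",
    "mae",
    "rmse",
    "metric_triple",
    "DimensionScan",
    "dimension_scan",
    "EvalReport",
    "compare_models",
]


def mape(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Mean absolute percentage error, on the printed scale (%)."""
    act = np.asarray(actual, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if act.shape != pred.shape:
        raise ValueError("actual and predicted must have equal length")
    if np.any(act == 0):
        raise ZeroDivisionError("MAPE undefined for zero actual values")
    return float(np.mean(np.abs((act - pred) / act)) * 100.0)


def mae(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Mean absolute error, in the units of the series."""
    act = np.asarray(actual, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if act.shape != pred.shape:
        raise ValueError("actual and predicted must have equal length")
    return float(np.mean(np.abs(act - pred)))


def rmse(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Root mean squared error, in the units of the series."""
    act = np.asarray(actual, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if act.shape != pred.shape:
        raise ValueError("actual and predicted must have equal length")
    return float(np.sqrt(np.mean((act - pred) ** 2)))


def metric_triple(
    actual: Sequence[float], predicted: Sequence[float]
) -> tuple[float, float, float]:
    return mape(actual, predicted), mae(actual, predicted), rmse(actual, predicted)


@dataclass(frozen=True)
class DimensionScan:
    """Dependent-series MAPE per MGM(1,n) model order."""

    mapes: Mapping[int, float]
    factors_used: Mapping[int, tuple[str, ...]]
    failures: Mapping[int, str] = field(default_factory=dict)

    @property
    def selected_n(self) -> int:
        """Argmin of the scan; ties break toward the smallest order."""
        if not self.mapes:
            raise ValueError("dimension scan produced no successful fits")
        return min(sorted(self.mapes), key=lambda n: self.mapes[n])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "n": n,
                "factors": ",".join(self.factors_used[n]),
                "mape": self.mapes[n],
                "selected": n == self.selected_n,
            }
            for n in sorted(self.mapes)
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        frame = self.to_frame()
        frame["mape"] = frame["mape"].map(lambda v: f"{v:.2f}%")
        out = "MGM(1,n) dimension scan\n" + frame.to_string(index=False)
        for n, reason in self.failures.items():
            out += f"\n  n={n}: fit failed ({reason})"
        return out


def dimension_scan(
    panel: SeriesPanel,
    relational: RelationalResult,
    n_range: tuple[int, int] = (2, 6),
    round_fitted: bool = True,
) -> DimensionScan:
    """Fit MGM(1,n) over a range of orders and score the dependent fit.

    Factors enter in descending relational-grade order, restricted to the
    screened (kept) set.  A failed fit is recorded and excluded from the
    argmin.
    """
    kept = relational.kept
    lo, hi = n_range
    if lo < 1:
        raise ValueError("model order must be >= 1")
    hi = min(hi, len(kept))
    if hi < lo:
        raise ValueError(
            f"dimension range ({lo}..{n_range[1]}) has no orders within the "
            f"{len(kept)} screened factors"
        )
    actual = panel.dependent_array
    mapes: dict[int, float] = {}
    used: dict[int, tuple[str, ...]] = {}
    failures: dict[int, str] = {}
    for n in range(lo, hi + 1):
        factor_ids = kept[:n]
        try:
            res = MGM.from_panel(panel, factor_ids).fit()
            fitted = res.fitted_counts if round_fitted else res.fittedvalues
            mapes[n] = mape(actual, fitted)
            used[n] = tuple(factor_ids)
        except (DegenerateModelError, ValueError, np.linalg.LinAlgError) as exc:
            failures[n] = str(exc)
            warnings.warn(
                f"MGM(1,{n}) fit failed and is excluded from the scan: {exc}",
                UserWarning,
                stacklevel=2,
            )
    return DimensionScan(mapes=mapes, factors_used=used, failures=failures)


@dataclass(frozen=True)
class EvalReport:
    """MAPE/MAE/RMSE per model plus the per-year error table."""

    metrics: Mapping[str, tuple[float, float, float]]
    per_year: pd.DataFrame
    scan: DimensionScan | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"model": label, "MAPE_pct": m, "MAE": a, "RMSE": r}
                for label, (m, a, r) in self.metrics.items()
            ]
        )

    def summary(self) -> str:
        frame = self.to_frame()
        for col, fmt in [("MAPE_pct", "{:.2f}"), ("MAE", "{:.2f}"), ("RMSE", "{:.2f}")]:
            frame[col] = frame[col].map(fmt.format)
        out = "Model comparison\n" + frame.to_string(index=False)
        if self.scan is not None:
            out += "\n\n" + self.scan.summary()
        return out


def compare_models(
    panel: SeriesPanel, config: AnalysisConfig | None = None
) -> EvalReport:
    """Three-way comparison: GM(1,1), MGM(1,n*), and the Markov-corrected fit.

    ``n*`` is chosen by the dimension scan over the screened factors.
    """
    from .gra import relational_grades  # local import to avoid cycle at import time

    cfg = config or AnalysisConfig()
    actual = panel.dependent_array
    relational = relational_grades(panel, cfg)
    scan = dimension_scan(
        panel, relational, cfg.dimension_range, round_fitted=cfg.round_fitted
    )
    n_star = scan.selected_n
    mgm_res = MGM.from_panel(panel, scan.factors_used[n_star]).fit()
    mgm_fit = mgm_res.fitted_counts if cfg.round_fitted else mgm_res.fittedvalues

    gm11_res = GM11(actual).fit()
    gm11_fit = gm11_res.fitted_counts if cfg.round_fitted else gm11_res.fittedvalues

    if np.array_equal(mgm_fit, actual):
        # perfect fit: no residual states to correct
        corrected = mgm_fit.copy()
    else:
        chain = MarkovCorrection.from_series(
            actual,
            mgm_fit,
            n_states=cfg.n_states,
            denominator=cfg.residual_denominator,
            lookback=cfg.markov_lookback,
        )
        corrected = chain.corrected

    labels = {
        "GM(1,1)": gm11_fit,
        f"MGM(1,{n_star})": mgm_fit,
        f"MGM(1,{n_star})-Markov": corrected,
    }
    metrics = {label: metric_triple(actual, fit) for label, fit in labels.items()}
    per_year = pd.DataFrame({"year": list(panel.years), "actual": actual})
    for label, fit in labels.items():
        per_year[label] = fit
        per_year[f"{label} rel. error"] = (actual - fit) / actual
    if cfg.round_fitted:
        per_year["MGM corrected (counts)"] = round_counts(
            per_year[f"MGM(1,{n_star})-Markov"]
        )
    return EvalReport(metrics=metrics, per_year=per_year, scan=scan)
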