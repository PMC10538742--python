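"""End-to-end grey–Markov modelling of a count panel.

The four-stage procedure: grey relational screening of the candidate
factors, model-order selection by dimension scan, multivariate grey fit,
and Markov correction of the residual chain with a corrected one-step
forecast.  :class:`GreyMarkovModel` is the statsmodels-style entry point;
:func:`run_pipeline` additionally serializes every stage's output and
returns a :class:`RunManifest`.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from collections.abc import Sequence
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import DimensionScan, EvalReport, compare_models, dimension_scan
from .gra import RelationalResult, relational_grades
from .grey import MGM, MGMResults
from .markov import MarkovCorrection
from .panel import AnalysisConfig, SeriesPanel, read_panel

__all__ = ["GreyMarkovModel", "GreyMarkovResults", "RunManifest", "run_pipeline"]


class GreyMarkovModel:
    """Hybrid multivariate grey–Markov forecaster for a count panel.

    Parameters
    ----------
    panel
        Validated multivariate count panel.
    config
        Pipeline knobs; defaults reproduce the reference Michigan analysis.
    factor_ids
        Optional explicit factor set for the grey model; when omitted the
        order is chosen by the dimension scan over the screened factors.
    """

    def __init__(
        self,
        panel: SeriesPanel,
        config: AnalysisConfig | None = None,
        factor_ids: Sequence[str] | None = None,
    ) -> None:
        self.panel = panel
        self.config = config or AnalysisConfig()
        self.factor_ids = tuple(factor_ids) if factor_ids is not None else None

    def fit(self) -> "GreyMarkovResults":
        cfg = self.config
        relational = relational_grades(self.panel, cfg)
        scan = dimension_scan(
            self.panel, relational, cfg.dimension_range, round_fitted=cfg.round_fitted
        )
        factors = (
            self.factor_ids
            if self.factor_ids is not None
            else scan.factors_used[scan.selected_n]
        )
        grey_res = MGM.from_panel(self.panel, factors).fit()
        fitted = (
            grey_res.fitted_counts if cfg.round_fitted else grey_res.fittedvalues
        )
        chain = MarkovCorrection.from_series(
            self.panel.dependent_array,
            fitted,
            n_states=cfg.n_states,
            denominator=cfg.residual_denominator,
            lookback=cfg.markov_lookback,
        )
        report = compare_models(self.panel, cfg)
        return GreyMarkovResults(
            model=self,
            relational=relational,
            scan=scan,
            grey=grey_res,
            chain=chain,
            report=report,
        )


@dataclass(frozen=True)
class GreyMarkovResults:
    """Fitted grey–Markov pipeline: screening, grey fit, chain, comparison."""

    model: GreyMarkovModel
    relational: RelationalResult
    scan: DimensionScan
    grey: MGMResults
    chain: MarkovCorrection
    report: EvalReport

    @property
    def panel(self) -> SeriesPanel:
        return self.model.panel

    @property
    def config(self) -> AnalysisConfig:
        return self.model.config

    @property
    def corrected_fitted(self) -> np.ndarray:
        return self.chain.corrected

    def forecast(self, horizon: int = 1) -> np.ndarray:
        """Markov-corrected dependent forecasts for the next ``horizon`` steps.

        The first step corrects a base value — the last observed actual by
        default, or the grey model's own one-step forecast under
        ``forecast_base="model_forecast"`` — by the modal future state's
        midpoint.  Steps beyond the first use the grey forecast corrected by
        the same midpoint (the chain supplies no further information).
        """
        if horizon < 1:
            raise ValueError(f"horizon must be >= 1, got {horizon}")
        grey_fc = self.grey.forecast(horizon)
        mid = float(self.chain.partition.midpoints[self.chain.modal_state])
        if self.config.forecast_base == "last_actual":
            first = self.panel.dependent_array[-1] * (1.0 + mid)
        else:
            first = grey_fc[0] * (1.0 + mid)
        rest = grey_fc[1:] * (1.0 + mid)
        return np.concatenate([[first], rest])

    def summary(self) -> str:
        fc = self.forecast(1)[0]
        next_year = self.panel.years[-1] + (self.panel.years[1] - self.panel.years[0])
        parts = [
            self.relational.summary(),
            self.scan.summary(),
            self.grey.summary(),
            self.chain.summary(),
            self.report.summary(),
            f"Corrected forecast for {next_year}: {fc:.1f} "
            f"(base = {self.config.forecast_base}, modal state "
            f"S{self.chain.modal_state + 1})",
        ]
        return ("\n" + "=" * 70 + "\n").join(parts)


@dataclass
class RunManifest:
    """Record of one pipeline run: inputs, config, artifacts, warnings."""

    config: dict[str, Any]
    input_digest: str
    version: str
    outputs: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=str)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: AnalysisConfig,
    input_path: str | Path,
    out_dir: str | Path,
    dependent_column: str = "total",
    horizon: int = 1,
) -> RunManifest:
    """Run the full pipeline on a CSV panel, writing one file per stage."""
    input_path = Path(input_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = read_panel(input_path, dependent_column)
    manifest = RunManifest(
        config=dict(config.__dict__),
        input_digest=_sha256(input_path),
        version=__version__,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        results = GreyMarkovModel(panel, config).fit()
        forecast = results.forecast(horizon)
    manifest.warnings = [str(w.message) for w in caught]

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest.outputs[name] = str(path)

    emit("grades.csv", lambda p: results.relational.to_frame().to_csv(p, index=False))
    emit("dimension_scan.csv", lambda p: results.scan.to_frame().to_csv(p, index=False))
    emit(
        "grey_params.json",
        lambda p: p.write_text(
            json.dumps(
                {
                    "label": results.grey.label,
                    "factors": list(results.grey.model.factor_ids),
                    "a": results.grey.a,
                    "b": dict(
                        zip(results.grey.model.factor_ids, results.grey.b.tolist())
                    ),
                },
                indent=2,
            )
        ),
    )
    emit(
        "state_table.csv",
        lambda p: results.chain.state_table(panel.years).to_csv(p, index=False),
    )
    trans = results.chain.transitions
    emit(
        "transitions.json",
        lambda p: p.write_text(
            json.dumps(
                {
                    "counts": trans.counts.tolist(),
                    "P1_exact": [[str(v) for v in row] for row in trans.P_frac],
                    "P1_float": trans.P.tolist(),
                    "future_weights_exact": [str(w) for w in results.chain.future_weights],
                    "modal_state": f"S{results.chain.modal_state + 1}",
                },
                indent=2,
            )
        ),
    )
    emit("comparison.csv", lambda p: results.report.to_frame().to_csv(p, index=False))
    emit("per_year.csv", lambda p: results.report.per_year.to_csv(p, index=False))
    step = panel.years[1] - panel.years[0]
    emit(
        "forecast.csv",
        lambda p: pd.DataFrame(
            {
                "year": [panel.years[-1] + step * (h + 1) for h in range(horizon)],
                "corrected_forecast": forecast,
            }
        ).to_csv(p, index=False),
    )
    emit("manifest.json", lambda p: p.write_text(manifest.to_json()))
    return manifest
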