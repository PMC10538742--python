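"""Grey relational analysis (Deng's relational degree).

Grey relational analysis ranks candidate factor series by the geometric
similarity of their curves to a reference (dependent) series.  After
removing scale by a dimensionless transform, the pointwise relational
coefficient between the reference ``x1`` and comparison ``xi`` is

    zeta_i(k) = (d_min + rho * d_max) / (|x1(k) - xi(k)| + rho * d_max)

where ``d_min`` and ``d_max`` are the two-level (over all comparison series
and all time points) minimum and maximum of the absolute discrepancy
``|x1 - xi|``, and ``rho`` in [0, 1] is the distinguishing coefficient that
damps the influence of the global maximum discrepancy.  The relational
grade ``r_i`` is the arithmetic mean of ``zeta_i(k)`` over time; factors
whose grade falls below a screening threshold are dropped before
multivariate grey modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import AnalysisConfig, PanelError, SeriesPanel

__all__ = [
    "NormalizationError",
    "normalize_series",
    "relational_coefficients",
    "relational_grades",
    "GreyRelationalAnalysis",
    "RelationalResult",
]


class NormalizationError(PanelError):
    """A series cannot be made dimensionless (zero divisor)."""


def _normalize(values: np.ndarray, method: str, name: str) -> np.ndarray:
    if method == "initial":
        div = values[0]
    elif method == "mean":
        div = values.mean()
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    if div == 0:
        raise NormalizationError(
            f"cannot normalize series {name!r}: zero {method} value"
        )
    return values / div


def normalize_series(panel: SeriesPanel, method: str = "initial") -> SeriesPanel:
    """Return the panel with every series made dimensionless.

    ``initial`` divides each series by its first element (all curves start
    at 1); ``mean`` divides by the series mean (all curves average 1).
    """
    dep = _normalize(panel.dependent_array, method, panel.dependent_name)
    factors = {
        fid: tuple(_normalize(panel.factor_array(fid), method, fid))
        for fid in panel.factor_ids
    }
    return SeriesPanel(
        years=panel.years,
        dependent=tuple(dep),
        factors=factors,
        labels=panel.labels,
        dependent_name=panel.dependent_name,
    )


def relational_coefficients(
    reference: Sequence[float],
    comparison: Sequence[float],
    delta_min: float,
    delta_max: float,
    rho: float,
) -> np.ndarray:
    """Deng relational coefficient sequence for one comparison series.

    ``delta_min``/``delta_max`` must be the two-level extrema of
    ``|reference - comparison|`` taken over *all* comparison series jointly.
    When every series is identical to the reference (``delta_max == 0``) the
    coefficients are 1 by convention.
    """
    ref = np.asarray(reference, dtype=float)
    comp = np.asarray(comparison, dtype=float)
    if ref.shape != comp.shape:
        raise ValueError("reference and comparison must have equal length")
    diff = np.abs(ref - comp)
    if delta_max == 0.0:
        return np.ones_like(diff)
    return (delta_min + rho * delta_max) / (diff + rho * delta_max)


@dataclass(frozen=True)
class RelationalResult:
    """Grades, coefficient sequences and the screening outcome."""

    rho: float
    normalization: str
    threshold: float
    delta_min: float
    delta_max: float
    coefficients: Mapping[str, np.ndarray]
    grades: Mapping[str, float]
    labels: Mapping[str, str] = field(default_factory=dict)

    @property
    def ranking(self) -> tuple[str, ...]:
        """Factor ids by descending grade; ties keep original column order."""
        ids = list(self.grades)
        return tuple(sorted(ids, key=lambda fid: (-self.grades[fid], ids.index(fid))))

    @property
    def kept(self) -> tuple[str, ...]:
        """Ranked factors whose grade reaches the screening threshold."""
        return tuple(f for f in self.ranking if self.grades[f] >= self.threshold)

    @property
    def dropped(self) -> tuple[str, ...]:
        return tuple(f for f in self.ranking if self.grades[f] < self.threshold)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "factor": fid,
                "label": self.labels.get(fid, ""),
                "grade": self.grades[fid],
                "kept": self.grades[fid] >= self.threshold,
            }
            for fid in self.ranking
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        frame = self.to_frame()
        frame["grade"] = frame["grade"].map(lambda g: f"{g:.4f}")
        head = (
            "Grey relational analysis\n"
            f"  distinguishing coefficient rho = {self.rho}\n"
            f"  normalization = {self.normalization}, "
            f"screening threshold = {self.threshold}\n"
        )
        return head + frame.to_string(index=False)


class GreyRelationalAnalysis:
    """Deng-degree relational screening of factor series against a reference.

    Parameters
    ----------
    panel
        The raw count panel; the dependent series is the reference.
    rho
        Distinguishing coefficient in [0, 1].
    normalization
        ``initial`` (default) or ``mean`` dimensionless transform.
    """

    def __init__(
        self,
        panel: SeriesPanel,
        rho: float = 0.5,
        normalization: str = "initial",
    ) -> None:
        if not 0.0 <= rho <= 1.0:
            raise ValueError(f"rho must lie in [0, 1], got {rho}")
        self.panel = panel
        self.rho = rho
        self.normalization = normalization

    def fit(self, threshold: float = 0.7) -> RelationalResult:
        norm = normalize_series(self.panel, self.normalization)
        ref = norm.dependent_array
        diffs = {
            fid: np.abs(ref - norm.factor_array(fid)) for fid in norm.factor_ids
        }
        stacked = np.concatenate(list(diffs.values())) if diffs else np.zeros(1)
        delta_min = float(stacked.min())
        delta_max = float(stacked.max())
        coeffs = {
            fid: relational_coefficients(
                ref, norm.factor_array(fid), delta_min, delta_max, self.rho
            )
            for fid in norm.factor_ids
        }
        grades = {fid: float(z.mean()) for fid, z in coeffs.items()}
        return RelationalResult(
            rho=self.rho,
            normalization=self.normalization,
            threshold=threshold,
            delta_min=delta_min,
            delta_max=delta_max,
            coefficients=coeffs,
            grades=grades,
            labels=dict(self.panel.labels),
        )


def relational_grades(
    panel: SeriesPanel, config: AnalysisConfig | None = None
) -> RelationalResult:
    """Convenience wrapper: grades/ranking/screen under a config."""
    cfg = config or AnalysisConfig()
    model = GreyRelationalAnalysis(
        panel, rho=cfg.rho, normalization=cfg.normalization
    )
    return model.fit(threshold=cfg.screen_threshold)
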