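"""Bundled example data.

The Michigan roundabout panel is the annual count of police-reported traffic
crashes occurring in Michigan roundabouts, 2016-2021, together with eight
candidate explanatory count series, compiled from the public Michigan
Traffic Crash Facts (MTCF) query tool.  Earlier years did not flag whether a
crash occurred inside a roundabout, which is why the panel starts in 2016.
"""

from __future__ import annotations

from importlib import resources

from .panel import SeriesPanel, read_panel

__all__ = ["michigan_roundabouts", "MICHIGAN_LABELS"]

MICHIGAN_LABELS = {
    "X1": "crash on snow-covered road",
    "X2": "head-on crash on left turn",
    "X3": "sideswipe crash",
    "X4": "crash with distracted driver",
    "X5": "crash resulting in injury",
    "X6": "crash on the median",
    "X7": "crash involving buses/trucks",
    "X8": "crash in rainy weather",
}


def michigan_roundabouts() -> SeriesPanel:
    """Annual Michigan roundabout crash panel (6 years, 8 factor series)."""
    with resources.as_file(
        resources.files("greycast.data").joinpath("michigan_roundabouts.csv")
    ) as path:
        panel = read_panel(path, dependent_column="total")
    return SeriesPanel(
        years=panel.years,
        dependent=panel.dependent,
        factors=panel.factors,
        labels=MICHIGAN_LABELS,
        dependent_name="total",
    )
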