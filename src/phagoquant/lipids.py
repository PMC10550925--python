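"""Phagosomal phospholipid enrichment tracks and window statistics.

Lipid-probe enrichment of a phagosome at time t is

    E(t) = mean phagosomal fluorescence at t
           / mean whole-cell fluorescence at the first analyzed frame - 1

computed on background-subtracted maximum projections.  Condition contrasts
are taken on named time windows anchored either to ingestion start (e.g.
5-10 min after ingestion) or to the initial peak (e.g. 5-25 min after the
peak, with the peak defined as the global maximum of E within 10 min of
ingestion start).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import ImageStack, LabelMask, make_summary_table, project
from .puncta import bootstrap_percent_change

__all__ = ["Track", "Window", "enrichment_track", "window_stats", "condition_contrast"]

PEAK_SEARCH_MIN = 10.0  # the initial peak is sought within 10 min of ingestion


@dataclass
class Window:
    start_min: float
    end_min: float
    anchor: str = "ingestion"  # "ingestion" | "peak" | "full"

    def bounds(self, peak_time_min: float) -> tuple[float, float]:
        if self.anchor == "peak":
            return self.start_min + peak_time_min, self.end_min + peak_time_min
        return self.start_min, self.end_min


@dataclass
class Track:
    """Per-phagosome enrichment time series, minutes since ingestion start."""

    phagosome_id: int
    t_min: np.ndarray
    E: np.ndarray
    scenario: str = ""
    windows: dict[str, Window] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, float)
        self.E = np.asarray(self.E, float)

    @property
    def peak_value(self) -> float:
        sel = (self.t_min >= 0) & (self.t_min <= PEAK_SEARCH_MIN)
        return float(np.nanmax(self.E[sel]))

    @property
    def peak_time_min(self) -> float:
        sel = (self.t_min >= 0) & (self.t_min <= PEAK_SEARCH_MIN)
        ts, es = self.t_min[sel], self.E[sel]
        return float(ts[np.nanargmax(es)])

    def window_mean(self, window: Window) -> float:
        if window.anchor == "full":
            sel = self.t_min >= 0
        else:
            a, b = window.bounds(self.peak_time_min)
            sel = (self.t_min >= a) & (self.t_min <= b)
        if not sel.any():
            return float("nan")
        return float(np.nanmean(self.E[sel]))


def enrichment_track(
    stack: ImageStack,
    phag_mask: LabelMask,
    cell_mask: LabelMask,
    ingestion_start_frame: int,
    phagosome_label: int = 1,
    channel: int = 0,
    scenario: str = "",
) -> Track:
    """Compute E(t) for one phagosome from a time-lapse stack.

    The stack is max-projected over z; the denominator is the mean
    whole-cell intensity of the first frame (initial total cell
    fluorescence).  Time is reported in minutes relative to
    ``ingestion_start_frame``.
    """
    proj = project(stack, "max").data[channel, :, 0]
    cell = cell_mask.foreground
    phag = phag_mask.region(phagosome_label)
    if not phag.any():
        raise ValueError(f"phagosome label {phagosome_label} absent")
    f0 = proj[0][cell].mean()
    if f0 == 0:
        raise ValueError("zero initial cell fluorescence")
    e = proj[:, phag].mean(axis=1) / f0 - 1.0
    dt_min = (stack.frame_interval_s or 60.0) / 60.0
    t = (np.arange(stack.n_frames) - ingestion_start_frame) * dt_min
    return Track(phagosome_id=phagosome_label, t_min=t, E=e, scenario=scenario)


def window_stats(track: Track, windows: dict[str, Window]) -> pd.DataFrame:
    """Peak value/time and mean enrichment per named window for one track."""
    rows = [
        dict(scenario=track.scenario, phagosome_id=track.phagosome_id,
             metric="peak_value", value=track.peak_value, units="enrichment"),
        dict(scenario=track.scenario, phagosome_id=track.phagosome_id,
             metric="peak_time", value=track.peak_time_min, units="min"),
    ]
    for name, win in windows.items():
        val = track.window_mean(win)
        rows.append(
            dict(scenario=track.scenario, phagosome_id=track.phagosome_id,
                 metric=f"window_mean:{name}",
                 value=val, units="enrichment" if np.isfinite(val) else "missing")
        )
    return make_summary_table(rows)


def condition_contrast(
    groups: dict[str, list[Track]],
    metric: Window | str,
    reference: str,
    seed: int = 0,
    n_boot: int = 10_000,
) -> pd.DataFrame:
    """Mean +/- SEM of a window metric per scenario plus contrasts vs reference.

    ``metric`` is a :class:`Window` (window mean) or the string "peak"
    (per-track initial peak value).  Contrasts report fold change and
    percent change with a seeded bootstrap 95% CI over tracks.
    """
    if reference not in groups:
        raise ValueError(f"reference scenario {reference!r} absent")
    rng = np.random.default_rng(seed)

    def values(tracks):
        if metric == "peak":
            return np.array([tr.peak_value for tr in tracks])
        return np.array([tr.window_mean(metric) for tr in tracks])

    ref_vals = values(groups[reference])
    if len(ref_vals) == 0:
        raise ValueError("empty reference group")
    rows = []
    for name, tracks in groups.items():
        if not tracks:
            raise ValueError(f"empty group {name!r}")
        vals = values(tracks)
        rows.append(dict(scenario=name, metric="mean", value=float(np.nanmean(vals)),
                         units="enrichment"))
        rows.append(dict(scenario=name, metric="sem",
                         value=float(np.nanstd(vals, ddof=1) / np.sqrt(len(vals))),
                         units="enrichment"))
        rows.append(dict(scenario=name, metric="n", value=float(len(vals)), units="tracks"))
        if name != reference:
            pct, lo, hi = bootstrap_percent_change(ref_vals, vals, rng, n_boot)
            rows.append(dict(scenario=name, metric=f"fold_vs_{reference}",
                             value=float(np.nanmean(vals) / np.nanmean(ref_vals)),
                             units="fold"))
            rows.append(dict(scenario=name, metric=f"pct_change_vs_{reference}",
                             value=pct, units="%"))
            rows.append(dict(scenario=name, metric="pct_change_ci_low", value=lo, units="%"))
            rows.append(dict(scenario=name, metric="pct_change_ci_high", value=hi, units="%"))
    return make_summary_table(rows)
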