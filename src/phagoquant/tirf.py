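"""TIRF puncta kinetics: ER-PM contact puncta over time and Boltzmann fits.

STIM1 recruitment to ER-plasma-membrane contact sites after store depletion
appears in the TIRF plane as puncta whose number and mean size rise along a
sigmoidal time course.  Puncta are regions above whole-cell mean + 1 SD
larger than 4 px; the kinetics are summarized by fitting

    y(t) = A1 + (A2 - A1) / (1 + exp((t50 - t) / slope))

where t50 is the half-rise time and slope the Boltzmann slope parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .core_io import ImageStack, LabelMask, label_regions
from .puncta import Punctum, PunctaSet

__all__ = [
    "KineticsFit",
    "detect_tirf_puncta",
    "exclude_baseline_cells",
    "puncta_timeseries",
    "fit_boltzmann",
    "boltzmann",
]


@dataclass
class KineticsFit:
    A1: float
    A2: float
    t50_s: float
    slope_s: float
    rss: float
    converged: bool
    degenerate: bool = False


def boltzmann(t, A1, A2, t50, slope):
    return A1 + (A2 - A1) / (1.0 + np.exp((t50 - t) / slope))


def detect_tirf_puncta(
    frame: ImageStack,
    cell_mask: LabelMask,
    min_area_px: int = 4,
    time: int = 0,
    channel: int = 0,
) -> PunctaSet:
    """Puncta = connected regions above (cell mean + 1 SD) larger than 4 px.

    Threshold statistics are recomputed per frame over within-cell pixels of
    the background-subtracted image.
    """
    cell = cell_mask.foreground
    if not cell.any():
        raise ValueError("cell mask is empty")
    plane = frame.data[channel, time, 0]
    vals = plane[cell]
    threshold = vals.mean() + vals.std()
    above = cell & (plane > threshold)
    comps = label_regions(above, connectivity=8)
    px_area = frame.pixel_size_nm**2
    puncta = []
    for cid in comps.label_ids:
        pix = comps.region(cid)
        n = int(pix.sum())
        if n > min_area_px:
            ys, xs = np.nonzero(pix)
            puncta.append(
                Punctum((float(ys.mean()), float(xs.mean())), n * px_area,
                        float(plane[pix].mean()))
            )
    return PunctaSet(puncta, source_region="whole_cell")


def puncta_timeseries(
    stack: ImageStack, cell_mask: LabelMask
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame puncta count and mean area for one cell.

    Returns (t_s, n_puncta, mean_area_nm2); mean area is NaN on frames with
    no puncta.
    """
    dt = stack.frame_interval_s or 1.0
    t = np.arange(stack.n_frames) * dt
    n = np.zeros(stack.n_frames)
    area = np.full(stack.n_frames, np.nan)
    for i in range(stack.n_frames):
        ps = detect_tirf_puncta(stack, cell_mask, time=i)
        n[i] = ps.count
        if ps.count:
            area[i] = float(np.mean([p.area_nm2 for p in ps.puncta]))
    return t, n, area


def exclude_baseline_cells(
    series_by_cell: dict[int, ImageStack],
    cell_masks: dict[int, LabelMask],
    max_baseline_area_nm2: float = 500.0,
) -> tuple[dict[int, ImageStack], list[int]]:
    """Drop cells showing any punctum above the area bound at frame 0.

    Cells with pre-existing contact-site puncta (>500 nm^2 at baseline)
    cannot report recruitment kinetics and are excluded; returns the kept
    series and the list of excluded cell ids.
    """
    kept, excluded = {}, []
    for cid, stack in series_by_cell.items():
        ps = detect_tirf_puncta(stack, cell_masks[cid], time=0)
        if any(p.area_nm2 > max_baseline_area_nm2 for p in ps.puncta):
            excluded.append(cid)
        else:
            kept[cid] = stack
    return kept, excluded


def fit_boltzmann(t, y, stimulus_time_s: float = 0.0) -> KineticsFit:
    """Least-squares Boltzmann sigmoid fit of a rising track.

    Initialization: A1 = min(y), A2 = max(y), t50 = time of half-range
    crossing, slope = (t_90% - t_10%) / 4.4, with slope bounded positive.
    A constant series returns a degenerate fit (A1 = A2, t50 undefined).
    The reported t50 is relative to ``stimulus_time_s``.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    ok = ~np.isnan(y)
    t, y = t[ok], y[ok]
    if len(t) < 6:
        raise ValueError("need at least 6 points spanning the rise")
    lo, hi = float(y.min()), float(y.max())
    if hi == lo:
        return KineticsFit(lo, hi, float("nan"), float("nan"), 0.0,
                           converged=False, degenerate=True)

    def crossing(frac):
        level = lo + frac * (hi - lo)
        idx = np.argmax(y >= level)
        return t[idx]

    t50_0 = crossing(0.5)
    slope_0 = max((crossing(0.9) - crossing(0.1)) / 4.4, (t[1] - t[0]) / 2.0)
    p0 = [lo, hi, t50_0, slope_0]
    span = t[-1] - t[0]
    rng = hi - lo
    bounds = (
        [lo - 2 * rng, lo - 2 * rng, t[0] - span, 1e-9],
        [hi + 2 * rng, hi + 2 * rng, t[-1] + span, 10 * span],
    )
    try:
        popt, _ = curve_fit(boltzmann, t, y, p0=p0, bounds=bounds, maxfev=20000)
        converged = True
    except RuntimeError:
        popt, converged = p0, False
    resid = y - boltzmann(t, *popt)
    return KineticsFit(
        A1=float(popt[0]),
        A2=float(popt[1]),
        t50_s=float(popt[2] - stimulus_time_s),
        slope_s=float(popt[3]),
        rss=float((resid**2).sum()),
        converged=converged,
    )
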