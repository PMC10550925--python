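"""Ratiometric calcium analysis: Fura-2 SOCE metrics and Fluo-8 hotspots.

Store-operated calcium entry (SOCE) is scored on per-cell F340/F380 ratio
traces as the maximum slope and peak amplitude after extracellular Ca2+
re-addition.  Periphagosomal Ca2+ hotspots are connected regions of Fluo-8
fluorescence at least 2 SD above the cytosolic mean, at least 4 px in area,
within 750 nm of a phagosome border.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core_io import ImageStack, LabelMask, label_regions

__all__ = [
    "RatioTrace",
    "Hotspot",
    "HotspotSet",
    "fura_ratio",
    "soce_metrics",
    "detect_hotspots",
    "phagocytic_index",
]


@dataclass
class RatioTrace:
    """Per-cell F340/F380 ratio time course with Ca2+ re-addition anchor."""

    t_s: np.ndarray
    ratio: np.ndarray
    readd_time_s: float
    cell_id: int = 0
    valid: np.ndarray | None = None  # False where a frame had a zero denominator

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, float)
        self.ratio = np.asarray(self.ratio, float)
        if np.any(np.diff(self.t_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.valid is None:
            self.valid = np.ones_like(self.ratio, bool)


@dataclass
class Hotspot:
    centroid_yx: tuple[float, float]
    area_nm2: float
    peak_f_over_fave: float
    phagosome_id: int


@dataclass
class HotspotSet:
    hotspots: list[Hotspot] = field(default_factory=list)
    f_over_fave: np.ndarray | None = None

    @property
    def count(self) -> int:
        return len(self.hotspots)

    def per_phagosome(self, label_ids) -> dict[int, int]:
        out = {int(i): 0 for i in label_ids}
        for h in self.hotspots:
            out[h.phagosome_id] = out.get(h.phagosome_id, 0) + 1
        return out


def fura_ratio(
    f340: ImageStack,
    f380: ImageStack,
    cell_mask: LabelMask,
    readd_time_s: float = 0.0,
) -> dict[int, RatioTrace]:
    """Per-cell mean(F340)/mean(F380) per frame.

    Frames where the F380 cell mean is zero are flagged invalid (ratio NaN)
    rather than dropped, so traces keep a shared clock.
    """
    if f340.data.shape != f380.data.shape:
        raise ValueError("F340/F380 geometry mismatch")
    dt = f340.frame_interval_s or 3.0
    t = np.arange(f340.n_frames) * dt
    traces = {}
    for cid in cell_mask.label_ids:
        region = cell_mask.region(cid)
        num = f340.data[0, :, 0][:, region].mean(axis=1)
        den = f380.data[0, :, 0][:, region].mean(axis=1)
        valid = den != 0
        ratio = np.full_like(num, np.nan)
        ratio[valid] = num[valid] / den[valid]
        traces[cid] = RatioTrace(t, ratio, readd_time_s, cell_id=cid, valid=valid)
    return traces


def soce_metrics(
    trace: RatioTrace,
    baseline_window_s: float = 30.0,
    slope_window_pts: int = 5,
) -> tuple[float, float]:
    """(max_slope, peak_amplitude) of a SOCE trace after Ca2+ re-addition.

    Baseline is the mean ratio over ``baseline_window_s`` immediately before
    re-addition; peak amplitude is max(post-re-addition ratio) - baseline;
    max slope is the largest least-squares slope over sliding windows of
    ``slope_window_pts`` consecutive post-re-addition samples.
    """
    t, r = trace.t_s, trace.ratio
    pre = (t < trace.readd_time_s) & (t >= trace.readd_time_s - baseline_window_s)
    post = t >= trace.readd_time_s
    if post.sum() < slope_window_pts:
        raise ValueError("too few post-re-addition samples")
    if not pre.any():
        raise ValueError("baseline window empty")
    baseline = float(np.nanmean(r[pre]))
    rp, tp = r[post], t[post]
    peak_amplitude = float(np.nanmax(rp) - baseline)
    w = slope_window_pts
    slopes = []
    for i in range(len(rp) - w + 1):
        ts, ys = tp[i : i + w], rp[i : i + w]
        ok = ~np.isnan(ys)
        if ok.sum() < 2:
            continue
        slopes.append(np.polyfit(ts[ok], ys[ok], 1)[0])
    return float(max(slopes)), peak_amplitude


def detect_hotspots(
    fluo8: ImageStack,
    cyto_mask: LabelMask,
    phag_mask: LabelMask,
    k_sd: float = 2.0,
    max_dist_nm: float = 750.0,
    min_area_px: int = 4,
    avg_frames: int = 2,
) -> HotspotSet:
    """Detect periphagosomal Ca2+ hotspots on a temporally averaged frame.

    The first ``avg_frames`` frames are averaged (6 s at 3 s/frame), the
    threshold is cytosolic mean + ``k_sd`` x SD, and connected
    above-threshold regions of at least ``min_area_px`` pixels lying mostly
    outside the phagosome, whose centroid is within ``max_dist_nm`` of the
    nearest phagosome-border pixel (exact Euclidean distance), are
    hotspots, assigned to the nearest phagosome.  Also returns the F/F_ave
    map (pixel intensity over cytosolic mean).
    """
    cyto = cyto_mask.foreground
    if not cyto.any():
        raise ValueError("cytosol mask is empty")
    navg = min(avg_frames, fluo8.n_frames)
    frame = fluo8.data[0, :navg, 0].mean(axis=0)
    mu = frame[cyto].mean()
    sd = frame[cyto].std()
    threshold = mu + k_sd * sd
    f_over_fave = frame / mu if mu > 0 else np.full_like(frame, np.nan)
    fg = phag_mask.foreground
    out = HotspotSet(f_over_fave=f_over_fave)
    if not fg.any():
        return out
    border = fg & ~ndimage.binary_erosion(fg)
    by, bx = np.nonzero(border)
    tree = cKDTree(np.column_stack([by, bx]))
    comps = label_regions(frame > threshold, connectivity=8)
    px = fluo8.pixel_size_nm
    for cid in comps.label_ids:
        pix = comps.region(cid)
        if pix.sum() < min_area_px:
            continue
        ys, xs = np.nonzero(pix)
        if fg[ys, xs].mean() > 0.5:
            continue  # predominantly intraphagosomal, not periphagosomal
        cyf, cxf = float(ys.mean()), float(xs.mean())
        d_px, nearest = tree.query([cyf, cxf])
        d_nm = float(d_px) * px
        if d_nm > max_dist_nm:
            continue
        pid = int(phag_mask.labels[by[nearest], bx[nearest]])
        out.hotspots.append(
            Hotspot(
                centroid_yx=(float(ys.mean()), float(xs.mean())),
                area_nm2=float(pix.sum() * px**2),
                peak_f_over_fave=float(f_over_fave[pix].max()),
                phagosome_id=pid,
            )
        )
    return out


def phagocytic_index(phag_mask: LabelMask, cell_mask: LabelMask) -> float:
    """Internalized targets per 100 cells."""
    n_cells = len(cell_mask.label_ids)
    if n_cells == 0:
        raise ValueError("no cells in mask")
    return 100.0 * len(phag_mask.label_ids) / n_cells
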