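"""Phagolysosome fusion (FRET), phagosomal pH and antigen degradation.

The phagolysosome fusion (PLF) index is a per-cell measure of lysosomal
acceptor dye delivered into donor-labelled phagosomes: the phagosomal
FRET/donor(green) pixel ratio, averaged per phagosome and summed across the
cell's phagosomes, normalized to the cell's total acceptor (red) loading.
A donor-independent FRET ratio (phagosomal FRET sum over total red) is
reported alongside.

Phagosomal pH is read from dual-excitation FITC ratio images through a
monotone Boltzmann calibration against nigericin/monensin-clamped buffers
spanning pH 4-9.  Antigen degradation is the bead fluorescence of ingested
beads as a percentage of non-ingested (free) beads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .core_io import ImageStack, LabelMask, project
from .tirf import boltzmann

__all__ = [
    "PlfMeasurement",
    "PhCalibration",
    "plf_index",
    "fit_ph_calibration",
    "ratio_to_ph",
    "antigen_remaining",
]


@dataclass
class PlfMeasurement:
    cell_id: int
    plf_index: float
    fret_ratio: float
    acceptor_loading: float
    phagosome_count: int
    excluded_pixel_fraction: float = 0.0
    flagged: bool = False


@dataclass
class PhCalibration:
    buffer_ph: np.ndarray
    mean_ratio: np.ndarray
    A1: float  # ratio plateau at low pH
    A2: float  # ratio plateau at high pH
    pKa: float
    slope: float
    ascending: bool
    valid_range: tuple[float, float]

    def ratio_at(self, ph: float) -> float:
        return float(boltzmann(ph, self.A1, self.A2, self.pKa, self.slope))


def _max_proj_plane(stack: ImageStack, channel: int = 0, time: int = 0) -> np.ndarray:
    return project(stack, "max").data[channel, time, 0]


def plf_index(
    fret: ImageStack,
    green: ImageStack,
    red: ImageStack,
    phag_mask: LabelMask,
    cell_mask: LabelMask,
) -> dict[int, PlfMeasurement]:
    """Per-cell PLF index from registered FRET/green/red stacks.

    All three stacks are max-projected over z.  For each cell: every
    phagosome inside the cell contributes the mean of pixel-wise FRET/green
    over its pixels (zero-green pixels excluded; a phagosome with >50%
    excluded pixels is flagged); the sum over phagosomes is divided by the
    cell's total red (acceptor) fluorescence.  Cells with no phagosome get
    ``plf_index = NaN`` (undefined, flagged), not zero.
    """
    f = _max_proj_plane(fret)
    g = _max_proj_plane(green)
    r = _max_proj_plane(red)
    if not (f.shape == g.shape == r.shape == cell_mask.labels.shape):
        raise ValueError("channel/mask geometry mismatch")
    out = {}
    for cid in cell_mask.label_ids:
        cell = cell_mask.region(cid)
        red_total = float(r[cell].sum())
        phag_ids = [p for p in phag_mask.label_ids if cell[phag_mask.region(p)].any()]
        ratio_sum = 0.0
        fret_sum = 0.0
        n_pix = n_excl = 0
        flagged = False
        for pid in phag_ids:
            pix = phag_mask.region(pid) & cell
            gv, fv = g[pix], f[pix]
            ok = gv != 0
            n_pix += len(gv)
            n_excl += int((~ok).sum())
            if ok.sum() == 0 or ok.mean() < 0.5:
                flagged = True
            if ok.any():
                ratio_sum += float((fv[ok] / gv[ok]).mean())
            fret_sum += float(fv.sum())
        if not phag_ids:
            out[cid] = PlfMeasurement(cid, float("nan"), float("nan"), red_total, 0,
                                      flagged=True)
            continue
        if red_total == 0:
            raise ValueError(f"cell {cid}: zero acceptor loading")
        out[cid] = PlfMeasurement(
            cell_id=cid,
            plf_index=ratio_sum / red_total,
            fret_ratio=fret_sum / red_total,
            acceptor_loading=red_total,
            phagosome_count=len(phag_ids),
            excluded_pixel_fraction=(n_excl / n_pix) if n_pix else 0.0,
            flagged=flagged,
        )
    return out


def fit_ph_calibration(
    images_by_buffer: dict[float, list[tuple[ImageStack, ImageStack]]],
    roi: LabelMask | None = None,
) -> PhCalibration:
    """Fit a monotone Boltzmann of (440/480 excitation ratio) vs buffer pH.

    ``images_by_buffer`` maps buffer pH to replicate (num, den) excitation
    image pairs; the per-buffer mean ratio is taken over the ROI (whole
    frame if none).  Requires >= 4 distinct pH points spanning >= 3 pH
    units and strictly monotone buffer means; the curve direction is
    auto-detected from the means.
    """
    phs = np.array(sorted(images_by_buffer), float)
    if len(phs) < 4 or phs.max() - phs.min() < 3.0:
        raise ValueError("need >= 4 buffers spanning >= 3 pH units")
    means = []
    for ph in phs:
        vals = []
        for num, den in images_by_buffer[ph]:
            a = _max_proj_plane(num)
            b = _max_proj_plane(den)
            sel = roi.foreground if roi is not None else np.ones_like(a, bool)
            ok = sel & (b != 0)
            vals.append(float((a[ok] / b[ok]).mean()))
        means.append(np.mean(vals))
    means = np.array(means)
    diffs = np.diff(means)
    if np.all(diffs > 0):
        ascending = True
    elif np.all(diffs < 0):
        ascending = False
    else:
        raise ValueError("buffer mean ratios are not monotone in pH; fit rejected")
    lo, hi = float(means.min()), float(means.max())
    rng = hi - lo
    p0 = [means[0], means[-1], float(np.median(phs)), 1.0]
    bounds = ([lo - 2 * rng, lo - 2 * rng, phs.min() - 3, 1e-3],
              [hi + 2 * rng, hi + 2 * rng, phs.max() + 3, 10.0])
    popt, _ = curve_fit(boltzmann, phs, means, p0=p0, bounds=bounds, maxfev=20000)
    cal = PhCalibration(
        buffer_ph=phs, mean_ratio=means,
        A1=float(popt[0]), A2=float(popt[1]), pKa=float(popt[2]),
        slope=float(popt[3]), ascending=ascending,
        valid_range=(float(phs.min()), float(phs.max())),
    )
    # round-trip sanity at the buffer points
    err = max(abs(ratio_to_ph(cal.ratio_at(p), cal) - p) for p in phs)
    if err > 0.25:
        raise ValueError(f"calibration round-trip error {err:.2f} pH units; fit rejected")
    return cal


def ratio_to_ph(ratio: float, cal: PhCalibration) -> float:
    """Invert the calibration Boltzmann; out-of-range ratios clamp with a warning."""
    lo_ratio = cal.ratio_at(cal.valid_range[0])
    hi_ratio = cal.ratio_at(cal.valid_range[1])
    rmin, rmax = sorted((lo_ratio, hi_ratio))
    if not rmin <= ratio <= rmax:
        warnings.warn(
            f"ratio {ratio:.3g} outside calibrated range [{rmin:.3g}, {rmax:.3g}]; clamped",
            stacklevel=2,
        )
        ratio = min(max(ratio, rmin), rmax)
    # y = A1 + (A2-A1)/(1+exp((pKa-x)/s))  =>  x = pKa - s*ln((A2-A1)/(y-A1) - 1)
    frac = (cal.A2 - cal.A1) / (ratio - cal.A1) - 1.0
    eps = 1e-12
    frac = max(frac, eps)
    ph = cal.pKa - cal.slope * np.log(frac)
    return float(min(max(ph, cal.valid_range[0]), cal.valid_range[1]))


def antigen_remaining(
    img: ImageStack,
    ingested_rois: LabelMask,
    free_rois: LabelMask,
) -> dict[int, float]:
    """Percent antigen remaining per ingested bead.

    100 x (mean intensity of each ingested-bead ROI) / (mean intensity over
    all free-bead ROI pixels), measured on the sum projection.
    """
    plane = project(img, "sum").data[0, 0, 0]
    free = free_rois.foreground
    if not free.any():
        raise ValueError("need at least one free (non-ingested) bead ROI")
    free_mean = float(plane[free].mean())
    if free_mean == 0:
        raise ValueError("zero free-bead mean intensity")
    return {
        pid: 100.0 * float(plane[ingested_rois.region(pid)].mean()) / free_mean
        for pid in ingested_rois.label_ids
    }
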