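"""Periphagosomal puncta counting in a fixed-width ring outside the phagosome.

Recruitment of contact-site reporters (e.g. the artificial tether MAPPER)
is scored as the number of punctate structures larger than 0.01 um^2 found
in a 0.2 um annulus just outside each phagosome border, using a threshold
of cytosolic mean + 2 SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core_io import ImageStack, LabelMask, label_regions, make_summary_table

__all__ = [
    "Punctum",
    "PunctaSet",
    "make_ring",
    "make_cytosol_mask",
    "detect_ring_puncta",
    "recruitment_summary",
    "auto_threshold",
]


@dataclass
class Punctum:
    centroid_yx: tuple[float, float]
    area_nm2: float
    mean_intensity: float


@dataclass
class PunctaSet:
    puncta: list[Punctum]
    source_region: str = "ring"

    @property
    def count(self) -> int:
        return len(self.puncta)


def make_ring(phagosome_mask: LabelMask, pixel_size_nm: float, width_um: float = 0.2) -> LabelMask:
    """Annulus of pixels outside each phagosome within ``width_um`` of its border.

    Each ring pixel carries the label of its nearest phagosome, so
    overlapping rings of adjacent phagosomes are partitioned without double
    counting.
    """
    width_px = width_um * 1000.0 / pixel_size_nm
    if width_px < 1.0:
        raise ValueError(f"ring width {width_um} um is below one pixel")
    fg = phagosome_mask.foreground
    if not fg.any():
        return LabelMask(np.zeros_like(phagosome_mask.labels), role="ring")
    dist, (iy, ix) = ndimage.distance_transform_edt(~fg, return_indices=True)
    ring = (dist > 0) & (dist <= width_px)
    labels = np.zeros_like(phagosome_mask.labels)
    labels[ring] = phagosome_mask.labels[iy[ring], ix[ring]]
    return LabelMask(labels, role="ring")


def make_cytosol_mask(phag_mask: LabelMask, margin_px: float = 12.0) -> LabelMask:
    """Cytosolic reference region: pixels farther than ``margin_px`` from any phagosome.

    Used for the automatic threshold so periphagosomal structures do not
    contaminate the background statistics.
    """
    dist = ndimage.distance_transform_edt(~phag_mask.foreground)
    return LabelMask((dist > margin_px).astype(np.int32), role="cytosol")


def auto_threshold(img_plane: np.ndarray, cytosol: LabelMask, k_sd: float = 2.0) -> float:
    """Cytosolic mean + ``k_sd`` standard deviations of cytosolic pixels."""
    vals = img_plane[cytosol.foreground]
    if vals.size == 0:
        raise ValueError("cytosol mask is empty")
    return float(vals.mean() + k_sd * vals.std())


def detect_ring_puncta(
    img: ImageStack,
    ring: LabelMask,
    threshold="auto",
    min_area_um2: float = 0.01,
    cytosol: LabelMask | None = None,
    connectivity: int = 8,
    channel: int = 0,
    time: int = 0,
) -> dict[int, PunctaSet]:
    """Count above-threshold puncta inside each phagosome's ring.

    Puncta are connected components of strictly-above-threshold ring pixels
    with area strictly greater than ``min_area_um2``.  ``threshold="auto"``
    uses cytosolic mean + 2 SD (requires ``cytosol``).  Returns one
    :class:`PunctaSet` per phagosome label present in the ring mask.
    """
    plane = np.max(img.data[channel, time], axis=0)  # max projection over z
    if threshold == "auto":
        if cytosol is None:
            raise ValueError('threshold="auto" requires a cytosol mask')
        threshold = auto_threshold(plane, cytosol)
    threshold = float(threshold)
    px_area_nm2 = img.pixel_size_nm**2
    min_area_nm2 = min_area_um2 * 1e6
    out: dict[int, PunctaSet] = {}
    ring_ids = ring.label_ids
    if not ring_ids:
        warnings.warn("ring mask is empty; no puncta counted", stacklevel=2)
    for pid in ring_ids:
        region = ring.region(pid)
        above = region & (plane > threshold)
        comps = label_regions(above, connectivity=connectivity)
        puncta = []
        for cid in comps.label_ids:
            pix = comps.region(cid)
            area_nm2 = pix.sum() * px_area_nm2
            if area_nm2 > min_area_nm2:
                ys, xs = np.nonzero(pix)
                puncta.append(
                    Punctum(
                        centroid_yx=(float(ys.mean()), float(xs.mean())),
                        area_nm2=float(area_nm2),
                        mean_intensity=float(plane[pix].mean()),
                    )
                )
        out[pid] = PunctaSet(puncta, source_region="ring")
    return out


def bootstrap_percent_change(
    counts_ref: np.ndarray,
    counts_other: np.ndarray,
    rng: np.random.Generator,
    n_boot: int = 10_000,
) -> tuple[float, float, float]:
    """Percent change of means (other vs ref) with a bootstrap 95% CI."""
    ref = np.asarray(counts_ref, float)
    oth = np.asarray(counts_other, float)
    point = 100.0 * (oth.mean() / ref.mean() - 1.0)
    idx_r = rng.integers(0, len(ref), size=(n_boot, len(ref)))
    idx_o = rng.integers(0, len(oth), size=(n_boot, len(oth)))
    means_r = ref[idx_r].mean(axis=1)
    means_o = oth[idx_o].mean(axis=1)
    reps = 100.0 * (means_o / means_r - 1.0)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return float(point), float(lo), float(hi)


def recruitment_summary(
    counts_by_scenario: dict[str, np.ndarray],
    reference: str,
    seed: int = 0,
    n_boot: int = 10_000,
) -> pd.DataFrame:
    """Per-scenario mean +/- SEM and percent change vs a reference scenario.

    Percent changes carry a seeded bootstrap 95% CI over per-phagosome
    counts (``n_boot`` resamples).
    """
    if reference not in counts_by_scenario:
        raise ValueError(f"reference scenario {reference!r} absent")
    rng = np.random.default_rng(seed)
    rows = []
    for name, counts in counts_by_scenario.items():
        counts = np.asarray(counts, float)
        n = len(counts)
        sem = counts.std(ddof=1) / np.sqrt(n) if n > 1 else float("nan")
        rows.append(dict(scenario=name, metric="mean_count", value=float(counts.mean()),
                         units="puncta/phagosome"))
        rows.append(dict(scenario=name, metric="sem", value=float(sem), units="puncta/phagosome"))
        rows.append(dict(scenario=name, metric="n", value=float(n), units="phagosomes"))
        if name != reference:
            pct, lo, hi = bootstrap_percent_change(
                np.asarray(counts_by_scenario[reference], float), counts, rng, n_boot
            )
            rows.append(dict(scenario=name, metric=f"pct_change_vs_{reference}",
                             value=pct, units="%"))
            rows.append(dict(scenario=name, metric="pct_change_ci_low", value=lo, units="%"))
            rows.append(dict(scenario=name, metric="pct_change_ci_high", value=hi, units="%"))
    return make_summary_table(rows)
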