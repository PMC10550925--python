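"""ER-phagosome membrane contact sites on 2-D EM cross-section profiles.

A contact site is a stretch of ER membrane running within a fixed gap
(default 30 nm) of the phagosomal membrane.  Profiles are abstracted as a
closed phagosome boundary polyline plus open ER polylines, all in nm.  The
detector samples each ER polyline at 1 nm arc steps, thresholds the
point-to-boundary distance, and reports maximal contiguous runs as contacts
with their along-membrane arc length.  Only cross-sections more than 1 um
in diameter are analyzed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import stats

from .core_io import make_summary_table

__all__ = [
    "EMProfile",
    "Contact",
    "ContactSet",
    "detect_contacts",
    "filter_profiles",
    "contact_stats",
    "variance_f_test",
    "profiles_to_json",
    "profiles_from_json",
]


@dataclass
class EMProfile:
    """One phagosome cross-section: boundary plus ER membrane polylines (nm)."""

    phagosome_boundary: np.ndarray  # (n, 2) closed polyline, nm
    er_segments: list[np.ndarray]  # each (m, 2) open polyline, nm
    phagosome_diameter_nm: float
    phagosome_id: int = 0

    def __post_init__(self) -> None:
        self.phagosome_boundary = np.asarray(self.phagosome_boundary, float)
        self.er_segments = [np.asarray(s, float) for s in self.er_segments]
        ext = self.phagosome_boundary.max(0) - self.phagosome_boundary.min(0)
        if self.phagosome_diameter_nm <= 0 or not np.isfinite(ext).all():
            raise ValueError("invalid profile geometry")


@dataclass
class Contact:
    segment_id: int
    arc_length_nm: float
    min_gap_nm: float


@dataclass
class ContactSet:
    phagosome_id: int
    contacts: list[Contact] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.contacts)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([c.arc_length_nm for c in self.contacts], float)


def _resample_polyline(points: np.ndarray, step_nm: float) -> tuple[np.ndarray, float]:
    """Resample an open polyline at even arc-length steps; returns (points, step)."""
    seg = np.diff(points, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    total = float(seglen.sum())
    if total == 0.0:
        return points[:1], 0.0
    n = max(int(np.ceil(total / step_nm)), 1)
    s = np.linspace(0.0, total, n + 1)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    x = np.interp(s, cum, points[:, 0])
    y = np.interp(s, cum, points[:, 1])
    return np.column_stack([x, y]), total / n


def detect_contacts(
    profile: EMProfile,
    gap_max_nm: float = 30.0,
    min_run_nm: float = 20.0,
    sample_step_nm: float = 1.0,
) -> ContactSet:
    """Find maximal ER sub-arcs lying within ``gap_max_nm`` of the boundary.

    Each ER polyline is resampled at ``sample_step_nm`` arc steps and the
    Euclidean distance of every sample to the boundary is thresholded
    (``<= gap_max_nm``); contiguous runs longer than ``min_run_nm`` are
    returned as contacts with arc length measured along the ER polyline.
    """
    if gap_max_nm <= 0:
        raise ValueError("gap_max_nm must be > 0")
    boundary = shapely.LinearRing(profile.phagosome_boundary)
    out = ContactSet(phagosome_id=profile.phagosome_id)
    for seg_id, seg in enumerate(profile.er_segments):
        if len(seg) < 2:
            warnings.warn(f"segment {seg_id}: degenerate polyline skipped", stacklevel=2)
            continue
        pts, step = _resample_polyline(seg, sample_step_nm)
        if step == 0.0:
            warnings.warn(f"segment {seg_id}: zero-length polyline skipped", stacklevel=2)
            continue
        gaps = shapely.distance(shapely.points(pts), boundary)
        close = gaps <= gap_max_nm
        # run boundaries over the sampled gap function
        padded = np.concatenate([[False], close, [False]])
        starts = np.flatnonzero(padded[1:] & ~padded[:-1])
        ends = np.flatnonzero(~padded[1:] & padded[:-1])
        for a, b in zip(starts, ends):
            length = (b - 1 - a) * step
            if length >= min_run_nm:
                out.contacts.append(
                    Contact(seg_id, float(length), float(gaps[a:b].min()))
                )
    return out


def filter_profiles(
    profiles: list[EMProfile], min_diameter_um: float = 1.0
) -> list[EMProfile]:
    """Keep profiles whose cross-section diameter strictly exceeds the bound."""
    return [p for p in profiles if p.phagosome_diameter_nm > min_diameter_um * 1000.0]


def contact_stats(
    sets: list[ContactSet],
    scenario: str = "",
    large_contact_nm: float = 400.0,
) -> pd.DataFrame:
    """Cohort summary: contact frequency, length stats, large-contact fraction."""
    if not sets:
        raise ValueError("need at least one phagosome")
    counts = np.array([s.count for s in sets], float)
    lengths = np.concatenate([s.lengths for s in sets]) if counts.sum() else np.array([])
    rows = [
        dict(scenario=scenario, metric="mean_contacts_per_phagosome",
             value=float(counts.mean()), units="contacts/phagosome"),
        dict(scenario=scenario, metric="n_phagosomes", value=float(len(sets)), units="count"),
        dict(scenario=scenario, metric="n_contacts", value=float(len(lengths)), units="count"),
    ]
    if len(lengths):
        rows += [
            dict(scenario=scenario, metric="median_contact_length",
                 value=float(np.median(lengths)), units="nm"),
            dict(scenario=scenario, metric="mean_contact_length",
                 value=float(lengths.mean()), units="nm"),
            dict(scenario=scenario, metric="large_contact_fraction",
                 value=float((lengths > large_contact_nm).mean()), units="fraction"),
        ]
    else:
        rows.append(dict(scenario=scenario, metric="length_stats_undefined",
                         value=float("nan"), units=""))
    return make_summary_table(rows)


def pooled_lengths(sets: list[ContactSet]) -> np.ndarray:
    arrays = [s.lengths for s in sets if s.count]
    return np.concatenate(arrays) if arrays else np.array([])


def variance_f_test(lengths_a, lengths_b) -> tuple[float, float]:
    """Two-sided F-test for equality of variances of two length samples.

    F is the ratio of the larger to the smaller sample variance (n-1
    denominators); p is twice the upper tail of the F distribution with
    matching degrees of freedom (capped at 1).
    """
    a = np.asarray(lengths_a, float)
    b = np.asarray(lengths_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 or vb == 0:
        raise ValueError("zero-variance sample")
    if va >= vb:
        F, dfn, dfd = va / vb, len(a) - 1, len(b) - 1
    else:
        F, dfn, dfd = vb / va, len(b) - 1, len(a) - 1
    p = min(1.0, 2.0 * stats.f.sf(F, dfn, dfd))
    return float(F), float(p)


# ---------------------------------------------------------------------------
# Profile serialization (JSON, nm units)


def profiles_to_json(profiles: list[EMProfile]) -> str:
    return json.dumps(
        [
            {
                "phagosome_id": p.phagosome_id,
                "phagosome_diameter_nm": p.phagosome_diameter_nm,
                "boundary": p.phagosome_boundary.tolist(),
                "er_segments": [s.tolist() for s in p.er_segments],
            }
            for p in profiles
        ]
    )


def profiles_from_json(text: str) -> list[EMProfile]:
    return [
        EMProfile(
            phagosome_boundary=np.array(d["boundary"], float),
            er_segments=[np.array(s, float) for s in d["er_segments"]],
            phagosome_diameter_nm=float(d["phagosome_diameter_nm"]),
            phagosome_id=int(d.get("phagosome_id", i)),
        )
        for i, d in enumerate(json.loads(text))
    ]
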