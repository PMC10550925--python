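"""Independent brute-force oracles used to cross-check the detectors.

Deliberately naive implementations (explicit flood fill, per-pixel scans,
dense 1-nm sampling against the exact circle) that share no code with the
library paths they verify.
"""

from __future__ import annotations

import numpy as np


def flood_fill_label(binary: np.ndarray, connectivity: int) -> tuple[np.ndarray, int]:
    """Stack-based flood fill connected-component labeling."""
    binary = np.asarray(binary, bool)
    h, w = binary.shape
    labels = np.zeros((h, w), dtype=int)
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    n = 0
    for y in range(h):
        for x in range(w):
            if binary[y, x] and labels[y, x] == 0:
                n += 1
                stack = [(y, x)]
                labels[y, x] = n
                while stack:
                    cy, cx = stack.pop()
                    for dy, dx in nbrs:
                        ny, nx = cy + dy, cx + dx
                        if 0 <= ny < h and 0 <= nx < w and binary[ny, nx] and labels[ny, nx] == 0:
                            labels[ny, nx] = n
                            stack.append((ny, nx))
    return labels, n


def brute_force_puncta_count(
    plane: np.ndarray,
    region: np.ndarray,
    threshold: float,
    min_area_px: int,
    connectivity: int = 8,
) -> int:
    """Explicit pixel scan + flood fill + strict area filter."""
    above = region & (plane > threshold)
    labels, n = flood_fill_label(above, connectivity)
    count = 0
    for lab in range(1, n + 1):
        if (labels == lab).sum() > min_area_px:
            count += 1
    return count


def brute_force_components_with_area(
    plane: np.ndarray, threshold: float, min_area_px: int
) -> list[tuple[float, float, int]]:
    """(centroid_y, centroid_x, area) of every 8-connected region >= min area."""
    labels, n = flood_fill_label(plane > threshold, 8)
    out = []
    for lab in range(1, n + 1):
        ys, xs = np.nonzero(labels == lab)
        if len(ys) >= min_area_px:
            out.append((float(ys.mean()), float(xs.mean()), len(ys)))
    return out


def min_dist_to_mask_px(cy: float, cx: float, mask: np.ndarray) -> float:
    """Brute-force minimum Euclidean distance from a point to any True pixel."""
    ys, xs = np.nonzero(mask)
    if len(ys) == 0:
        return float("inf")
    return float(np.sqrt((ys - cy) ** 2 + (xs - cx) ** 2).min())


def circle_contact_runs(
    er_polyline: np.ndarray,
    center: tuple[float, float],
    radius_nm: float,
    gap_max_nm: float,
    min_run_nm: float,
    step_nm: float = 1.0,
) -> list[float]:
    """Contact run lengths of an ER polyline against an exact circle boundary.

    Samples the polyline densely by walking its vertices at ``step_nm`` arc
    increments and thresholds |distance to center - radius|; independent of
    the shapely-based detector path.
    """
    pts = np.asarray(er_polyline, float)
    seg = np.diff(pts, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    total = seglen.sum()
    if total == 0:
        return []
    n = max(int(np.ceil(total / step_nm)), 1)
    s = np.linspace(0.0, total, n + 1)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    x = np.interp(s, cum, pts[:, 0])
    y = np.interp(s, cum, pts[:, 1])
    gap = np.abs(np.hypot(x - center[0], y - center[1]) - radius_nm)
    close = gap <= gap_max_nm
    runs, run_start = [], None
    for i, c in enumerate(close):
        if c and run_start is None:
            run_start = i
        elif not c and run_start is not None:
            runs.append((i - 1 - run_start) * (total / n))
            run_start = None
    if run_start is not None:
        runs.append((len(close) - 1 - run_start) * (total / n))
    return [r for r in runs if r >= min_run_nm]
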