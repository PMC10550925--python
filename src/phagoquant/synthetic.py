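"""Scenario-driven synthetic data generators with recorded ground truth.

Every assay input the quantification modules consume can be generated here
with known ground truth, so each pipeline stage is testable end to end:
EM cross-section profiles with ER contact arcs, ring-puncta images, Fluo-8
hotspot frames, TIRF time-lapses with sigmoidally growing puncta,
per-phagosome lipid enrichment time-lapses, three-channel FRET fusion
stacks, dual-excitation pH images with buffer calibration series, Fura-2
ratio traces, and antigen-bead images.

Scenario presets encode the measured condition contrasts between control
(shCTR) and Sec22b-knockdown (shSec22b) phagocytes: contact frequency 4.5
vs 3.0 per phagosome, median contact length 93 vs 81 nm with a 3%
population of >400 nm contacts unique to the knockdown, ~50% loss of
MAPPER ring puncta, 2.5-fold higher PI(4)P 5-25 min after the initial
peak, ~45% lower PI(3)P 5-10 min after ingestion, ~20% lower PS, a
1.5-fold higher phagolysosome-fusion index, and the ORP8 rescue (-35%
PI(4)P at peak, -48% at 5-25 min vs a KDEL control in the knockdown
background).

Counts are drawn by fixed-cohort-total multinomial allocation: the cohort
total is ``round(rate * n)`` and events are assigned uniformly across
entities.  Marginal counts are binomial(T, 1/n), indistinguishable from
Poisson(rate) at these sizes, but the cohort mean is pinned to the
configured rate, so recovery error measures the detection pipeline rather
than count sampling noise.  Structured populations (large contacts,
fluctuating lipid tracks) use exact ``round(fraction * n)`` allocation for
the same reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator
from scipy import ndimage

from .calcium import RatioTrace
from .core_io import ImageStack, LabelMask
from .em_contacts import EMProfile
from .tirf import boltzmann

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "PRESETS",
    "preset",
    "gen_em_profiles",
    "gen_ring_puncta_image",
    "gen_fluo8_frame",
    "gen_tirf_series",
    "gen_lipid_tracks",
    "gen_lipid_timelapse",
    "gen_plf_stacks",
    "gen_ph_images",
    "gen_fura_traces",
    "gen_antigen_image",
]


class ScenarioConfig(BaseModel):
    """All generator parameters for one named experimental condition.

    The same seed and parameters always produce bit-identical outputs.
    """

    name: str
    seed: int = 0
    pixel_size_nm: float = Field(50.0, gt=0)
    noise_sd: float = Field(8.0, ge=0)

    # EM contact sites
    contact_rate: float = Field(4.5, ge=0)  # mean contacts per phagosome
    contact_length_median_nm: float = Field(93.0, gt=0)
    contact_length_sigma: float = Field(0.4, gt=0)  # lognormal shape
    large_contact_fraction: float = Field(0.0, ge=0, le=1)
    large_contact_min_nm: float = Field(400.0, gt=0)

    # ring puncta / hotspots
    puncta_rate: float = Field(6.0, ge=0)
    hotspot_rate: float = Field(1.2, ge=0)

    # lipid enrichment tracks
    lipid_peak: float = Field(2.0, ge=0)
    lipid_window_level: float = Field(0.2, ge=0)  # target cohort window mean
    lipid_window_start_min: float = 5.0
    lipid_window_end_min: float = 25.0
    lipid_window_anchor: str = "peak"  # "peak" | "ingestion" | "full"
    fluctuating_fraction: float = Field(0.3, ge=0, le=1)

    # fusion / pH / SOCE / antigen / TIRF
    plf_level: float = Field(6e-6, ge=0)
    phagosomes_per_cell: float = Field(3.0, gt=0)
    ph_true: float = Field(6.0, ge=4, le=9)
    soce_peak: float = Field(0.5, ge=0)
    antigen_remaining_pct: float = Field(65.0, ge=0)
    tirf_t50_s: float = Field(180.0, gt=0)
    tirf_slope_s: float = Field(30.0, gt=0)
    tirf_n_final: int = Field(18, ge=0)

    @field_validator("lipid_window_anchor")
    @classmethod
    def _anchor_ok(cls, v):
        if v not in ("peak", "ingestion", "full"):
            raise ValueError("anchor must be peak, ingestion or full")
        return v

    def with_seed(self, seed: int) -> "ScenarioConfig":
        return self.model_copy(update={"seed": int(seed)})


@dataclass
class GroundTruth:
    """Per-entity true values emitted by a generator, one record per structure."""

    records: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def values(self, metric: str) -> np.ndarray:
        return np.array([r["value"] for r in self.records if r["metric"] == metric])


# ---------------------------------------------------------------------------
# Scenario presets: the measured condition contrasts as generator truth.

_BASE = dict(pixel_size_nm=50.0, noise_sd=8.0)

PRESETS: dict[str, ScenarioConfig] = {}


def _register(name: str, **kw) -> None:
    PRESETS[name] = ScenarioConfig(name=name, **{**_BASE, **kw})


# Core condition pair. Contact frequency 4.5 vs 3.0 per phagosome; median
# contact length 93 vs 81 nm; 3% of knockdown contacts very large (>400 nm);
# MAPPER ring puncta halved by the knockdown; hotspot frequency and
# phagocytic index unchanged; PLF index 1.5-fold higher in the knockdown;
# small SOCE peak-amplitude increase; phagosomal pH unchanged.
_register(
    "shCTR",
    contact_rate=4.5, contact_length_median_nm=93.0, large_contact_fraction=0.0,
    puncta_rate=6.0, hotspot_rate=1.2, plf_level=6e-6, soce_peak=0.50,
    ph_true=6.0, antigen_remaining_pct=65.0,
)
_register(
    "shSec22b",
    contact_rate=3.0, contact_length_median_nm=81.0, large_contact_fraction=0.03,
    puncta_rate=3.0, hotspot_rate=1.2, plf_level=9e-6, soce_peak=0.58,
    ph_true=6.0, antigen_remaining_pct=45.0,
)

# Lipid-probe scenarios. Window levels are the cohort mean enrichment over
# the probe's reporting window; the PI(4)P window is anchored to the initial
# peak, the PI(3)P window to ingestion start, PS uses the full observation.
_LIPID = dict(hotspot_rate=0.0)
_register("pi4p:shCTR", lipid_peak=2.0, lipid_window_level=0.20,
          fluctuating_fraction=0.3, lipid_window_anchor="peak",
          lipid_window_start_min=5, lipid_window_end_min=25, **_LIPID)
_register("pi4p:shSec22b", lipid_peak=2.0, lipid_window_level=0.50,
          fluctuating_fraction=0.6, lipid_window_anchor="peak",
          lipid_window_start_min=5, lipid_window_end_min=25, **_LIPID)
_register("pi3p:shCTR", lipid_peak=1.5, lipid_window_level=1.00,
          fluctuating_fraction=1.0, lipid_window_anchor="ingestion",
          lipid_window_start_min=5, lipid_window_end_min=10, **_LIPID)
_register("pi3p:shSec22b", lipid_peak=1.5, lipid_window_level=0.55,
          fluctuating_fraction=1.0, lipid_window_anchor="ingestion",
          lipid_window_start_min=5, lipid_window_end_min=10, **_LIPID)
_register("ps:shCTR", lipid_peak=0.8, lipid_window_level=0.50,
          fluctuating_fraction=1.0, lipid_window_anchor="full", **_LIPID)
_register("ps:shSec22b", lipid_peak=0.8, lipid_window_level=0.40,
          fluctuating_fraction=1.0, lipid_window_anchor="full", **_LIPID)
_register("pip2:shCTR", lipid_peak=1.0, lipid_window_level=0.30,
          fluctuating_fraction=1.0, lipid_window_anchor="peak",
          lipid_window_start_min=5, lipid_window_end_min=25, **_LIPID)
_register("pip2:shSec22b", lipid_peak=1.0, lipid_window_level=0.30,
          fluctuating_fraction=1.0, lipid_window_anchor="peak",
          lipid_window_start_min=5, lipid_window_end_min=25, **_LIPID)
# ORP8 rescue in the knockdown background: wild-type ORP8 lowers PI(4)P by
# 35% at peak and 48% over 5-25 min vs the ER-marker (KDEL) control; the
# lipid-transfer-dead mutant does not.
_register("pi4p:shSec22b+KDEL", lipid_peak=2.0, lipid_window_level=0.50,
          fluctuating_fraction=0.6, lipid_window_anchor="peak",
          lipid_window_start_min=5, lipid_window_end_min=25, **_LIPID)
_register("pi4p:shSec22b+ORP8", lipid_peak=1.3, lipid_window_level=0.26,
          fluctuating_fraction=0.6, lipid_window_anchor="peak",
          lipid_window_start_min=5, lipid_window_end_min=25, **_LIPID)
_register("pi4p:shSec22b+ORP8-Mut", lipid_peak=2.0, lipid_window_level=0.50,
          fluctuating_fraction=0.6, lipid_window_anchor="peak",
          lipid_window_start_min=5, lipid_window_end_min=25, **_LIPID)
_register("pi4p:shSec22b+MAPPER", lipid_peak=2.0, lipid_window_level=0.20,
          fluctuating_fraction=0.3, lipid_window_anchor="peak",
          lipid_window_start_min=5, lipid_window_end_min=25, **_LIPID)
_register("pi4p:shSec22b+Sec22b", lipid_peak=2.0, lipid_window_level=0.20,
          fluctuating_fraction=0.3, lipid_window_anchor="peak",
          lipid_window_start_min=5, lipid_window_end_min=25, **_LIPID)
_register("pi4p:siCTR", lipid_peak=2.0, lipid_window_level=0.20,
          fluctuating_fraction=0.3, lipid_window_anchor="peak",
          lipid_window_start_min=5, lipid_window_end_min=25, **_LIPID)
_register("pi4p:siORP5/8", lipid_peak=2.0, lipid_window_level=0.30,
          fluctuating_fraction=0.45, lipid_window_anchor="peak",
          lipid_window_start_min=5, lipid_window_end_min=25, **_LIPID)


def preset(name: str, seed: int | None = None) -> ScenarioConfig:
    """Look up a named scenario preset, optionally re-seeded."""
    cfg = PRESETS[name]
    return cfg.with_seed(seed) if seed is not None else cfg.model_copy()


# ---------------------------------------------------------------------------
# Count allocation helpers (see module docstring).


def _alloc_counts(rng: np.random.Generator, rate: float, n: int) -> np.ndarray:
    """Counts with cohort total round(rate*n), split uniformly over n entities."""
    total = int(round(rate * n))
    if total == 0:
        return np.zeros(n, dtype=int)
    return np.bincount(rng.integers(0, n, size=total), minlength=n)


def _alloc_flags(rng: np.random.Generator, fraction: float, n: int) -> np.ndarray:
    """Boolean flags with exactly round(fraction*n) True, positions random."""
    flags = np.zeros(n, dtype=bool)
    k = int(round(fraction * n))
    if k > 0:
        flags[rng.choice(n, size=min(k, n), replace=False)] = True
    return flags


def _spread_angles(rng: np.random.Generator, k: int, min_sep_rad: float) -> np.ndarray:
    """k angles on the circle with pairwise separation >= ~min_sep_rad.

    Stratified placement: equally spaced slots with jitter bounded to a
    quarter slot, plus a random global rotation.  Keeps rendered structures
    resolvable so counting is not confounded by merging.
    """
    if k == 0:
        return np.array([])
    slot = 2 * np.pi / k
    jitter_amp = min(0.25 * slot, max(0.0, (slot - min_sep_rad) / 2.0))
    jitter = rng.uniform(-1.0, 1.0, size=k) * jitter_amp
    return (rng.uniform(0, 2 * np.pi) + np.arange(k) * slot + jitter) % (2 * np.pi)


# ---------------------------------------------------------------------------
# Electron-microscopy cross-section profiles


def gen_em_profiles(
    cfg: ScenarioConfig, n_phagosomes: int
) -> tuple[list[EMProfile], GroundTruth]:
    """Synthetic 2-D EM cross-sections with ER contact arcs and distractors.

    Each profile is a circular phagosome boundary of diameter 1.5-3 um.
    Contacts are ER arcs held 5-25 nm off the boundary with lognormal arc
    lengths (configured median and shape); a configured fraction is replaced
    by very large contacts uniform on [large_min, 1.5*large_min].
    Distractor ER arcs sit 60-300 nm away and must not be detected.
    """
    if n_phagosomes < 1:
        raise ValueError("n_phagosomes must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    counts = _alloc_counts(rng, cfg.contact_rate, n_phagosomes)
    total = int(counts.sum())
    lengths = np.exp(
        rng.normal(np.log(cfg.contact_length_median_nm), cfg.contact_length_sigma, total)
    )
    large = _alloc_flags(rng, cfg.large_contact_fraction, total)
    lengths[large] = rng.uniform(
        cfg.large_contact_min_nm, 1.5 * cfg.large_contact_min_nm, int(large.sum())
    )
    profiles, gt = [], GroundTruth()
    idx = 0
    for i in range(n_phagosomes):
        radius = rng.uniform(750.0, 1500.0)
        theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        boundary = radius * np.column_stack([np.cos(theta), np.sin(theta)])
        segments = []
        k = int(counts[i])
        angles = _spread_angles(rng, k, 0.0)
        for j in range(k):
            length = float(lengths[idx])
            gap = rng.uniform(5.0, 25.0)
            r = radius + gap
            arc = length / r
            a0 = angles[j] if k else 0.0
            npts = max(int(np.ceil(length / 2.0)) + 1, 2)
            ang = np.linspace(a0, a0 + arc, npts)
            segments.append(r * np.column_stack([np.cos(ang), np.sin(ang)]))
            gt.records.append(dict(phagosome_id=i, metric="contact_length_nm",
                                   value=length, is_large=bool(large[idx])))
            idx += 1
        for _ in range(int(rng.integers(2, 6))):
            d = rng.uniform(60.0, 300.0)
            dl = rng.uniform(100.0, 500.0)
            r = radius + d
            a0 = rng.uniform(0, 2 * np.pi)
            ang = np.linspace(a0, a0 + dl / r, max(int(dl / 4), 2))
            segments.append(r * np.column_stack([np.cos(ang), np.sin(ang)]))
        profiles.append(
            EMProfile(boundary, segments, phagosome_diameter_nm=2 * radius, phagosome_id=i)
        )
        gt.records.append(dict(phagosome_id=i, metric="contact_count", value=float(k)))
    return profiles, gt


# ---------------------------------------------------------------------------
# Ring-puncta (MAPPER recruitment) images


def gen_ring_puncta_image(
    cfg: ScenarioConfig,
    n_phagosomes: int,
    tile_px: int = 96,
    bg_mean: float = 100.0,
) -> tuple[ImageStack, LabelMask, GroundTruth]:
    """Confocal-scale image of phagosomes with bright puncta in the 0.2 um ring.

    Phagosomes are disks tiled on a grid inside one cell; each receives its
    allocated number of Gaussian puncta (sigma ~2 px, amplitude >= 5x the
    cytosolic noise SD) centered in the annulus just outside its border,
    with a minimum angular separation so puncta stay resolvable.
    """
    rng = np.random.default_rng(cfg.seed)
    ncol = int(np.ceil(np.sqrt(n_phagosomes)))
    nrow = int(np.ceil(n_phagosomes / ncol))
    h, w = nrow * tile_px, ncol * tile_px
    img = bg_mean + rng.normal(0.0, cfg.noise_sd, size=(h, w))
    labels = np.zeros((h, w), dtype=np.int32)
    counts = _alloc_counts(rng, cfg.puncta_rate, n_phagosomes)
    amp = max(5.0 * cfg.noise_sd, 0.2 * bg_mean)
    sigma = 2.0
    gt = GroundTruth()
    yy, xx = np.mgrid[0:tile_px, 0:tile_px]
    for i in range(n_phagosomes):
        r0, c0 = divmod(i, ncol)
        oy, ox = r0 * tile_px, c0 * tile_px
        cy = cx = tile_px / 2.0
        rad = rng.uniform(24.0, 28.0)  # 2.4-2.8 um diameter at 50 nm pitch
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= rad**2
        labels[oy : oy + tile_px, ox : ox + tile_px][disk] = i + 1
        r_center = rad + 2.0  # middle of the 4-px ring
        # cap the count so the minimum angular separation stays feasible
        k = min(int(counts[i]), int(2 * np.pi * r_center / 9.0))
        angles = _spread_angles(rng, k, 9.0 / r_center)
        for a in angles:
            py, px_ = cy + r_center * np.sin(a), cx + r_center * np.cos(a)
            d2 = (yy - py) ** 2 + (xx - px_) ** 2
            g = np.where(d2 <= (2 * sigma) ** 2,
                         amp * np.exp(-d2 / (2 * sigma**2)), 0.0)
            img[oy : oy + tile_px, ox : ox + tile_px] += g
        gt.records.append(dict(phagosome_id=i + 1, metric="puncta_count", value=float(len(angles))))
    stack = ImageStack.from_array(np.clip(img, 0, None), pixel_size_nm=cfg.pixel_size_nm)
    return stack, LabelMask(labels, role="phagosome"), gt


# ---------------------------------------------------------------------------
# Fluo-8 hotspot frames


def gen_fluo8_frame(
    cfg: ScenarioConfig,
    n_phagosomes: int,
    tile_px: int = 48,
    pixel_size_nm: float = 250.0,
    bg_mean: float = 100.0,
    n_frames: int = 2,
) -> tuple[ImageStack, LabelMask, LabelMask, GroundTruth]:
    """Cytosolic Ca2+ frames with 2x2-px periphagosomal hotspots.

    Hotspot amplitude is max(3 x noise_sd, 0.25 x background), so generated
    hotspots stay detectable by the mean + 2 SD rule even at zero noise.
    ``n_frames`` identically-placed frames with independent noise emulate
    the 6-s temporal averaging window.  Returns (stack, phagosome mask,
    cytosol mask, ground truth).
    """
    rng = np.random.default_rng(cfg.seed)
    ncol = int(np.ceil(np.sqrt(n_phagosomes)))
    nrow = int(np.ceil(n_phagosomes / ncol))
    h, w = nrow * tile_px, ncol * tile_px
    signal = np.full((h, w), bg_mean)
    labels = np.zeros((h, w), dtype=np.int32)
    counts = _alloc_counts(rng, cfg.hotspot_rate, n_phagosomes)
    amp = max(3.0 * cfg.noise_sd, 0.25 * bg_mean)
    gt = GroundTruth()
    yy, xx = np.mgrid[0:tile_px, 0:tile_px]
    for i in range(n_phagosomes):
        r0, c0 = divmod(i, ncol)
        oy, ox = r0 * tile_px, c0 * tile_px
        cy = cx = tile_px / 2.0
        rad = 6.0  # 3 um diameter at 250 nm pitch
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= rad**2
        labels[oy : oy + tile_px, ox : ox + tile_px][disk] = i + 1
        k = int(counts[i])
        angles = _spread_angles(rng, k, 4.0 / rad)
        for a in angles:
            d = rng.uniform(1.0, 1.7)  # border distance, px (<= 3 px / 750 nm)
            # 2x2 block centered on the target radius, fully outside the disk
            py = int(round(cy + (rad + d) * np.sin(a) - 0.5))
            px_ = int(round(cx + (rad + d) * np.cos(a) - 0.5))
            py = np.clip(py, 0, tile_px - 2)
            px_ = np.clip(px_, 0, tile_px - 2)
            signal[oy + py : oy + py + 2, ox + px_ : ox + px_ + 2] += amp
        gt.records.append(dict(phagosome_id=i + 1, metric="hotspot_count", value=float(k)))
    frames = np.stack(
        [np.clip(signal + rng.normal(0, cfg.noise_sd, signal.shape), 0, None)
         for _ in range(n_frames)]
    )
    stack = ImageStack.from_array(frames, pixel_size_nm=pixel_size_nm,
                                  frame_interval_s=3.0)
    phag = LabelMask(labels, role="phagosome")
    dist = ndimage.distance_transform_edt(labels == 0)
    cyto = LabelMask((dist > 6).astype(np.int32), role="cytosol")
    return stack, phag, cyto, gt


# ---------------------------------------------------------------------------
# TIRF time-lapse with sigmoidal puncta growth


def gen_tirf_series(
    cfg: ScenarioConfig,
    n_frames: int = 90,
    frame_interval_s: float = 1.0,
    size_px: int = 128,
    pixel_size_nm: float = 110.0,
    bg_mean: float = 100.0,
    baseline_punctum: bool = False,
) -> tuple[ImageStack, LabelMask, GroundTruth]:
    """TIRF movie of one cell where puncta count follows a Boltzmann sigmoid.

    Puncta are 3x3 blocks appearing at pre-shuffled grid positions; the
    active count at frame t is round(boltzmann(t, 0, n_final, t50, slope)).
    ``baseline_punctum`` plants a large pre-existing punctum at frame 0 (for
    baseline-exclusion tests).
    """
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(n_frames) * frame_interval_s
    n_t = np.round(
        boltzmann(t, 0.0, cfg.tirf_n_final, cfg.tirf_t50_s, cfg.tirf_slope_s)
    ).astype(int)
    margin = 10
    grid = [
        (y, x)
        for y in range(margin, size_px - margin, 8)
        for x in range(margin, size_px - margin, 8)
    ]
    order = rng.permutation(len(grid))[: max(cfg.tirf_n_final, 1)]
    positions = [grid[i] for i in order]
    amp = max(5.0 * cfg.noise_sd, 0.2 * bg_mean)
    movie = np.empty((n_frames, size_px, size_px))
    for f in range(n_frames):
        frame = np.full((size_px, size_px), bg_mean)
        for y, x in positions[: n_t[f]]:
            frame[y : y + 3, x : x + 3] += amp
        if baseline_punctum:
            frame[4:9, 4:9] += amp
        movie[f] = np.clip(frame + rng.normal(0, cfg.noise_sd, frame.shape), 0, None)
    stack = ImageStack.from_array(movie, pixel_size_nm=pixel_size_nm,
                                  frame_interval_s=frame_interval_s)
    cell = LabelMask(np.ones((size_px, size_px), dtype=np.int32), role="cell")
    gt = GroundTruth(
        [dict(metric="n_puncta", frame=f, value=float(n_t[f])) for f in range(n_frames)]
        + [dict(metric="t50_s", value=cfg.tirf_t50_s),
           dict(metric="slope_s", value=cfg.tirf_slope_s)]
    )
    return stack, cell, gt


# ---------------------------------------------------------------------------
# Lipid enrichment tracks and rendered time-lapses

_T_PEAK_MIN = 2.0  # enrichment peaks ~2 min after ingestion
_DECAY_TAU_MIN = 2.0
_PLATEAU_RAMP_MIN = 3.0
_DECAYER_LEVEL = 0.02
_FLUCT_AMP = 0.25
_FLUCT_PERIOD_MIN = 8.0


def _peak_shape(t: np.ndarray) -> np.ndarray:
    """Unit peak: linear rise over [0, t_peak], exponential decay after."""
    g = np.zeros_like(t)
    rise = (t >= 0) & (t <= _T_PEAK_MIN)
    g[rise] = t[rise] / _T_PEAK_MIN
    fall = t > _T_PEAK_MIN
    g[fall] = np.exp(-(t[fall] - _T_PEAK_MIN) / _DECAY_TAU_MIN)
    return g


def _plateau_shape(t: np.ndarray) -> np.ndarray:
    """Unit plateau: ramps 0 to 1 over [t_peak, t_peak + ramp], then holds."""
    h = np.clip((t - _T_PEAK_MIN) / _PLATEAU_RAMP_MIN, 0.0, 1.0)
    h[t < _T_PEAK_MIN] = 0.0
    return h


def _window_selector(cfg: ScenarioConfig, t: np.ndarray) -> np.ndarray:
    if cfg.lipid_window_anchor == "full":
        return t >= 0
    off = _T_PEAK_MIN if cfg.lipid_window_anchor == "peak" else 0.0
    return (t >= cfg.lipid_window_start_min + off) & (t <= cfg.lipid_window_end_min + off)


def _solve_plateau_level(cfg: ScenarioConfig, t: np.ndarray) -> float:
    """Fluctuator plateau level that makes the cohort window mean hit the target.

    The configured ``lipid_window_level`` is the expected cohort mean of the
    window metric; the deterministic peak-tail contribution and the decayer
    residual are subtracted analytically on the same sampling grid the
    pipeline measures on.
    """
    sel = _window_selector(cfg, t)
    g_bar = float(_peak_shape(t)[sel].mean())
    h_bar = float(_plateau_shape(t)[sel].mean())
    f = cfg.fluctuating_fraction
    target = cfg.lipid_window_level - cfg.lipid_peak * g_bar
    if f == 0:
        return _DECAYER_LEVEL
    lam = (target - (1 - f) * _DECAYER_LEVEL * h_bar) / (f * h_bar)
    if lam < 0:
        raise ValueError(
            f"{cfg.name}: window level {cfg.lipid_window_level} below the peak-tail floor"
        )
    return lam


def gen_lipid_tracks(
    cfg: ScenarioConfig,
    n_tracks: int,
    t_total_min: float = 30.0,
) -> tuple[list[dict], GroundTruth]:
    """Track-space lipid enrichment cohort (math core, no rendering).

    Each track dict has keys t_min, E, fluctuating, peak.  All tracks share
    a peak at ~2 min post-ingestion; a fixed fraction then fluctuates around
    a plateau level solved so the cohort mean of the configured window
    metric equals ``lipid_window_level``; the rest decay to ~0.
    """
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(0.0, t_total_min + 0.5, 1.0)
    lam = _solve_plateau_level(cfg, t)
    fluct = _alloc_flags(rng, cfg.fluctuating_fraction, n_tracks)
    peaks = cfg.lipid_peak * np.clip(rng.normal(1.0, 0.10, n_tracks), 0.7, 1.3)
    g, h = _peak_shape(t), _plateau_shape(t)
    tracks, gt = [], GroundTruth()
    for i in range(n_tracks):
        if fluct[i]:
            phase = rng.uniform(0, 2 * np.pi)
            mod = 1.0 + _FLUCT_AMP * np.sin(2 * np.pi * t / _FLUCT_PERIOD_MIN + phase)
            plateau = lam * h * mod
        else:
            plateau = _DECAYER_LEVEL * h
        e = peaks[i] * g + plateau
        tracks.append(dict(t_min=t.copy(), E=e, fluctuating=bool(fluct[i]),
                           peak=float(peaks[i])))
        gt.records.append(dict(phagosome_id=i + 1, metric="peak", value=float(peaks[i])))
        gt.records.append(dict(phagosome_id=i + 1, metric="fluctuating",
                               value=float(fluct[i])))
    gt.records.append(dict(metric="window_level", value=cfg.lipid_window_level))
    return tracks, gt


def gen_lipid_timelapse(
    cfg: ScenarioConfig,
    n_tracks: int,
    tile_px: int = 96,
    pixel_size_nm: float = 100.0,
    base_intensity: float = 100.0,
    ingestion_start_frame: int = 2,
    t_total_min: float = 30.0,
) -> tuple[list[dict], GroundTruth]:
    """Rendered lipid time-lapses: one single-phagosome movie per track.

    Each bundle dict has keys stack, phag_mask, cell_mask,
    ingestion_start_frame, true_E.  The phagosome disk carries intensity
    base * (1 + E(t)); the surrounding cell carries the baseline, so the
    enrichment formula recovers E(t) exactly up to noise.
    """
    tracks, gt = gen_lipid_tracks(cfg, n_tracks, t_total_min)
    rng = np.random.default_rng(cfg.seed + 1)
    n_frames = len(tracks[0]["t_min"]) + ingestion_start_frame
    yy, xx = np.mgrid[0:tile_px, 0:tile_px]
    cell = (yy - tile_px / 2) ** 2 + (xx - tile_px / 2) ** 2 <= (tile_px / 2 - 8) ** 2
    phag = (yy - tile_px / 2 - 10) ** 2 + (xx - tile_px / 2) ** 2 <= 8.0**2
    cell_mask = LabelMask(cell.astype(np.int32), role="cell")
    phag_mask = LabelMask(phag.astype(np.int32), role="phagosome")
    bundles = []
    for tr in tracks:
        e_full = np.concatenate([np.zeros(ingestion_start_frame), tr["E"]])
        movie = np.zeros((n_frames, tile_px, tile_px))
        for f in range(n_frames):
            frame = np.where(cell, base_intensity, 0.0).astype(float)
            frame[phag] = base_intensity * (1.0 + e_full[f])
            movie[f] = np.clip(frame + rng.normal(0, cfg.noise_sd, frame.shape), 0, None)
        stack = ImageStack.from_array(movie, pixel_size_nm=pixel_size_nm,
                                      frame_interval_s=60.0)
        bundles.append(dict(stack=stack, phag_mask=phag_mask, cell_mask=cell_mask,
                            ingestion_start_frame=ingestion_start_frame,
                            true_E=tr["E"], fluctuating=tr["fluctuating"]))
    return bundles, gt


# ---------------------------------------------------------------------------
# FRET phagolysosome-fusion stacks


def gen_plf_stacks(
    cfg: ScenarioConfig,
    n_cells: int,
    tile_px: int = 96,
    n_planes: int = 3,
    pixel_size_nm: float = 100.0,
    donor_level: float = 200.0,
) -> tuple[list[dict], GroundTruth]:
    """Three-channel (FRET/green/red) stacks, one cell per bundle.

    Each cell holds an allocated number of donor-labelled phagosomes whose
    pixel-wise FRET/green ratio averages v_i.  Lysosomal acceptor loading is
    the same across conditions (a fixed uniform red level over the cell, as
    measured in the study); the per-phagosome FRET ratio is scaled so the
    true per-cell PLF index equals ``plf_level`` in expectation.
    Out-of-focus planes carry attenuated signal so the max projection
    recovers the in-focus plane.
    """
    rng = np.random.default_rng(cfg.seed)
    counts = np.maximum(_alloc_counts(rng, cfg.phagosomes_per_cell, n_cells), 1)
    yy, xx = np.mgrid[0:tile_px, 0:tile_px]
    cy = cx = tile_px / 2.0
    cell = (yy - cy) ** 2 + (xx - cx) ** 2 <= (tile_px / 2 - 8) ** 2
    cell_area = int(cell.sum())
    bundles, gt = [], GroundTruth()
    red_px = 50.0  # acceptor loading, identical across conditions
    for c in range(n_cells):
        k = int(counts[c])
        v_base = cfg.plf_level * red_px * cell_area / k
        v = v_base * np.clip(rng.normal(1.0, 0.10, k), 0.7, 1.3)
        phag_labels = np.zeros((tile_px, tile_px), dtype=np.int32)
        ring_r = tile_px / 2 - 24
        angles = _spread_angles(rng, k, 14.0 / max(ring_r, 1))
        fret = np.zeros((tile_px, tile_px))
        green = np.full((tile_px, tile_px), 20.0)
        for j, a in enumerate(angles):
            py, px_ = cy + ring_r * np.sin(a), cx + ring_r * np.cos(a)
            disk = (yy - py) ** 2 + (xx - px_) ** 2 <= 6.0**2
            phag_labels[disk] = j + 1
            green[disk] = donor_level
            fret[disk] = donor_level * v[j]
        red = np.where(cell, red_px, 0.0)

        def _stack(plane: np.ndarray) -> ImageStack:
            planes = np.stack([plane * 0.5, plane, plane * 0.5][:n_planes])
            noisy = np.clip(planes + rng.normal(0, cfg.noise_sd, planes.shape), 0, None)
            return ImageStack.from_array(noisy, axes="zyx",
                                         pixel_size_nm=pixel_size_nm, z_step_nm=800.0)

        true_plf = float(v.sum() / (red_px * cell_area))
        bundles.append(dict(
            fret=_stack(fret), green=_stack(green), red=_stack(red),
            phag_mask=LabelMask(phag_labels, role="phagosome"),
            cell_mask=LabelMask(cell.astype(np.int32), role="cell"),
        ))
        gt.records.append(dict(cell_id=c + 1, metric="plf_index", value=true_plf))
        gt.records.append(dict(cell_id=c + 1, metric="phagosome_count", value=float(k)))
    return bundles, gt


# ---------------------------------------------------------------------------
# pH calibration and test images

PH_BUFFERS = (4.0, 4.5, 5.0, 5.5, 6.0, 6.5, 7.0, 7.5, 8.0, 8.5, 9.0)
_PH_CURVE = dict(A1=0.3, A2=2.0, pKa=6.3, slope=0.8)  # ratio vs pH, ascending


def true_ph_ratio(ph) -> np.ndarray:
    """The generator's ground-truth ratio-vs-pH Boltzmann."""
    return boltzmann(np.asarray(ph, float), _PH_CURVE["A1"], _PH_CURVE["A2"],
                     _PH_CURVE["pKa"], _PH_CURVE["slope"])


def gen_ph_images(
    cfg: ScenarioConfig,
    size_px: int = 64,
    n_replicates: int = 5,
    den_level: float = 100.0,
    pixel_size_nm: float = 160.0,
) -> tuple[dict[float, list[tuple[ImageStack, ImageStack]]],
           tuple[ImageStack, ImageStack], LabelMask, GroundTruth]:
    """Buffer calibration image series plus a test image pair at ``ph_true``.

    Calibration: for each clamped buffer pH, ``n_replicates`` image pairs
    whose pixel ratio follows the ground-truth Boltzmann.  Test: a phagosome
    disk imaged at the scenario's true phagosomal pH.
    """
    rng = np.random.default_rng(cfg.seed)

    def _pair(ratio_map: np.ndarray) -> tuple[ImageStack, ImageStack]:
        den = den_level + rng.normal(0, cfg.noise_sd, (size_px, size_px))
        den = np.clip(den, 1.0, None)
        num = ratio_map * den + rng.normal(0, cfg.noise_sd * 0.1, (size_px, size_px))
        mk = lambda a: ImageStack.from_array(np.clip(a, 0, None),
                                             pixel_size_nm=pixel_size_nm)
        return mk(num), mk(den)

    calib = {
        ph: [_pair(np.full((size_px, size_px), true_ph_ratio(ph)))
             for _ in range(n_replicates)]
        for ph in PH_BUFFERS
    }
    yy, xx = np.mgrid[0:size_px, 0:size_px]
    disk = (yy - size_px / 2) ** 2 + (xx - size_px / 2) ** 2 <= 10.0**2
    ratio_map = np.where(disk, float(true_ph_ratio(cfg.ph_true)),
                         float(true_ph_ratio(7.2)))  # cytosol at resting pH
    test = _pair(ratio_map)
    roi = LabelMask(disk.astype(np.int32), role="phagosome")
    gt = GroundTruth([dict(metric="ph_true", value=cfg.ph_true)])
    return calib, test, roi, gt


# ---------------------------------------------------------------------------
# Fura-2 SOCE traces


def gen_fura_traces(
    cfg: ScenarioConfig,
    n_cells: int,
    duration_s: float = 600.0,
    readd_time_s: float = 300.0,
    baseline_ratio: float = 0.6,
    rise_tau_s: float = 20.0,
    trace_noise: float = 0.005,
) -> tuple[list[RatioTrace], GroundTruth]:
    """Per-cell F340/F380 traces with a Ca2+ re-addition step.

    After re-addition the ratio rises exponentially toward baseline +
    ``soce_peak`` with time constant ``rise_tau_s`` (initial slope
    soce_peak / rise_tau_s).
    """
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(0.0, duration_s, 3.0)
    traces, gt = [], GroundTruth()
    for c in range(n_cells):
        peak = cfg.soce_peak * np.clip(rng.normal(1.0, 0.05), 0.8, 1.2)
        r = np.full_like(t, baseline_ratio)
        post = t >= readd_time_s
        r[post] += peak * (1.0 - np.exp(-(t[post] - readd_time_s) / rise_tau_s))
        r = r + rng.normal(0, trace_noise, t.shape)
        traces.append(RatioTrace(t, r, readd_time_s, cell_id=c + 1))
        gt.records.append(dict(cell_id=c + 1, metric="soce_peak", value=float(peak)))
        gt.records.append(dict(cell_id=c + 1, metric="max_slope",
                               value=float(peak / rise_tau_s)))
    return traces, gt


# ---------------------------------------------------------------------------
# Antigen-bead images


def gen_antigen_image(
    cfg: ScenarioConfig,
    n_ingested: int,
    n_free: int,
    tile_px: int = 32,
    free_level: float = 1000.0,
    pixel_size_nm: float = 100.0,
) -> tuple[ImageStack, LabelMask, LabelMask, GroundTruth]:
    """Bead field with ingested beads dimmed to the configured percentage.

    Ingested beads carry antigen_remaining_pct% of the free-bead intensity
    (degraded antigen); both populations are disks on a dark background.
    """
    rng = np.random.default_rng(cfg.seed)
    n = n_ingested + n_free
    ncol = int(np.ceil(np.sqrt(n)))
    nrow = int(np.ceil(n / ncol))
    h, w = nrow * tile_px, ncol * tile_px
    img = np.zeros((h, w))
    ingested = np.zeros((h, w), dtype=np.int32)
    free = np.zeros((h, w), dtype=np.int32)
    yy, xx = np.mgrid[0:tile_px, 0:tile_px]
    disk = (yy - tile_px / 2) ** 2 + (xx - tile_px / 2) ** 2 <= 6.0**2
    gt = GroundTruth()
    ing_level = free_level * cfg.antigen_remaining_pct / 100.0
    for i in range(n):
        r0, c0 = divmod(i, ncol)
        sl = (slice(r0 * tile_px, (r0 + 1) * tile_px),
              slice(c0 * tile_px, (c0 + 1) * tile_px))
        if i < n_ingested:
            level = ing_level * np.clip(rng.normal(1.0, 0.03), 0.9, 1.1)
            img[sl][disk] = level
            ingested[sl][disk] = i + 1
            gt.records.append(dict(phagosome_id=i + 1, metric="pct_remaining",
                                   value=100.0 * level / free_level))
        else:
            img[sl][disk] = free_level
            free[sl][disk] = i - n_ingested + 1
    img = np.clip(img + rng.normal(0, cfg.noise_sd, img.shape), 0, None)
    stack = ImageStack.from_array(img, pixel_size_nm=pixel_size_nm)
    return stack, LabelMask(ingested, role="bead_ingested"), \
        LabelMask(free, role="bead_free"), gt
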