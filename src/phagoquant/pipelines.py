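"""End-to-end assay pipelines: generate -> render -> detect -> summarize.

Each function runs a complete measurement path for one scenario, from the
synthetic generator through the relevant detectors, and returns the
quantities the assay reports.  These are the paths exercised by the
recovery tests and the reproduction script, and the bodies double as usage
examples for the underlying modules.
"""

from __future__ import annotations

import numpy as np

from . import calcium, em_contacts, fusion, lipids, puncta, synthetic
from .synthetic import ScenarioConfig

__all__ = [
    "run_em",
    "run_ring_puncta",
    "run_lipid",
    "run_plf",
    "run_hotspots",
    "run_ph",
    "run_antigen",
]


def run_em(cfg: ScenarioConfig, n_phagosomes: int = 500, gap_max_nm: float = 30.0) -> dict:
    """EM contact pipeline: profiles -> diameter filter -> contact detection -> stats.

    Returns mean contacts/phagosome, median/mean contact length (nm), the
    percentage of contacts longer than 400 nm, and the pooled length list.
    """
    profiles, _ = synthetic.gen_em_profiles(cfg, n_phagosomes)
    kept = em_contacts.filter_profiles(profiles, min_diameter_um=1.0)
    sets = [em_contacts.detect_contacts(p, gap_max_nm=gap_max_nm) for p in kept]
    lengths = em_contacts.pooled_lengths(sets)
    counts = np.array([s.count for s in sets], float)
    return dict(
        mean_contacts=float(counts.mean()),
        median_length_nm=float(np.median(lengths)),
        mean_length_nm=float(lengths.mean()),
        pct_large=float(100.0 * (lengths > 400.0).mean()),
        lengths=lengths,
        counts=counts,
        n_profiles=len(kept),
    )


def run_ring_puncta(cfg: ScenarioConfig, n_phagosomes: int = 200) -> np.ndarray:
    """Ring-puncta pipeline: image -> 0.2 um ring -> detection -> per-phagosome counts."""
    img, phag_mask, _ = synthetic.gen_ring_puncta_image(cfg, n_phagosomes)
    ring = puncta.make_ring(phag_mask, img.pixel_size_nm, width_um=0.2)
    cyto = puncta.make_cytosol_mask(phag_mask)
    sets = puncta.detect_ring_puncta(img, ring, threshold="auto", cytosol=cyto)
    return np.array([sets[pid].count if pid in sets else 0
                     for pid in phag_mask.label_ids], float)


def run_lipid(cfg: ScenarioConfig, n_tracks: int = 60, from_images: bool = True) -> list:
    """Lipid pipeline: time-lapses -> enrichment tracks (or track-space shortcut)."""
    if from_images:
        bundles, _ = synthetic.gen_lipid_timelapse(cfg, n_tracks)
        return [
            lipids.enrichment_track(
                b["stack"], b["phag_mask"], b["cell_mask"],
                b["ingestion_start_frame"], scenario=cfg.name,
            )
            for b in bundles
        ]
    tracks, _ = synthetic.gen_lipid_tracks(cfg, n_tracks)
    return [
        lipids.Track(phagosome_id=i + 1, t_min=tr["t_min"], E=tr["E"], scenario=cfg.name)
        for i, tr in enumerate(tracks)
    ]


def lipid_window(cfg: ScenarioConfig) -> lipids.Window:
    """The scenario's reporting window as a :class:`lipids.Window`."""
    return lipids.Window(cfg.lipid_window_start_min, cfg.lipid_window_end_min,
                         anchor=cfg.lipid_window_anchor)


def run_plf(cfg: ScenarioConfig, n_cells: int = 40) -> np.ndarray:
    """FRET fusion pipeline: three-channel stacks -> per-cell PLF index."""
    bundles, _ = synthetic.gen_plf_stacks(cfg, n_cells)
    vals = []
    for b in bundles:
        per_cell = fusion.plf_index(b["fret"], b["green"], b["red"],
                                    b["phag_mask"], b["cell_mask"])
        vals.extend(m.plf_index for m in per_cell.values() if np.isfinite(m.plf_index))
    return np.array(vals)


def run_hotspots(cfg: ScenarioConfig, n_phagosomes: int = 100) -> np.ndarray:
    """Hotspot pipeline: Fluo-8 frames -> detection -> per-phagosome frequency."""
    stack, phag, cyto, _ = synthetic.gen_fluo8_frame(cfg, n_phagosomes)
    hs = calcium.detect_hotspots(stack, cyto, phag)
    per = hs.per_phagosome(phag.label_ids)
    return np.array([per[pid] for pid in phag.label_ids], float)


def run_ph(cfg: ScenarioConfig) -> float:
    """pH pipeline: buffer calibration fit -> phagosome ratio -> pH."""
    calib, (num, den), roi, _ = synthetic.gen_ph_images(cfg)
    cal = fusion.fit_ph_calibration(calib)
    sel = roi.foreground
    a = num.data[0, 0, 0][sel]
    b = den.data[0, 0, 0][sel]
    ratio = float((a[b != 0] / b[b != 0]).mean())
    return fusion.ratio_to_ph(ratio, cal)


def run_antigen(cfg: ScenarioConfig, n_ingested: int = 40, n_free: int = 10) -> np.ndarray:
    """Antigen pipeline: bead image -> percent antigen remaining per ingested bead."""
    img, ingested, free, _ = synthetic.gen_antigen_image(cfg, n_ingested, n_free)
    return np.array(list(fusion.antigen_remaining(img, ingested, free).values()))
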