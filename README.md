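# phagoquant

Quantification pipelines for **ER–phagosome membrane contact sites (MCS)**
and their functional consequences during phagosome maturation, with
synthetic fluorescence-microscopy and EM data generators that carry ground
truth for every assay.

## Scientific background

When a phagocyte ingests a target, the resulting phagosome matures by
fusing with endosomes and lysosomes. The endoplasmic reticulum forms
non-fusogenic membrane contact sites (appositions of 10–30 nm) with the
phagosome, and tethering at these contacts — by proteins such as STIM1,
the SNARE Sec22b and the lipid-transfer protein ORP8 — regulates local
Ca²⁺ signaling, phagosomal phospholipids (PI(4)P, PI(3)P, PS), and
ultimately phagolysosome fusion and antigen degradation. Quantifying these
processes requires a family of image-analysis procedures:

- **EM contact sites** — on a 2-D cross-section, a contact is a maximal ER
  membrane stretch whose every point lies within 30 nm of the phagosomal
  membrane; only cross-sections > 1 µm in diameter are scored. Reported
  per condition: mean contacts/phagosome, median contact length, the
  fraction of very large (> 400 nm) contacts, and an F-test on length
  variances.
- **Periphagosomal puncta** — reporter puncta (> 0.01 µm²) counted in a
  0.2 µm ring outside the phagosome border, thresholded at cytosolic
  mean + 2 SD.
- **Ca²⁺** — store-operated Ca²⁺ entry (SOCE) metrics (max slope, peak
  amplitude of the Fura-2 F340/F380 ratio after Ca²⁺ re-addition) and
  Fluo-8 hotspots: ≥ 4 px regions ≥ 2 SD above the cytosolic mean within
  750 nm of a phagosome border.
- **TIRF kinetics** — ER–plasma-membrane puncta (area > 4 px above
  whole-cell mean + 1 SD) counted per frame and fitted with a Boltzmann
  sigmoid `y(t) = A1 + (A2−A1)/(1+exp((t50−t)/slope))`.
- **Lipid enrichment** — per-phagosome probe enrichment
  `E(t) = F_phagosome(t)/F_cell(0) − 1` on background-subtracted max
  projections, summarized over peak- or ingestion-anchored time windows.
- **Phagolysosome fusion (PLF)** — per cell, the phagosomal FRET/donor
  pixel ratio (averaged per phagosome, summed over phagosomes) normalized
  to total acceptor (red) loading.
- **pH and antigen** — dual-excitation FITC ratios converted to pH through
  a monotone Boltzmann calibration against nigericin/monensin-clamped
  buffers (pH 4–9), and percent antigen remaining on ingested vs free
  beads.

The `synthetic` module generates every input these pipelines consume, with
named scenario presets (`shCTR`, `shSec22b`, lipid-probe and rescue
variants) that encode the measured condition contrasts as generator ground
truth — e.g. 4.5 vs 3.0 contacts/phagosome, 93 vs 81 nm median contact
length, a 3% population of > 400 nm contacts unique to the knockdown,
50% loss of ring puncta, 2.5-fold higher PI(4)P 5–25 min after the peak,
and a 1.5-fold higher PLF index.

## Worked example

```python
from phagoquant import pipelines, em_contacts
from phagoquant.synthetic import preset

ctr = pipelines.run_em(preset("shCTR", seed=1), n_phagosomes=200)
kd  = pipelines.run_em(preset("shSec22b", seed=2), n_phagosomes=200)

print(f"contacts/phagosome : {ctr['mean_contacts']:.2f} (shCTR) vs {kd['mean_contacts']:.2f} (shSec22b)")
print(f"median length (nm) : {ctr['median_length_nm']:.1f} vs {kd['median_length_nm']:.1f}")
print(f"contacts > 400 nm  : {ctr['pct_large']:.2f}% vs {kd['pct_large']:.2f}%")
F, p = em_contacts.variance_f_test(ctr["lengths"], kd["lengths"])
print(f"length variance F  : {F:.2f} (p = {p:.2e})")
```

prints

```
contacts/phagosome : 4.50 (shCTR) vs 3.00 (shSec22b)
median length (nm) : 93.1 vs 81.4
contacts > 400 nm  : 0.11% vs 3.00%
length variance F  : 3.33 (p = 1.37e-59)
```

Sec22b knockdown removes a third of the contacts and slightly shortens the
median contact, while a small population of very large contacts appears —
visible here as the 3% tail and the highly significant variance F-test,
exactly the signature injected by the `shSec22b` preset.

A command-line interface mirrors the library:

```sh
phagoquant simulate --assay em --scenario shCTR --out em_data/ --seed 1 --n 50
phagoquant em --input em_data/profiles.json --out em_stats.csv
phagoquant contrast --assay lipid --scenario-a pi4p:shCTR --scenario-b pi4p:shSec22b
```

## Layout

| module | contents |
|---|---|
| `phagoquant.core_io` | `ImageStack`/`LabelMask` data model, TIFF I/O, background subtraction, projections, connected components |
| `phagoquant.synthetic` | `ScenarioConfig`, presets, all data generators with ground truth |
| `phagoquant.em_contacts` | contact detection on EM profiles, diameter filter, stats, F-test |
| `phagoquant.puncta` | ring construction, ring-puncta detection, recruitment summaries |
| `phagoquant.calcium` | Fura-2 ratio traces, SOCE metrics, Fluo-8 hotspot detection, phagocytic index |
| `phagoquant.tirf` | TIRF puncta detection, baseline exclusion, Boltzmann fits |
| `phagoquant.lipids` | enrichment tracks, window statistics, condition contrasts |
| `phagoquant.fusion` | PLF index, pH calibration/inversion, percent antigen remaining |
| `phagoquant.pipelines` | end-to-end per-scenario assay runs |

See `docs/methods.md` for the measurement definitions, generator models
and the numerical choices behind them.
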