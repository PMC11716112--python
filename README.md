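# extruderquant

Quantitative-imaging analysis of SMC loop extruders (Condensin I/II,
Cohesin-STAG1/2) and the boundary factor CTCF on chromatin through mitotic
exit, built for researchers who count molecules rather than compare
intensities. The package implements the full inference chain from raw
photon-count and image measurements to absolute, per-megabase genome
occupancies and single-cell chromatin geometry:

- **FCS calibration** (`extruderquant.fcs`) — autocorrelation of photon-count
  traces, one-component 3D-diffusion fits
  `g(τ) = offset + (1/N)(1 + τ/τ_D)⁻¹(1 + τ/(κ²τ_D))^(−1/2)`, effective
  detection volume `V_eff = π^{3/2} w₀³ κ` with `w₀ = √(4Dτ_D)`, and the
  fluorescence→concentration calibration line that turns masked voxel
  intensities into absolute copy numbers.
- **FRAP kinetics** (`extruderquant.frap`) — the half-nucleus bleach readout
  `d(t) = (F_ub(t) − F_b(t)) / (F_ub(0) − F_b(0))` fit with
  `d(t) = a + (1 − a)e^(−k_off t)`, yielding the immobile ("long-term
  bound") fraction `a` and residence time `1/k_off`.
- **Spot-bleach assay** (`extruderquant.spotbleach`) — the 30-s
  continuous-illumination depletion statistic, two-point calibration against
  H2B-EGFP (fully bound) and free mEGFP (unbound), timecourse interpolation
  and reconstruction of bound copies per Mb across mitotic exit.
- **Occupancy accounting** (`extruderquant.occupancy`) — bound copies =
  nuclear copies × bound fraction, densities per 15,800 Mb (2 × 7.9 Gb
  hypotriploid HeLa content), loop size = residence time × extrusion rate,
  and a Monte-Carlo loop-encounter probability. A packaged measurement
  table (`data/tables_1_2.csv`) is reproduced cell by cell.
- **STED spot analysis** (`extruderquant.sted`) — nuclear masking, Otsu +
  watershed sub-diffraction spot segmentation, spot densities per µm³,
  labeling efficiency with the 1.67 undercount correction, Pearson
  colocalization and spot-intensity statistics for the dimerization
  argument.
- **Trace geometry** (`extruderquant.traces`) — QC gating, median
  pairwise-distance and contact maps (120 nm), difference maps, scaling
  curves, per-trace contacts (100 nm), k-NN distances and nested-loop
  frequencies for 3D chromatin traces (12-kb bins).
- **Synthetic data** (`extruderquant.synth`) — ground-truth-known generators
  for every assay, so the whole chain is testable without any downloads.
- **Pipeline/CLI** (`extruderquant.pipeline`, console script
  `extruderquant`) — YAML-configured multi-stage runs with manifests.

## Worked example

Why does Cohesin-STAG2 start colocalizing only in late G1? Count it:

```python
from extruderquant.occupancy import (
    MeasurementRecord, chromatin_bound_copies, per_megabase, loop_size,
    encounter_probability, round_half_up)

rec = MeasurementRecord("STAG2", "eG1", nuclear_copies=102_150,
                        bound_fraction=0.47, residence_time_s=108)
copies = chromatin_bound_copies(rec.nuclear_copies, rec.bound_fraction)
print(round_half_up(copies), round_half_up(per_megabase(copies), 2))
print(loop_size(120, 1.0))
print(encounter_probability(3, 120, n_draws=200_000, seed=1))
print(encounter_probability(8, 120, n_draws=200_000, seed=1))
```

prints

```
48011.0 3.04
120.0
0.614805
1.0
```

48,011 STAG2 complexes are chromatin-bound in early G1, i.e. 3.04 per Mb.
At an extrusion rate of 1 kb/s a complex resident for ~120 s grows a 120-kb
loop; with only ~3 such loops per Mb, random placements overlap in 61% of
draws, while at the late-G1 occupancy of ~8 per Mb overlap is essentially
certain — the occupancy shift alone makes extruder encounters (and hence
loop stacking/dimerization) unavoidable.

The same chain runs from the shell:

```bash
extruderquant validate-tables          # reproduce the packaged table
extruderquant occupancy --out derived.csv
extruderquant frap my_recovery.csv     # CSV: t_s, f_ub, f_b
```

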