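# octa-compare

Paired comparison of spectral-domain (SD, ~840 nm) and swept-source (SS,
~1050 nm) OCT/OCTA instruments on the same eyes, with central serous
retinopathy (CSR) as the test case.  The serous fluid dome of CSR lengthens
the optical path to everything beneath it; the package quantifies how much
each device's returns from the deep layers suffer as the fluid volume
grows, and whether the two devices agree on the measurements clinicians
actually use.

The package is aimed at readers who want a fully reproducible, ground-truth
version of this comparison: every analysis runs on synthetic paired
acquisitions with analytically known answers, generated by the package
itself.

## The quantities

With `S_m(x,y,z)` the measured voxel signal, scans from both devices are
put on a common unit-energy scale by total-signal normalization

    S_norm(x,y,z) = S_m(x,y,z) / S_sum

(`S_sum` summed over the whole scanned volume).  Per anatomical layer the
signal strength is the mean normalized signal per voxel,

    S_sd, S_ss = S_layer_sum / N_layer_voxel

and the per-subject inter-device difference is `ΔS = S_ss − S_sd`.  Layers:
superficial retina (ILM-IPL), deep retina (IPL-OPL), and fixed-thickness
Sattler (100 µm) and Haller (200 µm) bands below Bruch's membrane.  Central
serous volume (CSV) is whole-voxel counting of the IS/OS-RPE gap.  Retinal
vessel density is computed on co-registered en-face angiograms inside the
largest common fovea-centred circle, after Otsu binarization and exclusion
of the foveal avascular zone.  Group comparisons use paired t-tests, OLS
regression, and Bland-Altman limits of agreement (mean ± 1.96·SD).

The synthetic generator renders the four commercial scan protocols the
study design calls for — SD 3×3 mm (245², 12.2 µm), SD 6×6 mm (350²,
17.1 µm), SS 3×3 mm (300², 10 µm), SS 6×6 mm (500², 12 µm) — through a
phenomenological device model (sensitivity roll-off, tissue and serous-fluid
attenuation, noise) over a layered retina with a half-ellipsoid detachment
of exactly known volume `(2/3)·π·a·b·c`.  See `docs/methods.md` for the
model and its limits.

## Worked example

The numbered scripts under `analysis/` run the study stages; for example,
inter-device CSV agreement (a few seconds, no volume rendering):

```sh
$ python analysis/03_csv_agreement.py --seed 0
3x3mm: contained-eye regression R2 = 1.0000 (slope 1.000, n = 7)
        Bland-Altman mean +3.19e-04 mm^3, limits [-1.45e-03, +2.09e-03], outliers: ['csr007']
6x6mm: contained-eye regression R2 = 1.0000 (slope 1.000, n = 8)
        Bland-Altman mean -2.05e-05 mm^3, limits [-8.97e-05, +4.86e-05], outliers: none
```

Read: on eyes whose lesion fits the field of view the two devices measure
essentially identical fluid volumes (R² = 1.000, slope 1.0, bias well below
a voxel layer).  Eye `csr007` carries a lesion wider than the 3×3 mm
raster; its volume is truncated differently by the two instruments' grids
and it falls outside the 3×3 mm limits of agreement, while the 6×6 mm scans
cover the lesion and show no outlier — the field-of-view failure mode this
comparison is designed to expose.

The fluid-attenuation mechanism (several minutes; renders full volumes):

```sh
$ python analysis/04_delta_s_mechanism.py --noiseless --seed 0
5 CSR eyes, 3x3 mm pattern (noiseless):
  deep_retina  R2 = 0.266, slope +3.47e-08 per mm^3, p = 0.374 -> uncorrelated
  sattler      R2 = 1.000, slope +1.64e-09 per mm^3, p = 0.000 -> correlated
  haller       R2 = 0.999, slope +1.20e-09 per mm^3, p = 0.000 -> correlated
```

ΔS in the layers beneath the dome rises linearly with fluid volume — the
swept source's advantage grows with the lesion — while the deep retina,
above the fluid, carries no such relationship.

`analysis/01_simulate_cohort.py` writes the ground-truth table,
`02_run_study.py` runs the full pipeline end to end (per-layer paired
tests, densities, regressions, Bland-Altman → `results/study/`), and
`05_vessel_density.py` checks density recovery against the pixel-counted
truth.  The same pipeline is scriptable via the `octa-compare run` and
`octa-sim` command-line tools with a YAML configuration.

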