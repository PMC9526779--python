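# petinsert

Hybrid PET lesion-insertion simulation: synthetic spheres inserted into
acquired raw data prior to reconstruction, for the quantitative assessment
of PET scanner performance.

## The problem

Physical phantom experiments give ground truth but are expensive to repeat:
each sphere-to-background ratio (SBR) means refilling, repositioning and
rescanning. A hybrid alternative inserts *synthetic* lesions into *real*
acquired raw data: model the sphere as a fractional-voxel mask, assign it
an activity concentration tied to the measured background, forward-project
it through the scanner's system model into a sinogram, add a Poisson noise
realization, sum it with the original sinogram, and reconstruct the
modified raw data exactly like the original. One baseline acquisition then
yields any number of lesion configurations with known size, location and
activity.

`petinsert` implements this pipeline end-to-end and — because no raw
clinical data can ship with a package — pairs it with a digital NEMA-IQ-style
body phantom (torso cross-section, lung insert, ring of six spheres of
internal diameter ~13/10/8/6/5/4 mm) so the whole method can be validated
in silico: acquire hot-sphere series directly, insert synthetic spheres
into a cold-sphere baseline at the same ratios, and compare the two arms.

It is intended for medical-physics and image-reconstruction researchers who
want a transparent, fully inspectable reference implementation of the
insertion method and its evaluation statistics.

## What is computed

* **Fractional sphere masks** — each voxel holds the fraction of its
  `factor^3` (default 16^3) sub-voxel centers inside the sphere, the
  sub-voxel equivalent of upsample → binarize → block-average.
* **Forward model** — per axial slice, a 2-D parallel-beam projector with
  exact pixel/strip overlap weights:
  `E[s,a,r] = sens · T · eff[a,r] · e^{-∫μ dl} · L[s,a,r](G_σ * λ) · A_bin`,
  where `λ` is the activity image (Bq/mL), `G_σ` an in-plane Gaussian
  resolution kernel, `L` the strip line integral and `A_bin` the bin
  cross-section. The back projector is the exact matrix adjoint.
* **Reconstruction** — MLEM and OSEM,
  `x ← x · A_Sᵀ(y_S / A_S x) / A_Sᵀ 1` per angle subset `S`, fixed
  iteration count, Gaussian post-filter.
* **Quantification** — per-sphere VOI measurements AC_mean / AC_max and
  recovery coefficients `RC = AC_measured / AC_theoretical`, replicate
  averaged.
* **Agreement battery** — Mann–Whitney U, Spearman ρ, D'Agostino–Pearson
  normality and Bland–Altman limits of agreement (d̄ ± 1.96 SD, %) between
  experimental and simulated RC tables, overall and per algorithm. The
  published RC tables ship as a fixture (`load_reference_rc_tables`).

## Worked example

```sh
python examples/sphere_masks.py
```

```
  d (mm)  analytic (mm^3)  mask (mm^3)   err % eq. d (mm)
   12.43          1005.57      1005.37  -0.020      12.43
    9.89           506.51       506.55   0.008       9.89
    7.86           254.25       254.26   0.001       7.86
    6.23           126.61       126.65   0.030       6.23
    4.95            63.51        63.49  -0.021       4.95
    3.95            32.27        32.28   0.026       3.95
```

Even the 3.95 mm sphere — smaller than two voxels across in-plane — is
represented to 0.03% in volume by the factor-16 fractional mask.

```sh
python examples/agreement_stats.py
```

```
        subset   n   MW p    rho  BA mean %  BA 1.96SD %
       RC_MEAN  48  0.639  0.975       1.95         16.7
   BPL RC_MEAN  24  0.665  0.963      -0.17         17.9
  OSEM RC_MEAN  24  0.621  0.980       4.08         14.6
        RC_MAX  48  0.728  0.974       3.26         22.5
    BPL RC_MAX  24  0.853  0.969       0.65         22.0
   OSEM RC_MAX  24  0.599  0.971       5.87         22.3
```

Read: across all 48 paired conditions the simulated recovery coefficients
are statistically indistinguishable from the experimental ones
(Mann–Whitney p ≫ 0.05), strongly correlated (ρ ≈ 0.97), with a mean
quantitative shift of ~2% (RC_mean) and ~3% (RC_max).

Other examples: `forward_and_reconstruct.py` (one scenario, RC vs sphere
size), `insert_spheres.py` (the insertion step on baseline raw data),
`twin_protocol.py` (the full in-silico validation, a few minutes).

## Command line

The same stages are available as a thin CLI for scripted runs:

```sh
petinsert acquire --config cfg.yaml --scenario "SBR 0:1" --seed 7 --out base
petinsert insert  --config cfg.yaml --baseline base --sbr 3.93 --seed 9 --out ins
petinsert recon   --config cfg.yaml --sinos ins --out ins_img
petinsert analyze --config cfg.yaml --series ins_img --out sim.csv
petinsert report  --experimental exp.csv --simulated sim.csv --out report/
```

Each stage writes its product (HDF5 sinograms, NIfTI + rescale-tag JSON
sidecar series, CSV tables) and a provenance log line; reruns with the same
config and seed are byte-identical.

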