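# cb1tacs

Quantification and test–retest reliability of type-1 cannabinoid (CB1)
receptor PET, built around dynamic time–activity curves (TACs) of a
reversible, slowly clearing radioligand with a metabolite-corrected
arterial plasma input function.

CB1 receptors are expressed throughout the brain, so no true reference
region exists and quantification has to work either from arterial blood
data or from semi-quantitative tissue measures. This package implements
the seven quantification routes such a study compares, plus the statistics
that decide which of them is *reliable* — i.e. stable enough across a
test–retest pair of scans to detect biological differences:

| route | needs blood? | outcome |
|---|---|---|
| `2kbv` — one-tissue compartment model, variable blood volume | yes | V_T = K1/k2 |
| `4kbv` — two-tissue compartment model, variable blood volume | yes | V_T = (K1/k2)(1 + k3/k4) |
| `sa_roi` — classic spectral analysis (NNLS) on regional TACs | yes | V_T = Σ αⱼ/βⱼ |
| `sa_map` — voxelwise spectral analysis, sampled parametric maps | yes | V_T per voxel |
| `rs_sa` — rank-shaping regularised spectral analysis | yes | V_T from the V_T(R) plateau |
| `srtm` — simplified reference tissue model, pons as pseudo-reference | no | BP_ND |
| `msuv` — modified SUV, activity·((weight+70)/2)/dose over ~30–59 min | no | mSUV |

Fits are weighted least squares with frame weights `w_i = L_i / T_i` (frame
length over true-coincidence rate). Reliability is summarised per region
by the signed test–retest difference 2·(retest−test)/(test+retest)·100, the
one-way random single-measures intraclass correlation coefficient
ICC(1,1) = (MSBS−MSWS)/(MSBS+(k−1)·MSWS), the between-subject coefficient
of variation, Bland–Altman limits of agreement, and the pallidum/pons
ratio as an index of preserved binding heterogeneity (ICC ≥ 0.75 reads as
good reliability).

Because raw human scans of this kind are not publicly available, the
package ships a first-class synthetic-data generator
(`cb1tacs.simulate`): a Feng-type bolus input function with
plasma-over-blood and parent-fraction corrections, one/two-tissue kinetics
with a vascular signal fraction, frame-averaged sampling on the 33-frame
~89-min acquisition design, count-dependent noise, and two-session cohorts
with separate between-subject and within-subject variability. Every
estimator can therefore be validated against known ground truth, and the
characteristic failure modes seen on real data — the over-parameterised
`4kbv` model and the pseudo-reference `srtm` collapsing to ICC ≈ 0 —
emerge from the simulation rather than being asserted.

## Worked example

Estimators follow the scikit-learn convention (constructor holds options,
`fit` returns `self`, fitted values carry a trailing underscore):

```python
import numpy as np
from cb1tacs import (OneTissueModel, SpectralVT, TruthEntry, default_schedule,
                     simulate_input, simulate_tac)

schedule = default_schedule()            # 33 frames, injection at scan second 30
plasma = simulate_input()                # bolus-shaped arterial input, 1 s grid

truth = TruthEntry(K1=0.15, k2=0.015, bv=0.05)   # V_T = 10, pallidum-like
tac = simulate_tac(truth, plasma, schedule, noise_scale=1.0, seed=7,
                   region_id="pallidum")

ct = OneTissueModel().fit(tac, plasma)
sa = SpectralVT().fit(tac, plasma)
print(f"true V_T        {truth.vt:.2f}")
print(f"2kbv  V_T       {ct.vt_:.2f}   (K1={ct.K1_:.3f}, k2={ct.k2_:.4f}, bv={ct.bv_:.3f})")
print(f"SA    V_T       {sa.vt_:.2f}   ({np.count_nonzero(sa.amplitudes_)} spectral components)")
```

```
true V_T        10.00
2kbv  V_T       9.91   (K1=0.147, k2=0.0148, bv=0.048)
SA    V_T       9.81   (4 spectral components)
```

At this noise level a single regional fit lands within ~1–2 % of the true
volume of distribution; the interesting question is how that error behaves
across sessions, which is what the pipeline answers. A full run —
simulate a cohort, quantify it with all seven methods, and build the
reliability tables — is one call (or `cb1tacs run` from the shell):

```python
from cb1tacs import RunConfig, run_pipeline
out = run_pipeline(RunConfig(seed=7, n_subjects=5, out_dir="demo"))
```

`demo/tables/summary_icc.csv` from that exact run (5 subjects, so the
per-region ICCs are noisy — the mean row is the headline):

```
          region_id     2kbv      4kbv   sa_roi     rs_sa      srtm     msuv   sa_map
          accumbens 0.934904 -0.071556 0.539557  0.887142 -0.313025 0.841175 0.947330
 anterior_cingulate 0.917154 -0.210761 0.529541 -0.000055 -0.040088 0.831254 0.899115
            caudate 0.944487 -0.170049 0.934490  0.966544 -0.473166 0.669694 0.960577
        hippocampus 0.942058 -0.067476 0.919482  0.795645 -0.351546 0.936239 0.938541
   inferior_frontal 0.963016 -0.062038 0.539252  0.773276 -0.536923 0.854848 0.916650
           pallidum 0.927934  0.016988 0.946497  0.944776 -0.790494 0.952707 0.893479
               pons 0.937382 -0.130866 0.920089  0.925972       NaN 0.948511 0.938869
           thalamus 0.946505 -0.087500 0.925369  0.918612  0.798175 0.866449 0.956024
               mean 0.939180 -0.097907 0.781785  0.776489 -0.243867 0.862610 0.931323
                 sd 0.013582  0.070956 0.203637  0.321298  0.513325 0.092313 0.025400
ratio_pallidum_pons 3.567090  3.574343 3.602709  3.733456       NaN 2.971583 3.953490
```

Reading it: the compartmental `2kbv` fit and the spectral-analysis maps
are highly repeatable (mean ICC ≈ 0.93), `4kbv` and the pseudo-reference
`srtm` are not (ICC ≈ 0), and the well-behaved methods preserve the ~3.6×
pallidum-over-pons binding gradient; the SRTM ratio is undefined because
the pons is its own reference (BP_ND ≈ 0). This is the qualitative
fingerprint expected of these methods on 90-min CB1 data.

## Command line

```bash
cb1tacs simulate --n 15 --bs-cv 0.35 --ws-cv 0.10 --seed 7 --out cohort/
cb1tacs fit --method 2kbv --method msuv --cohort cohort/ --out fits.csv
cb1tacs report --fits fits.csv --out tables/
cb1tacs run --config run.yaml          # everything, with provenance + logs
```

All CSV outputs carry `#`-prefixed provenance headers (package version,
seed, config hash); a fixed seed reproduces every artifact byte for byte.

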