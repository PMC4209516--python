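# relaxovb

Voxelwise **fractional blood volume (v_b)** mapping of white-matter
hyperintensities (WMHs) and normal-appearing white matter (NAWM) by
**T1 relaxographic imaging**: quantitative R1 (= 1/T1) maps are measured
before injection of an intravascular gadolinium contrast reagent (CR) and
repeatedly during its ~1-hour washout, and the tissue R1 time course is fit
to a two-site transendothelial water-exchange ("shutter-speed") model.  The
package targets researchers studying small-vessel contributions to deep
(dWMH) versus periventricular (pWMH) white-matter lesions in the aging
brain, and ships a digital brain phantom so every stage can be exercised
and validated without patient data.

## The model

Only blood water "sees" an intravascular CR, so during washout the blood
rate constant R1b(t) is elevated while the extravascular rate R1e is not.
Water exchanges across the capillary wall with mean intravascular residence
time τ_b, so the observed tissue rate R1t(t) is the smaller eigenvalue of
the two-site exchange-relaxation system

```
R1t(t) = smaller eigenvalue of  [ R1b(t) + k_b      -k_e      ]
                                [    -k_b        R1e + k_e    ]

k_b = 1/τ_b,   k_e = p / (τ_b (1 - p)),   p = v_b / f_w
R1e = (R1t(0) - R1b(0) p) / (1 - p)
```

where f_w accounts for CR being restricted to blood plasma.  With τ_b and
f_w held at 0.3 s and 0.8, the single free parameter v_b is estimated per
voxel by nonlinear least squares.  Plasma CR concentration follows from
blood R1 via `R1b = R1b(0) + r1 (1 - h) [CR_p]` with relaxivity
r1 = 3.3 s⁻¹mM⁻¹ and microvascular hematocrit h = 0.40.

R1 itself is estimated per voxel from four variable-inversion-time MPRAGE
images (TI = 300, 1800, 3200 ms, and no inversion; TR = 3500 ms, 6° flip)
using a closed-form steady-state signal model of the segmented
inversion-recovery gradient-echo sequence, validated against step-by-step
Bloch simulation.  Ventricular permeability (the rate of CR accumulation in
CSF, in μM/hr) is estimated from the linear rise of CSF R1 in a small
pure-CSF ROI in a posterior horn of the lateral ventricles.

## Worked example

Run the full synthetic study — phantom generation, R1 mapping, blood-curve
extraction, v_b mapping, region summaries, CSF permeability, and Monte Carlo
uncertainty — with the library:

```python
from relaxovb import StudyConfig, run_study

res = run_study(StudyConfig(out_dir="study_out", seed=7))
for s in res.region_summaries.values():
    print(s.summary())
print(res.permeability.summary())
```

which prints (seed 7):

```
Region dWMH
  voxels (kept/total)   522/522
  excluded              0.0%
  distribution          gaussian
  mean v_b              1.77 mL/100 g
  dispersion (SD)       0.55 mL/100 g
Region pWMH
  voxels (kept/total)   7168/7168
  excluded              0.0%
  distribution          gaussian
  mean v_b              2.40 mL/100 g
  dispersion (SD)       0.49 mL/100 g
Region NAWM
  voxels (kept/total)   3822/3822
  excluded              0.0%
  distribution          gaussian
  mean v_b              2.40 mL/100 g
  dispersion (SD)       0.55 mL/100 g
Ventricular permeability estimate
=================================
method            slope
window            40.0 min
total dR1         0.0075 s^-1
relaxivity r1     3.30 s^-1 mM^-1
permeability      3.39 uM hr^-1
```

The phantom's ground truth is v_b = 1.8 mL/100 g in deep lesions and
2.4 mL/100 g in periventricular lesions and NAWM, with a CSF CR
accumulation rate of 3.4 μM/hr — the pipeline recovers the deep-lesion
blood-volume deficit and the permeability from noisy images (SNR 100).

Voxel-level fits are exposed as statsmodels-style model objects:

```python
from relaxovb import TwoSiteExchangeModel, VoxelRelaxationSeries
res = TwoSiteExchangeModel(series, blood_curve).fit()
print(res.summary())        # v_b, std err, residual SS, convergence
```

The same pipeline is available from the shell:

```bash
relaxo-vb run --config study.yaml --out study_out --seed 7
relaxo-vb phantom --out phantom_dir      # NIfTI volumes + truth tables
relaxo-vb permeability --csv csf_series.csv
```

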