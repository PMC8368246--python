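# mfiseg

Automated quantification of **muscle fat infiltration (MFI)** from Dixon
fat-water MRI, built for the multi-muscle cervical-spine setting where
manual segmentation of the seven bilateral muscle groups (multifidus +
semispinalis cervicis, longus colli/capitis, semispinalis capitis,
splenius capitis, levator scapulae, sternocleidomastoid, trapezius; 14
labels total) takes hours per scan. The toolkit is aimed at
musculoskeletal imaging researchers who want to (a) quantify per-muscle
fat infiltration and volume from fat/water or in-phase/out-of-phase image
pairs, (b) train and evaluate a 3D segmentation network for the task, and
(c) run the full accuracy/reliability and cohort-characterisation
statistics on the resulting measures.

## The quantities at the core

Two-point Dixon MRI gives in-phase and out-of-phase images,
IP = W + F and OOP = W − F, from which fat-only and water-only signal
follow algebraically: F = (IP − OOP)/2, W = (IP + OOP)/2. For a muscle
region M,

&nbsp;&nbsp;&nbsp;&nbsp;MFI = 100 · mean(F|M) / ( mean(F|M) + mean(W|M) )&nbsp;&nbsp;[%],
&nbsp;&nbsp;&nbsp;&nbsp;volume = |M| · dx·dy·dz / 1000&nbsp;&nbsp;[ml].

Segmentations are compared with Dice, Jaccard, conformity coefficient
CC = (3·Dice − 2)/Dice, TPR, TNR, PPV and volume ratio; paired measures
with Bland-Altman bias ± 1.96 SD limits, MAE, RMSE, r², through-origin β,
and ICC(2,1) (two-way random, absolute agreement, single measure) with
F-test and confidence interval. Cohort tables get paired t-tests, sex
ANCOVA with marginal means, partial correlations, and a repeated-measures
ANCOVA with Greenhouse-Geisser correction.

Because clinical scans with expert labels are rarely shareable, the
package ships a phantom simulator that generates Dixon volumes of the
14-label anatomy with exact ground truth (deep muscles fattier than
superficial, bone/subcutaneous-fat/air compartments, Gaussian signal
noise), simulated imperfect raters, and synthetic cohorts with injected
sex/age/BMI effects — so the entire pipeline is testable end to end. The
segmentation model is a compact 3D dense V-Net (dense feature stacks at
three scales, dilated convolutions, V-Net down/upsampling with skip
forwarding, spatial dropout, Dice-hinge loss) implemented in NumPy and
sized to train on a CPU in minutes.

## Worked example

```python
from mfiseg import (PhantomSpec, generate_phantom, measure_all,
                    average_bilateral, default_scheme)

scheme = default_scheme(12)
dixon, mask, truth = generate_phantom(PhantomSpec.cervical(noise_sd=2.0, seed=42))
measures = measure_all(dixon, mask, scheme, scan_id="phantom042")
print(measures.head(6).to_string(index=False))
print(average_bilateral(measures, scheme).to_string(index=False))
```

prints

```
   scan_id  label group  side  mfi_percent  volume_ml  voxel_count flags
phantom042      2  MFSS  left    16.896297    0.28224          192
phantom042      1  MFSS right    16.872415    0.28224          192
phantom042      4    LC  left    14.201837    0.18816          128
phantom042      3    LC right    13.876309    0.18816          128
phantom042      8 SSCap  left    14.878761    0.24696          168
phantom042      7 SSCap right    15.121459    0.24696          168

group  mfi_percent  volume_ml flags
 MFSS    16.884356    0.56448
   LC    14.039073    0.37632
SSCap    15.000110    0.49392
SPCap    10.026142    0.61152
   LS     6.939116    0.37632
  SCM     9.127627    0.47040
   TR     8.013624    0.14112
```

One row per label: the deep extensor MFSS (true fat fraction 0.17) is
measured at ≈16.9% MFI under noise, left and right agree to ~0.1
percentage points, and volumes follow directly from voxel counts at
0.7 × 0.7 × 3.0 mm. The bilateral table averages left/right MFI per group
— the form the cohort statistics consume.

The same operations are available from the shell:

```sh
mfiseg simulate --out sim/ --n-scans 3 --seed 1
mfiseg quantify --fat sim/phantom000_fat.nii.gz --water sim/phantom000_water.nii.gz \
                --mask sim/phantom000_mask.nii.gz --out measures.csv
mfiseg evaluate --gt sim/phantom000_mask.nii.gz --pred pred.nii.gz --out metrics.csv
mfiseg characterize --cohort cohort.csv --out results/
mfiseg demo --out demo/ --seed 0        # simulate -> train -> evaluate
```

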