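# muscleseg

Transfer learning for data-efficient skeletal-muscle segmentation at the
L3 vertebral level, rebuilt end-to-end on synthetic CT phantoms.

Automatic delineation of skeletal muscle on a single axial CT slice at L3
is the standard way to quantify sarcopenia — muscle area (SMA, cm²) and
muscle density (SMD, mean HU) are established prognostic biomarkers in
oncology. Training segmentation networks normally demands hundreds of
expert delineations; the central question here is how far *pre-training*
(network-based transfer learning) can cut that requirement. The package
implements the full experimental machinery for studying this question on a
desk: a seeded phantom generator with ground-truth muscle and bone masks,
four pre-training source tasks (image reconstruction, self-supervised
jigsaw solving, image classification, and an auxiliary dense segmentation
task), cross-architecture weight transfer by layer name, fine-tuning on
nested training subsets (n = 5 ⊂ 10 ⊂ 25 ⊂ …), evaluation, and a
simulated inter-observer study as the human baseline.

It is aimed at researchers studying transfer learning and evaluation
methodology for medical image segmentation who want a fully reproducible,
CPU-only sandbox with exact ground truth.

## Core quantities

For a predicted mask Ŷ and reference Y:

* Dice similarity coefficient: `DSC = 2|Ŷ∩Y| / (|Ŷ|+|Y|)`
* RMS distance-to-agreement: root mean square, over the K points Ŷ_k of
  the predicted boundary, of the distance to the nearest reference
  boundary point, in cm.
* Training loss: `L = 1/N Σ_n (L_BCE + L_DSC)` with pixel-mean binary
  cross-entropy and soft Dice loss.
* SMD = mean HU inside the (bone-subtracted) mask; SMA = pixel count ×
  pixel area in cm². Bone is removed by thresholding at 175 HU and
  dilating 2 mm.
* Adam fine-tuning at learning rate 3e-3 from scratch, 3e-4 after weight
  transfer; checkpoint at minimum validation loss.
* Dunnett's many-to-one test compares every (source task, n) cell against
  the observer control with family-wise error control.

See `docs/methods.md` for the model of the phantom and observers, all
defaults, and design discussion.

## Worked example

```python
import numpy as np
from muscleseg import (
    PhantomParams, generate_phantom, calibrate_observer, simulate_observer,
    dsc, rms_dta, sma, smd, bone_mask, remove_bone,
)

params = PhantomParams(cohort_size=30, image_side=64, spacing_mm=6.0)
cohort = generate_phantom(params, seed=7)
ct, muscle, bone = cohort[0]
print(f"SMA {sma(muscle):.1f} cm^2, SMD {smd(ct, muscle):.1f} HU")

model = calibrate_observer([m for _, m, _ in cohort[:10]], target_dsc=0.90, seed=1)
scores = [
    (dsc(o, m), rms_dta(o, m))
    for i, (_, m, _) in enumerate(cohort)
    for o in [simulate_observer(m, model, seed=100 + i)]
]
d, r = np.mean(scores, axis=0)
print(f"panel mean DSC {d:.3f}, mean RMS-DTA {r:.3f} cm over {len(scores)} contours")

clean = remove_bone(muscle, bone_mask(ct))
print(f"bone-subtracted SMD {smd(ct, clean):.1f} HU over {clean.area_px} px")
```

prints

```
SMA 124.2 cm^2, SMD 39.9 HU
panel mean DSC 0.903, mean RMS-DTA 0.333 cm over 30 contours
bone-subtracted SMD 39.9 HU over 345 px
```

i.e. the first phantom has a plausible muscle compartment (~124 cm², ~40 HU
— this patient drew a low muscle density from the cohort's myosteatosis
spread); a simulated observer panel calibrated to a 0.90 Dice target
reproduces it at mean DSC 0.903 with ~3.3 mm RMS boundary disagreement;
and bone subtraction leaves SMD unchanged here because the muscle ring and
the expanded bone mask barely overlap on this slice.

The full pipeline (simulate → observers → pretrain → fine-tune → evaluate
→ report) runs from the command line:

```sh
muscleseg all --out runs/ --seed 0          # desk-scale smoke grid
muscleseg write-config experiment.json --scale paper
```

outputs land under `runs/`: the cohort as 2-D NIfTI files with a CSV
manifest, pre-trained weight archives, per-run loss histories and metric
CSVs, summary/Dunnett tables, learning-curve plots, and a checksummed
manifest. Reruns are cached: completed stages and runs are skipped.

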