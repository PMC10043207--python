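# afablate

In-silico study of deep-learning interpretability for atrial-fibrillation
(AF) ablation therapy on 2D left-atrial tissue disks.

Radiofrequency catheter ablation destroys or isolates arrhythmogenic
tissue to terminate AF, but choosing the right lesion set for a given
atrium is hard.  This package builds the whole study pipeline needed to
ask whether an image-based classifier predicting ablation outcomes *looks
at the right tissue*:

1. **Synthetic cohorts** of circular LA tissue disks (0.3 mm pixels) with
   pulmonary-vein (PV) openings and spatially correlated fibrosis, plus a
   weighted-average + affine augmentation scheme for virtual patients.
2. **Electrophysiology**: a three-variable Fenton–Karma monodomain model
   (`du/dt = ∇·D∇u − (I_fi + I_so + I_si)`, forward Euler, 5-point
   Laplacian with harmonic-mean face conductances, zero-flux boundaries),
   AF induced by the standard cross-field S1–S2 protocol (S2 at 28 ms).
3. **Three ablation strategies** per disk — PVI (rings around the PVs),
   FIBRO (perimeters of fibrotic patches), ROTOR (discs at detected
   phase-singularity sites) — each judged *successful* if AF terminates
   within the episode limit with <40% of tissue ablated.
4. **A multi-label CNN** (4×32-filter conv blocks; 2048/128/3 linear
   units; dropout 0.8; sigmoid) trained with the multi-label MSE loss
   `Σᵢ(ŷᵢ−yᵢ)²/N` (Adam, lr 1e-4) under a hold-out + fold-rotation
   protocol to predict the three success labels from the tissue image.
5. **Attribution analysis**: GradCAM, occlusion and LIME maps per
   strategy, thresholded at a multiple of their mean attribution into
   "informative regions" and scored against the hidden lesions with IoU,
   lesion percentage and NAT (non-arrhythmogenic tissue) percentage;
   Wilcoxon signed-rank comparisons between methods at the
   Bonferroni-corrected alpha 0.05/3 ≈ 0.017.

The network, its backpropagation and all attribution methods are
implemented in numpy; the solver's inner loop is compiled with numba.
See `docs/methods.md` for the model, parameter choices and the scaled
study conditions.

## Worked example

```python
from afablate import tissue, ablation, epsim

# one synthetic disk
disks, manifest = tissue.generate_cohort(
    n_base=1, n_synthetic=0, seed=4,
    config=tissue.CohortConfig(threshold_range=(0.5, 0.7)))
disk = disks[0]
print(f"fibrotic fraction: {disk.fibrotic_fraction:.2f}")

# simulate AF and judge the three strategies (scaled settings)
cfg = ablation.LabelConfig(dt=0.1, t_end=1200.0, lesion_time=400.0)
labels, outcomes = ablation.label_disk(disk, cfg)
for s, o in outcomes.items():
    print(f"{s.value:5s} ablated {o.lesions.ablated_fraction:5.1%} "
          f"terminated={o.terminated} success={o.success}")
```

prints

```
fibrotic fraction: 0.19
pvi   ablated  4.4% terminated=False success=False
fibro ablated  3.8% terminated=True success=True
rotor ablated  0.0% terminated=False success=False
```

Ablating the fibrosis perimeters (3.8% of tissue) terminated this disk's
episode; PV isolation did not, and the rotor strategy found no stable
phase-singularity sites to ablate (empty lesion set, so it fails by
non-termination).  The resulting label vector (0, 1, 0) — ordered
(PVI, FIBRO, ROTOR) — is what the CNN learns to predict from the image
alone.

The whole study (cohort → labels → CNN → attribution → report files) runs
with

```bash
afablate run-all --seed 1 --out results/study
```

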