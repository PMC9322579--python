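# srqt2

Super-resolution T2-weighted reconstruction and quantitative T2 mapping
from orthogonal multi-echo fast-spin-echo volumes, with a full forward
simulator so every stage is testable without scanner data.

## The problem

Portable low-field MRI systems (tens of mT) trade signal-to-noise for
accessibility. To keep scan times clinically tolerable, images are
acquired with strongly anisotropic voxels — for example 1.5 × 1.5 mm
in-plane with 5 mm slices — which hampers visualization and makes
quantitative mapping expensive: a conventional quantitative T2 (qT2)
protocol repeats the whole acquisition at several echo times.

This package implements a combined strategy: acquire **three** anisotropic
fast-spin-echo volumes in **orthogonal orientations** (axial, sagittal,
coronal), each with a **different echo time** (≈123, 182, 242 ms). The
three volumes are fused by registration-based super-resolution into one
1.5 mm isotropic T2-weighted volume for anatomical reading, and — because
each orientation carries its own TE weighting — a voxelwise T2 map comes
for free from the same data.

## The model

Magnitude signal of a (single-compartment) tissue at echo time TE:

```
S(TE) = M0 · exp(−TE / T2)
```

Each voxel of the aligned multi-TE stack is fit in two stages: an ordinary
least-squares line through `ln S` vs `TE` (slope −1/T2) initializes a
Nelder–Mead simplex search (100 iterations) that minimizes the residual
sum of squares of the untransformed model. Agreement between T2 estimates
from different protocols is summarized with the intraclass correlation in
its two-way, absolute-agreement, single-measures form ICC(A,1).

The toolkit contains:

* `volumes` — NIfTI I/O, RAS grid geometry, rigid resampling;
* `phantoms` — digital ground-truth phantoms (multi-element relaxometry
  phantom and a brain-like head with six white-matter ROIs);
* `acquisition` — forward simulator: TE weighting, rigid motion, ideal
  boxcar thick slices, in-plane binning, Rician noise;
* `registration` — rigid multi-resolution registration and iterative
  template-construction super-resolution;
* `denoise` — spatially adaptive non-local-means filtering;
* `fitting` — batched two-stage voxelwise T2 estimation;
* `metrics` — ICC, T2-to-noise ratio, ROI and recovery statistics;
* `pipeline` / `cli` — end-to-end experiments and the `srqt2` command.

## Worked example

Simulate the three orthogonal acquisitions of the brain phantom without
noise, reconstruct, and fit:

```python
from srqt2 import ExperimentConfig, run_sr_experiment

config = ExperimentConfig(phantom_kind="brain", mode="none",
                          denoise=False, seed=1)
result = run_sr_experiment(config)
print("template grid:", result.sr.template.data.shape,
      "at", result.sr.template.spacing, "mm")
print(result.roi_stats[["name", "true_t2_ms", "n_voxels", "mean_t2_ms"]]
      .to_string(index=False, float_format=lambda v: f"{v:.1f}"))
```

prints

```
template grid: (96, 96, 96) at (1.5, 1.5, 1.5) mm
              name  true_t2_ms  n_voxels  mean_t2_ms
     cerebellar_wm       110.0       156       110.0
   corpus_callosum       112.0       148       112.2
   left_frontal_wm       114.0       116       114.0
  right_frontal_wm       118.0       117       118.0
 left_posterior_wm        98.0       112        98.0
right_posterior_wm       102.0       112       102.0
```

i.e. the super-resolved map recovers every regional T2 to well within a
millisecond of ground truth in the noiseless limit; the residual 0.2 ms
on the corpus callosum is thick-slice partial volume. With noise enabled
(`mode="invivo"` or `mode="phantom"`) the same call reports the
noise-level-dependent estimates, and `run_agreement_study` compares the
super-resolution pipeline against a five-TE single-orientation reference
on the same phantom instances.

The command-line interface stages the same pipeline through files:

```
srqt2 simulate config.yaml     # phantom + 8 simulated acquisitions
srqt2 reconstruct config.yaml  # SR template, aligned inputs, transforms
srqt2 fit config.yaml          # T2 / M0 / RSS maps + masks
srqt2 evaluate config.yaml     # per-ROI statistics table
srqt2 run-all config.yaml      # agreement study, ICC report
```

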