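# glottiseg

Training and re-training toolkit for glottis segmentation in laryngeal
high-speed video (HSV).

During phonation the vocal folds oscillate at hundreds of hertz; HSV
endoscopy captures the motion, and quantitative voice analysis needs the
glottal gap segmented in every frame.  Clinics record with heterogeneous
hardware — different cameras, light sources, spatial resolutions, rigid
and flexible endoscopes — so a segmentation network trained on one pool
of systems faces *concept shift* on the next one.  `glottiseg` implements
the full lifecycle for this setting, for researchers working with
BAGLS-style annotated frame corpora:

* **ROI preprocessing** — per video, the union of the mask bounding boxes
  defines a reference box `B_ref`; the smallest and largest 2:1
  (height:width) boxes around it bound a family of valid crops, and each
  training epoch samples a random 2:1 crop `B_Var` from that family.
  Frames reach the network at 2:1 without distorting the glottis, unlike
  plain whole-frame resizing (also provided, as `legacy`).
* **U-Net training** — canonical encoder–decoder with skip connections
  (micro: depth 3 / 8 channels for CPU work; full: depth 5 / 32), soft
  Dice loss, Adam with a triangular cyclic learning rate in
  [1e-6, 1e-3], mini-batches of 8, early stopping on validation Dice
  (patience 10, best weights restored), per-epoch re-augmentation
  (brightness/contrast, gamma, noise, blur, ≤30° rotation, horizontal
  flip) and per-epoch ROI re-sampling.  The network and its
  backpropagation are implemented in numpy and are exactly reproducible
  under a seed.
* **Re-training strategies** for absorbing a new camera domain: training
  from **scratch** on old + new data; **incremental** finetuning on
  sequential new-data batches b ∈ {25%, 50%, 75%, 100%}; **mixed**
  finetuning (each batch half new data, half old); and finetuning with
  **knowledge distillation** (`fkd`), where the student minimizes
  `α·Dice(student, truth) + (1−α)·Dice(student, teacher)` against a
  frozen **static** teacher (the baseline) or a **dynamic** teacher that
  tracks the student after every batch.
* **Evaluation** — per-frame IoU, per-camera-group mIoU ± sd, and ΔmIoU
  in percentage points against a named baseline.
* **Synthetic HSV generator** — oscillating elliptical glottal gap with
  exact analytic masks, rendered under configurable camera domains
  (resolution, brightness, contrast, noise, blur, vignette, honeycomb
  fiber-optic lattice), written in the BAGLS-style on-disk layout.  It
  makes every pipeline stage testable end to end on one CPU with no
  downloads.

See `docs/methods.md` for the model details, parameter choices, and what
the synthetic studies do and do not demonstrate.

## Worked example

Generate a two-domain synthetic corpus (the second domain gets the
honeycomb lattice of a flexible endoscope), train a micro U-Net on it,
and evaluate per camera group:

```sh
glottiseg synth --domains 2 --videos 6 --frames 8 --seed 1 --out corpus
glottiseg train --data corpus --out run --arch micro --max-epochs 25 --seed 1
glottiseg evaluate --checkpoint run/model.npz --data corpus --out eval
cat eval/summary.json
```

which prints (numbers from this exact command sequence):

```json
[
 {"group": "cam0", "n_frames": 48, "miou": 0.9091, "miou_sd": 0.2007},
 {"group": "cam1", "n_frames": 48, "miou": 0.9092, "miou_sd": 0.1074},
 {"group": "all", "n_frames": 96, "miou": 0.9092, "miou_sd": 0.1609}
]
```

`miou` is the mean per-frame intersection-over-union on each camera
group (1.0 = perfect; frames where prediction and ground truth are both
empty — a correctly recognized closed glottis — count as 1).  Both
domains score alike here because both were in the training pool; train a
model on one domain only and evaluate on the other (the
`glottiseg.experiments` module automates this) to see the concept-shift
gap the re-training strategies exist to close.  Note this evaluation is
on the training corpus for brevity; the library API
(`glottiseg.experiments`, `cross_validate`) does proper video-level
held-out evaluation.

The same pipeline pieces are available as library functions:

```python
import glottiseg as g
from glottiseg.experiments import forgetting_study

study = forgetting_study(master_seed=1)   # ~5 min on one CPU
print(study.medians)
```

runs the full forgetting/mitigation comparison (baseline on a rigid-like
domain, then incremental / mixed / dynamic-distillation finetuning on a
flexible-endoscope-like domain) and reports paired median effects.

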