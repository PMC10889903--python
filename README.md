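# illusionprobe

Does a convolutional network that has learned to see tilt also see a tilt
*illusion*?

`illusionprobe` is a research package for probing CNN tilt classifiers with
an oblique-grating illusion of the Café-Wall family: horizontal coloured
bars decorated with alternating black/white diamonds on a striped
background appear tilted to human observers even though every bar is
physically horizontal.  The package is aimed at vision researchers who want
a fully reproducible, CPU-scale version of this experiment: synthesize the
stimuli, score perceived tilt into strength classes, train a classifier on
genuinely tilted images, and then ask — through classifications,
permutation significance, Grad-CAM and representational dissimilarity —
whether the network treats the illusion like a real tilt.

## The experiment in brief

1. **Stimuli.** A fixed grid of 144 illusion images: 12 bar hues × 6
   diamond widths (5–10 px) × 2 mirror "positional settings" that reverse
   the apparent tilt direction.
2. **Perceived strength.** For each stimulus, illusion strength is the mean
   of the absolute four-bar angles an observer sets in an adjustment task
   (here produced by a documented synthetic response model; real angle
   tables drop in via CSV).  Strengths bin into eight 0.1° levels; levels
   1–4 (≤ 0.4°) are class **C1** ("no illusion"), levels 5–8 are **C2**
   ("with illusion").
3. **Classifier.** A compact CNN (`desknet`) is trained to discriminate
   genuinely tilted bar gratings — tilt magnitudes drawn from the same
   eight levels — from near-horizontal ones, and validated on an
   independent tilted test set.
4. **Probe.** The trained network then sees the 144 physically horizontal
   illusion images, and its internals are examined: Grad-CAM maps
   L^c = ReLU(Σ_k α_k A^k) with α_k the spatial mean of ∂y^c/∂A^k; 8 × 8
   cross-set RDMs R = r / mean(r) pairing perceived-tilt renders with
   illusion renders by level; a permutation test that retrains on shuffled
   labels; and a scalar framework score combining the Grad-CAM and RDM
   evidence.

See `docs/methods.md` for the full model, parameter and numerics account.

## Worked example

```python
from illusionprobe import (
    ResponseModelParams, aggregate_strengths, enumerate_stimulus_grid,
    simulate_responses,
)

grid = enumerate_stimulus_grid()
records = simulate_responses(grid, ResponseModelParams(seed=0))
strengths = aggregate_strengths(records)
print(len(grid), "stimuli")
print({c: sum(1 for s in strengths if s.illusion_class == c)
       for c in ("C1", "C2")})
```

prints

```
144 stimuli
{'C1': 89, 'C2': 55}
```

— the stimulus grid, scored from 23 synthetic observers into 89 weak-
illusion (C1) and 55 strong-illusion (C2) stimuli.  From there,
`examples/train_tilt_classifier.py` trains the classifier and prints its
per-epoch log and independent-test accuracy, `examples/gradcam_overlay.py`
writes class-evidence overlays, and `examples/cross_set_rdm.py` prints the
per-depth RDM diagonal contrasts.  Each script in `examples/` is a short
narrative: build a small input, run one capability, print what the numbers
mean.

The same workflow is scriptable from the shell:

```bash
illusionprobe simulate-humans --seed 0 --out angles.csv
illusionprobe score-strengths --angles angles.csv --out strengths.csv
illusionprobe build-datasets --seed 0 --out-dir data --angles angles.csv
illusionprobe train --seed 0 --train-manifest data/train.csv \
    --val-manifest data/val.csv --out model.npz
illusionprobe run-all --seed 0 --out-dir results/run   # everything at once
```

`run-all` writes every artefact (manifests, trained weights, Grad-CAM
overlays, per-layer RDMs, the depth profile and `run_report.json`) under
one directory, reproducibly from the single seed.

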