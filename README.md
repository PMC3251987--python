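# veinline

Finger-vein verification with the **local line binary pattern (LLBP)**
texture descriptor.

Finger veins are an internal biometric trait: they are captured by
near-infrared transillumination, are hard to forge, and are unaffected by
skin condition. `veinline` implements a complete verification pipeline for
such images — preprocessing, alignment, binary feature codes, template
matching and accuracy evaluation — together with a seeded synthetic
vein-image generator, so every stage is testable without a capture device.

## The pipeline

1. **ROI extraction.** The bright finger is segmented from the dark
   background at the Otsu threshold; a fixed 480 × 160 window is cropped
   around the object centroid and downscaled by 0.4 to 192 × 64 pixels.
2. **Enhancement.** A modified Gaussian high-pass mask
   `H(x, y) = a (1 − e^{−D²(x,y) / 2D₀²}) + b` (with `D` the distance to
   the mask center) suppresses the slowly varying finger profile and
   raises the contrast of the dark vein lines.
3. **Alignment.** The integer translation between two enhanced images is
   estimated from the peak of their phase-only correlation (POC) surface;
   the overlapping common regions are cropped. A pair whose shift reaches
   `|t_x| ≥ 20` or `|t_y| ≥ 10` is rejected as two different fingers.
4. **Feature extraction.** LLBP compares every pixel on a length-`N`
   horizontal and vertical line against the line's center through
   `s(x) = 1 if x ≥ 0 else 0`, giving `2(N − 1)` bits per pixel
   (`N − 1` for the single-direction variants). The line-shaped
   neighborhood follows the elongated vein structures better than the
   square `LBP(P, R)` neighborhood, which is included as a baseline.
5. **Matching.** The normalized Hamming distance
   `HD = ‖codeA ⊗ codeB‖ / CodeLength` scores the pair: near 0 for the
   same finger, near 0.5 for different fingers, exactly 1.0 for rejected
   alignments.
6. **Evaluation.** False-acceptance and false-rejection rates over a
   threshold grid, the equal error rate (EER) at their crossing, and an
   `(N, S)` grid search for the descriptor line length and enhancement
   mask size. The defaults are the tuned operating point `S = 15`,
   `N = 21` (full LLBP; `N = 17` for the vertical-only variant).

## Worked example

```python
import numpy as np
from veinline import make_finger_model, generate_finger_image, verify_pair

finger_a = make_finger_model(11)
finger_b = make_finger_model(22)
probe    = generate_finger_image(finger_a, sample_seed=1)
gallery  = generate_finger_image(finger_a, sample_seed=2)
imposter = generate_finger_image(finger_b, sample_seed=1)

genuine = verify_pair(probe, gallery)
attack  = verify_pair(probe, imposter)
print(f"genuine : hd={genuine.hd:.4f} shift=({genuine.translation.t_x}, {genuine.translation.t_y}) rejected={genuine.rejected}")
print(f"imposter: hd={attack.hd:.4f} shift=({attack.translation.t_x}, {attack.translation.t_y}) rejected={attack.rejected}")
```

prints

```
genuine : hd=0.0876 shift=(0, 0) rejected=False
imposter: hd=1.0000 shift=(0, 24) rejected=True
```

Two samples of the same synthetic finger differ on ~9 % of their 302,720
LLBP code bits after POC alignment found no residual shift, well below
any sensible acceptance threshold. The cross-finger pair produced a
spurious 24-pixel POC shift — beyond the alignment limit — so it was
rejected outright and scored the maximal distance 1.0.

The same steps are available from a shell:

```sh
veinline synthesize --subjects 2 --fingers 2 --samples 3 --seed 7 --out data/
veinline verify --probe data/S001/left-index_01.png --gallery data/S001/left-index_02.png
veinline evaluate --manifest data/manifest.csv --out report.json
veinline gridsearch --manifest data/manifest.csv --N 17,19,21 --S 13,15
veinline describe --image data/S001/left-index_01.png --raw --out codes.png
```

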