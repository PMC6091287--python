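# vpmmi — valve-guided probability-map mutual-information registration

`vpmmi` registers a 2-D intraoperative ultrasound (TEE-like) image to a
preoperative CT-like reference of the same heart. The two modalities show
the same anatomy with very different gray levels — contrast-filled chambers
are bright on CT but anechoic (dark) on echo — which makes similarity
metrics computed on raw intensities unreliable. The package implements a
two-stage method built for that gap:

1. **Coarse stage.** Three corresponding valve landmarks per image (valves
   are conspicuous in both modalities) determine a planar affine transform
   `T_basic` exactly: three non-collinear point pairs fix the six affine
   degrees of freedom.
2. **Probability remapping.** Each image `I` with foreground segmentation
   `G` is *region-enhanced*: a constant level (`N = 80` for the reference,
   `M = 100` for the floating image) is added inside the ROI, separating
   foreground and background intensity bins. The per-intensity ROI fraction

   `f(i) = #(ROI pixels of intensity i) / #(all pixels of intensity i)`

   then converts the enhanced image into a *probability map* `P(x) = f(I_h(x))`
   — the probability that pixel `x` lies inside the ROI. Both modalities
   land on a common [0, 1] scale regardless of their gray-level conventions.
3. **Fine stage.** Normalized mutual information,
   `NMI(A, B) = (H(A) + H(B)) / H(A, B) ∈ [1, 2]`,
   between the two probability maps is maximized over affine parameters
   with Powell's derivative-free direction-set method, warm-started at
   `T_basic` so the search begins inside the right basin. The floating
   image is finally resampled through `T_final` with cubic interpolation.

Evaluation utilities (Dice overlap, RMS target registration error against a
reference "bronze standard" transform) and a seeded synthetic phantom
generator (pseudo-CT / speckled fan-masked pseudo-TEE pairs with known
ground-truth transform) make the whole pipeline testable without clinical
data.

Intended users: researchers in multimodal medical image registration and
image-guided intervention who need a transparent, scriptable 2-D baseline.

## Worked example

```python
import vpmmi
from vpmmi.phantom import make_phantom_pair, perturb_landmarks

# synthetic CT/TEE-like pair with a known moving->fixed affine
pair = make_phantom_pair(seed=0)

# simulate 2 px operator click error on the valve landmarks
f_lm = perturb_landmarks(pair.fixed_lm, sd=2.0, seed=1, shape=pair.fixed.shape)
m_lm = perturb_landmarks(pair.moving_lm, sd=2.0, seed=2, shape=pair.moving.shape)

result = vpmmi.register_vpmmi(pair.fixed, pair.moving, pair.fixed_mask,
                              pair.moving_mask, f_lm, m_lm)
print(f"NMI {result.nmi_initial:.4f} -> {result.nmi_final:.4f} "
      f"in {result.iterations} Powell iterations")

report = vpmmi.evaluate_run(result, pair.moving_mask, pair.t_true,
                            pair.fixed.pixel_size, out_shape=pair.fixed.shape)
print(f"Dice vs ground truth: {report.dice:.4f}")
print(f"TRE (RMS): {report.tre_rms_mm:.4f} mm over {report.n_points} ROI pixels")
```

Output:

```
NMI 1.6544 -> 1.8656 in 7 Powell iterations
Dice vs ground truth: 0.9930
TRE (RMS): 0.5660 mm over 14171 ROI pixels
```

The fine stage lifts the similarity of the probability maps from its
warm-start value (1.65, limited by the noisy landmarks) toward the
identical-image limit of 2, and the recovered transform overlaps the
ground-truth warp at Dice 0.993 with sub-pixel RMS error (pixel spacing is
1 mm in the phantom).

The same pipeline is available from the shell:

```sh
vpmmi simulate --seed 0 --out-dir pair/
vpmmi register --fixed pair/fixed.png --moving pair/moving.png \
  --fixed-mask pair/fixed_mask.png --moving-mask pair/moving_mask.png \
  --fixed-landmarks pair/fixed_landmarks.csv \
  --moving-landmarks pair/moving_landmarks.csv \
  --mode vpmmi --out-dir run/
vpmmi evaluate --result-dir run/ --roi pair/moving_mask.png \
  --reference pair/t_true.txt
```

`--mode vmi` runs the ablation baseline that maximizes NMI on the raw
intensities instead of probability maps.

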