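# Methods

## Model

`edgegan` classifies image tiles with a collection of class-specific
conditional GANs. For each class `c` a generator `G_c` learns the mapping

```
edge condition y = canny_rgb(x)   →   reconstruction  x̂ = G_c(y)
```

where `canny_rgb` applies the Canny detector to each of the three
intensity channels independently, producing an H×W×3 binary mask (channel
`i` derives only from channel `i`). A tile is classified by

```
label(x) = argmin_c  d( x, G_c(canny_rgb(x)) )
```

with dissimilarity `d` one of MSE (default), 1−SSIM, or a ceiling-shifted
−PSNR. Because the condition is binary, all colour information is removed
from the generator's input; the generator can only succeed by having
learnt the class-typical mapping from structure to appearance, which is
what makes reconstruction error class-specific.

### Conditioning

Canny parameters are `sigma` (Gaussian smoothing SD, pixels) and
hysteresis thresholds expressed as fractions of the full intensity scale
(each channel is mapped to [0, 1] before gradient computation). Shipped
presets: `sigma_2` and `sigma_5`; intuitively, sigma below ~2 picks up
noise edges and sigma above ~5 leaves too few edges to reconstruct from.
The hysteresis fractions default to low = 0.1, high = 0.2 — the detector's
conventional float-image defaults; they are a free design choice here, and
are therefore stored inside every trained model so classification always
reuses the exact training-time conditioning. Smoothing uses reflective
padding and edges on the outermost pixel ring are kept. Channels are
processed on raw intensities with no colour-space transform.

### Architecture

The generator is a U-Net: `depth` stride-2 4×4 convolutions (LeakyReLU
0.2), channel widths `base_filters · 2^i`, mirrored by stride-2 4×4
transposed convolutions with skip connections concatenating each encoder
stage's output into the matching decoder stage; final activation tanh.
Dropout (default rate 0.5) acts in the inner decoder stages and doubles as
the GAN noise source (`noise_mode="dropout"`); an explicit noise-channel
mode (`noise_mode="input"`) is available for fidelity experiments.
Inference always runs with dropout disabled (and a zero noise channel in
input mode) so reconstructions — and hence classifications — are
deterministic.

The discriminator receives the condition concatenated with a real or
generated tile (6 channels), applies `conv_stages` stride-2 convolutions
(LeakyReLU 0.2) and a dense two-way softmax head: a single global
real/fake probability pair per sample. A patch-wise head was considered
and rejected in favour of the single global head, matching the simplest
reading of a "standard convolutional network with softmax classification";
the global head also keeps the loss bookkeeping scalar per sample.

No normalisation layers are used: at the network widths and tile sizes
this package targets (depth 2–3, 8–16 base filters, 32–64 px), Adam with
the MSE-dominated objective trains stably without them, and their absence
keeps training exactly reproducible without tracking running statistics.

### Losses and training

Per mini-batch, with `p_real = D(y, x)` and `p_fake = D(y, G(y))`:

- discriminator: cross-entropy `−log p_real − log(1 − p_fake)`;
- generator: `λ_adv · g_adv + λ_mse · g_mse`, where `g_adv = −log p_fake`
  (the non-saturating form; the textbook saturating `log(1 − p_fake)` is
  available behind `adversarial_form="saturating"` — the two share fixed
  points but the non-saturating form avoids vanishing gradients early in
  training, and is the reason the logged `g_adv` is always ≥ 0) and
  `g_mse` is the mean squared difference on the model's internal [−1, 1]
  intensity scale.

Defaults `λ_mse = 100, λ_adv = 1` follow the pix2pix convention of a
dominant reconstruction term. The optimizer is Adam with `beta1 = 0.5`,
`beta2 = 0.999`; the library default learning rate is 2e-4. One
discriminator update and one generator update alternate per shuffled
mini-batch; the generator step is taken against the just-updated
discriminator. Weights are initialised N(0, 0.02); all randomness
(initialisation, shuffling, dropout masks) flows from the single config
seed through one `numpy.random.Generator`, making training bit-reproducible
and giving each model a content-hash fingerprint over its serialized
weights.

Training a class model reads **only** that class's tiles — the function
receives a single-label tile collection and rejects mixed labels. This is
what makes the registry modular: adding class `c+1` cannot perturb classes
`1..c` (their fingerprints are unchanged by construction), and imbalance
between classes cannot bias any individual model.

### Classification scales and tie-breaks

Reported dissimilarities are computed on the 0–255 scale (not the internal
[−1, 1]) so errors are comparable across configurations. PSNR is turned
into a dissimilarity as `10·log10(255²·N) − PSNR` — the ceiling is the
largest PSNR a nonzero integer difference can attain on `N` samples — so
identical images score 0 and the ordering matches MSE. Exact per-tile
error ties resolve to the lexicographically smaller label and set a
`tie_broken` flag. HPF vote ties resolve to the label with the smaller
summed dissimilarity over its winning windows, then lexicographically.
Registry iteration is lexicographic by label everywhere, which pins down
all tie-breaking.

HPF window sampling draws top-left corners uniformly **with replacement**
(the sampling scheme is otherwise unspecified in the winner-take-all
design); the seed is required and logged.

### Stereology sampling

A square point grid (offset, spacing) is laid over the image; each point
anchors the **top-left corner** (0-based) of a half-open `[r, r+T) ×
[c, c+T)` square, emitted iff every pixel lies inside the annotation mask.
"Strictly inside" is read literally as 100% containment; a
`min_containment` knob relaxes it. Default spacing equals the tile size
(non-overlapping grid). Containment is evaluated with a summed-area table
and is deterministic.

### Evaluation conventions

Precision `100·tp/(tp+fp)` and sensitivity `100·tp/(tp+fn)` guard empty
denominators by returning 0 with a degenerate flag; F1 is the harmonic
mean on the percent scale; reports round to two decimals. The positive
class defaults to `"tumor"` when present, else the lexicographically first
label. Grouped k-fold shuffles the distinct group ids (slides) by seed and
partitions them as evenly as possible; tiles always follow their group, so
no group spans a training/validation boundary. Fold aggregation reports
mean, **sample** standard deviation (ddof = 1), and median. Imbalance
resampling keeps a uniform, seeded, without-replacement subset of
`floor(ratio · majority_count)` minority tiles.

## Synthetic data

The generator emulates the *mechanism* the classifier relies on — class
identity carried by edge structure — not histology itself:

- **tumorlike**: dense anti-aliased elliptical blobs (≈ 8 per 1000 px²,
  radii 3–6 px), a quarter rendered as rings to imitate gland lumina;
  hematoxylin-like palette (dark blue-purple foreground `(70,40,120)` on
  lavender `(214,188,226)`).
- **stromalike**: sparse wavy fibers (4 strokes whose headings follow a
  random walk, ≈ 2.6 px wide) with a few small blobs; eosin-like palette (pink
  `(225,130,170)` on pale pink `(247,228,233)`).

Both add Gaussian intensity noise (SD 3). All parameters live in
`TextureClassSpec`; generation is a pure function of (spec, n, tile size)
with the seed carried by the spec. The defaults were chosen once so that
the two classes' mean Canny edge-pixel densities at sigma 2 differ by well
over the 1.5× margin the conditioning needs (measured ≈ 2.5×), and so
that, when the palettes are equalised ("colour drained"), chromaticity
statistics no longer separate the classes while edge statistics still do.

What the fixture does **not** model: real nuclear texture and chromatin,
stain variation between labs, scanner artifacts and focus issues, mixed
and boundary tissue, or any spatial correlation between neighbouring
tiles. Passing tests therefore certify the *machinery* — conditioning,
training, arg-min classification, voting, sampling, reporting — under
conditions where structure is the only class signal; they do not certify
accuracy on real slides.

## Scaled-down study conditions

The acceptance-level study runs at 64 px tiles, 200 training + 50 held-out
tiles per class, U-Net depth 3 with 16 base filters, discriminator with 3
conv stages, 5 epochs, batch size 4, learning rate 1e-3, sigma-2
conditioning. Batch 4 / lr 1e-3 are the small-data analogue of the
pix2pix-style defaults (larger batches, lr 2e-4, many epochs at 256 px):
with only 250 optimisation steps per model, the slightly higher rate lets
the MSE term converge to the class palette and coarse structure, which is
the signal the arg-min classifier uses. The demo config
(`configs/demo.yaml`) is a further-reduced 32 px variant for smoke runs.

## Numerical notes

- Convolutions are 4×4, stride 2, pad 1 throughout (each stage exactly
  halves/doubles resolution); tile sizes must be divisible by `2^depth`.
- im2col/col2im implement the convolution adjoint pair; transposed
  convolution is the exact adjoint of the strided convolution, verified
  by finite differences in the test suite.
- Probabilities entering log terms are clipped to `[1e-7, 1 − 1e-7]`.
- Generator output in [−1, 1] maps back to 8-bit via
  `clip(rint((y+1)·127.5))`.
- All tensors are float32; fingerprints hash dtype, shape and raw bytes of
  every weight array, so "bit-identical" claims are literal.

## Known limitations

- No confidence measure: the arg-min rule yields a label and an error map
  but no calibrated probability.
- The numpy engine is CPU-bound and intended for the small study sizes
  above; 256 px × thousands-of-tiles training is expressible but slow.
- SSIM is available as a classification metric only, not as a training
  objective.
- Mixed-content windows are classified like any other window; filtering
  them (e.g. at region boundaries) is left to the evaluator.
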