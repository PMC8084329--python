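# mbiclean

Preprocessing for multiplexed mass-based imaging (MBI) count data —
MIBI-TOF, imaging mass cytometry and similar modalities that produce, per
field of view, a stack of registered 2-D images of nonnegative integer ion
counts, one per antibody channel. Raw stacks carry three characteristic
artifact classes that `mbiclean` removes in three independent stages:

1. **Channel crosstalk** — signal from a *source* channel (isotopic
   impurities, metal oxide/hydride adducts, bare-slide background,
   systematic off-target staining) contaminating a *target* channel. The
   source image `h` is capped at `c`, convolved with a radial Gaussian of
   standard deviation `σ`, rescaled to a maximum of 1 and thresholded at
   `t ∈ [0, 1]` into a binary contaminant mask; a removal value `v` is then
   subtracted from the target under the mask, clipping at zero:

   `f_clean = max(f − v, 0)` where `mask = 1`, `f_clean = f` elsewhere.

2. **Noise** — sparse stray counts outside the structures the antibody
   marks. Each positive pixel's local count density is summarized by the
   **ADK**: the average Euclidean distance to its K nearest *counts*, where
   a pixel holding `c` ions contributes `c` co-located events (so a query
   pixel of count `c` supplies `c − 1` zero-distance neighbors to itself).
   Pixels with ADK above a per-channel threshold `t_n` are zeroed; retained
   pixels keep their exact value. The ADK histogram of a typical channel is
   bimodal — a dense signal mode at low ADK, a sparse noise mode at high
   ADK — and the valley between them is a natural choice of `t_n`.

3. **Aggregates** — few-pixel high-intensity specks of conglomerated
   antibody. The channel is blurred (merging nearby patches of one
   biological structure), binarized at zero and partitioned into
   8-connected objects; every object with fewer than `t_a` pixels is
   treated as an aggregate and its pixels are zeroed in the original image.

All three stages only remove counts — every output pixel is either zero or
bit-identical to its input — and each batch run writes one new folder of
TIFFs plus a JSON log of the exact parameters used, so results are
reproducible from their outputs.

The package also ships TIFF stack I/O in the two common dialects (one
multipage TIFF per FOV, or one folder of single-channel TIFFs), a seeded
phantom generator with per-pixel ground truth for validation, a config-driven
batch pipeline, and a `mbiclean` command-line interface.

## Worked example

The ADK definition is pinned by a small worked configuration: a center
pixel holding 2 counts, 1 count one pixel to its right, and 3 counts two
pixels above. The center's five nearest counts are one zero-distance
neighbor inside its own pixel, the count at distance 1, and the three
counts at distance 2:

```python
>>> import numpy as np
>>> from mbiclean import adk
>>> img = np.zeros((7, 7), dtype=np.uint32)
>>> img[3, 3] = 2; img[3, 4] = 1; img[1, 3] = 3
>>> adk(img, 5)[3, 3]          # (0 + 1 + 2 + 2 + 2) / 5
1.4
```

`examples/` contains one narrative script per capability; for instance
`python examples/knn_denoising.py` prints

```
ADK(k=5) of the worked example center: 1.4
positive pixels: 4529, ADK range 0.68-26.97
threshold at histogram valley: t_n = 4.72
planted noise counts removed:  92.4%
planted signal counts kept:    100.0%
```

— on a seeded 256×256 phantom (cells at ~3 counts/pixel over a 0.02
counts/pixel background), denoising at K=25 with the threshold read off the
ADK-histogram valley removes 92% of the planted background counts while
keeping all planted cell signal. `examples/batch_pipeline.py` shows the
folder-per-stage batch workflow, and the same run is available from a shell:

```sh
mbiclean run --config pipeline.yaml --summary summary.csv
mbiclean denoise --input fov1/ --params denoise.csv --output fov1-denoised
```

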