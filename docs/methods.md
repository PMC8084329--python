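# Methods

`mbiclean` cleans stacks of per-channel ion-count images. This note
records the exact mathematical conventions the implementation follows, the
parameters that matter, what the synthetic phantoms do and do not emulate,
and the design choices made where more than one reading was defensible.

## Data model

A channel image is a 2-D grid of nonnegative integers (ions detected per
pixel); a stack is an ordered, dimension-consistent set of uniquely named
channels for one field of view. On disk, stacks are grayscale TIFFs in two
dialects: one multipage file per FOV (channel names in the per-page
description tag, page order preserved) or one folder of single-page TIFFs
(names from filenames, lexicographic order). Pixels are stored as unsigned
32-bit integers; whole-valued float TIFFs are coerced with a warning,
fractional ones rejected. Every stage writes a fresh output folder plus a
JSON log (stage, full parameter record, input/output paths, timestamp,
software version) sufficient to reproduce the output bit-exactly; stage
folders take the input name plus a suffix (`-crosstalk`, `-denoised`,
`-noagg`).

## Gaussian blur primitive

Both the crosstalk mask and the aggregate mask use convolution with the
radial Gaussian `g(x,y) = exp(−(x²+y²)/2σ²) / (2πσ²)` evaluated at integer
offsets in a square window of half-width `⌈3σ⌉`, with out-of-image pixels
treated as zero and `σ = 0` the identity. The kernel is *not* renormalized
to unit sum: the crosstalk path rescales the blurred image to a maximum of
1 immediately afterwards and the aggregate path only tests its support, so
the ≈0.4% truncated mass at σ=1 is immaterial, while the unnormalized form
keeps the kernel definition and the truncation radius (a documented,
configurable constant) the only conventions in play. The truncation radius
directly sets blurred object sizes: a single positive pixel at σ=1 becomes
a 7×7 = 49-pixel object.

## Crosstalk removal

Order of operations is fixed: cap at `c` → blur with `σ` → rescale to max 1
→ binarize at `t` (mask = 1 where the rescaled image is ≥ `t`) → subtract
`v` from each target pixel under the mask, clipping at 0. The threshold is
applied to the *rescaled* image: `t` is documented as living in [0, 1],
which is only meaningful after normalization. An all-zero source yields an
all-zero mask plus a warning rather than an error (an empty contaminant
means nothing to remove; division by a zero maximum is otherwise
undefined). Ties at the threshold map to mask = 1. Integer `v` on integer
counts stays integer; fractional `v` produces float intermediates that are
floored at write time with a warning. Consequences tested as invariants:
output ≤ input everywhere, pixels outside the mask bit-identical, output
non-decreasing in `t` and non-increasing in `v`, and repeated rounds are
valid (each output folder is a legal input). Multiple source→target rules
are applied sequentially in listed order, each seeing the previous rule's
output.

## Intensity-normalized KNN denoising

Each positive pixel's neighbor multiset contains `c − 1` zeros for its own
`c` co-located counts (the query count is not its own neighbor) plus, for
every other positive pixel, that pixel's center-to-center Euclidean
distance repeated once per count it holds. ADK is the mean of the K
smallest entries; ties at the cut are equal distances and cannot change the
mean, so tie order is irrelevant. The self-count convention is pinned by
the worked example: center of 2 counts, 1 count at distance 1, 3 counts at
distance 2 gives ADK₅ = (0+1+2+2+2)/5 = 1.4 — the alternative reading (all
`c` self-counts as neighbors) would give 1.0 and is rejected. If fewer than
K neighbor counts exist in the whole image the pixel's ADK is +∞ (removed)
with a warning, so near-empty channels degrade gracefully in batch runs.
ADK is undefined (NaN) at zero pixels, which trivially stay zero.

The implementation queries a k-d tree over positive pixels with an
expanding neighbor budget until the cumulative count multiplicity covers
K+1 entries (the guaranteed self zero is dropped from the sum), and is
required by test to agree with an O(N²) brute-force enumeration of the full
distance multiset to 1e-9 — the algorithm is an optimization, the multiset
definition is the contract. Denoising keeps a pixel exactly when
ADK ≤ `t_n` (the threshold binds on strict excess). Default K = 25; the
statistic is robust to K under fixed imaging conditions, while `t_n` is
per-channel. Automatic threshold selection is deliberately out of the
library's API — the ADK histogram (equal-width bins from 0 to the max
finite value, infinite values tallied separately) is exported so the
analyst picks the valley; the test-suite helper that reads the valley off
the smoothed histogram is validation tooling, not API.

## Aggregate removal

Blur with `σ`, binarize at strictly > 0 (with the truncated positive kernel
this is the input support dilated by the kernel footprint), partition into
8-connected objects (diagonal-inclusive, matching the common
connected-component convention; objects numbered deterministically by first
row-major pixel), and zero the original pixels of every object with size
**< `t_a`** — strict, so `t_a = 0` is the identity. Sizes are measured on
the blurred mask, not on raw support: at σ=1 an isolated pixel is a
49-pixel object, a 3-pixel speck at most 64 pixels, and a radius-5 cell
disk ≈ 200 pixels, so thresholds must be chosen on the blurred scale
(`t_a = 70` cleanly separates 1–3-pixel specks from radius-≥5 cells at
σ=1). Larger σ merges objects and can only grow them, which makes the
removed set shrink or stay fixed for a fixed threshold.

## Synthetic phantoms

A phantom is a two-channel stack (`source`, `target`) with per-pixel truth.
Cells are non-overlapping disks (default 20 per channel, radius 5–10 px,
minimum rim gap 8 px so blurred objects stay separate) with Poisson counts
inside (λ_sig = 3) and Poisson background outside (λ_noise = 0.02);
aggregates are 1–3-pixel 4-connected clusters at 30 counts/pixel planted in
the target with an 8-px margin from every disk and never on an existing
stray count; contamination duplicates each individual source count into
the target with probability ρ (binomial thinning, default ρ = 0.5). The
observed target equals signal + noise + aggregates + contamination exactly,
and generation is deterministic given the seed (NumPy PCG64). Defaults are
the validation conditions used throughout the tests and the acceptance
script; the 72–128 px variants in the faster tests shrink only the field
and cell count, not the rates.

What the phantom does *not* emulate: instrument physics (beam current,
dwell time, isotope purity), spatially structured off-target staining,
intensity-dependent noise, or contamination with its own spatial kernel.
Passing the recovery tests therefore shows the algorithms implement their
definitions and separate well-separated density regimes — not that any
particular parameter set is right for real tissue, where thresholds remain
per-channel expert choices.

Two idealized regimes are used deliberately in validation: (a) aggregate
recall is scored on noise-free phantoms, mirroring the pipeline order in
which denoising precedes aggregate removal — a stray background count
adjacent to a speck would otherwise merge with it under the blur and make
recall ambiguous; (b) crosstalk restoration uses `cap=1, σ=0, t=0.5` (mask
= exact source support) with an arbitrarily large `v` (zero-out), under
which every contaminated pixel of a target with no structure of its own on
the source support returns exactly to its clean value. Because per-count
duplication yields variable per-pixel contamination, no single finite `v`
can match it everywhere; the zero-out regime is the exact-recovery case.

## Pipeline and CLI

The batch runner applies an ordered stage list (default crosstalk →
denoise → aggregates, the order in which the artifacts are best separated:
denoising before aggregate removal isolates the specks) to every FOV under
an input root, each stage reading the previous stage's folder, and returns
a per-FOV/stage/channel summary (counts before/after, pixels altered).
Logs additionally record a config hash. A failed run drops a
`RUN_FAILED.txt` marker in the output root to flag partial outputs. The
`mbiclean` CLI exposes the stages, the phantom generator and the pipeline
as thin wrappers; per-channel parameter tables are CSV, configs YAML.

## Numerical and size choices

Distances and ADK values are float64; the brute-force agreement tolerance
(1e-9) covers summation-order effects only. Test problem sizes — 16×16
sparse images for oracle comparisons, 72–128 px phantoms for stage
invariants, one 256×256 phantom per recovery check — keep the full suite
around a few seconds while leaving every code path exercised at realistic
sparsity. Known limitations: no OME-TIFF metadata or pyramidal TIFF, no
spillover-matrix unmixing (the crosstalk model is mask subtraction, not
linear compensation), no automatic choice of which channels contaminate
which, and no automatic denoising threshold.
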