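"""Channel-crosstalk removal by masked subtraction.

In mass-based imaging, signal from a *source* channel (isotopic impurities,
metal oxide/hydride adducts, bare-slide background, systematic off-target
staining) can contaminate a *target* channel.  Because the contamination
mirrors real structure in the source channel, the source is used to locate
it: the source image is capped, blurred, rescaled to a maximum of one and
thresholded into a binary contaminant mask, and a fixed removal value is
subtracted from the target wherever the mask is positive, clipping at zero.

The pipeline is, in order:

    capped   = min(source, c)
    blurred  = g_sigma * capped          (truncated radial Gaussian)
    rescaled = blurred / max(blurred)
    mask     = rescaled >= t             (t in [0, 1])
    cleaned  = max(target - v, 0)  where mask == 1, else target
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np

from .filters import Histogram, gaussian_blur
from .image_io import ProcessingLog
from .stack import (
    ChannelImage,
    ChannelStack,
    DegenerateInputWarning,
    DimensionError,
    ImageLike,
    as_counts,
    like,
)

__all__ = [
    "CrosstalkParams",
    "cap_counts",
    "gaussian_blur",
    "rescale_max1",
    "binarize",
    "build_contaminant_mask",
    "intensity_histogram",
    "subtract_masked",
    "remove_crosstalk",
]


@dataclasses.dataclass
class CrosstalkParams:
    """One source -> targets contamination-removal rule.

    Parameters
    ----------
    source
        Name of the contaminating channel the mask is built from.
    targets
        Channels to clean under the mask.
    cap
        Maximum retained source intensity ``c`` (counts); homogenizes overly
        bright contaminant signal before blurring.
    sigma
        Gaussian blur standard deviation (pixels); ~1 is typical.
    threshold
        Mask threshold ``t`` on the rescaled [0, 1] source image.
    remove_value
        Counts ``v`` subtracted from each target pixel under the mask; an
        arbitrarily large value zeroes masked pixels outright.
    """

    source: str
    targets: Sequence[str]
    cap: float
    sigma: float = 1.0
    threshold: float = 0.5
    remove_value: float = 1.0

    def __post_init__(self) -> None:
        self.targets = list(self.targets)
        if self.cap <= 0:
            raise ValueError(f"cap must be positive, got {self.cap}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be nonnegative, got {self.sigma}")
        if not 0 <= self.threshold <= 1:
            raise ValueError(f"threshold must be in [0, 1], got {self.threshold}")
        if self.remove_value < 0:
            raise ValueError(f"remove_value must be nonnegative, got {self.remove_value}")
        if self.source in self.targets:
            raise ValueError(f"source channel {self.source!r} cannot be its own target")

    def as_record(self) -> dict:
        return dataclasses.asdict(self)


def cap_counts(image: ImageLike, cap: float) -> ImageLike:
    """Clip pixel values at ``cap``; integer inputs stay integer for integer caps."""
    if cap <= 0:
        raise ValueError(f"cap must be positive, got {cap}")
    counts = as_counts(image)
    if np.issubdtype(counts.dtype, np.integer) and float(cap).is_integer():
        cap = int(cap)
    return like(image, np.minimum(counts, cap))


def rescale_max1(image: ImageLike) -> np.ndarray:
    """Divide by the image maximum so max(output) == 1; all-zero input stays
    all-zero with a warning (an empty contaminant implies nothing to remove)."""
    arr = np.asarray(as_counts(image), dtype=float)
    peak = arr.max() if arr.size else 0.0
    if peak <= 0:
        warnings.warn(
            "rescale_max1: all-zero image, returning zeros",
            DegenerateInputWarning,
            stacklevel=2,
        )
        return np.zeros_like(arr)
    return arr / peak


def binarize(image: ImageLike, threshold: float) -> np.ndarray:
    """Binary mask: 1 where image >= threshold, else 0 (uint8)."""
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    arr = np.asarray(as_counts(image), dtype=float)
    return (arr >= threshold).astype(np.uint8)


def build_contaminant_mask(
    source: ImageLike, cap: float, sigma: float, threshold: float
) -> np.ndarray:
    """Cap, blur, rescale and threshold the source channel into a mask."""
    capped = as_counts(cap_counts(source, cap))
    return binarize(rescale_max1(gaussian_blur(capped, sigma)), threshold)


def intensity_histogram(image: ImageLike, nbins: int) -> Histogram:
    """Histogram of a [0, 1] intensity image over equal-width bins spanning
    [0, 1]; used to guide the choice of the mask threshold."""
    if nbins < 1:
        raise ValueError(f"nbins must be >= 1, got {nbins}")
    arr = np.asarray(as_counts(image), dtype=float)
    counts, edges = np.histogram(arr.ravel(), bins=nbins, range=(0.0, 1.0))
    return Histogram(edges=edges, counts=counts)


def subtract_masked(target: ImageLike, mask: np.ndarray, remove_value: float) -> ImageLike:
    """Subtract ``remove_value`` under the mask, clipping at zero; pixels
    outside the mask are returned bit-identical."""
    if remove_value < 0:
        raise ValueError(f"remove_value must be nonnegative, got {remove_value}")
    counts = as_counts(target)
    mask = np.asarray(mask)
    if mask.shape != counts.shape:
        raise DimensionError(f"mask shape {mask.shape} != target shape {counts.shape}")
    on = mask != 0
    if np.issubdtype(counts.dtype, np.integer) and float(remove_value).is_integer():
        work = counts.astype(np.int64)
        out = np.where(on, np.maximum(work - int(remove_value), 0), work)
        out = out.astype(counts.dtype)
    else:
        work = counts.astype(float)
        out = np.where(on, np.maximum(work - float(remove_value), 0.0), work)
    return like(target, out)


def remove_crosstalk(
    stack: ChannelStack, params: CrosstalkParams
) -> tuple[ChannelStack, ProcessingLog]:
    """Clean every target channel under a mask built once from the source.

    Non-target channels (including the source itself) pass through
    unchanged.  Returns the cleaned stack and a log recording the rule.
    """
    log = ProcessingLog(stage="crosstalk", parameters={"rules": [params.as_record()]})
    if not params.targets:
        return ChannelStack(list(stack.channels), fov_id=stack.fov_id), log
    source = stack.get(params.source)
    for name in params.targets:
        stack.get(name)  # fail fast, listing available channels
    mask = build_contaminant_mask(source, params.cap, params.sigma, params.threshold)
    channels = []
    for chan in stack:
        if chan.name in params.targets:
            channels.append(subtract_masked(chan, mask, params.remove_value))
        else:
            channels.append(chan)
    return ChannelStack(channels, fov_id=stack.fov_id), log


def remove_crosstalk_rules(
    stack: ChannelStack, rules: Sequence[CrosstalkParams]
) -> tuple[ChannelStack, ProcessingLog]:
    """Apply several source -> targets rules sequentially in listed order."""
    out = stack
    for rule in rules:
        out, _ = remove_crosstalk(out, rule)
    log = ProcessingLog(
        stage="crosstalk", parameters={"rules": [r.as_record() for r in rules]}
    )
    return out, log
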