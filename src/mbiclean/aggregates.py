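"""Removal of small antibody-aggregate specks by size-filtering objects.

Aggregates are few-pixel, high-intensity spots produced by conglomerated
antibody, uncorrelated with tissue structure.  They are found by their
size: the channel is blurred with the truncated Gaussian (merging nearby
patches that belong to one biological structure), binarized at zero into a
support mask, and partitioned into 8-connected objects.  Every object with
fewer than t_a pixels is treated as an aggregate and its pixels are zeroed
in the ORIGINAL image; larger objects pass through bit-identical.

Note that object sizes are measured on the blurred mask, so even a single
positive pixel becomes a (2*ceil(3*sigma)+1)^2-pixel object; thresholds
must be chosen on that scale (e.g. 49 pixels for one isolated count at
sigma=1).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import ndimage

from .filters import TRUNCATION_SIGMAS, gaussian_blur
from .image_io import ProcessingLog
from .stack import ChannelStack, ImageLike, as_counts, like

__all__ = [
    "AggregateParams",
    "LabeledObjects",
    "blur_binarize",
    "label_objects",
    "remove_aggregates",
    "remove_aggregates_stack",
]

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclasses.dataclass
class AggregateParams:
    """Per-channel aggregate-removal parameters: blur sigma (pixels) and the
    strict object-size lower bound t_a (pixels of the blurred mask)."""

    channel: str
    sigma: float = 1.0
    size_threshold: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be nonnegative, got {self.sigma}")
        if self.size_threshold < 0 or int(self.size_threshold) != self.size_threshold:
            raise ValueError(
                f"size_threshold must be a nonnegative integer, got {self.size_threshold}"
            )
        self.size_threshold = int(self.size_threshold)

    def as_record(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(eq=False)
class LabeledObjects:
    """8-connected components of a binary mask.

    ``labels`` is an int grid (0 = background, objects numbered from 1 in
    order of their first row-major pixel); ``sizes[i]`` is the pixel count
    of object i+1.
    """

    labels: np.ndarray
    sizes: np.ndarray

    @property
    def n(self) -> int:
        return len(self.sizes)

    @property
    def objects(self) -> list[np.ndarray]:
        """Pixel coordinates of each object, as (size_i, 2) arrays."""
        return [np.argwhere(self.labels == i + 1) for i in range(self.n)]


def blur_binarize(image: ImageLike, sigma: float, truncation: float = TRUNCATION_SIGMAS) -> np.ndarray:
    """Support mask of the blurred image: 1 where blur > 0, else 0.

    With the truncated positive kernel this equals the input support dilated
    by the kernel footprint; sigma=0 gives the raw support.
    """
    blurred = gaussian_blur(image, sigma, truncation)
    return (blurred > 0).astype(np.uint8)


def label_objects(mask: np.ndarray) -> LabeledObjects:
    """Partition mask=1 pixels into maximal 8-connected objects, numbered
    deterministically by first row-major pixel."""
    mask = np.asarray(mask)
    labels, n = ndimage.label(mask != 0, structure=_EIGHT_CONNECTED)
    if n == 0:
        return LabeledObjects(labels=labels, sizes=np.zeros(0, dtype=np.int64))
    flat = labels.ravel()
    positive = np.flatnonzero(flat)
    # first row-major occurrence of each label -> deterministic renumbering
    first = np.full(n + 1, flat.size, dtype=np.int64)
    np.minimum.at(first, flat[positive], positive)
    order = np.argsort(first[1:], kind="stable")
    remap = np.zeros(n + 1, dtype=labels.dtype)
    remap[order + 1] = np.arange(1, n + 1)
    labels = remap[labels]
    sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:].astype(np.int64)
    return LabeledObjects(labels=labels, sizes=sizes)


def remove_aggregates(
    image: ImageLike,
    sigma: float = 1.0,
    size_threshold: int = 0,
    truncation: float = TRUNCATION_SIGMAS,
) -> ImageLike:
    """Zero every pixel that falls in a blurred-mask object smaller than
    ``size_threshold`` (strict); all other pixels are unchanged.
    ``size_threshold=0`` is the identity."""
    if size_threshold < 0 or int(size_threshold) != size_threshold:
        raise ValueError(f"size_threshold must be a nonnegative integer, got {size_threshold}")
    counts = as_counts(image)
    labeled = label_objects(blur_binarize(counts, sigma, truncation))
    if labeled.n == 0:
        return like(image, counts.copy())
    small = np.concatenate(([False], labeled.sizes < int(size_threshold)))
    kill = small[labeled.labels]
    out = counts.copy()
    out[kill] = 0
    return like(image, out)


def remove_aggregates_stack(
    stack: ChannelStack, params: Sequence[AggregateParams]
) -> tuple[ChannelStack, ProcessingLog]:
    """Per-channel aggregate removal; unlisted channels pass through.
    Returns the cleaned stack and a log."""
    by_channel = {}
    for p in params:
        stack.get(p.channel)
        by_channel[p.channel] = p
    channels = []
    for chan in stack:
        p = by_channel.get(chan.name)
        if p is None:
            channels.append(chan)
        else:
            channels.append(remove_aggregates(chan, p.sigma, p.size_threshold))
    log = ProcessingLog(
        stage="aggregates",
        parameters={"channels": [p.as_record() for p in params]},
    )
    return ChannelStack(channels, fov_id=stack.fov_id), log
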