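"""Core containers for multiplexed ion-count image stacks.

A mass-based imaging acquisition yields one 2-D image of nonnegative integer
ion counts per antibody channel; a field of view is an ordered stack of such
channel images sharing one pixel grid.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator, Sequence, Union

import numpy as np

__all__ = [
    "ChannelImage",
    "ChannelStack",
    "MbicleanError",
    "DimensionError",
    "FormatError",
    "EmptyInputError",
    "ChannelLookupError",
    "OutputCollisionError",
    "PlacementError",
    "DegenerateInputWarning",
]


class MbicleanError(Exception):
    """Base class for all mbiclean errors."""


class DimensionError(MbicleanError):
    """Channel dimensions disagree within a stack or between operands."""


class FormatError(MbicleanError):
    """Pixel data is negative, non-numeric, or not a 2-D grid."""


class EmptyInputError(MbicleanError):
    """An input file or folder contains no channel images."""


class ChannelLookupError(MbicleanError, KeyError):
    """A named channel is not present in the stack."""


class OutputCollisionError(MbicleanError):
    """Refusing to write into an existing non-empty directory."""


class PlacementError(MbicleanError):
    """Phantom geometry could not be placed within the retry budget."""


class DegenerateInputWarning(UserWarning):
    """A defined but degenerate input path was taken (e.g. an all-zero
    contaminant channel, or too few counts to find k neighbors)."""


def _validate_counts(counts: np.ndarray, name: str) -> np.ndarray:
    counts = np.asarray(counts)
    if counts.ndim != 2:
        raise FormatError(f"channel {name!r}: expected a 2-D grid, got ndim={counts.ndim}")
    if not np.issubdtype(counts.dtype, np.number) or np.issubdtype(counts.dtype, np.complexfloating):
        raise FormatError(f"channel {name!r}: non-numeric pixel dtype {counts.dtype}")
    if counts.size == 0:
        raise FormatError(f"channel {name!r}: empty image")
    if np.any(counts < 0):
        raise FormatError(f"channel {name!r}: negative pixel values are not valid ion counts")
    return counts


@dataclasses.dataclass(eq=False)
class ChannelImage:
    """One named 2-D nonnegative count image for a single mass channel.

    Counts are integer ion counts on input; intermediate results of the
    cleaning stages may carry float grids (e.g. after a fractional removal
    value), which are floored back to integers at write time.
    """

    name: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        if not isinstance(self.name, str) or not self.name:
            raise FormatError("channel name must be a non-empty string")
        self.counts = _validate_counts(self.counts, self.name)

    @property
    def height(self) -> int:
        return self.counts.shape[0]

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def with_counts(self, counts: np.ndarray) -> "ChannelImage":
        """Return a new image with the same name and new pixel values."""
        return ChannelImage(self.name, counts)

    def total(self) -> float:
        return float(self.counts.sum())


ImageLike = Union[ChannelImage, np.ndarray]


def as_counts(image: ImageLike) -> np.ndarray:
    """Pixel grid of a ChannelImage, or the array itself."""
    return image.counts if isinstance(image, ChannelImage) else np.asarray(image)


def like(image: ImageLike, counts: np.ndarray):
    """Wrap ``counts`` as a ChannelImage if ``image`` was one, else return it."""
    if isinstance(image, ChannelImage):
        return image.with_counts(counts)
    return counts


@dataclasses.dataclass(eq=False)
class ChannelStack:
    """An ordered, dimension-consistent set of channel images for one FOV."""

    channels: Sequence[ChannelImage]
    fov_id: str = "fov"

    def __post_init__(self) -> None:
        self.channels = list(self.channels)
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise FormatError(f"duplicate channel names in stack: {dupes}")
        if self.channels:
            h, w = self.channels[0].shape
            for c in self.channels[1:]:
                if c.shape != (h, w):
                    raise DimensionError(
                        f"channel {c.name!r} has shape {c.shape}, "
                        f"expected {(h, w)} like {self.channels[0].name!r}"
                    )

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.channels]

    @property
    def shape(self) -> tuple[int, int]:
        if not self.channels:
            raise EmptyInputError("stack has no channels")
        return self.channels[0].shape

    def __len__(self) -> int:
        return len(self.channels)

    def __iter__(self) -> Iterator[ChannelImage]:
        return iter(self.channels)

    def __contains__(self, name: object) -> bool:
        return name in self.names

    def get(self, name: str) -> ChannelImage:
        for c in self.channels:
            if c.name == name:
                return c
        raise ChannelLookupError(
            f"channel {name!r} not in stack {self.fov_id!r}; available: {self.names}"
        )

    def __getitem__(self, key) -> ChannelImage:
        if isinstance(key, str):
            return self.get(key)
        return self.channels[key]

    def replace(self, name: str, image: ChannelImage) -> "ChannelStack":
        """Return a new stack with the named channel replaced."""
        if name not in self:
            raise ChannelLookupError(
                f"channel {name!r} not in stack {self.fov_id!r}; available: {self.names}"
            )
        new = [image if c.name == name else c for c in self.channels]
        return ChannelStack(new, fov_id=self.fov_id)
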