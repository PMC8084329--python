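"""Seeded phantom stacks with pixel-level ground truth.

A phantom emulates the artifact structure of a sparse two-channel mass-based
imaging field of view:

* ``source`` — a contaminating channel: Poisson signal inside non-overlapping
  cell disks plus diffuse Poisson background noise.
* ``target`` — the channel under test: its own disks and background noise,
  plus planted few-pixel high-intensity aggregates (off-disk, so removal
  recall is unambiguous) and crosstalk contamination created by duplicating
  each individual source count into the target with probability
  ``crosstalk_fraction`` (binomial thinning of the source image).

The observed target is exactly the sum of its truth components
(signal + noise + aggregates + contamination), so every cleaning stage can
be scored against known per-pixel ground truth.  Generation is fully
deterministic given the seed (NumPy PCG64 generator).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .stack import ChannelImage, ChannelStack, PlacementError

__all__ = ["PhantomSpec", "Phantom", "generate_phantom"]

SOURCE = "source"
TARGET = "target"


@dataclasses.dataclass
class PhantomSpec:
    """Phantom geometry and count model.

    Defaults describe a typical sparse acquisition: a 256x256 field with 20
    cells of radius 5-10 px per channel, ~3 counts per signal pixel against
    ~0.02 counts per background pixel, a dozen 1-3 px aggregates at 30
    counts/px (bright enough to mimic antibody conglomerates), and half of
    the source counts duplicating into the target.
    """

    height: int = 256
    width: int = 256
    n_cells: int = 20
    cell_radius: tuple[int, int] = (5, 10)
    signal_rate: float = 3.0
    noise_rate: float = 0.02
    n_aggregates: int = 12
    aggregate_size: tuple[int, int] = (1, 3)
    aggregate_intensity: int = 30
    crosstalk_fraction: float = 0.5
    seed: int = 0
    cell_margin: int = 8  # min gap between disk rims, keeps blurred objects separate
    aggregate_margin: int = 8  # min gap between an aggregate and any disk/aggregate
    max_tries: int = 2000

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("height and width must be positive")
        if self.n_cells < 0 or self.n_aggregates < 0:
            raise ValueError("n_cells and n_aggregates must be >= 0")
        rmin, rmax = self.cell_radius
        if rmin < 1 or rmax < rmin:
            raise ValueError(f"cell_radius must satisfy 1 <= min <= max, got {self.cell_radius}")
        amin, amax = self.aggregate_size
        if amin < 1 or amax < amin:
            raise ValueError(f"aggregate_size must satisfy 1 <= min <= max, got {self.aggregate_size}")
        if self.signal_rate < 0 or self.noise_rate < 0 or self.aggregate_intensity < 0:
            raise ValueError("rates and intensities must be nonnegative")
        if not 0 <= self.crosstalk_fraction <= 1:
            raise ValueError(f"crosstalk_fraction must be in [0, 1], got {self.crosstalk_fraction}")

    def as_record(self) -> dict:
        rec = dataclasses.asdict(self)
        rec["cell_radius"] = list(self.cell_radius)
        rec["aggregate_size"] = list(self.aggregate_size)
        return rec


@dataclasses.dataclass(eq=False)
class Phantom:
    """A generated stack plus its per-channel truth count images.

    ``truth[channel]`` maps component name ("signal", "noise", "aggregates",
    "contamination") to a count image; the observed channel equals the sum
    of its components exactly.
    """

    spec: PhantomSpec
    stack: ChannelStack
    truth: dict[str, dict[str, np.ndarray]]

    @property
    def source(self) -> ChannelImage:
        return self.stack.get(SOURCE)

    @property
    def target(self) -> ChannelImage:
        return self.stack.get(TARGET)

    def clean(self, channel: str = TARGET) -> np.ndarray:
        """The biological content of a channel: signal + background noise,
        without planted aggregates or contamination."""
        parts = self.truth[channel]
        return (parts["signal"] + parts["noise"]).astype(np.uint32)


def _place_disks(rng: np.random.Generator, spec: PhantomSpec, n_total: int):
    rmin, rmax = spec.cell_radius
    placed: list[tuple[int, int, int]] = []  # (row, col, radius)
    tries = 0
    while len(placed) < n_total:
        if tries >= spec.max_tries:
            raise PlacementError(
                f"could not place {n_total} non-overlapping disks of radius "
                f"{spec.cell_radius} in a {spec.height}x{spec.width} field after "
                f"{spec.max_tries} tries; reduce n_cells or cell_radius"
            )
        tries += 1
        r = int(rng.integers(rmin, rmax + 1))
        if spec.height - 1 - r < r or spec.width - 1 - r < r:
            raise PlacementError(f"cell radius {r} does not fit in the field")
        row = int(rng.integers(r, spec.height - r))
        col = int(rng.integers(r, spec.width - r))
        ok = all(
            (row - pr) ** 2 + (col - pc) ** 2 >= (r + prr + spec.cell_margin) ** 2
            for pr, pc, prr in placed
        )
        if ok:
            placed.append((row, col, r))
    return placed


def _disk_mask(shape: tuple[int, int], disks) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    for row, col, r in disks:
        mask |= (yy - row) ** 2 + (xx - col) ** 2 <= r**2
    return mask


def _chebyshev_window(mask: np.ndarray, row: int, col: int, margin: int) -> np.ndarray:
    h, w = mask.shape
    return mask[
        max(0, row - margin) : min(h, row + margin + 1),
        max(0, col - margin) : min(w, col + margin + 1),
    ]


def _plant_aggregates(
    rng: np.random.Generator,
    spec: PhantomSpec,
    structures: np.ndarray,
    stray: np.ndarray,
):
    """Grow n_aggregates 4-connected clusters keeping the aggregate margin
    from `structures` (cell disks and previously planted aggregates) and
    avoiding `stray` pixels (isolated counts) outright, so every planted
    speck is its own object and no pixel mixes truth components.  Returns
    the aggregate count image."""
    agg = np.zeros((spec.height, spec.width), dtype=np.uint32)
    amin, amax = spec.aggregate_size
    taken = structures.copy()  # pixels an aggregate must keep its margin from
    for _ in range(spec.n_aggregates):
        size = int(rng.integers(amin, amax + 1))
        for attempt in range(spec.max_tries):
            row = int(rng.integers(1, spec.height - 1))
            col = int(rng.integers(1, spec.width - 1))
            if _chebyshev_window(taken, row, col, spec.aggregate_margin + amax).any():
                continue
            cluster = [(row, col)]
            while len(cluster) < size:
                base = cluster[int(rng.integers(len(cluster)))]
                step = [(1, 0), (-1, 0), (0, 1), (0, -1)][int(rng.integers(4))]
                cand = (base[0] + step[0], base[1] + step[1])
                if (
                    0 < cand[0] < spec.height - 1
                    and 0 < cand[1] < spec.width - 1
                    and cand not in cluster
                ):
                    cluster.append(cand)
            if any(stray[r, c] for r, c in cluster):
                continue
            for r, c in cluster:
                agg[r, c] = spec.aggregate_intensity
                taken[r, c] = True
            break
        else:
            raise PlacementError(
                f"could not place {spec.n_aggregates} aggregates with margin "
                f"{spec.aggregate_margin}; reduce n_aggregates or the margin"
            )
    return agg


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Generate a seeded two-channel phantom with full ground truth."""
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)

    disks = _place_disks(rng, spec, 2 * spec.n_cells)
    source_mask = _disk_mask(shape, disks[: spec.n_cells])
    target_mask = _disk_mask(shape, disks[spec.n_cells :])

    truth: dict[str, dict[str, np.ndarray]] = {}
    observed: dict[str, np.ndarray] = {}
    for name, mask in ((SOURCE, source_mask), (TARGET, target_mask)):
        signal = (rng.poisson(spec.signal_rate, shape) * mask).astype(np.uint32)
        noise = (rng.poisson(spec.noise_rate, shape) * ~mask).astype(np.uint32)
        truth[name] = {"signal": signal, "noise": noise}
        observed[name] = signal + noise

    # aggregates keep their margin from cell disks (so the stage blur never
    # merges them into a real structure) and never land on an existing stray
    # count (so each pixel carries exactly one truth component)
    stray = (observed[TARGET] > 0) | (observed[SOURCE] > 0)
    aggregates = _plant_aggregates(rng, spec, source_mask | target_mask, stray & ~(source_mask | target_mask))
    contamination = rng.binomial(observed[SOURCE].astype(np.int64), spec.crosstalk_fraction)
    contamination = contamination.astype(np.uint32)
    truth[TARGET]["aggregates"] = aggregates
    truth[TARGET]["contamination"] = contamination
    observed[TARGET] = observed[TARGET] + aggregates + contamination

    stack = ChannelStack(
        [
            ChannelImage(SOURCE, observed[SOURCE]),
            ChannelImage(TARGET, observed[TARGET]),
        ],
        fov_id=f"phantom-{spec.seed}",
    )
    return Phantom(spec=spec, stack=stack, truth=truth)
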