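"""Reading and writing channel stacks as TIFF, plus reproducibility logs.

Two on-disk dialects are supported:

* ``multipage`` — one TIFF file per field of view, one page per channel;
  channel names travel in the per-page ImageDescription tag.
* ``folder`` — one directory per field of view containing one single-page
  grayscale TIFF per channel, named ``<channel>.tiff``; channel order is
  lexicographic by filename.

Every cleaning stage writes a fresh output directory plus a JSON log file
recording the full per-channel parameter record, so a run can be reproduced
bit-exactly from its outputs.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import warnings
from pathlib import Path
from typing import Any, Literal

import numpy as np
import tifffile

from . import __version__
from .stack import (
    ChannelImage,
    ChannelStack,
    DegenerateInputWarning,
    DimensionError,
    EmptyInputError,
    FormatError,
    OutputCollisionError,
)

__all__ = [
    "ProcessingLog",
    "read_stack",
    "write_stack",
    "write_log",
    "read_log",
    "STAGE_SUFFIXES",
    "LOG_FILENAME",
]

Dialect = Literal["multipage", "folder", "auto"]

#: Output-folder suffix appended by each cleaning stage.
STAGE_SUFFIXES = {"crosstalk": "-crosstalk", "denoise": "-denoised", "aggregates": "-noagg"}

LOG_FILENAME = "processing_log.json"

_TIFF_EXTS = (".tif", ".tiff")


@dataclasses.dataclass
class ProcessingLog:
    """Parameter record sufficient to reproduce one stage output bit-exactly."""

    stage: str
    parameters: dict[str, Any]
    input_path: str = ""
    output_path: str = ""
    timestamp: str = ""
    software_version: str = __version__

    def __post_init__(self) -> None:
        if self.stage not in STAGE_SUFFIXES:
            raise ValueError(f"stage must be one of {sorted(STAGE_SUFFIXES)}, got {self.stage!r}")
        if not self.timestamp:
            self.timestamp = datetime.datetime.now(datetime.timezone.utc).isoformat()


def _coerce_counts(arr: np.ndarray, name: str) -> np.ndarray:
    """Coerce a freshly read page to unsigned 32-bit integer counts."""
    if arr.ndim != 2:
        raise FormatError(f"channel {name!r}: expected a single-page 2-D image, got ndim={arr.ndim}")
    if not np.issubdtype(arr.dtype, np.number) or np.issubdtype(arr.dtype, np.complexfloating):
        raise FormatError(f"channel {name!r}: non-numeric pixel dtype {arr.dtype}")
    if np.any(arr < 0):
        raise FormatError(f"channel {name!r}: negative pixel values are not valid ion counts")
    if np.issubdtype(arr.dtype, np.floating):
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise FormatError(f"channel {name!r}: non-integer pixel values in a count image")
        warnings.warn(
            f"channel {name!r}: whole-valued float TIFF coerced to integer counts",
            DegenerateInputWarning,
            stacklevel=3,
        )
    if arr.size and arr.max() > np.iinfo(np.uint32).max:
        raise FormatError(f"channel {name!r}: counts exceed 32-bit range")
    return arr.astype(np.uint32)


def _read_folder(path: Path) -> ChannelStack:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in _TIFF_EXTS)
    if not files:
        raise EmptyInputError(f"no TIFF files in folder {path}")
    channels = []
    for f in files:
        arr = tifffile.imread(f)
        channels.append(ChannelImage(f.stem, _coerce_counts(np.asarray(arr), f.stem)))
    _check_dims(channels, path)
    return ChannelStack(channels, fov_id=path.name)


def _read_multipage(path: Path) -> ChannelStack:
    channels = []
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) == 0:
            raise EmptyInputError(f"TIFF file {path} has no pages")
        for i, page in enumerate(tif.pages):
            desc = (page.description or "").strip()
            if desc.startswith("{"):
                desc = ""  # tifffile JSON metadata, not a channel name
            name = desc if desc else f"ch{i:03d}"
            channels.append(ChannelImage(name, _coerce_counts(np.asarray(page.asarray()), name)))
    _check_dims(channels, path)
    return ChannelStack(channels, fov_id=path.stem)


def _check_dims(channels: list[ChannelImage], path: Path) -> None:
    if not channels:
        return
    h, w = channels[0].shape
    for c in channels[1:]:
        if c.shape != (h, w):
            raise DimensionError(
                f"{path}: channel {c.name!r} has shape {c.shape}, "
                f"but {channels[0].name!r} has {(h, w)}"
            )


def read_stack(path: str | Path, dialect: Dialect = "auto") -> ChannelStack:
    """Read a channel stack from a multipage TIFF or a folder of TIFFs.

    Channel order is page order (multipage) or lexicographic filename order
    (folder); names come from the per-page description tag (falling back to
    ``ch###``) or the filename without extension.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "auto":
        dialect = "folder" if path.is_dir() else "multipage"
    if dialect == "folder":
        if not path.is_dir():
            raise FormatError(f"folder dialect requires a directory, got {path}")
        return _read_folder(path)
    if dialect == "multipage":
        if not path.is_file():
            raise FormatError(f"multipage dialect requires a file, got {path}")
        return _read_multipage(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _writable_counts(image: ChannelImage) -> np.ndarray:
    counts = image.counts
    if np.issubdtype(counts.dtype, np.floating):
        if not np.all(np.equal(np.mod(counts, 1), 0)):
            warnings.warn(
                f"channel {image.name!r}: fractional counts floored at write time",
                DegenerateInputWarning,
                stacklevel=3,
            )
        counts = np.floor(counts)
    return counts.astype(np.uint32)


def write_stack(
    stack: ChannelStack,
    out_dir: str | Path,
    dialect: Literal["multipage", "folder"] = "folder",
    overwrite: bool = False,
) -> Path:
    """Write a stack losslessly as integer TIFFs; returns ``out_dir``.

    Refuses to write into an existing non-empty directory unless
    ``overwrite`` is set.
    """
    if len(stack) == 0:
        raise EmptyInputError("refusing to write an empty stack")
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise OutputCollisionError(f"{out_dir} exists and is not empty (pass overwrite=True)")
    out_dir.mkdir(parents=False, exist_ok=True)
    if dialect == "folder":
        for chan in stack:
            tifffile.imwrite(
                out_dir / f"{chan.name}.tiff",
                _writable_counts(chan),
                photometric="minisblack",
            )
    elif dialect == "multipage":
        with tifffile.TiffWriter(out_dir / f"{stack.fov_id}.tiff") as tw:
            for chan in stack:
                tw.write(
                    _writable_counts(chan),
                    photometric="minisblack",
                    description=chan.name,
                    contiguous=False,
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return out_dir


def write_log(log: ProcessingLog, out_dir: str | Path) -> Path:
    """Write the stage log as human-readable JSON; returns the file path."""
    out_dir = Path(out_dir)
    if not out_dir.is_dir():
        raise IOError(f"log destination {out_dir} is not an existing directory")
    path = out_dir / LOG_FILENAME
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(log), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_log(path: str | Path) -> ProcessingLog:
    """Re-parse a log file written by :func:`write_log`."""
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return ProcessingLog(**payload)
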