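"""Reading and writing of stacks, tables and configs.

Image stacks are multi-page grayscale TIFFs (via tifffile); tables are plain
CSV with documented column names; configs round-trip through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "read_stack",
    "write_stack",
    "read_tracks",
    "write_tracks",
    "read_config",
    "write_config",
]


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF into a (frames, height, width) array."""
    stack = tifffile.imread(str(path))
    if stack.ndim == 2:
        stack = stack[None, :, :]
    return stack


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write a (frames, height, width) array as a multi-page grayscale TIFF."""
    tifffile.imwrite(str(path), np.asarray(stack), photometric="minisblack")


def read_tracks(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_tracks(path: str | Path, tracks: pd.DataFrame) -> None:
    tracks.to_csv(path, index=False)


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_config(path: str | Path, config) -> None:
    data = asdict(config) if is_dataclass(config) else dict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
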