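"""Zero-mean / unit-std grid normalization and its inverse."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NormalizedGrid", "denormalize", "normalize"]

#: below this population std a grid is considered constant (degenerate input)
STD_FLOOR = 1e-12


@dataclass
class NormalizedGrid:
    """A standardized grid together with the statistics needed to invert it."""

    values: np.ndarray
    source_mean: float
    source_std: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)


def normalize(image: np.ndarray) -> NormalizedGrid:
    """Standardize a grid to zero mean and unit (population) std.

    Raises on (near-)constant input, whose standardization is undefined.
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("cannot normalize an empty grid")
    mean = float(arr.mean())
    std = float(arr.std())
    if std < STD_FLOOR:
        raise ValueError(f"degenerate (constant) input: std {std:.3e} < {STD_FLOOR}")
    return NormalizedGrid((arr - mean) / std, source_mean=mean, source_std=std)


def denormalize(grid: NormalizedGrid) -> np.ndarray:
    """Invert :func:`normalize` using the recorded source statistics."""
    return grid.values * grid.source_std + grid.source_mean
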