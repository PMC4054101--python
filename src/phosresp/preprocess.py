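"""Normalization, log transformation, and intensity filtering.

The quantification convention is two sequential normalizations:

1. total-intensity scaling — every sample column is scaled so that all
   column sums equal the grand mean of the original column sums (a proxy for
   equal total chromatogram intensity; relative abundances within a sample
   are preserved, and the choice of common constant is irrelevant once the
   row-mean step follows);
2. row-mean scaling — every peptide row is divided by its mean across
   samples, yielding fold-over-mean relative intensities with row mean 1.

Each step appends a tag to the matrix provenance so a pipeline can assert
the order in which they were applied.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import IntensityMatrix

__all__ = [
    "NormalizedMatrix",
    "normalize_total_intensity",
    "normalize_to_row_mean",
    "full_normalize",
    "log_transform",
    "intensity_cutoff_filter",
]

STEP_TOTAL = "total_intensity"
STEP_ROW_MEAN = "row_mean"


@dataclass(frozen=True)
class NormalizedMatrix:
    """Fold-over-mean relative intensities (or their logarithms).

    After :func:`normalize_to_row_mean` every row mean is 1 (+/- 1e-9) and
    all values are strictly positive; after :func:`log_transform` the values
    are logarithms of relative intensities and ``provenance`` carries a
    ``log2``/``ln`` tag.
    """

    data: pd.DataFrame
    provenance: tuple[str, ...] = ()

    @property
    def peptide_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def is_log(self) -> bool:
        return any(p.startswith("log") or p == "ln" for p in self.provenance)

    def with_provenance(self, step: str) -> "NormalizedMatrix":
        return dataclasses.replace(self, provenance=self.provenance + (step,))


def _require_no_missing(df: pd.DataFrame) -> None:
    if df.isna().any().any():
        raise ValueError("matrix contains missing values; resolve them with a missing_policy first")


def normalize_total_intensity(m: IntensityMatrix) -> IntensityMatrix:
    """Scale each sample column so all column sums equal the grand mean sum."""
    _require_no_missing(m.data)
    sums = m.data.sum(axis=0)
    if (sums <= 0).any():
        bad = list(sums.index[sums <= 0])
        raise ValueError(f"zero or negative column sum for samples: {bad}")
    target = float(sums.mean())
    scaled = m.data * (target / sums)
    return IntensityMatrix(scaled, provenance=m.provenance + (STEP_TOTAL,))


def normalize_to_row_mean(m: IntensityMatrix) -> NormalizedMatrix:
    """Divide each cell by its peptide's mean across samples (row means -> 1)."""
    _require_no_missing(m.data)
    means = m.data.mean(axis=1)
    if (means <= 0).any():
        bad = list(means.index[means <= 0])
        raise ValueError(f"zero rows cannot be mean-normalized: {bad[:10]}")
    rel = m.data.div(means, axis=0)
    return NormalizedMatrix(rel, provenance=m.provenance + (STEP_ROW_MEAN,))


def full_normalize(m: IntensityMatrix) -> NormalizedMatrix:
    """Total-intensity scaling followed by row-mean scaling, in that order."""
    return normalize_to_row_mean(normalize_total_intensity(m))


def log_transform(
    m: NormalizedMatrix, base: int | str = 2, floor_policy: str = "error"
) -> NormalizedMatrix:
    """Elementwise logarithm of relative intensities.

    ``base`` is 2 (default) or ``"e"``. ``floor_policy="half_min"`` replaces
    non-positive cells with half the matrix's minimum positive value before
    taking logs; ``"error"`` rejects them.
    """
    if base not in (2, "e"):
        raise ValueError(f"base must be 2 or 'e', got {base!r}")
    if floor_policy not in ("error", "half_min"):
        raise ValueError(f"unknown floor_policy {floor_policy!r}")
    if m.is_log:
        raise ValueError("matrix is already log-transformed (see provenance)")
    values = m.data.to_numpy(dtype=float)
    if np.any(values <= 0):
        if floor_policy == "error":
            r, c = np.argwhere(values <= 0)[0]
            raise ValueError(
                f"non-positive value at peptide {m.data.index[r]!r}, "
                f"sample {m.data.columns[c]!r} with floor_policy='error'"
            )
        positive = values[values > 0]
        if positive.size == 0:
            raise ValueError("matrix has no positive values to derive a floor from")
        floor = positive.min() / 2.0
        values = np.where(values > 0, values, floor)
    logged = np.log2(values) if base == 2 else np.log(values)
    tag = "log2" if base == 2 else "ln"
    return NormalizedMatrix(
        pd.DataFrame(logged, index=m.data.index, columns=m.data.columns),
        provenance=m.provenance + (tag,),
    )


def intensity_cutoff_filter(
    m: IntensityMatrix, mode: str = "top_n", threshold: float = 1500
) -> IntensityMatrix:
    """Keep peptides by maximum raw intensity across samples.

    ``top_n`` keeps the ``threshold`` peptides with the largest max-across-
    samples intensity (ties broken by peptide id, lexicographically);
    ``min_max_intensity`` keeps peptides whose maximum exceeds ``threshold``.
    Surviving rows are bit-identical to the input rows.
    """
    _require_no_missing(m.data)
    maxima = m.data.max(axis=1)
    if mode == "top_n":
        n = int(threshold)
        if n < 1:
            raise ValueError("top_n threshold must be >= 1")
        if n >= len(maxima):
            if n > len(maxima):
                warnings.warn(
                    f"top_n={n} exceeds peptide count {len(maxima)}; returning all peptides",
                    stacklevel=2,
                )
            return m
        order = sorted(maxima.index, key=lambda pid: (-maxima[pid], pid))
        keep = set(order[:n])
        kept = m.data.loc[[pid for pid in m.data.index if pid in keep]]
    elif mode == "min_max_intensity":
        kept = m.data.loc[maxima > float(threshold)]
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    return IntensityMatrix(kept, provenance=m.provenance + (f"filter:{mode}={threshold}",))
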