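"""Behavioral-domain decoding of a gradient by ten-percentile binning.

The gradient map is split into ten-percentile bins (binary masks from the
0-10% interval up to 90-100%); for each behavioral term-activation map the
mean z-statistic within each bin is extracted, and only cells exceeding the
one-sided z threshold (default 1.645, i.e. p < 0.05) are kept for
interpretation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spatial_stats import SeedMap

__all__ = ["TermMapSet", "BinTermProfile", "percentile_bins", "bin_term_profile", "filter_terms"]


@dataclass
class TermMapSet:
    """Named term-activation values (z-statistic scale) at seed voxels."""

    names: list
    values: np.ndarray  # (n_terms, n_voxels)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.names):
            raise ValueError("one row of values per term is required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("term maps must be finite")

    @classmethod
    def from_volumes(cls, volumes: dict, seed_mask: np.ndarray) -> "TermMapSet":
        """Sample a {name: 3D volume} mapping at the seed voxels."""
        seed_mask = np.asarray(seed_mask, dtype=bool)
        names = list(volumes)
        vals = np.stack([np.asarray(volumes[n], dtype=float)[seed_mask] for n in names])
        return cls(names=names, values=vals)


@dataclass
class BinTermProfile:
    """terms x percentile-bin matrix of mean activation z-statistics."""

    names: list
    matrix: np.ndarray  # (n_terms, n_bins)
    bin_edges: list  # percentile interval per bin, e.g. (0, 10)
    kept_terms: list

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.names), len(self.bin_edges)):
            raise ValueError("matrix shape inconsistent with names/bins")
        if not set(self.kept_terms) <= set(self.names):
            raise ValueError("kept_terms must be a subset of names")

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{lo:g}-{hi:g}%" for lo, hi in self.bin_edges]
        return pd.DataFrame(self.matrix, index=self.names, columns=cols)


def percentile_bins(gradient_map: SeedMap | np.ndarray, n_bins: int = 10) -> list:
    """Split a gradient map into percentile-bin binary masks.

    Bin b (1-based) holds the voxels whose value falls in the
    [100(b-1)/n_bins, 100b/n_bins) percentile interval (last bin closed).
    Masks are disjoint, cover every voxel, and bin sizes differ by at most
    one. Ties (repeated values straddling an edge) are assigned by stable
    sort order, lower voxel index first, so any strictly monotone transform
    of the map yields identical memberships.
    """
    vals = gradient_map.values if isinstance(gradient_map, SeedMap) else np.asarray(gradient_map, dtype=float)
    n = vals.size
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} voxels, got {n}")
    order = np.argsort(vals, kind="stable")
    masks = []
    for chunk in np.array_split(order, n_bins):
        m = np.zeros(n, dtype=bool)
        m[chunk] = True
        masks.append(m)
    return masks


def bin_term_profile(masks: list, terms: TermMapSet) -> BinTermProfile:
    """Mean term z-statistic within each percentile-bin mask."""
    n_bins = len(masks)
    mat = np.empty((len(terms.names), n_bins))
    for b, mask in enumerate(masks):
        if not np.any(mask):
            raise ValueError(f"bin {b + 1} is empty")
        mat[:, b] = terms.values[:, mask].mean(axis=1)
    edges = [(100.0 * b / n_bins, 100.0 * (b + 1) / n_bins) for b in range(n_bins)]
    return BinTermProfile(names=list(terms.names), matrix=mat, bin_edges=edges, kept_terms=list(terms.names))


def filter_terms(profile: BinTermProfile, z_threshold: float = 1.645) -> BinTermProfile:
    """Zero cells not strictly above the threshold; drop all-zero terms.

    The inequality is strict (a cell exactly at the threshold is zeroed);
    the operation is idempotent.
    """
    mat = np.where(profile.matrix > z_threshold, profile.matrix, 0.0)
    kept = [name for name, row in zip(profile.names, mat) if np.any(row != 0)]
    return BinTermProfile(names=list(profile.names), matrix=mat, bin_edges=list(profile.bin_edges), kept_terms=kept)
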