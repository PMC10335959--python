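"""Winner-take-all assignment of seed voxels to canonical functional networks.

Each seed voxel is assigned to the network whose mean BOLD time course it
correlates with most strongly. Network mean time courses are computed over
target voxels only (the seed region is excluded, mirroring the target-set
exclusion of the connectivity stage and avoiding self-correlation bias).
A network that wins no voxel is reported absent.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import BoldGroupMatrix
from .embedding import GradientSet

__all__ = [
    "NetworkAtlas",
    "SeedParcellation",
    "network_timecourses",
    "winner_take_all",
    "subdivision_profiles",
]


@dataclass
class NetworkAtlas:
    """Integer network labels (1..K) over target voxels, with names."""

    labels: np.ndarray  # (n_targets,) ints in 1..K
    names: list
    target_index: np.ndarray  # (n_targets, 3)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.target_index = np.asarray(self.target_index, dtype=int)
        if self.labels.ndim != 1 or self.target_index.shape != (self.labels.size, 3):
            raise ValueError("labels and target_index are inconsistent")
        if self.labels.min() < 1 or self.labels.max() > len(self.names):
            raise ValueError("every label must have a name (labels are 1-based)")

    @classmethod
    def from_volume(cls, label_volume: np.ndarray, target_mask: np.ndarray, names) -> "NetworkAtlas":
        target_mask = np.asarray(target_mask, dtype=bool)
        idx = np.argwhere(target_mask)
        return cls(labels=np.asarray(label_volume)[target_mask], names=list(names), target_index=idx)

    @property
    def n_networks(self) -> int:
        return len(self.names)


@dataclass
class SeedParcellation:
    """Winner-take-all network assignment of seed voxels."""

    assignment: np.ndarray  # network id (1-based) per seed voxel
    winning_r: np.ndarray
    margin: np.ndarray  # winner minus runner-up correlation
    seed_index: np.ndarray
    names: list

    def __post_init__(self):
        if np.any(self.margin < 0):
            raise ValueError("margin must be non-negative")

    @property
    def present_networks(self) -> list:
        """Ids of networks that won at least one voxel."""
        return sorted(set(self.assignment.tolist()))

    @property
    def absent_networks(self) -> list:
        """Names of networks with no winning voxel (reported absent)."""
        present = set(self.assignment.tolist())
        return [self.names[i - 1] for i in range(1, len(self.names) + 1) if i not in present]


def network_timecourses(bold: BoldGroupMatrix, atlas: NetworkAtlas) -> np.ndarray:
    """Unweighted mean time course per network, (time x n_networks)."""
    cols = bold.columns_for(_mask_from_index(atlas.target_index, bold.grid_shape))
    out = np.empty((bold.n_timepoints, atlas.n_networks))
    for net in range(1, atlas.n_networks + 1):
        members = cols[atlas.labels == net]
        if members.size == 0:
            raise ValueError(f"network {net} ({atlas.names[net - 1]!r}) has no target voxels")
        out[:, net - 1] = bold.data[:, members].mean(axis=1)
    return out


def _mask_from_index(index: np.ndarray, grid_shape: tuple) -> np.ndarray:
    mask = np.zeros(grid_shape, dtype=bool)
    mask[tuple(np.asarray(index, dtype=int).T)] = True
    return mask


def winner_take_all(bold: BoldGroupMatrix, seed_mask: np.ndarray, atlas: NetworkAtlas) -> SeedParcellation:
    """Assign each seed voxel to its most-correlated network.

    Ties in the argmax go to the lowest network id (logged as a warning).
    """
    tc = network_timecourses(bold, atlas)
    seed_cols = bold.columns_for(np.asarray(seed_mask, dtype=bool))
    X = bold.data[:, seed_cols]
    Xc = X - X.mean(axis=0)
    Tc = tc - tc.mean(axis=0)
    nx = np.linalg.norm(Xc, axis=0)
    nt = np.linalg.norm(Tc, axis=0)
    if np.any(nx == 0):
        bad = np.argwhere(seed_mask)[nx == 0][0]
        raise ValueError(f"zero-variance seed voxel at grid index {tuple(bad)}")
    if np.any(nt == 0):
        raise ValueError("a network mean time course has zero variance")
    R = (Xc.T @ Tc) / np.outer(nx, nt)  # (n_seed, K)
    if np.any(~np.isfinite(R)):
        raise ValueError("non-finite network correlations for some seed voxel")

    winner = np.argmax(R, axis=1)  # argmax takes the first (lowest id) on ties
    top = R[np.arange(R.shape[0]), winner]
    ties = np.sum(R == top[:, None], axis=1) > 1
    if np.any(ties):
        warnings.warn(f"{int(ties.sum())} seed voxels tie between networks; lowest id wins", stacklevel=2)
    R_rest = R.copy()
    R_rest[np.arange(R.shape[0]), winner] = -np.inf
    runner_up = R_rest.max(axis=1) if R.shape[1] > 1 else np.full(R.shape[0], -np.inf)
    return SeedParcellation(
        assignment=winner + 1,
        winning_r=top,
        margin=top - runner_up,
        seed_index=np.argwhere(np.asarray(seed_mask, dtype=bool)),
        names=list(atlas.names),
    )


def subdivision_profiles(parcellation: SeedParcellation, gradients: GradientSet, which=(1, 2)) -> pd.DataFrame:
    """Gradient-value distributions per functional subdivision.

    Returns a long-format DataFrame (gradient, network, value) whose
    networks are ordered, within each gradient, by ascending median
    gradient value (categorical ``network`` column carries the order).
    Absent networks do not appear. A companion summary is available via
    ``df.groupby(...)``; medians are recomputed trivially.
    """
    if parcellation.assignment.shape[0] != gradients.coordinates.shape[0]:
        raise ValueError("parcellation and gradients cover different seed voxel sets")
    rows = []
    for g in which:
        vals = gradients.gradient(g)
        present = parcellation.present_networks
        med = {net: float(np.median(vals[parcellation.assignment == net])) for net in present}
        for net in sorted(present, key=lambda n: med[n]):
            for v in vals[parcellation.assignment == net]:
                rows.append({"gradient": g, "network": parcellation.names[net - 1],
                             "network_id": net, "value": float(v), "median": med[net]})
    return pd.DataFrame(rows)
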