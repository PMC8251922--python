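"""Assign expression samples to labeled brain-network masks by MNI coordinate.

Each sample carries an MNI millimetre coordinate.  The atlas is a stack of
binary masks on a shared voxel grid with a voxel-to-mm affine.  A sample is
assigned to the network whose mask contains the voxel nearest to its
coordinate (half-away-from-zero rounding), or to no network if the voxel lies
outside the grid or outside every mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["NetworkAtlas", "assign_samples", "tabulate_assignments"]


@dataclass
class NetworkAtlas:
    """Labeled binary masks on a common grid.

    Attributes
    ----------
    labels : list of str
        One label per mask, e.g. ``["A", ..., "I"]``.
    masks : bool ndarray of shape (n_labels, ni, nj, nk)
    affine : (4, 4) ndarray
        Voxel-index -> MNI mm transform.
    """

    labels: list[str]
    masks: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.masks.ndim != 4:
            raise ValueError("masks must be a 4-D (label, i, j, k) array")
        if len(self.labels) != self.masks.shape[0]:
            raise ValueError("number of labels does not match number of masks")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate atlas labels")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.masks.shape[1:])

    def mask(self, label: str) -> np.ndarray:
        return self.masks[self.labels.index(label)]


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (avoids platform-dependent banker's rounding)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def mm_to_voxel(atlas: NetworkAtlas, xyz_mm: np.ndarray) -> np.ndarray:
    """Map (n, 3) mm coordinates to nearest integer voxel indices."""
    xyz_mm = np.atleast_2d(np.asarray(xyz_mm, dtype=float))
    inv = np.linalg.inv(atlas.affine)
    homog = np.column_stack([xyz_mm, np.ones(len(xyz_mm))])
    vox = (inv @ homog.T).T[:, :3]
    return _round_half_away(vox).astype(int)


def assign_samples(
    atlas: NetworkAtlas,
    bundles: Iterable,
    overlap_policy: str = "error",
) -> pd.DataFrame:
    """Assign every sample of every donor bundle to a network label or none.

    Parameters
    ----------
    atlas : NetworkAtlas
    bundles : iterable of DonorBundle
    overlap_policy : {"error", "first"}
        What to do when a voxel belongs to more than one mask: raise, or take
        the first label in atlas order (with a logged warning).

    Returns
    -------
    DataFrame with columns donor_id, sample_id, network_label (object, None
    when unassigned), voxel_i/j/k (nullable Int64).
    """
    if overlap_policy not in ("error", "first"):
        raise ValueError(f"unknown overlap_policy {overlap_policy!r}")
    rows = []
    shape = np.array(atlas.grid_shape)
    for bundle in bundles:
        coords = bundle.samples[["mni_x", "mni_y", "mni_z"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"donor {bundle.donor_id}: non-finite MNI coordinate")
        vox = mm_to_voxel(atlas, coords)
        in_grid = np.all((vox >= 0) & (vox < shape), axis=1)
        for sid, v, ok in zip(bundle.samples.index, vox, in_grid):
            label = None
            vi = vj = vk = None
            if ok:
                vi, vj, vk = (int(v[0]), int(v[1]), int(v[2]))
                hits = np.flatnonzero(atlas.masks[:, vi, vj, vk])
                if hits.size > 1:
                    labs = [atlas.labels[h] for h in hits]
                    if overlap_policy == "error":
                        raise ValueError(
                            f"voxel ({vi},{vj},{vk}) lies in multiple masks {labs} "
                            f"(donor {bundle.donor_id}, sample {sid})"
                        )
                    logger.warning(
                        "voxel (%d,%d,%d) in multiple masks %s; taking %s",
                        vi, vj, vk, labs, labs[0],
                    )
                    label = labs[0]
                elif hits.size == 1:
                    label = atlas.labels[hits[0]]
            rows.append((bundle.donor_id, sid, label, vi, vj, vk))
    out = pd.DataFrame(
        rows,
        columns=["donor_id", "sample_id", "network_label", "voxel_i", "voxel_j", "voxel_k"],
    )
    for c in ("voxel_i", "voxel_j", "voxel_k"):
        out[c] = out[c].astype("Int64")
    return out


def tabulate_assignments(
    assignment: pd.DataFrame, labels: Sequence[str] | None = None
) -> pd.DataFrame:
    """Count assigned samples per donor per network, with a Total row.

    Unassigned samples (label none) are excluded; rows therefore sum to the
    number of assigned samples per donor.
    """
    assigned = assignment[assignment["network_label"].notna()]
    if labels is None:
        labels = sorted(assigned["network_label"].unique())
    donors = list(pd.unique(assignment["donor_id"]))
    table = (
        assigned.groupby(["donor_id", "network_label"]).size().unstack(fill_value=0)
        if len(assigned)
        else pd.DataFrame(index=pd.Index([], name="donor_id"))
    )
    table = table.reindex(index=donors, columns=list(labels), fill_value=0).fillna(0).astype(int)
    table.index.name = "donor_id"
    table.loc["Total"] = table.sum(axis=0)
    return table
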