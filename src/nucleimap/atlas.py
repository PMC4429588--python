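"""Probabilistic atlas construction from multi-subject binary labels.

Superimposing each subject's spatially normalised nucleus mask on a common
1-mm reference grid yields, per nucleus, a voxelwise probability map — the
relative frequency with which the nucleus was labelled at each voxel across
subjects.  A maximum probability map (MPM) turns the per-nucleus maps into a
hard parcellation: each voxel is assigned to the nucleus with the locally
highest probability, with an auditable tie-break rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import Grid

__all__ = [
    "SubjectLabelVolume",
    "ProbabilityMap",
    "MaxProbabilityMap",
    "build_probability_map",
    "build_mpm",
    "atlas_overlap_report",
]


@dataclass
class SubjectLabelVolume:
    """One subject's binary mask for one nucleus on the reference grid."""

    subject_id: str
    nucleus: str
    mask: np.ndarray
    grid: Grid

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape must match grid shape")


@dataclass
class ProbabilityMap:
    """Voxelwise relative labelling frequency of one nucleus across subjects."""

    nucleus: str
    values: np.ndarray
    n_subjects: int
    grid: Grid

    def support(self, threshold: float = 0.0) -> np.ndarray:
        """Binary mask of voxels with probability strictly above threshold."""
        return self.values > threshold

    def volume_mm3(self, threshold: float = 0.0) -> float:
        return float(self.support(threshold).sum()) * self.grid.voxel_volume_mm3


@dataclass
class MaxProbabilityMap:
    """Hard parcellation: voxel -> nucleus index (0 = unassigned)."""

    labels: np.ndarray
    nuclei: list[str]
    grid: Grid
    min_prob: float
    provenance: list[dict] = field(default_factory=list)

    def mask_for(self, nucleus: str) -> np.ndarray:
        return self.labels == (self.nuclei.index(nucleus) + 1)

    def label_lookup(self) -> dict[int, str]:
        return {i + 1: n for i, n in enumerate(self.nuclei)}


def build_probability_map(masks: list[SubjectLabelVolume]) -> ProbabilityMap:
    """Probability map of one nucleus: per-voxel subject count over N.

    All inputs must lie on the same grid; a mismatch is an error rather than
    a silent resample.
    """
    if len(masks) < 2:
        raise ValueError("need at least 2 subjects to build a probability map")
    nuclei = {m.nucleus for m in masks}
    if len(nuclei) != 1:
        raise ValueError(f"masks mix nuclei: {sorted(nuclei)}")
    grid = masks[0].grid
    for m in masks[1:]:
        grid.require_match(m.grid)
    counts = np.zeros(grid.shape, dtype=np.int32)
    for m in masks:
        counts += m.mask
    return ProbabilityMap(
        nucleus=masks[0].nucleus,
        values=counts / len(masks),
        n_subjects=len(masks),
        grid=grid,
    )


def _neighborhood_mean(values: np.ndarray) -> np.ndarray:
    """Mean probability over the 26-voxel neighbourhood (centre excluded)."""
    from scipy.ndimage import uniform_filter

    box = uniform_filter(values.astype(float), size=3, mode="constant") * 27.0
    return (box - values) / 26.0


def build_mpm(
    maps: list[ProbabilityMap],
    min_prob: float = 0.0,
    tiebreak: str = "neighborhood",
) -> MaxProbabilityMap:
    """Maximum probability map over a set of nucleus probability maps.

    A voxel is assigned to the arg-max nucleus wherever the maximum
    probability is nonzero and at least ``min_prob``.  Exact ties are resolved
    by ``tiebreak``:

    * ``"neighborhood"`` — higher mean probability over the 26-voxel
      neighbourhood, then lower nucleus index;
    * ``"index"`` — lower nucleus index;
    * ``"error"`` — refuse to assign tied voxels.

    Every tie decision is logged in ``provenance``.
    """
    if not maps:
        raise ValueError("no probability maps given")
    if not 0.0 <= min_prob <= 1.0:
        raise ValueError("min_prob must lie in [0, 1]")
    grid = maps[0].grid
    for m in maps[1:]:
        grid.require_match(m.grid)
    stack = np.stack([m.values for m in maps])  # (K, nx, ny, nz)
    maxval = stack.max(axis=0)
    assignable = (maxval > 0) & (maxval >= min_prob)
    winner = stack.argmax(axis=0)

    n_max = (stack == maxval[None]).sum(axis=0)
    tied = assignable & (n_max > 1)
    provenance: list[dict] = []
    if tied.any():
        if tiebreak == "error":
            raise ValueError(
                f"{int(tied.sum())} voxels have tied maxima and tiebreak='error'"
            )
        if tiebreak == "neighborhood":
            nbh = np.stack([_neighborhood_mean(m.values) for m in maps])
        elif tiebreak != "index":
            raise ValueError(f"unknown tiebreak rule {tiebreak!r}")
        for ijk in zip(*np.nonzero(tied)):
            cands = np.nonzero(stack[(slice(None),) + ijk] == maxval[ijk])[0]
            if tiebreak == "neighborhood":
                scores = nbh[(cands,) + ijk]
                best = cands[scores == scores.max()]
                rule = "neighborhood" if best.size == 1 else "neighborhood+index"
                chosen = int(best.min())
            else:
                rule = "index"
                chosen = int(cands.min())
            winner[ijk] = chosen
            provenance.append(
                {
                    "voxel": tuple(int(i) for i in ijk),
                    "tied": [maps[c].nucleus for c in cands],
                    "chosen": maps[chosen].nucleus,
                    "rule": rule,
                }
            )
    labels = np.where(assignable, winner + 1, 0).astype(np.uint16)
    return MaxProbabilityMap(
        labels=labels,
        nuclei=[m.nucleus for m in maps],
        grid=grid,
        min_prob=min_prob,
        provenance=provenance,
    )


def atlas_overlap_report(
    maps: list[ProbabilityMap],
    thresholds: tuple[float, ...] = (0.0, 0.5),
) -> pd.DataFrame:
    """Pairwise overlap between nucleus probability maps.

    For every pair and threshold: joint supra-threshold volume (mm^3) and the
    Dice coefficient of the supra-threshold supports.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 maps for an overlap report")
    grid = maps[0].grid
    for m in maps[1:]:
        grid.require_match(m.grid)
    vv = grid.voxel_volume_mm3
    rows = []
    for i in range(len(maps)):
        for j in range(i + 1, len(maps)):
            for thr in thresholds:
                a = maps[i].support(thr)
                b = maps[j].support(thr)
                inter = int((a & b).sum())
                denom = int(a.sum()) + int(b.sum())
                rows.append(
                    {
                        "nucleus_a": maps[i].nucleus,
                        "nucleus_b": maps[j].nucleus,
                        "threshold": thr,
                        "joint_volume_mm3": inter * vv,
                        "dice": (2 * inter / denom) if denom else 0.0,
                    }
                )
    return pd.DataFrame(rows)
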