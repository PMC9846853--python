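"""ROI construction from probabilistic and statistical volumes.

Two ROI recipes from the voice-localizer literature are implemented:

* **A1**: center at the maximum of a probabilistic map of Heschl's gyrus,
  then the 57 voxels closest to that center (millimetre distance) whose
  probability exceeds 50%.
* **TVAs**: three temporal-voice-area peaks (posterior, middle, anterior)
  found as the supra-threshold local maxima of a voice > non-voice t-map
  nearest to reference coordinates; around each, the 19 closest
  supra-threshold voxels; the hemisphere ROI is the conjunction (union)
  of the three 19-voxel sub-ROIs, 57 voxels when they are disjoint.

Conventions, fixed for determinism: "above threshold" is a strict
inequality; ties in map value or in distance are broken by lexicographic
voxel coordinate; a local maximum is strictly greater than all 26
neighbors. Maps are assumed to already live in the functional space —
atlas registration is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InvalidArgumentError, PeakNotFoundError, ROIShortfallError
from .volumes import VolumeMap

A1_ROI_SIZE = 57
TVA_SUBROI_SIZE = 19
A1_PROBABILITY_THRESHOLD = 0.5


@dataclass
class ROIDefinition:
    """A named, ordered voxel subset with selection provenance."""

    name: str
    hemisphere: str
    voxel_indices: np.ndarray  # (n, 3) int array, ordered by distance to center
    center: tuple[int, int, int]
    source_map_id: str = ""
    selection_threshold: float = float("nan")
    overlap_count: int = 0  # duplicate voxels merged during a conjunction

    def __post_init__(self):
        self.voxel_indices = np.asarray(self.voxel_indices, dtype=int).reshape(-1, 3)
        uniq = np.unique(self.voxel_indices, axis=0)
        if len(uniq) != len(self.voxel_indices):
            raise InvalidArgumentError("ROI voxel list contains duplicates")

    @property
    def size(self) -> int:
        return len(self.voxel_indices)

    def to_mask(self, volume: VolumeMap) -> VolumeMap:
        grid = np.zeros(volume.shape)
        ii, jj, kk = self.voxel_indices.T
        grid[ii, jj, kk] = 1.0
        return VolumeMap(grid=grid, affine=volume.affine, kind="beta")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.voxel_indices, columns=["x", "y", "z"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path, name: str = "", hemisphere: str = "left") -> "ROIDefinition":
        vox = pd.read_csv(path, sep="\t")[["x", "y", "z"]].to_numpy(int)
        return cls(name=name, hemisphere=hemisphere, voxel_indices=vox,
                   center=tuple(vox[0]))


def _lex_sorted(coords: np.ndarray) -> np.ndarray:
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))
    return coords[order]


def find_map_maximum(
    volume: VolumeMap, mask: Optional[np.ndarray] = None
) -> tuple[int, int, int]:
    """Coordinate of the largest value, ties broken lexicographically.

    ``mask`` restricts the search to a boolean sub-grid or an (n, 3)
    coordinate list.
    """
    grid = volume.grid
    if mask is not None:
        mask = np.asarray(mask)
        if mask.dtype == bool:
            if not mask.any():
                raise InvalidArgumentError("mask is empty")
            candidates = np.argwhere(mask)
        else:
            if mask.size == 0:
                raise InvalidArgumentError("mask is empty")
            candidates = mask.reshape(-1, 3)
        values = grid[candidates[:, 0], candidates[:, 1], candidates[:, 2]]
    else:
        candidates = np.argwhere(np.ones(grid.shape, bool))
        values = grid.ravel()
    finite = np.isfinite(values)
    if not finite.any():
        raise InvalidArgumentError("map contains no finite values")
    candidates, values = candidates[finite], values[finite]
    best = values == values.max()
    return tuple(int(c) for c in _lex_sorted(candidates[best])[0])


def build_roi_around(
    volume: VolumeMap,
    center: tuple[int, int, int],
    size: int,
    threshold: float,
    name: str = "roi",
    hemisphere: str = "left",
    source_map_id: str = "",
) -> ROIDefinition:
    """The ``size`` voxels nearest to ``center`` (mm distance through the
    affine) among voxels with map value strictly above ``threshold``.

    Raises :class:`ROIShortfallError` (carrying the achievable count) if
    fewer than ``size`` voxels pass — never silently pads.
    """
    shape = np.asarray(volume.shape)
    center = tuple(int(c) for c in center)
    if any(c < 0 or c >= s for c, s in zip(center, shape)):
        raise InvalidArgumentError(f"center {center} outside grid")
    if size < 1:
        raise InvalidArgumentError("size must be positive")
    with np.errstate(invalid="ignore"):
        passing = np.argwhere(volume.grid > threshold)
    if len(passing) < size:
        raise ROIShortfallError(requested=size, achievable=len(passing))
    center_mm = volume.voxel_to_mm(np.asarray(center))[0]
    mm = volume.voxel_to_mm(passing)
    dist = np.linalg.norm(mm - center_mm, axis=1)
    order = np.lexsort((passing[:, 2], passing[:, 1], passing[:, 0], dist))
    chosen = passing[order[:size]]
    return ROIDefinition(
        name=name,
        hemisphere=hemisphere,
        voxel_indices=chosen,
        center=center,
        source_map_id=source_map_id,
        selection_threshold=threshold,
    )


def local_maxima(volume: VolumeMap, threshold: float = -np.inf) -> np.ndarray:
    """Coordinates strictly greater than all 26 neighbors and above threshold."""
    grid = volume.grid
    footprint = np.ones((3, 3, 3), bool)
    footprint[1, 1, 1] = False
    neighbor_max = ndimage.maximum_filter(
        grid, footprint=footprint, mode="constant", cval=-np.inf
    )
    peaks = np.argwhere((grid > neighbor_max) & (grid > threshold))
    return _lex_sorted(peaks) if len(peaks) else peaks.reshape(0, 3)


def find_tva_centers(
    t_map: VolumeMap,
    reference_coords_mm: Sequence[Sequence[float]],
    sig_threshold: float,
) -> list[tuple[int, int, int]]:
    """For each reference coordinate, the nearest supra-threshold local
    maximum of the t-map, with distinctness enforced.

    Assignment is greedy over all (reference, peak) pairs in order of
    increasing millimetre distance, so no two references claim the same
    peak; a reference whose candidates are exhausted raises
    :class:`PeakNotFoundError` naming it.
    """
    if t_map.kind != "tstat":
        raise InvalidArgumentError("find_tva_centers requires a tstat map")
    refs = np.atleast_2d(np.asarray(reference_coords_mm, dtype=float))
    peaks = local_maxima(t_map, threshold=sig_threshold)
    if len(peaks) == 0:
        raise PeakNotFoundError(
            f"no local maximum above {sig_threshold} for reference {refs[0].tolist()}"
        )
    peaks_mm = t_map.voxel_to_mm(peaks)
    # all pairwise distances, globally greedy assignment
    d = np.linalg.norm(refs[:, None, :] - peaks_mm[None, :, :], axis=2)
    assigned: dict[int, int] = {}
    used_peaks: set[int] = set()
    for flat in np.argsort(d, axis=None, kind="stable"):
        r, p = np.unravel_index(flat, d.shape)
        if r in assigned or p in used_peaks:
            continue
        assigned[int(r)] = int(p)
        used_peaks.add(int(p))
        if len(assigned) == len(refs):
            break
    for r in range(len(refs)):
        if r not in assigned:
            raise PeakNotFoundError(
                f"no distinct supra-threshold local maximum left for reference "
                f"{refs[r].tolist()}"
            )
    return [tuple(int(c) for c in peaks[assigned[r]]) for r in range(len(refs))]


def build_tva_conjunction(
    t_map: VolumeMap,
    centers: Sequence[tuple[int, int, int]],
    subsize: int = TVA_SUBROI_SIZE,
    sig_threshold: float = 0.0,
    hemisphere: str = "left",
    name: str = "TVA",
    source_map_id: str = "",
) -> ROIDefinition:
    """Union of per-center sub-ROIs of ``subsize`` voxels each.

    Voxels shared by several sub-ROIs are counted once and reported in
    ``overlap_count``; with disjoint sub-ROIs the conjunction has
    ``len(centers) * subsize`` voxels. Sub-ROI shortfalls propagate.
    """
    sub_rois = [
        build_roi_around(
            t_map, c, subsize, sig_threshold,
            name=f"{name}_sub{i}", hemisphere=hemisphere, source_map_id=source_map_id,
        )
        for i, c in enumerate(centers)
    ]
    stacked = np.vstack([r.voxel_indices for r in sub_rois])
    uniq, first_pos = np.unique(stacked, axis=0, return_index=True)
    # keep first-appearance order (sub-ROI order, then distance order within)
    uniq = uniq[np.argsort(first_pos)]
    overlap = len(stacked) - len(uniq)
    return ROIDefinition(
        name=name,
        hemisphere=hemisphere,
        voxel_indices=uniq,
        center=tuple(centers[0]),
        source_map_id=source_map_id,
        selection_threshold=sig_threshold,
        overlap_count=overlap,
    )
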