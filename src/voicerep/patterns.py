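"""ROI activity patterns and the two z-scoring schemes.

An activity pattern is an events-(or stimuli-)by-voxels matrix of GLM
response estimates. Two standardization schemes control for different
nuisances before multivariate analysis:

``along_stimuli``
    z-score each voxel across events (the familiar feature scaling of
    machine-learning pipelines). Between-event differences in overall
    activation level are preserved.

``along_voxels``
    z-score each event across voxels. Any voxel-uniform additive offset
    or multiplicative gain of an event is removed exactly, so only the
    *shape* of the pattern across voxels survives. This is the scheme
    that controls for one stimulus class simply driving the whole ROI
    harder.

For decoding, standardization is applied to all events of both runs
before the train/test split — matching the published protocol, which
standardized first and split afterwards. That introduces a mild
train/test leakage; a fold-wise variant is available through
``voicerep.decoding.decode_vocal_vs_nonvocal(..., standardize_within_fold=True)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import IncompatibleSpaceError, InvalidArgumentError
from .volumes import VolumeMap

STANDARDIZATIONS = ("none", "along_stimuli", "along_voxels")


@dataclass
class ActivityPattern:
    """Events-or-stimuli x voxels response matrix with provenance."""

    values: np.ndarray
    row_labels: list[str]
    run_labels: Optional[np.ndarray] = None
    roi: Optional[object] = None  # ROIDefinition, kept loose to avoid a cycle
    participant_id: str = ""
    standardization: str = "none"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidArgumentError("values must be a 2D matrix")
        if len(self.row_labels) != self.values.shape[0]:
            raise InvalidArgumentError("row_labels length must match row count")
        if self.run_labels is not None:
            self.run_labels = np.asarray(self.run_labels)
            if len(self.run_labels) != self.values.shape[0]:
                raise InvalidArgumentError("run_labels length must match row count")
        if self.standardization not in STANDARDIZATIONS:
            raise InvalidArgumentError(
                f"unknown standardization {self.standardization!r}"
            )

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def mean_by_stimulus(self) -> "ActivityPattern":
        """Average event rows sharing a row label (i.e. across runs).

        Output rows follow the first appearance order of each label, one
        row per stimulus — the stimulus-level matrix that feeds RSA.
        """
        labels = list(dict.fromkeys(self.row_labels))
        idx = {lab: [] for lab in labels}
        for i, lab in enumerate(self.row_labels):
            idx[lab].append(i)
        means = np.vstack([self.values[idx[lab]].mean(axis=0) for lab in labels])
        return ActivityPattern(
            values=means,
            row_labels=labels,
            run_labels=None,
            roi=self.roi,
            participant_id=self.participant_id,
            standardization=self.standardization,
        )

    def select_rows(self, mask: np.ndarray) -> "ActivityPattern":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return ActivityPattern(
            values=self.values[idx],
            row_labels=[self.row_labels[i] for i in idx],
            run_labels=None if self.run_labels is None else self.run_labels[idx],
            roi=self.roi,
            participant_id=self.participant_id,
            standardization=self.standardization,
        )

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=[f"v{i}" for i in range(self.n_voxels)])
        df.insert(0, "row_label", self.row_labels)
        if self.run_labels is not None:
            df.insert(1, "run", self.run_labels)
        df.to_csv(path, sep="\t", index=False)
        meta = {
            "participant_id": self.participant_id,
            "standardization": self.standardization,
            "n_events": self.n_events,
            "n_voxels": self.n_voxels,
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ActivityPattern":
        df = pd.read_csv(path, sep="\t")
        run = df.pop("run").to_numpy() if "run" in df.columns else None
        labels = df.pop("row_label").astype(str).tolist()
        meta_path = Path(str(path) + ".json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(
            values=df.to_numpy(dtype=float),
            row_labels=labels,
            run_labels=run,
            participant_id=meta.get("participant_id", ""),
            standardization=meta.get("standardization", "none"),
        )


def extract_patterns(
    beta_volumes: Sequence[VolumeMap],
    roi,
    labels: Sequence[str],
    run_labels: Optional[Sequence] = None,
    participant_id: str = "",
) -> ActivityPattern:
    """Sample each beta volume at the ROI's voxels, in the ROI's stored order."""
    if len(beta_volumes) == 0:
        raise InvalidArgumentError("need at least one beta volume")
    if len(labels) != len(beta_volumes):
        raise InvalidArgumentError("one label per volume required")
    ref = beta_volumes[0]
    for vol in beta_volumes[1:]:
        if not vol.same_space(ref):
            raise IncompatibleSpaceError("beta volumes differ in shape or affine")
    vox = np.asarray(roi.voxel_indices)
    if vox.size and (vox.min() < 0 or np.any(vox >= np.asarray(ref.shape))):
        raise IncompatibleSpaceError("ROI voxels fall outside the volume grid")
    ii, jj, kk = vox[:, 0], vox[:, 1], vox[:, 2]
    values = np.vstack([vol.grid[ii, jj, kk] for vol in beta_volumes])
    return ActivityPattern(
        values=values,
        row_labels=list(labels),
        run_labels=None if run_labels is None else np.asarray(run_labels),
        roi=roi,
        participant_id=participant_id,
    )


def _zscore(x: np.ndarray, axis: int, what: str) -> np.ndarray:
    # ddof=1: sample sd, the fixed convention throughout the package
    mean = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, ddof=1, keepdims=True)
    degenerate = (sd == 0) | ~np.isfinite(sd)
    if degenerate.any():
        which = np.flatnonzero(degenerate.ravel())
        warnings.warn(
            f"zero-variance {what}(s) {which.tolist()} mapped to zeros during "
            "standardization",
            RuntimeWarning,
            stacklevel=3,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x - mean) / sd
    return np.where(np.broadcast_to(degenerate, z.shape), 0.0, z)


def standardize_along_stimuli(pattern: ActivityPattern) -> ActivityPattern:
    """z-score each voxel (column) across events/stimuli (rows)."""
    if pattern.standardization != "none":
        raise InvalidArgumentError("pattern is already standardized")
    if pattern.n_events < 2:
        raise InvalidArgumentError("need at least 2 rows to standardize")
    z = _zscore(pattern.values, axis=0, what="column")
    return replace(pattern, values=z, standardization="along_stimuli")


def standardize_along_voxels(pattern: ActivityPattern) -> ActivityPattern:
    """z-score each event/stimulus (row) across voxels (columns)."""
    if pattern.standardization != "none":
        raise InvalidArgumentError("pattern is already standardized")
    if pattern.n_voxels < 2:
        raise InvalidArgumentError("need at least 2 voxels to standardize")
    z = _zscore(pattern.values, axis=1, what="row")
    return replace(pattern, values=z, standardization="along_voxels")


def standardize(pattern: ActivityPattern, scheme: str) -> ActivityPattern:
    """Dispatch on scheme name; ``none`` returns the pattern unchanged."""
    if scheme == "none":
        return pattern
    if scheme == "along_stimuli":
        return standardize_along_stimuli(pattern)
    if scheme == "along_voxels":
        return standardize_along_voxels(pattern)
    raise InvalidArgumentError(f"unknown standardization {scheme!r}")
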