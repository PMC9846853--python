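"""Representational similarity analysis.

Cerebral representational dissimilarity matrices (RDMs) are Euclidean
distances between stimuli in multi-voxel activity space, computed on the
stimulus-level pattern (event rows averaged across runs). They are
compared, by Spearman correlation over the upper triangle, against three
binary categorical models of the stimulus space:

* ``human`` — human voices (speech and non-speech vocal alike) vs.
  non-vocal sounds;
* ``speech`` — speech apart from all other sounds;
* ``nonspeech`` — non-speech human voices apart from all other sounds;

and optionally against an acoustic RDM built from modulation power
spectra. Planned within-vs-between comparisons use a one-tailed
bootstrapped two-sample t-test on the RDM cells, Bonferroni-corrected
over the full ROI x hemisphere x standardization x model factorial.

Statistics run on raw distances; the percentile transform is a
display-only monotone rescaling. The bootstrap resamples the within and
between cell pools with replacement after shifting both to the pooled
mean (the shift method); a condition-level resampling variant is
provided because cells sharing a condition are not independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .errors import InvalidArgumentError, UndefinedCorrelationError
from .patterns import ActivityPattern
from .stimuli import StimulusSet

MODEL_NAMES = ("human", "speech", "nonspeech")
#: Stimulus-level grouping each categorical model isolates.
_MODEL_GROUPS = {
    "human": lambda s: s.main_category == "vocal",
    "speech": lambda s: s.subcategory == "speech",
    "nonspeech": lambda s: s.subcategory == "nonspeech_vocal",
}


@dataclass
class RDM:
    """Symmetric condition-by-condition dissimilarity matrix."""

    condition_labels: list[str]
    matrix: np.ndarray
    metric_tag: str = "euclidean"  # euclidean | binary_model | mps_distance
    transform: str = "raw"  # raw | percentile
    name: str = ""

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.condition_labels)
        if self.matrix.shape != (n, n):
            raise InvalidArgumentError("matrix shape must match label count")
        if len(set(self.condition_labels)) != n:
            raise InvalidArgumentError("condition labels must be unique")
        if not np.allclose(self.matrix, self.matrix.T, equal_nan=True):
            raise InvalidArgumentError("RDM must be symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0):
            raise InvalidArgumentError("RDM diagonal must be zero")
        if np.nanmin(self.matrix) < -1e-12:
            raise InvalidArgumentError("dissimilarities must be non-negative")

    @property
    def n_conditions(self) -> int:
        return len(self.condition_labels)

    def upper_values(self) -> np.ndarray:
        """Strictly-upper-triangle entries in row-major order."""
        iu = np.triu_indices(self.n_conditions, k=1)
        return self.matrix[iu]

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.matrix, index=self.condition_labels, columns=self.condition_labels
        ).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "RDM":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(condition_labels=[str(c) for c in df.columns],
                   matrix=df.to_numpy(float), **kwargs)


def compute_rdm(pattern: ActivityPattern) -> RDM:
    """Euclidean-distance RDM over stimulus rows.

    Event-level patterns (duplicate row labels) are averaged per stimulus
    across runs first, yielding the stimuli x voxels matrix RSA operates on.
    """
    if len(set(pattern.row_labels)) != len(pattern.row_labels):
        pattern = pattern.mean_by_stimulus()
    mat = squareform(pdist(pattern.values, metric="euclidean"))
    return RDM(
        condition_labels=list(pattern.row_labels),
        matrix=mat,
        metric_tag="euclidean",
        name=f"{pattern.participant_id}:{pattern.standardization}",
    )


def percentile_transform(rdm: RDM) -> RDM:
    """Replace off-diagonal entries by their percentile rank (display only).

    Percentile of a cell is ``100 * (rank - 0.5) / n`` over the upper
    triangle with average ranks for ties (all-equal entries map to the
    50th percentile); rank order is preserved.
    """
    if rdm.transform != "raw":
        raise InvalidArgumentError("percentile transform expects a raw RDM")
    vals = rdm.upper_values()
    ranks = stats.rankdata(vals, method="average")
    perc = 100.0 * (ranks - 0.5) / len(vals)
    mat = squareform(perc)
    return RDM(
        condition_labels=list(rdm.condition_labels),
        matrix=mat,
        metric_tag=rdm.metric_tag,
        transform="percentile",
        name=rdm.name,
    )


def make_model_rdm(stimulus_set: StimulusSet, model_name: str) -> RDM:
    """Binary categorical model RDM: 0 within the partition cells, 1 between."""
    if model_name not in MODEL_NAMES:
        raise InvalidArgumentError(f"unknown model {model_name!r}")
    in_group = np.array([_MODEL_GROUPS[model_name](s) for s in stimulus_set])
    mat = (in_group[:, None] != in_group[None, :]).astype(float)
    return RDM(
        condition_labels=stimulus_set.ids,
        matrix=mat,
        metric_tag="binary_model",
        name=model_name,
    )


@dataclass
class RDMComparison:
    rdm_ids: tuple[str, str]
    spearman_rho: float


def correlate_rdms(a: RDM, b: RDM) -> RDMComparison:
    """Spearman rank correlation over the strictly-upper-triangle cells."""
    if a.condition_labels != b.condition_labels:
        raise InvalidArgumentError("RDMs must share condition labels and order")
    va, vb = a.upper_values(), b.upper_values()
    if np.all(va == va[0]) or np.all(vb == vb[0]):
        raise UndefinedCorrelationError(
            "rank correlation undefined for constant dissimilarities"
        )
    rho = stats.spearmanr(va, vb).statistic
    return RDMComparison(rdm_ids=(a.name, b.name), spearman_rho=float(rho))


def mds_embed(rdm_set: Sequence[RDM]) -> np.ndarray:
    """Classical MDS of the RDM set in the space of (1 - Spearman rho).

    Each RDM becomes a 2D point; pairwise dissimilarity between RDMs is
    one minus their Spearman correlation. Output is centered at the
    origin with a deterministic principal-axis sign convention (the
    entry of largest magnitude on each axis is positive).
    """
    if len(rdm_set) < 3:
        raise InvalidArgumentError("need at least 3 RDMs to embed")
    n = len(rdm_set)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 1.0 - correlate_rdms(rdm_set[i], rdm_set[j]).spearman_rho
    # classical (Torgerson) MDS: double-center the squared distances
    d2 = d**2
    j_mat = np.eye(n) - np.ones((n, n)) / n
    b_mat = -0.5 * j_mat @ d2 @ j_mat
    eigval, eigvec = np.linalg.eigh(b_mat)
    order = np.argsort(eigval)[::-1][:2]
    lam = np.clip(eigval[order], 0.0, None)
    coords = eigvec[:, order] * np.sqrt(lam)[None, :]
    coords -= coords.mean(axis=0, keepdims=True)
    for axis in range(coords.shape[1]):
        col = coords[:, axis]
        if col.any() and col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    return coords


# ---------------------------------------------------------------- planned tests


@dataclass
class PlannedComparisonResult:
    roi_name: str
    hemisphere: str
    standardization: str
    model_name: str
    t_stat: float
    p_boot: float
    n_iter: int
    p_corrected: float = float("nan")
    m: int = 0

    def correct(self, m: int) -> "PlannedComparisonResult":
        self.m = m
        self.p_corrected = min(1.0, self.p_boot * m)
        return self


def _pooled_t(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sample pooled-variance t statistic, mean(x) - mean(y)."""
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    return float((x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny)))


def within_between_cells(
    rdm: RDM, partition: Sequence[bool]
) -> tuple[np.ndarray, np.ndarray]:
    """Split upper-triangle cells into within-group and between-group pools.

    ``partition`` flags the in-group conditions; *within* pools cells
    whose two conditions fall on the same side of the partition, *between*
    pools cells crossing it.
    """
    part = np.asarray(partition, dtype=bool)
    if len(part) != rdm.n_conditions:
        raise InvalidArgumentError("partition length must match condition count")
    iu, ju = np.triu_indices(rdm.n_conditions, k=1)
    same = part[iu] == part[ju]
    vals = rdm.matrix[iu, ju]
    within, between = vals[same], vals[~same]
    if within.size == 0 or between.size == 0:
        raise InvalidArgumentError("partition leaves an empty cell pool")
    return within, between


def within_between_test(
    rdm: RDM,
    partition: Sequence[bool],
    n_iter: int = 10_000,
    seed: int = 0,
    resample: str = "cells",
    **meta,
) -> PlannedComparisonResult:
    """One-tailed bootstrapped two-sample t-test of between > within.

    The observed statistic is the pooled-variance t of between-group
    minus within-group dissimilarities. With the default
    ``resample="cells"`` the null resamples both cell pools with
    replacement (at their own sizes) after shifting each to the pooled
    mean, and ``p_boot`` is the fraction of null t values at or above
    the observed one. Cells sharing a condition are not independent,
    which makes the cell-level bootstrap anticonservative on real RDMs;
    ``resample="conditions"`` instead permutes the partition labels over
    conditions each iteration (a condition-label permutation null),
    which respects that dependence exactly and is what the pipeline uses
    for brain RDMs.
    """
    if n_iter < 1:
        raise InvalidArgumentError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    within, between = within_between_cells(rdm, partition)
    t_obs = _pooled_t(between, within)
    pooled_mean = np.concatenate([within, between]).mean()
    if resample == "cells":
        w0 = within - within.mean() + pooled_mean
        b0 = between - between.mean() + pooled_mean
        t_null = np.empty(n_iter)
        chunk = max(1, min(n_iter, 20_000_000 // max(1, w0.size + b0.size)))
        done = 0
        while done < n_iter:
            k = min(chunk, n_iter - done)
            wi = w0[rng.integers(0, w0.size, size=(k, w0.size))]
            bi = b0[rng.integers(0, b0.size, size=(k, b0.size))]
            t_null[done : done + k] = _pooled_t_rows(bi, wi)
            done += k
    elif resample == "conditions":
        part = np.asarray(partition, dtype=bool)
        n = rdm.n_conditions
        iu, ju = np.triu_indices(n, k=1)
        vals = rdm.matrix[iu, ju]
        # permute which conditions are in-group; cells move between pools
        # as whole condition-pair blocks, preserving their dependence
        perms = np.empty((n_iter, n), dtype=bool)
        for i in range(n_iter):
            perms[i] = rng.permutation(part)
        same = perms[:, iu] == perms[:, ju]  # (n_iter, n_cells)
        t_null = _masked_pools_t(vals, ~same, same)
    else:
        raise InvalidArgumentError(f"unknown resampling unit {resample!r}")
    p_boot = float(np.mean(t_null >= t_obs))
    return PlannedComparisonResult(
        roi_name=meta.get("roi_name", ""),
        hemisphere=meta.get("hemisphere", ""),
        standardization=meta.get("standardization", ""),
        model_name=meta.get("model_name", ""),
        t_stat=t_obs,
        p_boot=p_boot,
        n_iter=n_iter,
    )


def _masked_pools_t(vals: np.ndarray, x_mask: np.ndarray, y_mask: np.ndarray) -> np.ndarray:
    """Pooled two-sample t of vals[x_mask] vs vals[y_mask], row-wise over masks."""
    nx = x_mask.sum(axis=1)
    ny = y_mask.sum(axis=1)
    sx = x_mask @ vals
    sy = y_mask @ vals
    sx2 = x_mask @ vals**2
    sy2 = y_mask @ vals**2
    mx, my = sx / nx, sy / ny
    vx = (sx2 - nx * mx**2) / (nx - 1)
    vy = (sy2 - ny * my**2) / (ny - 1)
    sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mx - my) / np.sqrt(sp2 * (1 / nx + 1 / ny))
    return np.nan_to_num(t)


def _pooled_t_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise pooled two-sample t for (k, nx) vs (k, ny) resample blocks."""
    nx, ny = x.shape[1], y.shape[1]
    sp2 = ((nx - 1) * x.var(axis=1, ddof=1) + (ny - 1) * y.var(axis=1, ddof=1)) / (
        nx + ny - 2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (x.mean(axis=1) - y.mean(axis=1)) / np.sqrt(sp2 * (1 / nx + 1 / ny))
    return np.nan_to_num(t)


def enumerate_planned_comparisons(
    rois: Sequence[str],
    standardizations: Sequence[str],
    models: Sequence[str],
    hemispheres: Sequence[str] = ("left", "right"),
) -> tuple[list[dict], int]:
    """Full factorial of planned comparisons and its Bonferroni factor.

    The standard configuration (2 ROIs x 2 hemispheres x 2
    standardizations x 3 models) yields m = 24 corrected tests.
    """
    if not (rois and standardizations and models and hemispheres):
        raise InvalidArgumentError("all factor lists must be non-empty")
    specs = [
        {
            "roi_name": r,
            "hemisphere": h,
            "standardization": s,
            "model_name": mdl,
        }
        for r, h, s, mdl in product(rois, hemispheres, standardizations, models)
    ]
    return specs, len(specs)
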