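"""Voxelwise group statistics: within-group maps, union mask, group GLM,
FDR and cluster-extent thresholding, and per-seed difference masks.

The analysis mirrors the two-level seed-connectivity comparison: (1) a
one-sample t-test per group against zero, thresholded at voxel-level FWE
(Bonferroni) P < 0.05 with a minimum cluster extent; (2) the union of the
two within-group masks defines the search space for a general linear
model with a group contrast and age/sex/education covariates, thresholded
at voxel-level FDR (Benjamini-Hochberg) q < 0.05 with cluster size >= 10.
Seeds whose difference mask is empty are flagged and dropped from the
downstream brain-behavior analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .connectivity import FCMapStack

__all__ = [
    "StatMap",
    "DifferenceMask",
    "one_sample_map",
    "fwe_threshold",
    "union_mask",
    "group_glm",
    "fdr_bh",
    "cluster_filter",
    "within_group_mask",
    "difference_features",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class StatMap:
    """Per-voxel t statistics with two-tailed p values."""

    t: np.ndarray
    p: np.ndarray
    df: int
    contrast: str

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=np.float64)
        self.p = np.asarray(self.p, dtype=np.float64)
        if self.t.shape != self.p.shape:
            raise ValueError("t and p must have matching shapes")


@dataclass
class DifferenceMask:
    """Voxels with a significant group difference for one seed."""

    seed_name: str
    mask: np.ndarray       # 3D bool
    direction: np.ndarray  # 3D int: sign of the group contrast, 0 outside
    clusters: pd.DataFrame

    @property
    def n_voxels(self):
        return int(self.mask.sum())


def _t_test_against_zero(values):
    """Vectorized one-sample t over columns; zero-variance -> t=0, p=1."""
    values = np.asarray(values, dtype=np.float64)
    n = values.shape[0]
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    df = n - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_var = sd == 0
    t = np.where(zero_var, 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(zero_var, 1.0, np.clip(p, np.finfo(float).tiny, 1.0))
    return t, p, df


def one_sample_map(stack: FCMapStack, group) -> StatMap:
    """One-sample t of Fisher-z values against 0 within one group."""
    values = stack.rows_for_group(group)
    if values.shape[0] == 0:
        raise ValueError(f"group {group!r} absent from stack")
    if values.shape[0] < 3:
        raise ValueError("one-sample map needs at least 3 subjects")
    t, p, df = _t_test_against_zero(values)
    return StatMap(t=t, p=p, df=df, contrast=f"{group} vs 0")


def fwe_threshold(stat_map: StatMap, alpha=0.05):
    """Bonferroni voxel-level threshold: p <= alpha / n_voxels."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    p = stat_map.p
    if p.size == 0:
        raise ValueError("empty statistic map")
    return p <= alpha / p.size


def union_mask(a, b):
    """Voxelwise OR of two boolean masks on the same grid."""
    a, b = np.asarray(a, bool), np.asarray(b, bool)
    if a.shape != b.shape:
        raise ValueError("mask grids do not match")
    return a | b


def group_glm(stack: FCMapStack, covariates: pd.DataFrame | np.ndarray,
              contrast_group=None, voxel_subset=None) -> StatMap:
    """Per-voxel GLM t test on the group indicator with nuisance covariates.

    Design: intercept + group indicator (1 for ``contrast_group``, default
    the first group label) + covariate columns.  ``voxel_subset`` restricts
    the test to a boolean selection of stack features (the union mask).
    Positive t means the contrast group has higher connectivity.
    """
    groups = np.asarray(stack.group)
    labels = list(dict.fromkeys(groups.tolist()))
    if len(labels) != 2:
        raise ValueError("group GLM expects exactly two groups")
    if contrast_group is None:
        contrast_group = labels[0]
    indicator = (groups == contrast_group).astype(float)
    cov = np.asarray(covariates, dtype=np.float64)
    if cov.ndim == 1:
        cov = cov[:, None]
    n = stack.n_subjects
    design = np.column_stack([np.ones(n), indicator, cov])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError("rank-deficient design (group confounded with a covariate?)")

    values = stack.values if voxel_subset is None else stack.values[:, voxel_subset]
    beta, *_ = np.linalg.lstsq(design, values, rcond=None)
    resid = values - design @ beta
    df = n - rank
    sigma_sq = (resid ** 2).sum(axis=0) / df
    xtx_inv = np.linalg.inv(design.T @ design)
    se = np.sqrt(np.clip(sigma_sq * xtx_inv[1, 1], 0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta[1] / se
    zero = se == 0
    t = np.where(zero, 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(zero, 1.0, np.clip(p, np.finfo(float).tiny, 1.0))
    return StatMap(t=t, p=p, df=df,
                   contrast=f"{contrast_group} vs {[g for g in labels if g != contrast_group][0]}")


def fdr_bh(p_values, q=0.05):
    """Benjamini-Hochberg step-up rejection mask at level ``q``."""
    p_values = np.asarray(p_values, dtype=np.float64)
    if p_values.size == 0:
        raise ValueError("empty p-value vector")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    reject, *_ = multipletests(p_values, alpha=q, method="fdr_bh")
    return reject


def cluster_filter(mask, min_voxels=10, connectivity=18, stat=None):
    """Label connected components and drop those below ``min_voxels``.

    ``connectivity`` follows the 3D convention: 6 (faces), 18 (faces +
    edges) or 26 (faces + edges + corners).  Returns ``(table, filtered
    mask)`` with the table sorted by size descending; if a statistic
    volume is supplied, each cluster reports its peak |stat| and location.
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be one of 6, 18, 26")
    mask = np.asarray(mask, dtype=bool)
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labeled, n_comp = ndimage.label(mask, structure=structure)
    rows, keep = [], np.zeros_like(mask)
    for comp in range(1, n_comp + 1):
        comp_mask = labeled == comp
        size = int(comp_mask.sum())
        if size < min_voxels:
            continue
        keep |= comp_mask
        row = {"cluster_id": comp, "n_voxels": size}
        coords = np.column_stack(np.nonzero(comp_mask))
        if stat is not None:
            vals = np.asarray(stat)[comp_mask]
            peak = int(np.argmax(np.abs(vals)))
            row.update(peak_stat=float(vals[peak]),
                       peak_x=int(coords[peak, 0]), peak_y=int(coords[peak, 1]),
                       peak_z=int(coords[peak, 2]),
                       sign=int(np.sign(vals[peak])))
        rows.append(row)
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values("n_voxels", ascending=False).reset_index(drop=True)
        table["cluster_id"] = np.arange(1, len(table) + 1)
    return table, keep


def within_group_mask(stack: FCMapStack, group, alpha=0.05, min_voxels=10,
                      connectivity=18):
    """Within-group connectivity mask: Bonferroni voxel FWE + cluster extent.

    Returns the 3D boolean mask of voxels where the group shows reliable
    nonzero connectivity with the seed.
    """
    sm = one_sample_map(stack, group)
    voxel_pass = fwe_threshold(sm, alpha)
    vol = stack.index_map.unvectorize(voxel_pass.astype(np.int8)) > 0
    _, filtered = cluster_filter(vol, min_voxels, connectivity, stat=None)
    return filtered


def difference_features(stack: FCMapStack, covariates, *, contrast_group=None,
                        fwe_alpha=0.05, q=0.05, min_voxels=10,
                        connectivity=18) -> DifferenceMask:
    """Full between-group difference mask for one seed.

    Pipeline: within-group FWE masks for both groups -> union mask ->
    group GLM with covariates inside the union -> voxel FDR at ``q`` ->
    cluster filter at ``min_voxels``.  An empty mask is a valid result
    (the seed shows no group difference).
    """
    groups = list(dict.fromkeys(np.asarray(stack.group).tolist()))
    masks = [within_group_mask(stack, g, fwe_alpha, min_voxels, connectivity)
             for g in groups]
    union = union_mask(masks[0], masks[1])
    imap = stack.index_map
    in_union = imap.vectorize(union.astype(np.int8)) > 0
    empty = DifferenceMask(stack.seed_name, np.zeros(imap.shape, bool),
                           np.zeros(imap.shape, np.int8), pd.DataFrame())
    if not in_union.any():
        return empty
    sm = group_glm(stack, covariates, contrast_group=contrast_group,
                   voxel_subset=in_union)
    reject = fdr_bh(sm.p, q)
    if not reject.any():
        return empty
    sig_vec = np.zeros(imap.n_voxels, bool)
    sig_vec[np.flatnonzero(in_union)] = reject
    t_vec = np.zeros(imap.n_voxels)
    t_vec[np.flatnonzero(in_union)] = sm.t
    sig_vol = imap.unvectorize(sig_vec.astype(np.int8)) > 0
    t_vol = imap.unvectorize(t_vec)
    table, filtered = cluster_filter(sig_vol, min_voxels, connectivity, stat=t_vol)
    direction = np.where(filtered, np.sign(t_vol), 0).astype(np.int8)
    return DifferenceMask(stack.seed_name, filtered, direction, table)
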