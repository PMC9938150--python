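"""Behavioral PLS correlation between brain features and clinical scores.

The model takes a z-scored brain matrix X (subjects x voxel features) and
behavior matrix Y (subjects x clinical scores), forms the cross-covariance
R = X^T Y and decomposes it by SVD.  Each latent variable (LV) pairs a
voxel salience pattern V[:, l] with a behavior salience pattern U[:, l];
the singular value s_l measures the cross-block covariance captured, and
subject-level brain scores L_X = XV and behavior scores L_Y = YU express
how strongly each subject carries the pattern.

Inference is nonparametric:

* LV significance — permute subject rows of X (Y fixed), recompute the
  singular values, and compare rank-for-rank; p uses the add-one rule
  (1 + exceedances) / (1 + n_perm).
* Weight reliability — paired bootstrap of subjects in X and Y with
  within-replicate re-z-scoring; each voxel's bootstrap ratio (BSR) is its
  observed salience over the bootstrap standard error, with |BSR| >= 3.3
  (~ two-sided normal p < 0.001) marking stable voxels.
* Behavior relevance — the correlation of each behavior column with the
  brain score, with a percentile 95% bootstrap CI; a behavior counts as
  significant when the CI excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PLSModel",
    "PermutationResult",
    "BootstrapResult",
    "BehaviorLoadings",
    "residualize",
    "zscore_columns",
    "pls_fit",
    "permutation_test",
    "bootstrap_reliability",
    "threshold_bsr",
    "behavior_loadings",
    "combined_seed_matrix",
    "combined_seed_model",
    "cosine_similarity",
]

BSR_DEFAULT_THRESHOLD = 3.3


def residualize(data, confounds):
    """Replace each column of ``data`` by its OLS residual on the confounds.

    An intercept is always included, so residual columns are mean-zero and
    orthogonal to every confound column.
    """
    data = np.asarray(data, dtype=np.float64)
    squeeze = data.ndim == 1
    if squeeze:
        data = data[:, None]
    confounds = np.asarray(confounds, dtype=np.float64)
    if confounds.ndim == 1:
        confounds = confounds[:, None]
    n = data.shape[0]
    if confounds.shape[0] != n:
        raise ValueError("confound rows do not match data rows")
    design = np.column_stack([np.ones(n), confounds])
    if design.shape[1] >= n:
        raise ValueError("more confounds than subjects")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("confound design is rank deficient")
    beta, *_ = np.linalg.lstsq(design, data, rcond=None)
    resid = data - design @ beta
    return resid[:, 0] if squeeze else resid


def zscore_columns(matrix, names=None):
    """Column-wise z-scoring with the n-1 (sample) standard deviation.

    Raises on constant columns, naming the offender when ``names`` given.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2:
        raise ValueError("expected a 2D matrix")
    sd = matrix.std(axis=0, ddof=1)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        label = names[constant[0]] if names is not None else f"column {constant[0]}"
        raise ValueError(f"constant column cannot be z-scored: {label}")
    return (matrix - matrix.mean(axis=0)) / sd


def _is_zscored(matrix, tol=1e-8):
    return (np.abs(matrix.mean(axis=0)).max() < tol
            and np.abs(matrix.std(axis=0, ddof=1) - 1).max() < tol)


@dataclass
class PLSModel:
    """Fitted latent structure of the cross-covariance SVD."""

    U: np.ndarray                   # (B, L) behavior saliences
    V: np.ndarray                   # (M, L) voxel saliences
    S: np.ndarray                   # (L,) singular values, descending
    Lx: np.ndarray                  # (N, L) brain scores XV
    Ly: np.ndarray                  # (N, L) behavior scores YU
    explained_covariance: np.ndarray  # s_l^2 / sum s^2
    behavior_names: list | None = None
    feature_seed: np.ndarray | None = None  # seed of origin per feature (combined model)
    X: np.ndarray = field(default=None, repr=False)  # z-scored inputs kept for resampling
    Y: np.ndarray = field(default=None, repr=False)

    @property
    def n_lv(self):
        return self.S.size


def _svd_fit(Xz, Yz):
    R = Xz.T @ Yz
    V, S, Ut = np.linalg.svd(R, full_matrices=False)
    return V, S, Ut.T  # voxel saliences, singular values, behavior saliences


def _orient(U, V):
    """Deterministic sign convention: largest-|U| behavior weight positive."""
    for l in range(U.shape[1]):
        j = int(np.argmax(np.abs(U[:, l])))
        if U[j, l] < 0:
            U[:, l] *= -1
            V[:, l] *= -1
    return U, V


def pls_fit(X, Y, behavior_names=None, zscore=True) -> PLSModel:
    """Fit the PLS correlation model.

    Inputs are z-scored column-wise unless ``zscore=False`` (in which case
    they must already be z-scored).  The number of LVs is min(M, B) — the
    rank bound of R — each oriented so its largest-magnitude behavior
    weight is positive.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of subjects")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ValueError("non-finite entries in X or Y")
    Xz = zscore_columns(X) if zscore else X
    Yz = zscore_columns(Y, behavior_names) if zscore else Y
    if not zscore and not (_is_zscored(Xz) and _is_zscored(Yz)):
        raise ValueError("inputs must be z-scored when zscore=False")
    V, S, U = _svd_fit(Xz, Yz)
    U, V = _orient(U, V)
    total = (S**2).sum()
    explained = S**2 / total if total > 0 else np.zeros_like(S)
    return PLSModel(U=U, V=V, S=S, Lx=Xz @ V, Ly=Yz @ U,
                    explained_covariance=explained,
                    behavior_names=list(behavior_names) if behavior_names is not None else None,
                    X=Xz, Y=Yz)


@dataclass
class PermutationResult:
    p_values: np.ndarray       # per LV
    null_singular: np.ndarray  # (n_perm, L)
    n_perm: int
    seed: int | None

    def significant(self, alpha=0.05):
        return self.p_values < alpha


def permutation_test(model: PLSModel, n_perm=1000, seed=None) -> PermutationResult:
    """Permutation p value per LV from row-shuffled X against fixed Y.

    Row permutation leaves column means/sds untouched, so no re-z-scoring
    is needed.  Null singular values are compared rank-for-rank and
    p_l = (1 + #{s_perm >= s_obs}) / (1 + n_perm), never exactly zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    Xz, Yz, s_obs = model.X, model.Y, model.S
    n = Xz.shape[0]
    null = np.empty((n_perm, s_obs.size))
    for i in range(n_perm):
        perm = rng.permutation(n)
        null[i] = np.linalg.svd(Xz[perm].T @ Yz, compute_uv=False)[: s_obs.size]
    exceed = (null >= s_obs[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + n_perm)
    return PermutationResult(p_values=p, null_singular=null, n_perm=n_perm, seed=seed)


@dataclass
class BootstrapResult:
    bsr: np.ndarray            # (M, L) observed weight / bootstrap SE
    v_se: np.ndarray           # (M, L)
    u_se: np.ndarray           # (B, L)
    loadings_boot: np.ndarray  # (n_boot, B, L) behavior-score correlations
    n_boot: int
    n_redrawn: int
    seed: int | None


def bootstrap_reliability(model: PLSModel, n_boot=1000, seed=None,
                          max_redraw_fraction=0.2) -> BootstrapResult:
    """Paired subject-level bootstrap of the salience weights.

    Subjects are resampled with replacement jointly in X and Y, each
    replicate is re-z-scored and refit, and every replicate LV is aligned
    to the observed orientation by the sign of its dot product with the
    observed voxel salience.  Replicates that produce a constant column
    are redrawn and counted; more than ``max_redraw_fraction`` of n_boot
    redraws aborts with a diagnostic.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    Xz, Yz = model.X, model.Y
    n, L = Xz.shape[0], model.n_lv
    v_boot = np.empty((n_boot, Xz.shape[1], L))
    u_boot = np.empty((n_boot, Yz.shape[1], L))
    loadings = np.empty((n_boot, Yz.shape[1], L))
    n_redrawn = 0
    max_redraws = int(np.ceil(max_redraw_fraction * n_boot))
    i = 0
    while i < n_boot:
        idx = rng.integers(0, n, n)
        Xb, Yb = Xz[idx], Yz[idx]
        # inputs are z-scored (unit sd), so a tiny std marks a resample
        # that collapsed a column to a constant up to rounding
        if (Xb.std(axis=0) < 1e-10).any() or (Yb.std(axis=0) < 1e-10).any():
            n_redrawn += 1
            if n_redrawn > max_redraws:
                raise RuntimeError(
                    f"more than {max_redraw_fraction:.0%} of bootstrap replicates "
                    "were degenerate (constant column after resampling)")
            continue
        Xb = zscore_columns(Xb)
        Yb = zscore_columns(Yb)
        Vb, Sb, Ub = _svd_fit(Xb, Yb)
        Vb, Ub = Vb[:, :L], Ub[:, :L]
        signs = np.sign(np.einsum("ml,ml->l", Vb, model.V))
        signs[signs == 0] = 1.0
        Vb *= signs[None, :]
        Ub *= signs[None, :]
        v_boot[i], u_boot[i] = Vb, Ub
        Lxb = Xb @ Vb
        loadings[i] = _columnwise_correlation(Yb, Lxb)
        i += 1
    v_se = v_boot.std(axis=0, ddof=1)
    u_se = u_boot.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        bsr = model.V / v_se
    bsr[~np.isfinite(bsr)] = 0.0
    return BootstrapResult(bsr=bsr, v_se=v_se, u_se=u_se, loadings_boot=loadings,
                           n_boot=n_boot, n_redrawn=n_redrawn, seed=seed)


def _columnwise_correlation(Y, Lx):
    """corr(Y[:, b], Lx[:, l]) for all b, l -> (B, L)."""
    Yc = Y - Y.mean(axis=0)
    Lc = Lx - Lx.mean(axis=0)
    denom = np.outer(np.sqrt((Yc**2).sum(axis=0)), np.sqrt((Lc**2).sum(axis=0)))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Yc.T @ Lc) / denom
    corr[~np.isfinite(corr)] = 0.0
    return corr


def threshold_bsr(bsr, threshold=BSR_DEFAULT_THRESHOLD):
    """Two-sided salience mask: |BSR| >= threshold (boundary retained)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return np.abs(np.asarray(bsr)) >= threshold


def bsr_tail_probability(threshold=BSR_DEFAULT_THRESHOLD):
    """Two-sided standard-normal tail probability of a BSR threshold.

    Bootstrap ratios behave like z scores, so the conventional +/-3.3
    cutoff corresponds to a two-sided p just under 0.001.
    """
    from scipy.stats import norm

    return float(2.0 * norm.sf(threshold))


@dataclass
class BehaviorLoadings:
    behavior_names: list
    correlation: np.ndarray  # observed corr(Y_b, brain score)
    ci_low: np.ndarray
    ci_high: np.ndarray
    significant: np.ndarray  # CI excludes zero
    lv: int


def behavior_loadings(model: PLSModel, boot: BootstrapResult, lv=0,
                      ci=0.95) -> BehaviorLoadings:
    """Observed behavior-score correlations with percentile bootstrap CIs.

    A behavior is flagged significant when its CI does not cross zero.
    """
    if not 0 <= lv < model.n_lv:
        raise ValueError(f"LV index {lv} out of range (model has {model.n_lv})")
    obs = _columnwise_correlation(model.Y, model.Lx)[:, lv]
    tail = (1.0 - ci) / 2.0
    lo = np.quantile(boot.loadings_boot[:, :, lv], tail, axis=0)
    hi = np.quantile(boot.loadings_boot[:, :, lv], 1.0 - tail, axis=0)
    significant = (lo > 0) | (hi < 0)
    names = model.behavior_names or [f"behavior_{b}" for b in range(obs.size)]
    return BehaviorLoadings(behavior_names=list(names), correlation=obs,
                            ci_low=lo, ci_high=hi, significant=significant, lv=lv)


def combined_seed_matrix(per_seed_matrices):
    """Concatenate per-seed brain matrices feature-wise.

    ``per_seed_matrices`` maps seed name -> (N, M_seed) matrix; all must
    share subjects.  Returns ``(X, feature_seed)`` with the seed of origin
    recorded per feature column.
    """
    names = list(per_seed_matrices)
    if not names:
        raise ValueError("no seed matrices supplied")
    n = np.asarray(per_seed_matrices[names[0]]).shape[0]
    blocks, owner = [], []
    for name in names:
        m = np.asarray(per_seed_matrices[name], dtype=np.float64)
        if m.shape[0] != n:
            raise ValueError(f"subject count mismatch for seed {name}")
        blocks.append(m)
        owner.extend([name] * m.shape[1])
    return np.hstack(blocks), np.asarray(owner)


def combined_seed_model(per_seed_matrices, Y, behavior_names=None,
                        zscore=True) -> PLSModel:
    """One PLS model over the feature-wise concatenation of several seeds."""
    X, owner = combined_seed_matrix(per_seed_matrices)
    model = pls_fit(X, Y, behavior_names=behavior_names, zscore=zscore)
    model.feature_seed = owner
    return model


def cosine_similarity(a, b):
    """|cos| is the standard recovery measure for salience vectors."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.nan
    return float(a @ b / (na * nb))
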