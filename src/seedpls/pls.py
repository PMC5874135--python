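"""Grouped seed-PLS core: covariance stack, SVD, permutation and bootstrap.

The analysis relates a per-participant network seed value Y (average seed
gray-matter volume) to the whole-brain voxel matrix X, with participants
partitioned into ordered age groups.  Both X and Y are centered and scaled to
unit Euclidean norm *within* each age group, so that the stacked per-group
cross-products

    Z[g, :] = Yn_g' @ Xn_g

are exactly the within-group Pearson correlations of the seed value with every
voxel.  A singular value decomposition

    Z = U diag(s) V'

yields one latent variable (LV) per age group: a group salience profile
(column of U), a voxelwise spatial salience pattern (column of V) and a
singular value whose squared share of the total is the percent covariance
explained.  LV significance is assessed by permuting Y across participants
(5,000 permutations by default); voxel salience reliability by stratified
bootstrap resampling within age groups (1,000 by default), summarised as
bootstrap ratios (salience / bootstrap SE) thresholded like z-scores.
Brain scores L = X V project each participant's raw voxel data onto the
spatial saliences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .errors import AgeOutOfRangeError, DegenerateVarianceError

#: Age-group bins (inclusive integer ranges, years) used throughout.
DEFAULT_AGE_BINS = ((6, 15), (16, 25), (26, 35), (36, 59), (60, 75), (76, 94))

_NORM_TOL = 1e-12


@dataclass(frozen=True)
class AgeGroupScheme:
    """Ordered, non-overlapping, contiguous integer age bins."""

    bins: tuple[tuple[int, int], ...] = DEFAULT_AGE_BINS

    def __post_init__(self):
        if not self.bins:
            raise ValueError("scheme needs at least one bin")
        for lo, hi in self.bins:
            if hi < lo:
                raise ValueError(f"bin ({lo}, {hi}) is empty")
        for (lo0, hi0), (lo1, _) in zip(self.bins, self.bins[1:]):
            if lo1 != hi0 + 1:
                raise ValueError(
                    f"bins must be ascending and contiguous; ({lo0},{hi0}) is "
                    f"followed by a bin starting at {lo1}"
                )

    @property
    def n_groups(self) -> int:
        return len(self.bins)

    @property
    def age_min(self) -> int:
        return self.bins[0][0]

    @property
    def age_max(self) -> int:
        return self.bins[-1][1]

    def midpoints(self) -> np.ndarray:
        return np.array([(lo + hi) / 2.0 for lo, hi in self.bins])

    def labels(self) -> list[str]:
        return [f"{lo}-{hi}" for lo, hi in self.bins]


def assign_groups(ages, scheme: AgeGroupScheme | None = None) -> np.ndarray:
    """Map each age (years) to the index of the bin containing floor(age).

    Ages whose integer part falls outside the scheme raise
    :class:`AgeOutOfRangeError`.
    """
    scheme = scheme or AgeGroupScheme()
    ages = np.asarray(ages, dtype=float)
    floors = np.floor(ages)
    if np.any(floors < scheme.age_min) or np.any(floors > scheme.age_max):
        bad = ages[(floors < scheme.age_min) | (floors > scheme.age_max)]
        raise AgeOutOfRangeError(
            f"ages {np.unique(bad)} outside scheme coverage "
            f"[{scheme.age_min}, {scheme.age_max}]"
        )
    edges = np.array([hi for _, hi in scheme.bins], dtype=float)
    return np.searchsorted(edges, floors, side="left").astype(int)


def _group_indices(groups: np.ndarray) -> list[np.ndarray]:
    """Index arrays per group, ordered by group label."""
    groups = np.asarray(groups)
    labels = np.unique(groups)
    return [np.flatnonzero(groups == g) for g in labels]


def group_normalize(X, Y, groups):
    """Center and scale X columns and Y to unit norm within each age group.

    After normalization every voxel column and the seed vector have mean 0 and
    unit Euclidean norm inside each group block, so per-group cross-products
    are Pearson correlations.  Zero within-group variance in any voxel column
    or in Y raises :class:`DegenerateVarianceError` naming the offender.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    Xn = np.empty_like(X)
    Yn = np.empty_like(Y)
    for g, idx in enumerate(_group_indices(groups)):
        if idx.size < 3:
            raise DegenerateVarianceError(
                f"group {g} has {idx.size} members; need at least 3", group=g
            )
        xg = X[idx] - X[idx].mean(axis=0)
        norms = np.linalg.norm(xg, axis=0)
        zero = np.flatnonzero(norms <= _NORM_TOL)
        if zero.size:
            raise DegenerateVarianceError(
                f"voxel column(s) {zero[:5].tolist()} have zero variance in group {g}",
                group=g,
                column=int(zero[0]),
            )
        Xn[idx] = xg / norms
        yg = Y[idx] - Y[idx].mean()
        ynorm = np.linalg.norm(yg)
        if ynorm <= _NORM_TOL:
            raise DegenerateVarianceError(
                f"seed vector has zero variance in group {g}", group=g, column=None
            )
        Yn[idx] = yg / ynorm
    return Xn, Yn


def covariance_stack(Xn, Yn, groups) -> np.ndarray:
    """Stack per-group cross-products Z[g] = Yn_g' Xn_g (G x V).

    With group-normalized inputs each entry is the within-group Pearson
    correlation of the seed value with one voxel, bounded by 1 in magnitude.
    """
    Xn = np.asarray(Xn, dtype=float)
    Yn = np.asarray(Yn, dtype=float)
    if Xn.shape[0] != Yn.shape[0]:
        raise ValueError(f"X has {Xn.shape[0]} rows but Y has {Yn.shape[0]}")
    idx_groups = _group_indices(groups)
    Z = np.empty((len(idx_groups), Xn.shape[1]))
    for g, idx in enumerate(idx_groups):
        Z[g] = Yn[idx] @ Xn[idx]
    return Z


@dataclass
class LatentVariableSet:
    """Singular triplets of the covariance stack plus inference annotations.

    Columns of ``u`` (G x G) are group salience profiles, columns of ``v``
    (V x G) spatial salience patterns; ``singular_values`` are nonincreasing.
    ``cov_explained`` holds each LV's percent of the total squared singular
    value mass and sums to 100.  ``p_perm``, ``bootstrap_ratios``,
    ``threshold_masks`` and ``selected`` are filled by the inference steps.
    """

    u: np.ndarray
    singular_values: np.ndarray
    v: np.ndarray
    cov_explained: np.ndarray
    p_perm: np.ndarray | None = None
    bootstrap_ratios: np.ndarray | None = None
    threshold_masks: np.ndarray | None = None
    selected: np.ndarray | None = None

    @property
    def n_lvs(self) -> int:
        return self.singular_values.size


def _fix_signs(u: np.ndarray, v: np.ndarray):
    """Deterministic sign convention: largest-|entry| of each U column positive."""
    for j in range(u.shape[1]):
        i = int(np.argmax(np.abs(u[:, j])))
        if u[i, j] < 0:
            u[:, j] = -u[:, j]
            v[:, j] = -v[:, j]
    return u, v


def decompose(Z: np.ndarray) -> LatentVariableSet:
    """SVD of the covariance stack into G latent variables.

    Applies the sign convention (largest-magnitude group salience positive per
    LV) so results are reproducible across linear-algebra backends.
    """
    Z = np.asarray(Z, dtype=float)
    if not np.all(np.isfinite(Z)):
        raise ValueError("covariance stack contains non-finite entries")
    u, s, vt = linalg.svd(Z, full_matrices=False)
    v = vt.T
    u, v = _fix_signs(u, v)
    total = float(np.sum(s**2))
    cov_explained = (
        100.0 * s**2 / total if total > 0 else np.full_like(s, 100.0 / s.size)
    )
    return LatentVariableSet(
        u=u, singular_values=s, v=v, cov_explained=cov_explained
    )


def _renormalize_rows(Yp: np.ndarray, idx_groups) -> np.ndarray:
    """Center/normalize each row of a (n_perm x N) matrix within groups.

    Returns per-row group norms so callers can detect degenerate draws.
    """
    min_norms = np.full(Yp.shape[0], np.inf)
    for idx in idx_groups:
        block = Yp[:, idx]
        block = block - block.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(block, axis=1)
        ok = norms > _NORM_TOL
        block[ok] = block[ok] / norms[ok, None]
        Yp[:, idx] = block
        min_norms = np.minimum(min_norms, norms)
    return min_norms


def permutation_test(
    X,
    Y,
    groups,
    n_perm: int = 5000,
    rng: np.random.Generator | None = None,
    chunk: int = 250,
):
    """Permutation p-values for each LV's singular value.

    Y is permuted across *all* participants (group labels stay with the rows
    of X), renormalized within groups, and the singular values of the permuted
    covariance stack recomputed; the p-value of LV i is
    ``(#{s_perm_i >= s_obs_i} + 1) / (n_perm + 1)``.  Permutations that leave
    a group with zero seed variance are redrawn and counted.

    Returns
    -------
    p : ndarray, (G,)
    n_redrawn : int
        Number of degenerate permutations that were redrawn.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    rng = rng if rng is not None else np.random.default_rng()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    idx_groups = _group_indices(groups)
    G = len(idx_groups)
    Xn, Yn = group_normalize(X, Y, groups)
    s_obs = linalg.svdvals(covariance_stack(Xn, Yn, groups))

    exceed = np.zeros(G, dtype=int)
    n_redrawn = 0
    n_done = 0
    while n_done < n_perm:
        m = min(chunk, n_perm - n_done)
        Yp = np.empty((m, Y.size))
        for r in range(m):
            Yp[r] = Y[rng.permutation(Y.size)]
        min_norms = _renormalize_rows(Yp, idx_groups)
        # redraw rows whose within-group variance degenerated
        bad = np.flatnonzero(min_norms <= _NORM_TOL)
        guard = 0
        while bad.size:
            n_redrawn += bad.size
            sub = np.empty((bad.size, Y.size))
            for r in range(bad.size):
                sub[r] = Y[rng.permutation(Y.size)]
            min_norms_bad = _renormalize_rows(sub, idx_groups)
            Yp[bad] = sub
            bad = bad[min_norms_bad <= _NORM_TOL]
            guard += 1
            if guard > 1000:
                raise DegenerateVarianceError(
                    "could not draw a non-degenerate permutation after 1000 tries"
                )
        # batched singular values via the G x G Gram matrix of each permuted Z
        C = [Yp[:, idx] @ Xn[idx] for idx in idx_groups]  # each (m, V)
        gram = np.empty((m, G, G))
        for a in range(G):
            for b in range(a, G):
                dots = np.einsum("pv,pv->p", C[a], C[b])
                gram[:, a, b] = dots
                gram[:, b, a] = dots
        eigs = np.linalg.eigvalsh(gram)  # ascending
        s_perm = np.sqrt(np.clip(eigs[:, ::-1], 0.0, None))
        exceed += np.sum(s_perm >= s_obs[None, :], axis=0)
        n_done += m

    p = (exceed + 1.0) / (n_perm + 1.0)
    return p, n_redrawn


def select_lvs(p, cov_explained, p_threshold: float = 0.001, min_cov: float = 5.0):
    """Flag LVs that are significant (p < 0.001) and explain >= 5% covariance."""
    p = np.asarray(p, dtype=float)
    cov = np.asarray(cov_explained, dtype=float)
    if p.shape != cov.shape:
        raise ValueError("p and cov_explained must have equal length")
    return (p < p_threshold) & (cov >= min_cov)


def brain_scores(X_raw, v: np.ndarray) -> np.ndarray:
    """Brain scores L = X V from the *raw* (non-normalized) voxel matrix."""
    X_raw = np.asarray(X_raw, dtype=float)
    v = np.asarray(v, dtype=float)
    if X_raw.shape[1] != v.shape[0]:
        raise ValueError(
            f"X has {X_raw.shape[1]} voxels but V has {v.shape[0]} rows"
        )
    return X_raw @ v


def _procrustes_rotation(u_boot: np.ndarray, u_ref: np.ndarray) -> np.ndarray:
    """Orthogonal (rotation+reflection) alignment of a resample's U to the original."""
    w, _, qt = linalg.svd(u_boot.T @ u_ref)
    return w @ qt


def _group_corr(L: np.ndarray, Y: np.ndarray, idx_groups) -> np.ndarray:
    """Pearson r of each LV's scores with Y, per group: (G_groups, n_lv)."""
    out = np.empty((len(idx_groups), L.shape[1]))
    for g, idx in enumerate(idx_groups):
        lg = L[idx] - L[idx].mean(axis=0)
        yg = Y[idx] - Y[idx].mean()
        ln = np.linalg.norm(lg, axis=0)
        yn = np.linalg.norm(yg)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (yg @ lg) / (ln * yn)
        out[g] = np.where((ln > _NORM_TOL) & (yn > _NORM_TOL), r, 0.0)
    return np.clip(out, -1.0, 1.0)


@dataclass
class BootstrapResult:
    """Bootstrap reliability summaries for one analysis.

    ``bsr`` holds per-LV voxel bootstrap ratios (original salience divided by
    its bootstrap SE; exact zeros in the SE produce signed-infinity sentinels,
    counted in ``n_zero_se``).  ``r_obs`` are the observed per-group
    brain-score/seed correlations, with percentile CIs over the stratified
    resamples and a reliability flag that is False when the CI spans zero.
    """

    bsr: np.ndarray                 # (V, n_lv)
    salience_se: np.ndarray         # (V, n_lv)
    r_obs: np.ndarray               # (G_groups, n_lv)
    r_ci_low: np.ndarray
    r_ci_high: np.ndarray
    reliable: np.ndarray            # bool, (G_groups, n_lv)
    r_resamples: np.ndarray = field(repr=False)  # (n_boot, G_groups, n_lv)
    n_zero_se: int = 0
    n_redrawn: int = 0


def bootstrap_saliences(
    X,
    Y,
    groups,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    lvset: LatentVariableSet | None = None,
    ci_level: float = 0.95,
) -> BootstrapResult:
    """Stratified bootstrap of voxel saliences and group correlations.

    Participants are resampled with replacement *within* each age group
    (preserving group sizes, so the within-group normalization stays
    defined).  Each resample's SVD is aligned to the original by orthogonal
    Procrustes on U before accumulating salience statistics; bootstrap ratios
    are the original saliences divided by the resampling SE.  Resamples that
    collapse a group's seed variance are redrawn and counted.
    """
    if n_boot < 1:
        raise ValueError(f"n_boot must be >= 1, got {n_boot}")
    rng = rng if rng is not None else np.random.default_rng()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    groups = np.asarray(groups)
    idx_groups = _group_indices(groups)

    if lvset is None:
        Xn, Yn = group_normalize(X, Y, groups)
        lvset = decompose(covariance_stack(Xn, Yn, groups))
    n_lv = lvset.n_lvs

    L_obs = brain_scores(X, lvset.v)
    r_obs = _group_corr(L_obs, Y, idx_groups)

    v_sum = np.zeros_like(lvset.v)
    v_sumsq = np.zeros_like(lvset.v)
    r_resamples = np.empty((n_boot, len(idx_groups), n_lv))
    n_redrawn = 0

    for b in range(n_boot):
        for _attempt in range(1000):
            take = np.concatenate([rng.choice(idx, size=idx.size) for idx in idx_groups])
            Yb = Y[take]
            ok = True
            for idx_new in _group_indices(groups[take]):
                if np.ptp(Yb[idx_new]) <= _NORM_TOL:
                    ok = False
                    break
            if ok:
                break
            n_redrawn += 1
        else:
            raise DegenerateVarianceError(
                "could not draw a non-degenerate bootstrap resample"
            )
        Xb = X[take]
        gb = groups[take]
        try:
            Xnb, Ynb = group_normalize(Xb, Yb, gb)
        except DegenerateVarianceError:
            # a voxel went constant in a resample: fall back to observed values
            # for that column by jittering the norm floor
            Xb = Xb + 0.0
            Xnb, Ynb = _group_normalize_safe(Xb, Yb, gb)
        Zb = covariance_stack(Xnb, Ynb, gb)
        ub, sb, vtb = linalg.svd(Zb, full_matrices=False)
        vb = vtb.T
        rot = _procrustes_rotation(ub, lvset.u)
        vb = vb @ rot
        ub = ub @ rot
        v_sum += vb
        v_sumsq += vb**2
        Lb = Xb @ vb
        r_resamples[b] = _group_corr(Lb, Yb, _group_indices(gb))

    var = v_sumsq / n_boot - (v_sum / n_boot) ** 2
    # ddof-1 correction; clip tiny negatives from cancellation
    var = np.clip(var * n_boot / max(n_boot - 1, 1), 0.0, None)
    se = np.sqrt(var)
    zero_se = se <= 0.0
    n_zero_se = int(zero_se.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        bsr = lvset.v / se
    if n_zero_se:
        sign = np.sign(lvset.v)
        bsr = np.where(zero_se, np.where(sign == 0, 0.0, sign * np.inf), bsr)

    alpha = (1.0 - ci_level) / 2.0
    r_ci_low = np.quantile(r_resamples, alpha, axis=0)
    r_ci_high = np.quantile(r_resamples, 1.0 - alpha, axis=0)
    reliable = ~((r_ci_low <= 0.0) & (r_ci_high >= 0.0))

    return BootstrapResult(
        bsr=bsr,
        salience_se=se,
        r_obs=r_obs,
        r_ci_low=r_ci_low,
        r_ci_high=r_ci_high,
        reliable=reliable,
        r_resamples=r_resamples,
        n_zero_se=n_zero_se,
        n_redrawn=n_redrawn,
    )


def _group_normalize_safe(X, Y, groups):
    """group_normalize variant that tolerates constant voxel columns.

    Used only inside bootstrap resamples, where a voxel that is non-degenerate
    in the observed data can become constant by resampling; its normalized
    column is set to zero (contributing zero correlation) instead of aborting
    the resample.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    Xn = np.empty_like(X)
    Yn = np.empty_like(Y)
    for g, idx in enumerate(_group_indices(groups)):
        xg = X[idx] - X[idx].mean(axis=0)
        norms = np.linalg.norm(xg, axis=0)
        safe = np.where(norms > _NORM_TOL, norms, 1.0)
        Xn[idx] = np.where(norms > _NORM_TOL, xg / safe, 0.0)
        yg = Y[idx] - Y[idx].mean()
        ynorm = np.linalg.norm(yg)
        if ynorm <= _NORM_TOL:
            raise DegenerateVarianceError(
                f"seed vector has zero variance in group {g}", group=g
            )
        Yn[idx] = yg / ynorm
    return Xn, Yn


def threshold_pattern(bsr, level: float = 0.95) -> np.ndarray:
    """Binary voxel mask of saliences whose |BSR| clears the two-tailed cutoff.

    Bootstrap ratios behave like z-scores, so a 95% confidence threshold keeps
    voxels with |BSR| >= 1.96 (the (1+level)/2 normal quantile).
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    cutoff = stats.norm.ppf((1.0 + level) / 2.0)
    return np.abs(np.asarray(bsr, dtype=float)) >= cutoff


@dataclass
class GroupCorrelations:
    """Per-group brain-score/seed correlations with bootstrap CIs."""

    r: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    reliable: np.ndarray


def group_correlations(
    L,
    Y,
    groups,
    r_resamples: np.ndarray | None = None,
    ci_level: float = 0.95,
) -> GroupCorrelations:
    """Correlate brain scores with the seed vector within each age group.

    When bootstrap resample correlations are supplied (from
    :func:`bootstrap_saliences`), percentile CIs are attached and a group is
    flagged unreliable when its CI spans zero; without resamples the CIs are
    NaN and every group is conservatively flagged unreliable.
    """
    L = np.asarray(L, dtype=float)
    Y = np.asarray(Y, dtype=float)
    idx_groups = _group_indices(groups)
    for g, idx in enumerate(idx_groups):
        if idx.size < 3:
            raise ValueError(f"group {g} has {idx.size} members; need at least 3")
    r = _group_corr(L if L.ndim == 2 else L[:, None], Y, idx_groups)
    if r_resamples is None:
        nan = np.full_like(r, np.nan)
        return GroupCorrelations(
            r=r, ci_low=nan, ci_high=nan.copy(),
            reliable=np.zeros(r.shape, dtype=bool),
        )
    alpha = (1.0 - ci_level) / 2.0
    lo = np.quantile(r_resamples, alpha, axis=0)
    hi = np.quantile(r_resamples, 1.0 - alpha, axis=0)
    return GroupCorrelations(
        r=r, ci_low=lo, ci_high=hi, reliable=~((lo <= 0.0) & (hi >= 0.0))
    )
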