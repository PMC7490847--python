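"""Group statistics: fatigue classification, covariate-adjusted models,
and voxel-wise permutation testing with threshold-free cluster enhancement.

The group analyses mirror a standard clinical neuroimaging workflow:
left/right ROI means enter a repeated-measures ANCOVA with a
within-subject factor *side*, a between-subject factor *group*, and
age/sex (plus whole-brain streamline count for connectivity measures) as
covariates; associations between continuous measures use partial Pearson
correlations; voxel-wise maps are compared with two-sample permutation
tests corrected for family-wise error through max-TFCE.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla, ndimage, special, stats as sps

from .phantom import ValidationError

__all__ = [
    "SubjectRecord",
    "TfceParams",
    "PermutationResult",
    "classify_fatigue",
    "group_ancova",
    "adjusted_correlation",
    "tfce_transform",
    "permutation_test",
    "slice_group_test",
]

FSMC_MOTOR_MIN, FSMC_MOTOR_MAX = 10, 50
FSMC_MOTOR_CUTOFF = 27


@dataclass
class SubjectRecord:
    """Covariates and outcome summaries for one (synthetic) subject."""

    subject_id: str
    group: str  # HC / FMS / NFMS
    fsmc_motor: int
    fsmc_cognitive: int
    fsmc_total: int
    bdi: float
    edss: float
    age: float
    sex: str  # F / M
    total_acm: float = float("nan")
    roi_summary: dict | None = None
    lesion_volume_left: float = 0.0
    lesion_volume_right: float = 0.0

    def validate(self) -> None:
        if not (FSMC_MOTOR_MIN <= self.fsmc_motor <= FSMC_MOTOR_MAX):
            raise ValidationError("fsmc_motor outside the instrument range")
        if self.group in ("FMS", "NFMS") and self.group != classify_fatigue(self.fsmc_motor):
            raise ValidationError(
                f"group {self.group} inconsistent with fsmc_motor={self.fsmc_motor}"
            )


def classify_fatigue(fsmc_motor: float) -> str:
    """Motor-fatigue classification: scores at or above 27 are fatigued."""
    if not (FSMC_MOTOR_MIN <= fsmc_motor <= FSMC_MOTOR_MAX):
        raise ValidationError(
            f"fsmc_motor={fsmc_motor} outside instrument range "
            f"[{FSMC_MOTOR_MIN}, {FSMC_MOTOR_MAX}]"
        )
    return "FMS" if fsmc_motor >= FSMC_MOTOR_CUTOFF else "NFMS"


# ---------------------------------------------------------------------------
# Linear models
# ---------------------------------------------------------------------------

def _design(df: pd.DataFrame, covariates: Sequence[str], with_group: bool, group: str):
    """Design matrix with intercept, optional group dummies, and centred
    covariates; returns (matrix, column names)."""
    cols = [np.ones(len(df))]
    names = ["intercept"]
    if with_group:
        levels = sorted(df[group].unique())
        for level in levels[1:]:
            cols.append((df[group] == level).to_numpy(dtype=float))
            names.append(f"{group}[{level}]")
    for cov in covariates:
        v = df[cov]
        if v.dtype == object or isinstance(v.dtype, pd.CategoricalDtype):
            codes = pd.Categorical(v).codes.astype(float)
            x = codes
        else:
            x = v.to_numpy(dtype=float)
        cols.append(x - x.mean())
        names.append(cov)
    return np.column_stack(cols), names


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r, piv = sla.qr(X, pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        aliased = [names[piv[i]] for i in range(X.shape[1]) if i >= rank or diag[i] <= tol]
        raise ValidationError(f"collinear design; aliased columns: {sorted(set(aliased))}")


def _f_test_nested(y: np.ndarray, X_full: np.ndarray, drop: Sequence[int]):
    """F test comparing the full OLS model against one without ``drop`` columns."""
    n, p = X_full.shape
    X_red = np.delete(X_full, drop, axis=1)
    rss_full = _rss(y, X_full)
    rss_red = _rss(y, X_red)
    df1 = len(drop)
    df2 = n - p
    if df2 <= 0:
        raise ValidationError("not enough observations for the model")
    if rss_full <= 0:
        return 0.0, 1.0
    f = ((rss_red - rss_full) / df1) / (rss_full / df2)
    f = max(f, 0.0)
    p_val = float(sps.f.sf(f, df1, df2))
    return float(f), p_val


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def group_ancova(
    table: pd.DataFrame,
    left: str,
    right: str,
    group: str = "group",
    covariates: Sequence[str] = ("age", "sex", "total_acm"),
    alpha: float = 0.05,
) -> dict:
    """Repeated-measures ANCOVA with within-subject factor side (left/right).

    With exactly two within-subject levels the model decomposes exactly
    into two univariate ANCOVAs: between-subject effects act on the
    per-subject mean ``(left + right) / 2`` and the side main effect and
    side-by-group interaction act on the difference ``left - right``
    (covariates centred, so the intercept of the difference model is the
    side effect at covariate means).  Pairwise post-hoc F tests are run
    only when the corresponding omnibus F is significant at ``alpha``.
    """
    df = table.reset_index(drop=True)
    groups = sorted(df[group].unique())
    if len(groups) < 2:
        raise ValidationError("group_ancova needs at least two groups")
    counts = df[group].value_counts()
    if counts.min() < 2:
        raise ValidationError("every group needs n >= 2")

    y_mean = (df[left].to_numpy(float) + df[right].to_numpy(float)) / 2.0
    y_diff = df[left].to_numpy(float) - df[right].to_numpy(float)

    X, names = _design(df, covariates, with_group=True, group=group)
    _check_full_rank(X, names)
    group_cols = [i for i, nm in enumerate(names) if nm.startswith(f"{group}[")]

    def _effects(frame, ym, yd):
        Xg, nmg = _design(frame, covariates, with_group=True, group=group)
        gcols = [i for i, nm in enumerate(nmg) if nm.startswith(f"{group}[")]
        f_group, p_group = _f_test_nested(ym, Xg, gcols)
        f_int, p_int = _f_test_nested(yd, Xg, gcols)
        f_side, p_side = _f_test_nested(yd, Xg, [0])  # intercept = side effect
        return {
            "group": {"F": f_group, "p": p_group},
            "side": {"F": f_side, "p": p_side},
            "side_by_group": {"F": f_int, "p": p_int},
        }

    result = _effects(df, y_mean, y_diff)

    posthoc: dict = {"group": {}, "side_by_group": {}}
    for effect, y_all in (("group", y_mean), ("side_by_group", y_diff)):
        if result[effect]["p"] < alpha:
            for a, b in itertools.combinations(groups, 2):
                sub = df[df[group].isin([a, b])].reset_index(drop=True)
                y_sub = (
                    (sub[left].to_numpy(float) + sub[right].to_numpy(float)) / 2.0
                    if effect == "group"
                    else sub[left].to_numpy(float) - sub[right].to_numpy(float)
                )
                Xs, nms = _design(sub, covariates, with_group=True, group=group)
                gcols = [i for i, nm in enumerate(nms) if nm.startswith(f"{group}[")]
                f, p = _f_test_nested(y_sub, Xs, gcols)
                posthoc[effect][(a, b)] = {"F": f, "p": p}
    result["posthoc"] = posthoc
    return result


@dataclass
class AdjustedCorrelation:
    r: float
    p: float
    df: int
    n: int


def adjusted_correlation(x, y, covariates=None) -> AdjustedCorrelation:
    """Partial Pearson correlation after residualizing on covariates.

    Both variables are regressed on the covariates (with intercept); the
    residuals are correlated and the p value comes from the t transform
    with ``df = n - n_covariates - 2``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if covariates is None:
        Z = np.ones((n, 1))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        Z = np.column_stack([np.ones(n), cov])
    k = Z.shape[1] - 1
    if n <= k + 2:
        raise ValidationError(f"need n > n_covariates + 2 (n={n}, covariates={k})")

    bx, *_ = np.linalg.lstsq(Z, x, rcond=None)
    by, *_ = np.linalg.lstsq(Z, y, rcond=None)
    rx = x - Z @ bx
    ry = y - Z @ by
    sx = float(rx @ rx)
    sy = float(ry @ ry)
    if sx == 0 or sy == 0:
        raise ValidationError("zero-variance residuals; correlation undefined")
    r = float((rx @ ry) / math.sqrt(sx * sy))
    r = max(-1.0, min(1.0, r))
    df = n - k - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return AdjustedCorrelation(r=r, p=p, df=df, n=n)


# ---------------------------------------------------------------------------
# TFCE and permutation testing
# ---------------------------------------------------------------------------

_CONNECTIVITY_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class TfceParams:
    """Threshold-free cluster enhancement parameters.

    ``height_exponent`` (H) and ``extent_exponent`` (E) default to the de
    facto standard 2 and 0.5; ``dh = None`` resolves to 1/100 of the
    statistic map's positive maximum.
    """

    height_exponent: float = 2.0
    extent_exponent: float = 0.5
    dh: float | None = None
    connectivity: int = 26
    n_permutations: int = 5000
    alpha: float = 0.05
    rng_seed: int = 0

    def validate(self) -> None:
        if not (self.height_exponent > 0 and self.extent_exponent > 0):
            raise ValidationError("TFCE exponents must be positive")
        if self.dh is not None and not (self.dh > 0):
            raise ValidationError("dh must be positive")
        if self.connectivity not in _CONNECTIVITY_STRUCTURES:
            raise ValidationError("connectivity must be one of 6, 18, 26")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")


def tfce_transform(stat_map: np.ndarray, params: TfceParams | None = None) -> np.ndarray:
    """TFCE(v) = sum over thresholds h = dh, 2dh, ... <= stat(v) of
    e(h, v)^E * h^H * dh, where e(h, v) is the voxel count of the connected
    component containing v in the supra-threshold image {stat >= h}.
    Voxels with stat <= 0 map to 0.
    """
    params = params or TfceParams()
    params.validate()
    stat = np.asarray(stat_map, dtype=float)
    if not np.all(np.isfinite(stat)):
        raise ValidationError("stat map must be finite")
    out = np.zeros_like(stat)
    peak = stat.max()
    if peak <= 0:
        return out
    dh = params.dh if params.dh is not None else peak / 100.0
    structure = _CONNECTIVITY_STRUCTURES[params.connectivity]
    h = dh
    while h <= peak + 1e-12:
        supra = stat >= h
        labels, n_comp = ndimage.label(supra, structure=structure)
        if n_comp == 0:
            break
        sizes = np.bincount(labels.reshape(-1))
        out[supra] += (
            sizes[labels[supra]] ** params.extent_exponent
            * h**params.height_exponent
            * dh
        )
        h += dh
    return out


@dataclass
class PermutationResult:
    stat_map: np.ndarray
    tfce_map: np.ndarray
    null_max: np.ndarray
    fwe_p: np.ndarray
    n_permutations_used: int
    exhaustive: bool
    params: TfceParams


def _two_sample_t(data: np.ndarray, in_group1: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t (group1 - group2) per voxel."""
    n1 = int(in_group1.sum())
    n2 = data.shape[0] - n1
    g1 = data[in_group1]
    g2 = data[~in_group1]
    m1 = g1.mean(axis=0)
    m2 = g2.mean(axis=0)
    ss1 = ((g1 - m1) ** 2).sum(axis=0)
    ss2 = ((g2 - m2) ** 2).sum(axis=0)
    sp2 = (ss1 + ss2) / (n1 + n2 - 2)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / denom
    return np.where(denom > 0, t, 0.0)


def permutation_test(
    maps: np.ndarray,
    labels: Sequence,
    params: TfceParams | None = None,
) -> PermutationResult:
    """Two-sample permutation test on subject maps with max-TFCE FWE control.

    The observed voxel-wise t map (first label level minus second, positive
    contrast) is TFCE-enhanced; the null distribution records the maximum
    TFCE value under ``n_permutations`` random relabelings (or every
    distinct relabeling when fewer exist).  ``fwe_p(v) = (1 + #{null max >=
    TFCE_obs(v)}) / (1 + n_used)`` is never zero.
    """
    params = params or TfceParams()
    params.validate()
    maps = np.asarray(maps, dtype=float)
    labels = np.asarray(labels)
    levels = pd.unique(labels)
    if len(levels) != 2:
        raise ValidationError("permutation_test requires exactly two groups")
    in_g1 = labels == levels[0]
    n1, n2 = int(in_g1.sum()), int((~in_g1).sum())
    if min(n1, n2) < 2:
        raise ValidationError("each group needs n >= 2")

    vol_shape = maps.shape[1:]
    flat = maps.reshape(maps.shape[0], -1)

    t_obs = _two_sample_t(flat, in_g1)
    dh_eff = params.dh
    if dh_eff is None:
        peak = float(t_obs.max())
        dh_eff = peak / 100.0 if peak > 0 else 1.0
    eff_params = TfceParams(
        height_exponent=params.height_exponent,
        extent_exponent=params.extent_exponent,
        dh=dh_eff,
        connectivity=params.connectivity,
        n_permutations=params.n_permutations,
        alpha=params.alpha,
        rng_seed=params.rng_seed,
    )
    tfce_obs = tfce_transform(t_obs.reshape(vol_shape), eff_params).reshape(-1)

    n_subjects = maps.shape[0]
    n_distinct = int(special.comb(n_subjects, n1, exact=True))
    exhaustive = n_distinct <= params.n_permutations
    null_max = []
    if exhaustive:
        for combo in itertools.combinations(range(n_subjects), n1):
            perm = np.zeros(n_subjects, dtype=bool)
            perm[list(combo)] = True
            t_perm = _two_sample_t(flat, perm)
            null_max.append(tfce_transform(t_perm.reshape(vol_shape), eff_params).max())
        n_used = n_distinct
    else:
        rng = np.random.default_rng(params.rng_seed)
        for _ in range(params.n_permutations):
            perm = np.zeros(n_subjects, dtype=bool)
            perm[rng.choice(n_subjects, size=n1, replace=False)] = True
            t_perm = _two_sample_t(flat, perm)
            null_max.append(tfce_transform(t_perm.reshape(vol_shape), eff_params).max())
        n_used = params.n_permutations
    null_max = np.asarray(null_max)

    sorted_null = np.sort(null_max)
    n_ge = n_used - np.searchsorted(sorted_null, tfce_obs, side="left")
    fwe_p = (1.0 + n_ge) / (1.0 + n_used)

    return PermutationResult(
        stat_map=t_obs.reshape(vol_shape),
        tfce_map=tfce_obs.reshape(vol_shape),
        null_max=null_max,
        fwe_p=fwe_p.reshape(vol_shape),
        n_permutations_used=n_used,
        exhaustive=exhaustive,
        params=eff_params,
    )


def slice_group_test(
    profiles: np.ndarray,
    groups: Sequence,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-slice two-sample t tests on lateralization profiles.

    ``profiles`` is (n_subjects, n_slices) with NaN marking undefined
    slices.  Slices lacking two subjects per group or carrying zero
    variance are skipped with a warning.  P values are uncorrected.
    """
    profiles = np.asarray(profiles, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValidationError("slice_group_test requires exactly two groups")

    rows = []
    for z in range(profiles.shape[1]):
        col = profiles[:, z]
        a = col[(groups == levels[0]) & np.isfinite(col)]
        b = col[(groups == levels[1]) & np.isfinite(col)]
        if len(a) < 2 or len(b) < 2:
            continue
        if np.var(a) == 0 and np.var(b) == 0:
            warnings.warn(f"slice {z}: degenerate variance, skipped", stacklevel=2)
            continue
        t, p = sps.ttest_ind(a, b)
        rows.append(
            {
                "slice": z,
                "n1": len(a),
                "n2": len(b),
                "t": float(t),
                "p": float(p),
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows, columns=["slice", "n1", "n2", "t", "p", "significant"])
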