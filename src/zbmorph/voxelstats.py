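"""Voxelwise and regional group statistics.

Voxelwise operations run vectorised over whole map stacks and reproduce
their scalar per-voxel equivalents exactly.  Conventions follow common
neuroimaging practice: two-sided independent-samples t-tests (pooled
variance by default, Welch optional), an additive two-way ANOVA for
combining crispant experiments (main effects of genotype and batch, no
interaction), and a one-way ANOVA with unadjusted pairwise post hoc
t-tests for the three-condition rescue design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from zbmorph.io import ScalarMap

__all__ = [
    "StatMap",
    "GroupVolumeResult",
    "voxel_ttest",
    "voxel_anova2",
    "neglog10_pmap",
    "group_volume_test",
    "three_group_anova",
]


@dataclass
class StatMap:
    """Per-voxel statistic and p-value maps plus test metadata."""

    statistic: np.ndarray
    pvalue: np.ndarray
    df: tuple
    test: str
    spacing: tuple[float, float, float]
    flagged: np.ndarray | None = None  # zero-variance / degenerate voxels

    def statistic_map(self) -> ScalarMap:
        return ScalarMap(self.statistic, self.spacing)

    def pvalue_map(self) -> ScalarMap:
        return ScalarMap(self.pvalue, self.spacing)


def _stack(maps) -> tuple[np.ndarray, tuple]:
    arrs = [m.data if isinstance(m, ScalarMap) else np.asarray(m) for m in maps]
    shape = arrs[0].shape
    spacing = maps[0].spacing if isinstance(maps[0], ScalarMap) else (1.0, 1.0, 1.0)
    for a in arrs[1:]:
        if a.shape != shape:
            raise ValueError(f"maps must share a grid; got {a.shape} vs {shape}")
    return np.stack(arrs), spacing


def voxel_ttest(maps_a, maps_b, equal_var: bool = True) -> StatMap:
    """Two-sided independent-samples t-test at every voxel.

    Voxels with zero variance in both groups get t = 0, p = 1 and are
    flagged.  NaN voxels (outside the brain) propagate as NaN.
    """
    A, spacing = _stack(maps_a)
    B, _ = _stack(maps_b)
    if B.shape[1:] != A.shape[1:]:
        raise ValueError("the two groups must share a grid")
    na, nb = A.shape[0], B.shape[0]
    if na < 2 or nb < 2:
        raise ValueError(f"need >= 2 subjects per group, got {na} and {nb}")

    ma, mb = A.mean(axis=0), B.mean(axis=0)
    va, vb = A.var(axis=0, ddof=1), B.var(axis=0, ddof=1)
    if equal_var:
        df = float(na + nb - 2)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se2 = sp2 * (1.0 / na + 1.0 / nb)
        dfmap = np.full(ma.shape, df)
    else:
        se2 = va / na + vb / nb
        with np.errstate(divide="ignore", invalid="ignore"):
            dfmap = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        df = float(np.nanmedian(dfmap))
    zero = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        p = 2.0 * stats.t.sf(np.abs(t), dfmap)
    diff_zero = zero & np.isfinite(ma - mb)
    t = np.where(diff_zero, 0.0, t)
    p = np.where(diff_zero, 1.0, p)
    return StatMap(t, p, (df,), "ttest_ind" + ("" if equal_var else "_welch"),
                   spacing, flagged=zero)


def voxel_anova2(maps, genotype, batch, interaction: bool = False) -> StatMap:
    """Additive two-way ANOVA (genotype + batch) at every voxel.

    Returns the genotype main-effect F and p as the primary maps; the
    batch main effect is attached to the result as ``batch_F``,
    ``batch_p`` and ``batch_df``.

    The genotype test compares the full additive model against the model
    without genotype (Type II sums of squares); likewise for batch.  An
    optional interaction term extends the full model.  Empty design cells
    raise an error naming the cell.
    """
    Y, spacing = _stack(maps)
    genotype = np.asarray(genotype)
    batch = np.asarray(batch)
    n = Y.shape[0]
    if genotype.shape != (n,) or batch.shape != (n,):
        raise ValueError("genotype/batch labels must match the number of maps")
    glev = np.unique(genotype)
    blev = np.unique(batch)
    if len(glev) < 2 or len(blev) < 2:
        raise ValueError("need >= 2 genotypes and >= 2 batches")
    for g in glev:
        for b in blev:
            if not np.any((genotype == g) & (batch == b)):
                raise ValueError(f"empty design cell: genotype={g!r}, batch={b!r}")

    def dummies(labels, levels):
        return np.column_stack([(labels == l).astype(float) for l in levels[1:]])

    Xg = dummies(genotype, glev)
    Xb = dummies(batch, blev)
    cols = [np.ones((n, 1)), Xg, Xb]
    if interaction:
        inter = np.column_stack([
            Xg[:, i] * Xb[:, j] for i in range(Xg.shape[1]) for j in range(Xb.shape[1])
        ])
        cols.append(inter)
    X_full = np.hstack(cols)
    Yf = Y.reshape(n, -1)

    def sse(X):
        beta, *_ = np.linalg.lstsq(X, Yf, rcond=None)
        resid = Yf - X @ beta
        return (resid**2).sum(axis=0), X.shape[1]

    sse_full, p_full = sse(X_full)
    df_resid = n - p_full

    def effect(drop_block):
        keep = [c for i, c in enumerate(cols) if i != drop_block]
        sse_red, p_red = sse(np.hstack(keep))
        df_eff = p_full - p_red
        with np.errstate(divide="ignore", invalid="ignore"):
            F = ((sse_red - sse_full) / df_eff) / (sse_full / df_resid)
        p = stats.f.sf(F, df_eff, df_resid)
        zero = sse_full == 0
        F = np.where(zero & (sse_red - sse_full == 0), 0.0, F)
        p = np.where(zero & (np.nan_to_num(sse_red - sse_full) == 0), 1.0, p)
        return F.reshape(Y.shape[1:]), p.reshape(Y.shape[1:]), df_eff

    Fg, pg, dfg = effect(1)
    Fb, pb, dfb = effect(2)
    out = StatMap(Fg, pg, (dfg, df_resid), "anova2_genotype", spacing,
                  flagged=(sse_full == 0).reshape(Y.shape[1:]))
    out.batch_F = Fb
    out.batch_p = pb
    out.batch_df = (dfb, df_resid)
    return out


def neglog10_pmap(stat_map: StatMap) -> ScalarMap:
    """−log10(p) display map; NaN (non-brain) voxels preserved."""
    with np.errstate(divide="ignore"):
        data = -np.log10(stat_map.pvalue)
    return ScalarMap(data, stat_map.spacing)


@dataclass
class GroupVolumeResult:
    """Group comparison of regional volumes (percent of total brain)."""

    group_means: dict
    mean_difference: float | None
    ci_low: float | None
    ci_high: float | None
    statistic: float
    df: tuple
    pvalue: float
    posthoc: dict = field(default_factory=dict)
    test: str = "ttest_ind"


def group_volume_test(volumes_a, volumes_b, n_boot: int = 5000,
                      seed: int = 0, equal_var: bool = True,
                      labels: tuple[str, str] = ("A", "B")) -> GroupVolumeResult:
    """Two-sided independent t-test plus a seeded 5000-resample
    percentile-bootstrap 95% CI of the mean difference mean(A) − mean(B)."""
    a = np.asarray(volumes_a, dtype=float)
    b = np.asarray(volumes_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 observations per group")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    if not np.isfinite(p):  # identical constant groups
        t, p = 0.0, 1.0
    df = a.size + b.size - 2 if equal_var else None
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = (rng.choice(a, a.size).mean() - rng.choice(b, b.size).mean())
    lo, hi = np.percentile(boots, [2.5, 97.5])
    diff = float(a.mean() - b.mean())
    # percentile CI may exclude the point estimate only by resampling noise
    return GroupVolumeResult(
        {labels[0]: float(a.mean()), labels[1]: float(b.mean())},
        diff, float(lo), float(hi), float(t), (df,), float(p),
    )


def three_group_anova(volumes_by_group: dict, seed: int = 0) -> GroupVolumeResult:
    """One-way ANOVA over >= 3 conditions with unadjusted pairwise
    two-sided post hoc t-tests.

    For the rescue design the groups are control, single crispant and
    double crispant; df = (k−1, N−k).
    """
    names = list(volumes_by_group)
    if len(names) < 3:
        raise ValueError(f"need >= 3 groups, got {len(names)}")
    groups = [np.asarray(volumes_by_group[g], dtype=float) for g in names]
    for g, arr in zip(names, groups):
        if arr.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    F, p = stats.f_oneway(*groups)
    if not np.isfinite(F):  # all groups constant and equal
        F, p = 0.0, 1.0
    k = len(groups)
    N = sum(a.size for a in groups)
    posthoc = {}
    for i in range(k):
        for j in range(i + 1, k):
            t, pp = stats.ttest_ind(groups[i], groups[j])
            if not np.isfinite(pp):
                t, pp = 0.0, 1.0
            posthoc[(names[i], names[j])] = dict(t=float(t), p=float(pp))
    return GroupVolumeResult(
        {g: float(a.mean()) for g, a in zip(names, groups)},
        None, None, None, float(F), (k - 1, N - k), float(p),
        posthoc=posthoc, test="anova1",
    )
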