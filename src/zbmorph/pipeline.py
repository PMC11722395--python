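"""End-to-end orchestration of the synthetic study.

Reproduces the logic of the crispant screen on generated data:

1. discovery cohort → voxelwise LJD t-test → filtered bilateral mask;
2. independent validation cohort → per-subject mask volume (% of brain)
   → two-group t-test and crispant/control volume ratio;
3. three-condition rescue cohort (control / single / double crispant)
   → one-way ANOVA with post hoc pairwise tests;
4. paired DE tables → expression filter → BH FDR → sign-concordant
   overlap → Fisher convergence p;
5. synthetic traces → wildtype fractions → crispant inclusion calls.

Each step is also usable on real inputs through the module APIs; this
file only wires them together and scores results against generator truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from zbmorph import mapfilter, morphometry, synthetic, voxelstats
from zbmorph.io import LabelAtlas, RunConfig, ScalarMap
from zbmorph.mapfilter import RegionMask
from zbmorph.voxelstats import GroupVolumeResult

__all__ = [
    "dice",
    "ljd_maps",
    "truth_region_mask",
    "discovery_mask",
    "mask_volume_table",
    "validation_test",
    "rescue_test",
    "run_demo",
]


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 0 when both are empty."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 0.0
    return 2.0 * int((a & b).sum()) / denom


def _jacobian(sample) -> ScalarMap:
    if getattr(sample, "jacobian", None) is not None:
        return sample.jacobian
    return morphometry.jacobian_determinant(sample.field)


def ljd_maps(samples, min_jacobian: float = 0.05) -> list[ScalarMap]:
    """Log-Jacobian map per cohort subject."""
    return [morphometry.log_jacobian(_jacobian(s), min_jacobian) for s in samples]


def truth_region_mask(atlas: LabelAtlas, region: str) -> np.ndarray:
    names = {v: k for k, v in atlas.names.items()}
    labels = [names[n] for n in names
              if n == region or n in (region + "_L", region + "_R")]
    if not labels:
        raise ValueError(f"region {region!r} not in atlas")
    return np.isin(atlas.data, labels)


def discovery_mask(samples, atlas: LabelAtlas, config: RunConfig,
                   direction: str = "smaller") -> tuple[RegionMask, voxelstats.StatMap]:
    """Voxelwise crispant-vs-control t-test on LJD maps, then the full
    threshold/cluster/symmetry filter chain.  p outside the brain is NaN.

    The affected-region mask is directional by default: only voxels where
    crispants are locally *smaller* than controls (negative t for
    crispant − control) are eligible, since the phenotype mask marks the
    reduced region; pass ``direction="both"`` for a sign-blind mask or
    ``"larger"`` for local expansions.
    """
    maps = ljd_maps(samples, config.min_jacobian)
    ctl = [m for m, s in zip(maps, samples) if s.genotype == "control"]
    mut = [m for m, s in zip(maps, samples) if s.genotype != "control"]
    stat = voxelstats.voxel_ttest(mut, ctl)
    p = stat.pvalue.copy()
    p[~atlas.brain_mask()] = np.nan
    if direction == "smaller":
        p[stat.statistic >= 0] = np.nan
    elif direction == "larger":
        p[stat.statistic <= 0] = np.nan
    elif direction != "both":
        raise ValueError(f"direction must be smaller/larger/both, got {direction!r}")
    stat.pvalue = p
    # the second cluster pass removes the small fragments the symmetry
    # filter leaves behind when spatially correlated noise blobs happen to
    # have a partial mirror match
    mask = mapfilter.mask_from_pmap(
        p, atlas.spacing, alpha=config.alpha, min_cluster=config.min_cluster,
        connectivity=config.connectivity, midline_axis=0,
        sym_tol=config.sym_tol, recluster=True, allow_empty=True,
    )
    return mask, stat


def mask_volume_table(mask: np.ndarray, samples, atlas: LabelAtlas,
                      min_jacobian: float = 0.05) -> pd.DataFrame:
    """Per-subject volume of ``mask`` as percent of total brain volume."""
    rows = []
    for s in samples:
        J = _jacobian(s)
        pct = morphometry.mask_volume_pct(mask, atlas, J)
        rows.append(dict(subject=s.subject, genotype=s.genotype,
                         batch=s.batch, mask_pct=pct))
    return pd.DataFrame(rows)


def validation_test(mask: np.ndarray, samples, atlas: LabelAtlas,
                    config: RunConfig) -> tuple[GroupVolumeResult, float, pd.DataFrame]:
    """Replicate the mask phenotype in an independent cohort.

    Returns the two-group test on per-subject mask volume percentages, the
    crispant/control mean volume ratio, and the per-subject table.
    """
    tab = mask_volume_table(mask, samples, atlas, config.min_jacobian)
    ctl = tab.loc[tab.genotype == "control", "mask_pct"].to_numpy()
    mut = tab.loc[tab.genotype != "control", "mask_pct"].to_numpy()
    res = voxelstats.group_volume_test(mut, ctl, n_boot=config.bootstrap_resamples,
                                       seed=config.seed,
                                       labels=("crispant", "control"))
    ratio = float(mut.mean() / ctl.mean())
    return res, ratio, tab


def rescue_test(mask: np.ndarray, samples, atlas: LabelAtlas,
                config: RunConfig) -> tuple[GroupVolumeResult, pd.DataFrame]:
    """Three-condition ANOVA on mask volume with post hoc pairwise tests."""
    tab = mask_volume_table(mask, samples, atlas, config.min_jacobian)
    groups = {g: tab.loc[tab.genotype == g, "mask_pct"].to_numpy()
              for g in ("control", "crispant", "double")}
    res = voxelstats.three_group_anova(groups, seed=config.seed)
    return res, tab


@dataclass
class DemoReport:
    """Everything the end-to-end synthetic demo measures."""

    seed: int
    mask_n_voxels: int
    dice_vs_truth: float
    validation_p: float
    validation_ratio: float
    rescue_F: float
    rescue_df: tuple
    rescue_p: float
    rescue_posthoc: dict
    de_universe: int
    de_overlap: int
    de_concordant: int
    de_fisher_p: float
    included_crispants: int
    n_traces: int
    extras: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        d = {k: v for k, v in self.__dict__.items()
             if k not in ("rescue_posthoc", "extras")}
        return pd.DataFrame([d])


def run_demo(config: RunConfig | None = None,
             cohort_kwargs: dict | None = None,
             de_spec: synthetic.DEGenSpec | None = None) -> DemoReport:
    """Run the full synthetic study once under ``config.seed``."""
    config = config or RunConfig()
    atlas, image = synthetic.make_atlas()
    ck = dict(cohort_kwargs or {})
    base_seed = config.seed

    disc_spec = synthetic.CohortSpec(batches=("exp1",), seed=base_seed, **ck)
    disc, _ = synthetic.make_cohort(disc_spec, atlas, image)
    mask, _ = discovery_mask(disc, atlas, config)
    truth = truth_region_mask(atlas, disc_spec.atrophy_region)
    d = dice(mask.data, truth)

    val_spec = synthetic.CohortSpec(batches=("exp2",), seed=base_seed + 1, **ck)
    val, _ = synthetic.make_cohort(val_spec, atlas, image)
    mask_for_volumes = mask.data if mask.n_voxels else truth
    val_res, ratio, _ = validation_test(mask_for_volumes, val, atlas, config)

    resc_spec = synthetic.CohortSpec(
        group_sizes={"control": 16, "crispant": 14, "double": 12},
        batches=("exp3",), seed=base_seed + 2,
        **{k: v for k, v in ck.items() if k != "group_sizes"},
    )
    resc, _ = synthetic.make_cohort(resc_spec, atlas, image)
    resc_res, _ = rescue_test(mask_for_volumes, resc, atlas, config)

    de_spec = de_spec or synthetic.DEGenSpec(seed=base_seed + 3)
    ta, tb, _ = synthetic.make_de_tables(de_spec)
    from zbmorph import deg

    conv = deg.convergence(ta, tb, config.min_basemean, config.fdr_alpha)

    # fragment QC on a small injected-vs-control panel
    from zbmorph import fragqc

    rows = []
    fractions = [0.2, 0.35, 0.8, 1.0, 1.0]
    for i, f in enumerate(fractions):
        spec = synthetic.TraceGenSpec(wt_fraction=f, seed=base_seed + 10 + i)
        tr = synthetic.make_trace(spec)
        peaks = fragqc.detect_peaks(tr.size_bp, tr.signal, config.min_prominence)
        wt = fragqc.wildtype_fraction(peaks, spec.wt_size_bp, config.size_tolerance)
        rows.append(dict(subject=f"f{i}", guide="g1", wt_fraction=wt, truth=f))
    meas = pd.DataFrame(rows)
    rep = fragqc.guide_efficiency_report(meas[["subject", "guide", "wt_fraction"]])

    return DemoReport(
        seed=config.seed,
        mask_n_voxels=mask.n_voxels,
        dice_vs_truth=d,
        validation_p=val_res.pvalue,
        validation_ratio=ratio,
        rescue_F=resc_res.statistic,
        rescue_df=resc_res.df,
        rescue_p=resc_res.pvalue,
        rescue_posthoc=resc_res.posthoc,
        de_universe=conv.n_universe,
        de_overlap=conv.n_overlap,
        de_concordant=conv.n_concordant,
        de_fisher_p=conv.fisher_p,
        included_crispants=int(rep.per_subject["included"].sum()),
        n_traces=len(fractions),
        extras=dict(max_wt_error=float((meas.wt_fraction - meas.truth).abs().max())),
    )
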