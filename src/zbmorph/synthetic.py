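"""Synthetic ground-truth data for every pipeline stage.

Four generators, all pure functions of (spec, seed):

* a bilaterally symmetric labelled atlas brain with three intensity
  channels (pan-neuronal, glutamatergic-like, GABAergic-like),
* cohorts of smooth per-subject displacement fields with an implanted,
  volume-compensated contraction of a target division (the "atrophy"),
* paired negative-binomial count experiments with a known set of
  sign-concordant differentially expressed genes, summarised into
  DE result tables,
* capillary-electrophoresis-like traces as sums of Gaussian peaks with a
  known wildtype-peak area fraction.

The implanted atrophy is a radially symmetric contraction of the target
ellipsoid (uniform linear scale a = s^(1/3), so the Jacobian inside is
exactly s) blended back to the identity across a surrounding shell by a
monotone C¹ cubic radial profile.  The shell absorbs the lost volume
exactly — the transform maps the shell's outer ellipsoid onto itself — so
total brain volume is essentially unchanged, mimicking a localized
deficit with no overall brain-size phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter

from zbmorph.io import BrainImage, DisplacementField, LabelAtlas

__all__ = [
    "Division",
    "AtlasSpec",
    "CohortSpec",
    "DEGenSpec",
    "TraceGenSpec",
    "CohortSample",
    "FragmentTrace",
    "make_atlas",
    "make_displacement",
    "make_cohort",
    "make_de_tables",
    "de_table_from_counts",
    "make_trace",
    "mirror_labels",
]


# ---------------------------------------------------------------------------
# atlas


@dataclass(frozen=True)
class Division:
    """An ellipsoidal brain division: center and radii in voxel units."""

    name: str
    center: tuple[float, float, float]
    radii: tuple[float, float, float]


def _default_divisions() -> tuple[Division, ...]:
    # Midline divisions are centred on the mid-sagittal plane x=(nx-1)/2;
    # lateral divisions come in mirrored _L/_R twins.  Layout loosely
    # follows a dorsal larval brain: telencephalon, optic tecta, cerebellar
    # plate with lateral subregions, tegmentum, medulla.
    return (
        Division("Tel", (31.5, 14.0, 24.0), (13.0, 9.0, 10.0)),
        Division("TeO_L", (16.0, 34.0, 28.0), (11.0, 11.0, 10.0)),
        Division("TeO_R", (47.0, 34.0, 28.0), (11.0, 11.0, 10.0)),
        Division("CeP", (31.5, 52.0, 30.0), (13.0, 6.0, 6.0)),
        Division("LCeP_L", (10.0, 52.0, 22.0), (5.0, 4.0, 4.0)),
        Division("LCeP_R", (53.0, 52.0, 22.0), (5.0, 4.0, 4.0)),
        Division("Tg", (31.5, 60.0, 14.0), (11.0, 6.0, 6.0)),
        Division("Med", (31.5, 72.0, 20.0), (9.0, 6.0, 8.0)),
    )


_DEFAULT_INTENSITY: dict[str, tuple[float, float, float]] = {
    # (pan-neuronal, glutamatergic-like, GABAergic-like) channel means
    "Tel": (100.0, 60.0, 40.0),
    "TeO_L": (100.0, 80.0, 30.0),
    "TeO_R": (100.0, 80.0, 30.0),
    "CeP": (100.0, 70.0, 20.0),
    "LCeP_L": (100.0, 75.0, 15.0),
    "LCeP_R": (100.0, 75.0, 15.0),
    "Tg": (100.0, 40.0, 60.0),
    "Med": (100.0, 50.0, 50.0),
}


@dataclass(frozen=True)
class AtlasSpec:
    """Geometry of the synthetic labelled reference brain."""

    shape: tuple[int, int, int] = (64, 80, 48)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    divisions: tuple[Division, ...] = field(default_factory=_default_divisions)
    midline_axis: int = 0
    intensity_means: Mapping[str, tuple[float, float, float]] | None = None

    def __post_init__(self) -> None:
        if self.midline_axis not in (0, 1, 2):
            raise ValueError(f"midline_axis must be 0, 1 or 2, got {self.midline_axis}")
        mid = (self.shape[self.midline_axis] - 1) / 2.0
        by_name = {d.name: d for d in self.divisions}
        if len(by_name) != len(self.divisions):
            raise ValueError("division names must be unique")
        for d in self.divisions:
            c = d.center[self.midline_axis]
            if abs(c - mid) < 1e-9:
                continue
            twin = _twin_name(d.name)
            if twin is None or twin not in by_name:
                raise ValueError(
                    f"lateral division {d.name!r} has no mirrored twin (expected a _L/_R pair)"
                )
            t = by_name[twin]
            mirrored = list(d.center)
            mirrored[self.midline_axis] = 2 * mid - c
            if not (
                np.allclose(t.center, mirrored) and np.allclose(t.radii, d.radii)
            ):
                raise ValueError(f"divisions {d.name!r}/{twin!r} are not mirror twins")


def _twin_name(name: str) -> str | None:
    if name.endswith("_L"):
        return name[:-2] + "_R"
    if name.endswith("_R"):
        return name[:-2] + "_L"
    return None


def _elliptical_radius2(shape, center, radii) -> np.ndarray:
    """Squared normalized elliptical radius on the voxel grid."""
    axes = np.ogrid[tuple(slice(0, n) for n in shape)]
    r2 = np.zeros(shape)
    for ax, c, r in zip(axes, center, radii):
        r2 = r2 + ((ax - c) / r) ** 2
    return r2


def mirror_labels(atlas: LabelAtlas, midline_axis: int = 0) -> np.ndarray:
    """Mirror a label volume about the midline plane, swapping _L/_R twin
    labels so that a perfectly bilateral atlas maps onto itself exactly."""
    flipped = np.flip(atlas.data, axis=midline_axis).copy()
    by_name = {v: k for k, v in atlas.names.items()}
    out = flipped.copy()
    for label, name in atlas.names.items():
        twin = _twin_name(name)
        if twin is not None and twin in by_name:
            out[flipped == by_name[twin]] = label
    return out


def make_atlas(spec: AtlasSpec = AtlasSpec()) -> tuple[LabelAtlas, BrainImage]:
    """Build the labelled atlas and its 3-channel intensity image.

    The label volume is mirror-symmetric about the midline plane by
    construction.  Overlapping divisions raise an error naming the pair.
    """
    labels = np.zeros(spec.shape, dtype=np.int32)
    names: dict[int, str] = {}
    for k, div in enumerate(spec.divisions, start=1):
        inside = _elliptical_radius2(spec.shape, div.center, div.radii) <= 1.0
        clash = labels[inside]
        clash = clash[clash > 0]
        if clash.size:
            other = names[int(clash[0])]
            raise ValueError(f"divisions overlap: {other!r} and {div.name!r}")
        labels[inside] = k
        names[k] = div.name

    means = dict(_DEFAULT_INTENSITY if spec.intensity_means is None else spec.intensity_means)
    intensity = np.zeros(spec.shape + (3,), dtype=np.float64)
    for k, name in names.items():
        m = means.get(name, (100.0, 50.0, 50.0))
        intensity[labels == k] = np.asarray(m, dtype=np.float64)

    atlas = LabelAtlas(labels, spec.spacing, names=names,
                       divisions={d.name: d for d in spec.divisions})
    image = BrainImage(intensity, spec.spacing,
                       channel_names=("pan_neuronal", "glut", "gaba"))
    return atlas, image


# ---------------------------------------------------------------------------
# displacement fields and cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic imaging cohort.

    ``group_sizes`` gives subjects per genotype per batch.  Crispants get
    the implanted ``atrophy_scale`` (volume factor s ≤ 1) in the target
    region; double crispants get ``double_scale`` (1.0 models a rescue).
    The random warp emulates residual registration error: per-component
    Gaussian-smoothed white noise with kernel ``warp_sigma_um`` scaled to
    RMS amplitude ``warp_amplitude_um``.
    """

    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"control": 14, "crispant": 17}
    )
    batches: tuple[str, ...] = ("exp1",)
    warp_sigma_um: float = 12.0
    warp_amplitude_um: float = 0.5
    atrophy_region: str = "LCeP"
    atrophy_scale: float = 0.8
    double_scale: float = 1.0
    shell_factor: float = 2.0
    channel_noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.atrophy_scale <= 1) or not (0 < self.double_scale <= 1):
            raise ValueError("atrophy/double scale factors must be in (0, 1]")
        if self.warp_amplitude_um < 0 or self.warp_sigma_um <= 0:
            raise ValueError("warp amplitude must be >= 0 and sigma > 0")
        if self.shell_factor <= 1:
            raise ValueError("shell_factor must exceed 1")

    def scale_for(self, genotype: str) -> float:
        return {"control": 1.0, "crispant": self.atrophy_scale,
                "double": self.double_scale}[genotype]


@dataclass
class CohortSample:
    subject: str
    genotype: str
    batch: str
    scale: float
    seed: int
    field: DisplacementField
    channels: BrainImage
    jacobian: object | None = None  # ScalarMap computed during generation


def _atrophy_regions(atlas: LabelAtlas, region: str) -> list[Division]:
    divisions = atlas.divisions
    if region in divisions:
        return [divisions[region]]
    twins = [d for name, d in divisions.items()
             if name == region + "_L" or name == region + "_R"]
    if not twins:
        raise ValueError(f"atrophy region {region!r} not found in atlas divisions "
                         f"{sorted(divisions)}")
    return twins


def _contraction_field(atlas: LabelAtlas, div: Division, scale: float,
                       shell_factor: float) -> np.ndarray:
    """Analytic volume-compensated contraction of one ellipsoidal division.

    Inside the division (normalized elliptical radius r <= 1) the map is a
    uniform contraction about the centre with linear factor a = scale^(1/3),
    so det ∇T = scale exactly.  Across the shell 1 < r < R the mapped radius
    follows a cubic Hermite from (1 -> a, slope a) to (R -> R, slope 1), so
    the map is C¹, the shell's outer surface is fixed, and the volume lost
    inside is regained in the shell.
    """
    a = float(scale) ** (1.0 / 3.0)
    R = float(shell_factor)
    shape = atlas.shape
    spacing = np.asarray(atlas.spacing)
    center_phys = np.asarray(div.center) * spacing
    radii_phys = np.asarray(div.radii) * spacing

    coords = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)],
                         indexing="ij")
    delta = [c - cc for c, cc in zip(coords, center_phys)]
    r = np.sqrt(sum((d / rp) ** 2 for d, rp in zip(delta, radii_phys)))

    # mapped normalized radius phi(r); multiplier m = phi/r (m=a inside)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.clip((r - 1.0) / (R - 1.0), 0.0, 1.0)
        h = R - 1.0
        h00 = (1 + 2 * t) * (1 - t) ** 2
        h10 = t * (1 - t) ** 2
        h01 = t * t * (3 - 2 * t)
        h11 = t * t * (t - 1)
        phi = h00 * a + h10 * h * a + h01 * R + h11 * h
        m = np.where(r <= 1.0, a, np.where(r >= R, 1.0, phi / np.maximum(r, 1e-12)))
    u = np.stack([(m - 1.0) * d for d in delta], axis=-1)
    u[r >= R] = 0.0
    return u


def make_displacement(
    atlas: LabelAtlas,
    spec: CohortSpec,
    subject_seed: int,
    scale: float | None = None,
    max_retries: int = 5,
) -> DisplacementField:
    """One subject's reference→subject displacement field (µm).

    The field is the sum of a smooth random warp and, when ``scale`` < 1,
    the analytic contraction of the atrophy region.  The Jacobian is
    required to be strictly positive everywhere; on failure the random
    warp is regenerated with a perturbed seed, up to ``max_retries``.
    """
    from zbmorph.morphometry import jacobian_determinant

    if scale is None:
        scale = spec.atrophy_scale
    base = np.zeros(atlas.shape + (3,), dtype=np.float64)
    if scale < 1.0 and spec.atrophy_region.lower() != "none":
        cache = getattr(atlas, "_contraction_cache", None)
        if cache is None:
            cache = {}
            object.__setattr__(atlas, "_contraction_cache", cache)
        for div in _atrophy_regions(atlas, spec.atrophy_region):
            key = (div.name, float(scale), float(spec.shell_factor))
            if key not in cache:
                cache[key] = _contraction_field(atlas, div, scale, spec.shell_factor)
            base += cache[key]

    sigma_vox = [spec.warp_sigma_um / s for s in atlas.spacing]
    for attempt in range(max_retries):
        rng = np.random.default_rng(int(subject_seed) + attempt * 1_000_003)
        u = base.copy()
        if spec.warp_amplitude_um > 0:
            noise = rng.standard_normal((3,) + atlas.shape)
            for i in range(3):
                comp = gaussian_filter(noise[i], sigma_vox)
                rms = comp.std()
                if rms > 0:
                    comp *= spec.warp_amplitude_um / rms
                u[..., i] += comp
        fld = DisplacementField(u, atlas.spacing, subject=str(subject_seed))
        jmap = jacobian_determinant(fld)
        if jmap.data.min() > 0:
            fld.jacobian = jmap  # reusable by consumers; field data is authoritative
            return fld
    raise RuntimeError(
        f"could not generate a diffeomorphic field after {max_retries} retries "
        f"(seed {subject_seed}); reduce warp amplitude or increase smoothness"
    )


def make_cohort(
    spec: CohortSpec, atlas: LabelAtlas, image: BrainImage
) -> tuple[list[CohortSample], pd.DataFrame]:
    """Generate a full cohort of subjects plus a ground-truth table.

    Each subject gets an independent displacement field and noisy channel
    images; the truth table records genotype, batch, seed and the implanted
    volume scale.  Group sizes below 2 are rejected (group tests undefined).
    """
    for g, n in spec.group_sizes.items():
        if n < 2:
            raise ValueError(f"group {g!r} has n={n}; at least 2 subjects required")

    ss = np.random.SeedSequence(spec.seed)
    samples: list[CohortSample] = []
    rows = []
    idx = 0
    for batch in spec.batches:
        for genotype, n in spec.group_sizes.items():
            scale = spec.scale_for(genotype)
            for _ in range(n):
                child = ss.spawn(1)[0]
                subj_seed = int(child.generate_state(1, np.uint32)[0]) % (2**31)
                subject = f"s{idx:03d}"
                fld = make_displacement(atlas, spec, subj_seed, scale=scale)
                rng = np.random.default_rng(subj_seed ^ 0x5EED)
                chan = image.data + rng.normal(
                    0.0, spec.channel_noise_sd, size=image.data.shape
                )
                samples.append(
                    CohortSample(subject, genotype, batch, scale, subj_seed, fld,
                                 BrainImage(chan, atlas.spacing,
                                            channel_names=image.channel_names),
                                 jacobian=getattr(fld, "jacobian", None))
                )
                rows.append(
                    dict(subject=subject, genotype=genotype, batch=batch,
                         seed=subj_seed, scale=scale,
                         atrophy_region=spec.atrophy_region)
                )
                idx += 1
    return samples, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# differential-expression tables


@dataclass(frozen=True)
class DEGenSpec:
    """Two negative-binomial count "experiments" with shared true DE genes.

    Shared DE genes carry the same sign of effect in both experiments;
    each experiment additionally has its own unique DE genes.  Counts are
    NB with var = mu + dispersion * mu²; per-gene p-values come from a
    two-sided two-sample t-test on log2(count+1) — a deliberate simple
    stand-in for a full GLM fit, adequate because downstream stages only
    consume (baseMean, log2FC, p) tables.
    """

    n_genes: int = 5000
    n_shared_de: int = 40
    n_unique_de: tuple[int, int] = (60, 120)
    lfc_range: tuple[float, float] = (1.5, 3.0)
    mean_log_mu: float = 5.5     # lognormal location of NB means (~245 counts)
    mean_log_sigma: float = 1.2
    dispersion: float = 0.05
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError(f"dispersion must be > 0, got {self.dispersion}")
        if self.n_shared_de + sum(self.n_unique_de) > self.n_genes:
            raise ValueError("more DE genes requested than genes in the table")
        if self.replicates < 2:
            raise ValueError("at least 2 replicates per condition required")


def _nb_counts(rng, mu, dispersion, size):
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p, size=size)


def de_table_from_counts(genes, counts_ctl, counts_mut) -> pd.DataFrame:
    """Summarise a 2-condition count matrix into a DE result table.

    baseMean is the mean count over all samples; log2FoldChange and the
    two-sided t-test p-value are computed on log2(count + 1).  Genes with
    zero variance in both conditions get p = 1.
    """
    import warnings

    ctl = np.asarray(counts_ctl, dtype=float)
    mut = np.asarray(counts_mut, dtype=float)
    log_ctl = np.log2(ctl + 1.0)
    log_mut = np.log2(mut + 1.0)
    with warnings.catch_warnings():
        # near-identical replicates trigger a precision warning; those
        # genes are handled below by the zero-variance p=1 rule
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(log_mut, log_ctl, axis=1)
    p = np.where(np.isfinite(p), p, 1.0)  # zero variance in both groups
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {
            "gene": list(genes),
            "baseMean": np.hstack([ctl, mut]).mean(axis=1),
            "log2FoldChange": log_mut.mean(axis=1) - log_ctl.mean(axis=1),
            "pvalue": p,
        }
    )


def _de_experiment(rng, mu, lfc, replicates, dispersion):
    """Simulate one 2-condition experiment; return a DE result table."""
    n_genes = mu.size
    ctl = _nb_counts(rng, mu[:, None], dispersion, (n_genes, replicates))
    mut = _nb_counts(rng, (mu * 2.0 ** lfc)[:, None], dispersion,
                     (n_genes, replicates))
    return de_table_from_counts([f"g{i:05d}" for i in range(n_genes)], ctl, mut)


def make_de_tables(spec: DEGenSpec = DEGenSpec()):
    """Simulate the paired experiments; returns (tableA, tableB, truth).

    The truth table lists each true DE gene, its class (shared / unique to
    one experiment) and the sign of its implanted effect.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    mu = np.exp(rng.normal(spec.mean_log_mu, spec.mean_log_sigma, n))

    order = rng.permutation(n)
    ns, na, nb = spec.n_shared_de, *spec.n_unique_de
    shared = order[:ns]
    uniq_a = order[ns:ns + na]
    uniq_b = order[ns + na:ns + na + nb]

    def draw_lfc(size):
        mag = rng.uniform(*spec.lfc_range, size)
        sign = rng.choice([-1.0, 1.0], size)
        return mag * sign

    lfc_a = np.zeros(n)
    lfc_b = np.zeros(n)
    lfc_shared = draw_lfc(ns)
    lfc_a[shared] = lfc_shared      # same sign in both experiments
    lfc_b[shared] = lfc_shared
    lfc_a[uniq_a] = draw_lfc(na)
    lfc_b[uniq_b] = draw_lfc(nb)

    table_a = _de_experiment(rng, mu, lfc_a, spec.replicates, spec.dispersion)
    table_b = _de_experiment(rng, mu, lfc_b, spec.replicates, spec.dispersion)

    rows = []
    for idx_set, klass, lfc in ((shared, "shared", lfc_a),
                                (uniq_a, "unique_a", lfc_a),
                                (uniq_b, "unique_b", lfc_b)):
        for i in idx_set:
            rows.append(dict(gene=f"g{i:05d}", klass=klass,
                             true_lfc=lfc[i], sign=int(np.sign(lfc[i]))))
    truth = pd.DataFrame(rows, columns=["gene", "klass", "true_lfc", "sign"])
    return table_a, table_b, truth


# ---------------------------------------------------------------------------
# fragment-analysis traces


@dataclass(frozen=True)
class TraceGenSpec:
    """A synthetic electropherogram: Gaussian peaks on a noisy baseline.

    ``wt_fraction`` is the true fraction of total peak area at the
    wildtype product size; the remaining area is split over indel peaks at
    ``indel_offsets_bp`` according to ``indel_rel_areas`` (must sum to 1).
    """

    wt_size_bp: float = 250.0
    wt_fraction: float = 1.0
    indel_offsets_bp: tuple[float, ...] = (-10.0, -5.0, 4.0)
    indel_rel_areas: tuple[float, ...] = (0.4, 0.35, 0.25)
    peak_width_bp: float = 0.7
    noise_sd: float = 1.0
    total_area: float = 1000.0
    window_bp: float = 40.0
    step_bp: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.wt_fraction <= 1.0):
            raise ValueError(f"wt_fraction must be in [0, 1], got {self.wt_fraction}")
        if self.wt_size_bp <= 0 or self.peak_width_bp <= 0:
            raise ValueError("sizes and widths must be positive")
        if len(self.indel_offsets_bp) != len(self.indel_rel_areas):
            raise ValueError("indel offsets and relative areas must align")
        if self.indel_rel_areas and not np.isclose(sum(self.indel_rel_areas), 1.0):
            raise ValueError("indel relative areas must sum to 1")


@dataclass
class FragmentTrace:
    size_bp: np.ndarray
    signal: np.ndarray
    true_wt_fraction: float
    wt_size_bp: float
    overlap_warning: bool = False
    run_id: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"size_bp": self.size_bp, "signal": self.signal})


def make_trace(spec: TraceGenSpec = TraceGenSpec()) -> FragmentTrace:
    """Render the trace; peaks closer than one width set an overlap flag."""
    sizes: list[float] = []
    areas: list[float] = []
    if spec.wt_fraction > 0:
        sizes.append(spec.wt_size_bp)
        areas.append(spec.wt_fraction * spec.total_area)
    rest = (1.0 - spec.wt_fraction) * spec.total_area
    if rest > 0:
        for off, rel in zip(spec.indel_offsets_bp, spec.indel_rel_areas):
            if rel > 0:
                sizes.append(spec.wt_size_bp + off)
                areas.append(rel * rest)

    srt = np.sort(np.asarray(sizes))
    overlap = bool(srt.size > 1 and np.min(np.diff(srt)) < spec.peak_width_bp)

    x = np.arange(spec.wt_size_bp - spec.window_bp,
                  spec.wt_size_bp + spec.window_bp + spec.step_bp / 2,
                  spec.step_bp)
    y = np.zeros_like(x)
    for s, a in zip(sizes, areas):
        amp = a / (spec.peak_width_bp * np.sqrt(2 * np.pi))
        y += amp * np.exp(-0.5 * ((x - s) / spec.peak_width_bp) ** 2)
    rng = np.random.default_rng(spec.seed)
    y += rng.normal(0.0, spec.noise_sd, size=x.shape)
    return FragmentTrace(x, y, spec.wt_fraction, spec.wt_size_bp,
                         overlap_warning=overlap)
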