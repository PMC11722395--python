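"""Fragment-analysis quantification of CRISPR cutting efficiency.

A guide that cuts efficiently converts the single wildtype PCR-product
peak into a spread of indel product sizes; the fraction of total peak
area remaining at the wildtype size therefore measures (one minus) the
editing rate.  Subjects are included as crispants when at least one guide
reduced the wildtype peak below 50% of total product area.

Peak tables may come straight from the sequencer software or be detected
here from a raw (size, signal) trace.  Declared amplicon product sizes
exclude the universal fluorescent primer tags (18 bp forward + 7 bp
reverse), so the peak detected on the machine sits 25 bp above the
declared size; the offset is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "EfficiencyResult",
    "detect_peaks",
    "wildtype_fraction",
    "include_crispant",
    "guide_efficiency_report",
    "TAG_OFFSET_BP",
]

# forward tag TGTAAAACGACGGCCAGT (18 bp) + reverse tag GTGTCTT (7 bp)
TAG_OFFSET_BP = 25.0


def detect_peaks(size_bp, signal, min_prominence: float = 0.02,
                 noise_floor_sds: float = 5.0) -> pd.DataFrame:
    """Find peaks in a trace and integrate their areas.

    ``min_prominence`` is a fraction of the maximum signal; in addition a
    peak's height must clear ``noise_floor_sds`` × a robust estimate of
    the baseline noise (MAD of the first-differenced signal), so an
    all-noise trace yields an empty table.  The relative threshold is
    deliberately low — a guide that leaves only a minority wildtype
    product produces indel peaks a few percent of the dominant one, and
    those carry the quantification.  Peak area is the trapezoid integral
    between the signal minima separating adjacent peaks.
    """
    x = np.asarray(size_bp, dtype=float)
    y = np.asarray(signal, dtype=float)
    if x.size < 10:
        raise ValueError(f"trace too short: {x.size} samples")
    if np.any(np.diff(x) <= 0):
        raise ValueError("size_bp must be strictly increasing")
    if not np.all(np.isfinite(y)):
        raise ValueError("signal contains non-finite values")
    span = y.max() - y.min()
    if span == 0:
        return pd.DataFrame(columns=["size_bp", "height", "area"])
    # robust baseline noise: sd of successive differences / sqrt(2)
    noise_sd = np.median(np.abs(np.diff(y))) / (np.sqrt(2) * 0.6745)
    height_floor = noise_floor_sds * noise_sd
    idx, _ = find_peaks(y, prominence=min_prominence * y.max(),
                        height=height_floor if height_floor > 0 else None)
    if idx.size == 0:
        return pd.DataFrame(columns=["size_bp", "height", "area"])
    # integration boundaries: the signal minimum between adjacent peaks,
    # and the trace ends for the outermost peaks
    bounds = [0]
    for a, b in zip(idx[:-1], idx[1:]):
        bounds.append(int(a + np.argmin(y[a:b + 1])))
    bounds.append(y.size - 1)
    rows = []
    for i, peak in enumerate(idx):
        lo, hi = bounds[i], bounds[i + 1]
        area = float(np.trapezoid(y[lo:hi + 1], x[lo:hi + 1]))
        if area <= 0:
            continue
        rows.append(dict(size_bp=float(x[peak]), height=float(y[peak]), area=area))
    return pd.DataFrame(rows, columns=["size_bp", "height", "area"])


def wildtype_fraction(peaks: pd.DataFrame, expected_size_bp: float,
                      size_tolerance_bp: float = 2.0) -> float:
    """Fraction of total peak area at the wildtype product size.

    The wildtype peak is the one nearest ``expected_size_bp`` within
    ``size_tolerance_bp``; if none matches the fraction is 0 (the peak was
    extinguished).  ``expected_size_bp`` must already include any primer
    tag offset (see :data:`TAG_OFFSET_BP`).
    """
    if len(peaks) == 0:
        raise ValueError("empty peak table")
    if (peaks["area"] <= 0).any():
        raise ValueError("peak areas must be positive")
    dist = (peaks["size_bp"] - expected_size_bp).abs()
    total = float(peaks["area"].sum())
    if dist.min() > size_tolerance_bp:
        return 0.0
    return float(peaks.loc[dist.idxmin(), "area"]) / total


def include_crispant(fractions) -> bool:
    """Inclusion rule: keep a subject iff at least one guide reduced the
    wildtype peak to strictly less than 50% of total product."""
    fr = np.asarray(list(fractions), dtype=float)
    if fr.size == 0:
        raise ValueError("no wildtype fractions supplied")
    if np.any((fr < 0) | (fr > 1)):
        raise ValueError("wildtype fractions must lie in [0, 1]")
    return bool(fr.min() < 0.5)


@dataclass
class EfficiencyResult:
    per_measurement: pd.DataFrame   # subject, guide, wt_fraction
    per_guide: pd.DataFrame         # guide, mean/median wt_fraction
    per_subject: pd.DataFrame       # subject, included


def guide_efficiency_report(measurements: pd.DataFrame) -> EfficiencyResult:
    """Summarise a cohort of (subject, guide, wt_fraction) measurements.

    Emits per-guide mean/median wildtype fractions and per-subject
    inclusion flags under the <50% rule.
    """
    for c in ("subject", "guide", "wt_fraction"):
        if c not in measurements.columns:
            raise ValueError(f"measurements table missing column {c!r}")
    if len(measurements) == 0:
        raise ValueError("no measurements supplied")
    per_guide = (
        measurements.groupby("guide")["wt_fraction"]
        .agg(mean="mean", median="median", n="size")
        .reset_index()
    )
    per_subject = (
        measurements.groupby("subject")["wt_fraction"]
        .apply(lambda fr: include_crispant(fr.to_numpy()))
        .rename("included")
        .reset_index()
    )
    return EfficiencyResult(measurements.copy(), per_guide, per_subject)
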