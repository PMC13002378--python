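"""Per-unit firing statistics, population-burst detection, cell typing and the
associated statistical tests.

This module covers the "activity" half of the pipeline: firing rates per
condition, the 500-ms population-burst statistic (peaks >= 5 SD above the
mean of the summed raster), rate-change direction classification, K-means
separation of single units into putative pyramidal neurons (broad waveform,
lower rate) and putative interneurons (narrow waveform, higher rate), the
chi-square association between cell type and change direction, LFP band
power, and the normality-gated paired comparison used for every paired
endpoint.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats
from sklearn.cluster import KMeans

from .spike_io import LfpTrace, Raster, SpikeTrainSet

logger = logging.getLogger(__name__)

#: analysis bands (Hz); intervals are half-open [lo, hi) except the topmost
#: band, which is closed at its upper edge (gamma closed at 50 Hz)
FREQUENCY_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 10.0),
    "beta": (10.0, 25.0),
    "gamma": (25.0, 50.0),
}

CHANGE_DIRECTIONS = ("increase", "decrease", "unchanged")


# ---------------------------------------------------------------------------
# Firing rates


def unit_rates(sts: SpikeTrainSet,
               window_ms: tuple[float, float] | None = None) -> pd.Series:
    """Firing rate (Hz) per unit: spike count in the window / window length."""
    if window_ms is None:
        window_ms = (0.0, sts.duration_ms)
    t0, t1 = window_ms
    if t1 <= t0:
        raise ValueError("window must have positive length")
    if t0 < 0 or t1 > sts.duration_ms + 1e-9:
        raise ValueError("window outside the recording span")
    span_s = (t1 - t0) / 1000.0
    rates = {u.unit_id: np.count_nonzero(
        (u.timestamps_ms >= t0) & (u.timestamps_ms < t1)) / span_s
        for u in sts.units}
    return pd.Series(rates, name="rate_hz")


# ---------------------------------------------------------------------------
# Population bursts


@dataclass
class BurstResult:
    """Population-burst detection on the summed raster.

    ``popsum`` is the number of occupied 1-ms bins summed over units, per
    coarse (default 500 ms) bin; ``noise_rms`` is the RMS of the
    mean-subtracted popsum; events are local maxima whose height above the
    mean reaches ``k_sd * noise_rms``.  Event heights are stored as the excess
    above the mean.
    """

    bin_ms: float
    popsum: np.ndarray
    mean: float
    noise_rms: float
    threshold: float
    events: list[tuple[int, float]] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.events)

    def count_per_minute(self, duration_ms: float) -> float:
        return self.count / (duration_ms / 60000.0)

    @property
    def mean_height(self) -> float:
        """Mean event height above the popsum mean (0 when no events)."""
        if not self.events:
            return 0.0
        return float(np.mean([h for _b, h in self.events]))


def find_burst_events(popsum: np.ndarray, k_sd: float = 5.0,
                      bin_ms: float = 500.0) -> BurstResult:
    """Threshold a population-sum signal at ``mean + k_sd * RMS`` local maxima."""
    popsum = np.asarray(popsum, dtype=float)
    if popsum.size < 1:
        raise ValueError("population signal is empty")
    mean = float(popsum.mean())
    noise_rms = float(np.sqrt(np.mean((popsum - mean) ** 2)))
    threshold = k_sd * noise_rms
    events: list[tuple[int, float]] = []
    b = 0
    n = popsum.size
    while b < n:
        e = b + 1  # maximal plateau [b, e), credited to its first bin
        while e < n and popsum[e] == popsum[b]:
            e += 1
        left = popsum[b - 1] if b > 0 else -np.inf
        right = popsum[e] if e < n else -np.inf
        if popsum[b] > left and popsum[b] > right:
            height = popsum[b] - mean
            if noise_rms > 0 and height >= threshold:
                events.append((b, float(height)))
        b = e
    return BurstResult(bin_ms=bin_ms, popsum=popsum, mean=mean,
                       noise_rms=noise_rms, threshold=threshold, events=events)


def detect_bursts(raster: Raster, bin_ms: float = 500.0,
                  k_sd: float = 5.0) -> BurstResult:
    """Detect hypersynchrony events from a 1-ms raster.

    The raster is re-aggregated into ``bin_ms`` bins by summing occupied
    fine bins over all units, then peaks >= ``k_sd`` RMS above the mean of the
    resulting signal are counted.
    """
    factor = int(round(bin_ms / raster.bin_ms))
    if factor < 1 or raster.n_bins < factor:
        raise ValueError("recording shorter than one aggregation bin")
    n_coarse = raster.n_bins // factor
    occ = raster.occupancy[:, :n_coarse * factor]
    popsum = occ.reshape(occ.shape[0], n_coarse, factor).sum(axis=(0, 2)).astype(float)
    return find_burst_events(popsum, k_sd=k_sd, bin_ms=bin_ms)


# ---------------------------------------------------------------------------
# Rate-change classification


def classify_rate_change(base_rates: pd.Series, treated_rates: pd.Series,
                         rel_tol: float = 0.01) -> tuple[pd.Series, pd.Series]:
    """Per-unit direction of rate change and the population proportions.

    A unit is ``unchanged`` iff ``|treated - base| / max(base, eps) <
    rel_tol``; otherwise the sign of the difference decides.  Units present in
    only one condition are excluded with a warning.  The proportions always
    sum to 1 over the compared units.
    """
    common = base_rates.index.intersection(treated_rates.index)
    dropped = set(base_rates.index).symmetric_difference(treated_rates.index)
    if dropped:
        logger.warning("units present in only one condition excluded: %s",
                       sorted(dropped))
    if len(common) == 0:
        raise ValueError("no units common to both conditions")
    eps = 1e-12
    b = base_rates.loc[common].to_numpy(float)
    t = treated_rates.loc[common].to_numpy(float)
    rel = np.abs(t - b) / np.maximum(b, eps)
    directions = np.where(rel < rel_tol, "unchanged",
                          np.where(t > b, "increase", "decrease"))
    dir_series = pd.Series(directions, index=common, name="change_direction")
    props = pd.Series({d: float(np.mean(directions == d))
                       for d in CHANGE_DIRECTIONS}, name="proportion")
    return dir_series, props


# ---------------------------------------------------------------------------
# Cell typing


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with pooled standard deviation."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


@dataclass
class CellTypingResult:
    labels: pd.Series               # PPyrN / PIN per unit
    centers: pd.DataFrame           # cluster centers in feature units
    stats: pd.DataFrame             # per-feature medians, MWU p, Cohen's d
    proportions: dict[str, float]


def classify_cell_types(features: pd.DataFrame, k: int = 2, seed: int = 0,
                        restarts: int = 50) -> CellTypingResult:
    """K-means separation of single units into putative cell classes.

    ``features`` must have columns ``trough_to_peak_ms`` and ``rate_hz`` (one
    row per SUA).  The rate is log10-transformed, both features are z-scored,
    and K-means (k-means++ seeding, ``restarts`` restarts, fixed seed) splits
    the cloud in two.  The cluster with the larger mean trough-to-peak time is
    labeled ``PPyrN``, the other ``PIN`` — labels are anchored to waveform
    width, not cluster index.
    """
    required = {"trough_to_peak_ms", "rate_hz"}
    if not required.issubset(features.columns):
        raise ValueError(f"features must have columns {sorted(required)}")
    feats = features.dropna(subset=list(required))
    feats = feats[feats["rate_hz"] > 0]
    if len(feats) < 2 * k:
        raise ValueError(f"need at least {2 * k} units with waveform features")
    X = np.column_stack([feats["trough_to_peak_ms"].to_numpy(float),
                         np.log10(feats["rate_hz"].to_numpy(float))])
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0) and np.all(sd == 0):
        raise ValueError("degenerate clustering: all features identical")
    Z = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    raw = km.fit_predict(Z)
    # anchor labels by waveform width
    mean_ttp = [X[raw == c, 0].mean() for c in range(k)]
    pyr_cluster = int(np.argmax(mean_ttp))
    names = {c: ("PPyrN" if c == pyr_cluster else "PIN") for c in range(k)}
    labels = pd.Series([names[c] for c in raw], index=feats.index,
                       name="cell_class")
    centers = pd.DataFrame(
        {"trough_to_peak_ms": [X[raw == c, 0].mean() for c in range(k)],
         "log10_rate": [X[raw == c, 1].mean() for c in range(k)]},
        index=[names[c] for c in range(k)])
    rows = {}
    for col, vals in (("trough_to_peak_ms", X[:, 0]), ("log10_rate", X[:, 1])):
        a = vals[labels.to_numpy() == "PPyrN"]
        b = vals[labels.to_numpy() == "PIN"]
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows[col] = {"median_PPyrN": float(np.median(a)),
                     "median_PIN": float(np.median(b)),
                     "mannwhitney_u": float(u), "p": float(p),
                     "cohens_d": cohens_d(a, b)}
    prop = {name: float(np.mean(labels == name)) for name in ("PPyrN", "PIN")}
    return CellTypingResult(labels=labels, centers=centers,
                            stats=pd.DataFrame(rows).T, proportions=prop)


def unit_table(base: SpikeTrainSet, treated: SpikeTrainSet,
               rel_tol: float = 0.01, seed: int = 0) -> pd.DataFrame:
    """Per-unit summary: rates per condition, change direction, cell class.

    MUA units stay ``unassigned``; typing runs on the SUA waveform/rate cloud.
    """
    rb = unit_rates(base)
    rt = unit_rates(treated)
    directions, _props = classify_rate_change(rb, rt, rel_tol=rel_tol)
    df = pd.DataFrame({"rate_baseline_hz": rb, "rate_treated_hz": rt,
                       "change_direction": directions})
    df["kind"] = [u.kind for u in base.units]
    df["trough_to_peak_ms"] = [u.trough_to_peak_ms for u in base.units]
    df["cell_class"] = "unassigned"
    sua = df[df["kind"] == "SUA"]
    feats = pd.DataFrame({"trough_to_peak_ms": sua["trough_to_peak_ms"],
                          "rate_hz": sua["rate_baseline_hz"]})
    try:
        typing = classify_cell_types(feats, seed=seed)
        df.loc[typing.labels.index, "cell_class"] = typing.labels
    except ValueError as exc:
        logger.warning("cell typing skipped: %s", exc)
    return df


# ---------------------------------------------------------------------------
# Association statistics


def association_stats(table: np.ndarray, correction: bool = False,
                      exact: bool = False) -> dict:
    """Chi-square (default, no continuity correction) or Fisher's exact test
    on a cell-class x change-direction contingency table."""
    table = np.asarray(table)
    if table.ndim != 2 or np.any(table < 0):
        raise ValueError("contingency table must be 2-D and nonnegative")
    if exact:
        if table.shape != (2, 2):
            raise ValueError("Fisher's exact test requires a 2x2 table")
        odds, p = stats.fisher_exact(table)
        return {"test": "fisher_exact", "statistic": float(odds),
                "p": float(p), "df": None}
    chi2, p, df, expected = stats.chi2_contingency(table, correction=correction)
    if np.any(expected < 1):
        warnings.warn("expected cell count < 1; consider the exact test",
                      stacklevel=2)
    return {"test": "chi_square", "statistic": float(chi2), "p": float(p),
            "df": int(df)}


# ---------------------------------------------------------------------------
# LFP band power


def band_power(trace: LfpTrace, segment_s: float = 60.0,
               bands: dict[str, tuple[float, float]] | None = None) -> dict:
    """Hann-tapered periodogram band powers of the final ``segment_s`` seconds.

    Band intervals are half-open ``[lo, hi)``; the topmost band is closed at
    its upper edge.  ``broadband`` spans 0 to the topmost edge inclusive, so
    it equals the four band powers plus the 0-0.5 Hz remainder.
    """
    bands = bands or FREQUENCY_BANDS
    if trace.fs < 100.0:
        raise ValueError("sample rate too low to resolve the gamma band")
    n_seg = int(round(segment_s * trace.fs))
    if trace.samples.size < n_seg:
        raise ValueError("trace shorter than the analysis segment")
    x = trace.samples[-n_seg:]
    freqs, psd = signal.periodogram(x, fs=trace.fs, window="hann")
    top = max(hi for _lo, hi in bands.values())
    out: dict[str, float] = {}
    for name, (lo, hi) in bands.items():
        mask = (freqs >= lo) & ((freqs <= hi) if hi == top else (freqs < hi))
        out[name] = float(psd[mask].sum())
    out["broadband"] = float(psd[(freqs >= 0) & (freqs <= top)].sum())
    return out


# ---------------------------------------------------------------------------
# Paired comparisons


@dataclass
class PairedComparison:
    test: str
    statistic: float
    p: float
    shapiro_p: float | None
    n: int
    mean_a: float
    mean_b: float


def paired_compare(values_a, values_b, alpha_normality: float = 0.05
                   ) -> PairedComparison:
    """Shapiro-Wilk-gated paired test.

    The paired differences are tested for normality; a paired t-test is used
    when normality is not rejected, a Wilcoxon matched-pairs signed-rank test
    otherwise.  All-zero differences return the no-change convention
    (statistic 0, p = 1).
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if a.size < 3:
        raise ValueError("need n >= 3 pairs")
    diffs = b - a
    base = PairedComparison("", 0.0, 1.0, None, a.size,
                            float(a.mean()), float(b.mean()))
    if np.allclose(diffs, 0.0):
        base.test = "no_change"
        return base
    if np.ptp(diffs) == 0:  # constant nonzero shift: SE = 0, extreme by convention
        base.test = "paired_t"
        base.statistic = float(np.inf) * np.sign(diffs[0])
        base.p = 0.0
        return base
    sw_stat, sw_p = stats.shapiro(diffs)
    if sw_p > alpha_normality:
        t, p = stats.ttest_rel(b, a)
        base.test, base.statistic, base.p = "paired_t", float(t), float(p)
    else:
        w, p = stats.wilcoxon(b, a)
        base.test, base.statistic, base.p = "wilcoxon", float(w), float(p)
    base.shapiro_p = float(sw_p)
    return base


def ks_compare(values_a, values_b) -> dict:
    """Two-sample Kolmogorov-Smirnov test for cumulative-distribution shifts."""
    stat, p = stats.ks_2samp(values_a, values_b)
    return {"test": "kolmogorov_smirnov", "statistic": float(stat), "p": float(p)}
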