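"""Cross-correlogram functional connectivity.

Pairwise spike-time cross-correlograms are computed at 1-ms resolution over
+/-50 ms, normalized by ``sqrt(N_i * N_j)`` (which bounds weights by 1 and
makes the lag-0 value of a self-comparison exactly 1).  "Correlation noise"
is estimated from the flanking lags ``10 < |lag| <= 50`` ms, far outside the
+/-5 ms tight-synchrony window used for the peak, so that the estimator is
deterministic.  A pair is positively linked when the peak exceeds the flank
mean by ``k_sd`` flank standard deviations (5 by default), negatively linked
when the trough falls the same distance below; the stored weight is the
normalized peak (or trough) excess over the flank mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spike_io import SpikeTrainSet
from .activity import cohens_d
from scipy import stats

logger = logging.getLogger(__name__)

MIN_SPIKES = 10


@dataclass
class Correlogram:
    pair: tuple[str, str]
    lags: np.ndarray          # integer lags, -noise_lag..+noise_lag
    values: np.ndarray        # normalized coincidence counts per lag
    flank_mean: float
    flank_sd: float
    peak_lag: int
    peak_value: float
    trough_lag: int
    trough_value: float
    n_i: int
    n_j: int
    skipped: bool = False


def _lag_counts(ti: np.ndarray, tj: np.ndarray, max_lag: float,
                bin_ms: float = 1.0) -> np.ndarray:
    """Histogram of (tj - ti) in bins centered on integer lags."""
    half = max_lag + bin_ms / 2.0
    lo = np.searchsorted(tj, ti - half, side="left")
    hi = np.searchsorted(tj, ti + half, side="left")
    cnt = hi - lo
    total = int(cnt.sum())
    n_lags = int(2 * max_lag / bin_ms) + 1
    if total == 0:
        return np.zeros(n_lags)
    start_rep = np.repeat(lo, cnt)
    offsets = np.arange(total) - np.repeat(np.concatenate(([0], np.cumsum(cnt)[:-1])), cnt)
    diffs = tj[start_rep + offsets] - np.repeat(ti, cnt)
    edges = np.arange(-half, half + bin_ms, bin_ms)
    counts, _ = np.histogram(diffs, bins=edges)
    return counts.astype(float)


def cross_correlogram(train_i: np.ndarray, train_j: np.ndarray,
                      pair: tuple[str, str] = ("i", "j"),
                      analysis_lag_ms: float = 5.0,
                      noise_lag_ms: float = 50.0,
                      bin_ms: float = 1.0,
                      flank_min_ms: float = 10.0,
                      exclude_zero_lag: bool = False) -> Correlogram:
    """Normalized cross-correlogram with flank noise statistics.

    The correlogram of ``(j, i)`` is the lag-mirror of ``(i, j)``.  Pairs in
    which either train has fewer than ``MIN_SPIKES`` spikes are flagged
    ``skipped`` (unstable normalization) and never produce links.
    """
    ti = np.asarray(train_i, float)
    tj = np.asarray(train_j, float)
    lags = np.arange(-int(noise_lag_ms), int(noise_lag_ms) + 1)
    if ti.size < MIN_SPIKES or tj.size < MIN_SPIKES:
        logger.warning("pair %s skipped: fewer than %d spikes", pair, MIN_SPIKES)
        z = np.zeros(lags.size)
        return Correlogram(pair, lags, z, 0.0, 0.0, 0, 0.0, 0, 0.0,
                           ti.size, tj.size, skipped=True)
    counts = _lag_counts(ti, tj, max_lag=noise_lag_ms, bin_ms=bin_ms)
    norm = np.sqrt(float(ti.size) * float(tj.size))
    values = counts / norm
    if exclude_zero_lag:
        zero = lags == 0
        flank_for_fill = values[(np.abs(lags) > 0) & (np.abs(lags) <= 2)]
        values = values.copy()
        values[zero] = flank_for_fill.mean() if flank_for_fill.size else 0.0
    flank = values[(np.abs(lags) > flank_min_ms) & (np.abs(lags) <= noise_lag_ms)]
    flank_mean = float(flank.mean())
    flank_sd = float(flank.std(ddof=1)) if flank.size > 1 else 0.0
    window = np.abs(lags) <= analysis_lag_ms
    wvals = values[window]
    wlags = lags[window]
    k_max = int(np.argmax(wvals))
    k_min = int(np.argmin(wvals))
    return Correlogram(pair=pair, lags=lags, values=values,
                       flank_mean=flank_mean, flank_sd=flank_sd,
                       peak_lag=int(wlags[k_max]), peak_value=float(wvals[k_max]),
                       trough_lag=int(wlags[k_min]), trough_value=float(wvals[k_min]),
                       n_i=ti.size, n_j=tj.size)


def pairwise_correlograms(sts: SpikeTrainSet, **kwargs) -> list[Correlogram]:
    """Correlograms for all unordered unit pairs (SUA and MUA included)."""
    out = []
    for a in range(sts.n_units):
        ua = sts.units[a]
        for b in range(a + 1, sts.n_units):
            ub = sts.units[b]
            out.append(cross_correlogram(ua.timestamps_ms, ub.timestamps_ms,
                                         pair=(ua.unit_id, ub.unit_id), **kwargs))
    return out


@dataclass
class ConnectivityResult:
    """Signed weighted and binary symmetric link matrices for one recording."""

    unit_ids: list[str]
    W_pos: np.ndarray
    W_neg: np.ndarray
    A_pos: np.ndarray
    A_neg: np.ndarray

    @property
    def n_pos_links(self) -> int:
        return int(np.triu(self.A_pos, 1).sum())

    @property
    def n_neg_links(self) -> int:
        return int(np.triu(self.A_neg, 1).sum())

    @property
    def sum_pos_weights(self) -> float:
        return float(np.triu(self.W_pos, 1).sum())

    @property
    def sum_neg_weights(self) -> float:
        return float(np.triu(self.W_neg, 1).sum())


def build_connectivity(correlograms: list[Correlogram], unit_ids: list[str],
                       k_sd: float = 5.0,
                       weight_mode: str = "excess") -> ConnectivityResult:
    """Threshold correlogram peaks/troughs into link matrices.

    A positive link needs ``peak - flank_mean > k_sd * flank_sd``; a negative
    link needs ``trough - flank_mean < -k_sd * flank_sd``.  When both cross,
    the larger absolute excess wins.  ``weight_mode`` stores either the
    ``"excess"`` over the flank mean (default) or the raw ``"peak"`` height;
    positive weights are clipped into [0, 1].
    """
    if weight_mode not in ("excess", "peak"):
        raise ValueError("weight_mode must be 'excess' or 'peak'")
    index = {uid: k for k, uid in enumerate(unit_ids)}
    n = len(unit_ids)
    W_pos = np.zeros((n, n))
    W_neg = np.zeros((n, n))
    for cg in correlograms:
        if cg.pair[0] not in index or cg.pair[1] not in index:
            raise ValueError(f"correlogram pair {cg.pair} not in unit set")
        if cg.skipped or cg.flank_sd <= 0:
            continue
        i, j = index[cg.pair[0]], index[cg.pair[1]]
        pos_exc = cg.peak_value - cg.flank_mean
        neg_exc = cg.trough_value - cg.flank_mean
        pos_sig = pos_exc > k_sd * cg.flank_sd
        neg_sig = neg_exc < -k_sd * cg.flank_sd
        if pos_sig and neg_sig:  # larger |excess| wins
            if pos_exc >= -neg_exc:
                neg_sig = False
            else:
                pos_sig = False
        if pos_sig:
            w = pos_exc if weight_mode == "excess" else cg.peak_value
            W_pos[i, j] = W_pos[j, i] = float(np.clip(w, 0.0, 1.0))
        elif neg_sig:
            w = neg_exc if weight_mode == "excess" else cg.trough_value
            W_neg[i, j] = W_neg[j, i] = float(min(w, 0.0))
    return ConnectivityResult(unit_ids=list(unit_ids), W_pos=W_pos, W_neg=W_neg,
                              A_pos=(W_pos > 0).astype(int),
                              A_neg=(W_neg < 0).astype(int))


def connectivity_from_spikes(sts: SpikeTrainSet, k_sd: float = 5.0,
                             **kwargs) -> ConnectivityResult:
    """Convenience: correlograms for every pair, then threshold into matrices."""
    cgs = pairwise_correlograms(sts, **kwargs)
    return build_connectivity(cgs, sts.unit_ids, k_sd=k_sd)


def compare_connectivity(base: ConnectivityResult,
                         treated: ConnectivityResult) -> dict:
    """Between-condition correlation-change statistics.

    Per-pair ``delta = W_treated - W_base`` on the signed weighted matrix
    (positive plus negative parts); pairs split by the sign of delta, the
    |delta| distributions of the two groups compared (Mann-Whitney U — the
    groups differ in size) with Cohen's d for the effect size.
    """
    if base.unit_ids != treated.unit_ids:
        raise ValueError("connectivity results cover different unit sets")
    n = len(base.unit_ids)
    iu = np.triu_indices(n, k=1)
    wb = (base.W_pos + base.W_neg)[iu]
    wt = (treated.W_pos + treated.W_neg)[iu]
    delta = wt - wb
    inc = np.abs(delta[delta > 0])
    dec = np.abs(delta[delta < 0])
    out = {
        "n_increase": int(inc.size),
        "n_decrease": int(dec.size),
        "mean_abs_increase": float(inc.mean()) if inc.size else 0.0,
        "mean_abs_decrease": float(dec.mean()) if dec.size else 0.0,
        "cohens_d": cohens_d(inc, dec) if inc.size > 1 and dec.size > 1 else 0.0,
        "binary": {
            "pos_baseline": base.n_pos_links, "pos_treated": treated.n_pos_links,
            "neg_baseline": base.n_neg_links, "neg_treated": treated.n_neg_links},
        "weighted": {
            "pos_baseline": base.sum_pos_weights, "pos_treated": treated.sum_pos_weights,
            "neg_baseline": base.sum_neg_weights, "neg_treated": treated.sum_neg_weights},
    }
    if inc.size > 1 and dec.size > 1:
        u, p = stats.mannwhitneyu(inc, dec, alternative="two-sided")
        out["abs_delta_test"] = {"test": "mannwhitney_u",
                                 "statistic": float(u), "p": float(p)}
    else:
        out["abs_delta_test"] = {"test": "mannwhitney_u",
                                 "statistic": 0.0, "p": 1.0}
    return out


def edge_table(result: ConnectivityResult) -> pd.DataFrame:
    """Link list: one row per significant pair with weight and sign."""
    rows = []
    n = len(result.unit_ids)
    for i in range(n):
        for j in range(i + 1, n):
            if result.A_pos[i, j]:
                rows.append((result.unit_ids[i], result.unit_ids[j],
                             result.W_pos[i, j], "+"))
            elif result.A_neg[i, j]:
                rows.append((result.unit_ids[i], result.unit_ids[j],
                             result.W_neg[i, j], "-"))
    return pd.DataFrame(rows, columns=["node_i", "node_j", "weight", "sign"])
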