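"""cfDNA fragmentation metrics and the accessibility-fragmentation correlation.

Per-region fragment depth and median fragment length are the validation
readout: open chromatin is more exposed to nucleases, so accessible regions
should show fewer and shorter cfDNA fragments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import savgol_filter

from .intervals import PeakSet

FRAGMENT_COLUMNS = ["chrom", "start", "end"]


def fragments_frame(records) -> pd.DataFrame:
    """Coerce (chrom, start, end) records into a sorted fragment dataframe."""
    df = pd.DataFrame(records, columns=FRAGMENT_COLUMNS)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if ((df["end"] - df["start"]) <= 0).any():
        raise ValueError("fragment with non-positive length")
    return df.sort_values(["chrom", "start", "end"],
                          kind="mergesort").reset_index(drop=True)


def _is_sorted(df: pd.DataFrame) -> bool:
    key = df[["chrom", "start"]]
    return bool((key.reset_index(drop=True).equals(
        key.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True))))


def region_fragment_stats(fragments: pd.DataFrame, regions: PeakSet,
                          assignment_rule: str = "any_overlap") -> pd.DataFrame:
    """Per-region fragment depth and median fragment length.

    ``assignment_rule`` "any_overlap" assigns a fragment to every region it
    shares >= 1 bp with; "midpoint" assigns by fragment midpoint. Median of an
    even number of lengths is the mean of the middle two. Regions without
    fragments get depth 0 and NaN median length.
    """
    if assignment_rule not in ("any_overlap", "midpoint"):
        raise ValueError(f"unknown assignment rule {assignment_rule!r}")
    if not _is_sorted(fragments):
        raise ValueError("fragment input must be coordinate-sorted")
    names = regions.df["name"].to_numpy()
    depth = np.zeros(len(regions), dtype=np.int64)
    med = np.full(len(regions), np.nan)
    by_chrom = {c: sub for c, sub in fragments.groupby("chrom", sort=False)}
    for chrom, rsub in regions.df.groupby("chrom", sort=False):
        sub = by_chrom.get(chrom)
        if sub is None:
            continue
        fstart = sub["start"].to_numpy()
        fend = sub["end"].to_numpy()
        flen = fend - fstart
        if assignment_rule == "midpoint":
            fmid = (fstart + fend) // 2
            order = np.argsort(fmid, kind="stable")
            fmid_s = fmid[order]
            flen_s = flen[order]
            for i, r in zip(rsub.index, rsub.itertuples(index=False)):
                lo = np.searchsorted(fmid_s, r.start, side="left")
                hi = np.searchsorted(fmid_s, r.end, side="left")
                depth[i] = hi - lo
                if hi > lo:
                    med[i] = float(np.median(flen_s[lo:hi]))
        else:
            max_len = int(flen.max()) if len(flen) else 0
            for i, r in zip(rsub.index, rsub.itertuples(index=False)):
                # fragments starting before region end, within max_len of start
                lo = np.searchsorted(fstart, r.start - max_len, side="left")
                hi = np.searchsorted(fstart, r.end, side="left")
                hit = fend[lo:hi] > r.start
                depth[i] = int(hit.sum())
                if depth[i]:
                    med[i] = float(np.median(flen[lo:hi][hit]))
    return pd.DataFrame({"region_id": names, "depth": depth,
                         "n_fragments": depth,
                         "median_length": med}).set_index("region_id")


def normalize_depth(stats_df: pd.DataFrame, total_fragments: int) -> pd.DataFrame:
    """Scale depth to fragments-per-million of the library."""
    if total_fragments <= 0:
        raise ValueError("total_fragments must be positive")
    out = stats_df.copy()
    out["depth"] = out["depth"] * 1e6 / total_fragments
    return out


def compare_low_high(values_low, values_high) -> dict:
    """Welch two-sample two-sided t-test between the low/high groups."""
    lo = np.asarray(values_low, dtype=float)
    hi = np.asarray(values_high, dtype=float)
    lo = lo[np.isfinite(lo)]
    hi = hi[np.isfinite(hi)]
    if len(lo) < 2 or len(hi) < 2:
        raise ValueError("need at least 2 finite values per group")
    t, p = stats.ttest_ind(lo, hi, equal_var=False)
    return {"t": float(t), "pvalue": float(p),
            "mean_low": float(lo.mean()), "mean_high": float(hi.mean()),
            "n_low": int(len(lo)), "n_high": int(len(hi))}


def smooth_series(y, window: int = 15, order: int = 2) -> np.ndarray:
    """Savitzky-Golay smoothing: per-window least-squares polynomial fit.

    Edges are handled by fitting the polynomial on the truncated window
    (scipy "interp" mode). Polynomials of degree <= ``order`` pass through
    unchanged.
    """
    y = np.asarray(y, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if order >= window:
        raise ValueError("order must be smaller than window")
    if len(y) < window:
        raise ValueError(f"series of length {len(y)} shorter than window {window}")
    return savgol_filter(y, window_length=window, polyorder=order, mode="interp")


def accessibility_fragmentation_correlation(
        blood_weighted_mean: pd.Series, cfdna_metric: pd.Series,
        log2_outlier_floor: float = 1.0, window: int = 15,
        order: int = 2) -> dict:
    """Smoothed Pearson correlation of blood accessibility with a cfDNA metric.

    Both series are log2-transformed; regions where either log2 value is
    below ``log2_outlier_floor`` (or non-finite) are removed; the remainder
    is ordered by accessibility, both series are Savitzky-Golay smoothed
    (window 15, order 2 by default), and Pearson r is computed.
    """
    if not blood_weighted_mean.index.equals(cfdna_metric.index):
        raise ValueError("region index mismatch")
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.log2(blood_weighted_mean.to_numpy(dtype=float))
        m = np.log2(cfdna_metric.to_numpy(dtype=float))
    keep = np.isfinite(a) & np.isfinite(m) & (a >= log2_outlier_floor) \
        & (m >= log2_outlier_floor)
    a, m = a[keep], m[keep]
    if len(a) < window:
        raise ValueError(f"only {len(a)} regions survive outlier removal; "
                         f"need >= {window}")
    order_idx = np.argsort(a, kind="stable")
    a_s = smooth_series(a[order_idx], window, order)
    m_s = smooth_series(m[order_idx], window, order)
    r, p = stats.pearsonr(a_s, m_s)
    return {"r": float(r), "pvalue": float(p), "n_used": int(len(a)),
            "n_removed": int(np.sum(~keep)), "window": window, "order": order}
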