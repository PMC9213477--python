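"""Marker prioritization and tumor-cfDNA allele-frequency concordance.

Known markers (recurrent mutations, differentially methylated regions) are
assigned the relative accessibility score of the peak they fall in and ranked
ascending: the lower the score, the better the region is expected to be
represented in cfDNA. Variant-level concordance between matched tumor and
cfDNA is computed separately for markers in score-negative and
score-positive peaks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import PeakSet
from .scoring import ScoreTrack

MARKER_COLUMNS = ["chrom", "start", "end", "name", "marker_type", "source"]
VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "af", "depth", "mmq", "mbq"]


def _assign_peaks(chroms: np.ndarray, starts: np.ndarray, ends: np.ndarray,
                  peaks: PeakSet) -> np.ndarray:
    """Index of the overlapping peak per query interval (-1 if none).

    Requires a non-overlapping peak universe; a query spanning two peaks is
    assigned to the one with the larger overlap (leftmost on ties).
    """
    pdf = peaks.df
    for chrom, sub in pdf.groupby("chrom"):
        s = sub["start"].to_numpy()
        order = np.argsort(s, kind="stable")
        e = sub["end"].to_numpy()[order]
        if len(e) > 1 and (s[order][1:] < e[:-1]).any():
            raise ValueError("peak universe contains overlapping peaks; "
                             "consolidate before assignment")
    out = np.full(len(chroms), -1, dtype=np.int64)
    by_chrom = {c: sub for c, sub in pdf.groupby("chrom", sort=False)}
    for chrom in pd.unique(chroms):
        sub = by_chrom.get(chrom)
        if sub is None:
            continue
        ps = sub["start"].to_numpy()
        pe = sub["end"].to_numpy()
        pidx = sub.index.to_numpy()
        sel = np.nonzero(chroms == chrom)[0]
        for i in sel:
            qs, qe = starts[i], ends[i]
            lo = np.searchsorted(pe, qs, side="right")
            hi = np.searchsorted(ps, qe, side="left")
            if hi <= lo:
                continue
            ov = np.minimum(pe[lo:hi], qe) - np.maximum(ps[lo:hi], qs)
            out[i] = pidx[lo + int(np.argmax(ov))]
    return out


def rank_markers(markers: pd.DataFrame, peaks: PeakSet,
                 track: ScoreTrack) -> pd.DataFrame:
    """Rank markers by the score of their overlapping peak, ascending.

    Markers that do not overlap any peak are dropped. ``peaks`` rows must
    correspond 1:1 (by position) with ``track.region_ids`` and be
    non-overlapping.
    """
    if len(peaks) != len(track.region_ids):
        raise ValueError("peaks and score track have different lengths")
    idx = _assign_peaks(markers["chrom"].to_numpy(),
                        markers["start"].to_numpy(),
                        markers["end"].to_numpy(), peaks)
    out = markers.copy()
    out["assigned_peak_id"] = [
        track.region_ids[i] if i >= 0 else None for i in idx]
    out["score"] = [track.score.iloc[i] if i >= 0 else np.nan for i in idx]
    out = out[idx >= 0]
    return out.sort_values(["score", "chrom", "start"],
                           kind="mergesort").reset_index(drop=True)


def filter_variants(variants: pd.DataFrame, min_depth: int = 10,
                    min_mmq: float = 50, min_mbq: float = 20) -> pd.DataFrame:
    """Drop low-quality variants (depth < 10, MMQ < 50 or MBQ < 20 fail)."""
    keep = ((variants["depth"] >= min_depth)
            & (variants["mmq"] >= min_mmq)
            & (variants["mbq"] >= min_mbq))
    return variants[keep].reset_index(drop=True)


def remove_germline(tumor: pd.DataFrame, cfdna: pd.DataFrame,
                    germline_af: float = 0.20) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop putative germline variants (cfDNA AF > threshold) from both lists."""
    key = ["chrom", "pos", "ref", "alt"]
    bad = cfdna.loc[cfdna["af"] > germline_af, key]
    bad_keys = set(map(tuple, bad.to_numpy()))

    def ok(df: pd.DataFrame) -> pd.DataFrame:
        mask = [tuple(row) not in bad_keys for row in df[key].to_numpy()]
        return df[mask].reset_index(drop=True)

    return ok(tumor), ok(cfdna)


def filter_variant_pair(tumor: pd.DataFrame, cfdna: pd.DataFrame,
                        min_depth: int = 10, min_mmq: float = 50,
                        min_mbq: float = 20,
                        germline_af: float = 0.20) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quality-filter each list, then apply the germline rule to the pair."""
    t = filter_variants(tumor, min_depth, min_mmq, min_mbq)
    c = filter_variants(cfdna, min_depth, min_mmq, min_mbq)
    return remove_germline(t, c, germline_af)


def af_concordance_by_score_sign(tumor: pd.DataFrame, cfdna: pd.DataFrame,
                              peaks: PeakSet, track: ScoreTrack) -> dict:
    """Tumor vs cfDNA allele-frequency Pearson r, split by score sign.

    Variants detected in both lists (exact chrom/pos/ref/alt match) are
    assigned the score of the peak containing them (1-based position mapped
    to a 1 bp 0-based interval); variants with score exactly 0 or outside all
    peaks are excluded. Groups with fewer than 3 variants report r as NaN.
    """
    key = ["chrom", "pos", "ref", "alt"]
    both = tumor.merge(cfdna, on=key, suffixes=("_tumor", "_cfdna"))
    if not len(both):
        return {"r_neg": float("nan"), "n_neg": 0,
                "r_pos": float("nan"), "n_pos": 0}
    start = both["pos"].to_numpy(dtype=np.int64) - 1
    idx = _assign_peaks(both["chrom"].to_numpy(), start, start + 1, peaks)
    score = np.array([track.score.iloc[i] if i >= 0 else np.nan for i in idx])

    def group_r(mask: np.ndarray) -> tuple[float, int]:
        n = int(mask.sum())
        if n < 3:
            return float("nan"), n
        r, _ = stats.pearsonr(both.loc[mask, "af_tumor"],
                              both.loc[mask, "af_cfdna"])
        return float(r), n

    r_neg, n_neg = group_r(np.isfinite(score) & (score < 0))
    r_pos, n_pos = group_r(np.isfinite(score) & (score > 0))
    return {"r_neg": r_neg, "n_neg": n_neg, "r_pos": r_pos, "n_pos": n_pos}
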