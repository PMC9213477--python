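"""Count normalization and the relative accessibility score.

The score for a region is log2 of the mean normalized tumor count over the
weighted blood mean, quantifying how much more (positive) or less (negative)
accessible a region is in a tumor type than in blood cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_PSEUDOCOUNT = 0.01


@dataclass
class CountMatrix:
    """Region x sample count matrix with per-sample labels.

    ``counts`` rows are region ids, columns sample ids. ``sample_meta`` maps
    sample id to its label (cancer type or blood cell type). ``normalized``
    is "raw" or "cpm".
    """

    counts: pd.DataFrame
    sample_meta: pd.Series
    normalized: str = "raw"

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)}")
        self.sample_meta = self.sample_meta.loc[self.counts.columns]

    @property
    def region_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def select_label(self, label: str) -> "CountMatrix":
        """Submatrix of samples carrying ``label`` (case-insensitive)."""
        cols = self.sample_meta.index[
            self.sample_meta.str.lower() == label.lower()]
        if not len(cols):
            raise ValueError(f"no samples labeled {label!r}")
        return CountMatrix(self.counts[cols], self.sample_meta.loc[cols],
                           self.normalized)


@dataclass
class ScoreTrack:
    """Per-region relative accessibility (log2 tumor/blood) with provenance."""

    region_ids: pd.Index
    score: pd.Series
    tumor_mean: pd.Series
    blood_weighted_mean: pd.Series
    pseudocount: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "region_id": self.region_ids,
            "score": self.score.to_numpy(),
            "tumor_mean": self.tumor_mean.to_numpy(),
            "blood_weighted_mean": self.blood_weighted_mean.to_numpy(),
        }).set_index("region_id")


def cpm_normalize(matrix: CountMatrix) -> CountMatrix:
    """Counts-per-million: scale each sample column to sum to 1e6."""
    totals = matrix.counts.sum(axis=0)
    zero = totals.index[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-sum count column(s): {list(zero)}")
    return CountMatrix(matrix.counts * 1e6 / totals, matrix.sample_meta, "cpm")


def relative_accessibility(tumor: CountMatrix, blood_weighted_mean: pd.Series,
                           pseudocount: float = DEFAULT_PSEUDOCOUNT) -> ScoreTrack:
    """log2((mean tumor cpm + eps) / (blood weighted mean + eps)) per region.

    ``tumor`` must be cpm-normalized and share its region index with
    ``blood_weighted_mean``. With ``pseudocount`` > 0 the score is finite
    everywhere; with 0 a zero denominator raises.
    """
    if tumor.normalized != "cpm":
        raise ValueError("tumor matrix must be cpm-normalized")
    if not tumor.region_ids.equals(blood_weighted_mean.index):
        raise ValueError("region index mismatch between tumor counts and blood means")
    t_mean = tumor.counts.mean(axis=1)
    denom = blood_weighted_mean + pseudocount
    if pseudocount == 0 and (denom <= 0).any():
        raise ValueError("zero blood mean with pseudocount 0; use a positive pseudocount")
    score = np.log2((t_mean + pseudocount) / denom)
    return ScoreTrack(region_ids=tumor.region_ids, score=score,
                      tumor_mean=t_mean, blood_weighted_mean=blood_weighted_mean,
                      pseudocount=pseudocount)
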