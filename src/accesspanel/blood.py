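"""Consensus blood peak set construction and blood accessibility summaries.

Builds reproducible cell-type-specific peak sets from per-sample peak calls,
merges them into a single non-overlapping blood consensus set, computes the
2:1 neutrophil:PBMC weighted mean of normalized counts per region, and labels
regions by accessibility quartile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import PeakSet, consolidate_nonoverlapping, normalize_scores_spm, overlaps_any

logger = logging.getLogger(__name__)

DEFAULT_WEIGHTS = {"pbmc": 1.0, "neutrophil": 2.0}


@dataclass
class CellTypePeakSet:
    """Reproducible peak set for one cell type.

    ``n_supporting_samples[i]`` is the number of distinct input samples whose
    original (normalized) peaks overlap retained peak ``i`` with score above
    the support threshold.
    """

    cell_type: str
    peaks: PeakSet
    n_supporting_samples: np.ndarray


def build_celltype_peakset(sample_peaksets: list[PeakSet], cell_type: str = "",
                           min_samples: int = 2,
                           min_score: float = 5.0) -> CellTypePeakSet:
    """Combine per-sample peaks of one cell type into a reproducible set.

    Each sample is score-per-million normalized, all samples are pooled and
    consolidated with the iterative highest-score-first procedure, and only
    peaks supported (>= 1 bp overlap with an original per-sample peak whose
    normalized score exceeds ``min_score``) by at least ``min_samples``
    distinct samples are retained.
    """
    if not sample_peaksets:
        raise ValueError("need at least one sample peak set")
    widths = {ps.width for ps in sample_peaksets if ps.width is not None}
    if len(widths) > 1:
        raise ValueError(f"samples have differing fixed widths: {sorted(widths)}")
    normalized = [normalize_scores_spm(ps) for ps in sample_peaksets]
    pooled = PeakSet(pd.concat([ps.df for ps in normalized], ignore_index=True),
                     width=sample_peaksets[0].width, label=cell_type)
    consolidated = consolidate_nonoverlapping(pooled)
    support = np.zeros(len(consolidated), dtype=int)
    for ps in normalized:
        strong = ps.subset(ps.df["score"].to_numpy() > min_score)
        support += overlaps_any(consolidated, strong).astype(int)
    retained = consolidated.subset(support >= min_samples)
    if not len(retained):
        logger.warning("cell type %r: no peaks passed the reproducibility filter",
                       cell_type)
    return CellTypePeakSet(cell_type=cell_type, peaks=retained,
                           n_supporting_samples=support[support >= min_samples])


def build_blood_consensus(celltype_sets: list[CellTypePeakSet]) -> PeakSet:
    """Merge cell-type peak sets into the non-overlapping blood consensus set.

    Scores of each cell-type set are renormalized (score-per-million within
    the set) before pooling so that no cell type dominates by library depth.
    """
    if not celltype_sets:
        raise ValueError("need at least one cell-type peak set")
    renormed = [normalize_scores_spm(cs.peaks) for cs in celltype_sets]
    width = celltype_sets[0].peaks.width
    pooled = PeakSet(pd.concat([ps.df for ps in renormed], ignore_index=True),
                     width=width, label="consensus")
    return consolidate_nonoverlapping(pooled)


def weighted_blood_mean(pbmc_counts: pd.DataFrame, neut_counts: pd.DataFrame,
                        pbmc_weight: float = DEFAULT_WEIGHTS["pbmc"],
                        neut_weight: float = DEFAULT_WEIGHTS["neutrophil"]) -> pd.Series:
    """Per-region weighted mean of normalized blood counts.

    With default weights this is (mean(PBMC) + 2 * mean(neutrophil)) / 3,
    reflecting the roughly 2:1 neutrophil:PBMC abundance in whole blood.
    Matrices are region x sample and must share a region index.
    """
    if not pbmc_counts.index.equals(neut_counts.index):
        raise ValueError("PBMC and neutrophil matrices have mismatched region indices")
    p_mean = pbmc_counts.mean(axis=1)
    n_mean = neut_counts.mean(axis=1)
    return (pbmc_weight * p_mean + neut_weight * n_mean) / (pbmc_weight + neut_weight)


def classify_accessibility_quartiles(weighted_mean: pd.Series) -> pd.Series:
    """Label regions low / mid / high by accessibility rank.

    The floor(n/4) lowest-ranked regions are "low" and the floor(n/4)
    highest-ranked are "high"; remaining regions are "mid". Rank-based slicing
    (stable sort) keeps the group sizes exact under ties.
    """
    n = len(weighted_mean)
    if n < 4:
        raise ValueError("need at least 4 regions to form quartiles")
    k = n // 4
    order = np.argsort(weighted_mean.to_numpy(), kind="stable")
    labels = np.full(n, "mid", dtype=object)
    labels[order[:k]] = "low"
    labels[order[n - k:]] = "high"
    return pd.Series(labels, index=weighted_mean.index, name="accessibility")
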