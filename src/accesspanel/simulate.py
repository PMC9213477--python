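"""Seeded generators for every input the pipeline consumes.

The generators plant known structure (tissue-specifically open/closed
regions, accessibility-dependent cfDNA fragmentation, score-sign-dependent
allele-frequency fidelity) and return truth tables so that recall and
precision of every pipeline stage can be computed exactly.

Negative-binomial counts are parameterized by mean ``mu`` and dispersion
``alpha`` with variance ``mu + alpha * mu**2`` (numpy parameterization:
n = 1/alpha, p = 1 / (1 + alpha * mu)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import Peak, PeakSet
from .fragmentation import fragments_frame
from .scoring import CountMatrix, ScoreTrack

BLOOD_CELL_TYPES = ("pbmc", "neutrophil")


@dataclass
class SimulationConfig:
    n_regions: int = 2000
    n_cancer_types: int = 3
    samples_per_type: int = 12
    blood_samples_per_celltype: int = 5
    frac_open_per_type: float = 0.02     # cancer-specifically open regions
    frac_closed_per_type: float = 0.02   # cancer-specifically closed regions
    frac_shared_open: float = 0.21       # open in every tumor, closed in blood
    frac_shared_closed: float = 0.21     # closed in every tumor, open in blood
    effect_size: float = 8.0             # open/closed mean fold change
    base_mean: float = 4.0               # closed-state expected raw count
    dispersion: float = 0.2              # NB alpha
    tumor_fraction: float = 0.1          # cfDNA mixture weight of tumor signal
    frag_len_open: tuple[float, float] = (140.0, 25.0)    # mean, sd (bp)
    frag_len_closed: tuple[float, float] = (190.0, 25.0)
    depth_ratio_closed_over_open: float = 4.0
    base_depth: float = 40.0             # expected fragments in an open region
    af_noise_sd_neg: float = 0.03        # cfDNA AF noise, score < 0 variants
    af_noise_sd_pos: float = 0.12        # cfDNA AF noise, score > 0 variants
    variant_fail_fraction: float = 0.1   # fraction failing each quality filter
    region_width: int = 501
    region_spacing: int = 2000
    n_chroms: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        planted = self.n_cancer_types * (self.frac_open_per_type
                                         + self.frac_closed_per_type)
        total = planted + self.frac_shared_open + self.frac_shared_closed
        if total > 1:
            raise ValueError(f"planted fractions sum to {total:.3f} > 1")
        for frac in (self.frac_open_per_type, self.frac_closed_per_type,
                     self.frac_shared_open, self.frac_shared_closed,
                     self.tumor_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if min(self.effect_size, self.base_mean, self.dispersion,
               self.depth_ratio_closed_over_open, self.base_depth) <= 0:
            raise ValueError("effect size, means, dispersion and ratios must be > 0")

    @property
    def cancer_types(self) -> list[str]:
        return [f"cancer{chr(ord('A') + i)}" for i in range(self.n_cancer_types)]

    @property
    def open_mean(self) -> float:
        return self.base_mean * self.effect_size


def _region_layout(config: SimulationConfig) -> PeakSet:
    rows = []
    per_chrom = -(-config.n_regions // config.n_chroms)
    for i in range(config.n_regions):
        chrom = f"chr{i // per_chrom + 1}"
        start = (i % per_chrom) * config.region_spacing + 1000
        rows.append(Peak(chrom, start, start + config.region_width,
                         f"region_{i:05d}", 0.0,
                         config.region_width // 2, False))
    return PeakSet.from_peaks(rows, width=config.region_width, label="simulated")


def _truth_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_regions
    n_open = int(round(config.frac_open_per_type * n))
    n_closed = int(round(config.frac_closed_per_type * n))
    n_sh_open = int(round(config.frac_shared_open * n))
    n_sh_closed = int(round(config.frac_shared_closed * n))
    classes = []
    for ct in config.cancer_types:
        classes += [f"open_{ct}"] * n_open + [f"closed_{ct}"] * n_closed
    classes += ["shared_open"] * n_sh_open + ["shared_closed"] * n_sh_closed
    n_bg = n - len(classes)
    classes += ["background_open"] * (n_bg // 2)
    classes += ["background_closed"] * (n_bg - n_bg // 2)
    classes = np.asarray(classes, dtype=object)
    rng.shuffle(classes)
    truth = pd.DataFrame({
        "region_id": [f"region_{i:05d}" for i in range(n)],
        "class": classes,
    }).set_index("region_id")
    blood_open = np.isin(classes, ["background_open", "shared_closed"]) \
        | np.char.startswith(classes.astype(str), "closed_")
    truth["blood_open"] = blood_open
    truth["target_type"] = [c.split("_", 1)[1]
                            if c.startswith(("open_", "closed_")) else ""
                            for c in classes]
    return truth


def _mean_for_label(truth: pd.DataFrame, label: str,
                    config: SimulationConfig) -> np.ndarray:
    """Expected raw count per region for a sample group label."""
    lo, hi = config.base_mean, config.open_mean
    cls = truth["class"].to_numpy(dtype=str)
    if label in BLOOD_CELL_TYPES:
        return np.where(truth["blood_open"].to_numpy(), hi, lo)
    mu = np.full(len(truth), lo)
    mu[cls == "background_open"] = hi
    mu[cls == "shared_open"] = hi
    mu[cls == f"open_{label}"] = hi
    # cancer-specifically closed regions are open everywhere except the target
    closed_mask = np.char.startswith(cls, "closed_")
    mu[closed_mask & (cls != f"closed_{label}")] = hi
    mu[cls == "shared_closed"] = lo
    return mu


def _nb_draw(rng: np.random.Generator, mu: np.ndarray,
             alpha: float) -> np.ndarray:
    n_param = 1.0 / alpha
    p = 1.0 / (1.0 + alpha * np.maximum(mu, 1e-9))
    return rng.negative_binomial(n_param, p)


def simulate_atac(config: SimulationConfig):
    """Simulate regions, a raw count matrix and the planted truth table.

    Returns ``(regions, CountMatrix, truth)``. Samples comprise
    ``samples_per_type`` per cancer type plus ``blood_samples_per_celltype``
    for each of PBMC and neutrophils. Library sizes vary uniformly by ~1.3x.
    """
    rng = np.random.default_rng(config.seed)
    regions = _region_layout(config)
    truth = _truth_table(config, rng)
    labels, sample_ids, cols = [], [], []
    groups = [(ct, config.samples_per_type) for ct in config.cancer_types]
    groups += [(bt, config.blood_samples_per_celltype) for bt in BLOOD_CELL_TYPES]
    for label, n_samples in groups:
        mu = _mean_for_label(truth, label, config)
        for k in range(n_samples):
            lib = rng.uniform(0.7, 1.3)
            cols.append(_nb_draw(rng, mu * lib, config.dispersion))
            sample_ids.append(f"{label}_s{k:02d}")
            labels.append(label)
    counts = pd.DataFrame(np.column_stack(cols), index=truth.index,
                          columns=sample_ids).astype(np.int64)
    meta = pd.Series(labels, index=sample_ids, name="label")
    return regions, CountMatrix(counts, meta, "raw"), truth


def simulate_blood_peaksets(regions: PeakSet, truth: pd.DataFrame,
                            config: SimulationConfig,
                            detect_prob: float = 0.95,
                            n_private: int = 30) -> dict[str, list[PeakSet]]:
    """Per-sample blood peak calls: reproducible peaks at blood-open regions
    plus sample-private noise peaks, as summit-extended fixed-width intervals.
    """
    rng = np.random.default_rng(config.seed + 1)
    flank = (config.region_width - 1) // 2
    open_df = regions.df[truth["blood_open"].to_numpy()]
    out: dict[str, list[PeakSet]] = {}
    per_chrom = -(-config.n_regions // config.n_chroms)
    chrom_len = per_chrom * config.region_spacing + 10000
    for cell_type in BLOOD_CELL_TYPES:
        sets = []
        for _s in range(config.blood_samples_per_celltype):
            rows = []
            for r in open_df.itertuples(index=False):
                if rng.random() > detect_prob:
                    continue
                score = rng.gamma(20.0, 10.0)  # strong, well above threshold
                summit = r.start + flank
                rows.append(Peak(r.chrom, summit - flank, summit + flank + 1,
                                 r.name, score, flank, False))
            for _k in range(n_private):  # private noise peaks between regions
                chrom = f"chr{rng.integers(1, config.n_chroms + 1)}"
                summit = int(rng.integers(flank, chrom_len - flank))
                rows.append(Peak(chrom, summit - flank, summit + flank + 1,
                                 f"private_{_s}_{_k}", rng.gamma(2.0, 3.0),
                                 flank, False))
            sets.append(PeakSet.from_peaks(rows, width=config.region_width,
                                           label=cell_type))
        out[cell_type] = sets
    return out


def simulate_cfdna(regions: PeakSet, accessibility: pd.Series,
                   config: SimulationConfig,
                   tumor_accessibility: pd.Series | None = None,
                   rng: np.random.Generator | None = None):
    """Simulate a cfDNA fragment set whose depth and length track accessibility.

    Expected per-region fragment count decreases monotonically from
    ``base_depth * depth_ratio_closed_over_open`` (least accessible) to
    ``base_depth`` (most accessible); fragment lengths are Gaussian with
    means interpolated between the closed and open parameters, truncated at
    50 bp. When ``tumor_accessibility`` is given, effective accessibility is
    the ``tumor_fraction`` mixture of tumor and blood accessibility.
    Returns ``(fragments dataframe, total fragment count)``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    a = accessibility.to_numpy(dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("accessibility must be finite")
    if tumor_accessibility is not None:
        a = (1.0 - config.tumor_fraction) * a \
            + config.tumor_fraction * tumor_accessibility.to_numpy(dtype=float)
    lo, hi = float(a.min()), float(a.max())
    a_norm = (a - lo) / (hi - lo) if hi > lo else np.full_like(a, 0.5)
    lam = config.base_depth * config.depth_ratio_closed_over_open ** (1.0 - a_norm)
    len_mean = (config.frag_len_open[0] * a_norm
                + config.frag_len_closed[0] * (1.0 - a_norm))
    len_sd = (config.frag_len_open[1] * a_norm
              + config.frag_len_closed[1] * (1.0 - a_norm))
    counts = rng.poisson(lam)
    rows = []
    rdf = regions.df
    for i, r in enumerate(rdf.itertuples(index=False)):
        k = int(counts[i])
        if not k:
            continue
        lengths = np.maximum(
            np.rint(rng.normal(len_mean[i], len_sd[i], size=k)), 50).astype(int)
        mids = rng.integers(r.start, r.end, size=k)
        starts = np.maximum(mids - lengths // 2, 0)
        for s, ln in zip(starts, lengths):
            rows.append((r.chrom, int(s), int(s + ln)))
    frags = fragments_frame(rows)
    return frags, len(frags)


def simulate_variant_cohort(regions: PeakSet, track: ScoreTrack,
                            config: SimulationConfig, n_variants: int = 120,
                            rng: np.random.Generator | None = None):
    """Paired tumor/cfDNA variant tables with score-sign-dependent AF noise.

    Half the variants are placed in peaks with clearly negative score and
    half in clearly positive peaks. Tumor AF is uniform in [0.02, 0.18];
    cfDNA AF adds Gaussian noise with sd ``af_noise_sd_neg`` or
    ``af_noise_sd_pos`` by peak score sign. A ``variant_fail_fraction`` of
    records is planted to fail each quality filter. Returns
    ``(tumor_df, cfdna_df, truth_df)``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    score = track.score.to_numpy()
    neg_idx = np.nonzero(score < -0.5)[0]
    pos_idx = np.nonzero(score > 0.5)[0]
    if len(neg_idx) == 0 or len(pos_idx) == 0:
        raise ValueError("score track lacks clearly negative or positive regions")
    half = n_variants // 2
    chosen = np.concatenate([
        rng.choice(neg_idx, size=half, replace=len(neg_idx) < half),
        rng.choice(pos_idx, size=n_variants - half,
                   replace=len(pos_idx) < n_variants - half),
    ])
    bases = np.array(list("ACGT"))
    t_rows, c_rows, truth_rows = [], [], []
    rdf = regions.df
    for j, i in enumerate(chosen):
        r = rdf.iloc[i]
        pos = int((r["start"] + r["end"]) // 2) + 1  # 1-based
        ref, alt = rng.choice(bases, size=2, replace=False)
        sgn = "neg" if score[i] < 0 else "pos"
        sd = config.af_noise_sd_neg if sgn == "neg" else config.af_noise_sd_pos
        t_af = rng.uniform(0.02, 0.18)
        c_af = float(np.clip(t_af + rng.normal(0.0, sd), 0.0, 1.0))

        def qual():
            depth = int(rng.integers(20, 200))
            mmq, mbq = 60.0, 30.0
            if rng.random() < config.variant_fail_fraction:
                which = rng.integers(0, 3)
                if which == 0:
                    depth = int(rng.integers(1, 10))
                elif which == 1:
                    mmq = 30.0
                else:
                    mbq = 10.0
            return depth, mmq, mbq

        td, tmq, tbq = qual()
        cd, cmq, cbq = qual()
        t_rows.append((r["chrom"], pos, ref, alt, round(t_af, 4), td, tmq, tbq))
        c_rows.append((r["chrom"], pos, ref, alt, round(c_af, 4), cd, cmq, cbq))
        truth_rows.append((r["chrom"], pos, ref, alt, r["name"], sgn, sd))
    cols = ["chrom", "pos", "ref", "alt", "af", "depth", "mmq", "mbq"]
    tumor = pd.DataFrame(t_rows, columns=cols)
    cfdna = pd.DataFrame(c_rows, columns=cols)
    truth = pd.DataFrame(truth_rows, columns=["chrom", "pos", "ref", "alt",
                                              "region_id", "score_sign",
                                              "noise_sd"])
    return tumor, cfdna, truth
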