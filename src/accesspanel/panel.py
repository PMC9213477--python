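"""Targeted-panel design workflows.

Two directions are supported: "accessible" panels (regions open in one cancer
type and closed in blood) and "inaccessible" panels (regions closed in the
cancer type but open in blood). Both run the same stages: score filtering,
blood-overlap filtering, differential accessibility at FDR < threshold, and
5-fold cross-validated random-forest / linear-SVM / L1-logistic consensus
feature selection, followed by classifier evaluation on the selected regions.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC
from statsmodels.stats.multitest import multipletests

from .intervals import PeakSet, overlaps_any
from .scoring import CountMatrix, ScoreTrack, cpm_normalize

logger = logging.getLogger(__name__)


@dataclass
class PanelConfig:
    direction: str = "accessible"          # or "inaccessible"
    score_threshold: float = 1.5         # magnitude of the score cutoff
    fdr_threshold: float = 0.01
    n_folds: int = 5
    top_fraction: float = 0.10
    lasso_min_folds: int = 2
    consensus_min_methods: int = 2
    da_method: str = "nb_wald"             # or "ranksum"
    n_estimators: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.direction not in ("accessible", "inaccessible"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if self.consensus_min_methods not in (1, 2, 3):
            raise ValueError("consensus_min_methods must be 1, 2 or 3")


@dataclass
class SelectionResult:
    """Consensus-selected features plus the per-fold evidence behind them."""

    selected: list
    rf_set: set
    svm_set: set
    lasso_set: set
    fold_rf_importances: pd.DataFrame   # folds x features
    fold_svm_coefs: pd.DataFrame
    fold_lasso_coefs: pd.DataFrame


@dataclass
class Panel:
    cancer_type: str
    direction: str
    regions: PeakSet
    provenance: pd.DataFrame
    classifier_metrics: pd.DataFrame
    stage_log: list[dict] = field(default_factory=list)


def filter_by_score(track: ScoreTrack, config: PanelConfig) -> np.ndarray:
    """Boolean mask of regions passing the score filter.

    Accessible panels keep score >= +threshold ("filtered out peaks with
    score less than the threshold"); inaccessible panels keep score strictly
    below -threshold.
    """
    s = track.score.to_numpy()
    if config.direction == "accessible":
        return s >= config.score_threshold
    return s < -config.score_threshold


def blood_overlap_filter(regions: PeakSet, blood: PeakSet, direction: str) -> np.ndarray:
    """Boolean mask implementing the blood-overlap rule for each direction.

    Accessible panels must avoid blood-open chromatin (keep non-overlapping
    regions); inaccessible panels target it (keep overlapping regions).
    """
    hits = overlaps_any(regions, blood)
    return ~hits if direction == "accessible" else hits


def _nb_wald(tumor: np.ndarray, blood: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-region negative-binomial Wald test on library-size-normalized counts.

    Dispersion alpha (variance = mu + alpha * mu^2) is estimated per region by
    method of moments pooled across the two groups; the Wald statistic
    compares log group means with delta-method standard errors. Returns
    (log2 fold change tumor-over-blood, two-sided p-value).
    """
    eps = 0.5  # pseudo-cpm guarding log of empty regions
    n_t, n_b = tumor.shape[1], blood.shape[1]
    mu_t = tumor.mean(axis=1)
    mu_b = blood.mean(axis=1)
    var_t = tumor.var(axis=1, ddof=1)
    var_b = blood.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_t = (var_t - mu_t) / np.square(mu_t)
        a_b = (var_b - mu_b) / np.square(mu_b)
    a_t = np.nan_to_num(a_t, nan=0.0, posinf=0.0)
    a_b = np.nan_to_num(a_b, nan=0.0, posinf=0.0)
    alpha = np.clip(((n_t - 1) * a_t + (n_b - 1) * a_b) / (n_t + n_b - 2), 0.0, None)
    log2fc = np.log2((mu_t + eps) / (mu_b + eps))
    se2 = (1.0 / (mu_t + eps) + alpha) / n_t + (1.0 / (mu_b + eps) + alpha) / n_b
    z = (np.log(mu_t + eps) - np.log(mu_b + eps)) / np.sqrt(se2)
    pvals = 2.0 * stats.t.sf(np.abs(z), df=n_t + n_b - 2)
    return log2fc, pvals


def _ranksum(tumor: np.ndarray, blood: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    eps = 0.5
    log2fc = np.log2((tumor.mean(axis=1) + eps) / (blood.mean(axis=1) + eps))
    res = stats.mannwhitneyu(tumor, blood, axis=1, alternative="two-sided")
    return log2fc, res.pvalue


def differential_accessibility(tumor: CountMatrix, blood: CountMatrix,
                               fdr_threshold: float = 0.01,
                               method: str = "nb_wald") -> pd.DataFrame:
    """Two-group differential accessibility test with BH correction.

    Counts are cpm-normalized (library-size offset) before testing; the fold
    change is oriented tumor-over-blood. Returns a per-region table with
    columns log2fc, pvalue, qvalue, significant.
    """
    if tumor.counts.shape[1] < 2 or blood.counts.shape[1] < 2:
        raise ValueError("need at least 2 samples per group")
    if not tumor.region_ids.equals(blood.region_ids):
        raise ValueError("tumor and blood matrices have mismatched region indices")
    t = cpm_normalize(tumor).counts.to_numpy() if tumor.normalized == "raw" else tumor.counts.to_numpy()
    b = cpm_normalize(blood).counts.to_numpy() if blood.normalized == "raw" else blood.counts.to_numpy()
    if method == "nb_wald":
        log2fc, pvals = _nb_wald(t, b)
    elif method == "ranksum":
        log2fc, pvals = _ranksum(t, b)
    else:
        raise ValueError(f"unknown method {method!r}")
    pvals = np.clip(np.nan_to_num(pvals, nan=1.0), 0.0, 1.0)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return pd.DataFrame({
        "log2fc": log2fc,
        "pvalue": pvals,
        "qvalue": qvals,
        "significant": qvals < fdr_threshold,
    }, index=tumor.region_ids)


def consensus_from_fold_outputs(rf_imp: pd.DataFrame, svm_coef: pd.DataFrame,
                                lasso_coef: pd.DataFrame,
                                config: PanelConfig) -> tuple[list, set, set, set]:
    """Apply the top-10% / non-zero / >=k-fold / >=2-of-3 rules to fold outputs.

    Kept separate from the model fitting so the rule can be re-applied to
    logged importances and coefficients.
    """
    features = rf_imp.columns
    p = len(features)
    k = math.ceil(config.top_fraction * p)
    rf_mean = rf_imp.mean(axis=0)
    rf_top = rf_mean.to_numpy().argsort(kind="stable")[::-1][:k]
    rf_set = {features[i] for i in rf_top if rf_mean.iloc[i] > 0}
    svm_mean = svm_coef.mean(axis=0).abs()
    svm_top = svm_mean.to_numpy().argsort(kind="stable")[::-1][:k]
    svm_set = {features[i] for i in svm_top}
    nonzero_folds = (lasso_coef != 0).sum(axis=0)
    lasso_set = set(features[nonzero_folds >= config.lasso_min_folds])
    votes = pd.Series(0, index=features)
    for sel in (rf_set, svm_set, lasso_set):
        votes.loc[list(sel)] += 1
    selected = [f for f in features if votes[f] >= config.consensus_min_methods]
    return selected, rf_set, svm_set, lasso_set


def select_consensus_features(X: pd.DataFrame, y: np.ndarray,
                              config: PanelConfig) -> SelectionResult:
    """5-fold cross-validated RF / linear-SVM / L1-logistic consensus selection.

    ``X`` is samples x regions of log2(cpm + 1) values, ``y`` binary labels.
    Per fold, the three models are fitted on the training split; features are
    then selected by: top ``top_fraction`` of mean RF importance (non-zero
    only), top ``top_fraction`` of |mean SVM coefficient|, and non-zero
    L1-logistic coefficient in >= ``lasso_min_folds`` folds; the final set is
    features present in >= ``consensus_min_methods`` of those three sets.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("labels contain a single class")
    if min(np.sum(y == c) for c in classes) < config.n_folds:
        raise ValueError("each class needs at least n_folds samples")
    if X.shape[1] < 1:
        raise ValueError("no candidate features")
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                          random_state=config.seed)
    rf_rows, svm_rows, lasso_rows = [], [], []
    for fold, (train, _test) in enumerate(skf.split(X, y)):
        Xtr = X.iloc[train].to_numpy()
        ytr = y[train]
        scaler = StandardScaler().fit(Xtr)
        Xs = scaler.transform(Xtr)

        rf = RandomForestClassifier(n_estimators=config.n_estimators,
                                    random_state=config.seed + fold)
        rf.fit(Xtr, ytr)
        rf_rows.append(rf.feature_importances_)

        svm = LinearSVC(C=1.0, dual="auto", max_iter=20000)
        svm.fit(Xs, ytr)
        svm_rows.append(svm.coef_.ravel())

        lasso = LogisticRegressionCV(penalty="l1", solver="liblinear",
                                     Cs=np.logspace(-2, 2, 8), cv=3,
                                     max_iter=2000, random_state=config.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            lasso.fit(Xs, ytr)
        lasso_rows.append(lasso.coef_.ravel())

    cols = X.columns
    rf_imp = pd.DataFrame(rf_rows, columns=cols)
    svm_coef = pd.DataFrame(svm_rows, columns=cols)
    lasso_coef = pd.DataFrame(lasso_rows, columns=cols)
    selected, rf_set, svm_set, lasso_set = consensus_from_fold_outputs(
        rf_imp, svm_coef, lasso_coef, config)
    return SelectionResult(selected=selected, rf_set=rf_set, svm_set=svm_set,
                           lasso_set=lasso_set, fold_rf_importances=rf_imp,
                           fold_svm_coefs=svm_coef, fold_lasso_coefs=lasso_coef)


def evaluate_panel_classifier(X: pd.DataFrame, y: np.ndarray, features: list,
                              n_folds: int = 5, seed: int = 0,
                              n_estimators: int = 200) -> pd.DataFrame:
    """Stratified k-fold sensitivity/specificity of an RF on the panel regions."""
    if not features:
        raise ValueError("empty feature set")
    y = np.asarray(y)
    Xf = X[list(features)]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    rows = []
    for fold, (train, test) in enumerate(skf.split(Xf, y)):
        clf = RandomForestClassifier(n_estimators=n_estimators,
                                     random_state=seed + fold)
        clf.fit(Xf.iloc[train], y[train])
        pred = clf.predict(Xf.iloc[test])
        truth = y[test]
        tp = np.sum((pred == 1) & (truth == 1))
        fn = np.sum((pred == 0) & (truth == 1))
        tn = np.sum((pred == 0) & (truth == 0))
        fp = np.sum((pred == 1) & (truth == 0))
        rows.append({
            "fold": fold,
            "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
            "specificity": tn / (tn + fp) if tn + fp else np.nan,
        })
    return pd.DataFrame(rows).set_index("fold")


def log2_cpm1(matrix: CountMatrix) -> pd.DataFrame:
    """Samples x regions log2(cpm + 1) classifier input."""
    cpm = matrix.counts if matrix.normalized == "cpm" else cpm_normalize(matrix).counts
    return np.log2(cpm + 1.0).T


def design_panel(track: ScoreTrack, blood_peaks: PeakSet, regions: PeakSet,
                 tumor_counts: CountMatrix, blood_counts: CountMatrix,
                 all_cancer_counts: CountMatrix, cancer_type: str,
                 config: PanelConfig) -> Panel:
    """Run the full panel-design pipeline for one cancer type and direction.

    ``regions`` is the candidate region universe (ids matching the score
    track and all count matrices); ``tumor_counts``/``blood_counts`` are raw
    counts for the differential test; ``all_cancer_counts`` holds every tumor
    sample (all cancer types) for one-vs-rest classification.
    """
    log: list[dict] = []
    universe = track.region_ids

    mask = filter_by_score(track, config)
    log.append({"stage": "score_filter", "n_in": len(universe),
                "n_out": int(mask.sum())})
    surviving = regions.subset(mask)
    ids = universe[mask]

    if len(surviving):
        bmask = blood_overlap_filter(surviving, blood_peaks, config.direction)
        surviving = surviving.subset(bmask)
        ids = ids[bmask]
    log.append({"stage": "blood_overlap_filter", "n_in": int(mask.sum()),
                "n_out": len(ids)})

    if not len(ids):
        logger.warning("panel empty after blood-overlap filter")
        return Panel(cancer_type, config.direction, surviving,
                     pd.DataFrame(), pd.DataFrame(), log)

    # normalize on the full region universe, then subset: library sizes must
    # come from the whole library or uniformly-shifted subsets lose the signal
    tumor_cpm = cpm_normalize(tumor_counts) if tumor_counts.normalized == "raw" else tumor_counts
    blood_cpm = cpm_normalize(blood_counts) if blood_counts.normalized == "raw" else blood_counts
    da = differential_accessibility(
        CountMatrix(tumor_cpm.counts.loc[ids], tumor_cpm.sample_meta, "cpm"),
        CountMatrix(blood_cpm.counts.loc[ids], blood_cpm.sample_meta, "cpm"),
        fdr_threshold=config.fdr_threshold, method=config.da_method)
    da_ids = da.index[da["significant"]]
    log.append({"stage": "differential_accessibility", "n_in": len(ids),
                "n_out": len(da_ids)})
    if not len(da_ids):
        logger.warning("panel empty after differential accessibility")
        empty = surviving.subset(np.zeros(len(surviving), dtype=bool))
        return Panel(cancer_type, config.direction, empty,
                     pd.DataFrame(), pd.DataFrame(), log)

    X = log2_cpm1(all_cancer_counts)[list(da_ids)]
    y = (all_cancer_counts.sample_meta.str.lower()
         == cancer_type.lower()).to_numpy().astype(int)
    sel = select_consensus_features(X, y, config)
    log.append({"stage": "consensus_selection", "n_in": len(da_ids),
                "n_out": len(sel.selected)})

    if sel.selected:
        metrics = evaluate_panel_classifier(X, y, sel.selected,
                                            n_folds=config.n_folds,
                                            seed=config.seed,
                                            n_estimators=config.n_estimators)
    else:
        metrics = pd.DataFrame()

    sel_ids = pd.Index(sel.selected)
    keep = np.asarray([rid in set(sel_ids) for rid in ids])
    panel_regions = surviving.subset(keep)
    prov = pd.DataFrame({
        "region_id": sel_ids,
        "score": track.score.loc[sel_ids].to_numpy(),
        "log2fc": da.loc[sel_ids, "log2fc"].to_numpy(),
        "qvalue": da.loc[sel_ids, "qvalue"].to_numpy(),
        "rf_selected": [f in sel.rf_set for f in sel_ids],
        "svm_selected": [f in sel.svm_set for f in sel_ids],
        "lasso_selected": [f in sel.lasso_set for f in sel_ids],
    }).set_index("region_id")
    prov["n_methods"] = prov[["rf_selected", "svm_selected",
                              "lasso_selected"]].sum(axis=1)
    return Panel(cancer_type, config.direction, panel_regions, prov, metrics, log)
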