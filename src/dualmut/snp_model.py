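"""Germline constraint model: random-forest regression of rare-SNP ratio.

The model regresses the per-combination rare-SNP ratio (number of rare SNPs
over total SNPs, the purifying-selection signal) on binary feature
indicators, one row per feature combination.  Rows are weighted by their SNP
count by default — a ratio estimated from 12 SNPs is far noisier than one
from 12,000 — with unweighted fitting available.  The *SNP score* of a
position is the forest's predicted rare-SNP ratio for the position's feature
bitmask, clamped to [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .features import CombinationMatrix, indicator_matrix, segment_partition
from .genome import GenomeModel
from .intervals import FeatureTrack
from .selection import SelectionReport, two_phase_select

N_TREES_DEFAULT = 500
MIN_FIT_ROWS = 20


@dataclass
class SnpModelFit:
    feature_names: list[str]          # full catalogue order (bitmask bit order)
    selected_features: list[str]
    forest: RandomForestRegressor
    importances: dict[str, float]     # node-purity decrease, selected only
    oob_r2: float
    seed: int
    weighted: bool

    @property
    def selected_idx(self) -> list[int]:
        return [self.feature_names.index(f) for f in self.selected_features]


def select_features(
    matrix: CombinationMatrix, seed: int, **kwargs
) -> SelectionReport:
    """Two-phase (decoy threshold + backward elimination) feature selection
    on the combination matrix, rows weighted by SNP count."""
    frame = matrix.fit_frame()
    if len(matrix.feature_names) < 2:
        raise ValueError("need at least 2 candidate features")
    if len(frame) < MIN_FIT_ROWS:
        raise ValueError(f"only {len(frame)} fitted rows; need >= {MIN_FIT_ROWS}")
    return two_phase_select(
        matrix.design(frame),
        frame["rare_ratio"].to_numpy(),
        matrix.feature_names,
        sample_weight=frame["n_snp"].to_numpy(dtype=float),
        seed=seed,
        **kwargs,
    )


def fit_snp_model(
    matrix: CombinationMatrix,
    features: list[str] | None = None,
    weighted: bool = True,
    seed: int = 0,
    n_trees: int = N_TREES_DEFAULT,
    max_features: int | None = None,
) -> SnpModelFit:
    """Fit the forest on retained combination rows.

    *features* restricts the design to a selected subset (defaults to the
    full catalogue); *max_features* defaults to ceil(K/3), the regression
    convention.
    """
    # canonical row order: predictions must not depend on how rows were supplied
    frame = matrix.fit_frame().sort_values("bitmask").reset_index(drop=True)
    if len(frame) < MIN_FIT_ROWS:
        raise ValueError(f"only {len(frame)} rows after filtering; need >= {MIN_FIT_ROWS}")
    features = list(matrix.feature_names) if features is None else list(features)
    idx = [matrix.feature_names.index(f) for f in features]
    X = matrix.design(frame)[:, idx]
    y = frame["rare_ratio"].to_numpy()
    w = frame["n_snp"].to_numpy(dtype=float) if weighted else None
    if max_features is None:
        max_features = max(1, math.ceil(len(features) / 3))
    rf = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=max_features,
        random_state=seed,
        oob_score=True,
        n_jobs=1,
    )
    rf.fit(X, y, sample_weight=w)
    # weighted OOB R²: the unweighted score is dominated by rows whose ratio
    # rests on a handful of SNPs
    oob = rf.oob_prediction_
    ok = np.isfinite(oob)
    wk = np.ones(ok.sum()) if w is None else w[ok]
    ybar = np.average(y[ok], weights=wk)
    ss_res = np.average((y[ok] - oob[ok]) ** 2, weights=wk)
    ss_tot = np.average((y[ok] - ybar) ** 2, weights=wk)
    oob_r2 = float(1.0 - ss_res / ss_tot) if ss_tot > 0 else 0.0
    importances = dict(zip(features, rf.feature_importances_))
    return SnpModelFit(
        feature_names=list(matrix.feature_names),
        selected_features=features,
        forest=rf,
        importances={k: float(v) for k, v in importances.items()},
        oob_r2=oob_r2,
        seed=seed,
        weighted=weighted,
    )


def predict_snp_score(fit: SnpModelFit, bitmasks) -> np.ndarray:
    """SNP score per feature bitmask: predicted rare-SNP ratio in [0, 1].

    Identical bitmasks necessarily receive identical scores — the design row
    is a pure function of the bitmask.
    """
    bm = np.atleast_1d(np.asarray(bitmasks, dtype=np.int64))
    uniq, inv = np.unique(bm, return_inverse=True)
    X = indicator_matrix(uniq, len(fit.feature_names))[:, fit.selected_idx]
    pred = np.clip(fit.forest.predict(X), 0.0, 1.0)
    return pred[inv]


def score_positions(
    fit: SnpModelFit,
    chrom_arr,
    pos_arr,
    tracks: list[FeatureTrack],
    genome: GenomeModel,
    coding_mask: FeatureTrack | None = None,
) -> np.ndarray:
    """Per-position SNP score; NaN for positions in coding/excluded regions."""
    coding_mask = coding_mask or FeatureTrack("coding")
    chrom_arr = np.asarray(chrom_arr, dtype=object)
    pos_arr = np.asarray(pos_arr, dtype=np.int64)
    out = np.full(len(pos_arr), np.nan)
    for chrom in pd.unique(chrom_arr):
        sel = chrom_arr == chrom
        pos = pos_arr[sel]
        masks = np.zeros(len(pos), dtype=np.int64)
        for k, t in enumerate(tracks):
            masks |= t.contains(chrom, pos).astype(np.int64) << k
        blocked = coding_mask.contains(chrom, pos) | genome.excluded.contains(chrom, pos)
        scores = predict_snp_score(fit, masks)
        scores[blocked] = np.nan
        out[sel] = scores
    return out


def piecewise_to_bins(
    cuts: np.ndarray,
    values: np.ndarray,
    valid: np.ndarray,
    length: int,
    bin_bp: int,
) -> np.ndarray:
    """Average a piecewise-constant function onto a bin grid.

    Segment i = [cuts[i], cuts[i+1]) carries *values[i]* where *valid[i]*;
    each bin's score is the value mean over its valid bp, NaN when the bin
    contains no valid bp. Trailing partial bins are dropped.
    """
    n_bins = length // bin_bp
    edges = np.arange(n_bins + 1, dtype=np.int64) * bin_bp
    seg_len = np.diff(cuts).astype(float)
    contrib = np.where(valid, values, 0.0) * seg_len
    vlen = np.where(valid, seg_len, 0.0)
    cum_w = np.concatenate([[0.0], np.cumsum(contrib)])
    cum_l = np.concatenate([[0.0], np.cumsum(vlen)])

    j = np.searchsorted(cuts, edges, side="right") - 1
    j = np.clip(j, 0, len(seg_len) - 1)
    frac = (edges - cuts[j]).astype(float)
    w_at = cum_w[j] + np.where(valid[j], values[j], 0.0) * frac
    l_at = cum_l[j] + np.where(valid[j], 1.0, 0.0) * frac
    num = np.diff(w_at)
    den = np.diff(l_at)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
    return out


def snp_score_bins(
    fit: SnpModelFit,
    genome: GenomeModel,
    tracks: list[FeatureTrack],
    coding_mask: FeatureTrack | None = None,
    bin_bp: int = 1_000,
) -> dict[str, np.ndarray]:
    """Genome-wide SNP score averaged onto 1 kb bins.

    A bin's score is the length-weighted mean of its segment scores over
    analyzed (non-coding, non-excluded) bp; bins with no analyzed bp are NaN.
    """
    coding_mask = coding_mask or FeatureTrack("coding")
    out = {}
    aug = tracks + [coding_mask, genome.excluded]
    k_real = len(tracks)
    for chrom, length in genome.chromosomes:
        cuts, masks = segment_partition(genome, aug, chrom)
        analyzed = (masks >> k_real) == 0
        real = masks & ((1 << k_real) - 1)
        scores = predict_snp_score(fit, real)
        out[chrom] = piecewise_to_bins(cuts, scores, analyzed, length, bin_bp)
    return out


def crossval_correlation(
    matrix: CombinationMatrix,
    features: list[str] | None = None,
    weighted: bool = True,
    seed: int = 0,
    n_folds: int = 10,
    n_trees: int = 200,
) -> float:
    """Held-out calibration: K-fold CV over combinations, weighted Pearson r
    between out-of-fold predictions and observed rare ratios.

    The weighted OOB R² can be strongly negative even for a well-calibrated
    model, because the background combination carries most of the weight and
    is unpredictable when left out; the CV correlation is the metric that
    reflects how well the forest ranks combinations.
    """
    frame = matrix.fit_frame().sort_values("bitmask").reset_index(drop=True)
    features = list(matrix.feature_names) if features is None else list(features)
    idx_cols = [matrix.feature_names.index(f) for f in features]
    X = matrix.design(frame)[:, idx_cols]
    y = frame["rare_ratio"].to_numpy()
    w = frame["n_snp"].to_numpy(dtype=float) if weighted else np.ones(len(y))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    pred = np.full(len(y), np.nan)
    for fold in np.array_split(order, n_folds):
        mask = np.ones(len(y), dtype=bool)
        mask[fold] = False
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=max(1, math.ceil(len(features) / 3)),
            random_state=seed,
            n_jobs=1,
        )
        rf.fit(X[mask], y[mask], sample_weight=w[mask])
        pred[fold] = np.clip(rf.predict(X[fold]), 0.0, 1.0)
    mp = np.average(pred, weights=w)
    my = np.average(y, weights=w)
    cov = np.average((pred - mp) * (y - my), weights=w)
    return float(
        cov
        / np.sqrt(
            np.average((pred - mp) ** 2, weights=w)
            * np.average((y - my) ** 2, weights=w)
        )
    )


def report_importance(fit: SnpModelFit) -> pd.DataFrame:
    """Ranked node-purity-decrease importance table (descending)."""
    df = pd.DataFrame(
        {"feature": list(fit.importances), "importance": list(fit.importances.values())}
    )
    return df.sort_values("importance", ascending=False).reset_index(drop=True)
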