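"""Two-phase random-forest feature selection.

A documented substitute for interpretation-oriented wrapper selection:

1. *Decoy thresholding* — the design matrix is augmented with shuffled decoy
   copies of real columns; over R repeated forests the mean permutation
   importance of each real feature is compared with the largest mean decoy
   importance, and features at or below that noise floor are discarded.
2. *Backward elimination* — surviving features are ranked by importance and
   nested head subsets are refit; the smallest subset whose out-of-bag error
   is within one standard error of the best subset's error is returned.

Deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance


@dataclass
class SelectionReport:
    selected: list[str]
    mean_importance: dict[str, float]
    decoy_threshold: float
    oob_errors: dict[int, float]  # subset size -> weighted OOB MSE


def _weighted_mse(y, pred, w):
    err = (y - pred) ** 2
    return float(np.average(err, weights=w))


def _oob_error_and_se(rf, X, y, w) -> tuple[float, float]:
    pred = rf.oob_prediction_
    ok = np.isfinite(pred)
    err = (y[ok] - pred[ok]) ** 2
    wk = w[ok]
    mse = float(np.average(err, weights=wk))
    var = float(np.average((err - mse) ** 2, weights=wk))
    return mse, np.sqrt(var / max(ok.sum(), 1))


def two_phase_select(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    sample_weight: np.ndarray | None = None,
    seed: int = 0,
    n_repeats: int = 5,
    n_decoys: int = 5,
    n_trees: int = 300,
    se_rule: float = 1.0,
) -> SelectionReport:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if k < 1:
        raise ValueError("no candidate features")
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(11,)))

    # ---- phase 1: decoy-thresholded permutation importance ---------------
    real_imps = np.zeros((n_repeats, k))
    decoy_imps = np.zeros((n_repeats, n_decoys))
    for r in range(n_repeats):
        cols = rng.integers(0, k, size=n_decoys)
        decoys = np.column_stack([rng.permutation(X[:, c]) for c in cols])
        Xa = np.hstack([X, decoys])
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        )
        rf.fit(Xa, y, sample_weight=w)
        pi = permutation_importance(
            rf,
            Xa,
            y,
            n_repeats=5,
            random_state=int(rng.integers(0, 2**31 - 1)),
            sample_weight=w,
        )
        real_imps[r] = pi.importances_mean[:k]
        decoy_imps[r] = pi.importances_mean[k:]
    mean_real = real_imps.mean(axis=0)
    threshold = float(decoy_imps.mean(axis=0).max()) if n_decoys else 0.0
    surviving = [i for i in range(k) if mean_real[i] > threshold]
    if not surviving:
        raise ValueError(
            "all features fell below the decoy importance threshold "
            f"({threshold:.4g}); review thresholds or supply stronger features"
        )

    # ---- phase 2: backward elimination with the 1-SE rule ----------------
    order = sorted(surviving, key=lambda i: -mean_real[i])
    oob_errors: dict[int, float] = {}
    ses: dict[int, float] = {}
    for m in range(1, len(order) + 1):
        idx = order[:m]
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            random_state=int(rng.integers(0, 2**31 - 1)),
            oob_score=True,
            bootstrap=True,
            n_jobs=1,
        )
        rf.fit(X[:, idx], y, sample_weight=w)
        oob_errors[m], ses[m] = _oob_error_and_se(rf, X[:, idx], y, w)
    best_m = min(oob_errors, key=oob_errors.get)
    cut = oob_errors[best_m] + se_rule * ses[best_m]
    chosen_m = min(m for m in oob_errors if oob_errors[m] <= cut)
    selected_idx = sorted(order[:chosen_m])
    return SelectionReport(
        selected=[feature_names[i] for i in selected_idx],
        mean_importance={feature_names[i]: float(mean_real[i]) for i in range(k)},
        decoy_threshold=threshold,
        oob_errors=oob_errors,
    )
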