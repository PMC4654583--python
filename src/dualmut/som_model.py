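"""Somatic constraint model: per-cancer random forest on 1 Mb windows.

The response is the pooled somatic mutation count per retained 1 Mb window
(equivalently mutations/Mb, windows being constant-size); predictors are
ln(x+1)-scaled feature coverages and window means.  Genome-wide scoring
slides the 1 Mb window across each chromosome at a 1 kb step, predicts the
density for every valid offset, and averages the predictions of all valid
covering windows onto 1 kb bins — the *SOM score*.  Dividing by the patient
count converts the pooled score to mutations/Mb/patient at reporting time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .features import SOM_WINDOW_BP, WindowMatrix, window_predictors
from .genome import GenomeModel
from .intervals import FeatureTrack
from .selection import SelectionReport, two_phase_select
from .variants import VariantSet

N_TREES_DEFAULT = 500
MIN_FIT_WINDOWS = 20
STEP_BP = 1_000


@dataclass
class SomModelFit:
    cancer_label: str
    feature_names: list[str]      # training catalogue
    selected_features: list[str]
    forest: RandomForestRegressor
    n_patients: int
    oob_r2: float
    seed: int
    window_bp: int = SOM_WINDOW_BP
    log_transformed: bool = True
    selection: SelectionReport | None = None


def fit_som_model(
    window_matrix: WindowMatrix,
    seed: int = 0,
    cancer_label: str = "synthetic",
    n_patients: int = 1,
    select: bool = True,
    n_trees: int = N_TREES_DEFAULT,
    **select_kwargs,
) -> SomModelFit:
    """Fit (optionally after two-phase feature selection) the window forest."""
    df = window_matrix.df
    if len(df) < MIN_FIT_WINDOWS:
        raise ValueError(f"only {len(df)} retained windows; need >= {MIN_FIT_WINDOWS}")
    y = window_matrix.response
    if not np.any(y > 0):
        raise ValueError("all-zero mutation response: no somatic mutations supplied")
    names = list(window_matrix.feature_names)
    report = None
    if select and len(names) >= 2:
        report = two_phase_select(
            window_matrix.design(), y, names, seed=seed, **select_kwargs
        )
        names = report.selected
    X = df[names].to_numpy(dtype=float)
    rf = RandomForestRegressor(
        n_estimators=n_trees, random_state=seed, oob_score=True, n_jobs=1
    )
    rf.fit(X, y)
    return SomModelFit(
        cancer_label=cancer_label,
        feature_names=list(window_matrix.feature_names),
        selected_features=names,
        forest=rf,
        n_patients=n_patients,
        oob_r2=float(rf.oob_score_),
        seed=seed,
        window_bp=window_matrix.window_bp,
        log_transformed=window_matrix.log_transformed,
        selection=report,
    )


@dataclass
class ScoredTrack:
    """Per-1 kb-bin SNP and SOM scores with region labels.

    Bins tile each chromosome without overlap (trailing partial bins are not
    represented). ``label`` is one of hypomutated / hypermutated / other /
    unscored; any bin missing either score stays unscored.
    """

    df: pd.DataFrame  # chrom, start, snp_score, som_score, label
    bin_bp: int
    genome: GenomeModel

    @classmethod
    def empty(cls, genome: GenomeModel, bin_bp: int = STEP_BP) -> "ScoredTrack":
        frames = []
        for chrom, length in genome.chromosomes:
            n = length // bin_bp
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": np.arange(n, dtype=np.int64) * bin_bp,
                        "snp_score": np.nan,
                        "som_score": np.nan,
                        "label": "unscored",
                    }
                )
            )
        return cls(pd.concat(frames, ignore_index=True), bin_bp, genome)

    def set_channel(self, channel: str, per_chrom: dict[str, np.ndarray]) -> None:
        assert channel in ("snp_score", "som_score")
        for chrom, values in per_chrom.items():
            sel = self.df["chrom"] == chrom
            n = int(sel.sum())
            self.df.loc[sel, channel] = values[:n]

    def scored_mask(self) -> np.ndarray:
        return (
            self.df["snp_score"].notna().to_numpy()
            & self.df["som_score"].notna().to_numpy()
        )

    def bin_index(self, chrom_arr, pos_arr) -> np.ndarray:
        """Row index of the bin containing each position (-1 if unbinned)."""
        chrom_arr = np.asarray(chrom_arr, dtype=object)
        pos_arr = np.asarray(pos_arr, dtype=np.int64)
        out = np.full(len(pos_arr), -1, dtype=np.int64)
        offsets = {}
        base = 0
        for chrom, length in self.genome.chromosomes:
            offsets[chrom] = (base, length // self.bin_bp)
            base += length // self.bin_bp
        for chrom in pd.unique(chrom_arr):
            if chrom not in offsets:
                continue
            start, n = offsets[chrom]
            sel = chrom_arr == chrom
            b = pos_arr[sel] // self.bin_bp
            idx = np.where(b < n, start + b, -1)
            out[sel] = idx
        return out


def sliding_som_score(
    fit: SomModelFit,
    tracks: list[FeatureTrack],
    genome: GenomeModel,
    step_bp: int = STEP_BP,
    per_patient: bool = False,
) -> dict[str, np.ndarray]:
    """1 kb-resolution SOM score via sliding 1 Mb windows.

    Windows are anchored at offsets 0, step, 2·step, … and never extend past
    the chromosome end; a window is valid iff it does not overlap an
    excluded region (the training exclusion rule, applied at prediction
    time).  Each bin's score is the mean prediction over all valid covering
    windows; bins covered by no valid window are NaN.
    """
    by_name = {t.name: t for t in tracks}
    missing = [f for f in fit.selected_features if f not in by_name]
    if missing:
        raise ValueError(f"feature catalogue mismatch; missing tracks: {missing}")
    use = [by_name[f] for f in fit.selected_features]
    window = fit.window_bp
    win_bins = window // step_bp
    out: dict[str, np.ndarray] = {}
    for chrom, length in genome.chromosomes:
        n_bins = length // step_bp
        if length < window:
            out[chrom] = np.full(n_bins, np.nan)
            continue
        starts = np.arange(0, length - window + 1, step_bp, dtype=np.int64)
        excl = genome.excluded.coverage_before(chrom, starts + window) - \
            genome.excluded.coverage_before(chrom, starts)
        valid = excl == 0
        preds = np.full(len(starts), np.nan)
        if valid.any():
            feats = window_predictors(use, chrom, starts[valid], window)
            X = np.column_stack([feats[f] for f in fit.selected_features])
            if fit.log_transformed:
                X = np.log1p(X)
            preds[valid] = fit.forest.predict(X)
        # rolling mean of the <= win_bins predictions covering each bin
        vals = np.nan_to_num(preds, nan=0.0)
        cnts = valid.astype(float)
        cum_v = np.concatenate([[0.0], np.cumsum(vals)])
        cum_c = np.concatenate([[0.0], np.cumsum(cnts)])
        b = np.arange(n_bins)
        lo = np.clip(b - win_bins + 1, 0, len(starts))
        hi = np.clip(b + 1, 0, len(starts))
        tot = cum_v[hi] - cum_v[lo]
        cnt = cum_c[hi] - cum_c[lo]
        with np.errstate(invalid="ignore"):
            score = np.where(cnt > 0, tot / np.maximum(cnt, 1e-300), np.nan)
        if per_patient:
            score = score / fit.n_patients
        out[chrom] = score
    return out


def feature_mutation_density_profile(
    somatic: VariantSet, tracks: list[FeatureTrack], genome: GenomeModel
) -> pd.DataFrame:
    """Relative mutation density per feature, genome average normalized to 1."""
    som = somatic.of_kind("somatic")
    if len(som) == 0:
        raise ValueError("empty somatic variant set")
    genome_rate = len(som) / genome.total_size
    rows = []
    for t in tracks:
        bp = t.total_bp()
        if bp == 0:
            warnings.warn(f"feature {t.name!r} has zero length; skipped")
            continue
        n = 0
        for chrom in [c for c, _ in genome.chromosomes]:
            pos = som.positions(chrom)
            if len(pos):
                n += int(t.contains(chrom, pos).sum())
        rows.append(
            {
                "feature": t.name,
                "n_mutations": n,
                "feature_bp": bp,
                "relative_density": (n / bp) / genome_rate,
            }
        )
    return pd.DataFrame(rows)
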