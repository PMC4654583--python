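"""From raw tracks to model inputs.

Two model-facing structures are built here:

* :class:`CombinationMatrix` — the germline model's unit of analysis. The
  non-coding, non-excluded genome is partitioned into maximal runs of
  constant feature bitmask; each distinct bitmask becomes one row carrying
  its aggregate size and rare/total SNP counts, and rows smaller than a
  minimum aggregate size (default 10 kb) are excluded from fitting.
* :class:`WindowMatrix` — the somatic model's design matrix: one row per
  retained non-overlapping 1 Mb window, predictors = feature coverage (bp)
  or window means (value tracks), transformed x -> ln(x+1); response = raw
  pooled mutation count in the window.

Also here: the derived-feature classifiers (GC / recombination-rate /
methylation highs and lows on a 1 kb grid, replication-timing early/late via
the E/L ratio, RPKM expression classes). All thresholds are strict
inequalities; a value exactly at a threshold falls in no class.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeModel
from .intervals import FeatureTrack, coverage_in_window, mean_value_in_window
from .variants import VariantSet

MIN_COMBINATION_BP = 10_000
SOM_WINDOW_BP = 1_000_000
KB = 1_000


# ---------------------------------------------------------------------------
# genome partition by feature bitmask
# ---------------------------------------------------------------------------

def segment_partition(
    genome: GenomeModel, tracks: list[FeatureTrack], chrom: str
) -> tuple[np.ndarray, np.ndarray]:
    """Changepoints and per-segment feature bitmasks on one chromosome.

    Returns ``(cuts, masks)`` where segment i is ``[cuts[i], cuts[i+1])``
    and ``masks[i]`` has bit k set iff ``tracks[k]`` covers the segment.
    """
    if len(tracks) > 62:
        raise ValueError("at most 62 binary features fit in the bitmask")
    length = genome.lengths[chrom]
    parts = [np.array([0, length], dtype=np.int64)]
    for t in tracks:
        parts.append(np.clip(t.intervals(chrom).ravel(), 0, length))
    cuts = np.unique(np.concatenate(parts))
    seg_starts = cuts[:-1]
    masks = np.zeros(len(seg_starts), dtype=np.int64)
    for k, t in enumerate(tracks):
        masks |= t.contains(chrom, seg_starts).astype(np.int64) << k
    return cuts, masks


def indicator_matrix(bitmasks: np.ndarray, n_features: int) -> np.ndarray:
    """Expand bitmask integers into an (n, K) 0/1 design matrix."""
    bm = np.asarray(bitmasks, dtype=np.int64)
    return ((bm[:, None] >> np.arange(n_features)) & 1).astype(float)


# ---------------------------------------------------------------------------
# combination matrix (germline model input)
# ---------------------------------------------------------------------------

@dataclass
class CombinationMatrix:
    """Aggregate of the analyzed genome by feature-presence bitmask.

    ``df`` columns: bitmask, total_size, n_snp, n_rare, rare_ratio,
    retained (size filter). ``rare_ratio`` is NaN where n_snp = 0.
    """

    df: pd.DataFrame
    feature_names: list[str]
    min_size: int
    analyzed_bp: int
    n_snps_analyzed: int
    n_snps_outside: int = 0

    def fit_frame(self) -> pd.DataFrame:
        """Rows used for model fitting: size filter passed and >= 1 SNP."""
        return self.df[self.df["retained"] & (self.df["n_snp"] > 0)].reset_index(drop=True)

    def design(self, frame: pd.DataFrame | None = None) -> np.ndarray:
        frame = self.fit_frame() if frame is None else frame
        return indicator_matrix(frame["bitmask"].to_numpy(), len(self.feature_names))

    @property
    def global_rare_fraction(self) -> float:
        tot = self.df["n_snp"].sum()
        return float(self.df["n_rare"].sum() / tot) if tot else float("nan")

    def dropped_summary(self) -> dict[str, float]:
        dropped = self.df[~self.df["retained"]]
        return {
            "n_rows_total": int(len(self.df)),
            "n_rows_dropped": int(len(dropped)),
            "dropped_bp_fraction": float(dropped["total_size"].sum() / max(self.analyzed_bp, 1)),
            "dropped_snp_fraction": float(
                dropped["n_snp"].sum() / max(self.df["n_snp"].sum(), 1)
            ),
        }


def build_combination_matrix(
    tracks: list[FeatureTrack],
    snps: VariantSet,
    genome: GenomeModel,
    coding_mask: FeatureTrack | None = None,
    min_size: int = MIN_COMBINATION_BP,
) -> CombinationMatrix:
    """Partition the non-coding, non-excluded genome by feature bitmask and
    aggregate sizes and rare/total SNP counts per distinct bitmask."""
    if not tracks:
        raise ValueError("no feature tracks supplied")
    if coding_mask is None:
        coding_mask = FeatureTrack("coding")
    germ = snps.of_kind("germline")
    genome.validate_positions(germ.df["chrom"].to_numpy(), germ.df["pos"].to_numpy())

    # masking tracks appended after the real features; their bits select
    # segments out of the analysis rather than contributing features
    mask_tracks = [coding_mask, genome.excluded]
    aug = tracks + mask_tracks
    k_real = len(tracks)

    sizes: dict[int, int] = {}
    n_snp: dict[int, int] = {}
    n_rare: dict[int, int] = {}
    analyzed_bp = 0
    n_in = 0
    n_out = 0
    rare_flags_all = germ.is_rare[germ.df["kind"].to_numpy() == "germline"]
    for chrom, _length in genome.chromosomes:
        cuts, masks = segment_partition(genome, aug, chrom)
        seg_len = np.diff(cuts)
        analyzed = (masks >> k_real) == 0  # neither coding nor excluded bit set
        real_masks = masks & ((1 << k_real) - 1)
        for m, l in zip(real_masks[analyzed], seg_len[analyzed]):
            sizes[m] = sizes.get(m, 0) + int(l)
        analyzed_bp += int(seg_len[analyzed].sum())

        sel = germ.df["chrom"].to_numpy() == chrom
        pos = germ.df["pos"].to_numpy()[sel]
        rare = germ.is_rare[sel]
        if len(pos) == 0:
            continue
        seg_idx = np.searchsorted(cuts, pos, side="right") - 1
        ok = analyzed[seg_idx]
        n_out += int((~ok).sum())
        n_in += int(ok.sum())
        for m, r in zip(real_masks[seg_idx[ok]], rare[ok]):
            n_snp[m] = n_snp.get(m, 0) + 1
            n_rare[m] = n_rare.get(m, 0) + int(r)

    bitmasks = sorted(sizes)
    df = pd.DataFrame(
        {
            "bitmask": np.array(bitmasks, dtype=np.int64),
            "total_size": [sizes[m] for m in bitmasks],
            "n_snp": [n_snp.get(m, 0) for m in bitmasks],
            "n_rare": [n_rare.get(m, 0) for m in bitmasks],
        }
    )
    df["rare_ratio"] = np.where(df["n_snp"] > 0, df["n_rare"] / df["n_snp"].clip(lower=1), np.nan)
    df["retained"] = df["total_size"] >= min_size
    return CombinationMatrix(
        df=df,
        feature_names=[t.name for t in tracks],
        min_size=min_size,
        analyzed_bp=analyzed_bp,
        n_snps_analyzed=n_in,
        n_snps_outside=n_out,
    )


# ---------------------------------------------------------------------------
# derived features on the 1 kb grid
# ---------------------------------------------------------------------------

# (low, high): value < low -> "<name>_L", value > high -> "<name>_H"
DEFAULT_THRESHOLDS: dict[str, tuple[float, float]] = {
    "GC": (0.30, 0.50),
    "RR": (0.5, 4.0),
    "met": (0.4062, 0.7245),
}


def classify_derived_features(
    value_tracks: dict[str, FeatureTrack],
    thresholds: dict[str, tuple[float, float]] | None = None,
    grid: int = KB,
) -> dict[str, FeatureTrack]:
    """Binary high/low tracks from 1 kb-gridded value tracks.

    Strict inequalities: a window exactly at a threshold joins neither class.
    """
    thresholds = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    out: dict[str, FeatureTrack] = {}
    for name, track in value_tracks.items():
        if name not in thresholds:
            raise KeyError(f"no thresholds configured for {name!r}")
        low, high = thresholds[name]
        hi_rows, lo_rows = [], []
        for chrom in track.chromosomes:
            iv = track.intervals(chrom)
            if np.any(iv[:, 0] % grid != 0) or np.any((iv[:, 1] - iv[:, 0]) != grid):
                raise ValueError(
                    f"value track {name!r} on {chrom} is not aligned to the {grid} bp grid"
                )
            vals = track.interval_values(chrom)
            for (s, e), v in zip(iv, vals):
                if v > high:
                    hi_rows.append((chrom, int(s), int(e)))
                elif v < low:
                    lo_rows.append((chrom, int(s), int(e)))
        out[f"{name}_H"] = FeatureTrack(f"{name}_H", hi_rows)
        out[f"{name}_L"] = FeatureTrack(f"{name}_L", lo_rows)
    return out


# ---------------------------------------------------------------------------
# replication timing and expression classes
# ---------------------------------------------------------------------------

@dataclass
class ReplicationSignal:
    """Repli-seq cell-cycle fraction signals for one gene in one cell line."""

    g1b: float
    s1: float
    s4: float
    g2: float

    @property
    def el_ratio(self) -> float | None:
        """Early-to-late ratio (G1b+S1)/(S4+G2); None when denominator is 0."""
        denom = self.s4 + self.g2
        if denom <= 0:
            return None
        return (self.g1b + self.s1) / denom


def replication_class(signals: list[ReplicationSignal]) -> str:
    """'early' iff E/L > 1 in every cell line, 'late' iff < 1 in every,
    otherwise 'unclassified' (including any undefined ratio or exact 1)."""
    if not signals:
        raise ValueError("at least one cell line required")
    ratios = [s.el_ratio for s in signals]
    if any(r is None for r in ratios):
        return "unclassified"
    if all(r > 1 for r in ratios):
        return "early"
    if all(r < 1 for r in ratios):
        return "late"
    return "unclassified"


@dataclass
class ExpressionRecord:
    """Per-gene expression summary; RPKM = reads / (exon kb × library millions)."""

    read_count: float
    exon_length_bp: float
    library_size: float
    rpkm_high: float = 20.0
    rpkm_low: float = 0.25

    @property
    def rpkm(self) -> float:
        return self.read_count / ((self.exon_length_bp / 1e3) * (self.library_size / 1e6))

    @property
    def expression_class(self) -> str | None:
        r = self.rpkm
        if r > self.rpkm_high:
            return "HE"
        if r < self.rpkm_low:
            return "LE"
        return None


# ---------------------------------------------------------------------------
# window matrix (somatic model input)
# ---------------------------------------------------------------------------

@dataclass
class WindowMatrix:
    """One row per retained 1 Mb window; ln(x+1) predictors, count response."""

    df: pd.DataFrame  # chrom, start + predictor columns + n_mutations
    feature_names: list[str]
    window_bp: int
    n_windows_excluded: int
    log_transformed: bool = True

    def design(self, frame: pd.DataFrame | None = None) -> np.ndarray:
        frame = self.df if frame is None else frame
        return frame[self.feature_names].to_numpy(dtype=float)

    @property
    def response(self) -> np.ndarray:
        return self.df["n_mutations"].to_numpy(dtype=float)


def window_predictors(
    tracks: list[FeatureTrack], chrom: str, starts: np.ndarray, window_bp: int
) -> dict[str, np.ndarray]:
    """Predictor values for windows [s, s+window) on one chromosome:
    coverage bp for binary tracks, imputed length-weighted means for value
    tracks (zero-coverage windows take the track's genome-wide mean)."""
    out = {}
    ends = starts + window_bp
    for t in tracks:
        if t.is_valued:
            gmean = t.genome_mean()
            cov = t.coverage_before(chrom, ends) - t.coverage_before(chrom, starts)
            wsum = t.weighted_before(chrom, ends) - t.weighted_before(chrom, starts)
            vals = np.where(cov > 0, wsum / np.maximum(cov, 1), gmean)
        else:
            vals = (
                t.coverage_before(chrom, ends) - t.coverage_before(chrom, starts)
            ).astype(float)
        out[t.name] = vals
    return out


def build_window_matrix(
    tracks: list[FeatureTrack],
    somatic: VariantSet,
    genome: GenomeModel,
    window_bp: int = SOM_WINDOW_BP,
    log_transform: bool = True,
) -> WindowMatrix:
    """Non-overlapping windows anchored at 0; windows overlapping excluded
    regions and trailing partial windows are dropped."""
    som = somatic.of_kind("somatic")
    rows = []
    n_excluded = 0
    for chrom, length in genome.chromosomes:
        n_win = length // window_bp
        if n_win == 0:
            warnings.warn(f"{chrom} shorter than the {window_bp} bp window; skipped")
            continue
        starts = np.arange(n_win, dtype=np.int64) * window_bp
        ends = starts + window_bp
        excl_cov = genome.excluded.coverage_before(chrom, ends) - \
            genome.excluded.coverage_before(chrom, starts)
        keep = excl_cov == 0
        n_excluded += int((~keep).sum())
        starts = starts[keep]
        if len(starts) == 0:
            continue
        preds = window_predictors(tracks, chrom, starts, window_bp)
        pos = np.sort(som.positions(chrom))
        counts = np.searchsorted(pos, starts + window_bp) - np.searchsorted(pos, starts)
        frame = pd.DataFrame({"chrom": chrom, "start": starts, **preds})
        frame["n_mutations"] = counts
        rows.append(frame)
    if not rows:
        raise ValueError("no retained windows: genome too small or fully excluded")
    df = pd.concat(rows, ignore_index=True)
    names = [t.name for t in tracks]
    if log_transform:
        df[names] = np.log1p(df[names].to_numpy(dtype=float))
    if not np.isfinite(df[names].to_numpy()).all():
        raise ValueError("non-finite predictor values after log transform")
    return WindowMatrix(
        df=df,
        feature_names=names,
        window_bp=window_bp,
        n_windows_excluded=n_excluded,
        log_transformed=log_transform,
    )
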