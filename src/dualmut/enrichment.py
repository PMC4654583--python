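"""Enrichment of labelled regions in features and gene classes.

Enrichment is the odds ratio (Hf/Sf)/(Hg/Sg): labelled bp within the feature
over feature size, relative to labelled bp genome-wide over analyzed genome
size.  Significance is non-parametric: a position set of the same total size
as the labelled region is drawn at random from the analyzed genome many
times (default 1000) and the per-feature odds ratios recomputed; the min–max
range across permutations is the envelope, and only observed values outside
it are called significant.

Two null-placement modes are provided. *segment* (default) resamples
contiguous segments matching the labelled region's segment-length
distribution, preserving spatial autocorrelation; *bp* scatters independent
bins, a literal reading of "positions randomly sampled" that is
anti-conservative for clustered features.

All bookkeeping happens at the scored track's bin resolution, restricted to
the scored (analyzed) genome, so feature sizes are feature-bp within the
analyzed area — the convention under which a partition of the genome has
area-weighted mean odds ratio exactly 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import FeatureTrack, merge_intervals
from .som_model import ScoredTrack


def odds_ratio(hf: float, sf: float, hg: float, sg: float) -> float:
    """(Hf/Sf) / (Hg/Sg)."""
    if sf <= 0 or sg <= 0:
        raise ValueError("feature and genome sizes must be positive")
    if hg == 0:
        raise ValueError("no labelled positions genome-wide: odds ratio undefined")
    return (hf / sf) / (hg / sg)


@dataclass
class EnrichmentResult:
    feature_name: str
    hf: float
    sf: float
    hg: float
    sg: float
    odds_ratio: float
    env_low: float
    env_high: float
    significant: bool


def label_track(scored: ScoredTrack, label: str = "hypomutated") -> FeatureTrack:
    """Merge same-labelled bins into a feature track of labelled regions."""
    rows = []
    for chrom, sub in scored.df.groupby("chrom", sort=False):
        starts = sub.loc[sub["label"] == label, "start"].to_numpy(dtype=np.int64)
        if len(starts):
            s, e = merge_intervals(starts, starts + scored.bin_bp)
            rows.extend((chrom, int(a), int(b)) for a, b in zip(s, e))
    return FeatureTrack(label, rows)


def _bin_coverage(scored: ScoredTrack, track: FeatureTrack) -> np.ndarray:
    """Feature coverage (bp) of every bin of the scored track."""
    out = np.zeros(len(scored.df))
    for chrom, sub in scored.df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy(dtype=np.int64)
        cov = track.coverage_before(chrom, starts + scored.bin_bp) - \
            track.coverage_before(chrom, starts)
        out[sub.index.to_numpy()] = cov
    return out


def _run_lengths(mask: np.ndarray) -> np.ndarray:
    """Lengths of runs of True in a boolean vector."""
    if not mask.any():
        return np.empty(0, dtype=np.int64)
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return ends - starts


def _sample_null_mask(
    rng: np.random.Generator, n_bins: int, labelled_mask: np.ndarray, mode: str
) -> np.ndarray:
    """A random bin mask with the same number of selected bins."""
    m = int(labelled_mask.sum())
    if mode == "bp":
        idx = rng.choice(n_bins, size=m, replace=False)
        out = np.zeros(n_bins, dtype=bool)
        out[idx] = True
        return out
    if mode != "segment":
        raise ValueError(f"unknown permutation mode {mode!r}")
    runs = np.sort(_run_lengths(labelled_mask))[::-1]
    out = np.zeros(n_bins, dtype=bool)
    for run in runs:
        placed = False
        for _ in range(200):
            start = int(rng.integers(0, n_bins - run + 1))
            if not out[start : start + run].any():
                out[start : start + run] = True
                placed = True
                break
        if not placed:  # dense labelling: fall back to scattering the run
            free = np.flatnonzero(~out)
            idx = rng.choice(free, size=run, replace=False)
            out[idx] = True
    return out


def compute_enrichment(
    scored: ScoredTrack,
    features: list[FeatureTrack],
    label: str = "hypomutated",
    n_perm: int = 1000,
    seed: int = 0,
    mode: str = "segment",
) -> pd.DataFrame:
    """Observed odds ratio plus permutation envelope for each feature."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    present = scored.scored_mask()
    n_analyzed = int(present.sum())
    if n_analyzed == 0:
        raise ValueError("no scored bins")
    labels = scored.df["label"].to_numpy() == label
    labelled = labels[present]
    bin_bp = scored.bin_bp
    sg = n_analyzed * bin_bp
    hg = int(labelled.sum()) * bin_bp

    cov = np.vstack([_bin_coverage(scored, t)[present] for t in features])
    sf = cov.sum(axis=1)
    hf = cov[:, labelled].sum(axis=1)
    if hg == 0:
        # no labelled area at all: every enrichment is 0 and nothing is called
        return pd.DataFrame(
            {
                "feature": [t.name for t in features],
                "Hf": hf, "Sf": sf, "Hg": hg, "Sg": sg,
                "odds_ratio": 0.0, "env_low": 0.0, "env_high": 0.0,
                "significant": False,
            }
        )
    obs = np.array(
        [odds_ratio(hf[i], sf[i], hg, sg) if sf[i] > 0 else np.nan for i in range(len(features))]
    )

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(21,)))
    perms = np.empty((n_perm, len(features)))
    for p in range(n_perm):
        null_mask = _sample_null_mask(rng, n_analyzed, labelled, mode)
        hf_p = cov[:, null_mask].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            perms[p] = (hf_p / sf) / (hg / sg)
    env_low = np.nanmin(perms, axis=0)
    env_high = np.nanmax(perms, axis=0)
    return pd.DataFrame(
        {
            "feature": [t.name for t in features],
            "Hf": hf,
            "Sf": sf,
            "Hg": hg,
            "Sg": sg,
            "odds_ratio": obs,
            "env_low": env_low,
            "env_high": env_high,
            "significant": (obs < env_low) | (obs > env_high),
        }
    )


def _intersect(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Intersection of two sorted merged (n,2) interval arrays."""
    pieces = []
    j = 0
    for s, e in a:
        while j < len(b) and b[j, 1] <= s:
            j += 1
        k = j
        while k < len(b) and b[k, 0] < e:
            lo, hi = max(s, b[k, 0]), min(e, b[k, 1])
            if lo < hi:
                pieces.append((lo, hi))
            k += 1
    return np.array(pieces, dtype=np.int64).reshape(-1, 2)


def noncoding_extent(
    genes: pd.DataFrame, coding_mask: FeatureTrack, subset=None
) -> FeatureTrack:
    """Union of gene bodies minus coding sequence, as one track."""
    sel = genes if subset is None else genes[subset]
    per_chrom = {}
    for chrom, sub in sel.groupby("chrom", sort=False):
        s, e = merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
        body = np.column_stack([s, e])
        cod = coding_mask.intervals(chrom)
        if len(cod):
            kept = []
            ci = cod
            for bs, be in body:
                cuts = [bs]
                for cs, ce in ci[(ci[:, 1] > bs) & (ci[:, 0] < be)]:
                    cuts.extend([max(cs, bs), min(ce, be)])
                cuts.append(be)
                arr = np.array(cuts, dtype=np.int64)
                keep_s, keep_e = arr[::2], arr[1::2]
                for a, b in zip(keep_s, keep_e):
                    if a < b:
                        kept.append((a, b))
            body = np.array(kept, dtype=np.int64).reshape(-1, 2)
        per_chrom[chrom] = body
    return FeatureTrack("noncoding", per_chrom)


def gene_overlap_table(
    scored: ScoredTrack,
    genes: pd.DataFrame,
    coding_mask: FeatureTrack | None = None,
    label: str = "hypomutated",
) -> pd.DataFrame:
    """Per-gene overlap of labelled bp with the gene's non-coding extent.

    *genes* columns: chrom, start, end, name (and optionally gene_class).
    Genes with zero overlap are excluded from the output; genes that are
    entirely coding are skipped with a warning. Sorted by fraction.
    """
    coding_mask = coding_mask or FeatureTrack("coding")
    lab = label_track(scored, label)
    rows = []
    n_all_coding = 0
    for rec in genes.itertuples(index=False):
        gene_iv = np.array([[rec.start, rec.end]], dtype=np.int64)
        cod = _intersect(gene_iv, coding_mask.intervals(rec.chrom))
        noncoding_bp = int(rec.end - rec.start - (cod[:, 1] - cod[:, 0]).sum())
        if noncoding_bp == 0:
            n_all_coding += 1
            continue
        hypo = _intersect(gene_iv, lab.intervals(rec.chrom))
        overlap = int((hypo[:, 1] - hypo[:, 0]).sum())
        if len(cod) and len(hypo):
            overlap -= int((_intersect(hypo, cod)[:, 1] - _intersect(hypo, cod)[:, 0]).sum())
        if overlap == 0:
            continue
        rows.append(
            {
                "chrom": rec.chrom,
                "start": int(rec.start),
                "end": int(rec.end),
                "name": rec.name,
                "gene_class": getattr(rec, "gene_class", ""),
                "noncoding_length": noncoding_bp,
                "overlap_bp": overlap,
                "fraction": overlap / noncoding_bp,
            }
        )
    if n_all_coding:
        warnings.warn(f"{n_all_coding} gene(s) entirely coding; skipped")
    out = pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "name", "gene_class",
            "noncoding_length", "overlap_bp", "fraction",
        ],
    )
    return out.sort_values("fraction", ascending=False).reset_index(drop=True)


def class_enrichment_comparison(
    scored: ScoredTrack,
    genes: pd.DataFrame,
    class_a: str,
    class_b: str,
    coding_mask: FeatureTrack | None = None,
    label: str = "hypomutated",
    n_perm: int = 1000,
    seed: int = 0,
    mode: str = "segment",
) -> pd.DataFrame:
    """Labelled-position enrichment of two gene classes with envelopes.

    Each class contributes one pseudo-feature: the union of its genes'
    non-coding extents (Sf = total non-coding bp of the class).
    """
    coding_mask = coding_mask or FeatureTrack("coding")
    tracks = []
    for cls in (class_a, class_b):
        sel = genes["gene_class"] == cls
        if not sel.any():
            raise ValueError(f"gene class {cls!r} is empty")
        t = noncoding_extent(genes, coding_mask, subset=sel)
        t.name = cls
        tracks.append(t)
    return compute_enrichment(
        scored, tracks, label=label, n_perm=n_perm, seed=seed, mode=mode
    )
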