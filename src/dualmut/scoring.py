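"""Combining the germline and somatic channels: cutoffs and region labels.

The joint spectrum of (SNP score, SOM score) is partitioned by two empirical
cutoffs: the SNP cutoff keeps a fixed genome area of highest germline
constraint (100 Mb on the real genome, expressed here as the equivalent
fraction 100/3100 of the scored area so the logic scales to miniature
genomes), and the SOM cutoff is set so that the *hypomutated* intersection
(high SNP score AND low SOM score) has a fixed area (56 Mb, fraction
56/3100).  Bins above the SNP cutoff but above the SOM cutoff are
*hypermutated*; everything else scored is *other*.

Also here: the disease-variant statistics over the labelled spectrum — the
quadrant density/χ² test, rank-sum score comparisons between variant groups,
and the binned score-vs-density correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .som_model import ScoredTrack
from .variants import VariantSet

# real-genome defaults expressed as fractions of the scored area:
# 100 Mb high-SNP area and 56 Mb hypomutated area out of ~3100 Mb analyzed
SNP_AREA_FRACTION = 100 / 3100
HYPO_AREA_FRACTION = 56 / 3100


@dataclass
class CutoffSpec:
    snp_cutoff: float
    snp_target_bp: int
    som_cutoff: float
    hypo_target_bp: int


def derive_snp_cutoff(scored: ScoredTrack, target_area_bp: int) -> float:
    """Score at the target-area rank: the cutoff encompassing the
    *target_area_bp* highest-scoring bp.

    All bins tying the cutoff score are included, so the realized area can
    exceed the target by up to one tie-group (logged when it does) — a
    deterministic, order-independent tie rule.
    """
    snp = scored.df["snp_score"].to_numpy(dtype=float)
    snp = snp[~np.isnan(snp)]
    if len(snp) == 0:
        raise ValueError("no SNP-scored bins")
    scored_bp = len(snp) * scored.bin_bp
    if target_area_bp > scored_bp:
        raise ValueError(
            f"target area {target_area_bp} bp exceeds scored area {scored_bp} bp"
        )
    uniq, counts = np.unique(snp, return_counts=True)  # ascending
    uniq, counts = uniq[::-1], counts[::-1]            # descending
    cum_bp = np.cumsum(counts) * scored.bin_bp
    i = int(np.searchsorted(cum_bp, target_area_bp))   # first tie-group reaching target
    i = min(i, len(uniq) - 1)
    if cum_bp[i] > target_area_bp:
        warnings.warn(
            f"SNP cutoff tie-group overshoots the target area: "
            f"{int(cum_bp[i])} bp selected for a {target_area_bp} bp target"
        )
    return float(uniq[i])


def derive_som_cutoff(
    scored: ScoredTrack, snp_cutoff: float, hypo_target_bp: int
) -> float:
    """SOM value such that bp(snp >= snp_cutoff AND som <= c) encompasses the
    hypomutated target area, ties included (may overshoot; logged)."""
    df = scored.df
    mask = scored.scored_mask() & (df["snp_score"].to_numpy() >= snp_cutoff)
    som = df["som_score"].to_numpy(dtype=float)[mask]
    if len(som) == 0:
        raise ValueError("no bins above the SNP cutoff")
    high_bp = len(som) * scored.bin_bp
    if high_bp < hypo_target_bp:
        raise ValueError(
            f"high-SNP area ({high_bp} bp) smaller than the hypomutated target "
            f"({hypo_target_bp} bp): targets inconsistent"
        )
    uniq, counts = np.unique(som, return_counts=True)  # ascending
    cum_bp = np.cumsum(counts) * scored.bin_bp
    if hypo_target_bp <= 0:
        return float(np.nextafter(uniq[0], -np.inf))  # below min: zero bins
    i = int(np.searchsorted(cum_bp, hypo_target_bp))
    i = min(i, len(uniq) - 1)
    if cum_bp[i] > hypo_target_bp:
        warnings.warn(
            f"SOM cutoff tie-group overshoots the hypomutated target: "
            f"{int(cum_bp[i])} bp selected for a {hypo_target_bp} bp target"
        )
    return float(uniq[i])


def derive_cutoffs(
    scored: ScoredTrack,
    snp_target_bp: int | None = None,
    hypo_target_bp: int | None = None,
) -> CutoffSpec:
    """Derive both cutoffs; targets default to the real-genome area fractions
    applied to the scored area."""
    scored_bp = int(scored.scored_mask().sum()) * scored.bin_bp
    if snp_target_bp is None:
        snp_target_bp = int(round(SNP_AREA_FRACTION * scored_bp))
    if hypo_target_bp is None:
        hypo_target_bp = int(round(HYPO_AREA_FRACTION * scored_bp))
    snp_cutoff = derive_snp_cutoff(scored, snp_target_bp)
    som_cutoff = derive_som_cutoff(scored, snp_cutoff, hypo_target_bp)
    return CutoffSpec(
        snp_cutoff=snp_cutoff,
        snp_target_bp=snp_target_bp,
        som_cutoff=som_cutoff,
        hypo_target_bp=hypo_target_bp,
    )


def classify(scored: ScoredTrack, cutoffs: CutoffSpec) -> ScoredTrack:
    """Label every bin: hypomutated (snp >= cut AND som <= cut), hypermutated
    (snp >= cut AND som > cut), other (snp < cut), unscored (either missing)."""
    df = scored.df.copy()
    snp = df["snp_score"].to_numpy(dtype=float)
    som = df["som_score"].to_numpy(dtype=float)
    present = ~np.isnan(snp) & ~np.isnan(som)
    label = np.full(len(df), "unscored", dtype=object)
    high = present & (snp >= cutoffs.snp_cutoff)
    label[present & ~high] = "other"
    label[high & (som <= cutoffs.som_cutoff)] = "hypomutated"
    label[high & (som > cutoffs.som_cutoff)] = "hypermutated"
    df["label"] = label
    return ScoredTrack(df, scored.bin_bp, scored.genome)


def _density_per_mb(n_variants: int, n_bins: int, bin_bp: int) -> float:
    mb = n_bins * bin_bp / 1e6
    return n_variants / mb if mb > 0 else float("nan")


def quadrant_disease_test(
    scored: ScoredTrack, disease: VariantSet, cutoffs: CutoffSpec
) -> tuple[pd.DataFrame, float | None, float | None]:
    """Disease-variant density in high-SNP, low-SOM, their intersection and
    the rest of the scored genome, plus a 1-df χ² of intersection membership
    against the genome-area expectation (no continuity correction)."""
    dis = disease.of_kind("disease")
    df = scored.df
    snp = df["snp_score"].to_numpy(dtype=float)
    som = df["som_score"].to_numpy(dtype=float)
    present = scored.scored_mask()
    regions = {
        "high_snp": present & (snp >= cutoffs.snp_cutoff),
        "low_som": present & (som <= cutoffs.som_cutoff),
        "intersection": present
        & (snp >= cutoffs.snp_cutoff)
        & (som <= cutoffs.som_cutoff),
        "rest": present
        & ~((snp >= cutoffs.snp_cutoff) & (som <= cutoffs.som_cutoff)),
    }
    idx = scored.bin_index(dis.df["chrom"].to_numpy(), dis.df["pos"].to_numpy())
    in_bins = idx >= 0
    rows = []
    for name, mask in regions.items():
        n = int(mask[idx[in_bins]].sum())
        rows.append(
            {
                "region": name,
                "bp": int(mask.sum()) * scored.bin_bp,
                "n_disease": n,
                "density_per_mb": _density_per_mb(n, int(mask.sum()), scored.bin_bp),
            }
        )
    table = pd.DataFrame(rows)
    n_total = int((present[idx[in_bins]]).sum())
    if n_total == 0:
        warnings.warn("no disease variants in the scored genome; χ² test skipped")
        return table, None, None
    area_frac = regions["intersection"].sum() / present.sum()
    k = int(regions["intersection"][idx[in_bins]].sum())
    expected = np.array([n_total * area_frac, n_total * (1 - area_frac)])
    chi2, p = stats.chisquare([k, n_total - k], expected)
    return table, float(chi2), float(p)


def score_group_comparison(
    scored: ScoredTrack,
    variants_a: VariantSet,
    variants_b: VariantSet,
    channel: str = "snp_score",
) -> tuple[float, float]:
    """Two-sided rank-sum comparison of per-variant scores between groups."""
    if len(variants_a) == 0 or len(variants_b) == 0:
        raise ValueError("both variant sets must be non-empty")
    vals = scored.df[channel].to_numpy(dtype=float)

    def lookup(v: VariantSet) -> np.ndarray:
        idx = scored.bin_index(v.df["chrom"].to_numpy(), v.df["pos"].to_numpy())
        s = np.where(idx >= 0, vals[np.clip(idx, 0, None)], np.nan)
        return s[~np.isnan(s)]

    a, b = lookup(variants_a), lookup(variants_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("no scored positions in one of the groups")
    if np.ptp(np.concatenate([a, b])) == 0:
        return 0.0, 1.0  # every score tied
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(stat), float(p)


def binned_score_density_correlation(
    scored: ScoredTrack,
    disease: VariantSet,
    bin_total_bp: int,
    channel: str = "snp_score",
) -> tuple[pd.DataFrame, float, float]:
    """Sort bins by score, split into consecutive equal-bp groups, and
    correlate per-group mean score with disease-variant density."""
    vals = scored.df[channel].to_numpy(dtype=float)
    present = ~np.isnan(vals)
    dis = disease.of_kind("disease")
    idx = scored.bin_index(dis.df["chrom"].to_numpy(), dis.df["pos"].to_numpy())
    counts = np.bincount(idx[idx >= 0], minlength=len(vals))

    order = np.argsort(vals[present], kind="stable")
    svals = vals[present][order]
    scounts = counts[present][order]
    per_group = bin_total_bp // scored.bin_bp
    if per_group < 1:
        raise ValueError("bin_total_bp smaller than one bin")
    n_groups = len(svals) // per_group
    if n_groups < 3:
        raise ValueError(f"only {n_groups} groups; need >= 3")
    use = n_groups * per_group
    gs = svals[:use].reshape(n_groups, per_group)
    gc = scounts[:use].reshape(n_groups, per_group)
    table = pd.DataFrame(
        {
            "mean_score": gs.mean(axis=1),
            "n_disease": gc.sum(axis=1),
            "density_per_mb": gc.sum(axis=1) / (per_group * scored.bin_bp / 1e6),
        }
    )
    r, p = stats.pearsonr(table["mean_score"], table["density_per_mb"])
    return table, float(r), float(p)
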