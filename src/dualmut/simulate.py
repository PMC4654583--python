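"""Synthetic genomes with planted mutational structure.

The generator stands in for the population-SNP / tumor-WGS / annotation-track
inputs of the real analysis.  It emits:

* a miniature multi-chromosome genome;
* binary feature tracks drawn by a renewal process (geometric segment and gap
  lengths) hitting a requested coverage fraction;
* germline SNPs whose probability of being *rare* (allele frequency < 0.01)
  at a position is ``expit(logit(baseline) + sum of per-feature effects)`` —
  a logit-additive planted model of purifying selection;
* somatic point mutations whose local Poisson rate is
  ``baseline density × product of per-feature multipliers × n_patients`` —
  the planted analogue of chromatin/replication-timing effects on tumor
  mutation density;
* disease variants placed with a configurable bias toward "constrained"
  features (high rare effect and/or protective somatic multiplier).

All randomness flows from one integer seed; each stage draws from its own
fixed substream, so regenerating any one stage is reproducible in isolation.
Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.special import expit, logit

from .genome import GenomeModel
from .intervals import FeatureTrack, merge_intervals
from .io import write_bed, write_chrom_sizes, write_variant_tsv
from .variants import VariantSet

MIN_CHROM_BP = 1_000_000  # somatic 1 Mb windows are undefined below this

_STAGE = {"genome": 0, "tracks": 1, "snps": 2, "somatic": 3, "disease": 4}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STAGE[stage],)))


@dataclass
class FeatureSpec:
    name: str
    coverage_fraction: float
    mean_segment_length: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage_fraction <= 1.0:
            raise ValueError(
                f"feature {self.name!r}: coverage_fraction {self.coverage_fraction} "
                "outside [0, 1]"
            )
        if self.mean_segment_length < 1:
            raise ValueError(f"feature {self.name!r}: mean_segment_length < 1")


@dataclass
class SyntheticConfig:
    genome_size: int = 10_000_000
    n_chromosomes: int = 2
    feature_specs: list[FeatureSpec] = field(default_factory=list)
    snp_density: float = 0.01
    baseline_rare_fraction: float = 0.3
    rare_effect: dict[str, float] = field(default_factory=dict)
    somatic_baseline_density: float = 100.0  # mutations / Mb / patient
    somatic_multipliers: dict[str, float] = field(default_factory=dict)
    n_patients: int = 20
    n_disease_variants: int = 1000
    disease_placement_bias: float = 5.0
    constrained_features: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.baseline_rare_fraction <= 1.0:
            raise ValueError("baseline_rare_fraction outside [0, 1]")
        if self.disease_placement_bias < 1.0:
            raise ValueError("disease_placement_bias must be >= 1")
        if self.somatic_baseline_density < 0:
            raise ValueError("somatic_baseline_density must be >= 0")
        names = [f.name for f in self.feature_specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["feature_specs"] = [FeatureSpec(**f) for f in raw.get("feature_specs", [])]
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = {
            **{k: v for k, v in self.__dict__.items() if k != "feature_specs"},
            "feature_specs": [f.__dict__ for f in self.feature_specs],
        }
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))

    def default_constrained(self) -> list[str]:
        """Features treated as 'constrained' for disease-variant placement:
        positive planted rare effect or protective somatic multiplier."""
        if self.constrained_features is not None:
            return self.constrained_features
        out = []
        for f in self.feature_specs:
            if self.rare_effect.get(f.name, 0.0) > 0 or self.somatic_multipliers.get(
                f.name, 1.0
            ) < 1:
                out.append(f.name)
        return out


def generate_genome(config: SyntheticConfig) -> GenomeModel:
    """Evenly split chromosomes named chr1..chrN (remainder to the last)."""
    per = config.genome_size // config.n_chromosomes
    if per < MIN_CHROM_BP:
        raise ValueError(
            f"chromosomes of {per} bp are below the 1 Mb minimum required "
            "for somatic windows"
        )
    chroms = []
    for i in range(config.n_chromosomes):
        length = per
        if i == config.n_chromosomes - 1:
            length = config.genome_size - per * (config.n_chromosomes - 1)
        chroms.append((f"chr{i + 1}", length))
    return GenomeModel(chroms)


def _renewal_intervals(
    rng: np.random.Generator, length: int, coverage: float, mean_seg: int
) -> np.ndarray:
    """Alternating gap/segment renewal process with geometric lengths."""
    if coverage <= 0.0:
        return np.empty((0, 2), dtype=np.int64)
    if coverage >= 1.0:
        return np.array([[0, length]], dtype=np.int64)
    mean_gap = mean_seg * (1.0 - coverage) / coverage
    p_seg = min(1.0, 1.0 / mean_seg)
    p_gap = min(1.0, 1.0 / max(mean_gap, 1.0))
    starts, ends = [], []
    # start in a segment with probability = coverage (stationary start)
    pos = 0 if rng.random() < coverage else int(rng.geometric(p_gap))
    while pos < length:
        seg = int(rng.geometric(p_seg))
        starts.append(pos)
        ends.append(min(pos + seg, length))
        pos += seg + int(rng.geometric(p_gap))
    return np.column_stack([np.array(starts, dtype=np.int64), np.array(ends, dtype=np.int64)])


def generate_feature_tracks(
    genome: GenomeModel, config: SyntheticConfig
) -> list[FeatureTrack]:
    rng = _rng(config.seed, "tracks")
    tracks = []
    for spec in config.feature_specs:
        per_chrom = {}
        for chrom, length in genome.chromosomes:
            per_chrom[chrom] = _renewal_intervals(
                rng, length, spec.coverage_fraction, spec.mean_segment_length
            )
        tracks.append(FeatureTrack(spec.name, per_chrom))
    return tracks


def planted_rare_probability(
    config: SyntheticConfig, present: dict[str, np.ndarray]
) -> np.ndarray:
    """Planted P(rare) given per-feature presence booleans (the ground truth
    downstream models are asked to recover)."""
    eta = np.full(next(iter(present.values())).shape, logit(config.baseline_rare_fraction))
    for name, mask in present.items():
        eta = eta + config.rare_effect.get(name, 0.0) * mask
    return np.clip(expit(eta), 0.0, 1.0)


def generate_germline_snps(
    genome: GenomeModel, tracks: list[FeatureTrack], config: SyntheticConfig
) -> VariantSet:
    rng = _rng(config.seed, "snps")
    chroms, positions, afs = [], [], []
    for chrom, length in genome.chromosomes:
        n = rng.poisson(config.snp_density * length)
        if n == 0:
            continue
        pos = np.sort(rng.integers(0, length, size=n))
        present = {t.name: t.contains(chrom, pos) for t in tracks}
        p_rare = planted_rare_probability(config, present) if tracks else np.full(
            n, config.baseline_rare_fraction
        )
        rare = rng.random(n) < p_rare
        af = np.where(
            rare,
            rng.uniform(1e-6, 0.01, size=n),
            rng.uniform(0.01, 0.5, size=n),
        )
        chroms.extend([chrom] * n)
        positions.append(pos)
        afs.append(af)
    if not positions:
        return VariantSet.empty()
    return VariantSet.from_arrays(
        chroms, np.concatenate(positions), "germline", af=np.concatenate(afs)
    )


def _multiplier_segments(
    genome: GenomeModel, tracks: list[FeatureTrack], config: SyntheticConfig, chrom: str
) -> tuple[np.ndarray, np.ndarray]:
    """Changepoints and per-segment rate multipliers on one chromosome."""
    length = genome.lengths[chrom]
    mult_tracks = [t for t in tracks if config.somatic_multipliers.get(t.name, 1.0) != 1.0]
    bounds = [np.array([0, length], dtype=np.int64)]
    for t in mult_tracks:
        bounds.append(np.clip(t.intervals(chrom).ravel(), 0, length))
    cuts = np.unique(np.concatenate(bounds))
    seg_starts = cuts[:-1]
    mult = np.ones(len(seg_starts))
    for t in mult_tracks:
        inside = t.contains(chrom, seg_starts)
        mult *= np.where(inside, config.somatic_multipliers[t.name], 1.0)
    return cuts, mult


def generate_somatic_mutations(
    genome: GenomeModel, tracks: list[FeatureTrack], config: SyntheticConfig
) -> VariantSet:
    """Poisson point process with piecewise-constant planted rate.

    Rate per bp = baseline/1e6 × product of multipliers of overlapping
    features × n_patients; patient labels are then assigned uniformly (an
    exact thinning of independent identical per-patient processes).
    """
    if config.n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = _rng(config.seed, "somatic")
    base = config.somatic_baseline_density / 1e6
    chroms, positions = [], []
    for chrom, _length in genome.chromosomes:
        cuts, mult = _multiplier_segments(genome, tracks, config, chrom)
        seg_len = np.diff(cuts)
        means = base * mult * seg_len * config.n_patients
        counts = rng.poisson(means)
        total = int(counts.sum())
        if total == 0:
            continue
        seg_idx = np.repeat(np.arange(len(seg_len)), counts)
        offs = rng.random(total) * seg_len[seg_idx]
        pos = cuts[:-1][seg_idx] + offs.astype(np.int64)
        chroms.extend([chrom] * total)
        positions.append(np.sort(pos))
    if not positions:
        return VariantSet.from_arrays([], np.empty(0, dtype=np.int64), "somatic")
    pos_all = np.concatenate(positions)
    patients = rng.integers(0, config.n_patients, size=len(pos_all))
    labels = np.array([f"P{i:03d}" for i in range(config.n_patients)], dtype=object)
    return VariantSet.from_arrays(chroms, pos_all, "somatic", patient_id=labels[patients])


def planted_somatic_mean(
    genome: GenomeModel,
    tracks: list[FeatureTrack],
    config: SyntheticConfig,
    chrom: str,
    starts: np.ndarray,
    window_bp: int,
) -> np.ndarray:
    """Expected (planted) pooled mutation count in windows [s, s+window).

    The exact Poisson mean the somatic generator used — the ground truth
    against which a fitted model's window predictions are judged.
    """
    cuts, mult = _multiplier_segments(genome, tracks, config, chrom)
    seg_len = np.diff(cuts).astype(float)
    cum = np.concatenate([[0.0], np.cumsum(mult * seg_len)])

    def integral(x):
        x = np.asarray(x, dtype=np.int64)
        j = np.clip(np.searchsorted(cuts, x, side="right") - 1, 0, len(seg_len) - 1)
        return cum[j] + mult[j] * (x - cuts[j])

    base = config.somatic_baseline_density / 1e6 * config.n_patients
    starts = np.asarray(starts, dtype=np.int64)
    return base * (integral(starts + window_bp) - integral(starts))


def generate_disease_variants(
    genome: GenomeModel, tracks: list[FeatureTrack], config: SyntheticConfig
) -> VariantSet:
    """Sample positions with multiplicative bias toward constrained features.

    A position's sampling weight is ``bias ** (number of designated
    constrained features present)``: 1 in unconstrained background, *bias*
    inside a single constrained feature, *bias²* where two overlap, and so
    on — a conserved element inside a somatically protected domain is the
    most disease-enriched location, mirroring how curated disease variants
    concentrate in functional elements within protected environments.
    """
    rng = _rng(config.seed, "disease")
    n = config.n_disease_variants
    if n == 0:
        return VariantSet.from_arrays([], np.empty(0, dtype=np.int64), "disease")
    constrained = [t for t in tracks if t.name in set(config.default_constrained())]
    seg_chrom: list[str] = []
    seg_start: list[np.ndarray] = []
    seg_len: list[np.ndarray] = []
    seg_w: list[np.ndarray] = []
    for chrom, length in genome.chromosomes:
        parts = [np.array([0, length], dtype=np.int64)]
        for t in constrained:
            parts.append(np.clip(t.intervals(chrom).ravel(), 0, length))
        cuts = np.unique(np.concatenate(parts))
        starts = cuts[:-1]
        n_present = np.zeros(len(starts))
        for t in constrained:
            n_present += t.contains(chrom, starts)
        lens = np.diff(cuts)
        seg_chrom.extend([chrom] * len(starts))
        seg_start.append(starts)
        seg_len.append(lens)
        seg_w.append(config.disease_placement_bias**n_present * lens)
    starts = np.concatenate(seg_start)
    lens = np.concatenate(seg_len)
    weights = np.concatenate(seg_w).astype(float)
    idx = rng.choice(len(starts), size=n, p=weights / weights.sum())
    pos = starts[idx] + (rng.random(n) * lens[idx]).astype(np.int64)
    chroms = np.array(seg_chrom, dtype=object)[idx]
    return VariantSet.from_arrays(list(chroms), pos, "disease")


def write_world(
    outdir, genome: GenomeModel, tracks: list[FeatureTrack], variants: VariantSet
) -> dict[str, str]:
    """Persist a generated world as chrom.sizes + BED tracks + variant TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    write_chrom_sizes(genome, outdir / "genome.chrom.sizes")
    paths["genome"] = str(outdir / "genome.chrom.sizes")
    for t in tracks:
        p = outdir / f"feature_{t.name}.bed"
        write_bed(t, p)
        paths[t.name] = str(p)
    write_variant_tsv(variants, outdir / "variants.tsv")
    paths["variants"] = str(outdir / "variants.tsv")
    return paths
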