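"""End-to-end orchestration with provenance.

A single YAML config drives the run: a ``synthetic`` block (the generator's
world) or an ``inputs`` block (paths to chrom.sizes / BED tracks / variant
TSV), plus optional ``snp_model`` / ``som_model`` / ``scoring`` /
``enrichment`` blocks.  ``run_pipeline`` executes generation → feature
matrices → both forests → sliding scores → dual classification → enrichment,
emits plain-text artifacts into the output directory, and writes a
``manifest.json`` recording the config digest, per-stage seeds, stage counts
and the sha256 of every artifact, so identical configs yield identical
digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import compute_enrichment, label_track
from .features import build_combination_matrix, build_window_matrix
from .intervals import FeatureTrack
from .io import (
    read_bed,
    read_chrom_sizes,
    read_variant_tsv,
    write_bed,
    write_bedgraph_bins,
)
from .scoring import classify, derive_cutoffs, quadrant_disease_test
from .simulate import (
    SyntheticConfig,
    FeatureSpec,
    generate_disease_variants,
    generate_feature_tracks,
    generate_genome,
    generate_germline_snps,
    generate_somatic_mutations,
    write_world,
)
from .snp_model import fit_snp_model, select_features, snp_score_bins
from .som_model import ScoredTrack, fit_som_model, sliding_som_score
from .variants import VariantSet

log = logging.getLogger("dualmut")

STAGE_SEED_OFFSETS = {
    "synthetic": 0,
    "snp_select": 101,
    "snp_fit": 102,
    "som_select": 201,
    "som_fit": 202,
    "enrichment": 301,
}


def stage_seed(master_seed: int, stage: str) -> int:
    return int((master_seed * 1000 + STAGE_SEED_OFFSETS[stage]) % (2**31 - 1))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    config_digest: str
    seeds: dict[str, int]
    version: str
    counts: dict[str, float] = field(default_factory=dict)
    artifacts: dict[str, str] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def _load_world(cfg: dict, seed: int):
    """Build (genome, tracks, variants) from the synthetic or inputs block."""
    if "synthetic" in cfg:
        raw = dict(cfg["synthetic"])
        raw["feature_specs"] = [FeatureSpec(**f) for f in raw.get("feature_specs", [])]
        raw.setdefault("seed", stage_seed(seed, "synthetic"))
        sc = SyntheticConfig(**raw)
        genome = generate_genome(sc)
        tracks = generate_feature_tracks(genome, sc)
        parts = [
            generate_germline_snps(genome, tracks, sc),
            generate_somatic_mutations(genome, tracks, sc),
            generate_disease_variants(genome, tracks, sc),
        ]
        variants = VariantSet(
            pd.concat([p.df for p in parts], ignore_index=True)
        )
        return genome, tracks, variants, sc
    if "inputs" in cfg:
        inp = cfg["inputs"]
        for key in ("genome", "tracks", "variants"):
            if key not in inp:
                raise ValueError(f"inputs block missing {key!r}")
        genome = read_chrom_sizes(inp["genome"])
        tracks = [read_bed(p, name=Path(p).stem) for p in inp["tracks"]]
        variants = read_variant_tsv(inp["variants"])
        return genome, tracks, variants, None
    raise ValueError("config needs a 'synthetic' or an 'inputs' block")


def run_pipeline(config: dict | str | Path, outdir, seed: int = 0) -> RunManifest:
    cfg = load_config(config) if not isinstance(config, dict) else config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_digest=hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        seeds={s: stage_seed(seed, s) for s in STAGE_SEED_OFFSETS},
        version=__version__,
    )

    # ---- stage: world ----------------------------------------------------
    log.info("stage world: generating/loading inputs")
    genome, tracks, variants, _sc = _load_world(cfg, seed)
    write_world(outdir / "world", genome, tracks, variants)
    manifest.counts["n_tracks"] = len(tracks)
    manifest.counts["n_variants"] = len(variants)
    manifest.counts["genome_bp"] = genome.total_size

    coding_cfg = cfg.get("coding_track")
    coding_mask = read_bed(coding_cfg) if coding_cfg else FeatureTrack("coding")

    # ---- stage: germline model ------------------------------------------
    snp_cfg = cfg.get("snp_model", {})
    log.info("stage snp: combination matrix + forest")
    matrix = build_combination_matrix(
        tracks,
        variants,
        genome,
        coding_mask=coding_mask,
        min_size=snp_cfg.get("min_size", 10_000),
    )
    matrix.df.to_csv(outdir / "combination_matrix.tsv", sep="\t", index=False)
    manifest.counts.update(
        {f"combinations_{k}": v for k, v in matrix.dropped_summary().items()}
    )
    features = None
    if snp_cfg.get("select", True) and len(tracks) >= 2:
        report = select_features(
            matrix,
            seed=stage_seed(seed, "snp_select"),
            n_trees=snp_cfg.get("n_trees_select", 200),
        )
        features = report.selected
        manifest.counts["snp_features_selected"] = len(features)
    snp_fit = fit_snp_model(
        matrix,
        features=features,
        weighted=snp_cfg.get("weighted", True),
        seed=stage_seed(seed, "snp_fit"),
        n_trees=snp_cfg.get("n_trees", 500),
    )
    manifest.counts["snp_oob_r2"] = round(snp_fit.oob_r2, 6)
    snp_bins = snp_score_bins(snp_fit, genome, tracks, coding_mask)

    # ---- stage: somatic model -------------------------------------------
    som_cfg = cfg.get("som_model", {})
    log.info("stage som: window matrix + forest + sliding score")
    wm = build_window_matrix(tracks, variants, genome)
    wm.df.to_csv(outdir / "window_matrix.tsv", sep="\t", index=False)
    manifest.counts["windows_retained"] = len(wm.df)
    manifest.counts["windows_excluded"] = wm.n_windows_excluded
    som_fit = fit_som_model(
        wm,
        seed=stage_seed(seed, "som_fit"),
        cancer_label=som_cfg.get("cancer_label", "synthetic"),
        n_patients=max(variants.n_patients, 1),
        select=som_cfg.get("select", True) and len(tracks) >= 2,
        n_trees=som_cfg.get("n_trees", 500),
    )
    manifest.counts["som_oob_r2"] = round(som_fit.oob_r2, 6)
    som_bins = sliding_som_score(som_fit, tracks, genome)

    # ---- stage: dual scoring --------------------------------------------
    log.info("stage scoring: cutoffs + classification")
    scored = ScoredTrack.empty(genome)
    scored.set_channel("snp_score", snp_bins)
    scored.set_channel("som_score", som_bins)
    score_cfg = cfg.get("scoring", {})
    cutoffs = derive_cutoffs(
        scored,
        snp_target_bp=score_cfg.get("snp_target_bp"),
        hypo_target_bp=score_cfg.get("hypo_target_bp"),
    )
    labelled = classify(scored, cutoffs)
    write_bedgraph_bins(
        outdir / "snp_score.bedgraph",
        labelled.df["chrom"], labelled.df["start"],
        labelled.df["snp_score"].to_numpy(dtype=float), labelled.bin_bp,
    )
    write_bedgraph_bins(
        outdir / "som_score.bedgraph",
        labelled.df["chrom"], labelled.df["start"],
        labelled.df["som_score"].to_numpy(dtype=float), labelled.bin_bp,
    )
    for lab in ("hypomutated", "hypermutated"):
        write_bed(label_track(labelled, lab), outdir / f"{lab}.bed")
    manifest.counts["snp_cutoff"] = round(cutoffs.snp_cutoff, 6)
    manifest.counts["som_cutoff"] = round(cutoffs.som_cutoff, 6)
    manifest.counts["hypomutated_bins"] = int(
        (labelled.df["label"] == "hypomutated").sum()
    )

    disease = variants.of_kind("disease")
    if len(disease):
        table, chi2, p = quadrant_disease_test(labelled, disease, cutoffs)
        table.to_csv(outdir / "quadrant_report.tsv", sep="\t", index=False)
        manifest.counts["quadrant_chi2"] = None if chi2 is None else round(chi2, 4)
        manifest.counts["quadrant_p"] = None if p is None else float(p)

    # ---- stage: enrichment ----------------------------------------------
    enr_cfg = cfg.get("enrichment", {})
    log.info("stage enrichment: permutation envelopes")
    enr = compute_enrichment(
        labelled,
        tracks,
        label="hypomutated",
        n_perm=enr_cfg.get("n_perm", 1000),
        seed=stage_seed(seed, "enrichment"),
        mode=enr_cfg.get("mode", "segment"),
    )
    enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest.artifacts[str(p.relative_to(outdir))] = _sha256(p)
    manifest.write(outdir / "manifest.json")
    log.info("pipeline complete: %s", outdir / "manifest.json")
    return manifest
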