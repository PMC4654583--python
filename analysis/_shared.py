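"""Shared world definition for the numbered analysis scripts.

One synthetic world is used throughout the analysis: a 40 Mb genome with
kilobase-scale germline-constraint features (conserved elements, conserved
TFBS, DNase sites, promoters) and megabase-scale somatic mutation-rate
domains (early/late replication analogues), 20 patients at 100 mutations/Mb
baseline, and disease variants biased 5x toward constrained features.
Every script regenerates deterministically from SEED, so any script can be
run on its own.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from dualmut.features import build_combination_matrix, build_window_matrix
from dualmut.simulate import (
    FeatureSpec,
    SyntheticConfig,
    generate_disease_variants,
    generate_feature_tracks,
    generate_genome,
    generate_germline_snps,
    generate_somatic_mutations,
)
from dualmut.variants import VariantSet

SEED = 17
RESULTS = Path(__file__).resolve().parent.parent / "results"

CONFIG = SyntheticConfig(
    genome_size=40_000_000,
    n_chromosomes=2,
    feature_specs=[
        FeatureSpec("consv", 0.025, 5_000),
        FeatureSpec("ctfbs", 0.015, 3_000),
        FeatureSpec("early_domain", 0.35, 4_000_000),
        FeatureSpec("late_domain", 0.30, 4_000_000),
        FeatureSpec("dnase", 0.15, 2_000),
        FeatureSpec("promoter", 0.03, 2_500),
    ],
    snp_density=0.005,
    baseline_rare_fraction=0.3,
    rare_effect={"consv": 2.0, "ctfbs": 2.0, "promoter": 1.0, "dnase": 0.5},
    somatic_baseline_density=100.0,
    somatic_multipliers={"early_domain": 0.3, "late_domain": 3.5},
    n_patients=20,
    n_disease_variants=2_000,
    disease_placement_bias=5.0,
    constrained_features=["consv", "early_domain"],
    seed=SEED,
)


def make_world():
    g = generate_genome(CONFIG)
    tr = generate_feature_tracks(g, CONFIG)
    variants = VariantSet(
        pd.concat(
            [
                generate_germline_snps(g, tr, CONFIG).df,
                generate_somatic_mutations(g, tr, CONFIG).df,
                generate_disease_variants(g, tr, CONFIG).df,
            ],
            ignore_index=True,
        )
    )
    return g, tr, variants


def make_matrices(g, tr, variants):
    cm = build_combination_matrix(tr, variants, g)
    wm = build_window_matrix(tr, variants, g)
    return cm, wm


def outdir() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS
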