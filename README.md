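# dualmut — dual germline/somatic mutational-constraint scoring

Prioritizing mutations in the non-coding genome is hard because there is no
genetic code to tell damaging changes from neutral ones. `dualmut`
implements a dual-model strategy aimed at cancer genomics: two independent
measures of constraint are estimated at every genome position and then
intersected.

* **SNP model (germline constraint).** The fraction of *rare* SNPs (allele
  frequency < 0.01) among all SNPs in a region is a classic signal of
  purifying selection. Every non-coding position is described by its
  combination of binary genome features (conserved elements, TFBS, DNase,
  promoters, …); the genome is partitioned into maximal runs of constant
  feature bitmask, combinations smaller than 10 kb are dropped, and a random
  forest regresses the per-combination rare-SNP ratio
  `n_rare / n_snp` on the feature indicators. The **SNP score** of a
  position is the predicted rare-SNP ratio of its feature combination
  (in [0, 1]; high = constrained in the germline).

* **SOM model (tumor mutational background).** Somatic mutations from
  whole-genome-sequenced tumors are counted in non-overlapping 1 Mb windows
  (windows touching telomere/centromere-like excluded regions are dropped);
  feature coverages and window means, scaled `x → ln(x+1)`, predict the
  pooled mutation count per window with a second random forest. The window
  is then slid across the genome at 1 kb steps and predictions of all valid
  covering windows are averaged per 1 kb bin — the **SOM score**
  (mutations/Mb; low = protected in the tumor).

* **Dual classification.** A SNP cutoff keeps a fixed area of highest
  germline constraint (100 Mb on the human genome; the equivalent fraction
  100/3100 of the scored area here), and a SOM cutoff is set so that the
  **hypomutated** intersection (high SNP *and* low SOM) has a fixed area
  (56 Mb ≙ 56/3100). High-SNP bins above the SOM cutoff are
  **hypermutated**. Enrichment of any region set in a feature is the odds
  ratio `(Hf/Sf)/(Hg/Sg)` with significance from a min–max envelope over
  1000 random placements of an equal-sized region set.

Because the original inputs are hundreds of GB of population and tumor
sequencing, the package ships a first-class **synthetic-genome generator**
with planted ground truth: feature tracks drawn by a renewal process,
germline SNPs whose rare probability is logit-additive in local features,
somatic mutations with per-feature Poisson rate multipliers, and disease
variants placed with multiplicative bias toward constrained features. Every
claim in the test suite is checked against this known ground truth.

## Worked example

The `analysis/` scripts run a complete study on a 40 Mb synthetic world
(kb-scale constraint features, Mb-scale replication-timing-like domains,
20 patients at 100 mutations/Mb, 2000 disease variants at 5× bias):

```bash
python analysis/01_simulate_world.py
python analysis/02_build_matrices.py
python analysis/03_fit_snp_model.py
python analysis/04_fit_som_model.py
python analysis/05_dual_classification.py
python analysis/06_enrichment.py
```

Script 05 prints (seed 17):

```
SNP cutoff 0.438 (target 1.29 Mb); SOM cutoff 2235.3 mutations/Mb pooled (hypomutated target 0.72 Mb)
      region       bp  n_disease  density_per_mb
    high_snp  1336000        208      155.688623
     low_som 21156000       1298       61.353753
intersection   723000        133      183.955740
        rest 39277000       1867       47.534180
synergy (intersection > both margins): True; χ² = 264.2, p = 2.03e-59
```

Reading: disease variants are ~3.9× denser in the hypomutated intersection
than in the scored genome at large (184 vs 48 per Mb), and — the point of
the dual model — denser than in either the high-SNP margin (156/Mb) or the
low-SOM margin (61/Mb) alone. Script 04 shows the planted somatic structure
recovered (relative density 1.84 in late-replicating domains, 0.31 in early
ones; forest OOB R² 0.94), and script 06 shows conserved elements 25.6×
enriched for hypomutated positions, far outside the permutation envelope,
while late domains are significantly depleted.

## Library and CLI

All computation lives in `src/dualmut/` (interval arithmetic and BED/VCF
IO, the synthetic generator, feature engine, both models, dual scoring,
enrichment). A thin `dualmut` CLI wraps the pipeline:

```bash
dualmut run-all --config config.yaml --outdir out --seed 1
```

with stage subcommands (`simulate`, `snp-fit`, `som-fit`, `classify`,
`quadrant-test`, `enrich`, `gene-map`, …) that rerun deterministically from
the same config and seed. Every run writes a `manifest.json` with config
and artifact digests, per-stage seeds and row counts.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch on the demo synthetic world —
generation, both model fits, sliding scores, dual cutoffs, quadrant test
and permutation enrichment — writing artifacts under
`results/acceptance_run/` and the results JSON to `--out`.
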