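"""Fit the germline (SNP) model: feature selection, forest, importance.

Runs the two-phase decoy-threshold selection, fits the weighted forest on
the retained combinations, reports node-purity importances and the
weighted out-of-bag R², and emits the genome-wide 1 kb SNP score as
bedGraph. Features planted with strong rare-SNP effects should top the
importance table; pure-coverage features should be discarded.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

from _shared import SEED, make_matrices, make_world, outdir
from dualmut.io import write_bedgraph_bins
from dualmut.snp_model import (
    crossval_correlation,
    fit_snp_model,
    report_importance,
    select_features,
    snp_score_bins,
)
from dualmut.som_model import ScoredTrack


def main() -> None:
    g, tr, variants = make_world()
    cm, _ = make_matrices(g, tr, variants)
    out = outdir()

    report = select_features(cm, seed=SEED)
    print(f"selected features: {report.selected} "
          f"(decoy threshold {report.decoy_threshold:.4f})")

    fit = fit_snp_model(cm, features=report.selected, seed=SEED)
    cv_r = crossval_correlation(cm, features=report.selected, seed=SEED)
    print(f"10-fold CV correlation (held-out combinations): {cv_r:.3f}")
    print(f"weighted OOB R²: {fit.oob_r2:.3f} "
          "(dominated by the background combination; see docs/methods.md)")
    imp = report_importance(fit)
    imp.to_csv(out / "snp_importance.tsv", sep="\t", index=False)
    print(imp.to_string(index=False))

    bins = snp_score_bins(fit, g, tr)
    st = ScoredTrack.empty(g)
    st.set_channel("snp_score", bins)
    write_bedgraph_bins(
        out / "snp_score.bedgraph",
        st.df["chrom"], st.df["start"], st.df["snp_score"].to_numpy(float), st.bin_bp,
    )
    print(f"1 kb SNP score written to {out / 'snp_score.bedgraph'}")


if __name__ == "__main__":
    main()
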