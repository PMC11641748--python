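#!/usr/bin/env python
"""Rank correlation of gene expression with editing efficiency.

Simulates six-replicate negative-binomial counts for 50 genes coupled to
per-gene narrow-window editing efficiencies at a planted Spearman
correlation of 0.25, normalises counts (median-of-ratios + log2),
matches genes and computes Spearman's rho, plus a 30-seed mean showing
the generator hits the planted correlation.  Writes
results/expression_correlation.json and results/expression_pairs.tsv.

Finding: at n = 50 a planted rho of 0.25 is recovered in the mean but a
single cohort's estimate is noisy (sampling SD ~0.14) -- the same regime
in which a reported rho of this size fails to reach 5% significance.
"""

import json
import sys
from pathlib import Path

from ampedit.studies import expression_study

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    res = expression_study(seed)
    OUT.mkdir(exist_ok=True)
    res["pairs"].to_csv(OUT / "expression_pairs.tsv", sep="\t")
    payload = {k: res[k] for k in ("rho", "p_value", "n", "mean_recovered_rho",
                                   "correlation_target", "n_recovery_seeds")}
    (OUT / "expression_correlation.json").write_text(json.dumps(payload, indent=2) + "\n")
    print(f"single cohort: Spearman rho={res['rho']:.3f} (p={res['p_value']:.4f}, n={res['n']})")
    print(f"mean over {res['n_recovery_seeds']} seeds: rho={res['mean_recovered_rho']:.3f} "
          f"(planted {res['correlation_target']})")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
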