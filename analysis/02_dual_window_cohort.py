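#!/usr/bin/env python
"""Screen a cohort of sgRNA loci with the dual-window contrast.

Simulates 224 sgRNA loci (23% carrying planted flanking variation),
computes AEE in both windows per locus, groups loci at the 10-pp
threshold and runs the proportion statistics (arcsine transform, Levene,
two-level repeated-measures ANOVA) per group.  Writes
results/cohort.tsv and results/cohort_summary.json.

Finding: ~77% of loci stay within 10 pp.  The wide window is inflated in
both groups (it is never smaller by construction), but the effect sizes
differ by an order of magnitude: a ~1-pp sequencing-error offset in the
concordant group versus the tens of percentage points of planted
variation in the discordant group (repeated-measures p << 0.001).
"""

import json
import sys
from pathlib import Path

from ampedit.studies import cohort_study

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    res = cohort_study(seed)
    OUT.mkdir(exist_ok=True)
    res["table"].to_csv(OUT / "cohort.tsv", sep="\t", index=False)
    summary = {
        "n_loci": len(res["table"]),
        "threshold_pp": res["threshold_pp"],
        "fraction_below": res["fraction_below"],
        "stats": res["stats"],
    }
    (OUT / "cohort_summary.json").write_text(json.dumps(summary, indent=2, default=float) + "\n")
    print(f"{len(res['table'])} loci; {100 * res['fraction_below']:.1f}% within "
          f"{res['threshold_pp']:.0f} pp of window agreement")
    for group, s in res["stats"].items():
        print(f"  {group}: n={s['n']}  Levene W={s['levene_W']:.3f} (p={s['levene_p']:.3g})  "
              f"RM-ANOVA F={s['rm_anova_F']:.1f} (p={s['rm_anova_p']:.3g})")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
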