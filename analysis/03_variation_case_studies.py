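#!/usr/bin/env python
"""The three genetic-variation case studies, with allele tables.

Simulates one locus per artifact type -- a 49% SNP carrier 8 nt from the
cut, a divergent homologous allele at 21.6%, and repeat co-amplification
with ~10% narrow-window false editing -- runs the control/treated
pipeline on each, classifies them, and renders the allele tables.
Writes results/variation_cases.json and results/variation_alleles.txt.

Finding: each scenario reproduces its published signature (narrow window
quiet for SNP/homolog but not for repeats; a single matched major allele
only in the homolog case) and the classifier recovers the artifact type;
the control-corrected efficiency strips the pre-existing variation from
the treated estimate.
"""

import json
import sys
from pathlib import Path

from ampedit.quant import render_allele_table
from ampedit.studies import variation_cases_study

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    res = variation_cases_study(seed)
    OUT.mkdir(exist_ok=True)
    (OUT / "variation_cases.json").write_text(
        json.dumps(res["summary"], indent=2, default=float) + "\n"
    )
    blocks = []
    for name in ("snp", "homolog", "repeat"):
        case = res[name]
        blocks.append(f"=== {name} scenario (label {case['call'].label}) ===")
        blocks.append("-- sgRNA-free control --")
        blocks.append(render_allele_table(case["control"].alleles, case["amplicon"], max_rows=8))
        blocks.append("-- sgRNA-treated --")
        blocks.append(render_allele_table(case["treated"].alleles, case["amplicon"], max_rows=8))
        blocks.append("")
    (OUT / "variation_alleles.txt").write_text("\n".join(blocks))
    for k, v in res["summary"].items():
        print(f"{k}: {v if isinstance(v, str) else round(v, 2)}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
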