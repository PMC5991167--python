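"""Genomic constitution of the F6 cohort: crossovers, non-recombinant
chromosomes and the observable-crossover expectation.

Compares the confirmation-rule crossover counts on the framework map with
the closed-form expectation (cumulative 21.0 at F2, 27.5 at F6 for a
14-crossover F1 base) and tabulates non-recombinant chromosome classes.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import PIPELINE_DIR, RESULTS

from rilmap.constitution import CrossoverTheory, floor_one_decimal


def main():
    summary = json.loads((PIPELINE_DIR / "constitution_summary.json").read_text())
    theory = CrossoverTheory()
    print("expected observable crossovers per individual (cumulative):")
    rows = []
    for g in range(1, 7):
        rows.append(
            {"generation": f"F{g}",
             "per_generation": theory.per_generation(g),
             "cumulative": floor_one_decimal(theory.cumulative(g))}
        )
        print(f"  F{g}: per-generation {theory.per_generation(g):7.4f}  "
              f"cumulative {floor_one_decimal(theory.cumulative(g)):5.1f}")
    pd.DataFrame(rows).to_csv(RESULTS / "crossover_theory.tsv", sep="\t", index=False)

    print(f"\nobserved mean recombination events/individual: "
          f"{summary['mean_junctions_per_individual']:.1f} "
          f"(expectation without suppression: "
          f"{floor_one_decimal(theory.cumulative(6))})")
    print(f"non-recombinant chromosome pairs: {summary['non_recombinant']}"
          f"/{summary['denominator']} "
          f"({100 * summary['non_recombinant_fraction']:.1f}%)"
          f" — maternal {summary['maternal_non_recombinant']}, "
          f"paternal {summary['paternal_non_recombinant']}")
    per = pd.DataFrame(summary["per_chromosome"]).T
    print("\nper-chromosome breakdown:")
    print(per.to_string())
    per.to_csv(RESULTS / "nonrecombinant_per_chromosome.tsv", sep="\t")
    print(f"\naverage heterozygosity per locus: "
          f"{100 * summary['average_heterozygosity']:.2f}% "
          f"(neutral theory at F6: {100 * 0.5**5:.3f}%)")


if __name__ == "__main__":
    main()
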