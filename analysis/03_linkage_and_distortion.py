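"""Linkage grouping stability and segregation distortion on the framework map.

Reports the number of linkage groups across a LOD 6-9 sweep (seven groups
expected for a seven-chromosome genome) and the fraction of framework loci
departing from the 1:1 homozygote ratio at p < 0.05, per chromosome.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import PIPELINE_DIR, RESULTS


def main():
    groups = json.loads((PIPELINE_DIR / "linkage_groups.json").read_text())
    sizes = sorted((len(g) for g in groups["groups"]), reverse=True)
    print(f"linkage groups at LOD 6: {len(sizes)} (sizes {sizes})")
    print("LOD sweep:", groups["lod_sweep"])
    print("(seven groups expected; with only 41 lines a sparse bin region "
          "can split a chromosome — larger cohorts recover exactly seven)")

    sd = pd.read_csv(PIPELINE_DIR / "segregation_distortion.tsv", sep="\t")
    tested = sd[~sd["skipped"]]
    frac = tested["distorted"].mean()
    print(f"\ndistorted framework loci (p < 0.05): "
          f"{tested['distorted'].sum()}/{len(tested)} ({100 * frac:.0f}%)")
    per = pd.read_csv(
        PIPELINE_DIR / "distortion_per_chromosome.tsv", sep="\t", index_col=0
    )
    print("per-chromosome distorted fraction:")
    print(per.to_string())
    per.to_csv(RESULTS / "distortion_summary.tsv", sep="\t")
    print("note: no viability selection acts in this cohort, so distortion "
          "reflects chi-square type-I error (~5%) plus drift — recombination "
          "suppression lets whole chromosomes fix toward one founder in a "
          "small cohort, producing the chromosome-level distortion blocks "
          "visible above; add viability loci to emulate true selection")


if __name__ == "__main__":
    main()
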