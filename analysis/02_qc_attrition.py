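"""Audit the marker-QC cascade: how many markers each rule removes.

Reads the QC report from the pipeline run and prints the attrition of the
observed SNP panel through monomorphic exclusion, the 35% missingness cut,
depth-20 stringency masking, singleton correction and redundant binning —
the same narrative as a raw-SNPs-to-framework-bins count.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import PIPELINE_DIR, RESULTS


def main():
    rep = pd.read_csv(PIPELINE_DIR / "qc_report.tsv", sep="\t")
    print("QC attrition (markers in -> out, calls masked):")
    for _, row in rep.iterrows():
        print(
            f"  {row['stage']:12s} {row['markers_in']:5d} -> {row['markers_out']:5d}"
            f"   masked calls: {row['calls_masked']}"
        )
    total_in = rep["markers_in"].iloc[0]
    total_out = rep["markers_out"].iloc[-1]
    print(f"\n{total_in} observed SNPs resolved into {total_out} framework bins "
          f"({100 * total_out / total_in:.0f}%)")
    out = RESULTS / "qc_attrition.tsv"
    rep.to_csv(out, sep="\t", index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
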