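#!/usr/bin/env python
"""Simulate a Cas3 progressive-deletion screen on the top region.

Targets the midpoint of the rank-1 dispensable region, computes the
maximal deletion window permitted by the flanking essential genes,
simulates a 200-colony deletion library (uniform endpoint model, 5%
escapers), screens it with a 2 kb tiling-PCR panel, and inverts the
band patterns into inferred deletion bounds, reporting how often the
inference brackets the true interval.
"""

from pathlib import Path

import pandas as pd

from genoslim.io_formats import read_annotation, read_essentiality
from genoslim.pipeline import cmd_cas3

ROOT = Path(__file__).resolve().parents[1]
FIXTURES = ROOT / "results" / "fixtures"


def main() -> None:
    ann = read_annotation(FIXTURES / "genome.gb")
    ess = read_essentiality(ROOT / "results" / "essentiality.tsv")
    regions = pd.read_csv(ROOT / "results" / "regions" / "regions.tsv", sep="\t")
    top = regions.iloc[0]
    protospacer = int((top["start_coord"] + top["end_coord"]) // 2)
    print(f"targeting rank-1 region {top['first_locus']}..{top['last_locus']} "
          f"at protospacer {protospacer}")

    report = cmd_cas3(
        ann, ess, protospacer, ROOT / "results" / "cas3",
        n_colonies=200, escaper_prob=0.05, seed=42, force=True,
    )
    wl, wr = report["window"]
    print(f"flanking-essential window: [{wl}, {wr}) = {wr - wl} bp")
    print(f"escapers: {report['n_escapers']}/200; mean deletion {report['mean_length']:.0f} bp")
    print(f"tiling inference bracketed the true deletion in "
          f"{report['n_bracketed']}/200 colonies")
    print("library, band matrix, histogram and inference tables under results/cas3/")


if __name__ == "__main__":
    main()
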