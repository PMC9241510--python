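#!/usr/bin/env python
"""Classify every taxon pair as aggregated, segregated or random.

Runs the exact hypergeometric co-occurrence test on the filtered occurrence
matrix at alpha = 0.05 per tail, with an expected-joint-count testability
filter of 1.  Writes pair_tests.tsv.
"""

from pathlib import Path

import pandas as pd

import guildnet as gn
from guildnet.pipeline import write_tsv

OUT = Path("results/analysis")


def main() -> None:
    occ = pd.read_csv(OUT / "occurrence.tsv", sep="\t", index_col=0)
    pairs = gn.test_all_pairs(occ, alpha=0.05, min_expected=1.0)
    write_tsv(pairs, OUT / "pair_tests.tsv", index=False)
    counts = pairs["classification"].value_counts()
    n_untestable = int((~pairs["testable"]).sum())
    print(f"{len(pairs)} unordered pairs from {occ.shape[0]} taxa")
    print(f"aggregated (co-occurrence): {counts.get('aggregated', 0)}")
    print(f"segregated (co-exclusion):  {counts.get('segregated', 0)}")
    print(f"random: {counts.get('random', 0)} (of which {n_untestable} untestable "
          "by the expected-count filter)")
    print(f"wrote {OUT}/pair_tests.tsv")


if __name__ == "__main__":
    main()
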