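#!/usr/bin/env python
"""Generate the synthetic study corpus.

Writes four quarterly FAERS-style ASCII packages (10,000 reports, one
injected drug-event association at rate ratio 5) under scratch/corpus/,
plus the PT->SOC mapping implied by the generator vocabulary and the
analytic ground-truth table under results/.
"""

from pathlib import Path

import pandas as pd

from faers_signals.faers_io import write_quarter
from faers_signals.synthetic_faers import (
    SyntheticSpec,
    default_soc_mapping,
    generate,
    ground_truth,
)

ROOT = Path(__file__).resolve().parents[1]
CORPUS_DIR = ROOT / "scratch" / "corpus"
RESULTS = ROOT / "results"
SEED = 1


def main() -> None:
    spec = SyntheticSpec(seed=SEED)
    CORPUS_DIR.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    for quarter in generate(spec):
        write_quarter(quarter, CORPUS_DIR)
        print(f"{quarter.quarter_label}: {quarter.manifest}")

    mapping = default_soc_mapping(spec)
    pd.DataFrame(sorted(mapping.items()), columns=["pt", "soc"]).to_csv(
        CORPUS_DIR / "pt2soc.tsv", sep="\t", index=False, header=False)

    gt = ground_truth(spec)
    gt.to_csv(RESULTS / "ground_truth.tsv", sep="\t", index=False,
              float_format="%.6f")
    print("\ninjected associations (analytic expectations):")
    print(gt.to_string(index=False))


if __name__ == "__main__":
    main()
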