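#!/usr/bin/env python
"""Example box-plot of a filtered survey table (not part of the tested API).

Usage:  python scripts/plot_survey.py survey.tsv survey.png
"""

import sys

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def main(table_path: str, out_path: str) -> None:
    table = pd.read_csv(table_path, sep="\t")
    groups = [
        (stype, sub.log10_pct.values)
        for stype, sub in table.groupby("sample_type")
    ]
    fig, ax = plt.subplots(figsize=(1.2 * len(groups) + 2, 4))
    ax.boxplot([v for _, v in groups], tick_labels=[t for t, _ in groups])
    ax.set_ylabel("relative abundance, log10(%)  (-1 = 0.1%)")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    print(f"wrote {out_path}")


if __name__ == "__main__":
    main(sys.argv[1], sys.argv[2])
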