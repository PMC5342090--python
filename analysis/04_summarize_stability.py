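"""Summarize stability tiers by value type, filter, wavelet and family.

Reads results/repro_records.csv (run 03 first) and writes per-group tier
counts/percentages with mean/median CCC and ICC, plus fixed-width histogram
counts for plotting, under results/. Prints the per-value-type ranking of
volume-normalized features (the analysis the stability recommendation
rests on).
"""

from pathlib import Path

import pandas as pd

from radrepro import summarize
from radrepro.pipeline import SUMMARY_KEYS

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = pd.read_csv(OUT / "repro_records.csv")
    for key in SUMMARY_KEYS:
        summary, hist = summarize(records, group_by=key)
        summary.to_csv(OUT / f"summary_{key}.csv", index=False)
        hist.to_csv(OUT / f"hist_{key}.csv", index=False)

    norm = records[records["normalized"] & (records["repro_class"] != "missing")]
    summary, _ = summarize(norm, group_by="value_type")
    ranking = summary.sort_values("mean_icc", ascending=False)
    print("volume-normalized features, stability by value type:")
    print(
        ranking[["value_type", "n", "pct_high", "pct_medium", "pct_low", "mean_ccc", "mean_icc"]]
        .to_string(index=False)
    )
    print(f"most stable value type on this cohort: {ranking.iloc[0]['value_type']}")


if __name__ == "__main__":
    main()
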