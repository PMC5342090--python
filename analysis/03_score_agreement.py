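"""Score test-retest agreement for every extracted feature.

Reads results/features.csv (run 02 first) and computes, for each
(feature, value type, raw/normalized) combination across the cohort, Lin's
CCC and the two-way consistency ICC, then assigns the stability tier
(high >= 0.8 > medium >= 0.5 > low). Writes results/repro_records.csv.
"""

from pathlib import Path

import pandas as pd

from radrepro import score_feature_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    features = pd.read_csv(OUT / "features.csv")
    records = score_feature_table(features)
    records.to_csv(OUT / "repro_records.csv", index=False)

    defined = records[records["repro_class"] != "missing"]
    print(f"scored {len(records)} records ({len(records) - len(defined)} degenerate)")
    for normalized, grp in defined.groupby("normalized"):
        label = "volume-normalized" if normalized else "raw"
        print(
            f"  {label:>17}: mean CCC {grp['ccc'].mean():.3f}, "
            f"mean ICC {grp['icc'].mean():.3f}, "
            f"high tier {(grp['repro_class'] == 'high').mean() * 100:.1f}%"
        )


if __name__ == "__main__":
    main()
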