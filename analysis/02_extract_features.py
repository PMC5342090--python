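"""Extract geometry and texture features from the simulated cohort.

Reads results/cohort/cohort_manifest.csv (run 01 first), validates the
pairing, and extracts the texture feature table — per patient and scan, all
five slice-aggregation value types, raw and volume-normalized — plus the
Table-1-style geometry summary. Uses the reduced channel profile (original
+ one LoG width, 62 features) to keep the run short; switch to
ChannelConfig() for the full 775-feature manifest.
"""

from pathlib import Path

from radrepro import ChannelConfig, extract_cohort_features, validate_cohort
from radrepro.pipeline import load_manifest_pairs

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    manifest = OUT / "cohort" / "cohort_manifest.csv"
    issues = validate_cohort(manifest)
    if issues:
        raise SystemExit(f"cohort validation failed: {issues}")
    pairs = load_manifest_pairs(manifest)
    features, geometry, exclusions = extract_cohort_features(
        pairs, ChannelConfig.reduced()
    )
    features.to_csv(OUT / "features.csv", index=False)
    geometry.to_csv(OUT / "geometry.csv", index=False)

    n_excluded = sum(exclusions.values())
    by_scan = geometry.groupby("scan")[["volume_mm3", "area_mm2", "v_over_a_mm"]].agg(
        ["mean", "std"]
    )
    print(f"extracted {features['feature_id'].nunique()} features x "
          f"{features['value_type'].nunique()} value types for "
          f"{geometry['patient_id'].nunique()} patients ({n_excluded} degenerate slices)")
    print("cohort geometry (mean +/- sd by scan):")
    print(by_scan.round(1).to_string())


if __name__ == "__main__":
    main()
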