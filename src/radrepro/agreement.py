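"""Test-retest agreement scoring: CCC, ICC, stability tiers and summaries.

CCC is Lin's concordance correlation coefficient with population (1/n)
moments,

    CCC = 2 * cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2),

measuring agreement of paired measurements around the identity line. The
(n-1) sample-moment variant is available via ``sample_moments=True`` for
cross-checking against standard statistical packages; the two differ by
O(1/n).

ICC is the single-measure consistency coefficient from a two-way mixed
ANOVA (subjects x scans),

    ICC = (MS_R - MS_W) / (MS_R + (k - 1) * MS_W),   k = 2 scans,

where MS_R is the between-subject mean square and MS_W the residual mean
square after removing the scan effect; a constant between-scan offset
therefore does not reduce it. The absolute-agreement variant (which charges
the scan effect against agreement) is available via ``model="agreement"``.
Negative values are reported as computed and classified low.

Tiers: high (ICC >= 0.8), medium (0.8 > ICC >= 0.5), low (ICC < 0.5).
Degenerate series (both scans constant) yield missing records, excluded
from summary denominators and counted separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PairedSeries",
    "ccc",
    "icc",
    "classify_icc",
    "score_feature_table",
    "summarize",
    "feature_volume_association",
    "CLASS_ORDER",
]

CLASS_ORDER: tuple[str, ...] = ("high", "medium", "low")

#: ICC tier thresholds: high >= 0.8 > medium >= 0.5 > low
THRESH_HIGH = 0.8
THRESH_MEDIUM = 0.5


@dataclass(frozen=True)
class PairedSeries:
    """Per-patient values at scan 1 (x) and scan 2 (y), aligned by patient."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=np.float64))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=np.float64))
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1D arrays of equal length")
        if self.x.size < 2:
            raise ValueError("need at least 2 patients")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("non-finite values in paired series")

    @property
    def n(self) -> int:
        return self.x.size


def _as_series(series, y=None) -> PairedSeries:
    if y is not None:
        return PairedSeries(np.asarray(series), np.asarray(y))
    return series


def ccc(series: PairedSeries | np.ndarray, y: np.ndarray | None = None,
        sample_moments: bool = False) -> float:
    """Lin's concordance correlation coefficient; NaN if both series are constant."""
    s = _as_series(series, y)
    ddof = 1 if sample_moments else 0
    vx = s.x.var(ddof=ddof)
    vy = s.y.var(ddof=ddof)
    if vx == 0 and vy == 0:
        return float("nan")
    cov = ((s.x - s.x.mean()) * (s.y - s.y.mean())).sum() / (s.n - ddof)
    return float(2.0 * cov / (vx + vy + (s.x.mean() - s.y.mean()) ** 2))


def icc(series: PairedSeries | np.ndarray, y: np.ndarray | None = None,
        model: str = "consistency") -> float:
    """Single-measure two-way ICC for k = 2 scans; NaN when undefined.

    ``model="consistency"`` (default) uses the residual mean square after
    removing the scan effect; ``model="agreement"`` additionally charges the
    scan mean square to the denominator (ICC(A,1)).
    """
    s = _as_series(series, y)
    n, k = s.n, 2
    data = np.stack([s.x, s.y], axis=1)
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    resid = data - row_means[:, None] - col_means[None, :] + grand
    ss_err = np.sum(resid**2)
    ms_r = ss_rows / (n - 1)
    ms_w = ss_err / ((n - 1) * (k - 1))
    if model == "consistency":
        denom = ms_r + (k - 1) * ms_w
        if denom == 0:
            return float("nan")
        return float((ms_r - ms_w) / denom)
    if model == "agreement":
        ms_c = ss_cols / (k - 1)
        denom = ms_r + (k - 1) * ms_w + (k / n) * (ms_c - ms_w)
        if denom == 0:
            return float("nan")
        return float((ms_r - ms_w) / denom)
    raise ValueError(f"unknown ICC model {model!r}")


def classify_icc(icc_value: float) -> str:
    """Three stability tiers; boundaries inclusive downward (0.8 -> high)."""
    if icc_value is None or not np.isfinite(icc_value):
        return "missing"
    if icc_value >= THRESH_HIGH:
        return "high"
    if icc_value >= THRESH_MEDIUM:
        return "medium"
    return "low"


# ---------------------------------------------------------------------------
# cohort scoring


def score_feature_table(features: pd.DataFrame) -> pd.DataFrame:
    """Score every (feature, value type, normalization) across the cohort.

    ``features`` is the long-format table with columns (patient_id, scan,
    feature_id, value_type, raw_value, volume_normalized_value); scan must
    take the values 1 and 2 for every patient. Patients with a missing
    (NaN) value for a given feature are dropped pairwise. Returns one row
    per (feature_id, value_type, normalized) with ccc, icc and class.
    """
    required = {"patient_id", "scan", "feature_id", "value_type", "raw_value"}
    missing = required - set(features.columns)
    if missing:
        raise ValueError(f"feature table lacks columns {sorted(missing)}")
    value_cols = [("raw_value", False)]
    if "volume_normalized_value" in features.columns:
        value_cols.append(("volume_normalized_value", True))

    records = []
    for col, normalized in value_cols:
        wide = features.pivot_table(
            index=["feature_id", "value_type"],
            columns=["scan", "patient_id"],
            values=col,
            aggfunc="first",
        )
        patients = sorted(set(wide.columns.get_level_values("patient_id")))
        x_all = wide[1].reindex(columns=patients).to_numpy()
        y_all = wide[2].reindex(columns=patients).to_numpy()
        index = wide.index
        for row in range(x_all.shape[0]):
            x, y = x_all[row], y_all[row]
            ok = np.isfinite(x) & np.isfinite(y)
            feature_id, value_type = index[row]
            if ok.sum() < 2:
                c = i = float("nan")
            else:
                s = PairedSeries(x[ok], y[ok])
                c = ccc(s)
                i = icc(s)
            records.append(
                {
                    "feature_id": feature_id,
                    "value_type": value_type,
                    "normalized": normalized,
                    "n_patients": int(ok.sum()),
                    "ccc": c,
                    "icc": i,
                    "repro_class": classify_icc(i),
                }
            )
    out = pd.DataFrame(records)
    n_missing = int((out["repro_class"] == "missing").sum())
    if n_missing:
        logger.info("%d degenerate feature series recorded as missing", n_missing)
    return out


def _annotate_groups(records: pd.DataFrame) -> pd.DataFrame:
    parts = records["feature_id"].str.split("/", expand=True)
    out = records.copy()
    out["filter"] = parts[0]
    out["wavelet"] = parts[1]
    out["family"] = np.where(parts[2].str.startswith("glcm_"), "GLCM", "GLRLM")
    out["overall"] = "all"
    return out


def summarize(
    records: pd.DataFrame, group_by: str = "value_type", hist_bin_width: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group tier counts/percentages, mean/median CCC & ICC, histograms.

    ``group_by`` is one of value_type, filter, wavelet, family, overall.
    Missing records are excluded from denominators and reported in a
    separate ``n_missing`` column. Returns (summary, histogram) frames; the
    histogram uses fixed-width bins (default 0.05) on [-1, 1].
    """
    if records.empty:
        raise ValueError("no records to summarize")
    allowed = {"value_type", "filter", "wavelet", "family", "overall", "normalized"}
    if group_by not in allowed:
        raise ValueError(f"unknown grouping key {group_by!r}; expected one of {sorted(allowed)}")
    ann = _annotate_groups(records)

    edges = np.round(np.arange(-1.0, 1.0 + hist_bin_width / 2, hist_bin_width), 10)
    summary_rows = []
    hist_rows = []
    for key, grp in ann.groupby(group_by, sort=True):
        defined = grp[grp["repro_class"] != "missing"]
        n = len(defined)
        counts = {c: int((defined["repro_class"] == c).sum()) for c in CLASS_ORDER}
        row = {
            group_by: key,
            "n": n,
            "n_missing": int(len(grp) - n),
            **{f"n_{c}": counts[c] for c in CLASS_ORDER},
            **{
                f"pct_{c}": round(100.0 * counts[c] / n, 1) if n else float("nan")
                for c in CLASS_ORDER
            },
            "mean_ccc": float(defined["ccc"].mean()) if n else float("nan"),
            "median_ccc": float(defined["ccc"].median()) if n else float("nan"),
            "mean_icc": float(defined["icc"].mean()) if n else float("nan"),
            "median_icc": float(defined["icc"].median()) if n else float("nan"),
        }
        summary_rows.append(row)
        for stat in ("ccc", "icc"):
            vals = np.clip(defined[stat].to_numpy(), -1.0, 1.0)
            counts_h, _ = np.histogram(vals, bins=edges)
            for b, c in enumerate(counts_h):
                hist_rows.append(
                    {
                        group_by: key,
                        "statistic": stat,
                        "bin_left": edges[b],
                        "bin_right": edges[b + 1],
                        "count": int(c),
                    }
                )
    return pd.DataFrame(summary_rows), pd.DataFrame(hist_rows)


def feature_volume_association(
    feature: np.ndarray, volumes: np.ndarray, standardize: str = "z"
) -> tuple[float, str]:
    """ICC-based association between a feature series and tumor volumes.

    Because feature and volume live on incommensurate scales, both series
    are aligned first: ``standardize="z"`` (default) maps each to zero mean
    and unit variance (population moments); ``"rank"`` replaces values by
    ranks; ``"none"`` uses raw values. The aligned pair is scored with the
    consistency ICC and classified with the same tiers.
    """
    feature = np.asarray(feature, dtype=np.float64)
    volumes = np.asarray(volumes, dtype=np.float64)
    if feature.shape != volumes.shape or feature.ndim != 1:
        raise ValueError("feature and volume series must be 1D and aligned")
    if volumes.std() == 0:
        return float("nan"), "missing"
    if feature.std() == 0:
        return float("nan"), "missing"

    def align(v: np.ndarray) -> np.ndarray:
        if standardize == "z":
            return (v - v.mean()) / v.std()
        if standardize == "rank":
            from scipy.stats import rankdata

            return rankdata(v).astype(np.float64)
        if standardize == "none":
            return v
        raise ValueError(f"unknown standardization {standardize!r}")

    value = icc(PairedSeries(align(feature), align(volumes)))
    return value, classify_icc(value)
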