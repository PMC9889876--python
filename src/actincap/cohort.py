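"""Sample-level cohort analysis for actin-cap phenotyping studies.

Covers the disease-burden side of the pipeline: the CAG-Age Product (CAP)
score and its severity stratification for Huntington's-disease (HD)
fibroblast donors, per-well/per-sample median aggregation of cell features,
Mann-Whitney U group comparisons on those medians, PCA embedding with
explained-variance reporting, k-means phenotype clustering with per-group
composition tables, and least-squares trend fits of features against CAP
score.

The CAP score combines age at sampling and CAG-repeat length into a single
cumulative-burden index, parameterized so that a score near 100 corresponds
to the expected clinical onset:

    CAP = age * (CAG - 30) / 6.49

Severity classes: CAP < 90 Premanifest, 90 <= CAP <= 114 Mild, CAP > 114
Severe.  A reference cohort of 28 HD fibroblast donor samples (age, sex,
CAG-repeat length, reference CAP score and severity label) ships with the
package; see :func:`load_hd_cohort`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score  # noqa: F401  (re-export for users)
from sklearn.preprocessing import StandardScaler

__all__ = [
    "SampleMeta",
    "GroupTestResult",
    "ClusterReport",
    "TrendFit",
    "cap_score",
    "severity_class",
    "load_hd_cohort",
    "aggregate_medians",
    "mann_whitney",
    "pca_embed",
    "kmeans_phenotypes",
    "trend_fit",
    "benjamini_hochberg",
]

CAP_CAG_OFFSET = 30.0
CAP_NORMALIZER = 6.49
SEVERITY_CUTOFF_LOW = 90.0  # below: Premanifest
SEVERITY_CUTOFF_HIGH = 114.0  # above: Severe; Mild is inclusive of both ends


def cap_score(age: float, cag: float) -> float:
    """CAG-Age Product: ``age * (CAG - 30) / 6.49``.

    Parameters
    ----------
    age : years at sampling (> 0)
    cag : CAG-repeat length of the expanded allele (> 30)
    """
    if age <= 0:
        raise ValueError(f"age must be > 0 years, got {age}")
    if cag <= CAP_CAG_OFFSET:
        raise ValueError(
            f"CAP score undefined for CAG <= {CAP_CAG_OFFSET:.0f}, got {cag}"
        )
    return age * (cag - CAP_CAG_OFFSET) / CAP_NORMALIZER


def severity_class(cap: float) -> str:
    """Stratify a CAP score: Premanifest (<90), Mild (90-114), Severe (>114)."""
    if not cap > 0:
        raise ValueError(f"CAP score must be positive, got {cap}")
    if cap < SEVERITY_CUTOFF_LOW:
        return "Premanifest"
    if cap <= SEVERITY_CUTOFF_HIGH:
        return "Mild"
    return "Severe"


@dataclass
class SampleMeta:
    """Donor-sample metadata with computed CAP score and severity."""

    sample_id: str
    group: str  # HC | HD | HGPS | YoungHC
    age: float
    sex: str
    cag_repeats: int | None = None
    cap_score: float = np.nan
    severity: str = "NA"

    def __post_init__(self) -> None:
        if self.group == "HD":
            if self.cag_repeats is None or self.cag_repeats < 36:
                raise ValueError(
                    f"HD sample {self.sample_id}: CAG repeats must be >= 36"
                )
            if np.isnan(self.cap_score):
                self.cap_score = cap_score(self.age, self.cag_repeats)
            if self.severity == "NA":
                self.severity = severity_class(self.cap_score)


def load_hd_cohort() -> pd.DataFrame:
    """Bundled 28-sample HD fibroblast donor cohort with computed CAP scores.

    Columns include donor age, sex, CAG-repeat length, the reference
    (printed) CAP score and severity label, and freshly computed
    ``cap_score`` / ``severity`` columns from :func:`cap_score` and
    :func:`severity_class`.
    """
    with resources.files("actincap.data").joinpath("hd_cohort.csv").open() as fh:
        df = pd.read_csv(fh)
    df["cap_score"] = [
        cap_score(a, c) for a, c in zip(df["age_years"], df["cag_repeats"])
    ]
    df["severity"] = [severity_class(c) for c in df["cap_score"]]
    return df


def aggregate_medians(
    cells: pd.DataFrame, by: str, features: list[str] | None = None
) -> pd.DataFrame:
    """Per-group medians of numeric cell features (NaN excluded per feature).

    ``by`` is the grouping column (well or sample id); empty groups are
    dropped with a warning.
    """
    if by not in cells.columns:
        raise KeyError(f"grouping column {by!r} not in table")
    if features is None:
        features = [
            c
            for c in cells.columns
            if c != by and pd.api.types.is_numeric_dtype(cells[c])
        ]
    grouped = cells.groupby(by, sort=True)[features]
    out = grouped.median()
    empty = out.index[grouped.count().sum(axis=1) == 0]
    if len(empty):
        warnings.warn(f"dropping empty groups: {list(empty)}", stacklevel=2)
        out = out.drop(index=empty)
    return out


@dataclass
class GroupTestResult:
    """Mann-Whitney U comparison of one feature between two groups."""

    feature: str
    groups: tuple[str, str]
    n: tuple[int, int]
    u_statistic: float
    p_value: float
    medians: tuple[float, float]
    method: str = "exact"
    degenerate: bool = False


EXACT_MAX_N = 12


def mann_whitney(
    a, b, feature: str = "", groups: tuple[str, str] = ("a", "b")
) -> GroupTestResult:
    """Two-sided Mann-Whitney U test on two sets of (typically median) values.

    Uses the exact U-distribution when the pooled sample is small
    (n1 + n2 <= 12) and tie-free, otherwise the tie-corrected normal
    approximation with continuity correction.  Two identical constant
    groups are reported as p = 1 with a ``degenerate`` flag rather than an
    error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 1 or len(b) < 1:
        raise ValueError("each group needs at least one value")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return GroupTestResult(
            feature, groups, (len(a), len(b)),
            u_statistic=len(a) * len(b) / 2.0, p_value=1.0,
            medians=(float(np.median(a)), float(np.median(b))),
            method="degenerate", degenerate=True,
        )
    ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= EXACT_MAX_N and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupTestResult(
        feature, groups, (len(a), len(b)),
        u_statistic=float(res.statistic), p_value=float(min(res.pvalue, 1.0)),
        medians=(float(np.median(a)), float(np.median(b))),
        method=method,
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted q-values; provided as an option, off by default upstream."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


def pca_embed(
    table: pd.DataFrame, standardize: bool = True, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA embedding of a feature table: (scores, explained-variance ratios).

    Features are z-scored by default; zero-variance features are dropped
    with a warning; rows with missing values are not accepted (impute or
    drop beforehand).  Returns the PC scores indexed like the input and the
    per-component explained-variance ratios.
    """
    X = table.astype(float)
    if X.isna().any().any():
        raise ValueError("feature table contains missing values; impute or drop first")
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 features")
    zero_var = X.columns[X.std(ddof=0) == 0]
    if len(zero_var):
        warnings.warn(f"dropping zero-variance features: {list(zero_var)}", stacklevel=2)
        X = X.drop(columns=zero_var)
    vals = X.to_numpy()
    if standardize:
        vals = StandardScaler().fit_transform(vals)
    k = min(n_components, vals.shape[1], vals.shape[0])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(vals)
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(scores, index=table.index, columns=cols), pca.explained_variance_ratio_


@dataclass
class ClusterReport:
    """k-means phenotype clustering summary."""

    k: int
    labels: pd.Series  # cluster assignment per row
    cluster_means: pd.DataFrame  # per-cluster feature means (heat-map table)
    composition: pd.DataFrame | None  # per-cluster % of each group (rows sum to 100)
    inertia: float
    seed: int


def kmeans_phenotypes(
    table: pd.DataFrame,
    k: int = 3,
    seed: int = 0,
    n_init: int = 50,
    groups: pd.Series | None = None,
    standardize: bool = True,
) -> ClusterReport:
    """k-means clustering of per-cell/per-sample phenotypes.

    Features are z-scored, the best of ``n_init`` seeded runs (by inertia)
    is kept, and the report carries per-cluster feature means plus, when a
    group label per row is supplied, the per-cluster composition in percent
    (each cluster row sums to 100).
    """
    X = table.astype(float).to_numpy()
    if np.isnan(X).any():
        raise ValueError("feature table contains missing values")
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} rows, got {X.shape[0]}")
    if len(np.unique(X, axis=0)) < k:
        raise ValueError(f"fewer than k={k} distinct feature rows")
    Xs = StandardScaler().fit_transform(X) if standardize else X
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = pd.Series(km.fit_predict(Xs), index=table.index, name="cluster")
    means = table.groupby(labels).mean()
    composition = None
    if groups is not None:
        counts = pd.crosstab(labels, pd.Series(groups, index=table.index))
        composition = counts.div(counts.sum(axis=1), axis=0) * 100.0
    return ClusterReport(
        k=k,
        labels=labels,
        cluster_means=means,
        composition=composition,
        inertia=float(km.inertia_),
        seed=seed,
    )


@dataclass
class TrendFit:
    """Least-squares trend of a feature against CAP score.

    Solid line: fit on per-sample feature averages; dashed envelope lines:
    fits on per-sample maxima and minima; plus per-severity-subgroup mean
    points.
    """

    feature: str
    slope: float
    intercept: float
    slope_max: float = np.nan
    intercept_max: float = np.nan
    slope_min: float = np.nan
    intercept_min: float = np.nan
    subgroup_means: pd.DataFrame = field(default_factory=pd.DataFrame)

    def predict(self, cap) -> np.ndarray:
        return self.slope * np.asarray(cap, dtype=float) + self.intercept


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: trend line undefined")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def trend_fit(
    samples: pd.DataFrame,
    feature: str,
    cap_col: str = "cap_score",
    max_col: str | None = None,
    min_col: str | None = None,
    severity_col: str | None = "severity",
) -> TrendFit:
    """Ordinary least squares of a per-sample feature average on CAP score.

    ``samples`` holds one row per HD sample with its CAP score and the
    feature's per-sample average (and optionally per-sample max / min for
    the envelope lines).  At least 3 samples are required.
    """
    df = samples.dropna(subset=[cap_col, feature])
    if len(df) < 3:
        raise ValueError("trend fit needs >= 3 samples with CAP scores")
    x = df[cap_col].to_numpy(dtype=float)
    slope, intercept = _ols(x, df[feature].to_numpy(dtype=float))
    fit = TrendFit(feature=feature, slope=slope, intercept=intercept)
    if max_col is not None and max_col in df:
        fit.slope_max, fit.intercept_max = _ols(x, df[max_col].to_numpy(dtype=float))
    if min_col is not None and min_col in df:
        fit.slope_min, fit.intercept_min = _ols(x, df[min_col].to_numpy(dtype=float))
    if severity_col and severity_col in df:
        fit.subgroup_means = df.groupby(severity_col)[[cap_col, feature]].mean()
    return fit
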