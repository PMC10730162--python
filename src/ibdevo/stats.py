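"""Inferential layer: Bray-Curtis, PERMANOVA, PLS-DA, group scans, correlation.

The group-discrimination workflow pairs an ordination (PLS-DA) with a
permutation test of group separation (one-factor PERMANOVA on Bray-Curtis
distances, the adonis form); univariate screens use two-sample rank tests
with Benjamini-Hochberg correction across the panel.  The two-sample
comparisons here are between independent WT and KO groups, so the rank-sum
(Mann-Whitney) test is the default; the paired signed-rank variant is
available for explicitly paired designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import squareform
from sklearn.cross_decomposition import PLSRegression
from statsmodels.stats.multitest import multipletests

from ._util import ValidationError


@dataclass
class FeatureMatrix:
    """Samples x features table of nonnegative values with group labels."""

    data: pd.DataFrame  # index: sample_ids, columns: feature_ids
    groups: pd.Series  # index: sample_ids, values e.g. {"WT", "KO"}

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.data.index)
        self.validate()

    def validate(self) -> None:
        if self.data.isna().any().any():
            raise ValidationError("feature matrix contains missing cells")
        if self.groups.isna().any():
            raise ValidationError("every sample needs a group label")
        if (self.data.to_numpy() < 0).any():
            raise ValidationError("feature values must be nonnegative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int


@dataclass
class PlsdaFit:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    n_components: int
    dropped_features: list[str] = field(default_factory=list)


@dataclass
class ScanResult:
    feature_id: str
    statistic: float
    raw_p: float
    adjusted_p: float
    direction: str | None  # "higher-in-KO" | "higher-in-WT" | None


def bray_curtis(matrix: FeatureMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity BC(x,y) = sum|xi-yi| / sum(xi+yi).

    Symmetric, zero diagonal, entries in [0, 1].  A pair of all-zero samples
    has an undefined dissimilarity and raises.
    """
    data = matrix.data if isinstance(matrix, FeatureMatrix) else matrix
    values = np.asarray(data, dtype=float)
    if (values < 0).any():
        raise ValidationError("Bray-Curtis requires nonnegative values")
    totals = values.sum(axis=1)
    if (totals == 0).sum() >= 2:
        raise ValidationError("two all-zero samples: Bray-Curtis undefined for that pair")
    n = values.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(values[i] - values[i + 1 :]).sum(axis=1)
        denom = (values[i] + values[i + 1 :]).sum(axis=1)
        with np.errstate(invalid="ignore"):
            d = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), 0.0)
        dist[i, i + 1 :] = d
        dist[i + 1 :, i] = d
    return pd.DataFrame(dist, index=data.index, columns=data.index)


def _permanova_ssw(d2: np.ndarray, labels: np.ndarray) -> float:
    ssw = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        ssw += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ssw


def permanova(
    dist: pd.DataFrame | np.ndarray,
    groups: pd.Series | np.ndarray,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-factor PERMANOVA (adonis form) on a distance matrix.

    pseudo-F = (SS_among / (a-1)) / (SS_within / (N-a)) from squared
    distances; p = (1 + #{permuted F >= observed F}) / (1 + n_permutations)
    with free permutation of sample labels.
    """
    d = np.asarray(dist, dtype=float)
    labels = np.asarray(groups.loc[dist.index] if isinstance(groups, pd.Series) and isinstance(dist, pd.DataFrame) else groups)
    n = d.shape[0]
    if d.shape != (n, n) or labels.shape[0] != n:
        raise ValidationError("distance matrix and groups are inconsistent")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValidationError("PERMANOVA needs >= 2 groups")
    if (counts < 2).any():
        raise ValidationError("PERMANOVA needs >= 2 samples per group")
    a = uniq.size
    d2 = d**2
    sst = d2.sum() / (2.0 * n)

    def f_stat(lab: np.ndarray) -> float:
        ssw = _permanova_ssw(d2, lab)
        ssa = sst - ssw
        return (ssa / (a - 1)) / (ssw / (n - a))

    observed = f_stat(labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        if f_stat(rng.permutation(labels)) >= observed:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_permutations)
    return PermanovaResult(float(observed), float(p), n_permutations)


def plsda_fit(
    matrix: FeatureMatrix, n_components: int = 2, scale: bool = True
) -> PlsdaFit:
    """Partial least squares discriminant analysis against one-hot groups.

    Sequential NIPALS components maximize covariance between the (centered,
    optionally unit-scaled) feature block and the one-hot group encoding,
    with deflation between components.  Constant features are dropped with a
    warning.  Loadings rank which features drive the group separation.
    """
    counts = matrix.groups.value_counts()
    if (counts < 2).any() or counts.size < 2:
        raise ValidationError("PLS-DA needs >= 2 samples per group, >= 2 groups")
    data = matrix.data
    constant = data.columns[data.std(axis=0) == 0].tolist()
    if constant:
        warnings.warn(f"dropping {len(constant)} constant feature(s): {constant[:5]}")
        data = data.drop(columns=constant)
    n_components = min(n_components, min(data.shape))
    y = pd.get_dummies(matrix.groups).to_numpy(dtype=float)
    pls = PLSRegression(n_components=n_components, scale=scale)
    pls.fit(data.to_numpy(dtype=float), y)
    comps = [f"comp{i + 1}" for i in range(n_components)]
    return PlsdaFit(
        scores=pd.DataFrame(pls.x_scores_, index=data.index, columns=comps),
        loadings=pd.DataFrame(pls.x_loadings_, index=data.columns, columns=comps),
        n_components=n_components,
        dropped_features=constant,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def feature_scan(
    matrix: FeatureMatrix,
    test: str = "rank-sum",
    alternative: str = "two-sided",
) -> list[ScanResult]:
    """Per-feature two-group rank test with BH correction across the panel.

    ``rank-sum`` (Mann-Whitney, independent groups, midranks for ties; exact
    p for small tie-free samples, normal approximation otherwise) or
    ``signed-rank`` (Wilcoxon, for paired designs with equal group sizes and
    matching sample order).  Direction comes from the median difference; a
    feature with all values tied gets p = 1 and no direction.
    """
    labels = matrix.groups
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValidationError("feature_scan needs exactly two groups")
    g_ko = "KO" if "KO" in uniq else uniq[0]
    g_wt = [g for g in uniq if g != g_ko][0]
    ko = matrix.data.loc[labels == g_ko]
    wt = matrix.data.loc[labels == g_wt]
    raw_p, stats_, directions = [], [], []
    for feature in matrix.feature_ids:
        x, y = ko[feature].to_numpy(), wt[feature].to_numpy()
        if np.ptp(np.concatenate([x, y])) == 0:
            raw_p.append(1.0)
            stats_.append(np.nan)
            directions.append(None)
            continue
        if test == "rank-sum":
            res = sps.mannwhitneyu(x, y, alternative=alternative)
        elif test == "signed-rank":
            if x.size != y.size:
                raise ValidationError("signed-rank requires paired, equal-size groups")
            res = sps.wilcoxon(x, y, alternative=alternative)
        else:
            raise ValidationError(f"unknown test {test!r}")
        raw_p.append(float(res.pvalue))
        stats_.append(float(res.statistic))
        med = float(np.median(x) - np.median(y))
        directions.append(
            f"higher-in-{g_ko}" if med > 0 else (f"higher-in-{g_wt}" if med < 0 else None)
        )
    adjusted = bh_adjust(raw_p)
    return [
        ScanResult(f, s, p, float(q), d)
        for f, s, p, q, d in zip(matrix.feature_ids, stats_, raw_p, adjusted, directions)
    ]


def scan_to_frame(results: list[ScanResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.feature_id, r.statistic, r.raw_p, r.adjusted_p, r.direction) for r in results],
        columns=["feature_id", "statistic", "raw_p", "adjusted_p", "direction"],
    )


def trajectory_correlation(
    freq_series: pd.DataFrame,
    marker_series: pd.DataFrame,
    scope: str = "KO-only",
    cohort=None,
) -> tuple[float, float]:
    """Spearman correlation of focal-locus frequency with an inflammation marker.

    Pools (mouse, week) pairs: ``freq_series`` has columns (mouse_id, week,
    frequency), ``marker_series`` has (mouse_id, week, marker_per_gram).
    ``scope`` restricts to KO mice ("KO-only", needs ``cohort``) or keeps all
    mice.  Pairs with a missing marker are dropped; < 3 pairs is an error.
    """
    merged = freq_series.merge(marker_series, on=["mouse_id", "week"], how="inner")
    merged = merged.dropna(subset=["frequency", "marker_per_gram"])
    if scope == "KO-only":
        if cohort is None:
            raise ValidationError("KO-only scope needs the cohort design")
        ko = {m.mouse_id for m in cohort.mice if m.genotype == "KO"}
        merged = merged[merged.mouse_id.isin(ko)]
    elif scope != "all-mice":
        raise ValidationError(f"unknown scope {scope!r}")
    if len(merged) < 3:
        raise ValidationError("need >= 3 paired observations")
    rho, p = sps.spearmanr(merged["frequency"], merged["marker_per_gram"])
    return float(rho), float(p)


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H with midrank tie correction and chi-square p.

    All values identical across groups gives H = 0, p = 1.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValidationError("need >= 2 non-empty groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def condensed(dist: pd.DataFrame) -> np.ndarray:
    """Condensed form of a square distance matrix (scipy convention)."""
    return squareform(np.asarray(dist, dtype=float), checks=False)
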