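"""Validation statistics: distribution summaries, weighted kappa, contingency
tables and correlation matrices.

These are the computations used to validate a single index and its grade
thresholds: per-product median/IQR summaries of score distributions,
correlation of the index with the individual impact categories, and
chance-corrected ordinal agreement (weighted Cohen's kappa) between two
A-E categorizations (e.g. expert panel vs. automated grading).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .categorize import GRADES


@dataclass(frozen=True)
class DistributionSummary:
    """Median and interquartile range of one group of values."""

    group: str
    n: int
    median: float
    iqr: float
    quantile_method: str = "linear"


def distribution_summary(
    groups: Mapping[str, Sequence[float]]
) -> list[DistributionSummary]:
    """Summarize value distributions per group (median and IQR).

    Quantiles use linear interpolation between order statistics, the common
    default of mainstream statistical environments; the convention is
    recorded on each summary.  Groups are returned sorted by descending
    median, the order used for ranking displays.
    """
    out = []
    for name, values in groups.items():
        arr = np.asarray(list(values), dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {name!r} is empty")
        q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method="linear")
        out.append(
            DistributionSummary(
                group=str(name), n=int(arr.size), median=float(med), iqr=float(q3 - q1)
            )
        )
    out.sort(key=lambda s: -s.median)
    return out


@dataclass(frozen=True)
class ContingencyTable:
    """K x K cross-tabulation of two categorizations of the same items."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray  # integer K x K

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_percent(self) -> np.ndarray:
        """Row-wise percentages; rows with zero total are all-zero."""
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(totals > 0, 100.0 * self.counts / totals, 0.0)
        return pct

    def to_frame(self, percent: bool = False) -> pd.DataFrame:
        data = self.row_percent if percent else self.counts
        return pd.DataFrame(data, index=list(self.row_labels), columns=list(self.col_labels))


def _encode(labels: Sequence[str], categories: Sequence[str]) -> np.ndarray:
    index = {c: i for i, c in enumerate(categories)}
    try:
        return np.array([index[l] for l in labels], dtype=int)
    except KeyError as exc:
        raise ValueError(f"unknown label {exc.args[0]!r}; expected one of {list(categories)}")


def contingency(
    labels_a: Sequence[str],
    labels_b: Sequence[str],
    categories: Sequence[str] = GRADES,
) -> ContingencyTable:
    """Cross-tabulate two equal-length label sequences.

    ``counts[i, j]`` is the number of pairs with first label = row category i
    and second label = column category j.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError(f"length mismatch: {len(labels_a)} vs {len(labels_b)}")
    k = len(categories)
    a = _encode(labels_a, categories)
    b = _encode(labels_b, categories)
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (a, b), 1)
    return ContingencyTable(tuple(categories), tuple(categories), counts)


@dataclass(frozen=True)
class KappaResult:
    """Weighted Cohen's kappa between two ordinal categorizations."""

    kappa: float
    scheme: str
    n: int
    p_value: float | None = None


def _disagreement_weights(k: int, scheme: str) -> np.ndarray:
    i, j = np.indices((k, k))
    if scheme == "linear":
        return np.abs(i - j) / (k - 1)
    if scheme == "quadratic":
        return ((i - j) / (k - 1)) ** 2
    if scheme == "unweighted":
        return (i != j).astype(float)
    raise ValueError(f"unknown weighting scheme {scheme!r}")


def weighted_kappa_from_table(
    counts: np.ndarray, scheme: str = "linear"
) -> float:
    """Weighted kappa from a K x K contingency table of counts.

    kappa = 1 - sum(v * O) / sum(v * E), with v the ordinal disagreement
    weights, O the observed cell proportions and E the chance-expected
    proportions from the marginals.  A table whose chance-expected weighted
    disagreement is zero (all mass in one category) has undefined kappa and
    is reported as 1.0 when observed agreement is also perfect.
    """
    counts = np.asarray(counts, dtype=float)
    k = counts.shape[0]
    if counts.shape != (k, k) or k < 2:
        raise ValueError(f"need a square table of at least 2 categories, got {counts.shape}")
    n = counts.sum()
    if n < 2:
        raise ValueError("need at least 2 pairs")
    p = counts / n
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    v = _disagreement_weights(k, scheme)
    expected_dis = float((v * np.outer(r, c)).sum())
    observed_dis = float((v * p).sum())
    if expected_dis == 0.0:
        return 1.0 if observed_dis == 0.0 else float("-inf")
    return 1.0 - observed_dis / expected_dis


def weighted_kappa(
    labels_a: Sequence[str],
    labels_b: Sequence[str],
    scheme: str = "linear",
    categories: Sequence[str] = GRADES,
    p_value: bool = False,
    p_value_method: str = "asymptotic",
    n_permutations: int = 10000,
    rng: np.random.Generator | None = None,
) -> KappaResult:
    """Chance-corrected ordinal agreement between two label sequences.

    Parameters
    ----------
    scheme
        ``"linear"`` (default): disagreement weight |i-j|/(K-1);
        ``"quadratic"``: ((i-j)/(K-1))^2; ``"unweighted"``: 0/1.
    p_value
        If True, attach a two-sided p-value for H0: kappa = 0.
    p_value_method
        ``"asymptotic"`` uses the large-sample normal test on the
        null-hypothesis standard error; ``"permutation"`` permutes the second
        labeling (recommended for small n).
    """
    table = contingency(labels_a, labels_b, categories)
    kappa = weighted_kappa_from_table(table.counts, scheme)
    n = table.n
    pv = None
    if p_value:
        if p_value_method == "asymptotic":
            pv = _kappa_asymptotic_p(table.counts, scheme)
        elif p_value_method == "permutation":
            rng = rng or np.random.default_rng()
            b = np.array(labels_b, dtype=object)
            hits = 0
            for _ in range(n_permutations):
                perm = rng.permutation(b)
                kp = weighted_kappa_from_table(
                    contingency(labels_a, list(perm), categories).counts, scheme
                )
                if abs(kp) >= abs(kappa) - 1e-12:
                    hits += 1
            pv = (hits + 1) / (n_permutations + 1)
        else:
            raise ValueError(f"unknown p_value_method {p_value_method!r}")
    return KappaResult(kappa=float(kappa), scheme=scheme, n=n, p_value=pv)


def _kappa_asymptotic_p(counts: np.ndarray, scheme: str) -> float:
    """Two-sided normal-approximation p-value for H0: weighted kappa = 0.

    Uses the null-hypothesis variance of the weighted kappa (Fleiss, Cohen &
    Everitt), expressed in agreement weights w = 1 - v.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    k = counts.shape[0]
    p = counts / n
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    w = 1.0 - _disagreement_weights(k, scheme)
    pe = float((w * np.outer(r, c)).sum())
    if pe >= 1.0:
        return 1.0
    w_row = w @ c          # \bar w_{i.} under the column marginals
    w_col = r @ w          # \bar w_{.j} under the row marginals
    term = (w - (w_row[:, None] + w_col[None, :])) ** 2
    var0 = (float((np.outer(r, c) * term).sum()) - pe**2) / (n * (1.0 - pe) ** 2)
    if var0 <= 0:
        return 1.0
    kappa = weighted_kappa_from_table(counts, scheme)
    z = kappa / np.sqrt(var0)
    return float(2.0 * stats.norm.sf(abs(z)))


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric pairwise correlation matrix with unit diagonal."""

    variables: tuple[str, ...]
    method: str
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.variables), columns=list(self.variables))


def correlation_matrix(
    data: pd.DataFrame, method: str = "pearson"
) -> CorrelationMatrix:
    """Pairwise correlations between the columns of ``data``.

    ``method`` is ``"pearson"`` (default) or ``"spearman"``.  Requires at
    least 3 rows; a constant column is rejected (its correlation is
    undefined) rather than silently producing NaN.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    df = pd.DataFrame(data).astype(float)
    if len(df) < 3:
        raise ValueError(f"need at least 3 rows, got {len(df)}")
    constant = [c for c in df.columns if df[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant variable(s), correlation undefined: {constant}")
    corr = df.corr(method=method)
    values = corr.to_numpy()
    np.fill_diagonal(values, 1.0)
    return CorrelationMatrix(
        variables=tuple(str(c) for c in df.columns), method=method, values=values
    )
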