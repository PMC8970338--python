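"""Nonparametric tests, BH correction, and classical MDS, from first principles.

These are deliberately self-contained, oracle-testable implementations:

* Wilcoxon rank-sum (Mann-Whitney) — exact p by dynamic programming over
  rank-subset sums when both samples are small and untied, otherwise the
  normal approximation with tie-adjusted variance and 0.5 continuity
  correction.  The reported statistic is W, the rank sum of the first
  sample (U = W - n_x(n_x+1)/2).
* Wilcoxon signed-rank — exact p by DP over signed-rank subset sums for
  small n, otherwise the continuity-corrected normal approximation.
* Benjamini-Hochberg step-up FDR adjustment, optionally within families.
* Classical (Torgerson) multidimensional scaling by eigendecomposition of
  the double-centered squared-distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm, rankdata

from .core_types import ValidationError

__all__ = [
    "TestResult",
    "MDSResult",
    "rank_sum_test",
    "signed_rank_test",
    "bh_adjust",
    "classical_mds",
    "band_stats",
]

#: Largest combined sample size for which "auto" mode uses the exact test.
EXACT_LIMIT = 12


@dataclass
class TestResult:
    label: str
    statistic: float  # rank-sum W, or signed-rank W+ (sum of positive ranks)
    z_value: float | None  # normal approximation z (None in exact mode)
    p_raw: float
    p_adjusted: float | None = None
    method: str = "approx"  # exact | approx | degenerate
    n_x: int = 0
    n_y: int = 0


@dataclass
class MDSResult:
    coordinates: np.ndarray  # items x k
    eigenvalues: np.ndarray  # all, non-increasing
    explained_fraction: float  # top-k share of the positive eigenvalues
    truncated: bool = False  # fewer positive eigenvalues than requested k


# ---------------------------------------------------------------------------
# exact null distributions

def _rank_sum_counts(n_x: int, n_total: int) -> np.ndarray:
    """counts[s] = number of n_x-subsets of ranks {1..n_total} summing to s."""
    max_sum = n_total * (n_total + 1) // 2
    dp = np.zeros((n_x + 1, max_sum + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for r in range(1, n_total + 1):
        for k in range(min(r, n_x), 0, -1):
            dp[k, r:] += dp[k - 1, : max_sum + 1 - r]
    return dp[n_x]


def _signed_rank_counts(ranks: np.ndarray) -> tuple[np.ndarray, float]:
    """Distribution of W+ over all sign patterns; returns (counts, step).

    Ranks may be half-integers under ties, so sums are tracked on a grid of
    ``step`` = 0.5; counts[i] corresponds to W+ = i * step.
    """
    step = 0.5
    units = np.rint(np.asarray(ranks) / step).astype(int)
    total = int(units.sum())
    dp = np.zeros(total + 1, dtype=np.float64)
    dp[0] = 1.0
    for u in units:
        dp[u:] += dp[: total + 1 - u]
    return dp, step


def _two_sided_exact(counts: np.ndarray, observed_idx: int) -> float:
    total = counts.sum()
    lo = counts[: observed_idx + 1].sum() / total
    hi = counts[observed_idx:].sum() / total
    return float(min(1.0, 2.0 * min(lo, hi)))


# ---------------------------------------------------------------------------
# rank-sum (Mann-Whitney)

def rank_sum_test(x, y, mode: str = "auto", label: str = "") -> TestResult:
    """Two-sided Wilcoxon rank-sum test of two independent samples.

    ``mode='auto'`` uses the exact DP distribution when
    ``n_x + n_y <= 12`` and there are no ties, else the tie-corrected,
    continuity-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    if mode not in ("exact", "approx", "auto"):
        raise ValidationError(f"mode must be exact|approx|auto, got {mode!r}")
    n_x, n_y = x.size, y.size
    n = n_x + n_y
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    w = float(ranks[:n_x].sum())
    has_ties = np.unique(combined).size < n

    use_exact = mode == "exact" or (mode == "auto" and n <= EXACT_LIMIT and not has_ties)
    if use_exact and has_ties:
        raise ValidationError("exact rank-sum mode requires untied samples")
    if use_exact:
        counts = _rank_sum_counts(n_x, n)
        p = _two_sided_exact(counts, int(round(w)))
        return TestResult(label, w, None, p, method="exact", n_x=n_x, n_y=n_y)

    mu = n_x * (n + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n_x * n_y / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return TestResult(label, w, 0.0, 1.0, method="degenerate", n_x=n_x, n_y=n_y)
    diff = w - mu
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / np.sqrt(var) if diff != 0 else 0.0
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return TestResult(label, w, float(z), p, method="approx", n_x=n_x, n_y=n_y)


# ---------------------------------------------------------------------------
# signed-rank (paired)

def signed_rank_test(before, after, mode: str = "auto", label: str = "") -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Differences ``after - before``; zero differences are dropped.  The
    statistic is W+, the sum of ranks of positive differences.  Exact
    enumeration (DP over sign patterns) for n <= 12 in auto mode.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValidationError("paired samples must have equal length")
    if mode not in ("exact", "approx", "auto"):
        raise ValidationError(f"mode must be exact|approx|auto, got {mode!r}")
    d = after - before
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(label, 0.0, 0.0, 1.0, method="degenerate", n_x=before.size, n_y=after.size)
    if n < 2:
        # a single non-zero difference cannot reach significance two-sided
        return TestResult(label, float(d[0] > 0), None, 1.0, method="exact", n_x=n, n_y=n)
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    use_exact = mode == "exact" or (mode == "auto" and n <= EXACT_LIMIT)
    if use_exact:
        counts, step = _signed_rank_counts(ranks)
        p = _two_sided_exact(counts, int(round(w_plus / step)))
        return TestResult(label, w_plus, None, p, method="exact", n_x=n, n_y=n)

    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0
    if var <= 0:
        return TestResult(label, w_plus, 0.0, 1.0, method="degenerate", n_x=n, n_y=n)
    diff = w_plus - mu
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / np.sqrt(var) if diff != 0 else 0.0
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return TestResult(label, w_plus, float(z), p, method="approx", n_x=n, n_y=n)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg

def bh_adjust(p_values, family_labels=None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, preserving input order.

    q_(i) = min_{j >= i} (p_(j) * m / j), capped at 1, computed
    independently within each family when ``family_labels`` is given.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    out = np.empty_like(p)
    if family_labels is None:
        families = {None: np.arange(p.size)}
    else:
        family_labels = np.asarray(family_labels)
        if family_labels.shape != p.shape:
            raise ValidationError("family_labels must match p_values in length")
        families = {
            lab: np.flatnonzero(family_labels == lab) for lab in np.unique(family_labels)
        }
    for idx in families.values():
        sub = p[idx]
        m = sub.size
        order = np.argsort(sub, kind="stable")
        adjusted = sub[order] * m / np.arange(1, m + 1)
        adjusted = np.minimum.accumulate(adjusted[::-1])[::-1]
        adj = np.empty(m)
        adj[order] = np.minimum(adjusted, 1.0)
        out[idx] = adj
    return out


# ---------------------------------------------------------------------------
# classical MDS

def classical_mds(items, k: int = 2) -> MDSResult:
    """Classical (Torgerson) MDS of feature vectors or a distance matrix.

    Double-centers B = -1/2 J D^2 J, eigendecomposes, and scales the top-k
    eigenvectors by sqrt(eigenvalue).  Negative eigenvalues (non-Euclidean
    input) are excluded from the explained-fraction denominator; if fewer
    than ``k`` positive eigenvalues exist, fewer columns are returned with
    ``truncated=True``.
    """
    a = np.asarray(items, dtype=float)
    if a.ndim != 2:
        raise ValidationError("items must be 2-D (features or a distance matrix)")
    is_dist = (
        a.shape[0] == a.shape[1]
        and np.allclose(a, a.T, atol=1e-10)
        and np.allclose(np.diag(a), 0.0, atol=1e-10)
    )
    D = a if is_dist else squareform(pdist(a))
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-12 if n else 0.0
    n_pos = int(np.sum(eigvals > tol))
    m = min(k, n_pos)
    coords = eigvecs[:, :m] * np.sqrt(np.maximum(eigvals[:m], 0.0))
    pos_sum = float(eigvals[eigvals > tol].sum())
    explained = float(eigvals[:m].sum() / pos_sum) if pos_sum > 0 else 0.0
    return MDSResult(
        coordinates=coords,
        eigenvalues=eigvals,
        explained_fraction=explained,
        truncated=m < k,
    )


# ---------------------------------------------------------------------------
# band-power group comparisons

def band_stats(
    table: pd.DataFrame,
    control_label: str,
    family: str = "per_band",
    alpha: float = 0.05,
    mode: str = "auto",
    compound_of=None,
) -> pd.DataFrame:
    """Compare each treatment group's band power against control, per band.

    ``table`` must have columns (animal_id, group, band, normalized_amplitude)
    with one row per animal x band.  Rank-sum tests per (band, group) vs the
    control group; BH correction applied within the chosen family:
    ``per_band`` (across groups within a band), ``global`` (all comparisons),
    or ``per_compound`` (across bands/concentrations of one compound, where
    the compound is the first whitespace-delimited token of the group label
    unless ``compound_of`` is supplied).
    """
    required = {"animal_id", "group", "band", "normalized_amplitude"}
    if not required.issubset(table.columns):
        raise ValidationError(f"table must have columns {sorted(required)}")
    if family not in ("per_band", "global", "per_compound"):
        raise ValidationError(f"unknown BH family {family!r}")
    groups = table["group"].unique().tolist()
    if control_label not in groups:
        raise ValidationError(f"control group {control_label!r} not present in table")
    counts = table.groupby("group")["animal_id"].nunique()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValidationError(f"groups with fewer than 2 animals: {small}")
    if compound_of is None:
        compound_of = lambda lab: lab.split()[0]

    bands = table["band"].unique().tolist()
    treatments = [g for g in groups if g != control_label]
    rows = []
    for band in bands:
        sub = table[table["band"] == band]
        ctrl = sub.loc[sub["group"] == control_label, "normalized_amplitude"].to_numpy()
        for g in treatments:
            vals = sub.loc[sub["group"] == g, "normalized_amplitude"].to_numpy()
            res = rank_sum_test(vals, ctrl, mode=mode, label=f"{band}:{g}")
            rows.append(
                {
                    "band": band,
                    "group": g,
                    "statistic": res.statistic,
                    "z": np.nan if res.z_value is None else res.z_value,
                    "p_raw": res.p_raw,
                    "method": res.method,
                    "n_treated": res.n_x,
                    "n_control": res.n_y,
                }
            )
    df = pd.DataFrame(rows)
    if family == "per_band":
        labels = df["band"].to_numpy()
    elif family == "per_compound":
        labels = df["group"].map(compound_of).to_numpy()
    else:
        labels = None
    df["p_adjusted"] = bh_adjust(df["p_raw"].to_numpy(), labels)
    df["significant"] = df["p_adjusted"] < alpha
    return df
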