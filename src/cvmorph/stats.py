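"""Longitudinal change statistics for chunk-level morphometry.

Percent change between timepoints uses the convention

    pct_change = (mean_initial - mean_followup) / mean_initial * 100

which is *negative* when a quantity increases; because clinical reports
usually quote increases as positive percentages, the signed-increase
form ``(followup - initial)/initial * 100`` and the magnitude are
exposed alongside, and every output column is explicitly named.

Paired comparisons use the Wilcoxon signed-rank test: zero differences
are dropped (the classic convention — the alternative of keeping them,
Pratt's method, changes p and is deliberately not used), tied absolute
differences receive mid-ranks, and the null distribution of the
positive-rank sum is computed exactly by convolution for n <= 25, with
a continuity- and tie-corrected normal approximation beyond.  Covariate
associations are ordinary least squares with t-based 95% intervals, in
both univariable and multivariable form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

EXACT_WILCOXON_MAX_N = 25


# ------------------------------------------------------------ percent change

def percent_change(initial: float, followup: float) -> float:
    """(initial - followup) / initial * 100; negative for an increase."""
    if initial == 0:
        raise ValueError("percent change is undefined for initial value 0")
    return (initial - followup) / initial * 100.0


def percent_increase(initial: float, followup: float) -> float:
    """(followup - initial) / initial * 100; positive for an increase."""
    if initial == 0:
        raise ValueError("percent change is undefined for initial value 0")
    return (followup - initial) / initial * 100.0


def percent_change_magnitude(initial: float, followup: float) -> float:
    """|percent change| — how figures-of-merit are usually quoted."""
    return abs(percent_change(initial, followup))


# ------------------------------------------------------------ Wilcoxon

@dataclass
class StatResult:
    """A test or model-term result: statistic, two-sided p, CI, n."""

    statistic: float
    p_value: float
    n: int
    coefficient: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    term: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _signed_rank_statistic(diff: np.ndarray) -> tuple[float, np.ndarray]:
    """Positive-rank sum W+ and the mid-ranks of |diff| (zeros removed)."""
    ranks = sps.rankdata(np.abs(diff))
    w_plus = float(ranks[diff > 0].sum())
    return w_plus, ranks


def _exact_signed_rank_sf(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact null PMF of W+ for given (possibly tied mid-) ranks.

    Doubling mid-ranks makes them integers, so the distribution of the
    doubled rank sum over all 2^n sign assignments is computed by
    polynomial convolution.  Returns (support_of_2W, pmf).
    """
    r2 = np.round(2 * ranks).astype(np.int64)
    if not np.allclose(2 * ranks, r2):
        raise AssertionError("mid-ranks * 2 should be integral")
    total = int(r2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in r2:
        nxt = pmf.copy()
        nxt[r:] += pmf[: total + 1 - r]
        pmf = nxt / 2.0
    return np.arange(total + 1), pmf


def paired_wilcoxon(before, after) -> StatResult:
    """Two-sided Wilcoxon signed-rank test on paired observations.

    Missing pairs (NaN in either list) are dropped first, then zero
    differences.  Requires >= 5 usable pairs.  Exact two-sided p
    (2 * min tail, capped at 1) for n <= 25; normal approximation with
    continuity and tie corrections beyond.  Raises if every difference
    is zero.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before and after must have equal length")
    ok = ~(np.isnan(before) | np.isnan(after))
    diff = after[ok] - before[ok]
    if len(diff) and np.all(diff == 0):
        raise ValueError("all paired differences are zero; the signed-rank test "
                         "is undefined")
    diff = diff[diff != 0]
    n = len(diff)
    if n < 5:
        raise ValueError(f"only {n} nonzero paired differences; need >= 5")

    w_plus, ranks = _signed_rank_statistic(diff)
    mean_w = n * (n + 1) / 4.0

    if n <= EXACT_WILCOXON_MAX_N:
        support2, pmf = _exact_signed_rank_sf(ranks)
        w2 = int(round(2 * w_plus))
        p_le = float(pmf[support2 <= w2].sum())
        p_ge = float(pmf[support2 >= w2].sum())
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "exact"
    else:
        # variance with tie correction
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = ((counts ** 3 - counts) / 48.0).sum()
        var_w = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        d = w_plus - mean_w
        d -= 0.5 * np.sign(d)  # continuity correction
        z = d / np.sqrt(var_w)
        p = float(2 * sps.norm.sf(abs(z)))
        method = "normal-approx"
    return StatResult(statistic=w_plus, p_value=min(p, 1.0), n=n,
                      extra={"method": method})


def wilcoxon_exact_bruteforce(diff) -> float:
    """Reference two-sided p by enumerating all 2^n sign patterns.

    Independent oracle for the convolution implementation; only viable
    for small n (it walks every sign assignment explicitly).
    """
    diff = np.asarray(diff, dtype=float)
    diff = diff[diff != 0]
    n = len(diff)
    if n == 0 or n > 20:
        raise ValueError("brute-force enumeration needs 1 <= n <= 20")
    ranks = sps.rankdata(np.abs(diff))
    w_obs = ranks[diff > 0].sum()
    total = 2 ** n
    count_le = count_ge = 0
    for m in range(total):
        w = sum(ranks[i] for i in range(n) if (m >> i) & 1)
        if w <= w_obs + 1e-9:
            count_le += 1
        if w >= w_obs - 1e-9:
            count_ge += 1
    return min(1.0, 2.0 * min(count_le, count_ge) / total)


# ------------------------------------------------------------ OLS

def ols_regression(response, covariates: pd.DataFrame,
                   alpha: float = 0.05) -> list[StatResult]:
    """OLS of a response on named covariates, with intercept.

    Returns one :class:`StatResult` per covariate (plus the intercept),
    each with coefficient, two-sided p and t-based (1-alpha) CI.  Rows
    with any missing value are dropped (complete-case); a rank-deficient
    design raises an error naming the collinear columns.
    """
    import statsmodels.api as sm

    y = np.asarray(response, dtype=float)
    X = pd.DataFrame(covariates).copy()
    if len(y) != len(X):
        raise ValueError("response and covariates must have equal length")
    keep = ~(np.isnan(y) | X.isna().any(axis=1).to_numpy())
    y, X = y[keep], X.loc[keep]
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"n = {n} observations cannot support {p} covariates "
                         "plus an intercept")
    const = X.nunique() <= 1
    if const.any():
        raise ValueError(f"constant covariate column(s) besides the intercept: "
                         f"{X.columns[const].tolist()}")
    Xc = sm.add_constant(X, has_constant="raise")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        bad = _collinear_columns(Xc)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    fit = sm.OLS(y, Xc).fit()
    ci = fit.conf_int(alpha=alpha)
    out = []
    for term in Xc.columns:
        out.append(StatResult(
            statistic=float(fit.tvalues[term]), p_value=float(fit.pvalues[term]),
            n=int(n), coefficient=float(fit.params[term]),
            ci_low=float(ci.loc[term, 0]), ci_high=float(ci.loc[term, 1]),
            term=str(term)))
    return out


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    cols = list(X.columns)
    M = X.to_numpy()
    full = np.linalg.matrix_rank(M)
    for r in range(2, len(cols) + 1):
        for combo in combinations(range(len(cols)), r):
            sub = M[:, list(combo)]
            if np.linalg.matrix_rank(sub) < r:
                return [cols[i] for i in combo]
    return cols if full < len(cols) else []


# ------------------------------------------------------------ cohort table

@dataclass
class LongitudinalPair:
    """One subject's chunk summaries at two timepoints plus covariates.

    ``baseline`` / ``followup``: chunk summary DataFrames as produced by
    :func:`cvmorph.atlas.chunk_means` (must reference the same atlas).
    ``covariates``: scalar clinical variables (age, sex, SBP, ...);
    missing values allowed and handled complete-case downstream.
    """

    subject_id: str
    baseline: pd.DataFrame | None
    followup: pd.DataFrame | None
    covariates: dict = field(default_factory=dict)

    def complete(self) -> bool:
        return self.baseline is not None and self.followup is not None


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (reported alongside raw p, never a gate)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    prev = 1.0
    for rank_idx in range(n - 1, -1, -1):
        i = order[rank_idx]
        val = p[i] * n / (rank_idx + 1)
        prev = min(prev, val)
        adj[i] = prev
    return adj


def build_change_table(cohort: list[LongitudinalPair],
                       features: list[str] | None = None,
                       covariate_names: list[str] | None = None) -> pd.DataFrame:
    """Per-chunk, per-feature longitudinal change table for a cohort.

    For every (chunk, feature) cell: the cohort mean percent change in
    both sign conventions, the paired Wilcoxon p across subjects, a BH
    column, and — when covariates are requested — the univariable OLS
    slope of the signed percent increase on each covariate with its 95%
    CI.  Subjects missing a timepoint are excluded with a warning.
    Requires >= 5 complete subjects.
    """
    from .features import FEATURE_COLUMNS

    features = features or FEATURE_COLUMNS
    usable = []
    for pair in cohort:
        if not pair.complete():
            logger.warning("subject %s is missing a timepoint; excluded", pair.subject_id)
            continue
        usable.append(pair)
    if len(usable) < 5:
        raise ValueError(f"need >= 5 subjects with both timepoints, have {len(usable)}")

    chunk_ids = usable[0].baseline.chunk_id.tolist()
    chunk_names = dict(zip(usable[0].baseline.chunk_id, usable[0].baseline.chunk_name))
    rows = []
    for chunk_id in chunk_ids:
        for feat in features:
            base_v, fup_v, cov_rows = [], [], []
            for pair in usable:
                b = pair.baseline.loc[pair.baseline.chunk_id == chunk_id, feat]
                f = pair.followup.loc[pair.followup.chunk_id == chunk_id, feat]
                bv = float(b.iloc[0]) if len(b) else np.nan
                fv = float(f.iloc[0]) if len(f) else np.nan
                base_v.append(bv)
                fup_v.append(fv)
                cov_rows.append(pair.covariates)
            base_v = np.asarray(base_v)
            fup_v = np.asarray(fup_v)
            ok = ~(np.isnan(base_v) | np.isnan(fup_v)) & (base_v != 0)
            pct_paper = (base_v[ok] - fup_v[ok]) / base_v[ok] * 100.0
            pct_inc = -pct_paper
            try:
                wil = paired_wilcoxon(base_v[ok], fup_v[ok])
                p_val, w_stat = wil.p_value, wil.statistic
            except ValueError:
                p_val, w_stat = np.nan, np.nan
            row = {
                "chunk_id": chunk_id, "chunk_name": chunk_names.get(chunk_id, ""),
                "feature": feat, "n": int(ok.sum()),
                "pct_change_paper_sign": float(np.mean(pct_paper)) if ok.any() else np.nan,
                "pct_increase": float(np.mean(pct_inc)) if ok.any() else np.nan,
                "wilcoxon_w": w_stat, "p_value": p_val,
            }
            if covariate_names:
                cov_df = pd.DataFrame(cov_rows).loc[ok]
                for cov in covariate_names:
                    beta = lo = hi = pcv = np.nan
                    if cov in cov_df:
                        try:
                            res = ols_regression(pct_inc, cov_df[[cov]])
                            term = next(r for r in res if r.term == cov)
                            beta, lo, hi, pcv = (term.coefficient, term.ci_low,
                                                 term.ci_high, term.p_value)
                        except (ValueError, StopIteration):
                            pass
                    row[f"beta_{cov}"] = beta
                    row[f"ci_low_{cov}"] = lo
                    row[f"ci_high_{cov}"] = hi
                    row[f"p_{cov}"] = pcv
            rows.append(row)
    table = pd.DataFrame(rows)
    # BH within each feature across chunks, reported alongside raw p
    table["p_bh"] = np.nan
    for feat in features:
        sel = (table.feature == feat) & table.p_value.notna()
        if sel.any():
            table.loc[sel, "p_bh"] = benjamini_hochberg(table.loc[sel, "p_value"].to_numpy())
    return table
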