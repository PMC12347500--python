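"""Observer-statistics harness.

Normality gate (Shapiro–Wilk), paired Wilcoxon signed-rank with exact
small-sample p-values, Bonferroni correction, the Friedman omnibus test
for related ordinal samples, ICC(2,k) inter-rater reliability with a
95% confidence interval, and assembly of the benchmark report table
(per-method metric means with significance flags, per-rater medians,
Friedman chi-square and ICC).

Wilcoxon and Friedman are implemented here from their defining
rank-sum formulas (with mid-rank tie handling and the standard tie
corrections); Shapiro–Wilk is delegated to a validated routine since
it serves only as a gate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RatingMatrix",
    "StatResult",
    "DegenerateInputError",
    "shapiro_gate",
    "wilcoxon_signed_rank",
    "bonferroni",
    "friedman",
    "icc_2k",
    "build_benchmark_report",
]


class DegenerateInputError(ValueError):
    """Raised when a test's input carries no usable variation."""


@dataclass(frozen=True)
class RatingMatrix:
    """Subjects x raters grid of ordinal scores in {1..5}."""

    scores: np.ndarray
    subject_ids: tuple[str, ...] = ()
    rater_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 2:
            raise ValueError("scores must be a 2-D subjects x raters grid")
        if s.shape[0] < 2 or s.shape[1] < 2:
            raise ValueError("need at least 2 subjects and 2 raters")
        if np.isnan(s).any():
            raise ValueError("missing cells are not allowed")
        object.__setattr__(self, "scores", s)
        if not self.subject_ids:
            object.__setattr__(
                self, "subject_ids",
                tuple(f"s{i}" for i in range(s.shape[0])))
        if not self.rater_ids:
            object.__setattr__(
                self, "rater_ids",
                tuple(f"r{j}" for j in range(s.shape[1])))

    @property
    def n_subjects(self) -> int:
        return self.scores.shape[0]

    @property
    def n_raters(self) -> int:
        return self.scores.shape[1]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.scores, index=list(self.subject_ids),
                     columns=list(self.rater_ids)).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "RatingMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float),
                   tuple(map(str, df.index)), tuple(map(str, df.columns)))


@dataclass(frozen=True)
class StatResult:
    test_name: str
    statistic: float
    p_value: float
    p_adjusted: float | None = None
    df: float | None = None
    n: int | None = None
    extra: dict = field(default_factory=dict)


def shapiro_gate(samples: list[np.ndarray]) -> tuple[list[StatResult], bool]:
    """Shapiro–Wilk normality test per sample; flags any rejection.

    Returns per-vector results and an overall ``non_normal`` flag that
    is True when any sample rejects normality at alpha = 0.05,
    directing the downstream comparisons to non-parametric tests.
    """
    results = []
    non_normal = False
    for i, v in enumerate(samples):
        v = np.asarray(v, dtype=float)
        if v.size < 3:
            raise ValueError(f"sample {i}: Shapiro–Wilk needs n >= 3")
        if np.ptp(v) == 0:
            raise ValueError(f"sample {i}: zero variance")
        w, p = sps.shapiro(v)
        results.append(StatResult("shapiro-wilk", float(w), float(p), n=v.size))
        if p < 0.05:
            non_normal = True
    return results, non_normal


def _signed_rank_parts(a: np.ndarray, b: np.ndarray):
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d = d[d != 0]  # Wilcoxon's original rule: drop zero differences
    if d.size == 0:
        raise DegenerateInputError("all paired differences are zero")
    if d.size < 3:
        raise ValueError("need at least 3 nonzero differences")
    ranks = sps.rankdata(np.abs(d))  # mid-ranks for ties
    w_plus = float(ranks[d > 0].sum())
    return d, ranks, w_plus


def _exact_wilcoxon_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p by dynamic programming over sign assignments.

    Works on doubled ranks (mid-ranks are half-integers) and counts the
    sign patterns whose W+ is as or more extreme than the observed one
    on either tail: p = P(W+ <= w_small) + P(W+ >= S - w_small).
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[:total + 1 - r].copy()
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    w_small2 = min(w2, total - w2)
    p = counts[: w_small2 + 1].sum() + counts[total - w_small2:].sum()
    return float(min(1.0, p))


def wilcoxon_signed_rank(a: np.ndarray, b: np.ndarray,
                         exact_max_n: int = 25) -> StatResult:
    """Paired Wilcoxon signed-rank test, two-sided.

    Zero differences are dropped; ties among |differences| receive
    mid-ranks.  The statistic is ``W = min(W+, W-)``.  For up to
    ``exact_max_n`` nonzero pairs the p-value is exact (full
    enumeration of the 2^n sign patterns via dynamic programming);
    beyond that, the normal approximation with tie and continuity
    corrections is used.
    """
    d, ranks, w_plus = _signed_rank_parts(a, b)
    n = d.size
    total = float(ranks.sum())
    w = min(w_plus, total - w_plus)
    if n <= exact_max_n:
        p = _exact_wilcoxon_p(ranks, w_plus)
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        tie_counts = np.unique(np.abs(d), return_counts=True)[1]
        var = (n * (n + 1) * (2 * n + 1)) / 24.0 \
            - (tie_counts ** 3 - tie_counts).sum() / 48.0
        if var <= 0:
            raise DegenerateInputError("zero variance in signed ranks")
        z = (w - mean + 0.5) / math.sqrt(var)  # continuity correction
        p = min(1.0, 2.0 * sps.norm.cdf(z))
        method = "normal-approximation"
    return StatResult("wilcoxon-signed-rank", float(w), float(p), n=n,
                      extra={"w_plus": w_plus, "method": method})


def bonferroni(p_values: np.ndarray) -> np.ndarray:
    """Bonferroni adjustment: ``min(1, m * p)`` for a family of m tests."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p.size * p)


def friedman(matrix: np.ndarray) -> StatResult:
    """Friedman rank test for k related treatments over n subjects.

    Within-subject mid-ranks; the chi-square statistic
    ``(12 / (n k (k+1))) sum_j R_j^2 - 3 n (k+1)`` divided by the
    standard tie-correction factor
    ``1 - sum(t^3 - t) / (n k (k^2 - 1))``; p from the chi-square
    distribution with k - 1 degrees of freedom.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("matrix must be 2-D (subjects x treatments)")
    n, k = m.shape
    if k < 3:
        raise ValueError("Friedman test needs at least 3 treatments")
    if n < 2:
        raise ValueError("Friedman test needs at least 2 subjects")
    ranks = np.apply_along_axis(sps.rankdata, 1, m)
    rj = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * (rj ** 2).sum() - 3.0 * n * (k + 1)
    ties = 0.0
    for row in m:
        _, t = np.unique(row, return_counts=True)
        ties += float((t ** 3 - t).sum())
    correction = 1.0 - ties / (n * k * (k * k - 1.0))
    if correction <= 0:  # every row constant: no information
        return StatResult("friedman", 0.0, 1.0, df=k - 1, n=n)
    chi2 /= correction
    p = float(sps.chi2.sf(chi2, k - 1))
    return StatResult("friedman", float(chi2), p, df=k - 1, n=n)


def _icc_anova(scores: np.ndarray):
    n, k = scores.shape
    grand = scores.mean()
    row_means = scores.mean(axis=1)
    col_means = scores.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((scores - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_2k(matrix: RatingMatrix | np.ndarray) -> StatResult:
    """ICC(2,k): two-way random effects, absolute agreement, average of k.

    ``ICC = (MSR - MSE) / (MSR + (MSC - MSE) / n)`` from the two-way
    ANOVA mean squares (subjects MSR, raters MSC, residual MSE).  The
    95% CI is the F-based interval for the single-rater absolute-
    agreement coefficient transformed to the k-rater average by the
    Spearman–Brown relation.
    """
    scores = matrix.scores if isinstance(matrix, RatingMatrix) else \
        np.asarray(matrix, dtype=float)
    n, k = scores.shape
    if np.ptp(scores) == 0:
        raise DegenerateInputError("zero total variance in ratings")
    msr, msc, mse = _icc_anova(scores)
    denom = msr + (msc - mse) / n
    icc_k = (msr - mse) / denom if denom != 0 else 1.0

    # single-rater coefficient and its F-based CI (two-way random,
    # absolute agreement), then Spearman-Brown up to k raters
    icc_1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    alpha = 0.05
    if mse == 0.0:
        lo_k, hi_k = icc_k, icc_k
    else:
        a = (k * icc_1) / (n * (1.0 - icc_1))
        b = 1.0 + (k * icc_1 * (n - 1.0)) / (n * (1.0 - icc_1))
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
        f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lo_1 = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi_1 = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr)
        lo_k = k * lo_1 / (1.0 + (k - 1) * lo_1)
        hi_k = k * hi_1 / (1.0 + (k - 1) * hi_1)

    # significance vs ICC = 0: F test on MSR/MSE
    f_stat = msr / mse if mse > 0 else float("inf")
    p = float(sps.f.sf(f_stat, n - 1, (n - 1) * (k - 1))) if mse > 0 else 0.0
    return StatResult("icc(2,k)", float(icc_k), p, n=n,
                      extra={"ci95": (float(lo_k), float(hi_k)),
                             "msr": msr, "msc": msc, "mse": mse,
                             "k": k})


def _format_mean_sd(values: np.ndarray) -> str:
    finite = np.isfinite(values)
    if not finite.all():
        return "inf"
    return f"{values.mean():.2f} ({values.std(ddof=1) if values.size > 1 else 0.0:.2f})"


def build_benchmark_report(metric_df: pd.DataFrame,
                           ratings: dict[str, RatingMatrix] | None = None,
                           original_label: str = "original") -> dict:
    """Assemble the benchmark comparison table.

    ``metric_df`` must carry columns ``image_id, method`` plus the five
    metric columns, and include rows for ``original_label``.  For each
    method and metric the table reports mean (SD) to 2 dp, a paired
    Wilcoxon test against the original images, and Bonferroni
    adjustment over the whole method x metric family; significance is
    a separate boolean column.  When per-method rating matrices are
    given, per-rater and global medians, the Friedman chi-square across
    methods and ICC(2,k) over the pooled ratings are added.

    Returns a dict with keys ``metrics`` (DataFrame), and when ratings
    are given, ``ratings`` (DataFrame), ``friedman`` and ``icc``.
    """
    from .metrics import METRIC_COLUMNS

    df = metric_df.copy()
    methods = list(dict.fromkeys(df["method"]))
    if original_label not in methods:
        raise ValueError(f"no rows for the reference method {original_label!r}")
    orig = df[df["method"] == original_label].set_index("image_id")

    rows = []
    raw_p: list[float] = []
    p_slots: list[tuple[int, str]] = []
    for method in methods:
        sub = df[df["method"] == method].set_index("image_id")
        row: dict = {"method": method}
        for metric in METRIC_COLUMNS:
            vals = sub[metric].to_numpy(dtype=float)
            row[metric] = _format_mean_sd(vals)
            row[f"{metric}_mean"] = float(vals.mean()) if np.isfinite(vals).all() \
                else float("inf")
            if method != original_label:
                paired_ref = orig.loc[sub.index, metric].to_numpy(dtype=float)
                try:
                    res = wilcoxon_signed_rank(vals, paired_ref)
                    raw_p.append(res.p_value)
                    p_slots.append((len(rows), metric))
                    row[f"{metric}_p"] = res.p_value
                except (DegenerateInputError, ValueError):
                    row[f"{metric}_p"] = float("nan")
        rows.append(row)

    adjusted = bonferroni(np.array(raw_p)) if raw_p else np.array([])
    for (row_idx, metric), p_adj in zip(p_slots, adjusted):
        rows[row_idx][f"{metric}_p_adj"] = float(p_adj)
        rows[row_idx][f"{metric}_significant"] = bool(p_adj < 0.05)
    for row in rows:
        for metric in METRIC_COLUMNS:
            row.setdefault(f"{metric}_p", float("nan"))
            row.setdefault(f"{metric}_p_adj", float("nan"))
            row.setdefault(f"{metric}_significant", False)
            if row[f"{metric}_significant"]:
                row[metric] = row[metric] + " *"
    report = {"metrics": pd.DataFrame(rows)}

    if ratings:
        rmethods = list(ratings)
        first = next(iter(ratings.values()))
        med_rows = []
        for method in rmethods:
            rm = ratings[method]
            row = {"method": method}
            for j, rid in enumerate(rm.rater_ids):
                row[rid] = float(np.median(rm.scores[:, j]))
            row["global_median"] = float(np.median(rm.scores))
            med_rows.append(row)
        report["ratings"] = pd.DataFrame(med_rows)
        if len(rmethods) >= 3:
            per_image = np.column_stack(
                [ratings[m].scores.mean(axis=1) for m in rmethods])
            report["friedman"] = friedman(per_image)
        pooled = np.vstack([ratings[m].scores for m in rmethods])
        report["icc"] = icc_2k(pooled)
    return report
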