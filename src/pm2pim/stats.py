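"""Statistical validation of scenario results.

Paired t-tests with Cohen's d on the per-case KPI differences, a
Shapiro-Wilk normality gate, and the nonparametric track: Wilcoxon
signed-rank tests per scenario pair and a Friedman test across the three
scenario conditions (baseline, current optimization, full adherence).

The Wilcoxon test drops zero differences (the original formulation) and uses
the exact null distribution for effective n <= 25 — computed by dynamic
programming over doubled midranks so ties are handled exactly — and the
normal approximation with continuity correction above that.  The Friedman
statistic uses within-row midranks with the tie-correction factor; with many
completely tied rows the uncorrected statistic would grossly understate the
evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatsConfig",
    "PairedTestResult",
    "paired_t",
    "cohens_d",
    "shapiro_wilk",
    "wilcoxon_signed_rank",
    "friedman",
    "statistics_report",
]


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    two_sided: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class PairedTestResult:
    n: int
    mean_diff: float
    sd_diff: float
    t: float
    df: int
    p_two_sided: float
    cohens_d: float
    significant: bool
    degenerate: bool = False


def cohens_d(diffs) -> float:
    """Paired effect size: mean difference over sample sd of differences."""
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two differences")
    sd = d.std(ddof=1)
    if sd == 0.0:
        return 0.0
    return float(d.mean() / sd)


def paired_t(baseline, scenario, cfg: StatsConfig | None = None) -> PairedTestResult:
    """Paired-sample t-test: t = mean(d) / (sd(d) / sqrt(n)), df = n - 1."""
    cfg = cfg or StatsConfig()
    x = np.asarray(baseline, dtype=float)
    y = np.asarray(scenario, dtype=float)
    if x.shape != y.shape:
        raise ValueError("baseline and scenario must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    if sd_d == 0.0:
        if mean_d == 0.0:
            return PairedTestResult(n, 0.0, 0.0, 0.0, n - 1, 1.0, 0.0, False)
        return PairedTestResult(
            n, mean_d, 0.0, float("inf"), n - 1, 0.0, 0.0, True, degenerate=True
        )
    t = mean_d / (sd_d / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    if not cfg.two_sided:
        p = sps.t.sf(t, df=n - 1)
    return PairedTestResult(
        n, mean_d, sd_d, float(t), n - 1, float(p), float(mean_d / sd_d), bool(p < cfg.alpha)
    )


def shapiro_wilk(diffs) -> tuple[float, float]:
    """Shapiro-Wilk normality test, used as the nonparametric-track gate."""
    d = np.asarray(diffs, dtype=float)
    if not 3 <= d.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(d) == 0.0:
        raise ValueError("Shapiro-Wilk is undefined for a constant sample")
    w, p = sps.shapiro(d)
    return float(w), float(p)


def _exact_wilcoxon_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p by DP over doubled ranks (handles midranks)."""
    doubled = np.rint(2.0 * ranks).astype(int)
    total = int(doubled.sum())
    # distribution of 2*W+ over all sign assignments
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(2.0 * w_plus))
    lo = dist[: w2 + 1].sum()  # P(2W+ <= w2)
    hi = dist[w2:].sum()  # P(2W+ >= w2)
    return float(min(1.0, 2.0 * min(lo, hi)))


def wilcoxon_signed_rank(x, y) -> tuple[float, float]:
    """Wilcoxon signed-rank test with zero-difference dropping.

    Returns (W = min of signed-rank sums, two-sided p).  Exact null for
    effective n <= 25, normal approximation with continuity correction and
    tie correction otherwise.  All differences zero -> p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("samples must have equal length")
    d = x - y
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    if n <= 25:
        return w, _exact_wilcoxon_p(ranks, w_plus)
    mean = n * (n + 1) / 4.0
    # variance with tie correction
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = (counts**3 - counts).sum() / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w - mean + 0.5) / np.sqrt(var)  # continuity correction toward the null
    p = float(min(1.0, 2.0 * sps.norm.cdf(z)))
    return w, p


def _friedman_chi(m: np.ndarray) -> float:
    n, k = m.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, m)
    rank_sums = ranks.sum(axis=0)
    chi = 12.0 / (n * k * (k + 1)) * float((rank_sums**2).sum()) - 3.0 * n * (k + 1)
    # tie correction: 1 - sum(t^3 - t) / (n k (k^2 - 1))
    tie_sum = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float((counts**3 - counts).sum())
    correction = 1.0 - tie_sum / (n * k * (k**2 - 1))
    if correction <= 0.0:
        return 0.0  # all rows completely tied
    return max(chi / correction, 0.0)


def friedman(matrix) -> tuple[float, float]:
    """Friedman test over k related samples with midranks and tie correction.

    ``matrix`` is n cases x k conditions.  Returns (chi-square, p) with
    k - 1 degrees of freedom; identical columns give chi-square 0, p = 1.
    For n <= 5 and k <= 3 the p-value is exact, from full enumeration of all
    within-row orderings; otherwise the chi-square approximation is used.
    """
    import itertools

    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need an n x k matrix with k >= 2 conditions")
    n, k = m.shape
    if n < 2:
        raise ValueError("need at least two cases")
    chi = _friedman_chi(m)
    if chi == 0.0:
        return 0.0, 1.0
    if n <= 5 and k <= 3:
        perms = list(itertools.permutations(range(k)))
        hits = total = 0
        for combo in itertools.product(perms, repeat=n):
            mm = np.stack([m[i, list(p)] for i, p in enumerate(combo)])
            if _friedman_chi(mm) >= chi - 1e-9:
                hits += 1
            total += 1
        return float(chi), hits / total
    return float(chi), float(sps.chi2.sf(chi, df=k - 1))


def statistics_report(results: list[dict], cfg: StatsConfig | None = None) -> pd.DataFrame:
    """Tabulate test results (one row each) with significance flags.

    Each input dict needs ``test``, ``kpi``, ``comparison``, ``statistic``,
    ``p``; ``effect_size`` is optional.  No multiple-testing correction is
    applied; downstream consumers should treat borderline p-values with care.
    """
    cfg = cfg or StatsConfig()
    rows = []
    for r in results:
        rows.append(
            {
                "test": r["test"],
                "kpi": r.get("kpi", ""),
                "comparison": r.get("comparison", ""),
                "statistic": r["statistic"],
                "p_value": r["p"],
                "effect_size": r.get("effect_size", float("nan")),
                "significant": bool(r["p"] < cfg.alpha),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["test", "kpi", "comparison", "statistic", "p_value", "effect_size", "significant"],
    )
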