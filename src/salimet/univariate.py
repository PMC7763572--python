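"""Nonparametric per-metabolite statistics with Benjamini-Hochberg FDR.

Saliva metabolite concentrations are not normally distributed, so group
comparisons use rank tests: Kruskal-Wallis across the three groups (B, AT,
HI), the Wilcoxon signed-rank test for the paired B-vs-AT contrast, and the
Mann-Whitney U test for HI vs AT. Each test family's 31 p-values are
BH-adjusted separately. Exact p-values are computed by enumeration (dynamic
programming over the rank-sum distribution) for small tie-free samples — the
study's n of 11-12 falls in this regime — with a mid-rank normal
approximation including tie-variance correction otherwise. All tests are
two-sided. Clinical covariates, by contrast, use plain paired/Welch t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import FeatureMatrix, SampleMetadata

_WILCOXON_EXACT_MAX_N = 25
_MWU_EXACT_MAX_PRODUCT = 400


def _tie_term(values: np.ndarray) -> float:
    """sum over tie groups of (t^3 - t)."""
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H on mid-ranks with tie correction; p from chi-square
    with k-1 df. All-constant input returns (0, 1) rather than erroring."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    n = pooled.size
    if n < 3:
        raise ValueError("need total n >= 3")
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    ranks = stats.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + g.size]
        h += g.size * (r.mean() - (n + 1) / 2.0) ** 2
        start += g.size
    h *= 12.0 / (n * (n + 1))
    correction = 1.0 - _tie_term(pooled) / (n**3 - n)
    h /= correction
    p = float(stats.chi2.sf(h, df=len(groups) - 1))
    return float(h), p


def _signed_rank_distribution(n: int) -> np.ndarray:
    """Counts of the W+ statistic over all 2^n sign patterns (no ties)."""
    total = n * (n + 1) // 2
    f = np.zeros(total + 1, dtype=float)
    f[0] = 1.0
    for r in range(1, n + 1):
        f[r:] += f[:-r].copy()
    return f


def wilcoxon_signed_rank(
    before, after, method: str = "auto"
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped. Exact enumeration over all sign patterns
    when the effective n <= 25 and the |differences| are tie-free; otherwise
    mid-ranks with a tie-corrected normal approximation (no continuity
    correction). Returns (W+, p).
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before/after length mismatch")
    d = before - after
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("no informative pairs (all differences zero)")
    absd = np.abs(d)
    ranks = stats.rankdata(absd)
    w_plus = float(ranks[d > 0].sum())
    tie_free = np.unique(absd).size == n
    use_exact = method == "exact" or (
        method == "auto" and tie_free and n <= _WILCOXON_EXACT_MAX_N
    )
    if use_exact:
        if not tie_free:
            raise ValueError("exact method requires tie-free |differences|")
        f = _signed_rank_distribution(n)
        total = f.sum()
        w = int(round(w_plus))
        lower = f[: w + 1].sum() / total
        upper = f[w:].sum() / total
        p = min(1.0, 2.0 * min(lower, upper))
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - _tie_term(absd) / 48.0
        z = (w_plus - mu) / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return w_plus, float(p)


def _rank_sum_counts(m: int, total_n: int) -> np.ndarray:
    """Counts over s of ways to choose m distinct ranks from 1..total_n with
    sum s (tie-free rank-sum distribution)."""
    max_s = m * total_n
    f = np.zeros((m + 1, max_s + 1), dtype=float)
    f[0, 0] = 1.0
    for k in range(1, total_n + 1):
        for mm in range(min(m, k), 0, -1):
            f[mm, k:] += f[mm - 1, :-k]
    return f[m]


def mann_whitney_u(a, b, method: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (U counted for the first sample).

    Exact enumeration of the rank-sum distribution when n_a * n_b <= 400 and
    the pooled data are tie-free; otherwise mid-ranks with tie-corrected
    normal approximation (no continuity correction). Returns (U_a, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r_a = float(ranks[:na].sum())
    u_a = r_a - na * (na + 1) / 2.0
    tie_free = np.unique(pooled).size == pooled.size
    use_exact = method == "exact" or (
        method == "auto" and tie_free and na * nb <= _MWU_EXACT_MAX_PRODUCT
    )
    if use_exact:
        if not tie_free:
            raise ValueError("exact method requires tie-free pooled data")
        counts = _rank_sum_counts(na, na + nb)
        total = counts.sum()
        offset = na * (na + 1) // 2
        u_counts = counts[offset:]  # index = U value 0..na*nb
        u = int(round(u_a))
        lower = u_counts[: u + 1].sum() / total
        upper = u_counts[u:].sum() / total
        p = min(1.0, 2.0 * min(lower, upper))
    else:
        n = na + nb
        mu = na * nb / 2.0
        var = na * nb / 12.0 * ((n + 1) - _tie_term(pooled) / (n * (n - 1)))
        if var == 0:
            return u_a, 1.0
        z = (u_a - mu) / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return float(u_a), float(p)


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH step-up adjusted p-values: adj_(i) = min_{j>=i} p_(j) * m / j,
    capped at 1, returned in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-D vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


def clinical_t_tests(values_t0, values_t1, paired: bool) -> tuple[float, float]:
    """Paired t-test (within-group change over time) or Welch unpaired
    t-test (between groups); errors on degenerate zero-variance input."""
    x = np.asarray(values_t0, dtype=float)
    y = np.asarray(values_t1, dtype=float)
    if paired:
        if x.shape != y.shape:
            raise ValueError("paired t-test requires equal lengths")
        d = y - x
        if np.std(d, ddof=1) == 0:
            raise ValueError("zero variance of paired differences")
        res = stats.ttest_rel(x, y)
    else:
        if np.std(x, ddof=1) == 0 and np.std(y, ddof=1) == 0:
            if np.mean(x) == np.mean(y):
                return 0.0, 1.0
            raise ValueError("zero variance in both samples")
        res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue)


@dataclass
class MetaboliteStatsTable:
    """Per-metabolite group summaries with the three test families and their
    BH-FDR columns (one BH family per test, m = number of metabolites)."""

    table: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=True, index_label="metabolite")

    def significant(self, column: str, alpha: float = 0.05) -> list[str]:
        return self.table.index[self.table[column] < alpha].tolist()


def build_metabolite_stats_table(
    fm: FeatureMatrix, md: SampleMetadata
) -> MetaboliteStatsTable:
    """Run Kruskal-Wallis (B/AT/HI), paired Wilcoxon (B vs AT) and
    Mann-Whitney (HI vs AT) per metabolite, with per-family BH adjustment."""
    groups = md.group_of(fm.sample_ids)
    for g in ("B", "AT", "HI"):
        if g not in set(groups):
            raise ValueError(f"group {g!r} missing from data")
    pairs = md.pairing_map()
    row_of = {s: i for i, s in enumerate(fm.sample_ids)}
    b_rows = [row_of[b] for b, _ in pairs.values()]
    at_rows = [row_of[a] for _, a in pairs.values()]
    idx = {g: np.flatnonzero(groups == g) for g in ("B", "AT", "HI")}

    records = []
    for j, met in enumerate(fm.feature_ids):
        x = fm.values[:, j]
        rec = {"metabolite": met}
        for g in ("B", "AT", "HI"):
            rec[f"mean_{g}"] = float(x[idx[g]].mean())
            rec[f"sd_{g}"] = float(x[idx[g]].std(ddof=1))
        _, rec["p_kruskal_wallis"] = kruskal_wallis(
            [x[idx["B"]], x[idx["AT"]], x[idx["HI"]]]
        )
        _, rec["p_wilcoxon_paired"] = wilcoxon_signed_rank(
            x[b_rows], x[at_rows]
        )
        _, rec["p_mann_whitney"] = mann_whitney_u(x[idx["HI"]], x[idx["AT"]])
        records.append(rec)
    df = pd.DataFrame(records).set_index("metabolite")
    for col in ("p_kruskal_wallis", "p_wilcoxon_paired", "p_mann_whitney"):
        df[col.replace("p_", "fdr_")] = benjamini_hochberg(df[col].to_numpy())
    order = [
        "mean_B", "sd_B", "mean_AT", "sd_AT", "mean_HI", "sd_HI",
        "p_kruskal_wallis", "fdr_kruskal_wallis",
        "p_wilcoxon_paired", "fdr_wilcoxon_paired",
        "p_mann_whitney", "fdr_mann_whitney",
    ]
    return MetaboliteStatsTable(df[order])
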