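"""Validation-cohort statistics.

Implements the nonparametric toolbox used for per-patient, per-site qPCR
ratios and immunohistochemistry scores: reference-gene normalization,
tie-corrected Spearman association, a Kruskal-Wallis -> Mann-Whitney
post-hoc cascade for independent groups, a Friedman -> Wilcoxon signed-rank
cascade for matched sites, and the semiquantitative immune-reactivity score
(IRS).  Post-hoc tests run only after a significant global test, and their
p-values are Bonferroni-adjusted over the number of pairwise comparisons.
All tests are two-sided at alpha = 0.05 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IRSRecord",
    "TestCascadeResult",
    "PosthocComparison",
    "normalize_to_reference",
    "spearman_assoc",
    "compare_groups_cascade",
    "paired_site_comparison",
    "friedman_test",
    "irs_score",
    "cohort_correlations",
]


@dataclass(frozen=True)
class IRSRecord:
    """Immune-reactivity score: partition of positive cells x intensity.

    pp_score 0-10 encodes 0-100% positive cells in steps of 10%; si 0-3 is
    the staining intensity; irs = pp_score * si ranges 0-30.
    """

    pp_score: int
    si: int
    irs: int
    compartment: str = "tumor_center"

    def __post_init__(self) -> None:
        if not 0 <= self.pp_score <= 10:
            raise ValueError("pp_score must lie in 0..10")
        if self.si not in (0, 1, 2, 3):
            raise ValueError("si must lie in 0..3")
        if self.irs != self.pp_score * self.si:
            raise ValueError("irs must equal pp_score * si")
        if self.compartment not in ("tumor_center", "invasive_front"):
            raise ValueError("compartment must be tumor_center or invasive_front")


@dataclass(frozen=True)
class PosthocComparison:
    pair: tuple
    statistic: float
    p_raw: float
    p_adj: float
    significant: bool


@dataclass(frozen=True)
class TestCascadeResult:
    """A global nonparametric test plus its (possibly empty) post-hoc table."""

    global_test: str
    statistic: float
    p: float
    posthoc: tuple[PosthocComparison, ...] = field(default_factory=tuple)
    alpha: float = 0.05


def normalize_to_reference(target: float, reference: float) -> float:
    """Expression ratio of a target transcript to a reference transcript."""
    if reference <= 0:
        raise ValueError("reference must be > 0")
    return target / reference


def spearman_assoc(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    r is the Pearson correlation of average (tie-corrected) ranks.  For
    n >= 10 the p-value uses the t approximation on n-2 degrees of freedom;
    below that the exact permutation distribution is enumerated.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero rank variance")
    r = float(np.corrcoef(rx, ry)[0, 1])
    if n >= 10:
        r_ = min(max(r, -1.0), 1.0)
        if abs(r_) == 1.0:
            p = 0.0
        else:
            t = r_ * np.sqrt((n - 2) / (1.0 - r_ * r_))
            p = float(2.0 * stats.t.sf(abs(t), n - 2))
    else:
        # exact two-sided permutation distribution of r
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
        perms = np.array(list(permutations(ry_c)))
        r_perm = perms @ rx_c / denom
        p = float(np.mean(np.abs(r_perm) >= abs(r) - 1e-12))
    return r, min(p, 1.0)


def _mannwhitney(a: np.ndarray, b: np.ndarray, exact_below: int = 8):
    """Two-sided Mann-Whitney U: exact enumeration for small groups,
    normal approximation with continuity and tie correction otherwise."""
    method = "exact" if min(len(a), len(b)) < exact_below else "asymptotic"
    if method == "exact" and (len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)):
        method = "asymptotic"  # exact null invalid under ties
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def compare_groups_cascade(groups, alpha: float = 0.05) -> TestCascadeResult:
    """Kruskal-Wallis global test, Mann-Whitney post hoc when positive.

    Pairwise tests run only when the global p is below ``alpha`` and are
    Bonferroni-adjusted over the number of pairs.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(groups):
        if g.size < 3:
            raise ValueError(f"group {i} too small (n={g.size} < 3)")
    if np.ptp(np.concatenate(groups)) == 0:
        stat, p = 0.0, 1.0  # scipy refuses all-identical data
    else:
        stat, p = stats.kruskal(*groups)
    posthoc = []
    if p < alpha and len(groups) >= 2:
        pairs = list(combinations(range(len(groups)), 2))
        n_comp = len(pairs)
        for i, j in pairs:
            u, p_raw = _mannwhitney(groups[i], groups[j])
            p_adj = min(1.0, p_raw * n_comp)
            posthoc.append(
                PosthocComparison((i, j), u, p_raw, p_adj, p_adj < alpha)
            )
    return TestCascadeResult("kruskal-wallis", float(stat), float(p),
                             tuple(posthoc), alpha)


def friedman_test(x: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Friedman chi-square for an n-subjects x k-sites block.

    Works for k >= 2 (at k = 2 it reduces to the sign-test structure).
    Returns (statistic, p) with p from chi-square on k-1 df; identical
    values in every row give statistic 0 and p = 1.
    """
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    if k < 2:
        raise ValueError("need k >= 2 related samples")
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    rj = ranks.sum(axis=0)
    chi = 12.0 / (n * k * (k + 1)) * float((rj**2).sum()) - 3.0 * n * (k + 1)
    # tie correction: divide by 1 - sum(t^3 - t) / (n k (k^2 - 1))
    tie_sum = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float((counts**3 - counts).sum())
    denom = 1.0 - tie_sum / (n * k * (k * k - 1))
    if denom <= 0:
        return 0.0, 1.0
    chi /= denom
    p = float(stats.chi2.sf(chi, k - 1))
    return float(chi), p


def paired_site_comparison(values: pd.DataFrame, alpha: float = 0.05) -> TestCascadeResult:
    """Friedman global test over matched sites, Wilcoxon post hoc.

    ``values`` is patients x sites; only complete cases (patients with all
    sites) enter.  Pairwise Wilcoxon signed-rank tests (zero differences
    dropped, average ranks for ties) run after a significant global test,
    Bonferroni-adjusted over k(k-1)/2 pairs.
    """
    values = pd.DataFrame(values).dropna(axis=0, how="any")
    n, k = values.shape
    if k < 2:
        raise ValueError("need k >= 2 sites")
    if n < 5:
        raise ValueError(f"need >= 5 complete cases, got {n}")
    stat, p = friedman_test(values.to_numpy())
    sites = list(values.columns)
    posthoc = []
    if p < alpha:
        pairs = list(combinations(sites, 2))
        n_comp = len(pairs)
        for a, b in pairs:
            diff = values[a].to_numpy() - values[b].to_numpy()
            if np.all(diff == 0):
                w_stat, p_raw = 0.0, 1.0
            else:
                res = stats.wilcoxon(values[a], values[b], zero_method="wilcox",
                                     alternative="two-sided")
                w_stat, p_raw = float(res.statistic), float(res.pvalue)
            p_adj = min(1.0, p_raw * n_comp)
            posthoc.append(PosthocComparison((a, b), w_stat, p_raw, p_adj,
                                             p_adj < alpha))
    return TestCascadeResult("friedman", stat, p, tuple(posthoc), alpha)


def irs_score(pp_percent: float, si: int, compartment: str = "tumor_center") -> IRSRecord:
    """Immune-reactivity score from raw percent positive cells and intensity.

    The percentage is binned to the nearest 10% (half-up) giving pp_score
    0-10, multiplied by intensity 0-3 for an IRS of 0-30.
    """
    if not 0 <= pp_percent <= 100:
        raise ValueError("pp_percent must lie in [0, 100]")
    if si not in (0, 1, 2, 3):
        raise ValueError("si must be one of 0, 1, 2, 3")
    pp_score = int(np.floor(pp_percent / 10.0 + 0.5))
    return IRSRecord(pp_score=pp_score, si=int(si), irs=pp_score * int(si),
                     compartment=compartment)


def cohort_correlations(table: pd.DataFrame, gene_x: str, gene_y: str) -> pd.DataFrame:
    """Per-site Spearman correlation of two genes across patients.

    ``table`` is long-format (patient, site, gene, value); only patients
    with both genes measured at a site contribute to that site's estimate.
    """
    rows = []
    for site, sub in table.groupby("site", sort=False):
        wide = sub.pivot(index="patient", columns="gene", values="value")
        if gene_x not in wide or gene_y not in wide:
            continue
        wide = wide[[gene_x, gene_y]].dropna()
        r, p = spearman_assoc(wide[gene_x], wide[gene_y])
        rows.append({"site": site, "n": len(wide), "r": r, "p": p})
    return pd.DataFrame(rows)
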