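"""Statistics kernel for HR/LR group comparisons.

Implements the inferential toolbox used throughout the pipeline: pooled
two-sample t-tests (from raw samples or from printed mean/SD/n summaries),
the Wilcoxon rank-sum test with an exact small-sample path, Pearson's
chi-square for contingency tables, and a Spearman taxa-by-trait correlation
matrix with significance stars.

The "SEM" reported alongside each t-test is the pooled standard error of the
difference, ``sqrt(sp^2 * (1/n1 + 1/n2))`` with ``sp^2`` the pooled variance —
the convention used by the summary tables this package replicates.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

__all__ = [
    "GroupSummary",
    "GroupComparison",
    "ChiSquareResult",
    "CorrelationResult",
    "round_half_up",
    "t_from_summary",
    "t_raw",
    "wilcoxon_rank_sum",
    "chisq",
    "correlation_matrix",
    "stars",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (table-replication convention).

    Python's built-in ``round`` is banker's rounding; printed tables use
    conventional half-up rounding (0.005 -> 0.01).
    """
    if not math.isfinite(x):
        return x
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


def stars(p: float) -> str:
    """Significance flag: ``**`` for p<0.01, ``*`` for p<0.05, else empty."""
    if not math.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class GroupSummary:
    """Per-group mean, standard deviation and sample size."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group size must be >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"sd must be nonnegative, got {self.sd}")

    @classmethod
    def from_sample(cls, x) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        if x.size < 2:
            raise ValueError("need at least 2 observations per group")
        return cls(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=int(x.size))


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample comparison as reported in a mean ± SD summary table."""

    diff: float
    sem_pooled: float
    t: float
    df: float
    p: float
    method: str = "pooled-t"
    transform: str | None = None

    def rounded(self, ndigits: int = 2) -> dict:
        """Reporting layer: half-up rounding applied to every statistic."""
        return {
            "diff": round_half_up(self.diff, ndigits),
            "sem": round_half_up(self.sem_pooled, ndigits),
            "t": round_half_up(self.t, ndigits),
            "p": round_half_up(self.p, ndigits),
        }


@dataclass(frozen=True)
class ChiSquareResult:
    x2: float
    df: int
    p: float


def t_from_summary(a: GroupSummary, b: GroupSummary, welch: bool = False) -> GroupComparison:
    """Two-sample t-test computed from per-group mean/SD/n summaries.

    The default is the pooled-variance (Student) test with
    ``df = n1 + n2 - 2``; ``welch=True`` switches to the Welch unequal-variance
    test (note that the Welch SE does not reproduce the tables' SEM column).
    Both SDs zero with equal means yields t=0, p=1 rather than 0/0.
    """
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
    sem_pooled = math.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    diff = a.mean - b.mean

    if a.sd == 0.0 and b.sd == 0.0:
        if diff == 0.0:
            return GroupComparison(0.0, 0.0, 0.0, a.n + b.n - 2, 1.0,
                                   method="welch-t" if welch else "pooled-t")
        raise ValueError("zero variance in both groups with unequal means: t undefined")

    if welch:
        res = sps.ttest_ind_from_stats(a.mean, a.sd, a.n, b.mean, b.sd, b.n,
                                       equal_var=False)
        # Welch–Satterthwaite df comes back on the scipy result
        se = math.sqrt(a.sd**2 / a.n + b.sd**2 / b.n)
        df = (a.sd**2 / a.n + b.sd**2 / b.n) ** 2 / (
            (a.sd**2 / a.n) ** 2 / (a.n - 1) + (b.sd**2 / b.n) ** 2 / (b.n - 1)
        )
        return GroupComparison(diff, sem_pooled, diff / se, df,
                               float(res.pvalue), method="welch-t")

    res = sps.ttest_ind_from_stats(a.mean, a.sd, a.n, b.mean, b.sd, b.n,
                                   equal_var=True)
    return GroupComparison(diff, sem_pooled, float(res.statistic),
                           a.n + b.n - 2, float(res.pvalue), method="pooled-t")


def t_raw(x, y, welch: bool = False, check_assumptions: bool = False) -> GroupComparison:
    """Two-sample t-test on raw samples; defers to :func:`t_from_summary`.

    With ``check_assumptions=True`` each sample is screened with Shapiro–Wilk
    at alpha=0.05; if either fails and all values are positive, both samples
    are natural-log transformed before testing, and the decision is logged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")

    transform = None
    if check_assumptions:
        p_sw = min(sps.shapiro(x).pvalue, sps.shapiro(y).pvalue) if (
            np.ptp(x) > 0 and np.ptp(y) > 0) else 1.0
        if p_sw < 0.05:
            if (x > 0).all() and (y > 0).all():
                logger.info("normality check failed (Shapiro-Wilk p=%.3g); "
                            "applying natural-log transform", p_sw)
                x, y, transform = np.log(x), np.log(y), "log"
            else:
                logger.info("normality check failed (p=%.3g) but values are "
                            "not all positive; no transform applied", p_sw)

    cmp_ = t_from_summary(GroupSummary.from_sample(x), GroupSummary.from_sample(y),
                          welch=welch)
    if transform:
        cmp_ = GroupComparison(cmp_.diff, cmp_.sem_pooled, cmp_.t, cmp_.df,
                               cmp_.p, method=cmp_.method, transform=transform)
    return cmp_


def _mwu_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic for x (rank-sum form, tied values get average ranks)."""
    n1 = x.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


def wilcoxon_rank_sum(x, y, exact_max_n: int = 12) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Returns ``(U, p)`` where U is the Mann–Whitney statistic for the first
    sample. When ``n1 + n2 <= exact_max_n`` the p-value is computed by full
    enumeration of all C(n1+n2, n1) group assignments of the pooled values
    (so ties are handled exactly): p = P(|U - n1*n2/2| >= |U_obs - n1*n2/2|)
    under the permutation null. Larger samples use the tie-corrected normal
    approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    u_obs = _mwu_statistic(x, y)

    if n1 + n2 <= exact_max_n:
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        mid = n1 * n2 / 2.0
        dev_obs = abs(u_obs - mid)
        hits = total = 0
        offset = n1 * (n1 + 1) / 2.0
        for idx in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - offset
            total += 1
            if abs(u - mid) >= dev_obs - 1e-9:
                hits += 1
        return u_obs, hits / total

    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


def chisq(table) -> ChiSquareResult:
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction (matching the replicated tables). Zero row or
    column margins are rejected rather than producing 0/0 expected cells.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if (obs < 0).any():
        raise ValueError("counts must be nonnegative")
    if (obs.sum(axis=1) == 0).any() or (obs.sum(axis=0) == 0).any():
        raise ValueError("zero row or column margin")
    x2, p, df, _ = sps.chi2_contingency(obs, correction=False)
    return ChiSquareResult(float(x2), int(df), float(p))


@dataclass
class CorrelationResult:
    """Spearman correlation matrix between taxa abundances and traits."""

    rho: pd.DataFrame          # taxa x traits
    p: pd.DataFrame
    stars: pd.DataFrame
    row_order: list = field(default_factory=list)  # display order after clustering
    flagged: list = field(default_factory=list)    # (taxon, trait) undefined pairs

    def tidy(self) -> pd.DataFrame:
        out = (self.rho.stack().rename("rho").to_frame()
               .join(self.p.stack().rename("p"))
               .join(self.stars.stack().rename("stars")))
        out.index.names = ["taxon", "trait"]
        return out.reset_index()


def correlation_matrix(taxa_abund: pd.DataFrame, traits: pd.DataFrame) -> CorrelationResult:
    """Spearman rank correlation of each taxon against each trait.

    Rows of both frames are samples (aligned on index); output rows are taxa,
    columns are traits. Constant columns give an undefined coefficient (NaN)
    and are flagged instead of silently producing a number. Taxa rows are
    ordered for display by average-linkage hierarchical clustering of their
    correlation profiles.
    """
    common = taxa_abund.index.intersection(traits.index)
    if len(common) < 3:
        raise ValueError("need at least 3 shared samples")
    ta = taxa_abund.loc[common]
    tr = traits.loc[common]

    rho = pd.DataFrame(index=ta.columns, columns=tr.columns, dtype=float)
    pmat = pd.DataFrame(index=ta.columns, columns=tr.columns, dtype=float)
    flagged = []
    for taxon in ta.columns:
        for trait in tr.columns:
            a, b = ta[taxon].to_numpy(float), tr[trait].to_numpy(float)
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                rho.loc[taxon, trait] = np.nan
                pmat.loc[taxon, trait] = np.nan
                flagged.append((taxon, trait))
                continue
            r, p = sps.spearmanr(a, b)
            rho.loc[taxon, trait] = float(r)
            pmat.loc[taxon, trait] = float(p)

    star = pmat.map(lambda p: stars(p) if pd.notna(p) else "")

    row_order = list(ta.columns)
    profiles = rho.fillna(0.0).to_numpy(float)
    if len(row_order) > 2 and profiles.shape[1] >= 1:
        link = hierarchy.linkage(pdist(profiles), method="average")
        row_order = [rho.index[i] for i in hierarchy.leaves_list(link)]

    return CorrelationResult(rho=rho, p=pmat, stars=star,
                             row_order=row_order, flagged=flagged)
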