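"""Statistical decision procedure and analytic p-value kernels.

The workflow mirrors common practice in preclinical muscular-dystrophy
studies: two groups are compared with an unpaired Student's t test; three or
more groups with one-way ANOVA followed by Tukey's HSD.  Because group
variances in such data are often heterogeneous, a significant ANOVA triggers
an Anderson-Darling normality check on the pooled residuals and a label-
permutation ANOVA whose p value is reported alongside the parametric one.
Variables flagged as non-normal up front are routed to the rank-based
Mann-Whitney U / Kruskal-Wallis H tests instead.

Conventions that matter and are easy to get wrong:

* ``mann_whitney`` reports ``W`` as the rank sum of the FIRST sample (not the
  U statistic); this is the convention used by R's ``wilcox.test`` reporting
  in some legacy pipelines and is the only reading under which published
  W values with unequal n reproduce.
* Star annotations use the threshold scheme {0.05, 0.005, 0.001} — note the
  middle threshold is 0.005, not the more common 0.01.  It is configurable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


class StatError(ValueError):
    """Raised for undefined or degenerate test inputs."""


@dataclass
class DecisionConfig:
    """Knobs of the decision procedure.

    alpha            significance level for every gate (default 0.05)
    permutation_B    number of label shuffles for the permutation ANOVA
    seed             seed for the shuffle generator (mandatory for runs that
                     reach the permutation stage)
    star_thresholds  strictly decreasing p thresholds for '*', '**', '***'
    min_n_normality  smallest residual count for which the Anderson-Darling
                     case-3 approximation is trusted
    """

    alpha: float = 0.05
    permutation_B: int = 9999
    seed: int | None = None
    star_thresholds: tuple[float, float, float] = (0.05, 0.005, 0.001)
    min_n_normality: int = 8

    def __post_init__(self) -> None:
        t1, t2, t3 = self.star_thresholds
        if not (t1 > t2 > t3 > 0):
            raise StatError("star thresholds must be strictly decreasing")


@dataclass
class TestResult:
    statistic_kind: str  # {"t", "F", "W_ranksum", "H", "A2", "F_perm"}
    statistic: float
    df: tuple[int, ...]
    p: float
    posthoc: list[tuple[tuple[str, str], float]] = field(default_factory=list)
    decision_path: list[str] = field(default_factory=list)
    stars: str = ""
    extra: dict = field(default_factory=dict)


def stars_for(p: float, thresholds: tuple[float, float, float] = (0.05, 0.005, 0.001)) -> str:
    t1, t2, t3 = thresholds
    if p < t3:
        return "***"
    if p < t2:
        return "**"
    if p < t1:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# analytic p kernels
# ---------------------------------------------------------------------------

def p_from_t(t: float, df: int) -> float:
    """Two-sided p for a Student t statistic."""
    if df < 1:
        raise StatError(f"t distribution needs df >= 1, got {df}")
    return float(2.0 * sps.t.sf(abs(t), df))


def p_from_f(f: float, df1: int, df2: int) -> float:
    """Upper-tail p for an F statistic."""
    if df1 < 1 or df2 < 1:
        raise StatError(f"F distribution needs positive df, got ({df1}, {df2})")
    if f < 0:
        raise StatError("F statistic must be non-negative")
    return float(sps.f.sf(f, df1, df2))


def p_from_chi2(x: float, df: int) -> float:
    if df < 1:
        raise StatError("chi-square needs df >= 1")
    return float(sps.chi2.sf(x, df))


# ---------------------------------------------------------------------------
# two-sample and k-sample parametric tests
# ---------------------------------------------------------------------------

def _as_groups(groups) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float).ravel() for g in groups]
    if any(g.size < 2 for g in out):
        raise StatError("every group needs at least two values")
    return out


def t_test(x, y) -> TestResult:
    """Classical unpaired (pooled-variance) two-sample t test."""
    x, y = _as_groups([x, y])
    n1, n2 = x.size, y.size
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    if sp2 == 0:
        t = 0.0 if x.mean() == y.mean() else math.inf
    else:
        t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 1.0 if not math.isfinite(t) else p_from_t(t, df)
    return TestResult("t", float(t), (df,), p, decision_path=["t_test"],
                      stars=stars_for(p))


def _f_statistic(groups: list[np.ndarray]) -> tuple[float, int, int]:
    k = len(groups)
    ns = np.array([g.size for g in groups])
    n_total = int(ns.sum())
    grand = np.concatenate(groups).mean()
    ss_between = sum(n * (g.mean() - grand) ** 2 for n, g in zip(ns, groups))
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = k - 1, n_total - k
    if ss_within == 0:
        f = 0.0 if ss_between == 0 else math.inf
    else:
        f = (ss_between / df1) / (ss_within / df2)
    return float(f), df1, df2


def one_way_anova(groups) -> TestResult:
    groups = _as_groups(groups)
    if len(groups) < 2:
        raise StatError("ANOVA needs at least two groups")
    f, df1, df2 = _f_statistic(groups)
    p = 1.0 if not math.isfinite(f) else p_from_f(f, df1, df2)
    return TestResult("F", f, (df1, df2), p, decision_path=["anova"],
                      stars=stars_for(p))


def tukey_hsd(groups, names: list[str] | None = None) -> list[tuple[tuple[str, str], float]]:
    """All-pairs Tukey HSD p values (Tukey-Kramer SE for unbalanced groups)."""
    groups = _as_groups(groups)
    if len(groups) < 3:
        raise StatError("Tukey HSD is a post hoc for >= 3 groups")
    if names is None:
        names = [f"g{i}" for i in range(len(groups))]
    res = sps.tukey_hsd(*groups)
    out = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        out.append(((names[i], names[j]), float(res.pvalue[i, j])))
    return out


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

def _rank_with_ties(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ranks = sps.rankdata(values)
    _, counts = np.unique(values, return_counts=True)
    return ranks, counts


def _exact_ranksum_sf_table(n1: int, n2: int) -> np.ndarray:
    """Null distribution of the first-sample rank sum, by enumeration.

    Returns an array ``counts`` where ``counts[w]`` is the number of the
    C(n1+n2, n1) equally likely rank assignments with rank sum w.
    """
    n = n1 + n2
    wmax = sum(range(n - n1 + 1, n + 1))
    counts = np.zeros(wmax + 1, dtype=np.int64)
    for combo in itertools.combinations(range(1, n + 1), n1):
        counts[sum(combo)] += 1
    return counts


def mann_whitney(x, y, continuity: bool = True, exact_max_n: int = 12) -> TestResult:
    """Mann-Whitney U test reporting W = rank sum of the first sample.

    Exact p by enumeration when n1+n2 <= ``exact_max_n`` and there are no
    ties; otherwise a tie-corrected normal approximation, with continuity
    correction by default.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise StatError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks, tie_counts = _rank_with_ties(pooled)
    w = float(ranks[:n1].sum())
    has_ties = bool((tie_counts > 1).any())
    path = []
    if n1 + n2 <= exact_max_n and not has_ties:
        counts = _exact_ranksum_sf_table(n1, n2)
        total = counts.sum()
        wi = int(round(w))
        lower = counts[: wi + 1].sum() / total
        upper = counts[wi:].sum() / total
        p = min(1.0, 2.0 * min(lower, upper))
        path.append("mann_whitney_exact")
    else:
        u = w - n1 * (n1 + 1) / 2.0
        mu = n1 * n2 / 2.0
        n = n1 + n2
        tie_term = (tie_counts ** 3 - tie_counts).sum()
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var == 0:
            raise StatError("all values tied; rank test undefined")
        cc = 0.5 if continuity else 0.0
        num = abs(u - mu)
        z = max(num - cc, 0.0) / math.sqrt(var)
        p = float(2.0 * sps.norm.sf(z))
        path.append("mann_whitney_normal_approx" + ("_cc" if continuity else ""))
    return TestResult("W_ranksum", w, (n1, n2), min(p, 1.0),
                      decision_path=path, stars=stars_for(p))


def kruskal_wallis(groups, names: list[str] | None = None) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with chi-square p on k-1 df."""
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 3:
        raise StatError("Kruskal-Wallis needs >= 3 groups")
    if any(g.size < 1 for g in groups):
        raise StatError("empty group")
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks, tie_counts = _rank_with_ties(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    tie_correction = 1.0 - (tie_counts ** 3 - tie_counts).sum() / (n ** 3 - n)
    if tie_correction == 0:
        raise StatError("all values tied; H undefined")
    h /= tie_correction
    df = len(groups) - 1
    p = p_from_chi2(h, df)
    return TestResult("H", float(h), (df,), p,
                      decision_path=["kruskal_wallis"], stars=stars_for(p))


# ---------------------------------------------------------------------------
# Anderson-Darling normality (case 3: mean and variance estimated)
# ---------------------------------------------------------------------------

def anderson_darling(x) -> TestResult:
    """A-squared statistic with small-sample correction and case-3 p value.

    The p approximation follows the standard piecewise-exponential bands for
    the statistic corrected as A2* = A2 (1 + 0.75/n + 2.25/n^2).
    """
    x = np.sort(np.asarray(x, dtype=float).ravel())
    n = x.size
    if n < 3:
        raise StatError("Anderson-Darling needs n >= 3")
    s = x.std(ddof=1)
    if s == 0:
        raise StatError("constant sample: normality test undefined")
    z = sps.norm.cdf((x - x.mean()) / s)
    z = np.clip(z, 1e-12, 1 - 1e-12)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (np.log(z) + np.log(1 - z[::-1])))
    a2s = a2 * (1 + 0.75 / n + 2.25 / n ** 2)
    if a2s >= 0.6:
        p = math.exp(1.2937 - 5.709 * a2s + 0.0186 * a2s ** 2)
    elif a2s >= 0.34:
        p = math.exp(0.9177 - 4.279 * a2s - 1.38 * a2s ** 2)
    elif a2s >= 0.2:
        p = 1 - math.exp(-8.318 + 42.796 * a2s - 59.938 * a2s ** 2)
    else:
        p = 1 - math.exp(-13.436 + 101.14 * a2s - 223.73 * a2s ** 2)
    p = min(max(p, 0.0), 1.0)
    # p==0 only from floating underflow at extreme A2; keep it in (0, 1]
    p = max(p, 5e-324)
    return TestResult("A2", float(a2), (n,), p,
                      decision_path=["anderson_darling"], stars=stars_for(p))


# ---------------------------------------------------------------------------
# permutation ANOVA
# ---------------------------------------------------------------------------

def permutation_anova(groups, B: int = 9999, seed: int | None = None) -> TestResult:
    """One-way ANOVA with the F-statistic null built by label shuffling.

    p = (1 + #{F_perm >= F_obs}) / (B + 1); never smaller than 1/(B+1).
    """
    groups = _as_groups(groups)
    if B < 99:
        raise StatError("use at least B=99 shuffles")
    if seed is None:
        raise StatError("permutation analysis requires an explicit seed")
    f_obs, df1, df2 = _f_statistic(groups)
    ns = [g.size for g in groups]
    pooled = np.concatenate(groups)
    n = pooled.size
    rng = np.random.default_rng(seed)
    # one shuffled copy of the pooled data per row; group slices are fixed
    perm = rng.permuted(np.broadcast_to(pooled, (B, n)), axis=1)
    grand = pooled.mean()
    ss_total = ((pooled - grand) ** 2).sum()
    start = 0
    ss_between = np.zeros(B)
    for sz in ns:
        block = perm[:, start:start + sz]
        ss_between += sz * (block.mean(axis=1) - grand) ** 2
        start += sz
    ss_within = ss_total - ss_between
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = (ss_between / df1) / (ss_within / df2)
    exceed = int(np.count_nonzero(f_perm >= f_obs))
    p = (1 + exceed) / (B + 1)
    return TestResult("F_perm", f_obs, (df1, df2), p,
                      decision_path=[f"permutation_anova(B={B})"],
                      stars=stars_for(p), extra={"B": B})


# ---------------------------------------------------------------------------
# decision pipeline
# ---------------------------------------------------------------------------

def decision_pipeline(groups, cfg: DecisionConfig | None = None,
                      names: list[str] | None = None,
                      nonparametric: bool = False) -> TestResult:
    """Route a comparison through the study's decision tree.

    Two groups -> unpaired t test (or Mann-Whitney if ``nonparametric``).
    Three or more -> one-way ANOVA with Tukey HSD post hoc (or
    Kruskal-Wallis with pairwise Mann-Whitney).  When the ANOVA is
    significant at ``cfg.alpha``, the Anderson-Darling normality gate is run
    on pooled residuals and a permutation ANOVA is reported alongside; the
    primary p value (and stars) remain those of the parametric test, with
    the companion results stored in ``extra``.
    """
    if cfg is None:
        cfg = DecisionConfig()
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise StatError("need at least two groups")
    if names is None:
        names = [f"g{i}" for i in range(len(groups))]

    if nonparametric:
        if len(groups) == 2:
            res = mann_whitney(groups[0], groups[1])
            res.decision_path = ["route:nonparametric"] + res.decision_path
            return res
        res = kruskal_wallis(groups, names)
        res.decision_path = ["route:nonparametric"] + res.decision_path
        res.posthoc = [((names[i], names[j]),
                        mann_whitney(groups[i], groups[j]).p)
                       for i, j in itertools.combinations(range(len(groups)), 2)]
        return res

    if len(groups) == 2:
        res = t_test(groups[0], groups[1])
        res.decision_path = ["route:two_groups"] + res.decision_path
        res.stars = stars_for(res.p, cfg.star_thresholds)
        return res

    res = one_way_anova(groups)
    res.decision_path = ["route:k_groups"] + res.decision_path
    if res.p < cfg.alpha:
        res.posthoc = tukey_hsd(groups, names)
        res.decision_path.append("tukey_hsd")
        residuals = np.concatenate([g - g.mean() for g in groups])
        if residuals.size >= cfg.min_n_normality:
            ad = anderson_darling(residuals)
            res.decision_path.append("anderson_darling_gate")
            res.extra["anderson_darling"] = {"A2": ad.statistic, "p": ad.p}
        else:
            res.decision_path.append("anderson_darling_gate:skipped_small_n")
        perm = permutation_anova(groups, B=cfg.permutation_B, seed=cfg.seed)
        res.decision_path.append(perm.decision_path[-1])
        res.extra["permutation_anova"] = {"F": perm.statistic, "p": perm.p}
    res.stars = stars_for(res.p, cfg.star_thresholds)
    return res
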