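"""The study's inferential toolkit, implemented from explicit decompositions.

Covers the analyses applied to the cohort tables: a mixed-design ANOVA (one
between-participant factor, one within-participant factor) with Mauchly's
sphericity test and Greenhouse-Geisser correction, Bonferroni-corrected
paired post hocs with Cohen's d, one-way ANOVAs for the baseline-adjusted
measures, two-sample t-tests routed through the Brown-Forsythe variance
diagnostic, JZS Bayes-factor t-tests, and a BIC-approximate Bayesian
mixed-design ANOVA.

Sums of squares are computed by explicit marginal-mean decomposition (the
designs are balanced); the JZS Bayes factor integrates the Cauchy-prior
marginal likelihood numerically.  The Bayesian ANOVA uses the BIC
approximation BF01 ~= exp((BIC_model - BIC_null) / 2) with participant as a
random-intercept block term (a compound-symmetric Gaussian model fit by
maximum likelihood in closed form up to a two-parameter search), so its
Bayes-factor magnitudes are comparable across models but are not calibrated
to any particular prior choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats as sps

from .exceptions import DegenerateInputError, MissingCellError

ALPHA = 0.05


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaTerm:
    name: str
    ss: float
    df_num: float
    df_den: float
    ms: float
    F: float
    p: float
    partial_eta_sq: float


@dataclass(frozen=True)
class SphericityResult:
    applicable: bool
    mauchly_w: float = float("nan")
    chi2: float = float("nan")
    df: float = float("nan")
    p: float = float("nan")
    gg_epsilon: float = 1.0


@dataclass
class MixedAnovaResult:
    terms: dict[str, AnovaTerm]
    sphericity: SphericityResult
    ss_total: float
    degenerate: bool = False
    corrected: dict[str, AnovaTerm] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for term in self.terms.values():
            corr = self.corrected.get(term.name)
            rows.append({
                "term": term.name, "SS": term.ss, "df_num": term.df_num,
                "df_den": term.df_den, "F": term.F, "p": term.p,
                "partial_eta_sq": term.partial_eta_sq,
                "gg_df_num": corr.df_num if corr else term.df_num,
                "gg_df_den": corr.df_den if corr else term.df_den,
                "gg_p": corr.p if corr else term.p,
            })
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class PosthocResult:
    pair: str
    mean_diff: float
    sd_diff: float
    t: float
    p_raw: float
    p_adjusted: float
    cohen_d_z: float
    cohen_d_av: float


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    cohen_d: float
    welch: bool
    brown_forsythe_F: float
    brown_forsythe_p: float


@dataclass(frozen=True)
class BayesResult:
    model: str
    bf01: float

    @property
    def bf10(self) -> float:
        return 1.0 / self.bf01


# ---------------------------------------------------------------------------
# Mixed-design ANOVA
# ---------------------------------------------------------------------------

def _pivot_balanced(table: pd.DataFrame, value: str = "value"):
    """Pivot a long cohort table to (participants x times), checking balance."""
    req = {"participant_id", "group", "time_point", value}
    missing = req - set(table.columns)
    if missing:
        raise MissingCellError(f"table missing columns {sorted(missing)}")
    times = list(pd.unique(table["time_point"]))
    wide = table.pivot_table(index=["group", "participant_id"],
                             columns="time_point", values=value,
                             aggfunc="first")
    bad = wide.index[wide.isna().any(axis=1)]
    if len(bad):
        raise MissingCellError(
            "participants missing time points: "
            + ", ".join(str(p) for _, p in bad))
    return wide[times], times


def mixed_anova(table: pd.DataFrame, measure: Optional[str] = None) -> MixedAnovaResult:
    """Mixed-design ANOVA: Time within, Group between.

    ``table`` is long format with participant_id, group, time_point and a
    value column (named ``measure``, default "value").  Requires a balanced
    complete design.  Sums of squares are computed by explicit decomposition;
    partial eta squared is SS_effect / (SS_effect + SS_error) with each
    effect's own error term.  The within-factor terms are additionally
    reported with Greenhouse-Geisser-corrected degrees of freedom when
    Mauchly's test rejects sphericity at alpha = 0.05.
    """
    value = measure or "value"
    wide, times = _pivot_balanced(table, value)
    k = len(times)
    groups = wide.index.get_level_values("group")
    glabels = list(pd.unique(groups))
    g = len(glabels)
    counts = pd.Series(groups).value_counts()
    n_total = wide.shape[0]
    y = wide.to_numpy(dtype=float)

    grand = y.mean()
    subj_means = y.mean(axis=1)
    time_means = y.mean(axis=0)
    group_means = np.array([y[groups == lab].mean() for lab in glabels])
    cell_means = np.vstack([y[groups == lab].mean(axis=0) for lab in glabels])
    n_per_group = np.array([counts[lab] for lab in glabels], dtype=float)

    ss_total = float(((y - grand) ** 2).sum())
    ss_between_subj = float(k * ((subj_means - grand) ** 2).sum())
    ss_group = float(k * (n_per_group * (group_means - grand) ** 2).sum())
    ss_subj_within = ss_between_subj - ss_group
    ss_time = float(n_total * ((time_means - grand) ** 2).sum())
    inter = (cell_means - group_means[:, None] - time_means[None, :] + grand)
    ss_inter = float((n_per_group[:, None] * inter ** 2).sum())
    ss_err_within = ss_total - ss_group - ss_subj_within - ss_time - ss_inter

    df_group, df_subj = g - 1, n_total - g
    df_time = k - 1
    df_inter = (g - 1) * (k - 1)
    df_err_w = (n_total - g) * (k - 1)

    degenerate = ss_subj_within <= 1e-12 * max(ss_total, 1.0) and \
        ss_err_within <= 1e-12 * max(ss_total, 1.0)

    def term(name, ss, dfn, ss_err, dfd):
        if dfn <= 0 or dfd <= 0 or ss_err <= 0:
            return AnovaTerm(name, ss, dfn, dfd, float("nan"), float("nan"),
                             float("nan"), float("nan"))
        ms, ms_err = ss / dfn, ss_err / dfd
        F = ms / ms_err
        p = float(sps.f.sf(F, dfn, dfd))
        eta = ss / (ss + ss_err)
        return AnovaTerm(name, ss, dfn, dfd, ms, F, p, eta)

    terms = {
        "Group": term("Group", ss_group, df_group, ss_subj_within, df_subj),
        "Time": term("Time", ss_time, df_time, ss_err_within, df_err_w),
        "Time x Group": term("Time x Group", ss_inter, df_inter,
                             ss_err_within, df_err_w),
    }

    sphericity = _sphericity(y, groups, glabels, k, n_total, g)
    result = MixedAnovaResult(terms=terms, sphericity=sphericity,
                              ss_total=ss_total, degenerate=degenerate)

    if sphericity.applicable and sphericity.p < ALPHA:
        eps = sphericity.gg_epsilon
        for name in ("Time", "Time x Group"):
            t = terms[name]
            if math.isnan(t.F):
                continue
            dfn, dfd = t.df_num * eps, t.df_den * eps
            result.corrected[name] = AnovaTerm(
                name, t.ss, dfn, dfd, t.ms, t.F,
                float(sps.f.sf(t.F, dfn, dfd)), t.partial_eta_sq)
    return result


def _within_contrast_cov(y: np.ndarray, groups, glabels, k: int,
                         n_total: int, g: int) -> np.ndarray:
    """Pooled within-group covariance of orthonormal within-subject contrasts."""
    # orthonormal contrast basis: Helmert-style, k x (k-1)
    c = np.linalg.qr(np.eye(k) - 1.0 / k)[0][:, :k - 1]
    z = y @ c
    pooled = np.zeros((k - 1, k - 1))
    for lab in glabels:
        zi = z[groups == lab]
        pooled += (zi - zi.mean(axis=0)).T @ (zi - zi.mean(axis=0))
    return pooled / (n_total - g)


def _sphericity(y, groups, glabels, k, n_total, g) -> SphericityResult:
    if k < 3:
        return SphericityResult(applicable=False, gg_epsilon=1.0)
    s = _within_contrast_cov(y, groups, glabels, k, n_total, g)
    eig = np.linalg.eigvalsh(s)
    eig = np.clip(eig, 0.0, None)
    tr = eig.sum()
    if tr <= 0:
        return SphericityResult(applicable=False, gg_epsilon=1.0)
    w = float(np.prod(eig) / (tr / (k - 1)) ** (k - 1))
    n_e = n_total - g
    d = k - 1
    # Box's chi-square approximation with the second-order series term
    f_corr = 1.0 - (2.0 * d ** 2 + d + 2.0) / (6.0 * d * n_e)
    chi2 = -n_e * f_corr * math.log(max(w, 1e-300))
    df = d * (d + 1) / 2.0 - 1.0
    w2 = ((d + 2) * (d - 1) * (d - 2) * (2.0 * d ** 3 + 6.0 * d ** 2 + 3 * k + 2)
          / (288.0 * (n_e * d * f_corr) ** 2))
    p1 = float(sps.chi2.sf(chi2, df))
    p2 = float(sps.chi2.sf(chi2, df + 4))
    p = p1 + w2 * (p2 - p1)
    eps = float(tr ** 2 / (d * (eig ** 2).sum()))
    eps = min(max(eps, 1.0 / d), 1.0)
    return SphericityResult(applicable=True, mauchly_w=w, chi2=chi2, df=df,
                            p=p, gg_epsilon=eps)


def mauchly_test(table: pd.DataFrame, measure: Optional[str] = None) -> SphericityResult:
    """Mauchly's sphericity test for the within factor of a cohort table."""
    value = measure or "value"
    wide, times = _pivot_balanced(table, value)
    groups = wide.index.get_level_values("group")
    glabels = list(pd.unique(groups))
    return _sphericity(wide.to_numpy(float), groups, glabels, len(times),
                       wide.shape[0], len(glabels))


def gg_epsilon(table: pd.DataFrame, measure: Optional[str] = None) -> float:
    """Greenhouse-Geisser epsilon from the within-subject contrast covariance."""
    value = measure or "value"
    wide, times = _pivot_balanced(table, value)
    k = len(times)
    if k < 3:
        return 1.0
    groups = wide.index.get_level_values("group")
    glabels = list(pd.unique(groups))
    return _sphericity(wide.to_numpy(float), groups, glabels, k,
                       wide.shape[0], len(glabels)).gg_epsilon


# ---------------------------------------------------------------------------
# One-way ANOVA (baseline-adjusted measures)
# ---------------------------------------------------------------------------

def one_way_anova(values: Sequence[float], groups: Sequence) -> AnovaTerm:
    """Between-subjects one-way ANOVA with partial eta squared."""
    v = np.asarray(values, dtype=float)
    glab = pd.Series(groups)
    labels = list(pd.unique(glab))
    grand = v.mean()
    ss_between = sum(((v[glab == lab].mean() - grand) ** 2) * (glab == lab).sum()
                     for lab in labels)
    ss_within = sum(((v[glab == lab] - v[glab == lab].mean()) ** 2).sum()
                    for lab in labels)
    dfn, dfd = len(labels) - 1, v.size - len(labels)
    if ss_within <= 0 or dfd <= 0:
        raise DegenerateInputError("zero within-group variance")
    F = (ss_between / dfn) / (ss_within / dfd)
    return AnovaTerm("Group", float(ss_between), dfn, dfd,
                     float(ss_between / dfn), float(F),
                     float(sps.f.sf(F, dfn, dfd)),
                     float(ss_between / (ss_between + ss_within)))


# ---------------------------------------------------------------------------
# Post hocs and t-tests
# ---------------------------------------------------------------------------

def bonferroni_posthoc(table: pd.DataFrame, measure: Optional[str] = None,
                       pairs: Optional[list[tuple[str, str]]] = None) -> list[PosthocResult]:
    """Bonferroni-corrected paired t-tests between within-factor levels.

    Cohen's d is reported in both conventions: d_z (mean difference / SD of
    differences) and d_av (mean difference / average of the two level SDs).
    """
    value = measure or "value"
    wide, times = _pivot_balanced(table, value)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(times) for b in times[i + 1:]]
    m = len(pairs)
    out = []
    for a, b in pairs:
        diff = wide[b].to_numpy(float) - wide[a].to_numpy(float)
        mean_diff = float(diff.mean())
        sd_diff = float(diff.std(ddof=1))
        if sd_diff == 0.0:
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_rel(wide[b], wide[a])
            t, p = float(t), float(p)
        d_z = mean_diff / sd_diff if sd_diff > 0 else 0.0
        sd_av = 0.5 * (wide[a].std(ddof=1) + wide[b].std(ddof=1))
        d_av = mean_diff / sd_av if sd_av > 0 else 0.0
        out.append(PosthocResult(pair=f"{a} vs {b}", mean_diff=mean_diff,
                                 sd_diff=sd_diff, t=t, p_raw=p,
                                 p_adjusted=min(1.0, p * m),
                                 cohen_d_z=float(d_z), cohen_d_av=float(d_av)))
    return out


def brown_forsythe(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Brown-Forsythe homogeneity-of-variance test (ANOVA on absolute
    deviations from group medians)."""
    F, p = sps.levene(np.asarray(a, float), np.asarray(b, float),
                      center="median")
    return float(F), float(p)


def welch_or_student_t(a: Sequence[float], b: Sequence[float],
                       alpha: float = ALPHA) -> TTestResult:
    """Two-sample t-test routed by the Brown-Forsythe variance diagnostic.

    Welch's unequal-variance t is used when Brown-Forsythe rejects at
    ``alpha``; otherwise the pooled-variance Student t.  Cohen's d uses the
    pooled SD in both cases.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DegenerateInputError("need n >= 2 per group")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        raise DegenerateInputError("zero variance in both groups")
    bf_F, bf_p = brown_forsythe(x, y)
    welch = bf_p < alpha
    res = sps.ttest_ind(x, y, equal_var=not welch)
    sp = math.sqrt(((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1))
                   / (x.size + y.size - 2))
    d = (x.mean() - y.mean()) / sp if sp > 0 else 0.0
    return TTestResult(t=float(res.statistic), df=float(res.df),
                       p=float(res.pvalue), cohen_d=float(d), welch=welch,
                       brown_forsythe_F=bf_F, brown_forsythe_p=bf_p)


# ---------------------------------------------------------------------------
# JZS Bayes factor t-test
# ---------------------------------------------------------------------------

def jzs_bf01_from_t(t: float, n_eff: float, df: float,
                    r: float = math.sqrt(2) / 2) -> float:
    """JZS Bayes factor (null over alternative) from a t statistic.

    Numerically integrates the Cauchy-prior (scale ``r``) marginal likelihood
    in its g-prior representation (g ~ InverseGamma(1/2, 1/2), effect size
    delta | g ~ Normal(0, g r^2)).
    """
    if df <= 0 or n_eff <= 0:
        raise DegenerateInputError("invalid degrees of freedom")

    def integrand(g):
        return ((1.0 + n_eff * g * r * r) ** -0.5
                * (1.0 + t * t / ((1.0 + n_eff * g * r * r) * df)) ** (-(df + 1) / 2.0)
                * (2.0 * math.pi) ** -0.5 * g ** -1.5 * math.exp(-1.0 / (2.0 * g)))

    marginal, err = integrate.quad(integrand, 0.0, np.inf, limit=200)
    if not np.isfinite(marginal) or marginal <= 0:
        raise DegenerateInputError("JZS integration failed")
    null_like = (1.0 + t * t / df) ** (-(df + 1) / 2.0)
    return float(null_like / marginal)


def bayes_factor_ttest(x: Sequence[float], y: Optional[Sequence[float]] = None,
                       paired: bool = False,
                       r: float = math.sqrt(2) / 2) -> BayesResult:
    """JZS Bayes-factor t-test; returns BF01 (evidence for the null).

    One-sample / paired when ``y`` is None or ``paired``; otherwise
    two-sample with effective sample size n1*n2/(n1+n2).
    """
    x = np.asarray(x, dtype=float)
    if y is None or paired:
        d = x if y is None else x - np.asarray(y, dtype=float)
        n = d.size
        if n < 2 or d.std(ddof=1) == 0:
            raise DegenerateInputError("degenerate paired sample")
        t = d.mean() / (d.std(ddof=1) / math.sqrt(n))
        bf01 = jzs_bf01_from_t(float(t), n, n - 1, r)
        label = "paired"
    else:
        y = np.asarray(y, dtype=float)
        n1, n2 = x.size, y.size
        res = sps.ttest_ind(x, y, equal_var=True)
        bf01 = jzs_bf01_from_t(float(res.statistic), n1 * n2 / (n1 + n2),
                               n1 + n2 - 2, r)
        label = "two-sample"
    return BayesResult(model=label, bf01=bf01)


# ---------------------------------------------------------------------------
# BIC-approximate Bayesian mixed ANOVA
# ---------------------------------------------------------------------------

_ANOVA_MODELS = {
    "null": (),
    "Time": ("time",),
    "Group": ("group",),
    "Time + Group": ("time", "group"),
    "Time x Group": ("time", "group", "interaction"),
}


def _random_intercept_ml(y_blocks: np.ndarray, x_blocks: np.ndarray) -> tuple[float, int]:
    """Maximum likelihood of a balanced random-intercept Gaussian model.

    Each subject contributes ``k`` observations with covariance
    sigma^2 I + tau^2 J (compound symmetry); beta is profiled out by GLS and
    the two variance components are optimised directly on the log scale.
    Returns (log-likelihood, number of free parameters incl. variances).
    """
    n, k, p = x_blocks.shape[0], x_blocks.shape[1], x_blocks.shape[2]

    def negll(theta):
        s2 = math.exp(theta[0])
        t2 = math.exp(theta[1])
        denom = s2 + k * t2
        # Sigma^-1 = (I - w J) / s2 with w = t2 / denom
        w = t2 / denom
        logdet = (k - 1) * math.log(s2) + math.log(denom)
        xt_si_x = np.zeros((p, p))
        xt_si_y = np.zeros(p)
        for i in range(n):
            xi, yi = x_blocks[i], y_blocks[i]
            six = (xi - w * xi.sum(axis=0)) / s2
            xt_si_x += xi.T @ six
            xt_si_y += six.T @ yi
        try:
            beta = np.linalg.solve(xt_si_x, xt_si_y)
        except np.linalg.LinAlgError as e:
            raise DegenerateInputError("singular fixed-effects design") from e
        quad = 0.0
        for i in range(n):
            r = y_blocks[i] - x_blocks[i] @ beta
            quad += (r @ r - w * r.sum() ** 2) / s2
        return 0.5 * (n * k * math.log(2 * math.pi) + n * logdet + quad)

    var0 = max(float(y_blocks.var()), 1e-8)
    best = None
    for t2_frac in (0.5, 0.05):
        res = optimize.minimize(
            negll, x0=[math.log(var0 * (1 - t2_frac)), math.log(var0 * t2_frac)],
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    return -float(best.fun), p + 2


def _design_blocks(data: pd.DataFrame, terms: tuple[str, ...]):
    """Per-subject response and design-matrix blocks for one model."""
    times = list(pd.unique(data["time_point"]))
    groups = list(pd.unique(data["group"]))
    wide = data.pivot_table(index=["group", "participant_id"],
                            columns="time_point", values="value",
                            aggfunc="first")[times]
    y = wide.to_numpy(float)
    n, k = y.shape
    glab = wide.index.get_level_values("group")
    cols = [np.ones((n, k))]
    if "time" in terms:
        for t in range(1, k):
            m = np.zeros((n, k))
            m[:, t] = 1.0
            cols.append(m)
    if "group" in terms:
        for lab in groups[1:]:
            m = np.zeros((n, k))
            m[glab == lab] = 1.0
            cols.append(m)
    if "interaction" in terms:
        for lab in groups[1:]:
            for t in range(1, k):
                m = np.zeros((n, k))
                m[np.asarray(glab == lab), t] = 1.0
                cols.append(m)
    x_blocks = np.stack(cols, axis=2)  # n x k x p
    return y, x_blocks


def bayes_factor_anova(table: pd.DataFrame, measure: Optional[str] = None) -> list[BayesResult]:
    """BIC-approximate Bayes factors for the mixed-design model set.

    Each candidate model (Time, Group, Time + Group, Time x Group) is fit by
    maximum likelihood with a participant random intercept (the block term);
    BF01 ~= exp((BIC_model - BIC_null) / 2), so BF01 < 1 means the model
    beats the null.  Results are sorted best model first.
    """
    value = measure or "value"
    data = table.rename(columns={value: "value"})[
        ["participant_id", "group", "time_point", "value"]].copy()
    nobs = data.shape[0]
    bics = {}
    for name, terms in _ANOVA_MODELS.items():
        y, x = _design_blocks(data, terms)
        ll, n_par = _random_intercept_ml(y, x)
        bics[name] = -2.0 * ll + n_par * math.log(nobs)
    out = [BayesResult(name, math.exp((bic - bics["null"]) / 2.0))
           for name, bic in bics.items()]
    return sorted(out, key=lambda b: b.bf01)
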