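"""Behavioral statistics for the cued-set analyses.

Implements the study's inferential toolkit: fully-within-subject ANOVA with
partial eta-squared (uncorrected, as the integer error dfs in the reported
tests imply), Tukey HSD on the ANOVA error term, the BIC approximation to
the Bayes factor, pre-sleep regression adjustment, the subsampling
robustness procedure, one-way random-effects ICC with a permutation test of
the cued/non-cued difference, the within-set max-|Z| outlier statistic,
repetition-benefit correlations, and the sound-familiarity covariate model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "AnovaEffect",
    "AnovaResult",
    "IccResult",
    "SubsampleReport",
    "rm_anova",
    "tukey_hsd",
    "bic_bayes_factor",
    "interaction_bic_bayes_factor",
    "regress_out_presleep",
    "subsample_robustness",
    "icc_oneway",
    "icc_with_permutation",
    "max_abs_z",
    "compare_outlier_scores",
    "repetition_benefit_correlation",
    "familiarity_covariate_analysis",
]


@dataclass(frozen=True)
class AnovaEffect:
    name: str
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float


@dataclass
class AnovaResult:
    effects: dict[str, AnovaEffect]

    def __getitem__(self, name: str) -> AnovaEffect:
        return self.effects[name]

    def to_dict(self) -> dict:
        return {
            k: {"F": e.F, "df1": e.df1, "df2": e.df2, "p": e.p, "partial_eta_sq": e.partial_eta_sq}
            for k, e in self.effects.items()
        }


@dataclass
class IccResult:
    icc_cued: float
    icc_noncued: float
    diff: float
    p_perm: float
    n_perm: int


@dataclass
class SubsampleReport:
    n_kept: int
    n_attempted: int
    pct_cuing_significant: float
    pct_interaction_significant: float
    mean_p_cuing: float
    median_p_cuing: float
    skew_p_cuing: float
    mean_p_interaction: float
    median_p_interaction: float
    skew_p_interaction: float
    all_cued_above_noncued: bool
    p_cuing: np.ndarray = field(repr=False, default=None)
    p_interaction: np.ndarray = field(repr=False, default=None)


def _f_test(ss_eff, df_eff, ss_err, df_err) -> tuple[float, float, float]:
    """F, p and partial eta squared; a zero-SS effect is F = 0, p = 1."""
    if ss_eff <= 0 or df_err <= 0:
        return 0.0, 1.0, 0.0
    if ss_err <= 0:
        return float("inf"), 0.0, 1.0
    F = (ss_eff / df_eff) / (ss_err / df_err)
    p = float(sps.f.sf(F, df_eff, df_err))
    pes = ss_eff / (ss_eff + ss_err)
    return float(F), p, float(pes)


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: list[str] | str,
    subject: str,
) -> AnovaResult:
    """Fully-within-subject ANOVA by sums-of-squares partitioning.

    ``data`` holds one cell mean per subject × factor-level combination
    (complete and balanced; missing cells raise). One or two within factors
    are supported; each effect is tested against its own subject-interaction
    error term, with no sphericity correction. Partial eta squared is
    SS_effect / (SS_effect + SS_error).
    """
    within = [within] if isinstance(within, str) else list(within)
    if len(within) not in (1, 2):
        raise ValueError("rm_anova supports one or two within factors")
    cols = [subject] + within
    if data[cols + [dv]].isna().any().any():
        raise ValueError("missing values in ANOVA input")
    cell = data.groupby(cols)[dv].mean()
    shape = [data[c].nunique() for c in cols]
    if len(cell) != int(np.prod(shape)):
        raise ValueError("incomplete design: every subject needs every cell")
    Y = cell.unstack(within).to_numpy()
    n_s = shape[0]
    if len(within) == 1:
        a = shape[1]
        grand = Y.mean()
        m_a = Y.mean(axis=0)
        m_s = Y.mean(axis=1)
        ss_a = n_s * ((m_a - grand) ** 2).sum()
        resid = Y - m_a[None, :] - m_s[:, None] + grand
        ss_as = (resid**2).sum()
        F, p, pes = _f_test(ss_a, a - 1, ss_as, (a - 1) * (n_s - 1))
        return AnovaResult(
            {within[0]: AnovaEffect(within[0], F, a - 1, (a - 1) * (n_s - 1), p, pes)}
        )

    a, b = shape[1], shape[2]
    Y = Y.reshape(n_s, a, b)
    grand = Y.mean()
    m_s = Y.mean(axis=(1, 2))
    m_a = Y.mean(axis=(0, 2))
    m_b = Y.mean(axis=(0, 1))
    m_sa = Y.mean(axis=2)
    m_sb = Y.mean(axis=1)
    m_ab = Y.mean(axis=0)

    ss_a = n_s * b * ((m_a - grand) ** 2).sum()
    ss_b = n_s * a * ((m_b - grand) ** 2).sum()
    ss_ab = n_s * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_as = b * ((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2).sum()
    ss_bs = a * ((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2).sum()
    resid = (
        Y
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - grand
    )
    ss_abs = (resid**2).sum()

    nameA, nameB = within
    effects = {}
    for name, ss_eff, df_eff, ss_err, df_err in [
        (nameA, ss_a, a - 1, ss_as, (a - 1) * (n_s - 1)),
        (nameB, ss_b, b - 1, ss_bs, (b - 1) * (n_s - 1)),
        (f"{nameA}:{nameB}", ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n_s - 1)),
    ]:
        F, p, pes = _f_test(ss_eff, df_eff, ss_err, df_err)
        effects[name] = AnovaEffect(name, F, df_eff, df_err, p, pes)
    return AnovaResult(effects)


def tukey_hsd(
    means: np.ndarray | pd.Series,
    n_per_level: int,
    ms_error: float,
    df_error: int,
) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons from level means and an ANOVA error term.

    ``q = |m_i − m_j| / sqrt(MSE / n)`` referred to the studentized-range
    distribution with k levels and ``df_error`` degrees of freedom.
    """
    if df_error <= 0:
        raise ValueError("df_error must be > 0")
    means = pd.Series(means)
    if len(means) < 2:
        raise ValueError("need at least two levels")
    k = len(means)
    se = np.sqrt(ms_error / n_per_level)
    rows = []
    labels = list(means.index)
    for i in range(k):
        for j in range(i + 1, k):
            diff = means.iloc[i] - means.iloc[j]
            q = np.abs(diff) / se if se > 0 else (0.0 if diff == 0 else np.inf)
            p = float(sps.studentized_range.sf(q, k, df_error)) if np.isfinite(q) else 0.0
            rows.append(
                {"level_a": labels[i], "level_b": labels[j], "diff": diff, "q": float(q), "p": min(1.0, p)}
            )
    return pd.DataFrame(rows)


def bic_bayes_factor(bic_null: float, bic_alt: float) -> float:
    """BF01 = exp((BIC_alt − BIC_null)/2): evidence for the null model
    (values > 1 favor the null) under the BIC approximation with equal
    prior odds."""
    if not (np.isfinite(bic_null) and np.isfinite(bic_alt)):
        raise ValueError("BIC values must be finite")
    return float(np.exp((bic_alt - bic_null) / 2.0))


def interaction_bic_bayes_factor(
    summaries: pd.DataFrame,
    dv: str = "benefit",
) -> float:
    """BF01 for the cuing × set-size interaction on condition cell means.

    Fits the two nested fixed-effects linear models (main effects only vs
    main effects + interaction, with a subject intercept) and converts the
    BIC difference into the Bayes factor favoring no interaction.
    """
    df = summaries.dropna(subset=[dv]).copy()
    df["cued"] = df["cued"].astype(bool)
    null = smf.ols(
        f"{dv} ~ C(participant_id) + C(cued) + C(size_k)", data=df
    ).fit()
    alt = smf.ols(
        f"{dv} ~ C(participant_id) + C(cued) * C(size_k)", data=df
    ).fit()
    return bic_bayes_factor(null.bic, alt.bic)


def regress_out_presleep(pre_errors: np.ndarray, forgetting: np.ndarray) -> np.ndarray:
    """Adjust forgetting scores for their linear dependence on pre-sleep error.

    OLS of forgetting on pre-sleep error; the adjusted score is the residual
    plus the grand-mean forgetting, removing set-size-dependent regression
    to the mean while preserving the overall level.
    """
    pre = np.asarray(pre_errors, float)
    fg = np.asarray(forgetting, float)
    if pre.shape != fg.shape or pre.ndim != 1:
        raise ValueError("pre_errors and forgetting must be 1-D and equal length")
    if len(pre) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(pre) == 0:
        warnings.warn("zero variance in pre-sleep errors; returning raw scores")
        return fg.copy()
    slope, intercept = np.polyfit(pre, fg, 1)
    fitted = slope * pre + intercept
    return fg - fitted + fg.mean()


def _grouped_items(scored: pd.DataFrame):
    """Cache per (participant, size) item arrays for fast resampling."""
    groups = {}
    for (pid, size), grp in scored.groupby(["participant_id", "size_k"]):
        groups[(pid, size)] = (
            grp["err_pre"].to_numpy(float),
            grp["benefit"].to_numpy(float),
            grp["cued"].to_numpy(bool),
        )
    return groups


def subsample_robustness(
    scored: pd.DataFrame,
    n_datasets: int = 500,
    frac: float = 0.5,
    screen_alpha: float = 0.5,
    rng_seed=None,
    alpha: float = 0.05,
    max_attempts: int = 100_000,
) -> SubsampleReport:
    """The subsampling robustness procedure for the cuing effect.

    Repeatedly samples ``frac`` of items per participant per set size,
    keeps a dataset only when the pre-sleep set-size main effect is clearly
    absent (p >= ``screen_alpha``), and accumulates ``n_datasets`` kept
    datasets. On each kept dataset the benefit ANOVA (cuing × set size) is
    run; the report summarizes the two p-value distributions (share below
    ``alpha``, mean, median, bias-corrected sample skewness) and whether
    every kept dataset showed a larger mean cued than non-cued benefit.

    Aborts when fewer than 1% of attempts pass the screen after a burn-in,
    or when ``max_attempts`` is exhausted.
    """
    rng = np.random.default_rng(rng_seed)
    groups = _grouped_items(scored)
    pids = sorted({pid for pid, _ in groups})
    sizes = sorted({s for _, s in groups})

    p_cue, p_int, cued_higher = [], [], []
    attempts = 0
    while len(p_cue) < n_datasets:
        attempts += 1
        if attempts > max_attempts or (
            attempts >= 2000 and len(p_cue) < 0.01 * attempts
        ):
            raise RuntimeError(
                f"subsample acceptance rate too low: {len(p_cue)}/{attempts} kept"
            )
        rows_screen = []
        rows_benefit = []
        for pid in pids:
            for size in sizes:
                err_pre, benefit, cued = groups[(pid, size)]
                n = len(err_pre)
                idx = rng.permutation(n)[: max(1, int(round(frac * n)))]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    rows_screen.append((pid, size, np.nanmean(err_pre[idx])))
                    for flag in (True, False):
                        sel = idx[cued[idx] == flag]
                        rows_benefit.append(
                            (pid, size, flag, np.nanmean(benefit[sel]) if len(sel) else np.nan)
                        )
        screen = pd.DataFrame(rows_screen, columns=["participant_id", "size_k", "err_pre"])
        if screen["err_pre"].isna().any():
            continue
        p_size = rm_anova(screen, "err_pre", "size_k", "participant_id")["size_k"].p
        if p_size < screen_alpha:
            continue
        ben = pd.DataFrame(rows_benefit, columns=["participant_id", "size_k", "cued", "benefit"])
        if ben["benefit"].isna().any():
            continue
        res = rm_anova(ben, "benefit", ["cued", "size_k"], "participant_id")
        p_cue.append(res["cued"].p)
        p_int.append(res["cued:size_k"].p)
        cell = ben.groupby("cued")["benefit"].mean()
        cued_higher.append(cell[True] > cell[False])

    p_cue = np.asarray(p_cue)
    p_int = np.asarray(p_int)
    return SubsampleReport(
        n_kept=len(p_cue),
        n_attempted=attempts,
        pct_cuing_significant=100.0 * float((p_cue < alpha).mean()),
        pct_interaction_significant=100.0 * float((p_int < alpha).mean()),
        mean_p_cuing=float(p_cue.mean()),
        median_p_cuing=float(np.median(p_cue)),
        skew_p_cuing=float(sps.skew(p_cue, bias=False)),
        mean_p_interaction=float(p_int.mean()),
        median_p_interaction=float(np.median(p_int)),
        skew_p_interaction=float(sps.skew(p_int, bias=False)),
        all_cued_above_noncued=bool(np.all(cued_higher)),
        p_cuing=p_cue,
        p_interaction=p_int,
    )


def icc_oneway(groups: list[np.ndarray]) -> float:
    """One-way random-effects, single-measure ICC — ICC(1,1).

    ``groups``: per-set arrays of item benefits (unequal sizes allowed;
    the unbalanced one-way ANOVA estimator uses the adjusted mean group
    size k0). Raises on zero total variance.
    """
    groups = [np.asarray(g, float) for g in groups if len(g) > 0]
    a = len(groups)
    if a < 2:
        raise ValueError("need at least two sets")
    N = sum(len(g) for g in groups)
    allv = np.concatenate(groups)
    if np.ptp(allv) == 0:
        raise ValueError("zero total variance; ICC undefined")
    grand = allv.mean()
    n_i = np.array([len(g) for g in groups], float)
    means = np.array([g.mean() for g in groups])
    ssb = float((n_i * (means - grand) ** 2).sum())
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    msb = ssb / (a - 1)
    msw = ssw / (N - a) if N > a else 0.0
    k0 = (N - (n_i**2).sum() / N) / (a - 1)
    denom = msb + (k0 - 1) * msw
    if denom == 0:
        raise ValueError("degenerate ICC (zero denominator)")
    return float((msb - msw) / denom)


def _icc_from_matrix(M: np.ndarray, offsets: np.ndarray, n_i: np.ndarray) -> np.ndarray:
    """Vectorized ICC(1,1) across permutation rows (groups along columns)."""
    N = M.shape[1]
    a = len(n_i)
    gsum = np.add.reduceat(M, offsets, axis=1)
    gmean = gsum / n_i[None, :]
    grand = M.mean(axis=1)
    ssb = (n_i[None, :] * (gmean - grand[:, None]) ** 2).sum(axis=1)
    sstot = ((M - grand[:, None]) ** 2).sum(axis=1)
    ssw = sstot - ssb
    msb = ssb / (a - 1)
    msw = ssw / (N - a)
    k0 = (N - (n_i**2).sum() / N) / (a - 1)
    denom = msb + (k0 - 1) * msw
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom != 0, (msb - msw) / denom, 0.0)


def icc_with_permutation(
    benefits: pd.DataFrame,
    n_perm: int = 1_000_000,
    rng_seed=None,
    chunk: int = 100_000,
) -> IccResult:
    """ICC of within-set item benefits, cued vs non-cued, with a permutation
    test of the difference.

    ``benefits`` needs columns set_id, cued, benefit (one row per item;
    NaNs dropped). The observed statistic is ICC_noncued − ICC_cued; the
    null is built by shuffling the item-to-set assignment separately within
    the cued and non-cued pools (group sizes preserved), and the p-value
    uses the add-one correction, so it can never be exactly zero.
    """
    df = benefits.dropna(subset=["benefit"])
    pools = {}
    for flag in (True, False):
        sub = df[df["cued"].astype(bool) == flag]
        groups = [g["benefit"].to_numpy(float) for _, g in sub.groupby("set_id") if len(g) > 0]
        groups = [g for g in groups if len(g) > 0]
        if len(groups) < 2:
            raise ValueError("need at least two sets per condition")
        pools[flag] = groups
    icc_c = icc_oneway(pools[True])
    icc_n = icc_oneway(pools[False])
    obs = icc_n - icc_c

    rng = np.random.default_rng(rng_seed)
    null_diffs = np.empty(n_perm)
    per_pool = {}
    for flag, groups in pools.items():
        v = np.concatenate(groups)
        n_i = np.array([len(g) for g in groups], float)
        offsets = np.concatenate([[0], np.cumsum(n_i[:-1]).astype(int)])
        per_pool[flag] = (v, offsets, n_i)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        iccs = {}
        for flag, (v, offsets, n_i) in per_pool.items():
            M = rng.permuted(np.broadcast_to(v, (m, len(v))).copy(), axis=1)
            iccs[flag] = _icc_from_matrix(M, offsets, n_i)
        null_diffs[done : done + m] = iccs[False] - iccs[True]
        done += m
    p = (1.0 + np.count_nonzero(np.abs(null_diffs) >= abs(obs))) / (1.0 + n_perm)
    return IccResult(
        icc_cued=icc_c, icc_noncued=icc_n, diff=obs, p_perm=float(p), n_perm=n_perm
    )


def max_abs_z(values: np.ndarray) -> float:
    """Within-set outlier statistic: the maximum |z| over the set's six item
    benefits (sample mean/SD, ddof=1). A zero-spread set scores 0."""
    v = np.asarray(values, float)
    if len(v) != 6:
        raise ValueError("max_abs_z expects exactly six values (six-item sets)")
    sd = v.std(ddof=1)
    if sd == 0:
        warnings.warn("zero within-set SD; outlier statistic set to 0")
        return 0.0
    return float(np.abs((v - v.mean()) / sd).max())


def compare_outlier_scores(cued_scores: np.ndarray, noncued_scores: np.ndarray):
    """Unpaired t-test of max-|Z| outlier scores, cued vs non-cued sets,
    pooling sets across participants. Returns (t, df, p, cohen_d)."""
    a = np.asarray(cued_scores, float)
    b = np.asarray(noncued_scores, float)
    t, p = sps.ttest_ind(a, b)
    nx, ny = len(a), len(b)
    pooled = np.sqrt(((nx - 1) * a.var(ddof=1) + (ny - 1) * b.var(ddof=1)) / (nx + ny - 2))
    d = (a.mean() - b.mean()) / pooled if pooled > 0 else 0.0
    return float(t), nx + ny - 2, float(p), float(d)


def repetition_benefit_correlation(
    benefit: np.ndarray,
    repetitions: np.ndarray,
    transform=None,
) -> tuple[float, float]:
    """Pearson correlation between per-participant mean cued benefit and
    per-participant mean cue repetitions (two-sided p).

    ``transform`` optionally maps repetition counts before correlating —
    e.g. the at-least-once reactivation probability for a given set size.
    """
    x = np.asarray(repetitions, float)
    y = np.asarray(benefit, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if transform is not None:
        x = np.asarray([transform(v) for v in x], float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def familiarity_covariate_analysis(
    set_benefits: pd.DataFrame,
    dv: str = "benefit",
) -> dict:
    """Set-level benefit model with sound familiarity as a covariate.

    ``set_benefits`` needs columns cued, size_k, familiarity and the dv
    (one row per set, optionally per participant). Fits
    ``dv ~ C(cued) * C(size_k) + familiarity`` by OLS and reports type-II
    p-values for the cuing effect, set-size effect, their interaction, and
    the covariate. A constant familiarity column is dropped with a warning.
    """
    df = set_benefits.dropna(subset=[dv]).copy()
    df["cued"] = df["cued"].astype(bool)
    use_cov = np.ptp(df["familiarity"].to_numpy(float)) > 0
    if not use_cov:
        warnings.warn("familiarity is constant; covariate dropped")
    formula = f"{dv} ~ C(cued) * C(size_k)" + (" + familiarity" if use_cov else "")
    fit = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)

    def _p(label):
        return float(table.loc[label, "PR(>F)"]) if label in table.index else float("nan")

    return {
        "p_cued": _p("C(cued)"),
        "p_size": _p("C(size_k)"),
        "p_interaction": _p("C(cued):C(size_k)"),
        "p_familiarity": _p("familiarity") if use_cov else float("nan"),
        "params": dict(fit.params),
        "model": fit,
    }
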