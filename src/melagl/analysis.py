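"""Behavioral analysis pipeline for melodic AGL familiarity data.

Covers the full chain applied to the test-phase responses: accuracy coding
(grammatical items correct when endorsed familiar, ungrammatical when
rejected), outlier exclusion, planned one-sample t tests with the
sequential-Bonferroni (Holm) correction, the 2-between x 1-within mixed
ANOVA with partial eta squared and within-subject contrasts, per-participant
multiple logistic regressions of responses on average chunk strength (ACS)
and grammaticality, group-level t tests on the fitted coefficients, Type-2
d-prime for confidence metaknowledge, and the exposure/performance
correlation check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "TestResult",
    "LogisticFit",
    "code_accuracy",
    "exclude_outliers",
    "one_sample_t",
    "holm_adjust",
    "mixed_anova",
    "within_contrasts",
    "chunk_strength",
    "acs_features",
    "fit_participant_logistic",
    "group_beta_tests",
    "type2_dprime",
    "exposure_correlation",
    "ACC_COLUMNS",
]

ACC_COLUMNS = (
    "overall",
    "gram_all",
    "old_gram",
    "new_gram",
    "ungram_all",
    "et1",
    "et2",
    "et3",
    "et4",
    "et5",
)


@dataclass(frozen=True)
class TestResult:
    """One-sample t test summary."""

    t: float
    df: int
    p: float
    mean: float
    sd: float
    n: int


# ---------------------------------------------------------------------------
# accuracy coding and exclusions


def code_accuracy(responses: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Per-participant accuracy table from familiarity responses.

    Grammatical items are correct when endorsed *familiar*; ungrammatical
    items are correct when rejected.  With equally many grammatical and
    ungrammatical items, chance performance is 0.5 by construction.
    Returns one row per participant with the ``ACC_COLUMNS`` cells (plus any
    ``group`` / ``musician`` metadata carried through).
    """
    man = manifest.set_index("id")
    unknown = set(responses["stimulus"]) - set(man.index)
    if unknown:
        raise KeyError(f"responses reference unknown stimuli: {sorted(unknown)[:5]}")
    df = responses.merge(
        man[["category", "error_type"]], left_on="stimulus", right_index=True
    )
    grammatical = df["category"].isin(["old_gram", "new_gram"])
    df = df.assign(
        correct=np.where(grammatical, df["familiar"] == 1, df["familiar"] == 0)
    )

    rows = []
    meta_cols = [c for c in ("group", "musician") if c in responses.columns]
    for pid, sub in df.groupby("participant", sort=True):
        cell = {"participant": pid}
        for c in meta_cols:
            cell[c] = sub[c].iloc[0]
        cell["overall"] = sub["correct"].mean()
        gram = sub[sub["category"].isin(["old_gram", "new_gram"])]
        ung = sub[sub["category"] == "ungram"]
        cell["gram_all"] = gram["correct"].mean()
        cell["old_gram"] = sub.loc[sub["category"] == "old_gram", "correct"].mean()
        cell["new_gram"] = sub.loc[sub["category"] == "new_gram", "correct"].mean()
        cell["ungram_all"] = ung["correct"].mean()
        for et in range(1, 6):
            cell[f"et{et}"] = ung.loc[ung["error_type"] == et, "correct"].mean()
        rows.append(cell)
    return pd.DataFrame(rows)


def exclude_outliers(
    acc: pd.DataFrame, k: float = 2.0, column: str = "overall"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude participants more than ``k`` SD from the group mean.

    The criterion is computed once on the full group (no re-iteration after
    removal).  Returns ``(kept, excluded)``.
    """
    if len(acc) < 3:
        raise ValueError("need at least 3 participants for outlier screening")
    vals = acc[column].to_numpy(dtype=float)
    mean, sd = vals.mean(), vals.std(ddof=1)
    out = np.abs(vals - mean) > k * sd
    return acc.loc[~out].copy(), acc.loc[out].copy()


# ---------------------------------------------------------------------------
# planned tests and multiplicity


def one_sample_t(values: Sequence[float], mu: float) -> TestResult:
    """Two-tailed one-sample t test against ``mu`` (sample SD, df = n-1)."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: t statistic undefined")
    t = (x.mean() - mu) / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), df=n - 1)
    return TestResult(t=float(t), df=n - 1, p=float(p), mean=float(x.mean()), sd=float(sd), n=n)


def holm_adjust(pvals: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Holm step-down (sequential Bonferroni) rejection decisions.

    Sort p-values ascending, compare the i-th (1-based) to
    ``alpha / (m - i + 1)``, and stop at the first failure; returns boolean
    decisions in the original order.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for i, idx in enumerate(order):
        if p[idx] <= alpha / (m - i):
            reject[idx] = True
        else:
            break
    return reject


# ---------------------------------------------------------------------------
# mixed ANOVA and contrasts


def _long_to_wide(
    data: pd.DataFrame, within_levels: Sequence[str]
) -> pd.DataFrame:
    wide = data.pivot_table(
        index="participant", columns="level", values="value", aggfunc="mean"
    )
    missing = [l for l in within_levels if l not in wide.columns]
    if missing or wide[list(within_levels)].isna().any().any():
        raise ValueError("every participant needs a complete set of within levels")
    meta = data.drop_duplicates("participant").set_index("participant")
    cols = [c for c in ("group", "musician") if c in meta.columns]
    return wide[list(within_levels)].join(meta[cols])


def mixed_anova(
    data: pd.DataFrame, within_levels: Sequence[str] | None = None
) -> pd.DataFrame:
    """2-between (group, musician) x 1-within mixed-design ANOVA.

    ``data`` is long format with columns ``participant``, ``group``,
    ``musician``, ``level`` (within-factor level) and ``value``.  Unbalanced
    between cells are handled with Type III sums of squares (Sum coding).
    Between effects are tested on subject means against the subjects-within-
    cells error; within effects use the univariate orthonormal-contrast
    decomposition, pooling Type III SS per contrast variable against the
    subject x within residual.  Reports F, dfs, p and partial eta squared.
    """
    required = {"participant", "group", "musician", "level", "value"}
    if not required <= set(data.columns):
        raise ValueError(f"data must have columns {sorted(required)}")
    levels = list(within_levels) if within_levels is not None else sorted(data["level"].unique())
    K = len(levels)
    counts = data.groupby(["group", "musician"])["participant"].nunique()
    if (counts == 0).any() or len(counts) < 1:
        raise ValueError("empty between-subject cell")
    wide = _long_to_wide(data, levels)

    out_rows = []

    # Between part: subject means vs group*musician, Type III.
    sub = wide.copy()
    sub["m"] = wide[levels].mean(axis=1)
    model_b = smf.ols("m ~ C(group, Sum) * C(musician, Sum)", data=sub).fit()
    tab_b = anova_lm(model_b, typ=3)
    ss_err_b = float(tab_b.loc["Residual", "sum_sq"])
    df_err_b = int(tab_b.loc["Residual", "df"])
    name_map = {
        "C(group, Sum)": "group",
        "C(musician, Sum)": "musician",
        "C(group, Sum):C(musician, Sum)": "group:musician",
    }
    for term, label in name_map.items():
        ss = float(tab_b.loc[term, "sum_sq"])
        dfn = int(tab_b.loc[term, "df"])
        F = (ss / dfn) / (ss_err_b / df_err_b)
        p = stats.f.sf(F, dfn, df_err_b)
        out_rows.append(
            dict(effect=label, F=F, df_num=dfn, df_den=df_err_b, p=p,
                 partial_eta_sq=ss / (ss + ss_err_b))
        )

    # Within part: orthonormal contrasts over levels, pooled Type III SS.
    # (named cmat: patsy formulas below must still see their builtin C())
    cmat = _orthonormal_contrasts(K)
    Y = wide[levels].to_numpy(dtype=float)
    ss_terms = {"level": 0.0, "level:group": 0.0, "level:musician": 0.0,
                "level:group:musician": 0.0}
    ss_err_w = 0.0
    term_map = {
        "Intercept": "level",
        "C(group, Sum)": "level:group",
        "C(musician, Sum)": "level:musician",
        "C(group, Sum):C(musician, Sum)": "level:group:musician",
    }
    for r in range(K - 1):
        z = Y @ cmat[r]
        zdf = pd.DataFrame(
            {"z": z, "group": wide["group"].values, "musician": wide["musician"].values}
        )
        fit = smf.ols("z ~ C(group, Sum) * C(musician, Sum)", data=zdf).fit()
        tab = anova_lm(fit, typ=3)
        for term, label in term_map.items():
            ss_terms[label] += float(tab.loc[term, "sum_sq"])
        ss_err_w += float(tab.loc["Residual", "sum_sq"])
    df_err_w = df_err_b * (K - 1)
    # guard: a within factor that is numerically constant per participant
    # leaves only rounding noise in every SS; report F = 0 rather than 0/0
    tiny = 1e-12 * max(1.0, float((Y**2).sum()))
    degenerate = ss_err_w < tiny
    for label, ss in ss_terms.items():
        dfn = K - 1
        if degenerate or ss < tiny:
            F, p = 0.0, 1.0
        else:
            F = (ss / dfn) / (ss_err_w / df_err_w)
            p = stats.f.sf(F, dfn, df_err_w)
        out_rows.append(
            dict(effect=label, F=F, df_num=dfn, df_den=df_err_w, p=p,
                 partial_eta_sq=ss / (ss + ss_err_w) if (ss + ss_err_w) > 0 else 0.0)
        )
    return pd.DataFrame(out_rows).set_index("effect")


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (Helmert-style, normalized)."""
    rows = []
    for i in range(1, k):
        v = np.zeros(k)
        v[:i] = 1.0 / i
        v[i] = -1.0
        rows.append(v / np.linalg.norm(v))
    return np.array(rows)


def within_contrasts(
    data: pd.DataFrame,
    within_levels: Sequence[str] | None = None,
    kind: str = "simple",
) -> pd.DataFrame:
    """Within-subject contrasts on participant-level difference scores.

    ``simple``: each level against the first (reference) level;
    ``repeated``: each adjacent pair of levels.  Each contrast is an F test
    (the squared paired t) with df (1, n-1).
    """
    if kind not in ("simple", "repeated"):
        raise ValueError("kind must be 'simple' or 'repeated'")
    levels = list(within_levels) if within_levels is not None else sorted(data["level"].unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 within levels")
    wide = _long_to_wide(data, levels)
    if kind == "simple":
        pairs = [(levels[0], l) for l in levels[1:]]
    else:
        pairs = list(zip(levels[:-1], levels[1:]))
    rows = []
    for a, b in pairs:
        d = (wide[a] - wide[b]).to_numpy(dtype=float)
        n = len(d)
        sd = d.std(ddof=1)
        if sd == 0:
            F, p = 0.0, 1.0
        else:
            t = d.mean() / (sd / np.sqrt(n))
            F = t * t
            p = stats.f.sf(F, 1, n - 1)
        rows.append(dict(contrast=f"{a} vs {b}", F=F, df_num=1, df_den=n - 1,
                         p=p, mean_diff=d.mean()))
    return pd.DataFrame(rows).set_index("contrast")


# ---------------------------------------------------------------------------
# fragment (chunk) knowledge


def _view_tokens(seq: Sequence[int | str], view: str) -> tuple:
    if view == "pitch" or view == "symbol":
        return tuple(seq)
    if view == "interval":
        s = [int(x) for x in seq]
        if len(s) < 2:
            raise ValueError("interval view needs at least 2 tones")
        return tuple(b - a for a, b in zip(s, s[1:]))
    raise ValueError(f"unknown view {view!r}")


def chunk_strength(
    stimulus: Sequence, corpus: Iterable[Sequence], n: int, view: str = "pitch"
) -> float:
    """Average chunk strength (ACS) of a stimulus against a training corpus.

    Chunk strength of one n-gram is the number of its (overlapping)
    occurrences across all corpus items; ACS is the mean over the stimulus's
    n-grams in the chosen view (``pitch``/``symbol`` tokens, or the
    length-1-shorter ``interval`` sequence).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    toks = _view_tokens(stimulus, view)
    if len(toks) < n:
        raise ValueError(f"stimulus too short for {n}-grams in {view} view")
    corpus_toks = [_view_tokens(c, view) for c in corpus]
    counts = []
    for i in range(len(toks) - n + 1):
        gram = toks[i : i + n]
        c = 0
        for ct in corpus_toks:
            for j in range(len(ct) - n + 1):
                if ct[j : j + n] == gram:
                    c += 1
        counts.append(c)
    return float(np.mean(counts))


def acs_features(
    stimulus: Sequence,
    corpus: Iterable[Sequence],
    n_range: Sequence[int] = tuple(range(1, 9)),
    view: str = "pitch",
) -> dict[str, float]:
    """ACS for each chunk size in ``n_range`` (0 when the stimulus is too
    short to contain the n-gram size)."""
    corpus = list(corpus)
    out = {}
    for n in n_range:
        try:
            out[f"acs{n}"] = chunk_strength(stimulus, corpus, n, view)
        except ValueError:
            out[f"acs{n}"] = 0.0
    return out


# ---------------------------------------------------------------------------
# per-participant logistic regression


@dataclass
class LogisticFit:
    """Ridge-stabilized ML logistic fit for one participant."""

    coef: pd.Series
    converged: bool
    dropped: tuple[str, ...] = ()
    separated: bool = False


def fit_participant_logistic(
    features: pd.DataFrame,
    responses: Sequence[int],
    ridge: float = 1e-6,
    max_iter: int = 200,
) -> LogisticFit:
    """Multiple logistic regression of one participant's familiarity
    responses on raw (unstandardized) predictors.

    A Newton/IRLS maximum-likelihood fit with a tiny L2 penalty keeps the
    coefficients finite under complete separation.  Constant predictors are
    dropped with a warning and reported as missing.
    """
    y = np.asarray(responses, dtype=float)
    X = features.copy()
    dropped = tuple(c for c in X.columns if X[c].nunique() <= 1)
    if dropped:
        warnings.warn(f"dropping constant predictors: {list(dropped)}")
        X = X.drop(columns=list(dropped))
    names = ["intercept"] + list(X.columns)
    A = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])

    beta = np.zeros(A.shape[1])
    converged = False
    for _ in range(max_iter):
        eta = np.clip(A @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = A.T @ (y - mu) - ridge * beta
        W = mu * (1 - mu)
        H = (A * W[:, None]).T @ A + ridge * np.eye(A.shape[1])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # damped step to keep the iteration stable on near-separated data
        if np.max(np.abs(step)) > 50:
            step *= 50 / np.max(np.abs(step))
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            converged = True
            break
    eta = np.clip(A @ beta, -35, 35)
    mu = 1.0 / (1.0 + np.exp(-eta))
    separated = bool(np.all((mu > 0.999) == (y > 0.5)) and np.all((mu < 0.001) == (y < 0.5)))

    coef = pd.Series(beta, index=names, dtype=float)
    for c in dropped:
        coef[c] = np.nan
    order = ["intercept"] + list(features.columns)
    return LogisticFit(coef=coef.reindex(order), converged=converged,
                       dropped=dropped, separated=separated)


def group_beta_tests(betas: pd.DataFrame, mu: float = 0.0) -> pd.DataFrame:
    """One-sample t vs 0 of each fitted coefficient across participants."""
    rows = []
    for col in betas.columns:
        res = one_sample_t(betas[col].dropna(), mu)
        rows.append(dict(predictor=col, mean=res.mean, sd=res.sd, t=res.t,
                         df=res.df, p=res.p, n=res.n))
    return pd.DataFrame(rows).set_index("predictor")


# ---------------------------------------------------------------------------
# metaknowledge and exposure


def type2_dprime(correct: Sequence[int], high_confidence: Sequence[int]) -> float:
    """Type-2 d': sensitivity of confidence to one's own accuracy.

    ``hit`` = P(high confidence | correct), ``fa`` = P(high confidence |
    incorrect); d' = z(hit) - z(fa).  Extreme proportions 0 and 1 are
    replaced by 1/(2N) and 1 - 1/(2N) with N the trials in that cell.
    """
    c = np.asarray(correct, dtype=bool)
    h = np.asarray(high_confidence, dtype=bool)
    n_corr, n_inc = int(c.sum()), int((~c).sum())
    if n_corr == 0 or n_inc == 0:
        raise ValueError("Type-2 d' needs at least one correct and one incorrect trial")

    def rate(k: int, n: int) -> float:
        p = k / n
        if p == 0.0:
            return 1.0 / (2 * n)
        if p == 1.0:
            return 1.0 - 1.0 / (2 * n)
        return p

    hit = rate(int(h[c].sum()), n_corr)
    fa = rate(int(h[~c].sum()), n_inc)
    return float(stats.norm.ppf(hit) - stats.norm.ppf(fa))


def exposure_correlation(
    repetitions: Sequence[float], accuracies: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation (r, two-tailed p) of learning-phase exposure with
    performance."""
    x = np.asarray(repetitions, dtype=float)
    y = np.asarray(accuracies, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples, n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
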