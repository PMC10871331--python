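"""Group statistics for patch-clamp cohort comparisons.

Covers the test battery applied to electrophysiology readouts:

* Kruskal-Wallis with Dunn post-hoc comparisons (non-normal per-cell
  metrics across >= 3 groups);
* Mann-Whitney U for two-group contrasts;
* mixed ("split-plot") repeated-measures ANOVA — between-subject factors
  genotype and treatment, within-subject factor current/voltage step — with
  Greenhouse-Geisser correction of the within-subject degrees of freedom,
  and Tukey(-Kramer) post-hoc comparisons of the between-group means;
* origin-constrained curve fits (one-phase association y = Ymax(1-e^(-Kx))
  and line y = a x) compared pairwise by extra-sum-of-squares F-tests with
  Bonferroni correction.

Rank tests delegate to scipy.stats; the split-plot decomposition, the
epsilon estimate, Dunn, Tukey-Kramer and the nested F machinery are
implemented here (there is no installed implementation for this design).
The family-wise significance threshold is alpha = 0.05 throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.optimize import curve_fit

__all__ = [
    "TestResult",
    "PairwiseComparison",
    "CurveFit",
    "MixedAnovaResult",
    "kruskal_wallis",
    "dunn_posthoc",
    "mann_whitney",
    "rm_anova_gg",
    "tukey_posthoc",
    "fit_one_phase_origin",
    "fit_line_origin",
    "nested_f_test",
    "compare_groups_curvefit",
]

ALPHA = 0.05


@dataclass
class PairwiseComparison:
    pair: tuple[str, str]
    statistic: float
    p_unadjusted: float
    p_adjusted: float


@dataclass
class TestResult:
    statistic: float
    df: float | tuple
    p_value: float
    method: str
    pairwise: list[PairwiseComparison] | None = None


@dataclass
class CurveFit:
    model: str  # one_phase_association_origin | line_origin
    params: tuple
    rss: float
    df_residual: int
    n: int


# ----------------------------------------------------------- rank-based tests

def kruskal_wallis(groups: list[np.ndarray]) -> TestResult:
    """Kruskal-Wallis H across >= 3 groups, tie-corrected, chi-square p."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("Kruskal-Wallis needs >= 3 groups (use mann_whitney for 2)")
    if any(len(g) < 1 for g in groups):
        raise ValueError("every group needs at least one observation")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, len(groups) - 1, 1.0, "kruskal_wallis")
    h, p = sps.kruskal(*groups)
    return TestResult(float(h), len(groups) - 1, float(p), "kruskal_wallis")


def dunn_posthoc(
    groups: list[np.ndarray],
    labels: list[str] | None = None,
    adjust: str = "bonferroni",
) -> list[PairwiseComparison]:
    """Dunn's post-hoc z tests on mean ranks after Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt([N(N+1)/12 - T/(12(N-1))] (1/n_i + 1/n_j))
    with T = sum(t^3 - t) over tie groups.  ``adjust``: 'bonferroni'
    multiplies each two-sided p by the number of pairs; 'none' reports raw p.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ValueError("Dunn post-hoc requires non-empty groups")
    if labels is None:
        labels = [f"g{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    mean_ranks = []
    pos = 0
    for g in groups:
        mean_ranks.append(float(np.mean(ranks[pos : pos + len(g)])))
        pos += len(g)
    pairs = list(itertools.combinations(range(len(groups)), 2))
    m = len(pairs)
    out = []
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, m * p) if adjust == "bonferroni" else p
        out.append(PairwiseComparison((labels[i], labels[j]), float(z), float(p), float(p_adj)))
    return out


def mann_whitney(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Two-sided Mann-Whitney U.

    Exact null distribution when both groups have <= 8 observations and the
    data are tie-free; otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both groups need at least one observation")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), (len(a), len(b)), float(res.pvalue),
                      f"mann_whitney_{method}")


# ----------------------------------------------- mixed repeated-measures ANOVA

@dataclass
class MixedAnovaResult:
    """Split-plot ANOVA table with Greenhouse-Geisser-corrected within effects.

    ``effects`` maps effect name (e.g. 'genotype', 'treatment',
    'genotype:treatment', 'level', 'level:genotype', ...) to a TestResult;
    within-subject entries carry epsilon-scaled df and corrected p.
    """

    effects: dict = field(default_factory=dict)
    epsilon: float = 1.0
    n_subjects: int = 0
    n_levels: int = 0

    def __getitem__(self, key: str) -> TestResult:
        return self.effects[key]


def _dummies(labels: np.ndarray) -> np.ndarray:
    cats = np.unique(labels)
    return (labels[:, None] == cats[None, :]).astype(float)


def _interact(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # column-wise products of two dummy blocks
    return (a[:, :, None] * b[:, None, :]).reshape(len(a), -1)


def _rss(y: np.ndarray, design: np.ndarray | None) -> float:
    if design is None or design.size == 0:
        return float(y @ y)
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return float(resid @ resid)


def _gg_epsilon(wide: np.ndarray, group_codes: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the pooled within-group covariance."""
    k = wide.shape[1]
    if k < 3:
        return 1.0
    pooled = np.zeros((k, k))
    n_used = 0
    for g in np.unique(group_codes):
        block = wide[group_codes == g]
        if len(block) > 1:
            pooled += (len(block) - 1) * np.cov(block, rowvar=False)
            n_used += len(block) - 1
    if n_used == 0:
        return 1.0
    s = pooled / n_used
    # double-center
    rm = s.mean(axis=0, keepdims=True)
    cm = s.mean(axis=1, keepdims=True)
    s_dc = s - rm - cm + s.mean()
    num = np.trace(s_dc) ** 2
    den = (k - 1) * np.sum(s_dc**2)
    if den <= 0:
        return 1.0
    eps = float(num / den)
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def rm_anova_gg(
    data,
    dv: str = "value",
    subject: str = "cell_id",
    within: str = "level",
    between: list[str] | tuple = ("genotype", "treatment"),
) -> MixedAnovaResult:
    """Mixed-design repeated-measures ANOVA with Greenhouse-Geisser correction.

    ``data`` is a long-format DataFrame with one response per (subject,
    within-level).  Between-subject factors (one or two) are constant within
    subject.  The within-subject grid must be complete; incomplete subjects
    raise with instructions to exclude or impute explicitly.

    Between-subject effects are tested against the subjects-within-groups
    mean square (computed from subject means; Type II sums of squares).
    Within-subject effects (the level main effect and its interactions with
    the between factors) are tested against the subject-by-level residual,
    with numerator and denominator df scaled by the Greenhouse-Geisser
    epsilon estimated from the pooled within-group covariance of the level
    responses.
    """
    import pandas as pd

    between = list(between)
    if not 1 <= len(between) <= 2:
        raise ValueError("one or two between-subject factors are supported")
    wide_df = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    if wide_df.isna().any().any():
        bad = wide_df.index[wide_df.isna().any(axis=1)].tolist()
        raise ValueError(
            f"incomplete within-subject grid for subjects {bad}; exclude these "
            "cells or impute explicitly before testing"
        )
    k = wide_df.shape[1]
    if k < 2:
        raise ValueError("within factor needs >= 2 levels")
    subj_meta = data.drop_duplicates(subject).set_index(subject).loc[wide_df.index]
    factors = {b: subj_meta[b].to_numpy() for b in between}
    wide = wide_df.to_numpy(dtype=float)
    n_subj = wide.shape[0]

    # combined between-group coding
    if len(between) == 2:
        combo = np.char.add(
            np.char.add(factors[between[0]].astype(str), "|"),
            factors[between[1]].astype(str),
        )
    else:
        combo = factors[between[0]].astype(str)
    _, group_codes = np.unique(combo, return_inverse=True)
    n_groups = group_codes.max() + 1
    counts = np.bincount(group_codes)
    if np.any(counts < 2):
        raise ValueError("every between-subject group needs >= 2 subjects")

    result = MixedAnovaResult(n_subjects=n_subj, n_levels=k)

    # ---- between-subject part: Type II ANOVA on subject means -------------
    ybar = wide.mean(axis=1)
    inter = np.ones((n_subj, 1))
    dum = {b: _dummies(factors[b]) for b in between}
    df_err_b = n_subj - n_groups
    if len(between) == 1:
        b1 = between[0]
        rss_null = _rss(ybar - ybar.mean(), None)
        rss_a = _rss(ybar, np.hstack([inter, dum[b1]]))
        ss_a = rss_null - rss_a
        ms_err = rss_a / df_err_b
        df_a = dum[b1].shape[1] - 1
        f = (ss_a / df_a) / ms_err
        result.effects[b1] = TestResult(
            float(f), (df_a, df_err_b), float(sps.f.sf(f, df_a, df_err_b)), "between_f"
        )
        rss_full_b = rss_a
    else:
        b1, b2 = between
        d1, d2 = dum[b1], dum[b2]
        d12 = _interact(d1, d2)
        rss_1 = _rss(ybar, np.hstack([inter, d1]))
        rss_2 = _rss(ybar, np.hstack([inter, d2]))
        rss_12 = _rss(ybar, np.hstack([inter, d1, d2]))
        rss_full_b = _rss(ybar, np.hstack([inter, d12]))
        ms_err = rss_full_b / df_err_b
        specs = [
            (b1, rss_2 - rss_12, d1.shape[1] - 1),
            (b2, rss_1 - rss_12, d2.shape[1] - 1),
            (f"{b1}:{b2}", rss_12 - rss_full_b, (d1.shape[1] - 1) * (d2.shape[1] - 1)),
        ]
        for name, ss, df_n in specs:
            ss = max(ss, 0.0)
            f = (ss / df_n) / ms_err
            result.effects[name] = TestResult(
                float(f), (df_n, df_err_b), float(sps.f.sf(f, df_n, df_err_b)), "between_f"
            )

    # ---- within-subject part on subject-centered data ---------------------
    centered = wide - wide.mean(axis=1, keepdims=True)
    y = centered.ravel()  # subject-major
    lev = np.tile(np.arange(k), n_subj)
    dlev = _dummies(lev)
    reps = {b: np.repeat(factors[b], k) for b in between}
    dlev_b = {b: _interact(dlev, _dummies(reps[b])) for b in between}
    grp_rep = np.repeat(group_codes, k)
    dlev_g = _interact(dlev, _dummies(grp_rep.astype(str)))

    eps = _gg_epsilon(wide, group_codes)
    result.epsilon = eps
    rss_err = _rss(y, dlev_g)  # full within model: level x group cell means
    df_err_w = (n_subj - n_groups) * (k - 1)
    ms_err_w = rss_err / df_err_w

    def add_within(name: str, ss: float, df_n: int) -> None:
        ss = max(ss, 0.0)
        f = (ss / df_n) / ms_err_w
        p = float(sps.f.sf(f, eps * df_n, eps * df_err_w))
        result.effects[name] = TestResult(float(f), (eps * df_n, eps * df_err_w), p, "within_f_gg")

    rss_0 = _rss(y, None)
    rss_l = _rss(y, dlev)
    if len(between) == 1:
        b1 = between[0]
        add_within(within, rss_0 - rss_l, k - 1)
        l1 = dum[b1].shape[1]
        add_within(f"{within}:{b1}", rss_l - rss_err, (k - 1) * (l1 - 1))
    else:
        b1, b2 = between
        l1, l2 = dum[b1].shape[1], dum[b2].shape[1]
        rss_l1 = _rss(y, np.hstack([dlev, dlev_b[b1]]))
        rss_l2 = _rss(y, np.hstack([dlev, dlev_b[b2]]))
        rss_l12 = _rss(y, np.hstack([dlev, dlev_b[b1], dlev_b[b2]]))
        add_within(within, rss_0 - rss_l, k - 1)
        add_within(f"{within}:{b1}", rss_l2 - rss_l12, (k - 1) * (l1 - 1))
        add_within(f"{within}:{b2}", rss_l1 - rss_l12, (k - 1) * (l2 - 1))
        add_within(
            f"{within}:{b1}:{b2}", rss_l12 - rss_err, (k - 1) * (l1 - 1) * (l2 - 1)
        )

    # stash context for Tukey post-hoc
    result._tukey_ctx = {
        "group_labels": combo,
        "subject_means": ybar,
        "ms_error": ms_err,
        "df_error": df_err_b,
    }
    return result


def tukey_posthoc(anova: MixedAnovaResult) -> list[PairwiseComparison]:
    """Tukey(-Kramer) HSD on the between-group marginal means.

    Uses the subjects-within-groups mean square and the studentized-range
    distribution; with unequal group sizes the Tukey-Kramer standard error
    is applied.
    """
    ctx = getattr(anova, "_tukey_ctx", None)
    if ctx is None:
        raise ValueError("run rm_anova_gg first; its result carries the error term")
    labels = ctx["group_labels"]
    ybar = ctx["subject_means"]
    cats = np.unique(labels)
    if len(cats) < 2:
        raise ValueError("Tukey post-hoc needs >= 2 groups")
    means = {c: float(np.mean(ybar[labels == c])) for c in cats}
    ns = {c: int(np.sum(labels == c)) for c in cats}
    out = []
    for a, b in itertools.combinations(cats, 2):
        se = np.sqrt(ctx["ms_error"] / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
        q = abs(means[a] - means[b]) / se if se > 0 else 0.0
        p = float(sps.studentized_range.sf(q, len(cats), ctx["df_error"]))
        p = min(max(p, 0.0), 1.0)
        out.append(PairwiseComparison((str(a), str(b)), float(q), p, p))
    return out


# --------------------------------------------- origin-constrained curve fits

def fit_one_phase_origin(x: np.ndarray, y: np.ndarray) -> CurveFit:
    """Least-squares fit of y = Ymax (1 - exp(-K x)), constrained through 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("one-phase association fit needs >= 3 points")
    if np.any(x < 0):
        raise ValueError("x must be >= 0 for the one-phase association model")
    if np.allclose(y, 0.0):
        return CurveFit("one_phase_association_origin", (0.0, 1.0), 0.0, len(x) - 2, len(x))

    def model(xx, ymax, kk):
        return ymax * (1.0 - np.exp(-kk * xx))

    xpos = x[x > 0]
    k0 = 1.0 / float(np.mean(xpos)) if xpos.size else 1.0
    y0 = float(np.max(np.abs(y))) or 1.0
    try:
        popt, _ = curve_fit(
            model, x, y, p0=(y0, k0), maxfev=20000,
            bounds=([-np.inf, 1e-12], [np.inf, np.inf]),
        )
    except (RuntimeError, ValueError) as exc:
        resid = float(np.sum((y - model(x, y0, k0)) ** 2))
        raise RuntimeError(f"one-phase fit did not converge (rss at start {resid:.3g})") from exc
    rss = float(np.sum((y - model(x, *popt)) ** 2))
    return CurveFit("one_phase_association_origin", (float(popt[0]), float(popt[1])),
                    rss, len(x) - 2, len(x))


def fit_line_origin(x: np.ndarray, y: np.ndarray) -> CurveFit:
    """Closed-form fit of y = slope * x through the origin."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2:
        raise ValueError("line fit needs >= 2 points")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("all x are zero; slope through the origin is undefined")
    slope = float(np.sum(x * y) / sxx)
    rss = float(np.sum((y - slope * x) ** 2))
    return CurveFit("line_origin", (slope,), rss, len(x) - 1, len(x))


def nested_f_test(
    shared: CurveFit, separate: list[CurveFit], family_size: int = 1
) -> TestResult:
    """Extra-sum-of-squares F-test of one shared curve vs per-group curves.

    F = ((RSS_shared - RSS_sep)/(df_shared - df_sep)) / (RSS_sep/df_sep);
    the Bonferroni-adjusted p multiplies by ``family_size`` (the number of
    pairwise comparisons in the family).
    """
    if any(fit.model != shared.model for fit in separate):
        raise ValueError("shared and separate fits must use the same model")
    rss_sep = sum(fit.rss for fit in separate)
    df_sep = sum(fit.df_residual for fit in separate)
    df_diff = shared.df_residual - df_sep
    if df_diff <= 0:
        raise ValueError("shared model must have more residual df than the separate fits")
    if rss_sep > shared.rss * (1 + 1e-9) + 1e-12:
        raise RuntimeError(
            "separate fits have larger pooled RSS than the shared fit; "
            "nested least squares failed to converge"
        )
    if df_sep <= 0:
        raise ValueError("separate fits leave no residual df")
    if rss_sep == 0:
        f = 0.0 if shared.rss == 0 else np.inf
    else:
        f = ((shared.rss - rss_sep) / df_diff) / (rss_sep / df_sep)
    f = max(f, 0.0)
    p = float(sps.f.sf(f, df_diff, df_sep)) if np.isfinite(f) else 0.0
    p_adj = min(1.0, family_size * p)
    res = TestResult(float(f), (df_diff, df_sep), p, "nested_f")
    res.pairwise = [PairwiseComparison(("shared", "separate"), float(f), p, p_adj)]
    return res


def compare_groups_curvefit(
    x: np.ndarray,
    curves: dict,
    model: str = "one_phase_association_origin",
) -> list[PairwiseComparison]:
    """Pairwise nested F-tests of group firing-probability curves.

    Fits each group separately and every pair jointly; Bonferroni-corrects
    over the number of pairs.  ``curves`` maps group label -> y values on the
    shared x grid.
    """
    fitter = fit_one_phase_origin if model == "one_phase_association_origin" else fit_line_origin
    fits = {g: fitter(x, y) for g, y in curves.items()}
    pairs = list(itertools.combinations(sorted(curves), 2))
    m = len(pairs)
    out = []
    for a, b in pairs:
        pooled_x = np.concatenate([x, x])
        pooled_y = np.concatenate([curves[a], curves[b]])
        shared = fitter(pooled_x, pooled_y)
        res = nested_f_test(shared, [fits[a], fits[b]], family_size=m)
        out.append(
            PairwiseComparison(
                (a, b), res.statistic, res.p_value, min(1.0, m * res.p_value)
            )
        )
    return out
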