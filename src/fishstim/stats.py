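"""Statistical analysis of the social-approach assay, implemented from scratch.

The design is a split-plot (mixed) two-way layout: *group* (which stimulus a
subject saw) is a between-subjects factor with g levels, *time* (baseline and
each stimulus minute) is a within-subjects factor with k levels, and the
response is the per-minute difference score in seconds.  The analysis chain
is:

1. one-way ANOVA on baseline occupancy (groups should not differ before the
   stimulus appears);
2. two-way mixed ANOVA on the scores;
3. a multisample sphericity test on the pooled within-group covariance of
   orthonormal contrast scores — when sphericity fails, within-subject
   degrees of freedom are rescaled with the Huynh–Feldt epsilon;
4. simple main effects when the group x time interaction is significant;
5. Ryan's stepwise multiple-comparison procedure for post-hoc pairwise
   contrasts.

Everything returns plain pandas DataFrames / small dataclasses; p-values come
from scipy's F and chi-square distributions, never from tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats as sps

__all__ = [
    "MixedDesignData",
    "SphericityResult",
    "oneway_anova",
    "oneway_rm_anova",
    "mixed_anova",
    "mendoza_sphericity",
    "huynh_feldt_correction",
    "simple_main_effects",
    "ryan_posthoc",
    "analyze_scores",
]


@dataclass
class MixedDesignData:
    """Complete subjects x time score matrix with group labels.

    ``scores`` has shape ``(N, k)``; ``groups`` holds one label per subject.
    The design must be complete (no missing cells) and every group needs at
    least two subjects.
    """

    scores: np.ndarray
    groups: np.ndarray
    time_labels: tuple[str, ...] | None = None
    alpha: float = 0.05

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.groups = np.asarray(self.groups)
        if self.scores.ndim != 2 or self.scores.shape[1] < 2:
            raise ValueError("scores must be (N, k) with k >= 2")
        if len(self.groups) != self.scores.shape[0]:
            raise ValueError("need one group label per subject")
        if np.isnan(self.scores).any():
            raise ValueError("design must be complete (no missing cells)")
        labels, counts = np.unique(self.groups, return_counts=True)
        if len(labels) < 1 or counts.min() < 2:
            raise ValueError("every group needs n >= 2")
        if self.time_labels is None:
            self.time_labels = tuple(f"t{j}" for j in range(self.scores.shape[1]))

    @property
    def n_subjects(self) -> int:
        return self.scores.shape[0]

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    @property
    def group_labels(self) -> np.ndarray:
        # stable first-appearance order
        _, idx = np.unique(self.groups, return_index=True)
        return self.groups[np.sort(idx)]

    @classmethod
    def from_long(
        cls,
        df: pd.DataFrame,
        dv: str = "score",
        within: str = "time",
        subject: str = "subject",
        between: str = "group",
        alpha: float = 0.05,
    ) -> "MixedDesignData":
        wide = df.pivot(index=subject, columns=within, values=dv)
        # preserve the within-level order of first appearance
        order = df[within].drop_duplicates().tolist()
        wide = wide[order]
        grp = df.drop_duplicates(subject).set_index(subject)[between]
        grp = grp.loc[wide.index]
        return cls(
            scores=wide.to_numpy(),
            groups=grp.to_numpy(),
            time_labels=tuple(order),
            alpha=alpha,
        )


def _f_pvalue(f: float, df1: float, df2: float) -> float:
    return float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else float("nan")


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den <= 0:
        warnings.warn(f"{what}: zero error variance, F undefined", stacklevel=3)
        return float("nan")
    return num / den


def oneway_anova(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Classical one-way between-subjects ANOVA.

    Returns a single-row DataFrame (effect ``group``) with SS, df1, df2, MS,
    F and p.  A zero within-group variance yields F = NaN with a warning
    (degenerate fixtures are legitimate in tests).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    ns = np.array([(groups == g).sum() for g in labels])
    if ns.min() < 2:
        raise ValueError("every group needs n >= 2")
    grand = values.mean()
    means = np.array([values[groups == g].mean() for g in labels])
    ss_b = float(np.sum(ns * (means - grand) ** 2))
    ss_w = float(sum(np.sum((values[groups == g] - m) ** 2) for g, m in zip(labels, means)))
    df1, df2 = len(labels) - 1, len(values) - len(labels)
    f = _safe_ratio(ss_b / df1, ss_w / df2, "one-way ANOVA")
    return pd.DataFrame(
        [
            {
                "effect": "group",
                "SS": ss_b,
                "df1": df1,
                "df2": df2,
                "MS": ss_b / df1,
                "MS_error": ss_w / df2,
                "F": f,
                "p": _f_pvalue(f, df1, df2),
            }
        ]
    ).set_index("effect")


def oneway_rm_anova(scores: np.ndarray) -> pd.DataFrame:
    """One-way repeated-measures ANOVA on an (n, k) score matrix.

    Subject is the blocking factor; F = MS_time / MS_residual with df
    (k - 1, (n - 1)(k - 1)).
    """
    scores = np.asarray(scores, dtype=float)
    n, k = scores.shape
    grand = scores.mean()
    ss_time = float(n * np.sum((scores.mean(axis=0) - grand) ** 2))
    ss_subj = float(k * np.sum((scores.mean(axis=1) - grand) ** 2))
    ss_total = float(np.sum((scores - grand) ** 2))
    ss_res = ss_total - ss_time - ss_subj
    df1, df2 = k - 1, (n - 1) * (k - 1)
    f = _safe_ratio(ss_time / df1, ss_res / df2, "RM ANOVA")
    return pd.DataFrame(
        [
            {
                "effect": "time",
                "SS": ss_time,
                "df1": df1,
                "df2": df2,
                "MS": ss_time / df1,
                "MS_error": ss_res / df2,
                "F": f,
                "p": _f_pvalue(f, df1, df2),
            }
        ]
    ).set_index("effect")


def mixed_anova(data: MixedDesignData) -> pd.DataFrame:
    """Two-way mixed (split-plot) ANOVA: between = group, within = time.

    Decomposition: the between-subjects stratum tests *group* against the
    subject-within-group error; the within-subjects stratum tests *time* and
    *group x time* against the time-x-subject-within-group error.  Raw
    degrees of freedom are (g-1, N-g) for group, (k-1, (N-g)(k-1)) for time
    and ((g-1)(k-1), (N-g)(k-1)) for the interaction.

    The returned DataFrame has one row per tested effect; the error strata
    live in ``result.attrs["error_terms"]`` and the full SS decomposition in
    ``result.attrs`` (used by the conservation tests).
    """
    y = data.scores
    groups = data.groups
    labels = data.group_labels
    N, k = y.shape
    g = len(labels)
    if g < 2:
        raise ValueError("mixed design needs at least two groups")
    ns = np.array([(groups == lab).sum() for lab in labels])

    grand = y.mean()
    subj_mean = y.mean(axis=1)
    time_mean = y.mean(axis=0)
    group_mean = np.array([y[groups == lab].mean() for lab in labels])
    cell_mean = np.array([y[groups == lab].mean(axis=0) for lab in labels])

    ss_total = float(np.sum((y - grand) ** 2))
    ss_between_subj = float(k * np.sum((subj_mean - grand) ** 2))
    ss_group = float(k * np.sum(ns * (group_mean - grand) ** 2))
    ss_subj_within = ss_between_subj - ss_group
    ss_time = float(N * np.sum((time_mean - grand) ** 2))
    ss_cells = float(np.sum(ns[:, None] * (cell_mean - grand) ** 2))
    ss_inter = ss_cells - ss_group - ss_time
    ss_within_subj = ss_total - ss_between_subj
    ss_err_w = ss_within_subj - ss_time - ss_inter

    df_group, df_err_b = g - 1, N - g
    df_time = k - 1
    df_inter = (g - 1) * (k - 1)
    df_err_w = (N - g) * (k - 1)

    ms_err_b = ss_subj_within / df_err_b
    ms_err_w = ss_err_w / df_err_w

    rows = []
    for name, ss, df1, mse, df2 in [
        ("group", ss_group, df_group, ms_err_b, df_err_b),
        ("time", ss_time, df_time, ms_err_w, df_err_w),
        ("group x time", ss_inter, df_inter, ms_err_w, df_err_w),
    ]:
        f = _safe_ratio(ss / df1, mse, f"mixed ANOVA effect {name}")
        rows.append(
            {
                "effect": name,
                "SS": ss,
                "df1": float(df1),
                "df2": float(df2),
                "MS": ss / df1,
                "MS_error": mse,
                "F": f,
                "p": _f_pvalue(f, df1, df2),
            }
        )
    table = pd.DataFrame(rows).set_index("effect")
    table.attrs["error_terms"] = {
        "subject(group)": {"SS": ss_subj_within, "df": df_err_b, "MS": ms_err_b},
        "time x subject(group)": {"SS": ss_err_w, "df": df_err_w, "MS": ms_err_w},
    }
    table.attrs["SS_total"] = ss_total
    table.attrs["design"] = {"g": g, "k": k, "N": N, "n_per_group": ns.tolist()}
    return table


@dataclass
class SphericityResult:
    """Multisample sphericity test result plus epsilon estimates."""

    statistic: float
    df: float
    p: float
    eps_gg: float
    eps_hf: float
    W: float


def mendoza_sphericity(data: MixedDesignData) -> SphericityResult:
    """Multisample sphericity test on the pooled contrast covariance.

    Scores are projected onto a (k-1)-dimensional orthonormal contrast basis
    (normalised Helmert matrix); the within-group SSCP matrices of the
    contrast scores are pooled over the g groups (error df e = N - g) and
    the likelihood-ratio criterion for sphericity

        W = det(S) / (tr(S) / p)**p,     p = k - 1,

    is referred to chi-square via the Mauchly-type approximation
    X^2 = -(e - (2 p^2 + p + 2) / (6 p)) * ln W on p(p+1)/2 - 1 degrees of
    freedom (Mauchly 1940 one-sample factor with the pooled error df).

    Also returns the Greenhouse–Geisser epsilon from the pooled contrast
    covariance and the multi-group Huynh–Feldt epsilon, which uses (N - g)
    in place of the single-group (N - 1) and is clipped to [eps_GG, 1].
    """
    y = data.scores
    k = data.k
    p = k - 1
    labels = data.group_labels
    g = len(labels)
    C = linalg.helmert(k, full=False)  # (k-1, k), orthonormal rows
    S = np.zeros((p, p))
    for lab in labels:
        grp = y[data.groups == lab]
        z = (grp - grp.mean(axis=0)) @ C.T
        S += z.T @ z
    e = data.n_subjects - g
    tr = float(np.trace(S))
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0 or tr <= 0:
        raise ValueError(
            "pooled contrast covariance is singular; collect more subjects "
            "per group (need pooled error df >= number of contrasts)"
        )
    logW = logdet - p * np.log(tr / p)
    stat = -(e - (2 * p**2 + p + 2) / (6.0 * p)) * logW
    df = p * (p + 1) / 2.0 - 1.0
    pval = float(sps.chi2.sf(stat, df))

    eps_gg = tr**2 / (p * float(np.trace(S @ S)))
    num = (e + 1) * p * eps_gg - 2.0
    den = p * (e - p * eps_gg)
    eps_hf = num / den if den > 0 else 1.0
    eps_hf = float(np.clip(eps_hf, eps_gg, 1.0))
    return SphericityResult(
        statistic=float(stat), df=df, p=pval, eps_gg=float(eps_gg),
        eps_hf=eps_hf, W=float(np.exp(logW)),
    )


def huynh_feldt_correction(table: pd.DataFrame, eps: float) -> pd.DataFrame:
    """Rescale within-subject degrees of freedom by epsilon and recompute p.

    Both numerator and denominator df of the within-subject effects (every
    row except the between-subjects ``group`` effect) are multiplied by
    ``eps``; F is unchanged (it is a ratio of mean squares) and p is
    re-evaluated at the corrected df.  ``eps`` must lie in
    [1/(k-1), 1]; with eps = 1 the table is returned unchanged.
    """
    if not 0 < eps <= 1:
        raise ValueError("eps must be in (0, 1]")
    out = table.copy()
    out.attrs = dict(table.attrs)
    for effect in out.index:
        if effect == "group":
            continue
        df1 = table.loc[effect, "df1"] * eps
        df2 = table.loc[effect, "df2"] * eps
        out.loc[effect, "df1"] = df1
        out.loc[effect, "df2"] = df2
        out.loc[effect, "p"] = _f_pvalue(table.loc[effect, "F"], df1, df2)
    out.attrs["epsilon"] = eps
    return out


def simple_main_effects(data: MixedDesignData) -> pd.DataFrame:
    """Simple main effects after a significant group x time interaction.

    Two families of slices, each analysed with its own error term:

    * *group at time t* — one-way between-subjects ANOVA on the scores of
      time level t;
    * *time within group G* — one-way repeated-measures ANOVA restricted to
      group G's subjects.

    Returns one row per slice with SS, df, F and p.
    """
    rows = []
    for j, t in enumerate(data.time_labels):
        tab = oneway_anova(data.scores[:, j], data.groups)
        r = tab.iloc[0]
        rows.append(
            {
                "slice": f"group @ {t}",
                "SS": r["SS"], "df1": r["df1"], "df2": r["df2"],
                "F": r["F"], "p": r["p"],
            }
        )
    for lab in data.group_labels:
        tab = oneway_rm_anova(data.scores[data.groups == lab])
        r = tab.iloc[0]
        rows.append(
            {
                "slice": f"time @ {lab}",
                "SS": r["SS"], "df1": r["df1"], "df2": r["df2"],
                "F": r["F"], "p": r["p"],
            }
        )
    return pd.DataFrame(rows).set_index("slice")


def ryan_posthoc(
    means: np.ndarray,
    ns: np.ndarray,
    ms_error: float,
    df_error: float,
    alpha: float = 0.05,
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Ryan's stepwise multiple-comparison procedure on k means.

    Means are rank-ordered; the pair (i, j) whose ordered positions span r
    means (r = rank difference + 1) is tested with a two-sided t-test on the
    pooled error term,

        t = (m_i - m_j) / sqrt(MS_error * (1/n_i + 1/n_j)),

    at the stretch-adjusted nominal level

        alpha_r = 2 * alpha / (k * (r - 1)),

    which reduces to alpha itself for k = 2 (a plain two-mean test) and to
    the Bonferroni level for the full-range pair.  Stepwise coherence is
    enforced: a pair is declared significant only if its own test rejects
    AND every enclosing span's test also rejected, so no isolated
    significance can appear inside a non-significant stretch.

    The exact small-print of "Ryan's method" varies across sources (the
    REGWQ studentized-range variant is a common alternative); this is the
    stepwise adjusted-alpha t-test formulation.
    """
    means = np.asarray(means, dtype=float)
    ns = np.asarray(ns)
    kk = len(means)
    if kk < 2:
        raise ValueError("need at least two means")
    if labels is None:
        labels = [f"m{i}" for i in range(kk)]
    order = np.argsort(means)  # ascending
    tested: dict[tuple[int, int], bool] = {}
    rows = []
    for r in range(kk, 1, -1):  # stretch size, largest first
        alpha_r = alpha if kk == 2 else 2.0 * alpha / (kk * (r - 1))
        for a in range(0, kk - r + 1):
            b = a + r - 1
            i, j = order[b], order[a]  # larger mean first
            se = np.sqrt(ms_error * (1.0 / ns[i] + 1.0 / ns[j]))
            if se == 0:
                t, p = np.inf if means[i] != means[j] else 0.0, 0.0 if means[i] != means[j] else 1.0
            else:
                t = (means[i] - means[j]) / se
                p = 2.0 * float(sps.t.sf(abs(t), df_error))
            rejects = p <= alpha_r
            blocked = any(
                not tested[(aa, bb)]
                for (aa, bb) in tested
                if aa <= a and bb >= b and (aa, bb) != (a, b)
            )
            significant = rejects and not blocked
            tested[(a, b)] = significant
            rows.append(
                {
                    "pair": f"{labels[i]} vs {labels[j]}",
                    "hi": labels[i],
                    "lo": labels[j],
                    "stretch": r,
                    "diff": means[i] - means[j],
                    "t": float(t),
                    "p": p,
                    "alpha_nominal": alpha_r,
                    "blocked": blocked,
                    "significant": significant,
                }
            )
    return pd.DataFrame(rows)


def analyze_scores(
    long_df: pd.DataFrame, alpha: float = 0.05
) -> dict:
    """Full analysis chain on long-format scores (subject/group/time/score).

    Runs the mixed ANOVA, the multisample sphericity test, applies the
    Huynh–Feldt correction to the within-subject effects whenever the
    sphericity test rejects at ``alpha``, computes simple main effects if
    the (corrected) interaction is significant, and runs Ryan's post-hoc on
    the group means (per-subject means pooled over time, tested against the
    between-subjects error) and on the time means (pooled over groups,
    against the within error).

    Returns a dict with keys ``anova`` (possibly corrected), ``anova_raw``,
    ``sphericity``, ``simple_effects`` (or None), ``posthoc_group``,
    ``posthoc_time``.
    """
    data = MixedDesignData.from_long(long_df, alpha=alpha)
    raw = mixed_anova(data)
    sph = mendoza_sphericity(data)
    table = huynh_feldt_correction(raw, sph.eps_hf) if sph.p < alpha else raw

    simple = None
    if table.loc["group x time", "p"] < alpha:
        simple = simple_main_effects(data)

    labels = data.group_labels
    subj_means = data.scores.mean(axis=1)
    ns = np.array([(data.groups == lab).sum() for lab in labels])
    gmeans = np.array([subj_means[data.groups == lab].mean() for lab in labels])
    err_b = raw.attrs["error_terms"]["subject(group)"]
    # subject means average k scores, so the error mean square scales by 1/k
    posthoc_group = ryan_posthoc(
        gmeans, ns, err_b["MS"] / data.k, err_b["df"], alpha, list(labels)
    )
    err_w = raw.attrs["error_terms"]["time x subject(group)"]
    tmeans = data.scores.mean(axis=0)
    posthoc_time = ryan_posthoc(
        tmeans,
        np.full(data.k, data.n_subjects),
        err_w["MS"],
        err_w["df"],
        alpha,
        list(data.time_labels),
    )
    return {
        "anova": table,
        "anova_raw": raw,
        "sphericity": sph,
        "simple_effects": simple,
        "posthoc_group": posthoc_group,
        "posthoc_time": posthoc_time,
    }
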