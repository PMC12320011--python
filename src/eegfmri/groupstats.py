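"""Group-level consistency statistics for spatially averaged correlations.

Across the subjects of each dataset (and across all subjects pooled), the
spatially averaged EEG-fMRI correlation of every (RSN, band, delay) cell is
tested against zero with a two-sided one-sample t-test, preceded by a
Shapiro-Wilk normality check (reported, not used as a gate), and adjusted
for multiple comparisons across the (RSN, band, delay) family with the
Benjamini-Hochberg false-discovery-rate procedure.  Both corrected and
uncorrected flags are retained.  A repeated-measures ANOVA quantifies the
effects of dataset, RSN, band, and delay on the correlations; because
subjects are nested in datasets, the design is implemented as a split-plot
(dataset between-subject, the rest within-subject), with each effect tested
against its own subject-interaction error stratum.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "shapiro_wilk",
    "one_sample_t",
    "fdr_correct",
    "rm_anova",
    "posthoc_pairwise",
    "consistency_report",
]


def shapiro_wilk(values: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and approximate p-value.

    Requires 3 <= n <= 5000 and non-constant data.
    """
    v = np.asarray(values, dtype=float)
    if not 3 <= len(v) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(v) == 0:
        raise ValueError("Shapiro-Wilk undefined for constant data")
    res = sps.shapiro(v)
    return float(res.statistic), float(res.pvalue)


def one_sample_t(values: np.ndarray, mu: float = 0.0,
                 ) -> tuple[float, float, int]:
    """Two-sided one-sample t-test: ``t = (mean - mu) / (sd / sqrt(n))``.

    Returns ``(t, p_two_sided, df)``; a zero sample SD makes the statistic
    undefined and returns NaN for t and p.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = len(v)
    if n < 2:
        raise ValueError("need n >= 2")
    sd = v.std(ddof=1)
    df = n - 1
    if sd == 0:
        return float("nan"), float("nan"), df
    t = (v.mean() - mu) / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(p), df


def fdr_correct(p_values: np.ndarray, q: float = 0.05,
                ) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up over one family of p-values.

    The family is all (RSN, band, delay) cells of one dataset/space
    analysis.  Returns ``(flags, realized_threshold)`` where the threshold
    is the largest p-value declared significant (0 when none are).  NaN
    p-values are never significant and do not count toward the family size.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    flags = np.zeros(p.shape, dtype=bool)
    finite = np.isfinite(p)
    if finite.any():
        rej, *_ = multipletests(p[finite], alpha=q, method="fdr_bh")[:1]
        flags[finite] = rej
    threshold = float(p[flags].max()) if flags.any() else 0.0
    return flags, threshold


def _check_balanced(df: pd.DataFrame, subject: str, within: list[str]) -> None:
    counts = df.groupby([subject] + within, observed=True).size()
    if (counts != 1).any():
        bad = counts[counts != 1].index.tolist()[:5]
        raise ValueError(f"design not balanced; offending cells: {bad}")
    full = df.groupby(subject, observed=True).size()
    expected = int(np.prod([df[f].nunique() for f in within]))
    missing = full[full != expected]
    if len(missing):
        raise ValueError(
            f"incomplete within-subject crossing for subjects {missing.index.tolist()}")


def _margin_ss(df: pd.DataFrame, dv: str, cols: list[str], grand: float) -> float:
    """Sum of squares of a marginal-means table about the grand mean."""
    if not cols:
        return 0.0
    means = df.groupby(cols, observed=True)[dv].mean()
    per_cell = len(df) / len(means)
    return float(per_cell * ((means - grand) ** 2).sum())


def rm_anova(long_table: pd.DataFrame, dv: str, within: list[str],
             subject: str = "subject", between: str | None = None,
             ) -> pd.DataFrame:
    """Repeated-measures / split-plot ANOVA from partitioned sums of squares.

    ``within`` factors are crossed within subjects (one observation per
    cell); an optional ``between`` factor has subjects nested in its levels
    with equal group sizes.  Every within-involving effect is tested against
    its interaction with subjects (within groups); the between main effect
    is tested against subjects-within-groups.  No sphericity correction is
    applied.  Returns a table with columns
    ``effect, ss, df_num, ss_err, df_den, F, p``.
    """
    df = long_table.copy()
    factors = ([between] if between else []) + list(within)
    _check_balanced(df, subject, list(within))
    if between:
        per_sub = df.groupby(subject, observed=True)[between].nunique()
        if (per_sub != 1).any():
            raise ValueError("each subject must belong to exactly one group")
        group_sizes = df.drop_duplicates(subject).groupby(
            between, observed=True).size()
        if group_sizes.nunique() != 1:
            raise ValueError("between-subject groups must be equally sized")

    grand = df[dv].mean()
    levels = {f: df[f].nunique() for f in factors}
    n_subjects = df[subject].nunique()

    # Crossed-effect SS by inclusion-exclusion over marginal SS.
    effect_ss: dict[frozenset, float] = {}
    effect_df: dict[frozenset, int] = {}
    for k in range(1, len(factors) + 1):
        for combo in combinations(factors, k):
            key = frozenset(combo)
            ss = _margin_ss(df, dv, list(combo), grand)
            for j in range(1, k):
                for sub in combinations(combo, j):
                    ss -= effect_ss[frozenset(sub)]
            effect_ss[key] = ss
            effect_df[key] = int(np.prod([levels[f] - 1 for f in combo]))

    # Error strata.
    ss_subj = _margin_ss(df, dv, [subject], grand)
    if between:
        a = levels[between]
        err_between_ss = ss_subj - effect_ss[frozenset([between])]
        err_between_df = n_subjects - a
    else:
        err_between_ss = ss_subj
        err_between_df = n_subjects - 1

    err_ss: dict[frozenset, float] = {}
    err_df: dict[frozenset, int] = {}
    for k in range(1, len(within) + 1):
        for combo in combinations(within, k):
            v = frozenset(combo)
            ss = _margin_ss(df, dv, list(combo) + [subject], grand) - ss_subj
            for j in range(1, k + 1):
                for sub in combinations(combo, j):
                    u = frozenset(sub)
                    ss -= effect_ss[u]
                    if between:
                        ss -= effect_ss[u | {between}]
                    if u != v:
                        ss -= err_ss[u]
            err_ss[v] = max(ss, 0.0)
            err_df[v] = int(np.prod([levels[f] - 1 for f in combo])
                            * err_between_df)

    rows = []
    for key in sorted(effect_ss, key=lambda s: (len(s), sorted(s))):
        wpart = key - ({between} if between else set())
        if wpart:
            e_ss, e_df = err_ss[frozenset(wpart)], err_df[frozenset(wpart)]
        else:
            e_ss, e_df = err_between_ss, err_between_df
        ms = effect_ss[key] / effect_df[key] if effect_df[key] else np.nan
        mse = e_ss / e_df if e_df else np.nan
        f_val = ms / mse if mse and mse > 0 else (0.0 if effect_ss[key] == 0
                                                  else np.nan)
        p = float(sps.f.sf(f_val, effect_df[key], e_df)) if np.isfinite(f_val) \
            else float("nan")
        rows.append({"effect": " x ".join(sorted(key, key=factors.index)),
                     "ss": effect_ss[key], "df_num": effect_df[key],
                     "ss_err": e_ss, "df_den": e_df,
                     "F": float(f_val), "p": p})
    return pd.DataFrame(rows)


def posthoc_pairwise(long_table: pd.DataFrame, dv: str, effect: list[str],
                     subject: str = "subject", between: str | None = None,
                     correction: str = "bonferroni") -> pd.DataFrame:
    """Pairwise comparisons exploring a significant effect.

    Levels of the first factor in ``effect`` are compared pairwise within
    every combination of the remaining effect factors, with paired t-tests
    for within-subject factors and two-sample t-tests for a between-subject
    factor.  Bonferroni adjustment multiplies each p by the family size —
    the number of cells in the effect crossing (e.g. 3 datasets x 7 RSNs x
    5 bands = 105) — capped at 1.
    """
    for f in effect:
        if f not in long_table.columns:
            raise ValueError(f"unknown effect factor {f!r}")
    if correction != "bonferroni":
        raise ValueError("only Bonferroni correction is supported")
    family = int(np.prod([long_table[f].nunique() for f in effect]))
    compare, rest = effect[0], effect[1:]
    cell_means = (long_table.groupby([subject] + effect, observed=True)[dv]
                  .mean().reset_index())
    paired = compare != between
    rows = []
    groups = cell_means.groupby(rest, observed=True) if rest \
        else [((), cell_means)]
    for ctx, g in groups:
        ctx = ctx if isinstance(ctx, tuple) else (ctx,)
        lv = sorted(g[compare].unique())
        for a, b in combinations(lv, 2):
            ga = g[g[compare] == a].set_index(subject)[dv]
            gb = g[g[compare] == b].set_index(subject)[dv]
            if paired:
                common = ga.index.intersection(gb.index)
                t, p = sps.ttest_rel(ga.loc[common], gb.loc[common])
            else:
                t, p = sps.ttest_ind(ga, gb)
            rows.append({**dict(zip(rest, ctx)), "level_a": a, "level_b": b,
                         "t": float(t), "p_raw": float(p),
                         "p_adjusted": float(min(1.0, p * family)),
                         "family_size": family})
    return pd.DataFrame(rows)


def consistency_report(avg_correlations: pd.DataFrame,
                       dataset_of: dict | None = None,
                       q: float = 0.05) -> pd.DataFrame:
    """Full consistency table: t-tests with FDR per analysis family.

    ``avg_correlations`` holds one spatially averaged r per (subject, space,
    rsn, band, delay); ``dataset_of`` maps subject to dataset.  For every
    dataset (and the grand all-subject group) and every space present, each
    (rsn, band, delay) cell is tested against zero; Benjamini-Hochberg runs
    within each (group, space) family.  Groups need >= 2 subjects.
    """
    avg = avg_correlations.copy()
    if dataset_of is None:
        dataset_of = {s: "all" for s in avg["subject"].unique()}
    avg["dataset"] = avg["subject"].map(dataset_of)
    groups = [(d, g) for d, g in avg.groupby("dataset")]
    if len(groups) > 1:
        groups.append(("grand", avg))
    tables = []
    for gname, g in groups:
        if g["subject"].nunique() < 2:
            raise ValueError(f"group {gname!r} has fewer than 2 subjects")
        for space, gs in g.groupby("space"):
            rows = []
            for (rsn, band, delay), cell in gs.groupby(["rsn", "band", "delay"]):
                vals = cell["r"].to_numpy(dtype=float)
                vals = vals[np.isfinite(vals)]
                if len(vals) < 2:
                    continue
                t, p, _ = one_sample_t(vals)
                try:
                    w, wp = shapiro_wilk(vals)
                except ValueError:
                    w, wp = float("nan"), float("nan")
                rows.append({"group": gname, "space": space, "rsn": rsn,
                             "band": band, "delay": delay, "n": len(vals),
                             "mean_r": float(vals.mean()), "t": t, "p": p,
                             "shapiro_W": w, "shapiro_p": wp,
                             "uncorrected_significant": bool(p < q)})
            if not rows:
                continue
            tab = pd.DataFrame(rows)
            flags, thresh = fdr_correct(tab["p"].to_numpy(), q=q)
            tab["fdr_significant"] = flags
            tab["p_threshold_family"] = thresh
            tables.append(tab)
    if not tables:
        raise ValueError("no testable cells in the input table")
    return pd.concat(tables, ignore_index=True)
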