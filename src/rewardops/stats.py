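"""Group-level inference for the behavioural and photometry tables.

Reproduces the classical analysis chain: boxplot-rule outlier screening,
Shapiro-Wilk / Levene assumption checks (advisory only), mixed-design ANOVA
with one between-subjects factor (group) and one or two within-subjects
factors (test day, time interval), Tukey-Kramer studentized-range post-hocs,
and the two-step planned-contrast rule that pools two control groups when
they do not differ.

The ANOVA uses the classical univariate sums-of-squares decomposition:
between effects are tested against subjects-within-groups, within effects
against their subject x factor interaction strata.  Subjects missing any
within cell are dropped listwise for that analysis and reported.  No
sphericity correction is applied by default (Greenhouse-Geisser is
available as an option); significance is two-sided at 0.05.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaSpec",
    "screen_outliers",
    "check_assumptions",
    "mixed_anova",
    "tukey_posthoc",
    "sidak_adjust",
    "planned_contrast_pooling",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass
class AnovaSpec:
    """Design declaration for :func:`mixed_anova`."""

    dv: str
    subject: str
    between: str
    within: tuple[str, ...]

    def __post_init__(self) -> None:
        if isinstance(self.within, str):
            self.within = (self.within,)
        if not 1 <= len(self.within) <= 2:
            raise ValueError("mixed_anova supports one or two within factors")


def screen_outliers(values: pd.Series | np.ndarray, groups=None) -> np.ndarray:
    """Boxplot-rule outlier flags: outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Applied per group when ``groups`` is given.  Groups with fewer than 4
    values are not screened (flagged False) and a warning is logged.
    Flagged values are removed before inference by callers and reported in
    QC output.
    """
    v = np.asarray(values, dtype=float)
    if groups is None:
        groups = np.zeros(v.size)
    groups = np.asarray(groups)
    flags = np.zeros(v.size, dtype=bool)
    for g in pd.unique(groups):
        m = groups == g
        if m.sum() < 4:
            logger.warning("group %r has < 4 values; outlier screening skipped", g)
            continue
        q1, q3 = np.percentile(v[m], [25, 75])
        iqr = q3 - q1
        flags[m] = (v[m] < q1 - 1.5 * iqr) | (v[m] > q3 + 1.5 * iqr)
    return flags


def check_assumptions(values, groups) -> dict:
    """Advisory normality (Shapiro-Wilk per group) and variance-homogeneity
    (Levene) report; the pipeline proceeds regardless and retains it."""
    v = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    report: dict = {"shapiro": {}, "levene": None, "degenerate": False}
    samples = []
    for g in pd.unique(groups):
        x = v[groups == g]
        samples.append(x)
        if x.size < 3 or np.ptp(x) == 0:
            report["shapiro"][g] = {"W": np.nan, "p": np.nan, "degenerate": True}
            report["degenerate"] = True
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w, p = sps.shapiro(x)
        report["shapiro"][g] = {"W": float(w), "p": float(p), "degenerate": False}
    if len(samples) >= 2 and all(s.size >= 2 for s in samples) and not report["degenerate"]:
        stat, p = sps.levene(*samples, center="median")
        report["levene"] = {"W": float(stat), "p": float(p)}
    return report


def _component_ss(y, g_codes, n_g):
    """Classical mixed-design decomposition of y[subject, a, b].

    Returns dict of (SS, df) per effect plus error strata.  All subjects
    carry equal weight (complete within cells); group sums are weighted by
    group size, the conventional weighted-means solution for unequal n.
    """
    S, KA, KB = y.shape
    n_groups = len(n_g)
    GM = y.mean()
    m_s = y.mean(axis=(1, 2))  # subject means
    G_mean = np.array([m_s[g_codes == g].mean() for g in range(n_groups)])
    ya = y.mean(axis=(0, 2))
    yb = y.mean(axis=(0, 1))
    yab = y.mean(axis=0)
    yga = np.stack([y[g_codes == g].mean(axis=(0, 2)) for g in range(n_groups)])
    ygb = np.stack([y[g_codes == g].mean(axis=(0, 1)) for g in range(n_groups)])
    ygab = np.stack([y[g_codes == g].mean(axis=0) for g in range(n_groups)])
    ysa = y.mean(axis=2)
    ysb = y.mean(axis=1)

    eff_G = G_mean - GM
    eff_S = m_s - G_mean[g_codes]
    eff_A = ya - GM
    eff_B = yb - GM
    eff_GA = yga - G_mean[:, None] - ya[None, :] + GM
    eff_GB = ygb - G_mean[:, None] - yb[None, :] + GM
    eff_AB = yab - ya[:, None] - yb[None, :] + GM
    eff_GAB = (
        ygab
        - yga[:, :, None]
        - ygb[:, None, :]
        - yab[None, :, :]
        + G_mean[:, None, None]
        + ya[None, :, None]
        + yb[None, None, :]
        - GM
    )
    eff_SA = ysa - m_s[:, None] - yga[g_codes] + G_mean[g_codes, None]
    eff_SB = ysb - m_s[:, None] - ygb[g_codes] + G_mean[g_codes, None]
    fitted = (
        GM
        + eff_G[g_codes][:, None, None]
        + eff_S[:, None, None]
        + eff_A[None, :, None]
        + eff_B[None, None, :]
        + eff_GA[g_codes][:, :, None]
        + eff_GB[g_codes][:, None, :]
        + eff_AB[None, :, :]
        + eff_GAB[g_codes]
        + eff_SA[:, :, None]
        + eff_SB[:, None, :]
    )
    resid = y - fitted

    n_g = np.asarray(n_g, dtype=float)
    out = {
        "group": (KA * KB * float(np.sum(n_g * eff_G**2)), n_groups - 1),
        "subjects": (KA * KB * float(np.sum(eff_S**2)), S - n_groups),
        "A": (S * KB * float(np.sum(eff_A**2)), KA - 1),
        "group:A": (
            KB * float(np.sum(n_g[:, None] * eff_GA**2)),
            (n_groups - 1) * (KA - 1),
        ),
        "subjects:A": (KB * float(np.sum(eff_SA**2)), (S - n_groups) * (KA - 1)),
    }
    if KB > 1:
        out.update(
            {
                "B": (S * KA * float(np.sum(eff_B**2)), KB - 1),
                "group:B": (
                    KA * float(np.sum(n_g[:, None] * eff_GB**2)),
                    (n_groups - 1) * (KB - 1),
                ),
                "subjects:B": (
                    KA * float(np.sum(eff_SB**2)),
                    (S - n_groups) * (KB - 1),
                ),
                "A:B": (S * float(np.sum(eff_AB**2)), (KA - 1) * (KB - 1)),
                "group:A:B": (
                    float(np.sum(n_g[:, None, None] * eff_GAB**2)),
                    (n_groups - 1) * (KA - 1) * (KB - 1),
                ),
                "subjects:A:B": (
                    float(np.sum(resid**2)),
                    (S - n_groups) * (KA - 1) * (KB - 1),
                ),
            }
        )
    return out


def mixed_anova(data: pd.DataFrame, spec: AnovaSpec) -> pd.DataFrame:
    """Classical mixed-design ANOVA table.

    ``data`` is tidy (one row per subject x within-cell; replicates within a
    cell are averaged).  Subjects with missing within cells are dropped
    listwise; the count is attached as ``result.attrs['n_dropped']``.
    Effects named after the design columns; each row carries SS, df, MS, F,
    p and the error stratum used.  A constant dv yields F = 0 rows flagged
    degenerate.
    """
    wf = list(spec.within)
    for col in [spec.dv, spec.subject, spec.between, *wf]:
        if col not in data.columns:
            raise ValueError(f"column {col!r} missing from data")
    for f in [spec.between, *wf]:
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least 2 levels")

    piv = data.pivot_table(
        index=spec.subject, columns=wf, values=spec.dv, aggfunc="mean", dropna=False
    )
    complete = piv.dropna()
    n_dropped = piv.shape[0] - complete.shape[0]
    if complete.shape[0] < 3:
        raise ValueError("fewer than 3 subjects with complete within cells")
    subj_group = data.groupby(spec.subject, sort=False)[spec.between].first()
    groups = subj_group.loc[complete.index]
    glabels = pd.unique(groups)
    g_codes = pd.Categorical(groups, categories=glabels).codes.astype(int)
    n_g = np.bincount(g_codes, minlength=len(glabels))
    if (n_g < 2).any():
        raise ValueError("every group needs >= 2 complete subjects")

    if len(wf) == 1:
        KA = complete.shape[1]
        y = complete.to_numpy(float).reshape(-1, KA, 1)
        level_names = {"A": wf[0]}
    else:
        lv_a = piv.columns.get_level_values(0).unique()
        lv_b = piv.columns.get_level_values(1).unique()
        # reorder columns into the full a x b grid
        cols = pd.MultiIndex.from_product([lv_a, lv_b])
        complete = complete.reindex(columns=cols)
        if complete.isna().any().any():
            raise ValueError("within factors are not fully crossed")
        y = complete.to_numpy(float).reshape(-1, len(lv_a), len(lv_b))
        level_names = {"A": wf[0], "B": wf[1]}

    comp = _component_ss(y, g_codes, n_g)

    def name(key: str) -> str:
        parts = [level_names.get(p, p) for p in key.split(":")]
        return ":".join(parts).replace("group", spec.between)

    error_of = {
        "group": "subjects",
        "A": "subjects:A",
        "group:A": "subjects:A",
        "B": "subjects:B",
        "group:B": "subjects:B",
        "A:B": "subjects:A:B",
        "group:A:B": "subjects:A:B",
    }
    rows = []
    degenerate = float(np.ptp(y)) == 0.0
    for key, (ss, df) in comp.items():
        if key.startswith("subjects"):
            continue
        err_key = error_of[key]
        ss_e, df_e = comp[err_key]
        ms = ss / df if df else np.nan
        ms_e = ss_e / df_e if df_e else np.nan
        if degenerate or ms_e == 0 or not np.isfinite(ms_e):
            F, p = 0.0, np.nan
        else:
            F = ms / ms_e
            p = float(sps.f.sf(F, df, df_e))
        rows.append(
            {
                "effect": name(key),
                "SS": ss,
                "df1": df,
                "df2": df_e,
                "MS": ms,
                "MS_error": ms_e,
                "F": F,
                "p": p,
                "error_term": name(err_key),
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["n_dropped"] = int(n_dropped)
    table.attrs["n_subjects"] = int(y.shape[0])
    table.attrs["group_sizes"] = {str(l): int(n) for l, n in zip(glabels, n_g)}
    table.attrs["degenerate"] = bool(degenerate)
    return table


def tukey_posthoc(
    means: dict, ns: dict, ms_error: float, df_error: float
) -> pd.DataFrame:
    """Tukey-Kramer all-pairs comparisons from cell means and an ANOVA
    error term; adjusted p from the studentized-range distribution."""
    labels = list(means)
    k = len(labels)
    rows = []
    for a, b in itertools.combinations(labels, 2):
        diff = means[a] - means[b]
        se = np.sqrt(ms_error / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
        if se == 0:
            q, p = np.inf if diff else 0.0, 0.0 if diff else 1.0
        else:
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, df_error))
        rows.append(
            {"A": a, "B": b, "diff": diff, "q": q, "p_adj": min(p, 1.0),
             "method": "tukey-kramer"}
        )
    return pd.DataFrame(rows)


def sidak_adjust(pvals) -> np.ndarray:
    """Sidak family-wise adjustment for small planned families."""
    p = np.asarray(pvals, dtype=float)
    return 1.0 - (1.0 - p) ** p.size


@dataclass
class ContrastReport:
    """Two-step planned-contrast report for control pooling."""

    control_vs_control: dict
    pooled: bool
    final: list[dict] = field(default_factory=list)


def planned_contrast_pooling(
    values, groups, control_labels: tuple[str, str], experimental_label: str
) -> ContrastReport:
    """Two-step planned contrasts for designs with two control groups.

    Step 1 compares the two control groups (pooled-variance t test).  If
    they do not differ at 0.05 they are combined and a single pooled-control
    vs experimental contrast is run; otherwise pooling is refused and the
    experimental group is contrasted against each control separately.
    """
    v = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    missing = {*control_labels, experimental_label} - set(groups)
    if missing:
        raise ValueError(f"groups missing from data: {sorted(missing)}")
    ca, cb = (v[groups == lab] for lab in control_labels)
    ex = v[groups == experimental_label]
    t, p = sps.ttest_ind(ca, cb)
    step1 = {
        "comparison": f"{control_labels[0]} vs {control_labels[1]}",
        "t": float(t), "p": float(p),
    }
    final = []
    pooled = p > ALPHA
    if pooled:
        t2, p2 = sps.ttest_ind(np.concatenate([ca, cb]), ex)
        final.append(
            {"comparison": f"pooled-control vs {experimental_label}",
             "t": float(t2), "p": float(p2)}
        )
    else:
        for lab, arr in zip(control_labels, (ca, cb)):
            t2, p2 = sps.ttest_ind(arr, ex)
            final.append(
                {"comparison": f"{lab} vs {experimental_label}",
                 "t": float(t2), "p": float(p2)}
            )
    return ContrastReport(control_vs_control=step1, pooled=pooled, final=final)
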