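"""Repeated-measures ANOVA, Greenhouse-Geisser correction, Bonferroni
post-hocs, behavioural outlier trimming and the correlation screen that
decides which touch covariates enter the GLM.

The two-way within-subject ANOVA is computed from cell means by the standard
sums-of-squares decomposition (each effect tested against its interaction
with subjects).  The Greenhouse-Geisser epsilon is computed per effect from
the covariance of orthonormal within-subject contrasts,
epsilon = tr(S)^2 / (r * tr(S^2)), bounded by 1/r and 1 (r = effect df);
epsilon is reported always and the corrected degrees of freedom are applied
when Mauchly's sphericity test rejects at .05 (or always, on request).
Effect size is partial eta squared, SS_effect / (SS_effect + SS_error).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats


class StatsError(ValueError):
    """Labelled error from the behavioural statistics stage."""


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (Helmert, normalised)."""
    c = np.zeros((k - 1, k))
    for i in range(k - 1):
        c[i, : i + 1] = 1.0
        c[i, i + 1] = -(i + 1.0)
        c[i] /= np.linalg.norm(c[i])
    return c


def _gg_epsilon(D: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from subject scores on orthonormal
    contrasts (n x r)."""
    r = D.shape[1]
    if r <= 1:
        return 1.0
    S = np.cov(D, rowvar=False)
    eps = np.trace(S) ** 2 / (r * np.trace(S @ S))
    return float(np.clip(eps, 1.0 / r, 1.0))


def _mauchly_p(D: np.ndarray) -> float:
    """Mauchly's sphericity test on contrast scores (n x r); p = 1 when the
    test is undefined (r = 1 or too few subjects)."""
    n, r = D.shape
    if r <= 1 or n <= r:
        return 1.0
    S = np.cov(D, rowvar=False)
    eig = np.linalg.eigvalsh(S)
    if np.any(eig <= 0):
        return 0.0
    W = np.prod(eig) / (eig.mean() ** r)
    d = n - 1
    f = 1.0 - (2 * r**2 + r + 2) / (6.0 * r * d)
    chi2 = -d * f * np.log(W)
    dof = r * (r + 1) // 2 - 1
    return float(sp_stats.chi2.sf(chi2, dof))


@dataclass
class AnovaEffect:
    effect: str
    F: float
    df1: float
    df2: float
    p: float
    np2: float
    eps: float
    mauchly_p: float
    sphericity_applied: bool
    df1_corr: float
    df2_corr: float
    p_corr: float


def rm_anova(
    table: pd.DataFrame,
    dv: str,
    within: list[str],
    subject: str = "subject",
    *,
    gg: str = "auto",
    on_unbalanced: str = "error",
) -> pd.DataFrame:
    """Two-way (or one-way) fully within-subject ANOVA on a long table.

    The table is aggregated to cell means per subject first; the design must
    be balanced (every subject contributes every cell).  ``gg`` controls the
    sphericity correction: ``"auto"`` applies Greenhouse-Geisser corrected
    dfs when Mauchly's test rejects at .05, ``"always"`` applies it whenever
    the effect has more than one df, ``"never"`` reports epsilon only.
    ``on_unbalanced='listwise'`` drops subjects with incomplete cells
    instead of raising.

    Returns one row per effect (main effects and, for two factors, their
    interaction) with F, dfs, p, partial eta squared, epsilon, Mauchly p and
    the corrected df/p.
    """
    if len(within) not in (1, 2):
        raise StatsError("within must list one or two factors")
    if gg not in ("auto", "always", "never"):
        raise StatsError("gg must be 'auto', 'always' or 'never'")
    cell = table.groupby([subject] + within, observed=True)[dv].mean().reset_index()
    levels = [sorted(cell[f].unique()) for f in within]
    subjects = sorted(cell[subject].unique())
    n = len(subjects)
    if n < 3:
        raise StatsError("repeated-measures ANOVA needs >= 3 subjects")
    shape = (n,) + tuple(len(lv) for lv in levels)
    Y = np.full(shape, np.nan)
    sidx = {s: i for i, s in enumerate(subjects)}
    lidx = [{lv: i for i, lv in enumerate(lvs)} for lvs in levels]
    for _, row in cell.iterrows():
        key = (sidx[row[subject]],) + tuple(lidx[i][row[f]] for i, f in enumerate(within))
        Y[key] = row[dv]
    if np.isnan(Y).any():
        if on_unbalanced == "listwise":
            complete = ~np.isnan(Y.reshape(n, -1)).any(axis=1)
            Y = Y[complete]
            n = int(complete.sum())
            if n < 3:
                raise StatsError("fewer than 3 subjects with complete cells")
        else:
            bad = [
                (subjects[i],) + tuple(levels[d][k] for d, k in enumerate(idx))
                for i, *idx in np.argwhere(np.isnan(Y))
            ]
            raise StatsError(f"unbalanced design; empty subject-cell combinations: {bad[:10]}")

    if len(within) == 1:
        Y = Y[..., None]  # fake second factor with one level
        factors = within + ["_one"]
        levels = levels + [[0]]
    else:
        factors = list(within)

    a, b = Y.shape[1], Y.shape[2]
    grand = Y.mean()
    m_s = Y.mean(axis=(1, 2))
    m_a = Y.mean(axis=(0, 2))
    m_b = Y.mean(axis=(0, 1))
    m_sa = Y.mean(axis=2)
    m_sb = Y.mean(axis=1)
    m_ab = Y.mean(axis=0)

    ss_a = n * b * ((m_a - grand) ** 2).sum()
    ss_b = n * a * ((m_b - grand) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
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

    Ca = _orthonormal_contrasts(a) if a > 1 else np.zeros((0, a))
    Cb = _orthonormal_contrasts(b) if b > 1 else np.zeros((0, b))
    ones_a = np.ones((1, a)) / np.sqrt(a)
    ones_b = np.ones((1, b)) / np.sqrt(b)
    flat = Y.reshape(n, a * b)

    effects = []
    specs = [
        (factors[0], ss_a, a - 1, ss_as, (a - 1) * (n - 1), np.kron(Ca, ones_b)),
        (factors[1], ss_b, b - 1, ss_bs, (b - 1) * (n - 1), np.kron(ones_a, Cb)),
        (f"{factors[0]}*{factors[1]}", ss_ab, (a - 1) * (b - 1), ss_abs,
         (a - 1) * (b - 1) * (n - 1), np.kron(Ca, Cb)),
    ]
    for name, ss_eff, df1, ss_err, df2, M in specs:
        if df1 == 0:
            continue
        F = (ss_eff / df1) / (ss_err / df2)
        D = flat @ M.T
        eps = _gg_epsilon(D)
        mau = _mauchly_p(D)
        apply_corr = (gg == "always" and df1 > 1) or (gg == "auto" and df1 > 1 and mau < 0.05)
        d1c, d2c = (df1 * eps, df2 * eps) if apply_corr else (float(df1), float(df2))
        effects.append(
            AnovaEffect(
                effect=name,
                F=float(F),
                df1=float(df1),
                df2=float(df2),
                p=float(sp_stats.f.sf(F, df1, df2)),
                np2=float(ss_eff / (ss_eff + ss_err)),
                eps=eps,
                mauchly_p=mau,
                sphericity_applied=bool(apply_corr),
                df1_corr=float(d1c),
                df2_corr=float(d2c),
                p_corr=float(sp_stats.f.sf(F, d1c, d2c)),
            )
        )
    return pd.DataFrame([vars(e) for e in effects])


def posthoc_pairwise(
    table: pd.DataFrame,
    dv: str,
    effect: str,
    subject: str = "subject",
    *,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Paired t-tests between all level pairs of ``effect`` on subject-level
    means, Bonferroni-adjusted (p_adj = min(1, p * m))."""
    means = table.groupby([subject, effect], observed=True)[dv].mean().unstack(effect)
    lvls = list(means.columns)
    pairs = list(itertools.combinations(lvls, 2))
    m = len(pairs)
    rows = []
    for x, y in pairs:
        d = means[x] - means[y]
        t, p = sp_stats.ttest_rel(means[x], means[y])
        p_adj = min(1.0, p * m) if correction == "bonferroni" else p
        rows.append(
            {
                "level_a": x,
                "level_b": y,
                "mean_diff": float(d.mean()),
                "t": float(t),
                "df": len(d) - 1,
                "p": float(p),
                "p_adj": float(p_adj),
            }
        )
    return pd.DataFrame(rows)


def outlier_trim(
    table: pd.DataFrame,
    value: str,
    group: list[str],
    *,
    z_limit: float = 2.0,
) -> pd.DataFrame:
    """Drop values with |z| strictly greater than ``z_limit`` within each
    group (single pass, sample SD); groups with < 3 values or zero SD pass
    through unchanged."""

    def _keep(g: pd.DataFrame) -> pd.DataFrame:
        v = g[value].to_numpy(dtype=float)
        if len(v) < 3:
            return g
        sd = v.std(ddof=1)
        if sd == 0:
            return g
        z = (v - v.mean()) / sd
        return g[np.abs(z) <= z_limit]

    out = (
        table.groupby(group, group_keys=False, observed=True)[table.columns]
        .apply(_keep)
        .reset_index(drop=True)
    )
    return out


def correlation_screen(
    touch_means: pd.DataFrame,
    anova_tables: dict[str, pd.DataFrame] | None = None,
    *,
    alpha: float = 0.05,
    behaviours: tuple[str, ...] = ("median_speed", "median_friction", "median_load"),
) -> dict:
    """Decide the covariate plan from per-subject touch-behaviour means.

    ``touch_means`` needs one row per subject x texture with the behaviour
    columns.  Pearson correlations are computed per texture between every
    behaviour pair; pairs significant (p < alpha) in *both* textures are
    marked "combine by summation".  Behaviours whose repeated-measures ANOVA
    (``anova_tables[behaviour]``) shows no significant texture or estimation
    effect are marked "exclude".  Returns the plan consumed by
    ``glm.build_design``: ``{"combine": [...], "exclude": [...],
    "covariates": [...], "correlations": {...}}``.
    """
    textures = sorted(touch_means["texture"].unique())
    n_sub = touch_means.groupby("texture")["subject"].nunique().min()
    if n_sub < 3:
        raise StatsError("correlation screen needs >= 3 subjects")
    correlations: dict[str, dict[str, float]] = {}
    combine: set[str] = set()
    for x, y in itertools.combinations(behaviours, 2):
        sig_all = True
        for tex in textures:
            sub = touch_means[touch_means["texture"] == tex].sort_values("subject")
            r, p = sp_stats.pearsonr(sub[x], sub[y])
            correlations[f"{x}~{y}|{tex}"] = {"r": float(r), "p": float(p)}
            if not (p < alpha):
                sig_all = False
        if sig_all:
            combine.update((x, y))

    exclude: list[str] = []
    if anova_tables:
        for beh, tab in anova_tables.items():
            if not (tab["p_corr"] < alpha).any():
                exclude.append(beh)
    covariates = [b for b in behaviours if b in combine and b not in exclude]
    return {
        "combine": sorted(combine),
        "exclude": sorted(exclude),
        "covariates": covariates,
        "correlations": correlations,
        "alpha": alpha,
    }
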