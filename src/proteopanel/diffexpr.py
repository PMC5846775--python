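"""Moderated differential abundance across the three clinical groups.

Each protein is fit by ordinary least squares on a one-way group design
(HC / IBS / UC), giving group means, a residual variance s_g^2 and residual
degrees of freedom d_g = n - 3.  With only ~7 samples per group the
per-protein variances are noisy, so they are shrunk towards a common prior
by empirical Bayes: assuming s_g^2 | sigma_g^2 ~ sigma_g^2 * chi^2_{d_g}/d_g
and a scaled inverse-chi-square prior sigma_g^2 ~ s0^2 d0 / chi^2_{d0}, the
posterior variance is

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and moderated t / F statistics use s~_g^2 with d_g + d0 degrees of freedom.
The hyperparameters (d0, s0^2) are estimated by moment-matching the
marginal distribution of log s_g^2 (trigamma inversion).

Pairwise contrasts are reported as log10 ratios (positive = higher in the
first-named group, e.g. IBS vs HC).  The overall 3-group effect is the
2-df moderated F; Benjamini-Hochberg adjustment of its p-values drives the
differential-protein selection, while pairwise p-values are reported
unadjusted, as in printed protease tables.  Each significant protein gets a
pattern-class label summarizing which comparisons moved and in which
direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import GROUPS, NormalizedMatrix, ValidationError

CONTRASTS = (("IBS", "HC"), ("UC", "HC"), ("IBS", "UC"))

PATTERN_CLASSES = (
    "up-IBS-vs-both",
    "up-IBS-vs-HC-and-UC-vs-HC",
    "up-IBS-vs-HC-only",
    "up-IBS-vs-UC-only",
    "down-IBS-vs-HC",
    "down-IBS-vs-HC-and-UC",
    "down-IBS-vs-UC-only",
    "other",
)


@dataclass
class GroupFit:
    """Per-protein OLS fit on the one-way group design (log10 scale)."""

    means: pd.DataFrame  # proteins x groups
    s2: pd.Series  # pooled residual variance per protein
    df_residual: int
    group_sizes: dict[str, int]


@dataclass
class ModeratedFit:
    """Group fit plus empirical-Bayes moderation."""

    fit: GroupFit
    d0: float
    s0_2: float
    s2_moderated: pd.Series


def fit_group_model(nm: NormalizedMatrix | pd.DataFrame, groups: pd.Series | None = None) -> GroupFit:
    """OLS group means and pooled residual variance per protein.

    Works on the log10-rescaled glog values so downstream contrasts read
    directly as log10 ratios.
    """
    if isinstance(nm, NormalizedMatrix):
        values, groups = nm.log10_values, nm.groups
    else:
        if groups is None:
            raise ValidationError("groups required with a bare DataFrame")
        values = nm
    present = [g for g in GROUPS if (groups == g).sum() > 0]
    if len(present) < 2:
        raise ValidationError("need >= 2 groups")
    sizes = {g: int((groups == g).sum()) for g in present}
    if any(n < 2 for n in sizes.values()):
        raise ValidationError(f"every group needs >= 2 samples, got {sizes}")
    x = values.to_numpy(dtype=float)
    n = x.shape[1]
    k = len(present)
    means = {}
    rss = np.zeros(x.shape[0])
    for g in present:
        cols = (groups == g).to_numpy()
        xg = x[:, cols]
        mg = xg.mean(axis=1)
        means[g] = mg
        rss += ((xg - mg[:, None]) ** 2).sum(axis=1)
    df = n - k
    return GroupFit(
        means=pd.DataFrame(means, index=values.index),
        s2=pd.Series(rss / df, index=values.index),
        df_residual=df,
        group_sizes=sizes,
    )


def trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValidationError("trigamma inverse requires x > 0")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif / y) < tol:
            return float(y)
    raise ValidationError("trigamma inversion did not converge")


def ebayes_moderate(s2: pd.Series | np.ndarray, df: int, d0_cap: float = 1e6) -> tuple[float, float, pd.Series]:
    """Estimate (d0, s0^2) and return moderated variances.

    Moment-matching on z = log s^2: under the scaled-F marginal,
    E[z] = log s0^2 + psi(d/2) - log(d/2) - psi(d0/2) + log(d0/2) and
    Var[z] = psi'(d/2) + psi'(d0/2); the excess variance of z over
    psi'(d/2) is inverted through the trigamma function to get d0.
    Proteins with zero variance are excluded from the moment fit (their
    log variance is undefined) but still receive moderated values.
    """
    s2 = pd.Series(s2) if not isinstance(s2, pd.Series) else s2
    pos = s2[s2 > 0]
    if len(pos) == 0:
        raise ValidationError("all residual variances are zero")
    if len(pos) < 10:
        raise ValidationError("need >= 10 positive variances for stable hyperparameters")
    z = np.log(pos.to_numpy())
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    excess = e_var - special.polygamma(1, df / 2.0)
    if excess > 0:
        d0 = min(2.0 * trigamma_inverse(excess), d0_cap)
        s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # observed scatter at or below pure sampling noise: effectively an
        # infinite prior df; the prior variance is then the geometric mean,
        # so exactly-equal variances shrink to their common value
        d0 = d0_cap
        s0_2 = float(np.exp(np.mean(z)))
    s2_mod = (d0 * s0_2 + df * s2) / (d0 + df)
    return float(d0), s0_2, s2_mod


def moderate(fit: GroupFit, d0: float | None = None, s0_2: float | None = None) -> ModeratedFit:
    """Apply empirical-Bayes moderation to a group fit.

    Passing ``d0=0`` disables shrinkage (s~^2 = s^2), which reduces every
    downstream statistic to its classical ANOVA counterpart.
    """
    if d0 is None:
        d0, s0_2, s2_mod = ebayes_moderate(fit.s2, fit.df_residual)
    else:
        if d0 < 0:
            raise ValidationError("d0 must be >= 0")
        if d0 == 0:
            s0_2 = float("nan") if s0_2 is None else s0_2
            s2_mod = fit.s2.copy()
        else:
            if s0_2 is None:
                raise ValidationError("s0_2 required when d0 is imposed")
            s2_mod = (d0 * s0_2 + fit.df_residual * fit.s2) / (d0 + fit.df_residual)
    return ModeratedFit(fit=fit, d0=float(d0), s0_2=float(s0_2), s2_moderated=s2_mod)


def moderated_tests(mfit: ModeratedFit, alpha: float = 0.05) -> pd.DataFrame:
    """Moderated pairwise t tests and the overall moderated F.

    Returns a table with, per protein: one (log10 ratio, p) pair per
    contrast, the overall F with its p-value and BH-adjusted p-value, and
    the pattern-class label.
    """
    fit = mfit.fit
    s2m = mfit.s2_moderated.to_numpy()
    d_total = fit.df_residual + mfit.d0
    out = pd.DataFrame(index=fit.means.index)
    groups = list(fit.means.columns)
    for a_g, b_g in CONTRASTS:
        if a_g not in groups or b_g not in groups:
            continue
        est = fit.means[a_g] - fit.means[b_g]
        se = np.sqrt(s2m * (1.0 / fit.group_sizes[a_g] + 1.0 / fit.group_sizes[b_g]))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, est.to_numpy() / se, 0.0)
        p = 2.0 * stats.t.sf(np.abs(t), d_total)
        out[f"log10_ratio_{a_g}_vs_{b_g}"] = est
        out[f"p_{a_g}_vs_{b_g}"] = p
    # moderated F on the (k-1)-df group effect: between-group SS / ((k-1) s~^2)
    sizes = np.array([fit.group_sizes[g] for g in groups], dtype=float)
    gm = fit.means.to_numpy()
    grand = (gm * sizes).sum(axis=1) / sizes.sum()
    ss_between = ((gm - grand[:, None]) ** 2 * sizes).sum(axis=1)
    df_num = len(groups) - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = np.where(s2m > 0, ss_between / (df_num * s2m), np.inf)
    p_f = stats.f.sf(f_stat, df_num, d_total)
    out["F"] = f_stat
    out["p_F"] = p_f
    out["adj_p_F"] = bh_adjust(pd.Series(p_f, index=out.index))
    out["pattern"] = [classify_pattern(row, alpha=alpha) for _, row in out.iterrows()]
    return out


def bh_adjust(p: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        raise ValidationError("empty p-value vector")
    if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    adj = multipletests(arr, method="fdr_bh")[1]
    if isinstance(p, pd.Series):
        return pd.Series(adj, index=p.index)
    return adj


def select_differential(table: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Proteins whose BH-adjusted overall-F p-value is below alpha."""
    if "adj_p_F" not in table:
        raise ValidationError("table lacks adjusted overall-F p-values")
    return list(table.index[table["adj_p_F"] < alpha])


def classify_pattern(row, alpha: float = 0.05) -> str:
    """Assign the abundance-pattern class from contrast signs and p-values.

    ``row`` must expose log10_ratio_/p_ entries for IBS vs HC, UC vs HC and
    IBS vs UC.  Classes follow the standard reading of a three-group
    protease table: e.g. a protein significantly higher in IBS than in both
    HC and UC is "up-IBS-vs-both"; one higher in IBS and in UC versus HC
    (but IBS ~ UC) is "up-IBS-vs-HC-and-UC-vs-HC".
    """
    def sig(a_g, b_g):
        return row[f"p_{a_g}_vs_{b_g}"] < alpha

    def est(a_g, b_g):
        return row[f"log10_ratio_{a_g}_vs_{b_g}"]

    up_ih = sig("IBS", "HC") and est("IBS", "HC") > 0
    dn_ih = sig("IBS", "HC") and est("IBS", "HC") < 0
    up_uh = sig("UC", "HC") and est("UC", "HC") > 0
    up_iu = sig("IBS", "UC") and est("IBS", "UC") > 0
    dn_iu = sig("IBS", "UC") and est("IBS", "UC") < 0
    any_ih = sig("IBS", "HC")
    any_iu = sig("IBS", "UC")

    if up_ih and up_iu:
        return "up-IBS-vs-both"
    if up_ih and up_uh and not any_iu:
        return "up-IBS-vs-HC-and-UC-vs-HC"
    if up_ih and not up_uh and not any_iu:
        return "up-IBS-vs-HC-only"
    if up_iu and not any_ih:
        return "up-IBS-vs-UC-only"
    if dn_ih and dn_iu:
        return "down-IBS-vs-HC-and-UC"
    if dn_ih and not dn_iu:
        return "down-IBS-vs-HC"
    if dn_iu and not any_ih:
        return "down-IBS-vs-UC-only"
    return "other"


def differential_table(nm: NormalizedMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Full moderated analysis: fit, moderate, test, adjust, classify."""
    fit = fit_group_model(nm)
    mfit = moderate(fit)
    table = moderated_tests(mfit, alpha=alpha)
    table.insert(0, "is_protease", nm.protease.reindex(table.index))
    table.attrs["d0"] = mfit.d0
    table.attrs["s0_2"] = mfit.s0_2
    return table
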