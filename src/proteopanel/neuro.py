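"""Neuroindex statistics for enteric-neuron activation recordings.

The neuroindex summarizes one imaged ganglion's response to a biopsy
supernatant as (% responding neurons) x (mean spike frequency of the
responders, Hz); it is reported unitless and is 0 exactly when no neuron
responds.  The calcium-imaging analogue (Ca-neuroindex) multiplies the mean
peak dF/F of responders by the percentage of responders relative to the
nicotine-responsive cell count.

Group comparisons use the nonparametric battery standard in this setting:
Kruskal-Wallis across HC/IBS/UC with Dunn's all-pairwise post-hoc test and
Bonferroni adjustment, Wilcoxon signed-rank for paired (pre/post drug)
designs, and the Mann-Whitney rank-sum test for unpaired two-group
contrasts.  Protease abundance is related to antagonist-induced inhibition
by Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GanglionRecording, ValidationError


def neuroindex(rec: GanglionRecording) -> float:
    """(% responders among imaged neurons) x (mean responder spike rate)."""
    if rec.responders == 0:
        return 0.0
    pct = 100.0 * rec.responders / rec.neurons_total
    return pct * float(np.mean(rec.magnitudes))


def ca_neuroindex(rec: GanglionRecording) -> float:
    """(% responders among nicotine-responsive cells) x (mean peak dF/F)."""
    if rec.nicotine_responders is None:
        raise ValidationError("calcium mode requires nicotine_responders")
    if rec.responders == 0:
        return 0.0
    pct = 100.0 * rec.responders / rec.nicotine_responders
    return pct * float(np.mean(rec.magnitudes))


def patient_neuroindex(
    recordings: list[GanglionRecording],
    mode: str = "voltage",
    aggregate: str = "median",
) -> pd.DataFrame:
    """Per-patient aggregation of per-ganglion neuroindex values.

    One row per (patient, condition); the patient-level value is the median
    (default) or mean across that patient's ganglia.
    """
    fn = neuroindex if mode == "voltage" else ca_neuroindex
    rows = [
        {
            "patient_id": r.patient_id,
            "group": r.group,
            "condition": r.condition,
            "neuroindex": fn(r),
        }
        for r in recordings
    ]
    df = pd.DataFrame(rows)
    agg = {"median": "median", "mean": "mean"}[aggregate]
    return (
        df.groupby(["patient_id", "group", "condition"], as_index=False)["neuroindex"]
        .agg(agg)
    )


@dataclass
class GroupComparison:
    h_statistic: float
    p_value: float
    dunn: pd.DataFrame  # pair, z, p_raw, p_bonferroni


def group_compare(values_by_group: dict[str, np.ndarray]) -> GroupComparison:
    """Kruskal-Wallis across groups plus Dunn's pairwise z with Bonferroni.

    Dunn's z uses the tie-corrected rank variance
    sigma_ij^2 = (N(N+1)/12 - sum(t^3-t)/(12(N-1))) (1/n_i + 1/n_j);
    adjusted p = min(1, p * number of pairwise comparisons).
    """
    names = list(values_by_group)
    samples = [np.asarray(values_by_group[g], dtype=float) for g in names]
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise ValidationError("need >= 2 nonempty groups")
    h, p = stats.kruskal(*samples)

    pooled = np.concatenate(samples)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes, start = {}, {}, 0
    for g, s in zip(names, samples):
        mean_ranks[g] = ranks[start : start + len(s)].mean()
        sizes[g] = len(s)
        start += len(s)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = list(combinations(names, 2))
    rows = []
    for a, b in pairs:
        se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {
                "pair": f"{a} vs {b}",
                "z": z,
                "p_raw": p_raw,
                "p_bonferroni": min(1.0, p_raw * len(pairs)),
            }
        )
    return GroupComparison(
        h_statistic=float(h), p_value=float(p), dunn=pd.DataFrame(rows)
    )


@dataclass
class PairedComparison:
    statistic: float
    p_value: float
    n_effective: int
    degenerate: bool = False


def paired_compare(pre, post, exact_max_n: int = 25) -> PairedComparison:
    """Wilcoxon signed-rank test for paired pre/post values.

    Zero differences are dropped (Wilcoxon convention); if all differences
    are zero the result is flagged degenerate with p = 1.  The exact null
    distribution is used up to ``exact_max_n`` nonzero differences (when
    untied), the normal approximation with continuity correction above.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValidationError("paired vectors must have equal length")
    d = post - pre
    nz = d[d != 0]
    if len(nz) == 0:
        return PairedComparison(statistic=0.0, p_value=1.0, n_effective=0, degenerate=True)
    if len(nz) < 5:
        raise ValidationError("need >= 5 nonzero differences")
    method = "exact" if (len(nz) <= exact_max_n and len(np.unique(np.abs(nz))) == len(nz)) else "approx"
    res = stats.wilcoxon(
        pre, post, zero_method="wilcox", correction=(method == "approx"), method=method
    )
    return PairedComparison(
        statistic=float(res.statistic), p_value=float(res.pvalue), n_effective=len(nz)
    )


@dataclass
class UnpairedComparison:
    u_statistic: float
    p_value: float


def unpaired_compare(a, b, exact_max_n: int = 20) -> UnpairedComparison:
    """Mann-Whitney rank-sum test, two-sided.

    Exact null distribution for small untied samples, tie-corrected normal
    approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both samples must be nonempty")
    small = max(len(a), len(b)) <= exact_max_n
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (small and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return UnpairedComparison(u_statistic=float(res.statistic), p_value=float(res.pvalue))


def percent_inhibition(pre: float, post: float) -> float:
    """Percentage decrease of the neuroindex under an inhibitor.

    Negative when the response grew (noise); undefined for pre = 0.
    """
    if pre <= 0:
        raise ValidationError("pre-treatment neuroindex must be > 0")
    return 100.0 * (pre - post) / pre


def abundance_inhibition_correlation(abundance, pct_decrease) -> dict:
    """Pearson correlation of protease abundance with % neuroindex decrease.

    Returns r, the two-sided p from t = r sqrt((n-2)/(1-r^2)), and n.
    """
    x = np.asarray(abundance, dtype=float)
    y = np.asarray(pct_decrease, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValidationError("need >= 3 paired finite values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite values in correlation input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance in correlation input")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": int(len(x))}
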