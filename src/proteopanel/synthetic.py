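"""Synthetic mucosal-biopsy-supernatant data with known ground truth.

Two families of generators are provided:

* ``gen_proteome`` builds a raw label-free protein intensity matrix
  (proteins x samples, three clinical groups HC / IBS / UC) under the
  additive-multiplicative error model that glog normalization assumes:

      x = exp(eta) * mu + eps,   eta ~ N(0, sigma_mult),  eps ~ N(0, sigma_add)

  so that the raw standard deviation grows with the mean while the additive
  floor dominates at low intensity.  A configurable subset of proteins
  carries planted between-group shifts on the log10 scale, allocated across
  the seven abundance-pattern classes seen in differential protease tables
  (up in IBS vs both comparators, up in IBS and UC vs HC, ...).

* ``gen_ganglion_responses`` / ``gen_paired_inhibition`` emulate
  voltage-sensitive-dye recordings of submucous ganglia: per-ganglion neuron
  counts, Bernoulli responder calls and log-normal spike frequencies whose
  group medians match published supernatant responses (IBS ~ 81% responders
  at ~3.8 Hz), plus paired pre/post antagonist neuroindex values whose
  percentage inhibition is correlated with a planted protease abundance at a
  configurable Pearson r.

All generators are deterministic functions of their config seed; every
operation draws from its own child stream of the master seed so stages can
be re-run independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, GanglionRecording, ValidationError

# Per-class (HC, IBS, UC) mean-shift multipliers, in units of the planted
# log10 effect delta.  Weights mirror the 4/1/3/2/4/2/1 split of the 17
# differentially expressed proteases across pattern classes.
PATTERN_SHIFTS: dict[str, tuple[float, float, float]] = {
    "up-IBS-vs-both": (0.0, 1.0, 0.0),
    "up-IBS-vs-HC-and-UC-vs-HC": (0.0, 1.0, 1.0),
    "up-IBS-vs-HC-only": (0.0, 1.0, 0.5),
    "up-IBS-vs-UC-only": (0.0, 0.0, -1.0),
    "down-IBS-vs-HC": (0.0, -1.0, -0.5),
    "down-IBS-vs-HC-and-UC": (0.0, -1.0, 0.0),
    "down-IBS-vs-UC-only": (0.0, 0.0, 1.0),
}
PATTERN_WEIGHTS: dict[str, int] = {
    "up-IBS-vs-both": 4,
    "up-IBS-vs-HC-and-UC-vs-HC": 1,
    "up-IBS-vs-HC-only": 3,
    "up-IBS-vs-UC-only": 2,
    "down-IBS-vs-HC": 4,
    "down-IBS-vs-HC-and-UC": 2,
    "down-IBS-vs-UC-only": 1,
}


@dataclass
class SynthProteomeConfig:
    """Study conditions for the proteome generator.

    Defaults emulate a 1081-protein, 22-sample supernatant cohort with 204
    group-differential proteins at |log10 ratio| effects between 0.1 and
    1.6.  ``baseline_loc``/``baseline_scale`` place per-protein mean
    intensities on the log10 scale (median ~1e6 instrument units);
    ``mult_cv`` is the multiplicative coefficient of variation and
    ``additive_sd`` the intensity-independent noise floor (~1% of the median
    intensity).  ``dropout`` optionally censors low intensities; it is off
    by default.
    """

    n_proteins: int = 1081
    group_sizes: tuple[int, int, int] = (7, 8, 7)  # HC, IBS, UC
    n_differential: int = 204
    effect_log10: tuple[float, float] = (0.1, 1.6)
    mult_cv: float = 0.35
    additive_sd: float = 1.0e4
    baseline_loc: float = 6.0
    baseline_scale: float = 0.8
    n_protease: int = 40
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or any(n < 2 for n in self.group_sizes):
            raise ValidationError("need >=1 protein and >=2 samples per group")
        if not 0 <= self.n_differential <= self.n_proteins:
            raise ValidationError("n_differential must lie in [0, n_proteins]")
        lo, hi = self.effect_log10
        if not 0 <= lo <= hi:
            raise ValidationError("effect range must satisfy 0 <= lo <= hi")
        if self.mult_cv < 0 or self.additive_sd < 0:
            raise ValidationError("noise parameters must be >= 0")
        if self.mult_cv == 0 and self.additive_sd == 0 and self.n_differential > 0:
            pass  # noiseless planted effects are a legitimate degenerate case
        if self.baseline_scale <= 0:
            raise ValidationError("baseline_scale must be > 0")
        if not 0 <= self.dropout < 1:
            raise ValidationError("dropout must lie in [0, 1)")


@dataclass
class SynthNeuroConfig:
    """Study conditions for the neurophysiology generators.

    Responder probabilities and log-normal spike-frequency medians default
    to the published group profiles (IBS: 81% responders, median 3.8 Hz;
    UC: 80%, 3.3 Hz; HC: marginal activation).  ``target_r`` is the planted
    Pearson correlation between protease abundance and antagonist-induced
    percentage decrease of the neuroindex.
    """

    patients_per_group: dict[str, int] = field(
        default_factory=lambda: {"HC": 7, "IBS": 14, "UC": 12}
    )
    ganglia_per_patient: int = 2
    neurons_range: tuple[int, int] = (3, 15)
    responder_p: dict[str, float] = field(
        default_factory=lambda: {"HC": 0.10, "IBS": 0.81, "UC": 0.80}
    )
    freq_median_hz: dict[str, float] = field(
        default_factory=lambda: {"HC": 0.5, "IBS": 3.8, "UC": 3.3}
    )
    freq_log_sigma: float = 0.5
    dff_median: float = 0.5
    dff_log_sigma: float = 0.5
    target_r: float = -0.69
    inhibition_mean: float = 55.0
    inhibition_sd: float = 18.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.patients_per_group.values()):
            raise ValidationError("need >=1 patient per group")
        if self.ganglia_per_patient < 1:
            raise ValidationError("need >=1 ganglion per patient")
        lo, hi = self.neurons_range
        if lo < 1 or hi < lo:
            raise ValidationError("neurons_range must satisfy 1 <= lo <= hi")
        if any(not 0 <= p <= 1 for p in self.responder_p.values()):
            raise ValidationError("responder probabilities must lie in [0, 1]")
        if any(f < 0 for f in self.freq_median_hz.values()):
            raise ValidationError("spike frequencies must be >= 0")
        if not -1 <= self.target_r <= 1:
            raise ValidationError("target_r must lie in [-1, 1]")


@dataclass
class GroundTruth:
    """Planted signal: which proteins differ, how, and what correlates."""

    differential: pd.DataFrame  # index protein_id; columns shift_HC/IBS/UC (log10), pattern
    protease_panel: tuple[str, ...]
    target_r: float

    @property
    def differential_ids(self) -> tuple[str, ...]:
        return tuple(self.differential.index)


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def _allocate_patterns(n_differential: int) -> list[str]:
    """Largest-remainder allocation of differential proteins to pattern classes."""
    names = list(PATTERN_WEIGHTS)
    weights = np.array([PATTERN_WEIGHTS[c] for c in names], dtype=float)
    quota = n_differential * weights / weights.sum()
    counts = np.floor(quota).astype(int)
    rem = n_differential - counts.sum()
    for i in np.argsort(-(quota - counts))[:rem]:
        counts[i] += 1
    out: list[str] = []
    for name, c in zip(names, counts):
        out.extend([name] * c)
    return out


def gen_proteome(config: SynthProteomeConfig) -> tuple[AbundanceMatrix, GroundTruth]:
    """Generate a raw intensity matrix plus the planted ground truth.

    Differential proteins occupy the first ``n_differential`` row slots
    after a seeded shuffle of protein ids, so their identity depends only on
    the seed.  Raw values are floored at 1 instrument unit to keep the
    matrix strictly positive under the additive noise floor.
    """
    cfg = config
    groups = ("HC", "IBS", "UC")
    n_samples = sum(cfg.group_sizes)
    sample_ids = [
        f"{g}{i+1:02d}" for g, n in zip(groups, cfg.group_sizes) for i in range(n)
    ]
    group_of = np.repeat(groups, cfg.group_sizes)

    rng = _child_rng(cfg.seed, 1)
    protein_ids = np.array([f"P{i:05d}" for i in range(cfg.n_proteins)])
    order = rng.permutation(cfg.n_proteins)
    diff_idx = order[: cfg.n_differential]

    baseline = rng.normal(cfg.baseline_loc, cfg.baseline_scale, size=cfg.n_proteins)

    patterns = _allocate_patterns(cfg.n_differential)
    lo, hi = cfg.effect_log10
    deltas = rng.uniform(lo, hi, size=cfg.n_differential)

    # per-protein, per-group log10 shift
    shift = np.zeros((cfg.n_proteins, 3))
    for slot, (idx, pat, d) in enumerate(zip(diff_idx, patterns, deltas)):
        shift[idx] = d * np.array(PATTERN_SHIFTS[pat])

    group_pos = {g: j for j, g in enumerate(groups)}
    col_group = np.array([group_pos[g] for g in group_of])
    log10_mu = baseline[:, None] + shift[:, col_group]
    mu = 10.0 ** log10_mu

    sigma_mult = np.sqrt(np.log1p(cfg.mult_cv**2))
    eta = rng.normal(0.0, 1.0, size=mu.shape) * sigma_mult
    eps = rng.normal(0.0, 1.0, size=mu.shape) * cfg.additive_sd
    x = np.exp(eta) * mu + eps
    x = np.maximum(x, 1.0)

    if cfg.dropout > 0:
        # intensity-dependent censoring: lowest-intensity values most at risk
        ranks = pd.DataFrame(x).rank(axis=None).to_numpy() / x.size
        drop = rng.random(x.shape) < cfg.dropout * (1.0 - ranks)
        x = np.where(drop, 1.0, x)

    # protease annotation: half the flags on planted up-in-IBS proteins (the
    # candidate biomarkers), the rest on random non-differential proteins
    up_classes = {"up-IBS-vs-both", "up-IBS-vs-HC-and-UC-vs-HC", "up-IBS-vs-HC-only"}
    up_idx = [i for i, p in zip(diff_idx, patterns) if p in up_classes]
    n_panel = min(len(up_idx), max(1, cfg.n_protease // 2)) if cfg.n_differential else 0
    panel_idx = list(rng.choice(up_idx, size=n_panel, replace=False)) if n_panel else []
    non_diff = np.setdiff1d(np.arange(cfg.n_proteins), diff_idx)
    n_extra = min(len(non_diff), cfg.n_protease - n_panel)
    extra_idx = list(rng.choice(non_diff, size=n_extra, replace=False))
    protease = np.zeros(cfg.n_proteins, dtype=bool)
    protease[panel_idx + extra_idx] = True

    intensities = pd.DataFrame(x, index=protein_ids, columns=sample_ids)
    matrix = AbundanceMatrix(
        intensities=intensities,
        groups=pd.Series(group_of, index=sample_ids),
        protease=pd.Series(protease, index=protein_ids),
    )
    truth = GroundTruth(
        differential=pd.DataFrame(
            {
                "shift_HC": shift[diff_idx, 0],
                "shift_IBS": shift[diff_idx, 1],
                "shift_UC": shift[diff_idx, 2],
                "pattern": patterns,
            },
            index=pd.Index(protein_ids[diff_idx], name="protein_id"),
        ),
        protease_panel=tuple(protein_ids[panel_idx]),
        target_r=0.0,
    )
    return matrix, truth


def gen_two_class_panel(
    n_candidates: int = 8,
    n_informative: int = 3,
    group_sizes: tuple[int, int] = (7, 8),
    shift_log10: float = 0.63,
    sd_log10: float = 0.05,
    seed: int = 0,
    exact_means: bool = True,
    subtype_mixture: bool = True,
) -> tuple[pd.DataFrame, np.ndarray, tuple[str, ...]]:
    """Two-class candidate-protease feature matrix for panel discovery.

    Returns (features: samples x candidates on the log10 abundance scale,
    labels: 0 = HC, 1 = IBS, informative candidate ids).  Informative
    candidates are elevated by ``shift_log10`` — the effect size of the
    strongest published single protease marker — in the IBS class, against
    a within-group sd of ``sd_log10``.

    With ``subtype_mixture`` (the default) the IBS class is generated as a
    mixture of marker subtypes: the IBS samples are assigned round-robin to
    the informative candidates and each sample is elevated in its own
    marker only.  This encodes explicitly why multi-marker panels beat
    single markers in a heterogeneous disease — each marker covers one
    patient subset, and only the complete informative set covers the whole
    class.  With ``subtype_mixture=False`` every informative candidate is
    elevated in every IBS sample.

    With ``exact_means`` (the default) the noise is centered within each
    class per candidate before planting, so realized class means equal the
    planted values exactly: at 15 samples the standard error of a realized
    standardized shift is ~0.5, and without centering, "noise" candidates
    routinely rival planted ones within the generated cohort, making
    recovery a measure of sampling luck rather than of the search
    procedure.
    """
    if not 0 <= n_informative <= n_candidates:
        raise ValidationError("n_informative must lie in [0, n_candidates]")
    rng = _child_rng(seed, 3)
    n0, n1 = group_sizes
    ids = tuple(f"C{i:02d}" for i in range(n_candidates))
    info = tuple(sorted(rng.choice(n_candidates, size=n_informative, replace=False)))
    X = rng.normal(0.0, sd_log10, size=(n0 + n1, n_candidates))
    labels = np.r_[np.zeros(n0, dtype=int), np.ones(n1, dtype=int)]
    if exact_means:
        for c in (0, 1):
            rows = labels == c
            X[rows] -= X[rows].mean(axis=0)
    pos_rows = np.flatnonzero(labels == 1)
    if subtype_mixture and n_informative > 0:
        subtype = rng.permutation(len(pos_rows)) % n_informative
        for k, j in enumerate(info):
            X[pos_rows[subtype == k], j] += shift_log10
    else:
        for j in info:
            X[pos_rows, j] += shift_log10
    features = pd.DataFrame(
        X, index=[f"S{i:02d}" for i in range(n0 + n1)], columns=ids
    )
    return features, labels, tuple(ids[j] for j in info)


def gen_ganglion_responses(config: SynthNeuroConfig) -> list[GanglionRecording]:
    """Simulate per-ganglion supernatant responses for all groups.

    Each neuron responds independently with the group's responder
    probability; responder spike frequencies are log-normal with the group's
    median.  The derived neuroindex medians approach
    ``100 * p * median_freq`` as the number of ganglia grows.
    """
    cfg = config
    rng = _child_rng(cfg.seed, 11)
    lo, hi = cfg.neurons_range
    recordings: list[GanglionRecording] = []
    for group in sorted(cfg.patients_per_group):
        p = cfg.responder_p[group]
        med = cfg.freq_median_hz[group]
        for pat in range(cfg.patients_per_group[group]):
            pid = f"{group}-pat{pat+1:02d}"
            for gi in range(cfg.ganglia_per_patient):
                n = int(rng.integers(lo, hi + 1))
                resp = int(rng.binomial(n, p))
                if med > 0:
                    freqs = tuple(
                        float(f)
                        for f in med * np.exp(rng.normal(0.0, cfg.freq_log_sigma, resp))
                    )
                else:
                    freqs = tuple(0.0 for _ in range(resp))
                recordings.append(
                    GanglionRecording(
                        patient_id=pid,
                        group=group,
                        condition="supernatant",
                        neurons_total=n,
                        responders=resp,
                        magnitudes=freqs,
                    )
                )
    return recordings


def gen_paired_inhibition(
    config: SynthNeuroConfig,
    truth: GroundTruth | None = None,
    n_patients: int | None = None,
) -> pd.DataFrame:
    """Paired pre/post-antagonist neuroindex values per IBS patient.

    Protease abundance (log10 relative units) and the percentage decrease
    in neuroindex under the antagonist are drawn from a bivariate normal
    with population correlation ``target_r``; the sample Pearson r
    converges to the target as the number of patients grows.  Negative
    draws of the percentage decrease leave post > pre — the rate of such
    noise-driven violations is governed by ``inhibition_mean`` and
    ``inhibition_sd`` (about Phi(-mean/sd) of patients at the defaults).
    """
    cfg = config
    n = n_patients if n_patients is not None else cfg.patients_per_group.get("IBS", 0)
    if n < 3:
        raise ValidationError("need >=3 patients for a defined correlation")
    r = cfg.target_r if truth is None else truth.target_r or cfg.target_r
    rng = _child_rng(cfg.seed, 12)
    z1 = rng.normal(size=n)
    z2 = rng.normal(size=n)
    abundance = z1  # log10 relative protease abundance
    decrease = cfg.inhibition_mean + cfg.inhibition_sd * (
        r * z1 + np.sqrt(max(0.0, 1.0 - r * r)) * z2
    )
    decrease = np.minimum(decrease, 100.0)  # a neuroindex cannot drop below 0
    p = cfg.responder_p.get("IBS", 0.8)
    f = cfg.freq_median_hz.get("IBS", 3.8)
    pre = 100.0 * p * f * np.exp(rng.normal(0.0, 0.3, size=n))
    post = pre * (1.0 - decrease / 100.0)
    return pd.DataFrame(
        {
            "patient_id": [f"IBS-pat{i+1:02d}" for i in range(n)],
            "abundance": abundance,
            "pre_neuroindex": pre,
            "post_neuroindex": post,
            "pct_decrease": decrease,
        }
    ).set_index("patient_id")


def null_config(seed: int = 0, **overrides) -> SynthProteomeConfig:
    """Proteome config with no planted signal (all group means equal)."""
    return replace(SynthProteomeConfig(seed=seed), n_differential=0, **overrides)
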