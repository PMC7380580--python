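"""Synthetic multi-omics cohorts with planted ground truth.

The generator emulates a two-group (consumer vs nonconsumer) gut microbiome
cohort with repeated weekly sampling and a paired metabolite table:

* per-sample microbial composition is ``softmax(base + group * beta +
  subject_effect + timepoint_noise)`` with counts drawn multinomially at a
  lognormally distributed library size;
* ``beta`` is a centered per-microbe group differential on the
  log-composition scale (the planted analogue of the differentials the
  regression stage estimates);
* subject effects follow a variance-preserving AR(1) across time points:
  ``e_t = sqrt(s) * e_{t-1} + sqrt(1-s) * fresh``, so ``subject_stability``
  (``s``) is the fraction of subject-level variance retained week to week;
* metabolite log-intensities are a low-rank microbe-metabolite latent
  product plus lognormal noise; one designated "CLA-like" metabolite gains
  ``planted_metabolite_effect`` on the log scale in the consumer group and
  carries no latent loading, so its group link comes from the planted
  effect alone;
* latent factor 1 of the microbe loadings is partially aligned with the
  planted differentials (``latent_group_coupling``), emulating cohorts
  where consumption is a dominant axis of microbe-metabolite covariation.

All randomness flows from ``SimulationConfig.seed``; outputs are
bit-identical across runs for a fixed config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CONSUMER = "consumer"
NONCONSUMER = "nonconsumer"
#: frequency answers mapped to each group (consumer answers first)
CONSUMER_FREQUENCIES = ("occasionally", "regularly", "daily")
NONCONSUMER_FREQUENCIES = ("never", "rarely")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted-truth cohort generator.

    Counts and scales default to a desk-size analogue of a longitudinal
    fermented-food cohort: ~100 subjects in two groups sampled weekly for
    four weeks, 150 microbial features, 100 metabolite features.
    """

    n_subjects_per_group: int = 50
    n_timepoints: int = 4
    n_microbes: int = 150
    n_metabolites: int = 100
    effect_scale: float = 1.0
    library_size_log_mean: float = 9.2  # exp(9.2) ~ 10,000 reads
    library_size_log_sd: float = 0.5
    subject_stability: float = 0.9
    subject_sd: float = 1.0
    timepoint_sd: float = 1.0
    n_latent: int = 2
    planted_metabolite_effect: float = 2.0
    latent_group_coupling: float = 0.7
    metabolite_noise_sd: float = 0.5
    metabolite_scale: float = 1.0e5
    base_logit_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_subjects_per_group", "n_timepoints", "n_microbes",
                     "n_metabolites", "n_latent"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_microbes < 2:
            raise ValueError("need at least 2 microbes")
        if self.effect_scale < 0:
            raise ValueError("effect_scale must be >= 0")
        if not 0.0 <= self.subject_stability <= 1.0:
            raise ValueError("subject_stability must be in [0, 1]")
        if not 0.0 <= self.latent_group_coupling <= 1.0:
            raise ValueError("latent_group_coupling must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Planted ground truth paired with a simulated cohort."""

    beta_true: pd.Series  # centered per-microbe group differential
    cooccurrence_true: pd.DataFrame  # microbes x metabolites latent affinity
    enriched_metabolite_id: str
    group_assignment: pd.Series  # per-subject group label
    microbe_latent: np.ndarray = field(repr=False, default=None)
    metabolite_latent: np.ndarray = field(repr=False, default=None)


def preset_16s(**overrides) -> SimulationConfig:
    """16S-like preset: 3,100-feature pool."""
    return replace(SimulationConfig(n_microbes=3100), **overrides)


def preset_metagenome(**overrides) -> SimulationConfig:
    """Shotgun-metagenome-like preset: 153-feature pool."""
    return replace(SimulationConfig(n_microbes=153), **overrides)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate (count table, sample metadata, planted truth).

    One sample per subject per time point. Metadata carries subject, time
    point, group, consumption-frequency answer, interior-valued host
    covariates (age/BMI/height/weight, no antibiotics) and the drawn read
    count, so the filtering stage can run on it unchanged.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    D, M, L = cfg.n_microbes, cfg.n_metabolites, cfg.n_latent

    microbe_ids = [f"otu{j:04d}" for j in range(D)]
    metabolite_ids = [f"met{j:04d}" for j in range(M)]
    enriched_id = metabolite_ids[0]

    base = rng.normal(0.0, cfg.base_logit_sd, D)
    beta = rng.normal(0.0, cfg.effect_scale, D) if cfg.effect_scale > 0 \
        else np.zeros(D)
    beta -= beta.mean()

    # latent microbe/metabolite loadings (cooccurrence ground truth);
    # column-centered, the same identifiability convention as the
    # differentials (affinities are meaningful up to a per-factor shift)
    U = rng.normal(0.0, 1.0, (D, L))
    V = rng.normal(0.0, 1.0, (M, L))
    lam = cfg.latent_group_coupling
    if lam > 0 and beta.std() > 0:
        beta_std = (beta - beta.mean()) / beta.std()
        U[:, 0] = lam * beta_std + np.sqrt(1.0 - lam**2) * U[:, 0]
    U -= U.mean(axis=0, keepdims=True)
    V[0, :] = 0.0  # designated metabolite: planted group effect only

    n_sub = 2 * cfg.n_subjects_per_group
    subject_ids = [f"subj{s:04d}" for s in range(n_sub)]
    group = np.array([0] * cfg.n_subjects_per_group
                     + [1] * cfg.n_subjects_per_group)
    group_labels = np.where(group == 1, CONSUMER, NONCONSUMER)

    rows, meta_rows, index = [], [], []
    for s, sid in enumerate(subject_ids):
        freq_pool = CONSUMER_FREQUENCIES if group[s] else NONCONSUMER_FREQUENCIES
        freq = freq_pool[rng.integers(len(freq_pool))]
        age = int(rng.integers(25, 65))
        bmi = float(np.round(rng.uniform(18.5, 32.0), 1))
        height = float(np.round(rng.uniform(152.0, 198.0), 1))
        weight = float(np.round(bmi * (height / 100.0) ** 2, 1))
        e = rng.normal(0.0, cfg.subject_sd, D)
        for t in range(1, cfg.n_timepoints + 1):
            if t > 1:
                s_frac = cfg.subject_stability
                e = (np.sqrt(s_frac) * e
                     + np.sqrt(1.0 - s_frac) * rng.normal(0.0, cfg.subject_sd, D))
            logits = base + group[s] * beta + e
            if cfg.timepoint_sd > 0:
                logits = logits + rng.normal(0.0, cfg.timepoint_sd, D)
            depth = max(1, int(np.rint(rng.lognormal(
                cfg.library_size_log_mean, cfg.library_size_log_sd))))
            counts = rng.multinomial(depth, _softmax(logits))
            sample_id = f"{sid}.t{t}"
            index.append(sample_id)
            rows.append(counts)
            meta_rows.append({
                "subject": sid,
                "timepoint": t,
                "group": group_labels[s],
                "fermented_plant_frequency": freq,
                "age": age,
                "bmi": bmi,
                "height_cm": height,
                "weight_kg": weight,
                "antibiotic_past_year": "No",
                "read_count": depth,
            })

    table = pd.DataFrame(np.asarray(rows), index=index, columns=microbe_ids)
    table.index.name = "#SampleID"
    meta = pd.DataFrame(meta_rows, index=index)
    meta.index.name = "#SampleID"
    truth = SyntheticTruth(
        beta_true=pd.Series(beta, index=microbe_ids, name="beta_true"),
        cooccurrence_true=pd.DataFrame(U @ V.T, index=microbe_ids,
                                       columns=metabolite_ids),
        enriched_metabolite_id=enriched_id,
        group_assignment=pd.Series(group_labels, index=subject_ids,
                                   name="group"),
        microbe_latent=U,
        metabolite_latent=V,
    )
    return table, meta, truth


def clr(table: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Centered log-ratio transform of a count table (rows are samples)."""
    x = np.log(table.to_numpy(float) + pseudocount)
    x -= x.mean(axis=1, keepdims=True)
    return pd.DataFrame(x, index=table.index, columns=table.columns)


def simulate_metabolites(
    table: pd.DataFrame,
    truth: SyntheticTruth,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Paired metabolite intensity table for a simulated cohort.

    Each microbial read "emits" metabolites from its microbe's affinity
    softmax ``p(j | m) = softmax_j(u_m . v_j)``: a sample's expected
    metabolite profile is its relative microbial abundances mixed over
    those emission distributions. The designated metabolite additionally
    gains the planted consumer-group effect on the log scale. Intensities
    get multiplicative lognormal noise and are scaled and rounded to
    nonnegative integer "peak heights".
    """
    cfg = config
    if truth.microbe_latent is None:
        raise ValueError("truth does not carry latent loadings")
    if list(table.columns) != list(truth.beta_true.index):
        raise ValueError("table features do not match truth (dimension mismatch)")
    subjects = pd.Series(table.index, index=table.index).str.rsplit(
        ".", n=1).str[0]
    unknown = set(subjects) - set(truth.group_assignment.index)
    if unknown:
        raise ValueError(f"samples from unknown subjects: {sorted(unknown)[:3]}")

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    U, V = truth.microbe_latent, truth.metabolite_latent
    enriched_idx = list(truth.cooccurrence_true.columns).index(
        truth.enriched_metabolite_id)
    logits = U @ V.T
    logits -= logits.max(axis=1, keepdims=True)
    emission = np.exp(logits)
    # the designated metabolite gets the same fixed emission share from
    # every microbe (its latent loadings are zero), so its group link is
    # exactly the planted effect and nothing else
    M = emission.shape[1]
    emission[:, enriched_idx] = 0.0
    emission /= emission.sum(axis=1, keepdims=True)
    emission *= (M - 1) / M
    emission[:, enriched_idx] = 1.0 / M  # p(metabolite | microbe)
    xrel = table.to_numpy(float)
    xrel /= np.maximum(xrel.sum(axis=1, keepdims=True), 1e-12)
    with np.errstate(divide="ignore"):
        log_intensity = np.log(xrel @ emission)
    is_consumer = (truth.group_assignment.reindex(subjects).to_numpy()
                   == CONSUMER).astype(float)
    log_intensity[:, enriched_idx] += cfg.planted_metabolite_effect * is_consumer
    if cfg.metabolite_noise_sd > 0:
        log_intensity = log_intensity + rng.normal(
            0.0, cfg.metabolite_noise_sd, log_intensity.shape)
    intensity = np.rint(cfg.metabolite_scale * np.exp(log_intensity))
    intensity = np.clip(intensity, 0, None).astype(np.int64)
    out = pd.DataFrame(intensity, index=table.index,
                       columns=truth.cooccurrence_true.columns)
    out.index.name = "#SampleID"
    return out
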