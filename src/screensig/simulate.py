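"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the study designs the pipeline consumes:

* :func:`generate_screen` — an arrayed perturbation screen read out by
  probe-level molecular counting: low-baseline tissue-restricted probes,
  housekeeping probes, a six-point geometric positive-spike ladder, negative
  controls, log-normal lane factors, negative-binomial counts, and a few
  planted multiplicative inductions.
* :func:`generate_three_condition_experiment` — log2 expression under
  control / treated / treated+inhibitor with planted dependence classes.
* :func:`generate_cohort` — a tumor/normal count cohort with a latent
  per-tumor activation factor loading on signature genes and coupled
  positively to one marker gene and negatively to another, Poisson counts
  around a log-normal mean, and log-normal library factors.

All generators are deterministic given ``seed`` and return truth objects
sufficient to compute every downstream recovery metric.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import (
    CohortTruth,
    GeneSignature,
    RawCountMatrix,
    ScreenTruth,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Relative concentrations of the six-point positive-spike ladder.
POS_SPIKE_LEVELS = (128.0, 32.0, 8.0, 2.0, 0.5, 0.125)

#: Counts per unit of relative spike concentration.
POS_SPIKE_SCALE = 150.0

HOUSEKEEPING_GENES = ("PGK1", "TBP", "TUBB2A")


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, size: float) -> np.ndarray:
    """Negative-binomial counts with the (mean, size) parametrisation."""
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_screen(
    n_endogenous: int = 42,
    n_perturbations: int = 160,
    n_controls: int = 12,
    n_hits: int = 3,
    hit_effect: float = 8.0,
    baseline_low: float = 20.0,
    dispersion: float = 10.0,
    seed: int = 0,
    arm: str = "sirna",
    n_housekeeping: int = 3,
    n_negative: int = 8,
    lane_sigma: float = 0.2,
    hk_baseline: float = 5000.0,
) -> tuple[RawCountMatrix, ScreenTruth]:
    """Simulate an arrayed screen with planted multiplicative inductions.

    Counts for probe p in sample s are NegativeBinomial with mean
    lane_s × baseline_p × effect (effect = ``hit_effect`` where a hit is
    planted, else 1) and size ``dispersion``. Lane factors are log-normal
    (σ = ``lane_sigma``). Endogenous baselines scatter around
    ``baseline_low``; housekeeping around ``hk_baseline``; positive spikes
    follow the fixed geometric ladder; negative controls sit near 2 counts.
    """
    if n_hits > 0 and hit_effect <= 1:
        raise ValidationError("hit_effect must be > 1")
    if dispersion <= 0:
        raise ValidationError("dispersion must be positive")
    if n_hits > n_endogenous * n_perturbations:
        raise ValidationError("more hits requested than probe × perturbation pairs")
    rng = np.random.default_rng(seed)

    endo = [f"TRG{i + 1:02d}" for i in range(n_endogenous)]
    hk_genes = (
        list(HOUSEKEEPING_GENES[:n_housekeeping])
        if n_housekeeping <= len(HOUSEKEEPING_GENES)
        else [f"HK{i + 1}" for i in range(n_housekeeping)]
    )
    hk = [f"HK_{g}" for g in hk_genes]
    pos = [f"POS_{chr(ord('A') + i)}" for i in range(len(POS_SPIKE_LEVELS))]
    neg = [f"NEG_{i + 1:02d}" for i in range(n_negative)]

    annotation = pd.DataFrame(
        {
            "target_gene": endo + hk_genes + pos + neg,
            "probe_class": (
                ["endogenous"] * n_endogenous
                + ["housekeeping"] * n_housekeeping
                + ["positive_spike"] * len(pos)
                + ["negative_spike"] * n_negative
            ),
            "spike_level": (
                [np.nan] * (n_endogenous + n_housekeeping)
                + list(POS_SPIKE_LEVELS)
                + [np.nan] * n_negative
            ),
        },
        index=pd.Index(endo + hk + pos + neg, name="probe_id"),
    )

    prefix = "si" if arm == "sirna" else "KIN"
    pert_ids = [f"{prefix}{i + 1:03d}" for i in range(n_perturbations)]
    pert_samples = [f"S{i + 1:03d}" for i in range(n_perturbations)]
    ctl_samples = [f"CTL{i + 1:02d}" for i in range(n_controls)]
    samples = pert_samples + ctl_samples
    design = pd.DataFrame(
        {
            "perturbation_id": pert_ids + ["control"] * n_controls,
            "arm": arm,
            "group": ["perturbed"] * n_perturbations + ["control"] * n_controls,
        },
        index=pd.Index(samples, name="sample_id"),
    )

    baselines = pd.Series(
        np.concatenate(
            [
                baseline_low * rng.uniform(0.5, 1.5, n_endogenous),
                hk_baseline * rng.uniform(0.8, 1.2, n_housekeeping),
                POS_SPIKE_SCALE * np.asarray(POS_SPIKE_LEVELS),
                np.full(n_negative, 2.0),
            ]
        ),
        index=annotation.index,
        name="baseline_mean",
    )
    lane = pd.Series(
        np.exp(rng.normal(0.0, lane_sigma, len(samples))), index=samples,
        name="lane_factor",
    )

    effects = np.ones((len(annotation), len(samples)))
    planted: list[tuple[str, str, float]] = []
    hit_samples: list[tuple[str, str, float]] = []
    if n_hits > 0:
        flat = rng.choice(n_endogenous * n_perturbations, size=n_hits, replace=False)
        for idx in flat:
            pi, si = int(idx // n_perturbations), int(idx % n_perturbations)
            effects[pi, si] = hit_effect
            planted.append((endo[pi], pert_ids[si], float(hit_effect)))
            hit_samples.append((endo[pi], pert_samples[si], float(hit_effect)))

    mean = baselines.to_numpy()[:, None] * lane.to_numpy()[None, :] * effects
    # Endogenous probes carry biological overdispersion (NB, size =
    # ``dispersion``); spike-ins and housekeeping probes are counting-limited
    # (Poisson), otherwise control-based normalization could not remove lane
    # noise even in principle.
    arr = _nb_counts(rng, mean, dispersion)
    is_control_probe = (annotation["probe_class"] != "endogenous").to_numpy()
    arr[is_control_probe] = rng.poisson(mean[is_control_probe])
    counts = pd.DataFrame(arr, index=annotation.index, columns=samples)
    counts.index.name = "probe_id"

    raw = RawCountMatrix(counts=counts, annotation=annotation, design=design)
    truth = ScreenTruth(
        planted_hits=planted,
        hit_samples=hit_samples,
        lane_factors=lane,
        dispersion=dispersion,
        baseline_means=baselines,
    )
    return raw, truth


def generate_three_condition_experiment(
    n_genes: int = 2000,
    n_responsive: int = 516,
    n_dependent: int = 190,
    n_repressed: int = 155,
    n_reps: int = 3,
    seed: int = 0,
    noise_sd: float = 0.25,
    effect_range: tuple[float, float] = (1.0, 2.5),
    amplification_range: tuple[float, float] = (2.0, 3.0),
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Simulate log2 expression under control / treated / treated+inhibitor.

    Responsive genes carry a treated-vs-control log2 effect drawn from
    ``effect_range`` (≥ 1 log2 unit, i.e. ≥ 2-fold). Dependent genes lose the
    effect entirely under the inhibitor; repressed genes have it multiplied by
    a factor from ``amplification_range``; the remaining responsive genes keep
    it unchanged. Gaussian noise with σ = ``noise_sd`` is added per replicate.

    Returns ``(expression, groups, truth)``: the gene × sample log2 matrix,
    the sample → condition mapping, and the per-gene truth table with columns
    ``dep_class``, ``log2_effect_t``, ``log2_effect_ti``.
    """
    n_independent = n_responsive - n_dependent - n_repressed
    if n_independent < 0 or n_responsive > n_genes:
        raise ValidationError(
            "need n_dependent + n_repressed <= n_responsive <= n_genes"
        )
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]

    order = rng.permutation(n_genes)
    dep = order[:n_dependent]
    rep = order[n_dependent : n_dependent + n_repressed]
    ind = order[n_dependent + n_repressed : n_responsive]

    dep_class = np.array(["not_responsive"] * n_genes, dtype=object)
    dep_class[dep] = "dependent"
    dep_class[rep] = "repressed"
    dep_class[ind] = "independent"

    effect_t = np.zeros(n_genes)
    responsive = order[:n_responsive]
    effect_t[responsive] = rng.uniform(*effect_range, size=n_responsive)
    effect_ti = effect_t.copy()
    effect_ti[dep] = 0.0
    effect_ti[rep] = effect_t[rep] * rng.uniform(
        *amplification_range, size=n_repressed
    )

    baseline = rng.uniform(4.0, 10.0, size=n_genes)
    conditions = ["control", "treated", "treated_inhibitor"]
    cond_effect = {
        "control": np.zeros(n_genes),
        "treated": effect_t,
        "treated_inhibitor": effect_ti,
    }
    columns, data = [], []
    for cond in conditions:
        for r in range(n_reps):
            columns.append(f"{cond}_{r + 1}")
            data.append(
                baseline + cond_effect[cond] + rng.normal(0.0, noise_sd, n_genes)
            )
    expr = pd.DataFrame(
        np.column_stack(data), index=pd.Index(genes, name="gene_id"), columns=columns
    )
    groups = pd.Series(
        {c: c.rsplit("_", 1)[0] for c in columns}, name="group"
    )
    truth = pd.DataFrame(
        {
            "dep_class": dep_class,
            "log2_effect_t": effect_t,
            "log2_effect_ti": effect_ti,
        },
        index=expr.index,
    )
    return expr, groups, truth


def generate_cohort(
    n_genes: int = 3000,
    n_signature: int = 190,
    n_normal: int = 112,
    n_tumor: int = 500,
    coupling: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    lib_sigma: float = 0.3,
    baseline_range: tuple[float, float] = (3.0, 9.0),
    loading_range: tuple[float, float] = (0.5, 1.5),
) -> tuple[pd.DataFrame, pd.DataFrame, CohortTruth, GeneSignature]:
    """Simulate a tumor/normal count cohort with a latent activation factor.

    Each tumor t draws a_t ~ Normal(0, 1); signature gene g gains a_t·w_g on
    its log2 mean (w_g ~ Uniform over ``loading_range``); one target marker
    gains ``coupling``·a_t and one anti-marker loses it; normals have a = 0.
    Counts are Poisson around 2^(log2 mean) × library factor with log-normal
    library factors (σ = ``lib_sigma``).

    Returns ``(counts, design, truth, signature)``.
    """
    if n_signature >= n_genes:
        raise ValidationError("n_signature must be < n_genes")
    if coupling <= 0:
        logger.warning(
            "coupling = %g <= 0: markers will not be positively coupled", coupling
        )
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]

    picked = rng.choice(n_genes, size=n_signature + 2, replace=False)
    target_idx, anti_idx = int(picked[0]), int(picked[1])
    sig_idx = np.sort(picked[2:])
    target_gene, anti_gene = genes[target_idx], genes[anti_idx]
    sig_genes = [genes[i] for i in sig_idx]

    normals = [f"N{i + 1:03d}" for i in range(n_normal)]
    tumors = [f"T{i + 1:03d}" for i in range(n_tumor)]
    samples = normals + tumors
    design = pd.DataFrame(
        {
            "perturbation_id": "none",
            "arm": "cohort",
            "group": ["normal"] * n_normal + ["tumor"] * n_tumor,
        },
        index=pd.Index(samples, name="sample_id"),
    )

    a = pd.Series(rng.normal(0.0, 1.0, n_tumor), index=tumors, name="activation")
    w = pd.Series(
        rng.uniform(*loading_range, size=n_signature), index=sig_genes,
        name="loading",
    )
    lib = pd.Series(
        np.exp(rng.normal(0.0, lib_sigma, len(samples))), index=samples,
        name="library_factor",
    )

    baseline = rng.uniform(*baseline_range, size=n_genes)
    log2_mean = np.tile(baseline[:, None], (1, len(samples)))
    a_full = np.concatenate([np.zeros(n_normal), a.to_numpy()])
    log2_mean[sig_idx] += np.outer(w.to_numpy(), a_full)
    log2_mean[target_idx] += coupling * a_full
    log2_mean[anti_idx] -= coupling * a_full
    log2_mean += rng.normal(0.0, noise_sd, size=log2_mean.shape)

    lam = (2.0**log2_mean) * lib.to_numpy()[None, :]
    counts = pd.DataFrame(
        rng.poisson(lam), index=pd.Index(genes, name="gene_id"), columns=samples
    )

    truth = CohortTruth(
        activation=a,
        loadings=w,
        target_gene=target_gene,
        anti_gene=anti_gene,
        coupling=coupling,
        library_factors=lib,
    )
    signature = GeneSignature.from_genes("planted_signature", sig_genes)
    return counts, design, truth, signature
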