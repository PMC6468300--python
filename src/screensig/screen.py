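"""Normalization and hit calling for arrayed perturbation screens read out by
digital molecular counting (nCounter-style probe-level counts).

The screen asks, for each of a few dozen tissue-restricted genes, whether any
single perturbation (an activated kinase, or an siRNA against a chromatin
factor) induces its expression in cells where it is normally silent. Counts
are rescaled first on the positive spike-in ladder (lane efficiency), then on
housekeeping genes (RNA content). Hits are probe × perturbation pairs whose
log2 normalized count lies more than k sample standard deviations above the
probe's mean across all samples of the arm, controls included; k = 2.5 and 3.5
by default, with a per-probe Shapiro–Wilk flag because the per-probe
distributions are not guaranteed normal.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .types import (
    NormalizationError,
    NormalizedMatrix,
    RawCountMatrix,
    ValidationError,
)

logger = logging.getLogger(__name__)


def _geometric_means(values: pd.DataFrame) -> pd.Series:
    """Per-sample (column) geometric mean; requires strictly positive input."""
    return np.exp(np.log(values).mean(axis=0))


def _control_factors(values: pd.DataFrame, what: str) -> pd.Series:
    """Per-sample rescaling factor from a block of control-probe values.

    factor_s = (arithmetic mean across samples of per-sample geometric means)
               / (sample s's geometric mean).
    """
    zero = values <= 0
    if zero.to_numpy().any():
        probe, sample = next(
            (p, s) for p in values.index for s in values.columns
            if values.at[p, s] <= 0
        )
        raise NormalizationError(
            f"zero count in {what} probe {probe!r}, sample {sample!r}"
        )
    geo = _geometric_means(values)
    return geo.mean() / geo


class NanostringNormalizer(TransformerMixin, BaseEstimator):
    """Two-stage control-probe rescaling of a probe × sample count matrix.

    Stage 1 divides out lane efficiency using the positive spike ladder; stage
    2 divides out content using housekeeping probes (computed on spike-
    normalized values). Both factors are "mean of geometric means over this
    sample's geometric mean", the conventional nCounter scheme. The negative-
    control background (per-sample mean + 2 SD) is recorded for QC only and is
    never subtracted.

    Fitted attributes: ``pos_factors_``, ``hk_factors_``, ``background_``.
    """

    def __init__(self, annotation: pd.DataFrame | None = None):
        self.annotation = annotation

    def _probes(self, probe_class: str) -> list[str]:
        ann = self.annotation
        return ann.index[ann["probe_class"] == probe_class].tolist()

    def fit(self, X: pd.DataFrame, y=None) -> "NanostringNormalizer":
        if self.annotation is None:
            raise ValidationError("NanostringNormalizer requires an annotation table")
        pos = self._probes("positive_spike")
        hk = self._probes("housekeeping")
        neg = self._probes("negative_spike")
        if len(pos) < 2:
            raise NormalizationError("need >=2 positive_spike probes")
        if len(hk) < 1:
            raise NormalizationError("need >=1 housekeeping probe")
        counts = X.astype(float)
        self.pos_factors_ = _control_factors(counts.loc[pos], "positive_spike")
        pos_normalized = counts.mul(self.pos_factors_, axis=1)
        self.hk_factors_ = _control_factors(pos_normalized.loc[hk], "housekeeping")
        if neg:
            neg_vals = pos_normalized.loc[neg].mul(self.hk_factors_, axis=1)
            sd = neg_vals.std(axis=0, ddof=1).fillna(0.0) if len(neg) > 1 else 0.0
            self.background_ = neg_vals.mean(axis=0) + 2.0 * sd
        else:
            self.background_ = pd.Series(0.0, index=X.columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        factors = self.pos_factors_ * self.hk_factors_
        return X.astype(float).mul(factors, axis=1)


def normalize_counts(raw: RawCountMatrix) -> NormalizedMatrix:
    """Rescale raw screen counts on spike and housekeeping controls."""
    norm = NanostringNormalizer(annotation=raw.annotation).fit(raw.counts)
    return NormalizedMatrix(
        values=norm.transform(raw.counts),
        pos_factors=norm.pos_factors_,
        hk_factors=norm.hk_factors_,
        background=norm.background_,
    )


def log2_levels(
    norm: NormalizedMatrix | pd.DataFrame, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Elementwise log2(value + pseudocount)."""
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    values = norm.values if isinstance(norm, NormalizedMatrix) else norm
    return np.log2(values + pseudocount)


def probe_zscores(
    log2_matrix: pd.DataFrame, arm_samples: Sequence[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-probe z-scores over all samples of a screen arm.

    Mean and sample SD (n−1) are taken over every sample of the arm, controls
    and experiments alike. Probes with zero SD yield NaN z-scores and are
    flagged downstream rather than raising.

    Returns ``(stats, z)``: per-probe mean/sd and the probe × sample z matrix.
    """
    sub = log2_matrix if arm_samples is None else log2_matrix.loc[:, list(arm_samples)]
    if sub.shape[1] < 3:
        raise ValidationError("an arm needs at least 3 samples for z-scores")
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = sub.sub(mean, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    stats_df = pd.DataFrame({"mean": mean, "sd": sd})
    return stats_df, z


def z_to_pvalue(z, tails: str = "one"):
    """Standard-normal tail probability for a z-score.

    one-tailed: upper tail P(Z > z); two-tailed: 2 · P(Z > |z|).
    """
    z = np.asarray(z, dtype=float)
    if not np.isfinite(z).all():
        raise ValidationError("z must be finite")
    if tails == "one":
        p = stats.norm.sf(z)
    elif tails == "two":
        p = 2.0 * stats.norm.sf(np.abs(z))
    else:
        raise ValidationError("tails must be 'one' or 'two'")
    return float(p) if p.ndim == 0 else p


def _shapiro_flags(log2_matrix: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """True where a probe's log2 distribution is compatible with normality."""
    flags = {}
    for probe, row in log2_matrix.iterrows():
        x = row.to_numpy(dtype=float)
        if np.ptp(x) == 0:
            flags[probe] = False  # degenerate; Shapiro undefined
            continue
        flags[probe] = bool(stats.shapiro(x).pvalue >= alpha)
    return pd.Series(flags, name="probe_normal")


class ScreenHitCaller(BaseEstimator):
    """Z-score hit calling on normalized screen counts, per arm.

    ``fit`` consumes a :class:`NormalizedMatrix` plus the sample design and
    computes log2 levels, per-probe statistics and z-scores within each screen
    arm; ``hit_table()`` (or the :func:`call_hits` wrapper) materialises the
    long-format hit table. Control samples are scored but never flagged as
    hits. Threshold comparison is strict (z > threshold).

    Fitted attributes: ``log2_``, ``zscores_``, ``probe_stats_``,
    ``probe_normal_``, ``hit_table_``.
    """

    def __init__(
        self,
        thresholds: tuple[float, float] = (2.5, 3.5),
        pseudocount: float = 1.0,
        shapiro_alpha: float = 0.05,
        endogenous_only: bool = True,
    ):
        self.thresholds = thresholds
        self.pseudocount = pseudocount
        self.shapiro_alpha = shapiro_alpha
        self.endogenous_only = endogenous_only

    def fit(
        self,
        X: NormalizedMatrix,
        design: pd.DataFrame,
        annotation: pd.DataFrame | None = None,
    ) -> "ScreenHitCaller":
        lo, hi = self.thresholds
        if not lo < hi:
            raise ValidationError("thresholds must be strictly increasing")
        values = X.values
        if annotation is not None and self.endogenous_only:
            keep = annotation.index[annotation["probe_class"] == "endogenous"]
            values = values.loc[[p for p in values.index if p in set(keep)]]
        self.log2_ = log2_levels(values, self.pseudocount)
        z_parts, stat_parts, normal_parts = [], [], []
        for arm, sub in design.groupby("arm", sort=False):
            samples = [s for s in values.columns if s in set(sub.index)]
            stats_df, z = probe_zscores(self.log2_, samples)
            z_parts.append(z)
            stats_df = stats_df.assign(arm=arm)
            stat_parts.append(stats_df)
            normal_parts.append(
                _shapiro_flags(self.log2_[samples], self.shapiro_alpha)
            )
        self.zscores_ = pd.concat(z_parts, axis=1)[values.columns]
        self.probe_stats_ = pd.concat(stat_parts)
        self.probe_normal_ = pd.concat(normal_parts).groupby(level=0).all()
        self.hit_table_ = self._build_table(X, design)
        return self

    def _build_table(self, X: NormalizedMatrix, design: pd.DataFrame) -> pd.DataFrame:
        lo, hi = self.thresholds
        long = (
            self.log2_.rename_axis("probe_id")
            .reset_index()
            .melt(id_vars="probe_id", var_name="sample_id", value_name="log2_value")
        )
        zlong = (
            self.zscores_.rename_axis("probe_id")
            .reset_index()
            .melt(id_vars="probe_id", var_name="sample_id", value_name="z")
        )
        table = long.merge(zlong, on=["probe_id", "sample_id"])
        table["perturbation_id"] = table["sample_id"].map(design["perturbation_id"])
        table["arm"] = table["sample_id"].map(design["arm"])
        is_control = table["perturbation_id"] == "control"
        table["hit_2p5"] = (table["z"] > lo) & ~is_control
        table["hit_3p5"] = (table["z"] > hi) & ~is_control
        table["probe_normal"] = table["probe_id"].map(self.probe_normal_)
        values_long = (
            X.values.rename_axis("probe_id")
            .reset_index()
            .melt(id_vars="probe_id", var_name="sample_id", value_name="_norm")
        )
        table = table.merge(values_long, on=["probe_id", "sample_id"])
        table["below_background"] = table["_norm"] < table["sample_id"].map(
            X.background
        )
        table = table.drop(columns="_norm")
        cols = [
            "probe_id", "sample_id", "perturbation_id", "arm", "log2_value",
            "z", "hit_2p5", "hit_3p5", "probe_normal", "below_background",
        ]
        return table[cols]

    def hit_table(self) -> pd.DataFrame:
        return self.hit_table_


def call_hits(
    norm: NormalizedMatrix,
    design: pd.DataFrame,
    thresholds: tuple[float, float] = (2.5, 3.5),
    pseudocount: float = 1.0,
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One-sided upper z-score hit calls at two thresholds (long format)."""
    caller = ScreenHitCaller(thresholds=thresholds, pseudocount=pseudocount)
    return caller.fit(norm, design, annotation=annotation).hit_table()


def fold_change_vs_controls(
    norm: NormalizedMatrix | pd.DataFrame,
    design: pd.DataFrame,
    reference_group: str = "control",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per probe × sample linear fold change over the mean of reference samples.

    fold = (value + pseudocount) / (reference-group mean + pseudocount), with a
    ``fold2plus`` flag for ≥2-fold signal.
    """
    values = norm.values if isinstance(norm, NormalizedMatrix) else norm
    ref_samples = design.index[design["group"] == reference_group]
    ref_samples = [s for s in values.columns if s in set(ref_samples)]
    if not ref_samples:
        raise ValidationError(f"reference group {reference_group!r} is empty")
    ref_mean = values[ref_samples].mean(axis=1)
    fc = values.add(pseudocount).div(ref_mean + pseudocount, axis=0)
    out = (
        fc.rename_axis("probe_id")
        .reset_index()
        .melt(id_vars="probe_id", var_name="sample_id", value_name="fold_change")
    )
    out["fold2plus"] = out["fold_change"] >= 2.0
    return out
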