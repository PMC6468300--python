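"""Domain containers shared across the pipeline.

All tabular data ride on :class:`pandas.DataFrame`; the dataclasses here bundle
the frames with their cross-referencing invariants (probe/sample id agreement,
control-class requirements) and the ground-truth records emitted by the
synthetic generators.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROBE_CLASSES = frozenset(
    {"endogenous", "housekeeping", "positive_spike", "negative_spike", "tag"}
)

ARMS = frozenset({"kinase", "sirna", "cohort", "other"})

DEPENDENCE_CLASSES = ("not_responsive", "independent", "repressed", "dependent")


class ValidationError(ValueError):
    """A table violates a structural invariant (ids, classes, signs)."""


class FormatError(ValueError):
    """A file does not parse under the expected dialect."""


class NormalizationError(ValueError):
    """Control probes are unusable for normalization (zeros, too few)."""


def _check_unique(values: pd.Index | pd.Series, what: str) -> None:
    dup = pd.Index(values)[pd.Index(values).duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"duplicate {what}: {dup}")


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Validate a probe annotation table (index probe_id).

    Required columns: ``target_gene``, ``probe_class``; optional ``spike_level``
    (required and positive exactly for positive_spike probes).
    """
    required = {"target_gene", "probe_class"}
    missing = required - set(annotation.columns)
    if missing:
        raise ValidationError(f"annotation missing columns: {sorted(missing)}")
    _check_unique(annotation.index, "probe ids")
    bad_class = annotation.loc[
        ~annotation["probe_class"].isin(PROBE_CLASSES), "probe_class"
    ]
    if len(bad_class):
        raise ValidationError(
            f"unknown probe_class values: {sorted(bad_class.unique().tolist())}"
        )
    is_pos = annotation["probe_class"] == "positive_spike"
    if "spike_level" not in annotation.columns:
        if is_pos.any():
            raise ValidationError("positive_spike probes require a spike_level column")
    else:
        lv = pd.to_numeric(annotation["spike_level"], errors="coerce")
        missing_lv = annotation.index[is_pos & ~(lv > 0)].tolist()
        if missing_lv:
            raise ValidationError(
                f"positive_spike probes without positive spike_level: {missing_lv}"
            )
        extra_lv = annotation.index[~is_pos & lv.notna()].tolist()
        if extra_lv:
            raise ValidationError(
                f"spike_level present on non-positive_spike probes: {extra_lv}"
            )
    return annotation


def validate_design(design: pd.DataFrame, require_controls: bool = True) -> pd.DataFrame:
    """Validate a sample design table (index sample_id).

    Required columns: ``perturbation_id``, ``arm``, ``group``. Screen arms
    (kinase/sirna) must contain at least one control sample.
    """
    required = {"perturbation_id", "arm", "group"}
    missing = required - set(design.columns)
    if missing:
        raise ValidationError(f"design missing columns: {sorted(missing)}")
    _check_unique(design.index, "sample ids")
    bad_arm = design.loc[~design["arm"].isin(ARMS), "arm"]
    if len(bad_arm):
        raise ValidationError(f"unknown arm values: {sorted(bad_arm.unique().tolist())}")
    if require_controls:
        for arm, sub in design.groupby("arm"):
            if arm in ("kinase", "sirna") and not (
                sub["perturbation_id"] == "control"
            ).any():
                raise ValidationError(f"screen arm {arm!r} has no control sample")
    return design


@dataclass
class RawCountMatrix:
    """Probe × sample nonnegative integer counts plus annotation and design."""

    counts: pd.DataFrame
    annotation: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        validate_annotation(self.annotation)
        validate_design(self.design)
        probes_counts = set(self.counts.index)
        probes_ann = set(self.annotation.index)
        problems = []
        only_counts = sorted(probes_counts - probes_ann)
        only_ann = sorted(probes_ann - probes_counts)
        if only_counts:
            problems.append(f"probes in counts but not annotation: {only_counts}")
        if only_ann:
            problems.append(f"probes in annotation but not counts: {only_ann}")
        samples_counts = set(self.counts.columns)
        samples_design = set(self.design.index)
        only_c = sorted(samples_counts - samples_design)
        only_d = sorted(samples_design - samples_counts)
        if only_c:
            problems.append(f"samples in counts but not design: {only_c}")
        if only_d:
            problems.append(f"samples in design but not counts: {only_d}")
        if problems:
            raise ValidationError("; ".join(problems))
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValidationError("counts are not numeric")
        if (vals < 0).any():
            bad = self.counts.index[(self.counts < 0).any(axis=1)].tolist()
            raise ValidationError(f"negative counts in probes: {bad}")
        if not np.allclose(vals, np.round(vals)):
            bad = self.counts.index[
                ~np.isclose(self.counts, np.round(self.counts)).all(axis=1)
            ].tolist()
            raise ValidationError(f"non-integer counts in probes: {bad}")

    def probes_of_class(self, probe_class: str) -> list[str]:
        return self.annotation.index[
            self.annotation["probe_class"] == probe_class
        ].tolist()


@dataclass(frozen=True)
class GeneSignature:
    """A named, ordered, duplicate-free gene set."""

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            logger.warning("signature %r is empty", self.name)
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"signature {self.name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    @classmethod
    def from_genes(
        cls, name: str, genes: Sequence[str], description: str = ""
    ) -> "GeneSignature":
        """Build a signature, collapsing duplicates (first occurrence wins)."""
        seen: dict[str, None] = {}
        n_dup = 0
        for g in genes:
            if g in seen:
                n_dup += 1
            else:
                seen[g] = None
        if n_dup:
            logger.warning(
                "signature %r: collapsed %d duplicate gene ids", name, n_dup
            )
        return cls(name=name, genes=tuple(seen), description=description)


@dataclass
class NormalizedMatrix:
    """Screen counts after positive-spike and housekeeping rescaling."""

    values: pd.DataFrame  # probe × sample positive reals
    pos_factors: pd.Series  # per-sample
    hk_factors: pd.Series  # per-sample
    background: pd.Series  # per-sample mean + 2 SD of negative-control probes


@dataclass
class ScreenTruth:
    """Ground truth for a simulated screen."""

    planted_hits: list[tuple[str, str, float]]  # (probe_id, perturbation_id, effect)
    hit_samples: list[tuple[str, str, float]]  # (probe_id, sample_id, effect)
    lane_factors: pd.Series
    dispersion: float
    baseline_means: pd.Series

    def __post_init__(self) -> None:
        if any(e <= 1 for _, _, e in self.planted_hits):
            raise ValidationError("planted effects must be > 1")
        if (self.lane_factors <= 0).any():
            raise ValidationError("lane factors must be positive")


@dataclass
class CohortTruth:
    """Ground truth for a simulated tumor/normal cohort."""

    activation: pd.Series  # per-tumor latent factor a_t
    loadings: pd.Series  # per-signature-gene positive loading w_g
    target_gene: str
    anti_gene: str
    coupling: float
    library_factors: pd.Series

    def __post_init__(self) -> None:
        sig = set(self.loadings.index)
        if self.target_gene in sig or self.anti_gene in sig or (
            self.target_gene == self.anti_gene
        ):
            raise ValidationError(
                "signature genes, target marker and anti-marker must be disjoint"
            )
        if (self.library_factors <= 0).any():
            raise ValidationError("library factors must be positive")


@dataclass
class NullModel:
    """Random-signature null for a score/gene correlation, with a Gumbel tail fit."""

    k: int
    n_draws: int
    seed: int
    null_r: np.ndarray
    gumbel_mu: float
    gumbel_beta: float
    observed_r: float
    p_value: float
    direction: str  # "greater" or "less" (tail actually tested)
    gene: str = ""

    def __post_init__(self) -> None:
        if self.n_draws != len(self.null_r):
            raise ValidationError("n_draws must equal len(null_r)")
        if not self.gumbel_beta > 0:
            raise ValidationError("gumbel_beta must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["null_r"] = [float(x) for x in self.null_r]
        return d


@dataclass
class ClusterResult:
    """Agglomerative clustering of samples with an optional label agreement."""

    linkage: np.ndarray
    labels: pd.Series  # cut to k groups, indexed by sample
    ari: float | None
    newick: str
    samples: list[str] = field(default_factory=list)
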