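"""Deriving an inhibitor-dependence signature from a three-condition design.

Cells are profiled under control, treated (e.g. TGF-β) and treated+inhibitor
(e.g. TGF-β plus a TAK1 kinase inhibitor) conditions. Genes responsive to the
treatment (fold change > 1.5, p < 0.05 on a Welch t-test of log2 expression)
are partitioned into three classes:

* dependent   — induction is lost when the inhibitor is present (the
                +inhibitor contrast fails the same responsiveness criterion);
                these genes form the pathway-activation signature;
* repressed   — induction is potentiated by the inhibitor (fold-change ratio
                ≥ 1.5), i.e. the inhibited kinase normally restrains them;
* independent — the residual class, induced equally well either way.

Evaluation order (not responsive → dependent → repressed → independent) makes
the classes mutually exclusive and exhaustive over responsive genes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .types import DEPENDENCE_CLASSES, GeneSignature, ValidationError

logger = logging.getLogger(__name__)


def differential_response(
    expr: pd.DataFrame,
    groups: pd.Series,
    group_a: str,
    group_b: str,
    min_replicates: int = 2,
) -> pd.DataFrame:
    """Per-gene fold change and p-value of group_b vs group_a.

    ``expr`` is gene × sample log2 expression; ``groups`` maps sample id to
    condition label. Fold change is 2^(mean_b − mean_a); p is from a two-sided
    Welch t-test on the log2 values.
    """
    a = [s for s in expr.columns if groups.get(s) == group_a]
    b = [s for s in expr.columns if groups.get(s) == group_b]
    if len(a) < min_replicates or len(b) < min_replicates:
        raise ValidationError(
            f"groups {group_a!r} (n={len(a)}) and {group_b!r} (n={len(b)}) "
            f"need >= {min_replicates} replicates"
        )
    xa = expr[a].to_numpy(dtype=float)
    xb = expr[b].to_numpy(dtype=float)
    log2_fc = xb.mean(axis=1) - xa.mean(axis=1)
    res = stats.ttest_ind(xb, xa, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # Degenerate zero-variance genes: identical groups mean no evidence.
    p = np.where(np.isnan(p), 1.0, p)
    return pd.DataFrame(
        {"fold_change": 2.0 ** log2_fc, "log2_fc": log2_fc, "p_value": p},
        index=expr.index,
    )


def classify_dependence(
    response_t: pd.DataFrame,
    response_ti: pd.DataFrame,
    fc_min: float = 1.5,
    p_max: float = 0.05,
    potentiation_ratio: float = 1.5,
) -> pd.DataFrame:
    """Partition genes into not_responsive / dependent / repressed / independent.

    ``response_t`` (treated vs control) and ``response_ti`` (treated+inhibitor
    vs control) must cover the same genes. A gene is responsive iff
    fc_t > fc_min and p_t < p_max. Responsive genes are dependent when the
    +inhibitor contrast fails that same criterion ("lost induction"),
    repressed when fc_ti / fc_t ≥ potentiation_ratio, independent otherwise.
    """
    only_t = set(response_t.index) - set(response_ti.index)
    only_ti = set(response_ti.index) - set(response_t.index)
    if only_t or only_ti:
        raise ValidationError(
            f"contrasts cover different genes; only in treated: {sorted(only_t)[:10]}, "
            f"only in +inhibitor: {sorted(only_ti)[:10]}"
        )
    t = response_t
    ti = response_ti.loc[t.index]
    responsive = (t["fold_change"] > fc_min) & (t["p_value"] < p_max)
    ti_fails = (ti["fold_change"] <= fc_min) | (ti["p_value"] >= p_max)
    potentiated = (ti["fold_change"] / t["fold_change"]) >= potentiation_ratio
    dep_class = np.select(
        [~responsive, ti_fails, potentiated],
        ["not_responsive", "dependent", "repressed"],
        default="independent",
    )
    out = pd.DataFrame(
        {
            "fc_t": t["fold_change"],
            "p_t": t["p_value"],
            "fc_ti": ti["fold_change"],
            "p_ti": ti["p_value"],
            "dep_class": pd.Categorical(dep_class, categories=DEPENDENCE_CLASSES),
        },
        index=t.index,
    )
    return out


def extract_signature(
    table: pd.DataFrame, which: str = "dependent", name: str = "signature"
) -> GeneSignature:
    """Collect all genes of one dependence class into an ordered signature."""
    if which not in DEPENDENCE_CLASSES:
        raise ValidationError(f"unknown class {which!r}")
    genes = table.index[table["dep_class"] == which].tolist()
    if not genes:
        logger.warning("no genes in class %r; emitting empty signature", which)
    return GeneSignature.from_genes(name, genes)


class DependenceClassifier(BaseEstimator):
    """Fit the full three-condition analysis on a log2 expression matrix.

    Parameters mirror the published procedure: responsiveness at fold change
    > ``fc_min`` and Welch p < ``p_max``, potentiation at a fold-change ratio
    ≥ ``potentiation_ratio``. An optional Benjamini–Hochberg adjustment is off
    by default (raw p-values, as in the original analysis).

    Fitted attributes: ``response_table_``, ``class_sizes_``, ``signature_``.
    """

    def __init__(
        self,
        fc_min: float = 1.5,
        p_max: float = 0.05,
        potentiation_ratio: float = 1.5,
        control: str = "control",
        treated: str = "treated",
        treated_inhibitor: str = "treated_inhibitor",
        min_replicates: int = 2,
        adjust_p: bool = False,
        signature_name: str = "dependent_signature",
    ):
        self.fc_min = fc_min
        self.p_max = p_max
        self.potentiation_ratio = potentiation_ratio
        self.control = control
        self.treated = treated
        self.treated_inhibitor = treated_inhibitor
        self.min_replicates = min_replicates
        self.adjust_p = adjust_p
        self.signature_name = signature_name

    def fit(self, X: pd.DataFrame, groups: pd.Series) -> "DependenceClassifier":
        resp_t = differential_response(
            X, groups, self.control, self.treated, self.min_replicates
        )
        resp_ti = differential_response(
            X, groups, self.control, self.treated_inhibitor, self.min_replicates
        )
        if self.adjust_p:
            for df in (resp_t, resp_ti):
                df["p_value"] = stats.false_discovery_control(df["p_value"])
        self.response_table_ = classify_dependence(
            resp_t,
            resp_ti,
            fc_min=self.fc_min,
            p_max=self.p_max,
            potentiation_ratio=self.potentiation_ratio,
        )
        self.class_sizes_ = (
            self.response_table_["dep_class"].value_counts().to_dict()
        )
        self.signature_ = extract_signature(
            self.response_table_, "dependent", self.signature_name
        )
        return self
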