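"""Scoring signature activation in tumor/normal expression cohorts.

Counts are normalized with median-of-ratios size factors (the DESeq2 scheme),
tumors are stratified into first/last deciles of a target marker's expression,
and each tumor receives an activation score: the sum over signature genes of
its log2 fold change relative to the mean of normal samples. The score's
association with a marker gene is tested against an empirical null built from
random gene sets of the same size, whose correlation distribution is
summarised by a method-of-moments Gumbel fit so that tail p-values below the
resolution of the draw count can be reported.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.metrics import adjusted_rand_score

from .types import ClusterResult, GeneSignature, NullModel, ValidationError

logger = logging.getLogger(__name__)

EULER_GAMMA = 0.5772156649015329


# ---------------------------------------------------------------------------
# Normalization


class MedianOfRatiosNormalizer(TransformerMixin, BaseEstimator):
    """Median-of-ratios library-size normalization of a gene × sample matrix.

    Reference genes are those with no zero count in any sample; each sample's
    size factor is the median over reference genes of count / (gene's
    geometric mean across samples). ``transform`` divides counts by the
    factors.

    Fitted attributes: ``size_factors_``, ``reference_genes_``.
    """

    def fit(self, X: pd.DataFrame, y=None) -> "MedianOfRatiosNormalizer":
        counts = X.astype(float)
        nonzero = (counts > 0).all(axis=1)
        if not nonzero.any():
            raise ValidationError(
                "no gene is nonzero in every sample; filter all-zero-prone "
                "genes before normalization"
            )
        ref = counts.loc[nonzero]
        log_geo = np.log(ref).mean(axis=1)
        ratios = ref.div(np.exp(log_geo), axis=0)
        self.size_factors_ = ratios.median(axis=0)
        self.reference_genes_ = ref.index.tolist()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.astype(float).div(self.size_factors_, axis=1)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Per-sample median-of-ratios size factors (DESeq2 scheme)."""
    return MedianOfRatiosNormalizer().fit(counts).size_factors_


# ---------------------------------------------------------------------------
# Stratification


def stratify_deciles(target_values: pd.Series) -> pd.Series:
    """Label tumors as low_decile / mid / high_decile by a marker's expression.

    Low and high strata each hold ⌈n/10⌉ tumors; ties are broken by the stable
    order of the input index, so the result is deterministic.
    """
    n = len(target_values)
    if n < 10:
        raise ValidationError("decile stratification needs >= 10 tumors")
    k = math.ceil(n / 10)
    order = np.argsort(target_values.to_numpy(), kind="stable")
    labels = np.array(["mid"] * n, dtype=object)
    labels[order[:k]] = "low_decile"
    labels[order[-k:]] = "high_decile"
    vals = target_values.to_numpy()
    if vals[order[k - 1]] == vals[order[k]] or vals[order[-k]] == vals[order[-k - 1]]:
        logger.warning(
            "tied target values straddle a decile boundary; strata fixed by "
            "stable input order"
        )
    return pd.Series(labels, index=target_values.index, name="stratum")


# ---------------------------------------------------------------------------
# Activation score


class ActivationScorer(BaseEstimator):
    """Signature activation scoring against a normal-tissue reference.

    ``fit`` learns the per-gene reference (arithmetic mean of normalized
    normal-sample values); ``score_samples`` sums, over signature genes
    present in the matrix, each tumor's log2 (default) or linear fold change
    versus that reference. Signature genes absent from the matrix are skipped
    and reported on ``missing_genes_``.

    Fitted attributes: ``normal_means_``, ``genes_used_``, ``missing_genes_``.
    """

    def __init__(
        self,
        signature: GeneSignature | Sequence[str] | None = None,
        scale: str = "log2",
        pseudocount: float = 1.0,
    ):
        self.signature = signature
        self.scale = scale
        self.pseudocount = pseudocount

    def fit(
        self, X: pd.DataFrame, normal_samples: Sequence[str]
    ) -> "ActivationScorer":
        if self.scale not in ("log2", "linear"):
            raise ValidationError("scale must be 'log2' or 'linear'")
        normal_samples = list(normal_samples)
        if len(normal_samples) < 2:
            raise ValidationError("need >= 2 normal samples for the reference")
        genes = list(self.signature)
        present = [g for g in genes if g in X.index]
        self.missing_genes_ = [g for g in genes if g not in X.index]
        if not present:
            raise ValidationError("no signature gene is present in the matrix")
        if self.missing_genes_:
            logger.warning(
                "%d signature genes absent from the matrix: %s...",
                len(self.missing_genes_),
                self.missing_genes_[:5],
            )
        self.genes_used_ = present
        self.normal_means_ = X.loc[present, normal_samples].mean(axis=1)
        return self

    def score_samples(self, X: pd.DataFrame, samples: Sequence[str]) -> pd.Series:
        sub = X.loc[self.genes_used_, list(samples)]
        pc = self.pseudocount
        ratios = sub.add(pc).div(self.normal_means_ + pc, axis=0)
        if self.scale == "log2":
            per_gene = np.log2(ratios)
        else:
            per_gene = ratios
        return per_gene.sum(axis=0).rename("activation_score")


def activation_score(
    normalized_counts: pd.DataFrame,
    signature: GeneSignature | Sequence[str],
    normal_samples: Sequence[str],
    tumor_samples: Sequence[str],
    scale: str = "log2",
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-tumor sum of signature-gene fold changes vs the normal reference."""
    scorer = ActivationScorer(signature=signature, scale=scale, pseudocount=pseudocount)
    scorer.fit(normalized_counts, normal_samples)
    return scorer.score_samples(normalized_counts, tumor_samples)


def score_table(
    normalized_counts: pd.DataFrame,
    signature: GeneSignature | Sequence[str],
    design: pd.DataFrame,
    target_gene: str,
    scale: str = "log2",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Full per-sample score table: activation score, target log2, stratum.

    Normal samples (design group == "normal") provide the reference and get
    stratum "normal"; tumors are stratified into target-expression deciles.
    """
    normals = design.index[design["group"] == "normal"].tolist()
    tumors = design.index[design["group"] != "normal"].tolist()
    if target_gene not in normalized_counts.index:
        raise ValidationError(f"target gene {target_gene!r} not in matrix")
    scores = activation_score(
        normalized_counts, signature, normals, tumors, scale, pseudocount
    )
    target_log2 = np.log2(normalized_counts.loc[target_gene] + pseudocount)
    strata = stratify_deciles(target_log2[tumors])
    table = pd.DataFrame(index=design.index)
    table["activation_score"] = scores.reindex(table.index)
    table["target_log2"] = target_log2
    table["stratum"] = strata.reindex(table.index).fillna("normal")
    table.index.name = "sample_id"
    return table


# ---------------------------------------------------------------------------
# Clustering


def _linkage_to_newick(Z: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Serialise a scipy linkage matrix as a Newick string."""
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def cluster_samples(
    values: pd.DataFrame,
    k_groups: int,
    reference_labels: pd.Series | None = None,
    variant: str = "D2",
) -> ClusterResult:
    """Ward-linkage agglomerative clustering of samples (columns) on log2 values.

    ``variant="D2"`` (default) is Ward on Euclidean distances in the
    squared-distance Lance–Williams formulation; ``variant="D"`` applies the
    same update to the unsquared distances (the other common Ward variant).
    The tree is cut to ``k_groups``; if reference labels are supplied the
    adjusted Rand index against them is reported.
    """
    samples = values.columns.tolist()
    if len(samples) < 2:
        raise ValidationError("need >= 2 samples to cluster")
    if k_groups > len(samples):
        raise ValidationError("k_groups exceeds the number of samples")
    X = values.to_numpy(dtype=float).T
    if variant == "D2":
        Z = hierarchy.linkage(X, method="ward")
    elif variant == "D":
        Z = hierarchy.linkage(pdist(X), method="ward")
    else:
        raise ValidationError("variant must be 'D2' or 'D'")
    cut = hierarchy.fcluster(Z, t=k_groups, criterion="maxclust")
    labels = pd.Series(cut, index=samples, name="cluster")
    ari = None
    if reference_labels is not None:
        ref = reference_labels.reindex(samples)
        ari = float(adjusted_rand_score(ref, labels))
    return ClusterResult(
        linkage=Z,
        labels=labels,
        ari=ari,
        newick=_linkage_to_newick(Z, samples),
        samples=samples,
    )


# ---------------------------------------------------------------------------
# Correlation and the random-signature Gumbel null


def score_gene_correlation(
    scores: pd.Series,
    normalized_counts: pd.DataFrame,
    gene: str,
    pseudocount: float = 1.0,
) -> float:
    """Pearson r between tumor activation scores and a gene's log2 expression."""
    if gene not in normalized_counts.index:
        raise ValidationError(f"gene {gene!r} not in matrix")
    if len(scores) < 3:
        raise ValidationError("need >= 3 tumors for a correlation")
    expr = np.log2(normalized_counts.loc[gene, scores.index] + pseudocount)
    x = scores.to_numpy(dtype=float)
    y = expr.to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance; correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def fit_gumbel(x: np.ndarray) -> tuple[float, float]:
    """Method-of-moments Gumbel fit: β̂ = s·√6/π, μ̂ = m − γ·β̂."""
    x = np.asarray(x, dtype=float)
    s = float(np.std(x, ddof=1))
    if s <= 0:
        raise ValidationError("null sample has zero variance; Gumbel fit undefined")
    beta = s * math.sqrt(6.0) / math.pi
    mu = float(np.mean(x)) - EULER_GAMMA * beta
    return mu, beta


def gumbel_tail_p(x: float, mu: float, beta: float) -> float:
    """Upper-tail survival 1 − exp(−exp(−(x−μ)/β)) of a Gumbel(μ, β)."""
    return float(-np.expm1(-np.exp(-(x - mu) / beta)))


def _null_scores(
    fc: np.ndarray, draws: np.ndarray, scale: str
) -> np.ndarray:
    """Scores of many random signatures at once.

    ``fc`` is the per-gene fold-change matrix (genes × tumors, already on the
    requested scale), ``draws`` an (n_draws, k) index array; returns
    (n_draws, tumors) score rows via a sparse indicator product.
    """
    n_draws, k = draws.shape
    indptr = np.arange(0, n_draws * k + 1, k)
    data = np.ones(n_draws * k)
    S = sparse.csr_matrix(
        (data, draws.ravel(), indptr), shape=(n_draws, fc.shape[0])
    )
    return S @ fc


def random_signature_null(
    normalized_counts: pd.DataFrame,
    signature: GeneSignature | Sequence[str],
    gene: str,
    normal_samples: Sequence[str],
    tumor_samples: Sequence[str],
    n_draws: int = 1000,
    seed: int = 0,
    exclude: Sequence[str] = (),
    direction: str = "auto",
    scale: str = "log2",
    pseudocount: float = 1.0,
) -> NullModel:
    """Random-signature null for the score/marker correlation.

    Each draw samples k = len(signature) genes uniformly without replacement
    from the matrix genes minus ``gene`` and ``exclude``, recomputes the
    activation score with that random set, and records its Pearson r against
    the marker's log2 expression. A Gumbel is fitted to the null sample by
    method of moments and the observed correlation's upper-tail p is reported;
    with ``direction="auto"`` a negative observed correlation is assessed on
    the negated values (lower tail).
    """
    genes = list(signature)
    k = len(genes)
    if k == 0:
        raise ValidationError("signature is empty")
    tumor_samples = list(tumor_samples)
    normal_samples = list(normal_samples)

    observed_scores = activation_score(
        normalized_counts, genes, normal_samples, tumor_samples, scale, pseudocount
    )
    observed_r = score_gene_correlation(
        observed_scores, normalized_counts, gene, pseudocount
    )

    banned = set(exclude) | {gene}
    universe = [g for g in normalized_counts.index if g not in banned]
    if k > len(universe):
        raise ValidationError(
            f"signature size {k} exceeds the {len(universe)}-gene null universe"
        )

    # Per-gene fold-change matrix vs the normal reference, on the score scale.
    sub = normalized_counts.loc[universe]
    ref = sub[normal_samples].mean(axis=1)
    ratios = sub[tumor_samples].add(pseudocount).div(ref + pseudocount, axis=0)
    fc = np.log2(ratios).to_numpy() if scale == "log2" else ratios.to_numpy()

    rng = np.random.default_rng(seed)
    draws = np.empty((n_draws, k), dtype=np.int64)
    for i in range(n_draws):
        draws[i] = rng.choice(len(universe), size=k, replace=False)
    scores = _null_scores(fc, draws, scale)

    y = np.log2(
        normalized_counts.loc[gene, tumor_samples].to_numpy(dtype=float) + pseudocount
    )
    yc = y - y.mean()
    sc = scores - scores.mean(axis=1, keepdims=True)
    denom = np.sqrt((sc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore"):
        null_r = (sc @ yc) / denom

    if direction not in ("auto", "greater", "less"):
        raise ValidationError("direction must be 'auto', 'greater' or 'less'")
    tail = direction
    if direction == "auto":
        tail = "greater" if observed_r >= 0 else "less"
    if tail == "greater":
        mu, beta = fit_gumbel(null_r)
        p = gumbel_tail_p(observed_r, mu, beta)
    else:
        mu, beta = fit_gumbel(-null_r)
        p = gumbel_tail_p(-observed_r, mu, beta)

    return NullModel(
        k=k,
        n_draws=n_draws,
        seed=seed,
        null_r=np.asarray(null_r),
        gumbel_mu=mu,
        gumbel_beta=beta,
        observed_r=observed_r,
        p_value=p,
        direction=tail,
        gene=gene,
    )
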