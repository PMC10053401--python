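"""Signature scoring, descriptive structure, reduction and responder fractions.

A signature score is the unweighted arithmetic mean of the signature
genes' expression per sample, kept on the log2(TPM+1) scale so absolute
scores are comparable across cohorts (z-scoring is used only for
heatmap-style displays, never for scoring). On top of the score this
module provides the descriptive machinery used around a signature —
per-gene z-scaling, complete-linkage/Euclidean hierarchical clustering,
gene–gene correlation and pooled PCA — plus two decision tools:

* ``reduce_signature`` — greedy backward elimination of signature genes:
  at each step remove the single gene whose removal most increases
  |corr(score, ln EC50)|, stopping when no removal improves the
  correlation (or two genes remain);
* ``responder_fraction`` — per-cancer-entity fraction of tumors whose
  score lies at or below a sensitive reference line's score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .io_formats import ExpressionMatrix, SensitivityVector, SignatureSet

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreVector",
    "ClusterResult",
    "score_samples",
    "zscore_genes",
    "hclust_complete",
    "gene_gene_corr",
    "pca_on_signature",
    "reduce_signature",
    "responder_fraction",
]


@dataclass
class ScoreVector:
    """Mean signature-gene expression per sample."""

    signature: str
    score: pd.Series

    @property
    def sample_ids(self) -> list[str]:
        return list(self.score.index)


def score_samples(m: ExpressionMatrix, sig: SignatureSet) -> ScoreVector:
    """Arithmetic mean of the signature genes, per sample.

    Every signature gene must be present; a silent mean over a subset
    would not be comparable across matrices, so absentees are an error.
    """
    missing = [g for g in sig.genes if g not in m.values.columns]
    if missing:
        raise KeyError(f"signature genes missing from matrix: {missing}")
    return ScoreVector(sig.name, m.values[list(sig.genes)].mean(axis=1))


def zscore_genes(m: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene z-scores (mean 0, sd 1 with the n-1 denominator).

    Display-scaling for heatmaps/clustering; constant genes are an error
    because their z-score is undefined.
    """
    sd = m.values.std(axis=0, ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant gene(s), z-score undefined: {constant[:5]}")
    return (m.values - m.values.mean(axis=0)) / sd


@dataclass
class ClusterResult:
    """Complete-linkage / Euclidean agglomeration over genes or samples.

    ``merges`` is a SciPy-format linkage matrix over ``item_ids`` (items
    sorted lexicographically before clustering, which makes tie-breaking
    deterministic); complete linkage guarantees non-decreasing heights.
    """

    item_ids: list[str]
    merges: np.ndarray
    leaf_order: list[str]
    linkage_method: str = "complete"
    metric: str = "euclidean"

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def hclust_complete(m: ExpressionMatrix, axis: str = "genes") -> ClusterResult:
    """Agglomerative complete-linkage clustering on Euclidean distances."""
    if axis == "genes":
        data = m.values.T
    elif axis == "samples":
        data = m.values
    else:
        raise ValueError("axis must be 'genes' or 'samples'")
    if data.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    data = data.sort_index()  # lexicographic order -> deterministic ties
    ids = list(data.index)
    Z = linkage(pdist(data.to_numpy(dtype=float)), method="complete")
    order = [ids[i] for i in leaves_list(Z)]
    return ClusterResult(item_ids=ids, merges=Z, leaf_order=order)


def gene_gene_corr(m: ExpressionMatrix, sig: SignatureSet) -> pd.DataFrame:
    """Pearson gene–gene correlation matrix over the signature genes.

    Symmetric with a unit diagonal; constant genes are dropped (with a
    log message) rather than reported as NaN rows.
    """
    missing = [g for g in sig.genes if g not in m.values.columns]
    if missing:
        raise KeyError(f"signature genes missing from matrix: {missing}")
    if m.shape[0] < 4:
        raise ValueError("need >= 4 samples for gene-gene correlations")
    sub = m.values[list(sig.genes)]
    constant = [g for g in sub.columns if sub[g].nunique(dropna=True) <= 1]
    if constant:
        logger.info("dropping constant gene(s) from correlation: %s", constant)
        sub = sub.drop(columns=constant)
    corr = sub.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def pca_on_signature(cohorts: dict[str, ExpressionMatrix],
                     sig: SignatureSet) -> tuple[pd.DataFrame, np.ndarray]:
    """Joint PCA of several cohorts restricted to the signature genes.

    Cohorts are concatenated and centered on the pooled per-gene means
    (no per-cohort batch correction). Components come from the eigen-
    decomposition of the pooled gene–gene covariance, so coordinates do
    not depend on cohort order; each component's sign is fixed by making
    its largest-magnitude gene loading positive.

    Returns (table with columns cohort, PC1, PC2 indexed by sample id,
    explained-variance fractions for all components, non-increasing).
    """
    blocks = []
    labels = []
    for label, m in cohorts.items():
        missing = [g for g in sig.genes if g not in m.values.columns]
        if missing:
            raise KeyError(f"cohort {label!r} lacks signature genes: {missing}")
        blocks.append(m.values[list(sig.genes)])
        labels.extend([label] * m.shape[0])
    data = pd.concat(blocks, axis=0)
    if data.shape[0] < 2:
        raise ValueError("need at least 2 samples for PCA")
    centered = data - data.mean(axis=0)
    cov = np.cov(centered.to_numpy(dtype=float), rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0.0, None), evecs[:, order]
    for j in range(evecs.shape[1]):  # deterministic sign convention
        i = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    coords = centered.to_numpy(dtype=float) @ evecs[:, :2]
    table = pd.DataFrame(
        {"cohort": labels, "PC1": coords[:, 0], "PC2": coords[:, 1]}, index=data.index
    )
    total = evals.sum()
    explained = evals / total if total > 0 else evals
    return table, explained


def _abs_score_corr(m: ExpressionMatrix, genes: tuple[str, ...],
                    y: np.ndarray, sample_ids: list[str]) -> float:
    score = m.values.loc[sample_ids, list(genes)].mean(axis=1).to_numpy(dtype=float)
    if np.ptp(score) == 0:
        return 0.0
    return abs(float(stats.pearsonr(score, y)[0]))


def reduce_signature(sig: SignatureSet, m: ExpressionMatrix, s: SensitivityVector,
                     transform: str = "ln") -> tuple[SignatureSet, list[tuple[str, float]]]:
    """Greedy backward elimination of genes that dilute the score correlation.

    At each step the single gene whose removal maximizes
    |corr(score, transform(sensitivity))| is dropped (ties broken by gene
    symbol); elimination stops when no removal improves |r| or when two
    genes remain. Returns the reduced signature and the trace of
    (removed gene, achieved |r|), which is non-decreasing by construction.
    """
    from .association import _transformed_sensitivity  # shared transform rules

    y_all = _transformed_sensitivity(s, transform)
    shared = [sid for sid in m.sample_ids if sid in y_all.index]
    if len(shared) < 4:
        raise ValueError("need >= 4 shared samples")
    y = y_all.loc[shared].to_numpy(dtype=float)

    genes = tuple(sig.genes)
    missing = [g for g in genes if g not in m.values.columns]
    if missing:
        raise KeyError(f"signature genes missing from matrix: {missing}")

    current = _abs_score_corr(m, genes, y, shared)
    trace: list[tuple[str, float]] = []
    while len(genes) > 2:
        candidates = sorted(genes)
        best_gene, best_r = None, current
        for g in candidates:
            reduced = tuple(x for x in genes if x != g)
            r = _abs_score_corr(m, reduced, y, shared)
            if r > best_r:
                best_gene, best_r = g, r
        if best_gene is None:
            break
        genes = tuple(x for x in genes if x != best_gene)
        current = best_r
        trace.append((best_gene, best_r))
    return SignatureSet(f"{sig.name}-reduced", genes), trace


def responder_fraction(scores: pd.Series, entities: pd.Series,
                       reference_score: float) -> pd.DataFrame:
    """Per-entity fraction of tumors scoring at or below the reference.

    ``scores`` and ``entities`` are aligned by sample id; ties with the
    reference count as responders. Entities with no scored tumors are
    omitted with a log message.
    """
    joined = pd.DataFrame({"score": scores, "entity": entities}).dropna(subset=["score", "entity"])
    dropped = set(entities.dropna().unique()) - set(joined["entity"].unique())
    if dropped:
        logger.info("omitting entities with no scored tumors: %s", sorted(dropped))
    grouped = joined.groupby("entity")["score"]
    out = pd.DataFrame(
        {
            "n": grouped.size(),
            "mean_score": grouped.mean(),
            "responder_fraction": grouped.apply(lambda g: float((g <= reference_score).mean())),
        }
    )
    out.index.name = "entity"
    return out
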