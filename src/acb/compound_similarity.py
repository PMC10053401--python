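"""Compound similarity in signature-correlation space and ROC enrichment.

Every screened compound is summarized by a correlation vector: one
Pearson coefficient per signature gene, correlating that gene's
expression with the compound's response (AUC, or EC50 for the reference)
across the cell-line panel. Compounds whose response tracks the same
transcriptional program as the reference land close to it in Euclidean
distance over these vectors. Ranking the library by that distance and
walking down the list yields an ROC-style enrichment of compounds
annotated as chemically reactive (electrophilic pharmacophores such as
Michael acceptors), plus a fold enrichment at a distance cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, SignatureSet
from .synthetic_data import CompoundLibrary

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundProfile",
    "EnrichmentResult",
    "FoldEnrichment",
    "correlation_vector",
    "distance_to_reference",
    "profile_library",
    "rank_by_distance",
    "roc_reactive",
    "fold_enrichment",
    "cutoff_for_top_k",
]


@dataclass
class CompoundProfile:
    """One compound's place in signature-correlation space."""

    compound_id: str
    response: pd.Series
    reactive: bool
    is_reference: bool = False
    corr_vector: np.ndarray | None = None
    distance: float | None = None
    relative_distance: float | None = None


def correlation_vector(m: ExpressionMatrix, sig: SignatureSet,
                       response: pd.Series) -> np.ndarray:
    """Per-signature-gene Pearson r with the compound's response.

    Genes appear in signature order; samples with a missing response are
    dropped pairwise. A constant response (correlation undefined) raises
    ``ValueError`` so the compound can be excluded and logged upstream.
    """
    missing = [g for g in sig.genes if g not in m.values.columns]
    if missing:
        raise KeyError(f"signature genes missing from matrix: {missing}")
    shared = [sid for sid in m.sample_ids if sid in response.index]
    if len(shared) < 4:
        raise ValueError(f"only {len(shared)} shared samples; need >= 4")
    y = response.loc[shared].to_numpy(dtype=float)
    ok = np.isfinite(y)
    y = y[ok]
    if y.size < 4:
        raise ValueError("fewer than 4 non-missing response values")
    if np.ptp(y) == 0:
        raise ValueError("constant response: correlation undefined")
    X = m.values.loc[shared, list(sig.genes)].to_numpy(dtype=float)[ok]
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((Xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / denom
    return r


def distance_to_reference(v: np.ndarray, v_ref: np.ndarray) -> float:
    """Euclidean distance between two correlation vectors (same gene order)."""
    v = np.asarray(v, dtype=float)
    v_ref = np.asarray(v_ref, dtype=float)
    if v.shape != v_ref.shape:
        raise ValueError(f"length mismatch: {v.shape} vs {v_ref.shape}")
    return float(np.linalg.norm(v - v_ref))


def profile_library(m: ExpressionMatrix, sig: SignatureSet,
                    library: CompoundLibrary) -> list[CompoundProfile]:
    """Compute correlation vectors and distances for a whole library.

    Compounds whose correlation vector is undefined (constant response,
    or a gene constant over the compound's screened subset) are dropped
    with a log message rather than imputed. Relative distance is distance
    divided by the maximum observed distance (reported, never used for
    cutoffs).
    """
    profiles: list[CompoundProfile] = []
    for spec in library.compounds:
        try:
            vec = correlation_vector(m, sig, spec.response)
        except ValueError as exc:
            logger.info("dropping compound %s: %s", spec.compound_id, exc)
            continue
        if not np.all(np.isfinite(vec)):
            logger.info("dropping compound %s: undefined correlation entries", spec.compound_id)
            continue
        profiles.append(CompoundProfile(spec.compound_id, spec.response, spec.reactive,
                                        spec.is_reference, corr_vector=vec))
    ref = next((p for p in profiles if p.compound_id == library.reference_id), None)
    if ref is None:
        raise KeyError(f"reference compound {library.reference_id!r} not in profiled library")
    for p in profiles:
        p.distance = distance_to_reference(p.corr_vector, ref.corr_vector)
    max_d = max(p.distance for p in profiles)
    for p in profiles:
        p.relative_distance = p.distance / max_d if max_d > 0 else 0.0
    return profiles


def rank_by_distance(profiles: list[CompoundProfile],
                     reference_id: str) -> list[CompoundProfile]:
    """Sort by ascending distance to the reference, which is excluded.

    Ties are broken by compound id, so the ranking is invariant to the
    input order.
    """
    ids = {p.compound_id for p in profiles}
    if reference_id not in ids:
        raise KeyError(f"reference compound {reference_id!r} not found")
    ranked = [p for p in profiles if p.compound_id != reference_id]
    if any(p.distance is None for p in ranked):
        raise ValueError("profiles must carry distances (run profile_library first)")
    ranked.sort(key=lambda p: (p.distance, p.compound_id))
    return ranked


@dataclass
class EnrichmentResult:
    """Ranked list plus the reactive-enrichment ROC.

    ``curve`` has one row per ranked compound: ``rank_fraction`` (position
    / library size), ``recall`` (cumulative fraction of all reactive
    compounds found) and ``precision`` (reactive fraction within the
    prefix). ``roc_auc`` is the standard trapezoidal area with the
    false-positive rate on x, so a reactive-first ranking scores exactly 1
    and reversing the ranking maps the area to its complement.
    """

    ranked_ids: list[str]
    reactive: list[bool]
    curve: pd.DataFrame
    roc_auc: float


def roc_reactive(ranked: list[CompoundProfile]) -> EnrichmentResult:
    """ROC enrichment of the reactive annotation along the distance ranking."""
    flags = np.array([p.reactive for p in ranked], dtype=bool)
    n_pos = int(flags.sum())
    n_neg = int(flags.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one reactive and one non-reactive compound")
    cum_pos = np.cumsum(flags)
    cum_neg = np.cumsum(~flags)
    tpr = cum_pos / n_pos
    fpr = cum_neg / n_neg
    ranks = np.arange(1, flags.size + 1)
    curve = pd.DataFrame(
        {
            "rank_fraction": ranks / flags.size,
            "recall": tpr,
            "precision": cum_pos / ranks,
        },
        index=[p.compound_id for p in ranked],
    )
    auc = float(np.trapezoid(np.concatenate([[0.0], tpr]), np.concatenate([[0.0], fpr])))
    return EnrichmentResult(
        ranked_ids=[p.compound_id for p in ranked],
        reactive=flags.tolist(),
        curve=curve,
        roc_auc=auc,
    )


@dataclass
class FoldEnrichment:
    """Reactive enrichment within the distance-< cutoff set."""

    cutoff: float
    set_size: int
    reactive_in_set: int
    total: int
    total_reactive: int
    fold: float | None  # None when the cutoff selects nothing


def fold_enrichment(ranked: list[CompoundProfile], cutoff: float) -> FoldEnrichment:
    """Fold enrichment of reactive compounds at distance < cutoff (strict).

    fold = (reactive_in_set / set_size) / (total_reactive / total); an
    empty selection leaves the fold undefined (None) but still reports
    the counts.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    total = len(ranked)
    total_reactive = sum(p.reactive for p in ranked)
    in_set = [p for p in ranked if p.distance < cutoff]
    set_size = len(in_set)
    reactive_in = sum(p.reactive for p in in_set)
    if set_size == 0 or total_reactive == 0:
        logger.info("empty selection or no reactive compounds; fold undefined")
        fold = None
    else:
        fold = (reactive_in / set_size) / (total_reactive / total)
    return FoldEnrichment(cutoff=float(cutoff), set_size=set_size,
                          reactive_in_set=reactive_in, total=total,
                          total_reactive=total_reactive, fold=fold)


def cutoff_for_top_k(ranked: list[CompoundProfile], k: int) -> float:
    """Distance cutoff whose strict-< set is the k nearest compounds."""
    if not 1 <= k <= len(ranked):
        raise ValueError("k out of range")
    if k == len(ranked):
        return float(np.nextafter(ranked[-1].distance, np.inf))
    d_k, d_next = ranked[k - 1].distance, ranked[k].distance
    if d_k == d_next:
        logger.info("tied distances at the top-%d boundary; set may exceed k", k)
    return float(d_next) if d_next > d_k else float(np.nextafter(d_k, np.inf))


def corr_vector_matrix(profiles: list[CompoundProfile], sig: SignatureSet,
                       top_k: int | None = None,
                       reference_id: str | None = None) -> pd.DataFrame:
    """Genes × compounds matrix of correlation vectors (heatmap-ready).

    With ``top_k`` only the k compounds nearest the reference (plus the
    reference itself, if given) are kept.
    """
    chosen = profiles
    if top_k is not None:
        ref = [p for p in profiles if reference_id and p.compound_id == reference_id]
        others = sorted((p for p in profiles if p not in ref),
                        key=lambda p: (p.distance, p.compound_id))
        chosen = ref + others[:top_k]
    data = {p.compound_id: p.corr_vector for p in chosen}
    return pd.DataFrame(data, index=list(sig.genes))
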