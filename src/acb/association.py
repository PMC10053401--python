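"""Gene-wise sensitivity association and rank-combined signature selection.

The discovery procedure: correlate every feature of an omics layer with a
per-sample drug-sensitivity vector (Pearson, two-sided p from the exact t
transform), rank features within each layer by ascending p-value (lower
p → lower rank, average ranks at ties), average the expression and
proteomics ranks over the features shared by both layers, and select the
signature as all features whose average rank falls strictly below a
cutoff (default 38).

Sensitivity is correlated on the ln(EC50) scale by default; pass
``transform="identity"`` to correlate the raw metric. Missing values are
removed pairwise per feature; features that are constant (or have fewer
than 4 complete pairs) are skipped with a logged reason rather than being
reported with r = 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, SensitivityVector, SignatureSet

logger = logging.getLogger(__name__)

__all__ = [
    "LayerAssociation",
    "CombinedAssociation",
    "pearson_with_p",
    "associate_layer",
    "combine_layers",
    "select_signature",
    "filter_by_p",
    "layer_table",
    "combined_table",
]

_MIN_PAIRS = 4
_P_FLOOR = np.finfo(float).tiny  # smallest positive normal double


@dataclass
class LayerAssociation:
    """Per-feature correlation with sensitivity within one omics layer."""

    feature_id: str
    r: float
    p: float
    n_used: int
    rank: float = math.nan


@dataclass
class CombinedAssociation:
    """Expression + proteomics evidence for one shared feature."""

    feature_id: str
    r_expr: float
    r_prot: float
    avg_r: float
    rank_expr: float
    rank_prot: float
    avg_rank: float


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Pearson r with a two-sided p-value after pairwise deletion.

    p comes from t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom;
    a numerically-zero p (|r| = 1) is reported as the smallest positive
    double. Raises ``ValueError`` on constant input or fewer than 4
    complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < _MIN_PAIRS:
        raise ValueError(f"need >= {_MIN_PAIRS} complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(max(p, _P_FLOOR)), int(n)


def _transformed_sensitivity(s: SensitivityVector, transform: str) -> pd.Series:
    if transform == "ln":
        return s.ln().values if s.metric == "ec50" else np.log(s.values)
    if transform == "identity":
        return s.values
    raise ValueError("transform must be 'ln' or 'identity'")


def associate_layer(m: ExpressionMatrix, s: SensitivityVector,
                    transform: str = "ln") -> list[LayerAssociation]:
    """Correlate every feature of one layer with (transformed) sensitivity.

    Returns one record per non-skipped feature with ranks assigned by
    ascending p-value (average ranks at ties). Requires at least 4 shared
    samples between the matrix and the sensitivity vector.
    """
    y_all = _transformed_sensitivity(s, transform)
    shared = [sid for sid in m.sample_ids if sid in y_all.index]
    if not shared:
        raise ValueError("no shared samples between matrix and sensitivity")
    if len(shared) < _MIN_PAIRS:
        raise ValueError(f"only {len(shared)} shared samples; need >= {_MIN_PAIRS}")
    X = m.values.loc[shared]
    y = y_all.loc[shared].to_numpy(dtype=float)

    records: list[LayerAssociation] = []
    Xv = X.to_numpy(dtype=float)
    y_ok = np.isfinite(y)
    for j, feat in enumerate(X.columns):
        x = Xv[:, j]
        ok = np.isfinite(x) & y_ok
        n = int(ok.sum())
        if n < _MIN_PAIRS:
            logger.info("skipping %s: only %d complete pairs", feat, n)
            continue
        xs, ys = x[ok], y[ok]
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            logger.info("skipping %s: constant vector", feat)
            continue
        r, p = stats.pearsonr(xs, ys)
        records.append(LayerAssociation(feat, float(r), float(max(p, _P_FLOOR)), n))

    ranks = stats.rankdata([rec.p for rec in records], method="average")
    for rec, rank in zip(records, ranks):
        rec.rank = float(rank)
    return records


def combine_layers(a_expr: list[LayerAssociation],
                   a_prot: list[LayerAssociation]) -> list[CombinedAssociation]:
    """Average per-layer p-value ranks over the shared-feature universe.

    Ranks are re-computed within the features present in both layers
    before averaging, so the combination is symmetric in its two inputs.
    Output is sorted by ascending average rank (ties by feature id).
    """
    by_expr = {a.feature_id: a for a in a_expr}
    by_prot = {a.feature_id: a for a in a_prot}
    shared = sorted(set(by_expr) & set(by_prot))
    if not shared:
        raise ValueError("no features shared between the two layers")
    re_expr = stats.rankdata([by_expr[f].p for f in shared], method="average")
    re_prot = stats.rankdata([by_prot[f].p for f in shared], method="average")
    combined = [
        CombinedAssociation(
            feature_id=f,
            r_expr=by_expr[f].r,
            r_prot=by_prot[f].r,
            avg_r=(by_expr[f].r + by_prot[f].r) / 2.0,
            rank_expr=float(re),
            rank_prot=float(rp),
            avg_rank=(float(re) + float(rp)) / 2.0,
        )
        for f, re, rp in zip(shared, re_expr, re_prot)
    ]
    combined.sort(key=lambda c: (c.avg_rank, c.feature_id))
    return combined


def select_signature(combined: list[CombinedAssociation],
                     avg_rank_cutoff: float = 38.0,
                     name: str = "signature") -> SignatureSet:
    """Select features with average rank strictly below the cutoff."""
    genes = [c.feature_id for c in sorted(combined, key=lambda c: (c.avg_rank, c.feature_id))
             if c.avg_rank < avg_rank_cutoff]
    if not genes:
        best = min((c.avg_rank for c in combined), default=math.nan)
        raise ValueError(
            f"no feature has avg_rank < {avg_rank_cutoff} (best is {best}); raise the cutoff"
        )
    return SignatureSet(name, tuple(genes))


def filter_by_p(assocs: list[LayerAssociation], p_cutoff: float) -> list[LayerAssociation]:
    """Strict p < cutoff subset (e.g. the methylation-layer screen at 0.001)."""
    return [a for a in assocs if a.p < p_cutoff]


def layer_table(assocs: list[LayerAssociation], bh: bool = False) -> pd.DataFrame:
    """Tabulate one layer; ``bh=True`` adds a Benjamini–Hochberg column
    (reporting only — selection is rank-based, not FDR-based)."""
    frame = pd.DataFrame(
        {
            "feature": [a.feature_id for a in assocs],
            "r": [a.r for a in assocs],
            "p": [a.p for a in assocs],
            "n_used": [a.n_used for a in assocs],
            "rank": [a.rank for a in assocs],
        }
    ).set_index("feature")
    if bh and len(frame):
        frame["p_bh"] = stats.false_discovery_control(frame["p"].to_numpy(), method="bh")
    return frame


def combined_table(combined: list[CombinedAssociation]) -> pd.DataFrame:
    """Volcano-ready table: per-feature average r and average p-value rank."""
    return pd.DataFrame(
        {
            "feature": [c.feature_id for c in combined],
            "r_expr": [c.r_expr for c in combined],
            "r_prot": [c.r_prot for c in combined],
            "avg_r": [c.avg_r for c in combined],
            "rank_expr": [c.rank_expr for c in combined],
            "rank_prot": [c.rank_prot for c in combined],
            "avg_rank": [c.avg_rank for c in combined],
        }
    ).set_index("feature")
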