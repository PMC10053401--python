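"""Tabular I/O, expression-unit conversions and bundled gene signatures.

The pipeline exchanges three kinds of tables:

* sample-by-feature numeric matrices (expression, proteomics, promoter
  methylation), canonically TSV with the sample id in the first column and
  one feature per remaining column;
* per-sample drug-sensitivity vectors (EC50 in µM, ln EC50, or AUC) as
  two-column tables;
* gene signatures, either as JSON ``{"name": ..., "genes": [...]}`` or as
  one gene symbol per line.

Missing values are written as ``NA`` and propagated as NaN; downstream
statistics handle them by pairwise deletion. Expression is kept on the
log2(TPM+1) scale throughout, the common unit for all cross-cohort
comparisons.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Layer",
    "Units",
    "ExpressionMatrix",
    "SensitivityVector",
    "SignatureSet",
    "read_matrix",
    "write_matrix",
    "read_sensitivity",
    "write_sensitivity",
    "rpkm_to_log2tpm",
    "load_builtin_signature",
    "read_signature",
    "write_signature",
    "BUILTIN_SIGNATURES",
]


class Layer(str, Enum):
    """Omics layer a matrix belongs to."""

    expression = "expression"
    proteomics = "proteomics"
    methylation = "methylation"


class Units(str, Enum):
    """Measurement units of a matrix."""

    log2tpm1 = "log2tpm1"
    normalized_protein = "normalized_protein"
    beta = "beta"
    raw_tpm = "raw_tpm"
    rpkm = "rpkm"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} ids: {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """Samples × features numeric matrix with a layer and unit tag.

    ``values`` is a pandas DataFrame indexed by sample id with feature ids
    as columns. Sample and feature ids must be unique; log2(TPM+1) values
    must be non-negative (NaN entries are allowed and mean "missing").
    """

    values: pd.DataFrame
    layer: Layer = Layer.expression
    units: Units = Units.log2tpm1

    def __post_init__(self) -> None:
        self.layer = Layer(self.layer)
        self.units = Units(self.units)
        _check_unique(self.values.index, "sample")
        _check_unique(self.values.columns, "feature")
        vals = self.values.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("matrix values must be numeric")
        if self.units is Units.log2tpm1 and np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("log2(TPM+1) values cannot be negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_features(self, features: Sequence[str]) -> "ExpressionMatrix":
        missing = [f for f in features if f not in self.values.columns]
        if missing:
            raise KeyError(f"features not in matrix: {missing}")
        return ExpressionMatrix(self.values.loc[:, list(features)], self.layer, self.units)


@dataclass
class SensitivityVector:
    """Per-sample drug-response scalar aligned to a matrix by sample id.

    ``metric`` is one of ``ec50`` (µM, strictly positive), ``ln_ec50`` or
    ``auc``. ``ln()`` converts an EC50 vector to natural-log units, the
    scale on which associations are computed by default.
    """

    values: pd.Series
    metric: str = "ec50"

    _METRICS = ("ec50", "ln_ec50", "auc")

    def __post_init__(self) -> None:
        if self.metric not in self._METRICS:
            raise ValueError(f"metric must be one of {self._METRICS}")
        _check_unique(self.values.index, "sample")
        self.values = self.values.astype(float)
        if self.metric == "ec50" and np.nanmin(self.values.to_numpy(), initial=np.inf) <= 0:
            raise ValueError("EC50 values must be strictly positive")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def ln(self) -> "SensitivityVector":
        """Natural log of an EC50 vector; identity on an ln_ec50 vector."""
        if self.metric == "ln_ec50":
            return self
        if self.metric != "ec50":
            raise ValueError("ln() is defined for EC50 vectors only")
        return SensitivityVector(np.log(self.values), metric="ln_ec50")


@dataclass(frozen=True)
class SignatureSet:
    """Ordered gene list scored as the unweighted mean expression."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        if len(self.genes) < 2:
            raise ValueError("a signature needs at least 2 genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")

    def __len__(self) -> int:
        return len(self.genes)

    def without(self, drop: Iterable[str], name: str | None = None) -> "SignatureSet":
        drop = set(drop)
        unknown = drop - set(self.genes)
        if unknown:
            raise KeyError(f"genes not in signature: {sorted(unknown)}")
        kept = tuple(g for g in self.genes if g not in drop)
        return SignatureSet(name or f"{self.name}-reduced", kept)


# The 15-gene antioxidant-capacity biomarker (ACB) set: NADPH regeneration
# (ME1, PGD, UGDH), antioxidation (GCLM, GSR, SLC7A11, TXN, AIFM2) and
# detoxification (CBR1, BLVRB, AKR1C1, AKR1C3, PTGR1, ALDH3A1, CYP4F11).
# AIFM2 is also known as FSP1. ACB11 is the reduced set after iterative
# elimination of the four members with minor contribution to the drug
# sensitivity correlation.
_ACB15 = (
    "ME1", "PGD", "UGDH",
    "GCLM", "GSR", "SLC7A11", "TXN", "AIFM2",
    "CBR1", "BLVRB", "AKR1C1", "AKR1C3", "PTGR1", "ALDH3A1", "CYP4F11",
)
_ACB11_DROPPED = ("AKR1C1", "BLVRB", "GSR", "PTGR1")

BUILTIN_SIGNATURES = {
    "ACB15": SignatureSet("ACB15", _ACB15),
    "ACB11": SignatureSet("ACB11", tuple(g for g in _ACB15 if g not in _ACB11_DROPPED)),
}


def load_builtin_signature(name: str) -> SignatureSet:
    """Return a bundled signature ("ACB15" or its 11-gene reduction "ACB11")."""
    try:
        return BUILTIN_SIGNATURES[name]
    except KeyError:
        raise KeyError(
            f"unknown signature {name!r}; available: {sorted(BUILTIN_SIGNATURES)}"
        ) from None


_NA_TOKENS = {"NA", "NaN", "nan", ""}


def _sniff_delimiter(header: str) -> str:
    return "\t" if "\t" in header else ","


def read_matrix(path: str | Path, layer: Layer | str = Layer.expression,
                units: Units | str = Units.log2tpm1) -> ExpressionMatrix:
    """Read a TSV/CSV matrix (first column sample id, header of feature ids).

    The delimiter is sniffed from the header line. Ragged rows, duplicate
    ids and non-numeric cells raise ``ValueError`` naming the offending
    row/column; ``NA`` cells become NaN.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise ValueError(f"{path}: empty file")
        delim = _sniff_delimiter(first)
        fh.seek(0)
        reader = csv.reader(fh, delimiter=delim)
        header = next(reader)
        features = [h.strip() for h in header[1:]]
        _check_unique(features, "feature")
        sample_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(header):
                raise ValueError(
                    f"{path}: row {lineno} has {len(row)} fields, expected {len(header)}"
                )
            sample_ids.append(row[0].strip())
            parsed = []
            for col, tok in zip(features, row[1:]):
                tok = tok.strip()
                if tok in _NA_TOKENS:
                    parsed.append(np.nan)
                    continue
                try:
                    parsed.append(float(tok))
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric cell {tok!r} at row {lineno}, column {col!r}"
                    ) from None
            rows.append(parsed)
    _check_unique(sample_ids, "sample")
    frame = pd.DataFrame(rows, index=sample_ids, columns=features, dtype=float)
    return ExpressionMatrix(frame, layer=layer, units=units)


def write_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV with ≥12 significant digits (round-trip safe)."""
    m.values.to_csv(path, sep="\t", float_format="%.12g", na_rep="NA",
                    index_label="sample")


def read_sensitivity(path: str | Path, metric: str = "ec50") -> SensitivityVector:
    """Read a two-column (sample, value) TSV/CSV sensitivity table."""
    path = Path(path)
    with path.open(newline="") as fh:
        delim = _sniff_delimiter(fh.readline())
    frame = pd.read_csv(path, sep=delim, index_col=0)
    if frame.shape[1] != 1:
        raise ValueError(f"{path}: expected exactly one value column, got {frame.shape[1]}")
    return SensitivityVector(frame.iloc[:, 0].astype(float), metric=metric)


def write_sensitivity(s: SensitivityVector, path: str | Path) -> None:
    s.values.to_frame(s.metric).to_csv(path, sep="\t", float_format="%.12g",
                                       na_rep="NA", index_label="sample")


def rpkm_to_log2tpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Convert an RPKM matrix to log2(TPM+1), per sample.

    TPM_g = RPKM_g / Σ_g RPKM_g × 1e6 within each sample, then log2(TPM+1).
    Scale-invariant per sample; a sample whose RPKM sum is zero is an error.
    """
    if m.units is not Units.rpkm:
        raise ValueError(f"expected units=rpkm, got {m.units.value}")
    vals = m.values.to_numpy(dtype=float)
    if np.nanmin(vals, initial=0.0) < 0:
        raise ValueError("RPKM values cannot be negative")
    totals = np.nansum(vals, axis=1)
    if np.any(totals <= 0):
        bad = [m.sample_ids[i] for i in np.nonzero(totals <= 0)[0]]
        raise ValueError(f"all-zero sample(s), cannot normalize: {bad[:5]}")
    tpm = vals / totals[:, None] * 1e6
    out = pd.DataFrame(np.log2(tpm + 1.0), index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(out, layer=m.layer, units=Units.log2tpm1)


def read_signature(path: str | Path) -> SignatureSet:
    """Read a signature from JSON ``{name, genes}`` or one-symbol-per-line text."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("{"):
        obj = json.loads(text)
        return SignatureSet(obj["name"], tuple(obj["genes"]))
    genes = tuple(line.strip() for line in text.splitlines() if line.strip())
    return SignatureSet(path.stem, genes)


def write_signature(sig: SignatureSet, path: str | Path) -> None:
    Path(path).write_text(json.dumps({"name": sig.name, "genes": list(sig.genes)}, indent=2) + "\n")
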