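"""Synthetic multi-omics panels with planted ground truth.

Every input the pipeline consumes can be generated here, so the whole
analysis is testable without any external download:

* ``generate_panel`` — a cell-line panel (default 31 samples × 2000 genes
  on the log2(TPM+1) scale) containing a planted block of co-regulated
  signature genes whose mean expression correlates with ln(EC50) at a
  configurable strength, plus a noisy proteomics layer derived from the
  expression layer.
* ``generate_compound_library`` — a drug screen in which a configurable
  fraction of "reactive" compounds share the reference compound's
  response profile (their AUC vectors track the signature score), the
  rest being inert noise.
* ``generate_dose_response`` / ``generate_growth_counts`` — viability
  curves and nuclei counts with known ground-truth parameters.

The planted block is built from a single latent Gaussian factor shared
with ln(EC50); the factor loadings are calibrated analytically (no
rejection sampling) so the *expected* correlation between the planted
block's mean and ln(EC50) equals ``target_r``. Low signature expression
corresponds to low EC50 (sensitive lines), i.e. the correlation is
positive, matching a signature that is repressed in sensitive cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dose_response import DoseResponseCurve, GRInput, four_pl
from .io_formats import ExpressionMatrix, Layer, SensitivityVector, SignatureSet, Units

__all__ = [
    "SyntheticConfig",
    "PanelBundle",
    "CompoundLibrary",
    "generate_panel",
    "generate_dose_response",
    "generate_compound_library",
    "generate_growth_counts",
]

# fixed per-component stream offsets derived from the master seed
_STREAM_PANEL = 11
_STREAM_PROTEOMICS = 12
_STREAM_COMPOUNDS = 13
_STREAM_DOSE = 14
_STREAM_GROWTH = 15


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(stream))))


@dataclass
class SyntheticConfig:
    """Study-condition parameters for the synthetic panel.

    Defaults mirror the real discovery setting: a 31-line panel, 2000
    protein-coding genes, a 15-gene planted signature whose score
    correlates with ln(EC50) at r = 0.86, and a 543-compound library of
    which 125 are reactive.
    """

    n_samples: int = 31
    n_genes: int = 2000
    n_signature: int = 15
    target_r: float = 0.86
    within_block_r: float = 0.7
    proteomics_noise_sd: float = 0.5
    n_compounds: int = 543
    frac_reactive: float = 125 / 543
    compound_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4 (correlation p-values degenerate)")
        if not 0 < self.n_signature < self.n_genes:
            raise ValueError("need 0 < n_signature < n_genes")
        if abs(self.target_r) > 1:
            raise ValueError("|target_r| must be <= 1")
        if not 0 <= self.within_block_r <= 1:
            raise ValueError("within_block_r must be in [0, 1]")
        if not 0 <= self.frac_reactive <= 1:
            raise ValueError("frac_reactive must be in [0, 1]")
        if self.proteomics_noise_sd < 0 or self.compound_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")


@dataclass
class PanelBundle:
    """Generated panel: expression + proteomics layers, sensitivity, truth."""

    expression: ExpressionMatrix
    proteomics: ExpressionMatrix
    sensitivity: SensitivityVector
    truth: list[str]

    def __post_init__(self) -> None:
        ids = self.expression.sample_ids
        if self.proteomics.sample_ids != ids or self.sensitivity.sample_ids != ids:
            raise ValueError("sample ids must be identical and identically ordered")
        missing = set(self.truth) - set(self.expression.feature_ids)
        if missing:
            raise ValueError(f"truth genes absent from expression: {sorted(missing)}")

    def truth_signature(self, name: str = "planted") -> SignatureSet:
        return SignatureSet(name, tuple(self.truth))


def _score_factor_correlation(within_block_r: float, k: int) -> float:
    """Correlation between the planted-block mean and the latent factor."""
    w = within_block_r
    return float(np.sqrt(w / (w + (1.0 - w) / k))) if w < 1.0 else 1.0


def generate_panel(config: SyntheticConfig) -> PanelBundle:
    """Generate expression, proteomics and EC50 data with a planted signature.

    Planted gene j is ``mu + sd * (sqrt(w) * f + sqrt(1-w) * e_j)`` with a
    shared latent factor ``f`` per sample, so planted genes have pairwise
    correlation ≈ ``within_block_r``. ln(EC50) loads on the same factor
    with a weight chosen analytically so that the expected correlation of
    the block mean with ln(EC50) equals ``target_r``. Background genes are
    independent noise on the log2(TPM+1) scale; all expression is floored
    at 0. Proteomics is the expression layer plus i.i.d. Gaussian noise.
    """
    cfg = config
    n, p, k = cfg.n_samples, cfg.n_genes, cfg.n_signature
    c_sf = _score_factor_correlation(cfg.within_block_r, k)
    rho_f = cfg.target_r / c_sf if c_sf > 0 else 0.0
    if (c_sf == 0 and cfg.target_r != 0) or abs(rho_f) > 1:
        raise ValueError(
            f"target_r={cfg.target_r} unreachable: the block mean correlates with "
            f"its latent factor at only {c_sf:.3f} (raise within_block_r or n_signature)"
        )

    rng = _rng(cfg.seed, _STREAM_PANEL)
    f = rng.standard_normal(n)

    sample_ids = [f"CL{i:03d}" for i in range(n)]
    sig_genes = [f"SIG{j:04d}" for j in range(k)]
    bg_genes = [f"GENE{j:05d}" for j in range(p - k)]

    w = cfg.within_block_r
    mu_sig, sd_sig = 6.0, 1.2
    eps = rng.standard_normal((n, k))
    block = mu_sig + sd_sig * (np.sqrt(w) * f[:, None] + np.sqrt(1.0 - w) * eps)

    # background: per-gene baseline means spanning the typical log2(TPM+1) range
    bg_mu = rng.uniform(0.5, 8.0, size=p - k)
    bg = bg_mu[None, :] + rng.standard_normal((n, p - k))

    expr = np.clip(np.concatenate([block, bg], axis=1), 0.0, None)
    frame = pd.DataFrame(expr, index=sample_ids, columns=sig_genes + bg_genes)

    # ln(EC50) shares the latent factor; EC50 centred near 2 µM
    eta = rng.standard_normal(n)
    ln_ec50 = np.log(2.0) + 1.2 * (rho_f * f + np.sqrt(max(0.0, 1.0 - rho_f**2)) * eta)
    sens = SensitivityVector(pd.Series(np.exp(ln_ec50), index=sample_ids), metric="ec50")

    prot_rng = _rng(cfg.seed, _STREAM_PROTEOMICS)
    prot = frame + prot_rng.standard_normal(frame.shape) * cfg.proteomics_noise_sd

    return PanelBundle(
        expression=ExpressionMatrix(frame, Layer.expression, Units.log2tpm1),
        proteomics=ExpressionMatrix(prot, Layer.proteomics, Units.normalized_protein),
        sensitivity=sens,
        truth=sig_genes,
    )


def generate_dose_response(ec50: float, hill: float, top: float, bottom: float,
                           concentrations: Sequence[float], noise_sd: float = 0.0,
                           replicates: int = 1, seed: int = 0) -> DoseResponseCurve:
    """Noisy 4PL viability measurements with known true parameters."""
    if ec50 <= 0:
        raise ValueError("ec50 must be positive")
    c = np.asarray(concentrations, dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentrations must be strictly positive")
    rng = _rng(seed, _STREAM_DOSE)
    clean = four_pl(c, ec50, hill, top, bottom)
    v = clean[:, None] + rng.standard_normal((c.size, replicates)) * noise_sd
    return DoseResponseCurve(concentrations=c, viability=v)


@dataclass
class CompoundProfileSpec:
    """One library member before correlation profiling."""

    compound_id: str
    response: pd.Series  # AUC (or rescaled lnEC50 for the reference) per sample
    reactive: bool
    is_reference: bool = False


@dataclass
class CompoundLibrary:
    """Generated screen: response vectors plus reactive annotations."""

    compounds: list[CompoundProfileSpec]
    reference_id: str

    def responses(self) -> pd.DataFrame:
        return pd.DataFrame({c.compound_id: c.response for c in self.compounds})

    def reactive_flags(self) -> pd.Series:
        return pd.Series({c.compound_id: c.reactive for c in self.compounds})


def generate_compound_library(bundle: PanelBundle, signature: SignatureSet,
                              config: SyntheticConfig) -> CompoundLibrary:
    """Simulate a compound screen over the panel's samples.

    Reactive compounds' AUC vectors are (noisy) linear transforms of the
    signature score, so their gene-correlation vectors resemble the
    reference compound's; inert compounds are independent noise. The
    designated reference compound ("reference") carries the panel's own
    ln(EC50), rescaled to the AUC range, and is flagged reactive.
    """
    missing = set(signature.genes) - set(bundle.expression.feature_ids)
    if missing:
        raise KeyError(f"signature genes absent from panel: {sorted(missing)}")
    n_reactive = int(round(config.n_compounds * config.frac_reactive))
    if config.n_compounds * config.frac_reactive < 1 and config.frac_reactive > 0:
        warnings.warn("n_compounds * frac_reactive < 1; emitting zero reactive compounds")
        n_reactive = 0

    score = bundle.expression.values[list(signature.genes)].mean(axis=1)
    z = (score - score.mean()) / score.std(ddof=1)
    rng = _rng(config.seed, _STREAM_COMPOUNDS)
    samples = bundle.expression.sample_ids
    n = len(samples)

    # AUC on a nominal 0..16 scale, lower = more sensitive
    def to_auc(u: np.ndarray) -> pd.Series:
        return pd.Series(8.0 + 2.0 * u, index=samples)

    ln_ec50 = np.log(bundle.sensitivity.values.to_numpy())
    ref = CompoundProfileSpec(
        compound_id="reference",
        response=to_auc((ln_ec50 - ln_ec50.mean()) / ln_ec50.std(ddof=1)),
        reactive=True,
        is_reference=True,
    )

    compounds = [ref]
    order = rng.permutation(config.n_compounds)
    reactive_set = set(order[:n_reactive].tolist())
    for i in range(config.n_compounds):
        noise = rng.standard_normal(n)
        if i in reactive_set:
            u = z.to_numpy() + config.compound_noise_sd * noise
            u = u / np.sqrt(1.0 + config.compound_noise_sd**2)
            compounds.append(CompoundProfileSpec(f"CPD{i:04d}", to_auc(u), reactive=True))
        else:
            compounds.append(CompoundProfileSpec(f"CPD{i:04d}", to_auc(noise), reactive=False))
    return CompoundLibrary(compounds=compounds, reference_id="reference")


def generate_growth_counts(gr_true: float, x0: float, fold_ctrl: float,
                           seed: int = 0, poisson_noise: bool = False) -> GRInput:
    """Nuclei counts that invert the GR formula exactly for ``gr_true``.

    x_ctrl = x0 * fold_ctrl and x_c = x0 * fold_ctrl^log2(gr_true + 1), so
    computing GR from the returned counts recovers ``gr_true`` exactly
    (before optional Poisson resampling of the counts).
    """
    if x0 <= 0:
        raise ValueError("x0 must be positive")
    if fold_ctrl <= 1:
        raise ValueError("fold_ctrl must exceed 1 (control must grow)")
    if gr_true <= -1:
        raise ValueError("gr_true <= -1 implies a non-positive treated count")
    x_ctrl = x0 * fold_ctrl
    x_c = x0 * fold_ctrl ** np.log2(gr_true + 1.0)
    if poisson_noise:
        rng = _rng(seed, _STREAM_GROWTH)
        x_c = float(max(rng.poisson(x_c), 1))
        x_ctrl = float(max(rng.poisson(x_ctrl), 1))
        x0 = float(max(rng.poisson(x0), 1))
    return GRInput(x_c=float(x_c), x_ctrl=float(x_ctrl), x0=float(x0))
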