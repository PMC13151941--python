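"""Summary-based transcriptome-wide association (TWAS) and conditioning of a
GWAS signal on genetically predicted expression.

Expression weights trained from eQTL summary statistics (top1 / top-k /
ridge schemes) combine GWAS z-scores into a gene-level statistic
Z = w'z / sqrt(w'Rw). Conditioning augments the LD matrix with one
pseudo-variant per gene (correlation rho_g = R w / sqrt(w'Rw), pseudo
z-score = the gene's TWAS Z) and applies the summary-statistics conditional
association formula; the same machinery also reuses meQTL weights verbatim
for methylation (MWAS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .finemap import LDMatrix, SummaryStats, _conditional_z_core

__all__ = [
    "ExpressionWeights",
    "TwasResult",
    "build_weights",
    "twas_z",
    "condition_gwas_on_genes",
    "joint_twas",
]


@dataclass
class ExpressionWeights:
    """Per-variant weights predicting one gene's expression."""

    gene: str
    ids: list[str]
    w: np.ndarray
    method: str = "custom"

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape[0] != len(self.ids):
            raise ValueError("weights must align to variant ids")
        if not np.any(self.w != 0):
            raise ValueError("at least one weight must be nonzero")

    def aligned(self, ld: LDMatrix) -> np.ndarray:
        if self.ids != ld.ids:
            raise ValueError(f"weights for {self.gene} not aligned to the LD matrix")
        return self.w


@dataclass
class TwasResult:
    """Gene-level TWAS statistic with the SNP/predicted-expression correlations."""

    gene: str
    z: float
    p: float
    rho: np.ndarray  # R w / sqrt(w'Rw), |rho| <= 1 elementwise

    def __post_init__(self):
        self.rho = np.asarray(self.rho, dtype=float)
        if np.any(np.abs(self.rho) > 1 + 1e-8):
            raise ValueError("predicted-expression/SNP correlations exceed 1")


def build_weights(
    eqtl: SummaryStats,
    ld: LDMatrix,
    method: str = "top1",
    k: int = 5,
    lam: float = 0.1,
) -> ExpressionWeights:
    """Train summary-based expression weights from eQTL z-scores.

    top1: indicator on the max-|z| variant; topk: marginal z-scores kept on
    the k largest-|z| variants; ridge: (R + lam I)^-1 z.
    """
    if not ld.aligned_to(eqtl):
        raise ValueError("LD matrix not aligned to the eQTL summary statistics")
    z = eqtl.z
    if method == "top1":
        if np.all(z == 0):
            warnings.warn(
                "all eQTL z-scores are zero; top1 selects the first variant",
                stacklevel=2,
            )
        j = int(np.argmax(np.abs(z)))
        w = np.zeros(eqtl.m)
        w[j] = 1.0
    elif method == "topk":
        order = np.argsort(-np.abs(z), kind="stable")[:k]
        w = np.zeros(eqtl.m)
        w[order] = z[order]
    elif method == "ridge":
        w = np.linalg.solve(ld.R + lam * np.eye(eqtl.m), z)
    else:
        raise ValueError(f"unknown weight-training method {method!r}")
    return ExpressionWeights(gene="gene", ids=eqtl.ids, w=w, method=method)


def twas_z(
    weights: ExpressionWeights, gwas: SummaryStats, ld: LDMatrix, tol: float = 1e-12
) -> TwasResult:
    """Gene-level association of predicted expression with the GWAS trait:
    Z = w'z / sqrt(w'Rw), two-sided p from the standard normal."""
    if not ld.aligned_to(gwas):
        raise ValueError("LD matrix not aligned to the GWAS summary statistics")
    w = weights.aligned(ld)
    denom2 = float(w @ ld.R @ w)
    if denom2 <= tol:
        raise ValueError(f"degenerate weights for {weights.gene}: w'Rw = {denom2:.3e}")
    denom = np.sqrt(denom2)
    z = float(w @ gwas.z) / denom
    rho = ld.R @ w / denom
    return TwasResult(gene=weights.gene, z=z, p=float(2 * norm.sf(abs(z))), rho=rho)


def _gene_correlations(ld: LDMatrix, weights: list[ExpressionWeights]):
    """SNP-gene and gene-gene correlations of predicted expression."""
    W = np.column_stack([w.aligned(ld) for w in weights])
    RW = ld.R @ W
    scale = np.sqrt(np.einsum("jk,jk->k", W, RW))
    if np.any(scale <= 1e-12):
        raise ValueError("degenerate weights (w'Rw = 0)")
    P = RW / scale  # m x k SNP-gene correlations
    G = (W.T @ RW) / np.outer(scale, scale)  # k x k gene-gene correlations
    G = (G + G.T) / 2.0
    np.fill_diagonal(G, 1.0)
    return P, G


def condition_gwas_on_genes(
    gwas: SummaryStats,
    ld: LDMatrix,
    weights: list[ExpressionWeights],
    ridge: float = 1e-8,
):
    """Condition the GWAS z-scores on the predicted expression of one or
    more genes (FUSION-style conditional analysis).

    The correlation structure is augmented with one pseudo-variant per gene
    whose z-score is the gene's marginal TWAS Z; the conditional z-score
    formula is then applied conditioning on the pseudo-variants. Conditioning
    on zero genes is the identity. Returns a
    :class:`~locusdissect.finemap.ConditionalResult`-like tuple
    (ids, conditional z, conditional p).
    """
    from .finemap import ConditionalResult

    if not ld.aligned_to(gwas):
        raise ValueError("LD matrix not aligned to the GWAS summary statistics")
    m = gwas.m
    if not weights:
        return ConditionalResult(
            ids=list(gwas.ids),
            z=gwas.z.copy(),
            p=2 * norm.sf(np.abs(gwas.z)),
            conditioned_on=[],
        )
    P, G = _gene_correlations(ld, weights)
    k = len(weights)
    off = G[np.triu_indices(k, 1)]
    if np.any(np.abs(off) > 1 - 1e-8):
        raise ValueError("collinear gene expression models; cannot condition jointly")
    z_genes = np.array([twas_z(w, gwas, ld).z for w in weights])
    z_aug = np.concatenate([gwas.z, z_genes])
    R_aug = np.block([[ld.R, P], [P.T, G]])
    cond = np.arange(m, m + k)
    # collinearity tolerance must sit above the ridge-induced floor of the
    # conditional variance (~ridge for a perfectly captured SNP)
    idx, zc, collinear_idx = _conditional_z_core(
        z_aug, R_aug, cond, ridge, collinear_tol=max(1e3 * ridge, 1e-10)
    )
    # a SNP perfectly captured by predicted expression (e.g. the sole weight
    # variant of a top1 model) has zero conditional variance and zero
    # conditional effect: report z_cond = 0 rather than dropping it
    z_out = np.zeros(m)
    z_out[idx[idx < m]] = zc[idx < m]
    return ConditionalResult(
        ids=list(gwas.ids),
        z=z_out,
        p=2 * norm.sf(np.abs(z_out)),
        conditioned_on=[w.gene for w in weights],
        collinear=[gwas.ids[i] for i in collinear_idx if i < m],
    )


def joint_twas(
    gwas: SummaryStats, ld: LDMatrix, weights: list[ExpressionWeights]
) -> dict[str, float]:
    """Joint gene-level z-scores from the marginal TWAS statistics.

    Solves the k-gene system against the gene-gene correlation matrix G
    (generalized least squares): Z_joint = G^-1 Z_marg, standardized by the
    joint precision, so uncorrelated genes recover their marginal Z.
    """
    if len(weights) < 2:
        raise ValueError("joint TWAS needs at least two genes")
    _, G = _gene_correlations(ld, weights)
    cond = np.linalg.cond(G)
    if cond > 1e8:
        raise ValueError(f"singular gene-gene correlation matrix (cond={cond:.2e})")
    z_marg = np.array([twas_z(w, gwas, ld).z for w in weights])
    Ginv = np.linalg.inv(G)
    beta = Ginv @ z_marg
    z_joint = beta / np.sqrt(np.diag(Ginv))
    return {w.gene: float(z) for w, z in zip(weights, z_joint)}
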