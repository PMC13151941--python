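"""Colocalization of two traits' association signals at a locus.

Single-causal-variant enumeration over the five hypotheses (H0 no
association, H1/H2 one trait only, H3 distinct causal variants, H4 shared
causal variant) from per-variant log approximate Bayes factors, plus the
per-signal variant in which each pair of fine-mapped effects is colocalized
separately using the effects' own per-variant log Bayes factors.

Decision convention: a shared-causal posterior (PP4) > 0.8 is strong
evidence for colocalization, < 0.2 evidence against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .finemap import FineMapResult

__all__ = ["ColocPriors", "ColocResult", "coloc_enumerate", "coloc_per_signal"]

# presets mirroring the tested magnitudes for the shared-causal prior
P12_PRESETS = {"stringent": 1e-5, "intermediate": 1e-4, "lenient": 1e-3}


@dataclass(frozen=True)
class ColocPriors:
    """Per-variant priors: p1/p2 single-trait causal, p12 shared causal."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self):
        for name in ("p1", "p2", "p12"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.p12 > min(self.p1, self.p2):
            warnings.warn(
                "p12 exceeds min(p1, p2); shared-causal prior larger than "
                "single-trait priors is usually unintended",
                stacklevel=2,
            )


@dataclass
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses."""

    pp: np.ndarray  # PP0..PP4
    priors: ColocPriors
    n_variants: int

    def __post_init__(self):
        self.pp = np.asarray(self.pp, dtype=float)
        if self.pp.shape != (5,):
            raise ValueError("expected five hypothesis probabilities")
        if not np.isclose(self.pp.sum(), 1.0, atol=1e-10):
            raise ValueError("hypothesis probabilities must sum to 1")

    @property
    def pp4(self) -> float:
        return float(self.pp[4])


def _log_diff_exp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b, -inf when equal to within rounding."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_enumerate(
    labf1: np.ndarray, labf2: np.ndarray, priors: ColocPriors | None = None
) -> ColocResult:
    """Five-hypothesis colocalization by single-causal enumeration.

    Hypothesis masses (computed in log space): H0 ∝ 1; H1 ∝ p1 Σ_i ABF1_i;
    H2 ∝ p2 Σ_j ABF2_j; H3 ∝ p1 p2 Σ_{i≠j} ABF1_i ABF2_j;
    H4 ∝ p12 Σ_i ABF1_i ABF2_i.
    """
    priors = priors or ColocPriors()
    labf1 = np.asarray(labf1, dtype=float)
    labf2 = np.asarray(labf2, dtype=float)
    if labf1.shape != labf2.shape or labf1.ndim != 1:
        raise ValueError("log-ABF vectors must be 1-D and of equal length")
    m = labf1.shape[0]
    if m < 1:
        raise ValueError("need at least one variant")

    l1 = float(logsumexp(labf1))
    l2 = float(logsumexp(labf2))
    l4 = float(logsumexp(labf1 + labf2))
    # sum over i != j equals (sum_i)(sum_j) minus the diagonal
    l3 = _log_diff_exp(l1 + l2, l4) if m > 1 else -np.inf

    lh = np.array(
        [
            0.0,
            np.log(priors.p1) + l1,
            np.log(priors.p2) + l2,
            np.log(priors.p1) + np.log(priors.p2) + l3,
            np.log(priors.p12) + l4,
        ]
    )
    pp = np.exp(lh - logsumexp(lh))
    pp /= pp.sum()
    return ColocResult(pp=pp, priors=priors, n_variants=m)


@dataclass
class PerSignalColoc:
    """Colocalization of every retained effect pair between two fits."""

    results: dict[tuple[int, int], ColocResult] = field(default_factory=dict)

    @property
    def max_pp4(self) -> float:
        if not self.results:
            return 0.0
        return max(r.pp4 for r in self.results.values())


def coloc_per_signal(
    fm1: FineMapResult, fm2: FineMapResult, priors: ColocPriors | None = None
) -> PerSignalColoc:
    """Colocalize each retained fine-mapped effect of trait 1 against each
    retained effect of trait 2 using the effects' per-variant log Bayes
    factors; a fit with no retained effects yields an empty matrix."""
    priors = priors or ColocPriors()
    if fm1.ids != fm2.ids:
        raise ValueError("fine-mapping results must be over the same variants")
    out = PerSignalColoc()
    effects1 = sorted({cs.effect for cs in fm1.credible_sets})
    effects2 = sorted({cs.effect for cs in fm2.credible_sets})
    for l1 in effects1:
        for l2 in effects2:
            out.results[(l1, l2)] = coloc_enumerate(
                fm1.lbf[l1], fm2.lbf[l2], priors
            )
    return out
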