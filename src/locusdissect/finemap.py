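"""Summary-statistics fine-mapping at a single locus.

Implements the z-score/LD ("RSS") likelihood z ~ N(R b, R), Wakefield's
approximate Bayes factor, a single-effect Bayesian fine-mapper, a SuSiE-style
sum-of-single-effects fit on summary statistics, credible-set construction
with a post-hoc retention filter, likelihood-ratio and LD-proxy variant
selection, the multi-method credible-causal-variant (CCV) union, and
COJO-style conditional association on the standardized scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp
from scipy.stats import norm

__all__ = [
    "SummaryStats",
    "LDMatrix",
    "ABFPrior",
    "CredibleSet",
    "FineMapResult",
    "CCVSet",
    "ConditionalResult",
    "wakefield_log_abf",
    "single_effect_finemap",
    "susie_rss",
    "llr_select",
    "ld_supplement",
    "retain_credible_sets",
    "union_ccv",
    "conditional_z",
]

_V_ZERO = 1e-9  # below this an effect is treated as switched off


@dataclass
class SummaryStats:
    """Per-variant association z-scores for one trait at one locus.

    Parameters
    ----------
    ids : variant identifiers (unique).
    z : z-scores from marginal association tests.
    n : GWAS/QTL sample size.
    chrom, pos, ref, alt : optional variant coordinates/alleles.
    """

    ids: list[str]
    z: np.ndarray
    n: int
    chrom: list[str] | None = None
    pos: np.ndarray | None = None
    ref: list[str] | None = None
    alt: list[str] | None = None

    def __post_init__(self):
        self.ids = list(map(str, self.ids))
        self.z = np.asarray(self.z, dtype=float)
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("variant ids must be unique")
        if len(self.ids) != self.z.shape[0]:
            raise ValueError("ids and z must have the same length")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("z-scores must be finite")
        if self.n < 1:
            raise ValueError("sample size n must be >= 1")
        if self.pos is not None:
            self.pos = np.asarray(self.pos, dtype=int)

    @property
    def m(self) -> int:
        return len(self.ids)

    def index_of(self, variant_id: str) -> int:
        try:
            return self.ids.index(variant_id)
        except ValueError:
            raise KeyError(f"variant {variant_id!r} not present in summary statistics")


@dataclass
class LDMatrix:
    """Correlation (LD) matrix aligned to a list of variant ids."""

    ids: list[str]
    R: np.ndarray

    def __post_init__(self):
        self.ids = list(map(str, self.ids))
        self.R = np.asarray(self.R, dtype=float)
        m = len(self.ids)
        if self.R.shape != (m, m):
            raise ValueError(f"LD matrix shape {self.R.shape} does not match {m} ids")
        if not np.allclose(self.R, self.R.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.R), 1.0, atol=1e-6):
            raise ValueError("LD matrix must have unit diagonal")

    @property
    def m(self) -> int:
        return len(self.ids)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.R)[0])

    def aligned_to(self, stats: SummaryStats) -> bool:
        return self.ids == stats.ids


@dataclass
class ABFPrior:
    """Prior for Wakefield's approximate Bayes factor.

    W is the prior variance of the (standardized) effect and V its sampling
    variance; with z-score-only input V = 1/n and W = sd^2 on the
    standardized-effect scale, so that W/V = n * sd^2 is the prior variance
    on the z scale. Only the ratio W/V affects variant ranking.
    """

    W: float = 0.15**2
    V: float = 1.0

    def __post_init__(self):
        if self.W <= 0 or self.V <= 0:
            raise ValueError("ABF prior variances W and V must be positive")

    @classmethod
    def from_sample_size(cls, n: int, sd: float = 0.15) -> "ABFPrior":
        """Standardized-effect prior N(0, sd^2) with sampling variance 1/n."""
        return cls(W=sd**2, V=1.0 / n)

    @property
    def z_scale_variance(self) -> float:
        """Prior effect variance expressed on the z scale, W/V."""
        return self.W / self.V


def wakefield_log_abf(z, prior: ABFPrior) -> np.ndarray | float:
    """Wakefield's log approximate Bayes factor for a single-variant test.

    log ABF = 1/2 log(V/(V+W)) + 1/2 z^2 W/(V+W); monotone in |z|.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z must be finite")
    r = prior.W / (prior.V + prior.W)
    out = 0.5 * np.log(prior.V / (prior.V + prior.W)) + 0.5 * z**2 * r
    return float(out) if out.ndim == 0 else out


@dataclass
class CredibleSet:
    """A per-effect credible set: smallest set of variants reaching coverage."""

    effect: int
    variants: list[str]
    alpha: np.ndarray  # inclusion probabilities of the members, same order
    cum_alpha: float
    purity: float  # min |r| over member pairs (1.0 for singleton)

    @property
    def size(self) -> int:
        return len(self.variants)


@dataclass
class FineMapResult:
    """Fine-mapping output: PIPs, per-effect inclusion vectors, credible sets."""

    method: str
    ids: list[str]
    pip: np.ndarray
    alpha: np.ndarray  # L x m per-effect inclusion probabilities
    lbf: np.ndarray  # L x m per-effect, per-variant log Bayes factors
    prior_variance: np.ndarray  # per-effect prior variance on the z scale
    credible_sets: list[CredibleSet] = field(default_factory=list)
    converged: bool = True
    elbo: list[float] = field(default_factory=list)

    def __post_init__(self):
        self.pip = np.asarray(self.pip, dtype=float)
        self.alpha = np.atleast_2d(np.asarray(self.alpha, dtype=float))
        self.lbf = np.atleast_2d(np.asarray(self.lbf, dtype=float))
        if np.any(self.pip < -1e-12) or np.any(self.pip > 1 + 1e-12):
            raise ValueError("PIPs must lie in [0, 1]")
        sums = self.alpha.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValueError("each per-effect alpha vector must sum to 1")


@dataclass
class CCVSet:
    """Union of credible causal variants with per-source provenance flags."""

    ids: list[str]
    provenance: dict[str, frozenset[str]]  # id -> subset of {bayesian, llr, ld_proxy}
    lead: str

    def __post_init__(self):
        if self.lead not in self.ids:
            raise ValueError("lead variant must be present in the CCV set")


@dataclass
class ConditionalResult:
    """COJO-style conditional z-scores (conditioned variants omitted)."""

    ids: list[str]
    z: np.ndarray
    p: np.ndarray
    conditioned_on: list[str]
    collinear: list[str] = field(default_factory=list)


def _greedy_credible_set(alpha: np.ndarray, coverage: float) -> np.ndarray:
    """Indices of the smallest set with cumulative alpha >= coverage.

    Ties broken by ascending variant index (stable sort on -alpha).
    """
    order = np.argsort(-alpha, kind="stable")
    cum = np.cumsum(alpha[order])
    k = int(np.searchsorted(cum, coverage - 1e-12)) + 1
    k = min(k, alpha.shape[0])
    return np.sort(order[:k])


def _purity(members: np.ndarray, R: np.ndarray, max_pairs: int = 200, seed: int = 0) -> float:
    if members.shape[0] <= 1:
        return 1.0
    idx = members
    if idx.shape[0] > max_pairs:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(idx, size=max_pairs, replace=False))
    sub = np.abs(R[np.ix_(idx, idx)])
    return float(sub.min())


def single_effect_finemap(
    stats: SummaryStats, prior: ABFPrior | None = None, coverage: float = 0.95
) -> FineMapResult:
    """Exact single-causal-variant fine-mapping under a uniform causal prior.

    PIP_i = ABF_i / sum_j ABF_j; equivalent to exhaustive enumeration of the
    m one-causal models. One credible set is built greedily to ``coverage``.
    """
    if stats.m < 1:
        raise ValueError("need at least one variant")
    if prior is None:
        prior = ABFPrior.from_sample_size(stats.n)
    lbf = wakefield_log_abf(stats.z, prior)
    lbf = np.atleast_1d(lbf)
    pip = np.exp(lbf - logsumexp(lbf))
    pip /= pip.sum()
    members = _greedy_credible_set(pip, coverage)
    cs = CredibleSet(
        effect=0,
        variants=[stats.ids[i] for i in members],
        alpha=pip[members],
        cum_alpha=float(pip[members].sum()),
        purity=1.0 if members.shape[0] <= 1 else float("nan"),
    )
    return FineMapResult(
        method="single_effect_abf",
        ids=stats.ids,
        pip=pip,
        alpha=pip[None, :],
        lbf=lbf[None, :],
        prior_variance=np.array([prior.z_scale_variance]),
        credible_sets=[cs],
    )


def _ser_fit(zr: np.ndarray, V: float, log_pi: np.ndarray):
    """Single-effect regression on residual z-scores with prior variance V.

    Returns (alpha, mu, s2, lbf_variable, effect_loglik). On the z scale the
    per-variant posterior is N(mu_j, s2) with s2 = V/(1+V), mu_j = s2 * zr_j.
    """
    m = zr.shape[0]
    if V <= _V_ZERO:
        alpha = np.full(m, 1.0 / m)
        return alpha, np.zeros(m), 0.0, np.zeros(m), float(logsumexp(log_pi))
    s2 = V / (1.0 + V)
    lbf = 0.5 * np.log(1.0 / (1.0 + V)) + 0.5 * zr**2 * s2
    w = log_pi + lbf
    loglik = float(logsumexp(w))
    alpha = np.exp(w - loglik)
    alpha /= alpha.sum()
    mu = s2 * zr
    return alpha, mu, s2, lbf, loglik


def _ser_optimize_V(zr: np.ndarray, log_pi: np.ndarray, v_init: float) -> float:
    """Empirical-Bayes prior variance for one effect: maximize the effect
    marginal likelihood over V >= 0 (compared against the V=0 null)."""

    def neg_loglik(log_v: float) -> float:
        return -_ser_fit(zr, float(np.exp(log_v)), log_pi)[4]

    res = minimize_scalar(neg_loglik, bounds=(-10.0, 15.0), method="bounded")
    v_star = float(np.exp(res.x))
    ll_star = -res.fun
    ll_zero = float(logsumexp(log_pi))
    if ll_star <= ll_zero + 1e-10:
        return 0.0
    return v_star


def susie_rss(
    stats: SummaryStats,
    ld: LDMatrix,
    L: int = 5,
    coverage: float = 0.95,
    min_abs_corr: float = 0.0,
    max_iter: int = 100,
    tol: float = 1e-4,
    prior_variance: float | None = None,
    estimate_prior_variance: bool = True,
    prior_weights: np.ndarray | None = None,
    ridge: float = 1e-8,
    reject_non_psd: bool = False,
) -> FineMapResult:
    """Sum-of-single-effects fine-mapping from z-scores and an LD matrix.

    Fits up to ``L`` single effects to the RSS likelihood z ~ N(R b, R) by
    iterative Bayesian stepwise regression: each effect is refit to the
    residual z-scores after removing the other effects' posterior-mean
    contributions through R. The variational objective (ELBO) is checked to
    be non-decreasing at every sweep.

    ``prior_variance`` is the per-effect prior variance on the z scale
    (default 0.15^2 * n). With ``estimate_prior_variance`` each effect's
    prior variance is re-optimized by empirical Bayes each sweep; effects
    whose optimized variance hits zero carry no signal and are excluded from
    PIP and credible-set reporting. Per-effect credible sets are the smallest
    sets reaching ``coverage`` by descending inclusion probability; sets with
    purity (min |r| over member pairs) below ``min_abs_corr`` are dropped —
    with the default 0, none are dropped for purity.
    """
    if not ld.aligned_to(stats):
        raise ValueError("LD matrix ids are not aligned to the summary statistics")
    if L < 1:
        raise ValueError("L must be >= 1")
    m = stats.m
    R = ld.R
    min_eig = ld.min_eigenvalue()
    if min_eig < -1e-8:
        if reject_non_psd:
            raise ValueError(f"LD matrix is not PSD (min eigenvalue {min_eig:.3e})")
        lam = ridge - min_eig
        warnings.warn(
            f"LD matrix not PSD (min eigenvalue {min_eig:.3e}); "
            f"regularizing diagonal by {lam:.3e}",
            stacklevel=2,
        )
        R = (R + lam * np.eye(m)) / (1.0 + lam)

    z = stats.z
    if prior_variance is None:
        prior_variance = 0.15**2 * stats.n
    if prior_weights is None:
        pi = np.full(m, 1.0 / m)
    else:
        pi = np.asarray(prior_weights, dtype=float)
        pi = pi / pi.sum()
    log_pi = np.log(pi)

    V = np.full(L, float(prior_variance))
    alpha = np.full((L, m), 1.0 / m)
    mu = np.zeros((L, m))
    s2 = np.zeros(L)
    lbf = np.zeros((L, m))
    b_bar = np.zeros((L, m))  # per-effect posterior mean alpha*mu
    Rb = np.zeros(m)  # R @ total posterior mean

    elbo_trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        for l in range(L):
            Rb -= R @ b_bar[l]
            zr = z - Rb
            if estimate_prior_variance:
                V[l] = _ser_optimize_V(zr, log_pi, V[l])
            alpha[l], mu[l], s2[l], lbf[l], _ = _ser_fit(zr, V[l], log_pi)
            b_bar[l] = alpha[l] * mu[l]
            Rb += R @ b_bar[l]
        elbo = _susie_elbo(z, R, alpha, mu, s2, V, log_pi)
        if elbo_trace:
            prev = elbo_trace[-1]
            if elbo < prev - 1e-6 * (1.0 + abs(prev)):
                raise RuntimeError(
                    f"susie_rss objective decreased: {prev:.10g} -> {elbo:.10g}"
                )
            if elbo - prev < tol:
                elbo_trace.append(elbo)
                converged = True
                break
        elbo_trace.append(elbo)

    active = V > _V_ZERO
    if active.any():
        pip = 1.0 - np.prod(1.0 - alpha[active], axis=0)
    else:
        pip = np.zeros(m)
    pip = np.clip(pip, 0.0, 1.0)

    sets: list[CredibleSet] = []
    for l in range(L):
        if not active[l]:
            continue
        members = _greedy_credible_set(alpha[l], coverage)
        purity = _purity(members, R)
        if purity < min_abs_corr:
            continue
        sets.append(
            CredibleSet(
                effect=l,
                variants=[stats.ids[i] for i in members],
                alpha=alpha[l][members],
                cum_alpha=float(alpha[l][members].sum()),
                purity=purity,
            )
        )

    return FineMapResult(
        method="susie_rss",
        ids=stats.ids,
        pip=pip,
        alpha=alpha,
        lbf=lbf,
        prior_variance=V.copy(),
        credible_sets=sets,
        converged=converged,
        elbo=elbo_trace,
    )


def _susie_elbo(z, R, alpha, mu, s2, V, log_pi) -> float:
    """Variational objective for the RSS likelihood z ~ N(R b, R).

    log-likelihood part (up to a beta-free constant): E[b]'z - E[b'Rb]/2,
    using E[b'Rb] = bbar'R bbar - sum_l bbar_l'R bbar_l + sum_l E[b_l^2]
    (unit LD diagonal). KL is the standard single-effect term.
    """
    L, m = alpha.shape
    b_l = alpha * mu  # L x m
    b = b_l.sum(axis=0)
    second = 0.0
    kl = 0.0
    for l in range(L):
        if V[l] <= _V_ZERO:
            continue
        eb2 = float(np.sum(alpha[l] * (mu[l] ** 2 + s2[l])))
        second += eb2 - float(b_l[l] @ R @ b_l[l])
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(alpha[l] > 0, np.log(alpha[l]) - log_pi, 0.0)
        kl += float(np.sum(alpha[l] * ratio))
        kl += float(
            np.sum(alpha[l] * 0.5 * ((mu[l] ** 2 + s2[l]) / V[l] - 1.0 - np.log(s2[l] / V[l])))
        )
    fit = float(b @ z) - 0.5 * (float(b @ R @ b) + second)
    return fit - kl


def llr_select(stats: SummaryStats, lead_id: str, ratio: float = 1000.0) -> set[str]:
    """Variants within a 1:``ratio`` likelihood ratio of the lead variant.

    Under the normal approximation the per-variant maximized log-likelihood
    difference is (z_i^2 - z_lead^2)/2; variants with LLR >= -ln(ratio) are
    retained (the lead itself always is).
    """
    j = stats.index_of(lead_id)
    llr = (stats.z**2 - stats.z[j] ** 2) / 2.0
    keep = llr >= -np.log(ratio)
    return {stats.ids[i] for i in np.flatnonzero(keep)}


def ld_supplement(
    lead_id: str,
    proxies: dict[str, float],
    stats_ids: set[str] | list[str],
    threshold: float = 0.8,
) -> set[str]:
    """LD-proxy supplementation: ids with r^2 strictly > ``threshold`` to the
    lead that are absent from the assessed summary statistics (e.g. indels
    missing from the imputation panel)."""
    stats_ids = set(stats_ids)
    return {
        vid
        for vid, r2 in proxies.items()
        if r2 > threshold and vid not in stats_ids and vid != lead_id
    }


def retain_credible_sets(
    result: FineMapResult, cum_pip_min: float = 0.85, var_pip_min: float = 0.005
) -> FineMapResult:
    """Post-hoc retention: keep credible sets with cumulative inclusion
    probability > ``cum_pip_min``; within surviving sets keep variants with
    overall PIP > ``var_pip_min``. Both thresholds strict."""
    pip_of = dict(zip(result.ids, result.pip))
    kept: list[CredibleSet] = []
    for cs in result.credible_sets:
        if cs.cum_alpha <= cum_pip_min:
            continue
        mask = np.array([pip_of[v] > var_pip_min for v in cs.variants], dtype=bool)
        if not mask.any():
            continue
        kept.append(
            CredibleSet(
                effect=cs.effect,
                variants=[v for v, k in zip(cs.variants, mask) if k],
                alpha=cs.alpha[mask],
                cum_alpha=cs.cum_alpha,
                purity=cs.purity,
            )
        )
    return replace(result, credible_sets=kept)


def union_ccv(
    results: list[FineMapResult],
    llr_set: set[str] | None,
    proxy_set: set[str] | None,
    lead_id: str,
    positions: dict[str, int] | None = None,
) -> CCVSet:
    """Union of credible causal variants across engines plus LLR and LD-proxy
    selections, with provenance flags; deterministic order by position then id."""
    llr_set = llr_set or set()
    proxy_set = proxy_set or set()
    prov: dict[str, set[str]] = {}
    for res in results:
        for cs in res.credible_sets:
            for v in cs.variants:
                prov.setdefault(v, set()).add("bayesian")
    for v in llr_set:
        prov.setdefault(v, set()).add("llr")
    for v in proxy_set:
        prov.setdefault(v, set()).add("ld_proxy")
    if not prov:
        raise ValueError("all CCV sources are empty")
    prov.setdefault(lead_id, set()).add("lead")
    positions = positions or {}
    ids = sorted(prov, key=lambda v: (positions.get(v, np.iinfo(np.int64).max), v))
    return CCVSet(
        ids=ids,
        provenance={v: frozenset(s) for v, s in prov.items()},
        lead=lead_id,
    )


def _conditional_z_core(
    z: np.ndarray,
    R: np.ndarray,
    cond: np.ndarray,
    ridge: float = 1e-8,
    collinear_tol: float = 1e-10,
):
    """Conditional z-scores on the standardized scale given a conditioning set.

    z_cond_j = (z_j - R_jC (R_CC + ridge I)^-1 z_C)
               / sqrt(1 - R_jC (R_CC + ridge I)^-1 R_Cj)
    """
    m = z.shape[0]
    rest = np.setdiff1d(np.arange(m), cond)
    if cond.size == 0:
        return rest, z.copy(), np.zeros(0, dtype=int)
    Rcc = R[np.ix_(cond, cond)] + ridge * np.eye(cond.size)
    Rrc = R[np.ix_(rest, cond)]
    sol_z = np.linalg.solve(Rcc, z[cond])
    sol_R = np.linalg.solve(Rcc, Rrc.T)  # |C| x |rest|
    num = z[rest] - Rrc @ sol_z
    denom = 1.0 - np.einsum("ij,ji->i", Rrc, sol_R)
    ok = denom > collinear_tol
    zc = np.full(rest.shape[0], np.nan)
    zc[ok] = num[ok] / np.sqrt(denom[ok])
    return rest[ok], zc[ok], rest[~ok]


def conditional_z(
    stats: SummaryStats,
    ld: LDMatrix,
    condition_ids: list[str],
    ridge: float = 1e-8,
    collinear_tol: float = 1e-10,
) -> ConditionalResult:
    """COJO-style conditional association from summary statistics.

    Conditions the locus z-scores on the named variants through the LD
    matrix; conditioned variants are omitted from the output and variants
    whose conditional variance collapses (collinear with the conditioning
    set) are flagged and excluded. An empty conditioning set is the identity.
    """
    if not ld.aligned_to(stats):
        raise ValueError("LD matrix ids are not aligned to the summary statistics")
    cond = np.array([stats.index_of(v) for v in condition_ids], dtype=int)
    idx, zc, collinear_idx = _conditional_z_core(stats.z, ld.R, cond, ridge, collinear_tol)
    p = 2.0 * norm.sf(np.abs(zc))
    return ConditionalResult(
        ids=[stats.ids[i] for i in idx],
        z=zc,
        p=p,
        conditioned_on=list(condition_ids),
        collinear=[stats.ids[i] for i in collinear_idx],
    )
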