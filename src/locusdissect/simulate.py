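"""Synthetic inputs with known ground truth for every pipeline stage.

Generates (i) block-AR(1) LD matrices and GWAS/QTL z-scores under the RSS
model z ~ MVN(sqrt(n) R b, R) with planted causal variants, (ii) genotype
dosages via a Gaussian copula for individual-level oracles, (iii) chromatin
annotation tracks, restriction-fragment maps and scored interactions with
planted enhancer-promoter pairs, and (iv) tumor cohorts with planted
wild-type-vs-mutant expression shifts and expression-dependent hazards.

All randomness flows through one seeded numpy Generator per call; identical
spec + seed reproduces identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .finemap import LDMatrix, SummaryStats
from .v2g import FragmentMap, GenomicInterval, InteractionTable

__all__ = [
    "LocusSpec",
    "SimulatedLocus",
    "AnnotationSpec",
    "AnnotationResult",
    "CohortSpec",
    "make_ld",
    "draw_zscores",
    "draw_genotypes",
    "simulate_locus",
    "make_annotations",
    "make_cohort",
]


@dataclass
class LocusSpec:
    """Ground-truth description of one simulated locus.

    causal_effects maps a trait label to a list of (variant index,
    standardized effect b); sample_sizes maps the same labels to n.
    """

    n_variants: int
    block_sizes: list[int]
    rho: float | list[float]
    causal_effects: dict[str, list[tuple[int, float]]] = field(default_factory=dict)
    sample_sizes: dict[str, int] = field(default_factory=dict)
    positions: np.ndarray | None = None
    chrom: str = "chr9"
    seed: int = 0

    def __post_init__(self):
        if sum(self.block_sizes) != self.n_variants:
            raise ValueError("block sizes must sum to the number of variants")
        rhos = self.rho_per_block
        if any(not (0.0 <= r < 1.0) for r in rhos):
            raise ValueError("rho must lie in [0, 1) for every block")
        for trait, effects in self.causal_effects.items():
            for j, b in effects:
                if not 0 <= j < self.n_variants:
                    raise ValueError(f"causal index {j} out of range for trait {trait}")
                if abs(b) >= 1:
                    raise ValueError("standardized effects must satisfy |b| < 1")
            if self.sample_sizes.get(trait, 1) < 1:
                raise ValueError("sample sizes must be >= 1")
        if self.positions is None:
            # 1 variant per kb starting at 1 Mb, monotone increasing
            self.positions = 1_000_000 + 1_000 * np.arange(self.n_variants)
        self.positions = np.asarray(self.positions, dtype=int)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def rho_per_block(self) -> list[float]:
        if np.isscalar(self.rho):
            return [float(self.rho)] * len(self.block_sizes)
        return [float(r) for r in self.rho]

    def variant_ids(self) -> list[str]:
        return [f"rs{i + 1}" for i in range(self.n_variants)]

    def effect_vector(self, trait: str) -> np.ndarray:
        b = np.zeros(self.n_variants)
        for j, bj in self.causal_effects.get(trait, []):
            b[j] = bj
        return b


@dataclass
class SimulatedLocus:
    """One realization of a locus: LD, per-trait z-scores, planted truth."""

    spec: LocusSpec
    ld: LDMatrix
    zscores: dict[str, np.ndarray]
    truth: dict[str, set[int]]
    genotypes: np.ndarray | None = None
    phenotypes: dict[str, np.ndarray] | None = None

    def __post_init__(self):
        m = self.ld.m
        for trait, z in self.zscores.items():
            if z.shape[0] != m:
                raise ValueError(f"z vector for {trait} does not match LD dimension")
        for trait, idx in self.truth.items():
            if any(not 0 <= j < m for j in idx):
                raise ValueError(f"truth indices out of range for {trait}")

    def stats(self, trait: str) -> SummaryStats:
        return SummaryStats(
            ids=self.ld.ids,
            z=self.zscores[trait],
            n=self.spec.sample_sizes[trait],
            chrom=[self.spec.chrom] * self.ld.m,
            pos=self.spec.positions,
        )


def make_ld(spec: LocusSpec) -> LDMatrix:
    """Block-diagonal AR(1) LD: within a block entry(i,j) = rho^|i-j|,
    zero across blocks. Symmetric, unit diagonal, positive semi-definite."""
    blocks = []
    for size, rho in zip(spec.block_sizes, spec.rho_per_block):
        idx = np.arange(size)
        blocks.append(rho ** np.abs(idx[:, None] - idx[None, :]))
    from scipy.linalg import block_diag

    R = block_diag(*blocks) if blocks else np.zeros((0, 0))
    return LDMatrix(ids=spec.variant_ids(), R=R)


def _chol_psd(R: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Cholesky-like factor of a PSD correlation matrix, with diagnostics."""
    try:
        return np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        w, U = np.linalg.eigh(R)
        if w[0] < -tol:
            raise ValueError(
                f"correlation matrix is not PSD (min eigenvalue {w[0]:.3e})"
            ) from None
        return U * np.sqrt(np.clip(w, 0.0, None))


def draw_zscores(
    ld: LDMatrix,
    b: np.ndarray,
    n: int,
    rng: np.random.Generator | int,
    size: int | None = None,
) -> np.ndarray:
    """Draw GWAS z-scores under the RSS model: z ~ MVN(sqrt(n) R b, R).

    ``size`` draws at once returns a (size, m) array; default one vector.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    b = np.asarray(b, dtype=float)
    if b.shape[0] != ld.m:
        raise ValueError("effect vector b must be aligned to the LD matrix")
    A = _chol_psd(ld.R)
    mean = np.sqrt(n) * ld.R @ b
    k = 1 if size is None else size
    z = mean + rng.standard_normal((k, ld.m)) @ A.T
    return z[0] if size is None else z


def simulate_locus(spec: LocusSpec) -> SimulatedLocus:
    """LD plus one z-score draw per trait, with the planted truth recorded."""
    ld = make_ld(spec)
    rng = np.random.default_rng(spec.seed)
    zscores = {}
    truth = {}
    for trait in spec.causal_effects:
        zscores[trait] = draw_zscores(
            ld, spec.effect_vector(trait), spec.sample_sizes[trait], rng
        )
        truth[trait] = {j for j, _ in spec.causal_effects[trait]}
    return SimulatedLocus(spec=spec, ld=ld, zscores=zscores, truth=truth)


def draw_genotypes(
    ld: LDMatrix,
    mafs: np.ndarray | float,
    n_samples: int,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Genotype dosages (0/1/2) via a Gaussian copula.

    A latent MVN(0, R) draw is thresholded at the Hardy-Weinberg genotype
    quantiles for each variant's minor allele frequency, so the empirical
    dosage correlation is a deterministic monotone transform of R.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    mafs = np.broadcast_to(np.asarray(mafs, dtype=float), (ld.m,))
    if np.any(mafs <= 0) or np.any(mafs > 0.5):
        raise ValueError("minor allele frequencies must lie in (0, 0.5]")
    A = _chol_psd(ld.R)
    latent = rng.standard_normal((n_samples, ld.m)) @ A.T
    p0 = (1.0 - mafs) ** 2
    p01 = p0 + 2.0 * mafs * (1.0 - mafs)
    t0 = norm.ppf(p0)
    t1 = norm.ppf(p01)
    return (latent > t0).astype(np.int8) + (latent > t1).astype(np.int8)


def marginal_zscores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-variant marginal regression z-scores (OLS t-statistics) from
    individual-level data; the empirical counterpart of ``draw_zscores``."""
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = Xc.std(axis=0, ddof=0)
    sx[sx == 0] = np.nan
    r = (Xc.T @ yc) / (n * sx * yc.std(ddof=0))
    return r * np.sqrt((n - 2) / np.clip(1.0 - r**2, 1e-12, None))


# ---------------------------------------------------------------------------
# Annotation / chromatin tracks


@dataclass
class AnnotationSpec:
    """Blueprint for synthetic chromatin tracks over one chromosome.

    state_intervals: list of ((start, end), state name); atac_peaks: list of
    (start, end); promoters: gene -> (start, end); planted_interactions:
    list of ((enh_start, enh_end), gene, score); background_interactions:
    (count, score_low, score_high) drawn uniformly between random fragment
    pairs.
    """

    chrom: str
    length: int
    cut_positions: list[int]
    state_intervals: list[tuple[tuple[int, int], str]] = field(default_factory=list)
    atac_peaks: list[tuple[int, int]] = field(default_factory=list)
    promoters: dict[str, tuple[int, int]] = field(default_factory=dict)
    planted_interactions: list[tuple[tuple[int, int], str, float]] = field(
        default_factory=list
    )
    background_interactions: tuple[int, float, float] = (0, 0.0, 5.0)
    seed: int = 0

    def __post_init__(self):
        cp = list(self.cut_positions)
        if any(b <= a for a, b in zip(cp, cp[1:])):
            raise ValueError("cut positions must be strictly increasing")
        if cp and (cp[0] <= 0 or cp[-1] >= self.length):
            raise ValueError("cut positions must lie strictly inside (0, length)")
        for gene, (s, e) in self.promoters.items():
            if not (0 <= s < e <= self.length):
                raise ValueError(f"promoter for {gene} outside chromosome bounds")
        for (s, e), _name in self.state_intervals:
            if not (0 <= s < e <= self.length):
                raise ValueError("state interval outside chromosome bounds")
        for (s, e), gene, _score in self.planted_interactions:
            if gene not in self.promoters:
                raise ValueError(f"planted interaction targets unknown gene {gene}")
            if not (0 <= s < e <= self.length):
                raise ValueError("enhancer interval outside chromosome bounds")


@dataclass
class AnnotationResult:
    """Synthetic tracks plus the planted enhancer-promoter truth."""

    states: pd.DataFrame  # chrom, start, end, state
    peaks: pd.DataFrame  # chrom, start, end
    fragments: FragmentMap
    interactions: InteractionTable
    promoters: dict[str, GenomicInterval]
    truth: pd.DataFrame  # gene, enh_fragment, prom_fragment, score


def make_annotations(spec: AnnotationSpec) -> AnnotationResult:
    """Build fragment map, state/peak tracks, and an interaction table with
    planted enhancer-promoter contacts plus uniform-score background pairs."""
    rng = np.random.default_rng(spec.seed)
    fragments = FragmentMap.from_cut_positions(
        spec.chrom, spec.cut_positions, spec.length
    )
    states = pd.DataFrame(
        [(spec.chrom, s, e, name) for (s, e), name in spec.state_intervals],
        columns=["chrom", "start", "end", "state"],
    )
    peaks = pd.DataFrame(
        [(spec.chrom, s, e) for s, e in spec.atac_peaks],
        columns=["chrom", "start", "end"],
    )
    rows = []
    truth_rows = []
    for (es, ee), gene, score in spec.planted_interactions:
        enh_frag = fragments.fragment_at((es + ee) // 2)
        ps, pe = spec.promoters[gene]
        prom_frag = fragments.fragment_at((ps + pe) // 2)
        rows.append((enh_frag, prom_frag, float(score)))
        truth_rows.append((gene, enh_frag, prom_frag, float(score)))
    n_bg, lo, hi = spec.background_interactions
    for _ in range(int(n_bg)):
        a, b = rng.choice(len(fragments), size=2, replace=False)
        rows.append((int(a), int(b), float(rng.uniform(lo, hi))))
    interactions = InteractionTable(
        pd.DataFrame(rows, columns=["frag_a", "frag_b", "score"]), fragments
    )
    promoters = {
        g: GenomicInterval(spec.chrom, s, e) for g, (s, e) in spec.promoters.items()
    }
    truth = pd.DataFrame(
        truth_rows, columns=["gene", "enh_fragment", "prom_fragment", "score"]
    )
    return AnnotationResult(states, peaks, fragments, interactions, promoters, truth)


# ---------------------------------------------------------------------------
# Tumor cohorts


@dataclass
class CohortSpec:
    """Blueprint for a synthetic tumor cohort.

    mutation_rates maps (gene, protein_change, driver flag) to the per-sample
    prevalence of that mutation. delta is the planted expression shift for
    the Model-1 wild-type group (expression units); covariate_effects are
    linear effects of (age, sex, purity, stage) on expression;
    log_hr_high_expr is the planted log hazard ratio of the high-expression
    group; baseline_hazard and censor_rate are per-day exponential rates.
    """

    n_samples: int
    mutation_rates: dict[tuple[str, str, bool], float] = field(default_factory=dict)
    delta: float = 0.0
    covariate_effects: dict[str, float] = field(default_factory=dict)
    baseline_hazard: float = 1.0 / 1500.0
    log_hr_high_expr: float = 0.0
    censor_rate: float = 1.0 / 3000.0
    treatment_class: str = "non-immunotherapy"
    baseline_expression: float = 10.0
    noise_sd: float = 1.0
    stage_probs: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("need at least one sample")
        for key, p in self.mutation_rates.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for {key} outside [0, 1]")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")
        if self.censor_rate < 0:
            raise ValueError("censoring rate must be non-negative")
        if self.stage_probs is None:
            self.stage_probs = {"I": 0.1, "II": 0.35, "III": 0.4, "IV": 0.15}


def make_cohort(spec: CohortSpec, name: str = "synthetic"):
    """Simulate a tumor cohort with planted expression and survival effects.

    Mutations are drawn independently per (gene, protein change) at the
    stated prevalence. Expression is baseline + delta for Model-1 wild-type
    samples + linear covariate effects + Gaussian noise. Survival is
    exponential with hazard h0 * exp(beta * 1[high expression]) (high = above
    the cohort-wide median) under independent exponential censoring; times in
    days.
    """
    from .tumor import Cohort, HOTSPOT_MODEL, classify_sample

    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    sample_ids = [f"{name}-{i:04d}" for i in range(n)]

    mut_rows = []
    for (gene, pchange, driver), rate in spec.mutation_rates.items():
        carriers = np.flatnonzero(rng.random(n) < rate)
        for i in carriers:
            mut_rows.append((sample_ids[i], gene, pchange, bool(driver)))
    mutations = pd.DataFrame(
        mut_rows, columns=["sample", "gene", "protein_change", "driver"]
    )

    age = rng.normal(60.0, 12.0, n).round(1)
    sex = rng.integers(0, 2, n)
    purity = rng.uniform(0.3, 1.0, n).round(3)
    stages = list(spec.stage_probs)
    stage = rng.choice(stages, size=n, p=np.array(list(spec.stage_probs.values())))

    muts_by_sample = {sid: [] for sid in sample_ids}
    for sid, gene, pchange, driver in mut_rows:
        muts_by_sample[sid].append((gene, pchange, driver))
    wt = np.array(
        [
            classify_sample(muts_by_sample[sid], HOTSPOT_MODEL) == "WT"
            for sid in sample_ids
        ]
    )

    cov = {"age": age, "sex": sex, "purity": purity, "stage": _stage_ordinal(stage)}
    expr = spec.baseline_expression + spec.delta * wt + rng.normal(0.0, spec.noise_sd, n)
    for key, gamma in spec.covariate_effects.items():
        expr = expr + gamma * cov[key]

    high = expr > np.median(expr)
    hazard = spec.baseline_hazard * np.exp(spec.log_hr_high_expr * high)
    event_time = rng.exponential(1.0 / hazard)
    if spec.censor_rate > 0:
        censor_time = rng.exponential(1.0 / spec.censor_rate, n)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    samples = pd.DataFrame(
        {
            "sample": sample_ids,
            "expression": expr,
            "age": age,
            "sex": sex,
            "purity": purity,
            "stage": stage,
            "survival_days": time,
            "event": event,
            "treatment_class": spec.treatment_class,
        }
    )
    return Cohort(name=name, samples=samples, mutations=mutations)


def _stage_ordinal(stage: np.ndarray) -> np.ndarray:
    order = {"I": 1, "II": 2, "III": 3, "IV": 4}
    return np.array([order.get(s, np.nan) for s in stage], dtype=float)
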