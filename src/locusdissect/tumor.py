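"""RAS-MAPK mutation-model classification, covariate-adjusted expression
association, Firth-penalized Cox survival, and sample-size-weighted z-score
meta-analysis across tumor cohorts.

Five nested classification models define the RAS-MAPK mutant subgroup:
Model 1 uses only the strongly-activating hotspots (BRAF codons 600/601,
NRAS codons 61/12/13); Models 2-5 cumulatively add any driver-flagged
mutation in BRAF/NRAS, then KRAS/HRAS, then NF1, then a configurable
pan-cancer MAPK gene panel, restricted to each cohort's assessed genes.
Expression is compared WT-vs-mutant by OLS adjusting for age, sex, tumor
purity and stage when available (positive coefficient = higher expression
in wild-type tumors). Survival in the hotspot-WT subgroup uses median
dichotomization of expression over the full cohort and a Cox model with
Firth's Jeffreys-prior penalty, which keeps estimates finite under the
monotone-likelihood (separation) regime common at these sample sizes.
Cohort z-scores are combined with sqrt(effective-sample-size) weights,
n_eff = n+ n- / (n+ + n-).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "Mutation",
    "ModelSpec",
    "Cohort",
    "ExprAssoc",
    "SurvAssoc",
    "MetaResult",
    "PanelResult",
    "HOTSPOT_MODEL",
    "model_spec",
    "classify_sample",
    "expr_association",
    "dichotomize",
    "filter_stage",
    "firth_cox",
    "meta",
    "run_cohort_panel",
]

HOTSPOT_RULES: dict[str, frozenset[int]] = {
    "BRAF": frozenset({600, 601}),
    "NRAS": frozenset({61, 12, 13}),
}

# Cumulative driver-gene panels for Models 2-4.
_MODEL_GENES = {
    2: frozenset({"BRAF", "NRAS"}),
    3: frozenset({"BRAF", "NRAS", "KRAS", "HRAS"}),
    4: frozenset({"BRAF", "NRAS", "KRAS", "HRAS", "NF1"}),
}

# Stand-in for the 44-gene pan-cancer MAPK panel (the full list is a
# configurable input); a 10-gene subset ships as the default for Model 5.
DEFAULT_MODEL5_GENES = frozenset(
    {
        "BRAF", "NRAS", "KRAS", "HRAS", "NF1",
        "MAP2K1", "MAP2K2", "RAF1", "RASA2", "PTPN11",
    }
)

_POSITION_RE = re.compile(r"(\d+)")


@dataclass(frozen=True)
class Mutation:
    """One somatic mutation: gene, protein change (e.g. V600E), driver flag."""

    gene: str
    protein_change: str
    driver: bool = False

    @property
    def position(self) -> int | None:
        m = _POSITION_RE.search(self.protein_change or "")
        return int(m.group(1)) if m else None


@dataclass
class ModelSpec:
    """One of the five RAS-MAPK classification models."""

    id: int
    hotspots: dict[str, frozenset[int]] = field(
        default_factory=lambda: dict(HOTSPOT_RULES)
    )
    genes: frozenset[str] = frozenset()
    assessed_genes: frozenset[str] | None = None  # None = all genes assessed

    def __post_init__(self):
        if self.id not in range(1, 6):
            raise ValueError("model id must be 1..5")
        if self.id >= 2 and not self.genes:
            self.genes = _MODEL_GENES.get(self.id, DEFAULT_MODEL5_GENES)


def model_spec(
    model_id: int,
    assessed_genes: frozenset[str] | None = None,
    model5_genes: frozenset[str] = DEFAULT_MODEL5_GENES,
) -> ModelSpec:
    genes = model5_genes if model_id == 5 else _MODEL_GENES.get(model_id, frozenset())
    return ModelSpec(id=model_id, genes=genes, assessed_genes=assessed_genes)


HOTSPOT_MODEL = ModelSpec(id=1)


def classify_sample(
    mutations: list[tuple[str, str, bool]] | list[Mutation], model: ModelSpec
) -> str:
    """Classify one sample as WT or mutant under a model.

    Model 1: mutant iff any mutation at a hotspot codon (BRAF 600/601, NRAS
    61/12/13) regardless of driver annotation. Models 2-5: mutant iff any
    driver-flagged mutation in the model's gene panel, restricted to the
    cohort's assessed genes; otherwise WT over the assessed genes.
    """
    muts = [
        m if isinstance(m, Mutation) else Mutation(*m) for m in (mutations or [])
    ]
    if model.id == 1:
        for m in muts:
            codons = model.hotspots.get(m.gene)
            if codons is None:
                continue
            pos = m.position
            if pos is None:
                warnings.warn(
                    f"unparseable protein change {m.protein_change!r} on hotspot "
                    f"gene {m.gene}; treated as non-hotspot",
                    stacklevel=2,
                )
                continue
            if pos in codons:
                return "mutant"
        return "WT"
    panel = model.genes
    if model.assessed_genes is not None:
        panel = panel & model.assessed_genes
    for m in muts:
        if m.driver and m.gene in panel:
            return "mutant"
    return "WT"


@dataclass
class Cohort:
    """A tumor cohort: per-sample table plus a MAF-like mutation table.

    samples columns: sample, expression, age, sex, purity, stage,
    survival_days, event, treatment_class (covariates optionally missing).
    mutations columns: sample, gene, protein_change, driver.
    """

    name: str
    samples: pd.DataFrame
    mutations: pd.DataFrame

    def __post_init__(self):
        if "sample" not in self.samples.columns:
            raise ValueError("samples table needs a 'sample' column")
        if "survival_days" in self.samples.columns:
            days = self.samples["survival_days"].dropna()
            if (days < 0).any():
                raise ValueError("survival times must be non-negative")
        if "event" in self.samples.columns:
            ev = self.samples["event"].dropna()
            if not set(ev.unique()) <= {0, 1}:
                raise ValueError("event indicator must be 0/1")

    @property
    def n(self) -> int:
        return len(self.samples)

    def mutations_by_sample(self) -> dict[str, list[Mutation]]:
        out: dict[str, list[Mutation]] = {s: [] for s in self.samples["sample"]}
        for row in self.mutations.itertuples(index=False):
            if row.sample in out:
                out[row.sample].append(
                    Mutation(row.gene, row.protein_change, bool(row.driver))
                )
        return out

    def classify(self, model: ModelSpec) -> pd.Series:
        muts = self.mutations_by_sample()
        labels = [
            classify_sample(muts[s], model) for s in self.samples["sample"]
        ]
        return pd.Series(labels, index=self.samples.index, name=f"model{model.id}")


@dataclass
class ExprAssoc:
    """WT-vs-mutant expression association (positive beta = higher in WT)."""

    cohort: str
    model_id: int
    beta: float
    se: float
    z: float
    p: float
    n_wt: int
    n_mut: int
    covariates: list[str]


@dataclass
class SurvAssoc:
    """Cox association of the high-expression group with survival."""

    cohort: str
    log_hr: float
    se: float
    z: float
    p: float
    n: int
    events: int
    n_high: int
    n_low: int
    firth: bool


@dataclass
class MetaResult:
    """Sample-size-weighted z-score meta-analysis."""

    z: np.ndarray
    n_eff: np.ndarray
    weights: np.ndarray
    z_meta: float
    p: float

    def __post_init__(self):
        if not np.isclose(np.sum(self.weights**2), 1.0, atol=1e-10):
            raise ValueError("meta weights must satisfy sum w_i^2 = 1")


_STAGE_ORDER = {"I": 1, "II": 2, "III": 3, "IV": 4}


def _covariate_matrix(df: pd.DataFrame, covariates: list[str]):
    """Numeric covariate columns; stage encoded ordinally I<II<III<IV.
    Covariates missing for the whole cohort are dropped; samples with
    remaining missingness are dropped by the caller via the returned frame."""
    cols = {}
    used = []
    for cov in covariates:
        if cov not in df.columns:
            continue
        col = df[cov]
        if cov == "stage":
            col = col.map(lambda s: _STAGE_ORDER.get(s, np.nan))
        col = pd.to_numeric(col, errors="coerce")
        if col.notna().sum() == 0:
            continue
        if col.nunique(dropna=True) < 2:
            continue  # constant covariate carries no information
        cols[cov] = col
        used.append(cov)
    return pd.DataFrame(cols, index=df.index), used


def expr_association(
    cohort: Cohort,
    model: ModelSpec,
    covariates: tuple[str, ...] = ("age", "sex", "purity", "stage"),
) -> ExprAssoc:
    """OLS of expression on the WT indicator plus available covariates."""
    import statsmodels.api as sm

    labels = cohort.classify(model)
    df = cohort.samples.copy()
    df["wt"] = (labels == "WT").astype(float)
    cov_df, used = _covariate_matrix(df, list(covariates))
    design = pd.concat([df[["expression", "wt"]], cov_df], axis=1).dropna()
    n_wt = int(design["wt"].sum())
    n_mut = int(len(design) - n_wt)
    if n_wt < 2 or n_mut < 2:
        raise ValueError(
            f"model {model.id} leaves an empty/degenerate group in cohort "
            f"{cohort.name} (WT={n_wt}, mutant={n_mut})"
        )
    X = sm.add_constant(design[["wt", *used]])
    fit = sm.OLS(design["expression"], X).fit()
    return ExprAssoc(
        cohort=cohort.name,
        model_id=model.id,
        beta=float(fit.params["wt"]),
        se=float(fit.bse["wt"]),
        z=float(fit.tvalues["wt"]),
        p=float(fit.pvalues["wt"]),
        n_wt=n_wt,
        n_mut=n_mut,
        covariates=used,
    )


def dichotomize(values: np.ndarray | pd.Series) -> np.ndarray:
    """High/low expression labels by the median of the full set of values;
    values equal to the median go to the low group."""
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least two values to dichotomize")
    med = np.median(values)
    high = values > med
    if not high.any():
        warnings.warn("all values at or below the median; no high group", stacklevel=2)
    return high


def filter_stage(cohort: Cohort, excluded: set[str] = frozenset({"I"})) -> Cohort:
    """Drop samples whose tumor stage is in ``excluded``; missing stage kept."""
    df = cohort.samples
    if "stage" not in df.columns or not excluded:
        return cohort
    keep = ~df["stage"].isin(list(excluded))
    keep |= df["stage"].isna()
    out = df[keep].reset_index(drop=True)
    if len(out) == 0:
        warnings.warn(f"stage filter removed every sample in {cohort.name}", stacklevel=2)
    muts = cohort.mutations[cohort.mutations["sample"].isin(out["sample"])]
    return Cohort(name=cohort.name, samples=out, mutations=muts.reset_index(drop=True))


# ---------------------------------------------------------------------------
# Firth-penalized Cox proportional hazards (Efron ties)


class _CoxData:
    """Pre-sorted survival data with tie groups for repeated evaluation."""

    def __init__(self, time, event, X):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != time.shape[0]:
            X = X.T
        order = np.argsort(time, kind="stable")
        self.t = time[order]
        self.d = event[order]
        self.X = X[order]
        self.n, self.p = self.X.shape
        # groups of tied event times
        self.groups = []
        uniq, starts = np.unique(self.t, return_index=True)
        starts = np.append(starts, self.n)
        for s, e in zip(starts[:-1], starts[1:]):
            D = np.arange(s, e)[self.d[s:e] == 1]
            if D.size:
                self.groups.append((int(s), D))

    def loglik_grad_info(self, beta):
        """Efron partial log-likelihood, score, and observed information."""
        eta = self.X @ beta
        eta = eta - eta.max()  # guard overflow; shifts cancel in all ratios
        w = np.exp(eta)
        wx = w[:, None] * self.X
        wxx = np.einsum("i,ij,ik->ijk", w, self.X, self.X)
        # suffix sums: risk set = samples with time >= t
        SW = np.cumsum(w[::-1])[::-1]
        SWX = np.cumsum(wx[::-1], axis=0)[::-1]
        SWXX = np.cumsum(wxx[::-1], axis=0)[::-1]
        ll = 0.0
        grad = np.zeros(self.p)
        info = np.zeros((self.p, self.p))
        for s, D in self.groups:
            m = D.size
            S, Sx, Sxx = SW[s], SWX[s], SWXX[s]
            ll += float(eta[D].sum())
            grad += self.X[D].sum(axis=0)
            if m == 1:
                mu = Sx / S
                ll -= np.log(S)
                grad -= mu
                info += Sxx / S - np.outer(mu, mu)
            else:
                SD = w[D].sum()
                SDx = wx[D].sum(axis=0)
                SDxx = wxx[D].sum(axis=0)
                for k in range(m):
                    f = k / m
                    phi = S - f * SD
                    mu = (Sx - f * SDx) / phi
                    ll -= np.log(phi)
                    grad -= mu
                    info += (Sxx - f * SDxx) / phi - np.outer(mu, mu)
        return ll, grad, info


def _penalized_loglik(data: _CoxData, beta, firth: bool):
    ll, grad, info = data.loglik_grad_info(beta)
    if not firth:
        return ll, grad, info
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf, grad, info
    return ll + 0.5 * logdet, grad, info


def _penalty_grad(data: _CoxData, beta, h: float = 1e-5) -> np.ndarray:
    """Central-difference gradient of 0.5 log det I(beta)."""
    p = beta.shape[0]
    g = np.zeros(p)
    for r in range(p):
        step = h * (1.0 + abs(beta[r]))
        bp, bm = beta.copy(), beta.copy()
        bp[r] += step
        bm[r] -= step
        _, _, ip = data.loglik_grad_info(bp)
        _, _, im = data.loglik_grad_info(bm)
        g[r] = 0.5 * (np.linalg.slogdet(ip)[1] - np.linalg.slogdet(im)[1]) / (2 * step)
    return g


def firth_cox(
    time,
    event,
    group,
    covariates: np.ndarray | None = None,
    firth: bool = True,
    max_iter: int = 100,
    tol: float = 1e-7,
    cohort: str = "cohort",
) -> SurvAssoc:
    """Cox proportional hazards for a binary (high-expression) group with
    optional covariates, maximizing the Firth-penalized partial likelihood
    l*(b) = l(b) + 1/2 log det I(b) by Newton steps with step-halving.

    Efron's method handles tied event times. With ``firth`` the estimate is
    finite even under complete separation, where the unpenalized partial
    likelihood is monotone. Standard errors come from the curvature of the
    penalized log-likelihood at the optimum.
    """
    group = np.asarray(group, dtype=float)
    cols = [group]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != group.shape[0]:
            cov = cov.T
        # standardize covariates for numerical stability; leaves the group
        # log-HR unchanged
        sd = cov.std(axis=0)
        sd[sd == 0] = 1.0
        cols.extend(((cov - cov.mean(axis=0)) / sd).T)
    X = np.column_stack(cols)
    event = np.asarray(event, dtype=int)
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("no events; Cox model is undefined")
    data = _CoxData(time, event, X)
    p = data.p

    beta = np.zeros(p)
    ll_pen, grad, info = _penalized_loglik(data, beta, firth)
    trace = [ll_pen]
    converged = False
    for _ in range(max_iter):
        score = grad + (_penalty_grad(data, beta) if firth else 0.0)
        try:
            direction = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            direction = np.linalg.lstsq(info, score, rcond=None)[0]
        step = 1.0
        for _half in range(40):
            cand = beta + step * direction
            ll_new, grad_new, info_new = _penalized_loglik(data, cand, firth)
            if ll_new >= ll_pen - 1e-12:
                break
            step /= 2.0
        else:
            raise RuntimeError(
                f"step-halving failed in Cox fit for {cohort}; trace={trace}"
            )
        beta, grad, info = cand, grad_new, info_new
        improvement = ll_new - ll_pen
        ll_pen = ll_new
        trace.append(ll_pen)
        if np.max(np.abs(score)) < tol or 0 <= improvement < 1e-12:
            converged = True
            break
    if not converged:
        if firth or np.max(np.abs(grad)) > 1e-2:
            raise RuntimeError(
                f"Cox fit did not converge for {cohort} after {max_iter} "
                f"iterations; trace tail={trace[-5:]}"
            )

    if firth:
        hess = _numeric_hessian(
            lambda b: _penalized_loglik(data, b, True)[0], beta
        )
        cov_matrix = np.linalg.inv(-hess)
    else:
        cov_matrix = np.linalg.inv(info)
    se = float(np.sqrt(cov_matrix[0, 0]))
    log_hr = float(beta[0])
    z = log_hr / se
    high = int(group.sum())
    return SurvAssoc(
        cohort=cohort,
        log_hr=log_hr,
        se=se,
        z=z,
        p=float(2 * norm.sf(abs(z))),
        n=int(group.shape[0]),
        events=n_events,
        n_high=high,
        n_low=int(group.shape[0] - high),
        firth=firth,
    )


def _numeric_hessian(f, x, h: float = 1e-4) -> np.ndarray:
    p = x.shape[0]
    H = np.zeros((p, p))
    f0 = f(x)
    steps = h * (1.0 + np.abs(x))
    for r in range(p):
        er = np.zeros(p)
        er[r] = steps[r]
        H[r, r] = (f(x + er) - 2 * f0 + f(x - er)) / steps[r] ** 2
        for c in range(r + 1, p):
            ec = np.zeros(p)
            ec[c] = steps[c]
            H[r, c] = H[c, r] = (
                f(x + er + ec) - f(x + er - ec) - f(x - er + ec) + f(x - er - ec)
            ) / (4 * steps[r] * steps[c])
    return H


# ---------------------------------------------------------------------------
# Meta-analysis


def meta(z, n_plus, n_minus) -> MetaResult:
    """Weighted z-score meta-analysis with effective sample sizes.

    n_eff_i = n+_i n-_i / (n+_i + n-_i); w_i = sqrt(n_eff_i / sum n_eff);
    Z_meta = sum w_i z_i, which is standard normal under the null. Any
    constant factor in n_eff cancels in the normalized weights.
    """
    z = np.asarray(z, dtype=float)
    n_plus = np.asarray(n_plus, dtype=float)
    n_minus = np.asarray(n_minus, dtype=float)
    if not (z.shape == n_plus.shape == n_minus.shape):
        raise ValueError("z, n_plus, n_minus must have equal length")
    if np.any(n_plus < 1) or np.any(n_minus < 1):
        raise ValueError("group sizes must be >= 1")
    n_eff = n_plus * n_minus / (n_plus + n_minus)
    w = np.sqrt(n_eff / n_eff.sum())
    z_meta = float(w @ z)
    return MetaResult(
        z=z, n_eff=n_eff, weights=w, z_meta=z_meta, p=float(2 * norm.sf(abs(z_meta)))
    )


@dataclass
class PanelResult:
    """Per-cohort results and per-stratum meta-analysis."""

    analysis: str
    per_cohort: dict[str, list]
    meta: dict[str, MetaResult]


def run_cohort_panel(
    cohorts: list[Cohort],
    model: ModelSpec,
    analysis: str = "expression",
    stratify_treatment: bool = True,
    expr_covariates: tuple[str, ...] = ("age", "sex", "purity", "stage"),
    surv_covariates: tuple[str, ...] = ("age",),
    excluded_stages: set[str] = frozenset({"I"}),
) -> PanelResult:
    """End-to-end cohort panel: classification, then per-cohort expression
    association or (stage filter -> dichotomize -> Firth-Cox on the WT
    subgroup) survival, then sqrt-effective-sample-size meta-analysis per
    treatment stratum.

    For the expression meta, n+/n- are the mutant/WT group sizes; for the
    survival meta, the high/low expression group sizes within the analyzed
    WT subgroup.
    """
    if analysis not in {"expression", "survival"}:
        raise ValueError("analysis must be 'expression' or 'survival'")
    strata: dict[str, list[Cohort]] = {}
    for c in cohorts:
        if stratify_treatment:
            key = str(c.samples["treatment_class"].mode().iloc[0])
        else:
            key = "all"
        strata.setdefault(key, []).append(c)
    if not strata:
        raise ValueError("no cohorts provided")

    per_cohort: dict[str, list] = {}
    metas: dict[str, MetaResult] = {}
    for stratum, members in strata.items():
        results = []
        for cohort in members:
            try:
                if analysis == "expression":
                    res = expr_association(cohort, model, expr_covariates)
                else:
                    filtered = filter_stage(cohort, excluded_stages)
                    high_all = dichotomize(filtered.samples["expression"].to_numpy())
                    wt_mask = (filtered.classify(model) == "WT").to_numpy()
                    sub = filtered.samples[wt_mask]
                    cov_df, _used = _covariate_matrix(sub, list(surv_covariates))
                    res = firth_cox(
                        sub["survival_days"].to_numpy(),
                        sub["event"].to_numpy(),
                        high_all[wt_mask].astype(float),
                        covariates=cov_df.to_numpy() if len(cov_df.columns) else None,
                        cohort=cohort.name,
                    )
            except Exception as exc:
                raise RuntimeError(
                    f"{analysis} analysis failed for cohort {cohort.name}: {exc}"
                ) from exc
            results.append(res)
        per_cohort[stratum] = results
        if analysis == "expression":
            z = [r.z for r in results]
            n_plus = [r.n_mut for r in results]
            n_minus = [r.n_wt for r in results]
        else:
            z = [r.z for r in results]
            n_plus = [r.n_high for r in results]
            n_minus = [r.n_low for r in results]
        metas[stratum] = meta(z, n_plus, n_minus)
    return PanelResult(analysis=analysis, per_cohort=per_cohort, meta=metas)
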