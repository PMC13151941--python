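"""Readers and writers for the pipeline's plain-text formats.

Summary statistics and cohort tables are TSV; LD matrices are
whitespace-delimited square matrices with a header row of variant ids;
interval tracks are BED (0-based half-open) with an optional name column;
interactions are BEDPE-like (chromA startA endA chromB startB endB score)
or a fragment-id dialect (frag_a frag_b score); mutations are a MAF-like
TSV (sample gene protein_change driver). Fine-mapping results use a TSV
schema (variant pip cs_index alpha method) that also accepts external
engines' output for the CCV union.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .finemap import CCVSet, CredibleSet, FineMapResult, LDMatrix, SummaryStats
from .tumor import Cohort
from .v2g import FragmentMap, InteractionTable

__all__ = [
    "write_summary", "read_summary",
    "write_ld", "read_ld",
    "write_bed", "read_bed",
    "write_fragments", "read_fragments",
    "write_interactions_bedpe", "read_interactions",
    "write_cohort", "read_cohort",
    "write_finemap", "read_finemap",
    "write_ccv", "write_weights", "read_weights",
]


def write_summary(stats: SummaryStats, path) -> None:
    m = stats.m
    df = pd.DataFrame(
        {
            "id": stats.ids,
            "chrom": stats.chrom if stats.chrom is not None else ["."] * m,
            "pos": stats.pos if stats.pos is not None else np.zeros(m, dtype=int),
            "ref": stats.ref if stats.ref is not None else ["A"] * m,
            "alt": stats.alt if stats.alt is not None else ["G"] * m,
            "z": stats.z,
            "n": stats.n,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_summary(path) -> SummaryStats:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str})
    return SummaryStats(
        ids=list(df["id"]),
        z=df["z"].to_numpy(float),
        n=int(df["n"].iloc[0]),
        chrom=list(df["chrom"]),
        pos=df["pos"].to_numpy(int),
        ref=list(df["ref"].astype(str)),
        alt=list(df["alt"].astype(str)),
    )


def write_ld(ld: LDMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(" ".join(ld.ids) + "\n")
        np.savetxt(fh, ld.R, fmt="%.10g")


def read_ld(path) -> LDMatrix:
    with open(path) as fh:
        ids = fh.readline().split()
        R = np.loadtxt(fh)
    return LDMatrix(ids=ids, R=np.atleast_2d(R))


def write_bed(df: pd.DataFrame, path, name_col: str | None = None) -> None:
    cols = ["chrom", "start", "end"] + ([name_col] if name_col else [])
    df[cols].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path, name_col: str | None = None) -> pd.DataFrame:
    names = ["chrom", "start", "end"] + ([name_col] if name_col else [])
    return pd.read_csv(
        path, sep="\t", header=None, names=names, usecols=range(len(names))
    )


def write_fragments(fm: FragmentMap, path) -> None:
    pd.DataFrame(
        {"chrom": fm.chrom, "start": fm.starts, "end": fm.ends,
         "id": np.arange(len(fm))}
    ).to_csv(path, sep="\t", index=False, header=False)


def read_fragments(path) -> FragmentMap:
    df = read_bed(path, name_col="id")
    chrom = str(df["chrom"].iloc[0])
    return FragmentMap(chrom, df["start"].to_numpy(int), df["end"].to_numpy(int))


def write_interactions_bedpe(
    table: InteractionTable, fm: FragmentMap, path
) -> None:
    rows = []
    for r in table.table.itertuples(index=False):
        a, b = fm.interval(r.frag_a), fm.interval(r.frag_b)
        rows.append((a.chrom, a.start, a.end, b.chrom, b.start, b.end, r.score))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def read_interactions(path, fm: FragmentMap) -> InteractionTable:
    """Read a fragment-id dialect (3 columns) or BEDPE (7 columns) file."""
    df = pd.read_csv(path, sep="\t", header=None)
    if df.shape[1] == 3:
        df.columns = ["frag_a", "frag_b", "score"]
    elif df.shape[1] >= 7:
        frag_a = [fm.fragment_at((int(r[1]) + int(r[2])) // 2) for r in df.itertuples(index=False)]
        frag_b = [fm.fragment_at((int(r[4]) + int(r[5])) // 2) for r in df.itertuples(index=False)]
        df = pd.DataFrame({"frag_a": frag_a, "frag_b": frag_b, "score": df[6]})
    else:
        raise ValueError("unrecognized interaction file layout")
    return InteractionTable(df, fm)


def write_cohort(cohort: Cohort, samples_path, mutations_path) -> None:
    cohort.samples.to_csv(samples_path, sep="\t", index=False)
    cohort.mutations.to_csv(mutations_path, sep="\t", index=False)


def read_cohort(samples_path, mutations_path, name: str = "cohort") -> Cohort:
    samples = pd.read_csv(samples_path, sep="\t", dtype={"sample": str})
    mutations = pd.read_csv(
        mutations_path, sep="\t", dtype={"sample": str, "gene": str}
    )
    if len(mutations) == 0:
        mutations = pd.DataFrame(
            columns=["sample", "gene", "protein_change", "driver"]
        )
    mutations["driver"] = mutations["driver"].astype(bool)
    return Cohort(name=name, samples=samples, mutations=mutations)


def write_finemap(result: FineMapResult, path) -> None:
    rows = []
    in_cs = {}
    for cs in result.credible_sets:
        for v, a in zip(cs.variants, cs.alpha):
            in_cs[v] = (cs.effect, a)
    pip_of = dict(zip(result.ids, result.pip))
    for v in result.ids:
        effect, a = in_cs.get(v, (-1, np.nan))
        rows.append((v, pip_of[v], effect, a, result.method))
    pd.DataFrame(
        rows, columns=["variant", "pip", "cs_index", "alpha", "method"]
    ).to_csv(path, sep="\t", index=False)


def read_finemap(path) -> FineMapResult:
    """Read a fine-mapping TSV (any engine's output in the documented
    schema: variant, pip, cs_index, alpha, method; cs_index -1 = no set)."""
    df = pd.read_csv(path, sep="\t", dtype={"variant": str})
    ids = list(df["variant"])
    pip = df["pip"].to_numpy(float)
    method = str(df["method"].iloc[0]) if len(df) else "external"
    effects = sorted({int(e) for e in df["cs_index"] if int(e) >= 0})
    m = len(ids)
    L = max(1, len(effects))
    alpha = np.zeros((L, m))
    lbf = np.zeros((L, m))
    sets = []
    if not effects:
        alpha[0] = 1.0 / m
    for row_l, effect in enumerate(effects):
        sub = df[df["cs_index"] == effect]
        members = [ids.index(v) for v in sub["variant"]]
        vals = sub["alpha"].to_numpy(float)
        alpha[row_l, members] = vals
        rest = np.setdiff1d(np.arange(m), members)
        leftover = max(0.0, 1.0 - vals.sum())
        if rest.size:
            alpha[row_l, rest] = leftover / rest.size
        sets.append(
            CredibleSet(
                effect=effect,
                variants=list(sub["variant"]),
                alpha=vals,
                cum_alpha=float(vals.sum()),
                purity=float("nan"),
            )
        )
    return FineMapResult(
        method=method, ids=ids, pip=pip, alpha=alpha, lbf=lbf,
        prior_variance=np.zeros(L), credible_sets=sets,
    )


def write_ccv(ccv: CCVSet, path) -> None:
    rows = [(v, ",".join(sorted(ccv.provenance[v]))) for v in ccv.ids]
    pd.DataFrame(rows, columns=["variant", "provenance"]).to_csv(
        path, sep="\t", index=False
    )


def write_weights(weights_list, path) -> None:
    rows = []
    for w in weights_list:
        for vid, val in zip(w.ids, w.w):
            if val != 0:
                rows.append((w.gene, vid, val, w.method))
    pd.DataFrame(rows, columns=["gene", "variant", "weight", "method"]).to_csv(
        path, sep="\t", index=False
    )


def read_weights(path, ids: list[str]):
    """Read a weights TSV into per-gene ExpressionWeights aligned to ids."""
    from .twas import ExpressionWeights

    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "variant": str})
    out = []
    index = {v: i for i, v in enumerate(ids)}
    for gene, sub in df.groupby("gene"):
        w = np.zeros(len(ids))
        for r in sub.itertuples(index=False):
            w[index[r.variant]] = r.weight
        method = str(sub["method"].iloc[0]) if "method" in sub else "custom"
        out.append(ExpressionWeights(gene=gene, ids=list(ids), w=w, method=method))
    return out


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
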