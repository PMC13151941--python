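"""Regulatory annotation of fine-mapped variants and capture-HiC-based
variant-to-gene nomination.

Variants are flagged enhancer/promoter/ATAC from chromHMM-style state tracks
and accessibility peaks (cis-regulatory = any of the three); each variant is
expanded into a +/-500 bp window, mapped to restriction fragments (plus the
immediately adjacent fragments), and genes are nominated when a
high-confidence interaction (score > 5) links a variant-harboring fragment
to the gene's promoter fragment. All interval logic is 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "RegulatoryClassMap",
    "FragmentMap",
    "InteractionTable",
    "VariantAnnotation",
    "CandidateGene",
    "GeneModel",
    "classify_state",
    "annotate_variants",
    "variant_window",
    "fragments_for",
    "nominate",
    "refine_regulatory",
    "assign_probe_to_gene",
]


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


# chromHMM vocabularies used to call enhancers and promoters, per source
# cell class: melanocyte tracks (Roadmap primary/auxiliary/imputed models)
# and a tumorigenic melanoma cell model.
MELANOCYTE_ENHANCER_STATES = frozenset(
    {
        "Enh", "EnhG", "EnhBiv",  # primary
        "EnhG1", "EnhG2", "EnhA1", "EnhA2", "EnhWk",  # auxiliary
        "TxEnh5", "TxEnh3", "TxEnhW", "EnhAF", "EnhW1", "EnhW2", "EnhAc",  # imputed
    }
)
MELANOCYTE_PROMOTER_STATES = frozenset(
    {"PromU", "PromD1", "PromD2", "TssA", "PromP", "PromBiv", "Tx_Reg"}
)
MELANOMA_ENHANCER_STATES = frozenset(
    {"4_EnhA", "5_EnhM", "6_EnhW", "7_TxEnhM", "7_TxEnhW", "9_TxWkEnhW"}
)
MELANOMA_PROMOTER_STATES = frozenset({"1_TssA", "2_PromWkD", "3_TssWkP"})


@dataclass
class RegulatoryClassMap:
    """Maps (source cell class, chromHMM state) to enhancer/promoter/other."""

    enhancer: dict[str, frozenset[str]] = field(
        default_factory=lambda: {
            "melanocyte": MELANOCYTE_ENHANCER_STATES,
            "melanoma": MELANOMA_ENHANCER_STATES,
        }
    )
    promoter: dict[str, frozenset[str]] = field(
        default_factory=lambda: {
            "melanocyte": MELANOCYTE_PROMOTER_STATES,
            "melanoma": MELANOMA_PROMOTER_STATES,
        }
    )


def classify_state(
    state: str, source: str, cmap: RegulatoryClassMap | None = None
) -> str:
    """Classify a chromHMM state name as enhancer, promoter, or other."""
    cmap = cmap or RegulatoryClassMap()
    if state in cmap.enhancer.get(source, frozenset()):
        return "enhancer"
    if state in cmap.promoter.get(source, frozenset()):
        return "promoter"
    known = cmap.enhancer.get(source, frozenset()) | cmap.promoter.get(
        source, frozenset()
    )
    if state not in known:
        warnings.warn(
            f"unknown chromHMM state {state!r} for source {source!r}; "
            "classified as other",
            stacklevel=2,
        )
    return "other"


@dataclass
class VariantAnnotation:
    """Regulatory flags for one variant; cis_regulatory is the OR of the rest."""

    variant: str
    enhancer: bool = False
    promoter: bool = False
    atac: bool = False

    @property
    def cis_regulatory(self) -> bool:
        return self.enhancer or self.promoter or self.atac


def _build_trees(track: pd.DataFrame, value_col: str | None = None):
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in track.groupby("chrom"):
        tree = IntervalTree()
        for row in sub.itertuples(index=False):
            data = getattr(row, value_col) if value_col else None
            tree.addi(int(row.start), int(row.end), data)
        trees[chrom] = tree
    return trees


def annotate_variants(
    variants: pd.DataFrame,
    state_tracks: list[tuple[str, pd.DataFrame]],
    atac_tracks: list[pd.DataFrame],
    cmap: RegulatoryClassMap | None = None,
    chrom_whitelist: set[str] | None = None,
) -> list[VariantAnnotation]:
    """Point-in-interval annotation of variants against chromatin tracks.

    ``variants`` needs columns (id, chrom, pos); each state track is a
    (source class, BED-like frame with chrom/start/end/state) pair; ATAC
    tracks are BED-like frames. Overlap is half-open: a variant at position
    ``end`` does not overlap [start, end).
    """
    cmap = cmap or RegulatoryClassMap()
    state_trees = [
        (source, _build_trees(track, "state")) for source, track in state_tracks
    ]
    atac_trees = [_build_trees(track) for track in atac_tracks]
    known_chroms = chrom_whitelist
    if known_chroms is None:
        known_chroms = set()
        for _, trees in state_trees:
            known_chroms |= set(trees)
        for trees in atac_trees:
            known_chroms |= set(trees)

    out = []
    for row in variants.itertuples(index=False):
        chrom, pos = str(row.chrom), int(row.pos)
        if known_chroms and chrom not in known_chroms:
            warnings.warn(
                f"variant {row.id} on {chrom} outside annotated chromosomes; skipped",
                stacklevel=2,
            )
            continue
        ann = VariantAnnotation(variant=str(row.id))
        for source, trees in state_trees:
            tree = trees.get(chrom)
            if tree is None:
                continue
            for hit in tree.at(pos):
                cls = classify_state(hit.data, source, cmap)
                if cls == "enhancer":
                    ann.enhancer = True
                elif cls == "promoter":
                    ann.promoter = True
        for trees in atac_trees:
            tree = trees.get(chrom)
            if tree is not None and tree.at(pos):
                ann.atac = True
        out.append(ann)
    return out


def variant_window(pos: int, pad: int = 500, chrom: str = "chr9") -> GenomicInterval:
    """+/- ``pad`` bp window around a 1-bp variant, clamped at position 0."""
    if pos < 0:
        raise ValueError("position must be non-negative")
    return GenomicInterval(chrom, max(0, pos - pad), pos + pad + 1)


@dataclass
class FragmentMap:
    """Ordered, gap-free restriction fragments tiling one chromosome span."""

    chrom: str
    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=int)
        self.ends = np.asarray(self.ends, dtype=int)
        if self.starts.shape != self.ends.shape:
            raise ValueError("starts/ends mismatch")
        if np.any(self.ends <= self.starts):
            raise ValueError("fragments must be non-empty intervals")
        if np.any(self.starts[1:] != self.ends[:-1]):
            raise ValueError("fragments must be sorted and gap-free")

    @classmethod
    def from_cut_positions(
        cls, chrom: str, cut_positions: list[int], length: int
    ) -> "FragmentMap":
        """Fragments tile [0, length) between consecutive cut positions."""
        bounds = [0, *cut_positions, length]
        return cls(chrom, np.array(bounds[:-1]), np.array(bounds[1:]))

    def __len__(self) -> int:
        return int(self.starts.shape[0])

    def interval(self, frag_id: int) -> GenomicInterval:
        return GenomicInterval(self.chrom, int(self.starts[frag_id]), int(self.ends[frag_id]))

    def fragment_at(self, pos: int) -> int:
        """Id of the fragment containing ``pos``; KeyError outside the span."""
        if pos < self.starts[0] or pos >= self.ends[-1]:
            raise KeyError(f"position {pos} outside fragment map span")
        return int(np.searchsorted(self.ends, pos, side="right"))

    def overlapping(self, window: GenomicInterval) -> np.ndarray:
        """Ids of fragments overlapping a half-open window (possibly empty)."""
        if window.chrom != self.chrom:
            return np.array([], dtype=int)
        lo = int(np.searchsorted(self.ends, window.start, side="right"))
        hi = int(np.searchsorted(self.starts, window.end, side="left"))
        return np.arange(lo, hi)

    def merged(self, k: int = 4) -> "FragmentMap":
        """Aggregate every ``k`` consecutive fragments (coarser resolution)."""
        starts = self.starts[::k]
        ends = np.append(self.ends[k - 1 :: k], self.ends[-1])[: starts.shape[0]]
        return FragmentMap(self.chrom, starts, ends)


def fragments_for(window: GenomicInterval, fm: FragmentMap) -> set[int]:
    """Fragments overlapping the window plus the immediate left/right
    neighbors of the overlapping run (adjacent-fragment rule)."""
    run = fm.overlapping(window)
    if run.size == 0:
        warnings.warn("window outside the fragment map span", stacklevel=2)
        return set()
    lo = max(0, int(run[0]) - 1)
    hi = min(len(fm) - 1, int(run[-1]) + 1)
    return set(range(lo, hi + 1))


class InteractionTable:
    """Scored fragment-pair chromatin contacts (unordered pairs).

    Duplicate pairs (in either orientation) are deduplicated keeping the
    maximum score.
    """

    def __init__(self, table: pd.DataFrame, fragments: FragmentMap | None = None):
        df = table[["frag_a", "frag_b", "score"]].copy()
        df["frag_a"] = df["frag_a"].astype(int)
        df["frag_b"] = df["frag_b"].astype(int)
        df["score"] = df["score"].astype(float)
        if not np.all(np.isfinite(df["score"])):
            raise ValueError("interaction scores must be finite")
        if fragments is not None:
            valid = (
                df[["frag_a", "frag_b"]].ge(0).all(axis=None)
                and df[["frag_a", "frag_b"]].lt(len(fragments)).all(axis=None)
            )
            if not valid:
                raise ValueError("interaction fragment ids outside the fragment map")
        lo = df[["frag_a", "frag_b"]].min(axis=1)
        hi = df[["frag_a", "frag_b"]].max(axis=1)
        df["frag_a"], df["frag_b"] = lo, hi
        df = df.groupby(["frag_a", "frag_b"], as_index=False)["score"].max()
        self.table = df
        self.fragments = fragments

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class CandidateGene:
    """A gene nominated by chromatin interaction, with supporting variants."""

    gene: str
    variants: list[str]
    evidence: str = "interaction_only"  # or "enhancer_promoter"

    def __post_init__(self):
        if not self.variants:
            raise ValueError("a candidate gene needs at least one supporting variant")


def nominate(
    variant_fragments: dict[str, set[int]],
    interactions: InteractionTable,
    promoter_fragments: dict[str, set[int]],
    score_min: float = 5.0,
) -> list[CandidateGene]:
    """Nominate genes whose promoter fragment is linked to a variant
    (or adjacent) fragment by an interaction with score strictly > score_min."""
    hi = interactions.table[interactions.table["score"] > score_min]
    pair_index: dict[int, set[int]] = {}
    for row in hi.itertuples(index=False):
        pair_index.setdefault(row.frag_a, set()).add(row.frag_b)
        pair_index.setdefault(row.frag_b, set()).add(row.frag_a)
    out = []
    for gene in sorted(promoter_fragments):
        prom = promoter_fragments[gene]
        supporters = []
        for variant in sorted(variant_fragments):
            frags = variant_fragments[variant]
            linked = set()
            for f in frags:
                linked |= pair_index.get(f, set())
            if linked & prom:
                supporters.append(variant)
        if supporters:
            out.append(CandidateGene(gene=gene, variants=supporters))
    return out


def refine_regulatory(
    candidates: list[CandidateGene], annotations: list[VariantAnnotation]
) -> list[CandidateGene]:
    """Upgrade evidence to enhancer_promoter when any supporting variant is
    cis-regulatory; purely interaction-supported genes are retained."""
    regulatory = {a.variant for a in annotations if a.cis_regulatory}
    out = []
    for cand in candidates:
        if any(v in regulatory for v in cand.variants):
            out.append(replace(cand, evidence="enhancer_promoter"))
        else:
            out.append(replace(cand, evidence="interaction_only"))
    return out


@dataclass
class GeneModel:
    """Gene features for CpG probe assignment (all half-open intervals)."""

    gene: str
    tss: int
    features: list[tuple[str, GenomicInterval]] = field(default_factory=list)


def assign_probe_to_gene(
    cpg_pos: int, genes: list[GeneModel], tss_window: int = 1500
) -> set[str]:
    """Assign a CpG probe to genes: within ``tss_window`` bp of the TSS, or
    inside the 5'UTR, first exon, gene body, or 3'UTR."""
    out = set()
    for gm in genes:
        if abs(cpg_pos - gm.tss) <= tss_window:
            out.add(gm.gene)
            continue
        if any(iv.contains(cpg_pos) for _, iv in gm.features):
            out.add(gm.gene)
    return out
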