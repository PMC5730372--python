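"""Compartment-list intersection, hypergeometric significance and laminar calls.

Two called lists drawn from a shared expressed-gene universe are intersected;
the size of the overlap is tested against the hypergeometric null (draw n2
genes from a universe of N containing n1 marked genes; upper tail P(X >= k)).
The nuclear-lamina workflow intersects a nuclear list with an ER-lumen list
and removes secretory mRNAs, whose overlap can be explained by nuclear
pre-mRNA plus mature ER-localized transcripts of the same gene rather than by
residence at the nuclear envelope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd
from scipy import stats

from .enrichment import EnrichedList
from .errors import ParameterError, ValidationError
from .io_tables import SECRETORY_FLAGS, normalize_gene_id

logger = logging.getLogger(__name__)


@dataclass
class OverlapResult:
    list_a_label: str
    list_b_label: str
    universe_size: int
    size_a: int
    size_b: int
    overlap: set[str]
    p_upper: float
    per_class: dict[str, tuple[int, int, int, int, float]] = field(default_factory=dict)
    bh_corrected: dict[str, float] | None = None

    @property
    def k(self) -> int:
        return len(self.overlap)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("all", self.k, self.size_a, self.size_b, self.universe_size, self.p_upper)
        ]
        for cls, (k, n1, n2, n, p) in sorted(self.per_class.items()):
            rows.append((cls, k, n1, n2, n, p))
        return pd.DataFrame(
            rows, columns=["class", "k", "n_a", "n_b", "universe", "p_upper"]
        )


@dataclass
class LaminarCandidates:
    all_overlap: set[str]
    candidates: set[str]
    removed_secretory_mrnas: set[str]
    class_counts: dict[str, int]


def intersect_lists(a: EnrichedList, b: EnrichedList) -> set[str]:
    """Exact intersection of two called lists (version-normalized ids)."""
    return set(a.genes) & set(b.genes)


def hypergeometric_upper(k: int, n1: int, n2: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, n1, n2).

    Computed through scipy's survival function, which works in log space and
    is stable for universes up to at least 1e5 genes.
    """
    if not (0 <= n1 <= N and 0 <= n2 <= N):
        raise ParameterError(f"need 0 <= n1, n2 <= N; got n1={n1}, n2={n2}, N={N}")
    if not 0 <= k <= min(n1, n2):
        raise ParameterError(f"need 0 <= k <= min(n1, n2); got k={k}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, n1, n2))


def overlap_analysis(
    a: EnrichedList,
    b: EnrichedList,
    universe: set[str],
    annot: pd.DataFrame | None = None,
    bh_correct: bool = False,
) -> OverlapResult:
    """Global and per-biotype-class overlap significance.

    The universe must contain both lists. Per-class tests restrict the
    universe, both lists and the overlap to genes of that class (biotype from
    ``annot``, falling back to the lists' own records); Benjamini–Hochberg
    correction across classes is available but off by default.
    """
    universe = {normalize_gene_id(g) for g in universe}
    stray = (a.genes | b.genes) - universe
    if stray:
        raise ValidationError(
            f"{len(stray)} called genes outside the declared universe, "
            f"e.g. {sorted(stray)[:5]}"
        )
    overlap = intersect_lists(a, b)
    result = OverlapResult(
        list_a_label=a.label,
        list_b_label=b.label,
        universe_size=len(universe),
        size_a=len(a.genes),
        size_b=len(b.genes),
        overlap=overlap,
        p_upper=hypergeometric_upper(len(overlap), len(a.genes), len(b.genes), len(universe)),
    )

    biotype_of: dict[str, str] = {}
    if annot is not None:
        sub = annot.drop_duplicates("gene_id_norm")
        biotype_of.update(zip(sub["gene_id_norm"], sub["biotype"]))
    for lst in (a, b):
        if not lst.records.empty and "biotype" in lst.records:
            for gid, bt in zip(lst.records["gene_id_norm"], lst.records["biotype"]):
                biotype_of.setdefault(gid, bt)

    classes = sorted({biotype_of.get(g, "unknown") for g in universe})
    for cls in classes:
        uni_c = {g for g in universe if biotype_of.get(g, "unknown") == cls}
        a_c = a.genes & uni_c
        b_c = b.genes & uni_c
        k_c = len(overlap & uni_c)
        p_c = hypergeometric_upper(k_c, len(a_c), len(b_c), len(uni_c)) if uni_c else 1.0
        result.per_class[cls] = (k_c, len(a_c), len(b_c), len(uni_c), p_c)

    if bh_correct and result.per_class:
        from statsmodels.stats.multitest import multipletests

        names = sorted(result.per_class)
        pvals = [result.per_class[c][4] for c in names]
        _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
        result.bh_corrected = dict(zip(names, map(float, p_adj)))
    return result


def laminar_candidates(
    nuclear: EnrichedList, er: EnrichedList, annot: pd.DataFrame
) -> LaminarCandidates:
    """Nominate lamina-proximal RNAs from the nuclear ∩ ER overlap.

    Protein-coding genes carrying any secretory flag are removed from the
    overlap; the survivors are split into mRNA (protein_coding) vs noncoding.
    Symmetric in its two list arguments.
    """
    overlap = intersect_lists(nuclear, er)
    sub = annot.drop_duplicates("gene_id_norm").set_index("gene_id_norm")
    # annotation is the biotype authority; list records are the fallback
    biotype_of: dict[str, str] = {}
    for lst in (nuclear, er):
        if not lst.records.empty and "biotype" in lst.records:
            biotype_of.update(zip(lst.records["gene_id_norm"], lst.records["biotype"]))
    biotype_of.update(zip(sub.index, sub["biotype"]))

    removed: set[str] = set()
    for g in overlap:
        if biotype_of.get(g, "unknown") == "protein_coding" and g in sub.index:
            if bool(sub.loc[g, list(SECRETORY_FLAGS)].any()):
                removed.add(g)
    candidates = overlap - removed
    class_counts = {
        "mRNA": sum(
            1 for g in candidates if biotype_of.get(g, "unknown") == "protein_coding"
        ),
    }
    class_counts["noncoding"] = len(candidates) - class_counts["mRNA"]
    logger.info(
        "laminar workflow: %d overlapping RNAs, %d secretory mRNAs removed, "
        "%d candidates (%d mRNA, %d noncoding)",
        len(overlap),
        len(removed),
        len(candidates),
        class_counts["mRNA"],
        class_counts["noncoding"],
    )
    return LaminarCandidates(
        all_overlap=overlap,
        candidates=candidates,
        removed_secretory_mrnas=removed,
        class_counts=class_counts,
    )


def venn_counts(lists: list[EnrichedList]) -> dict[str, int]:
    """Exclusive-region counts for 2 or 3 called lists.

    Region keys are '1', '2', '12', ... naming the member lists (1-based, in
    input order); counts over all regions sum to the union size.
    """
    if not 2 <= len(lists) <= 3:
        raise ParameterError(f"venn_counts supports 2 or 3 lists, got {len(lists)}")
    sets = [lst.genes for lst in lists]
    union = set().union(*sets)
    regions: dict[str, int] = {}
    idx = range(1, len(sets) + 1)
    for r in range(1, len(sets) + 1):
        for members in combinations(idx, r):
            inside = set.intersection(*(sets[i - 1] for i in members))
            outside = set().union(*(sets[i - 1] for i in idx if i not in members))
            regions["".join(map(str, members))] = len(inside - outside)
    assert sum(regions.values()) == len(union)
    return regions
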