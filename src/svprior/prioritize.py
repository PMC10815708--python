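"""The SV prioritization cascade.

Per caller and per subgroup: length filter -> ACMG filter -> within-subgroup
sharing by reciprocal overlap (single-linkage clusters, >= 2 carriers) ->
gene annotation (split rows) -> FLAGS/olfactory blacklist filter ->
severe-unique gene selection; the per-caller paths stay independent until a
final cross-caller consensus keeps only regions supported by at least two
callers.  Cross-caller SV-type conflicts (one caller says DEL, another DUP)
are flagged on the consensus record, never silently resolved beyond the
majority label.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from intervaltree import IntervalTree

from .model import (
    ACMGClass,
    CandidateRegion,
    GeneInterval,
    SVCall,
    SVCluster,
    SVType,
    normalize_chrom,
    worst_acmg,
)

logger = logging.getLogger("svprior")

DEFAULT_KEEP_ACMG = frozenset(
    {ACMGClass.PATHOGENIC, ACMGClass.LIKELY_PATHOGENIC, ACMGClass.UNCERTAIN}
)


# ---------------------------------------------------------------------------
# Elementary filters
# ---------------------------------------------------------------------------

def filter_by_length(calls: Sequence[SVCall], max_length: int = 100_000) -> List[SVCall]:
    """Rule out calls longer than ``max_length`` bp ("greater than" is
    strict: a call of exactly ``max_length`` survives).  Order preserved."""
    return [c for c in calls if c.length <= max_length]


def filter_by_acmg(
    calls: Sequence[SVCall],
    keep_classes: Iterable[ACMGClass] = DEFAULT_KEEP_ACMG,
) -> List[SVCall]:
    """Keep pathogenic / likely-pathogenic / uncertain calls (by default);
    benign, likely-benign and unclassified calls are dropped."""
    keep = frozenset(keep_classes)
    return [c for c in calls if c.acmg_class in keep]


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def overlap_bp(a: Tuple[str, int, int], b: Tuple[str, int, int]) -> int:
    """Intersection length of two (chrom, start, end] intervals, 0 when on
    different chromosomes."""
    if normalize_chrom(a[0]) != normalize_chrom(b[0]):
        return 0
    return max(0, min(a[2], b[2]) - max(a[1], b[1]))


def reciprocal_overlap(a: Tuple[str, int, int], b: Tuple[str, int, int]) -> float:
    """min(I/len(a), I/len(b)) with I the intersection length.

    Symmetric, in [0,1], equals 1 only for identical intervals, invariant
    under translation.  Zero-length intervals have no defined fraction.
    """
    len_a, len_b = a[2] - a[1], b[2] - b[1]
    if len_a <= 0 or len_b <= 0:
        raise ValueError("reciprocal overlap undefined for zero-length interval")
    inter = overlap_bp(a, b)
    return min(inter / len_a, inter / len_b)


def directional_overlap(a, b) -> float:
    """max of the two directional fractions (alternative matching mode)."""
    len_a, len_b = a[2] - a[1], b[2] - b[1]
    if len_a <= 0 or len_b <= 0:
        raise ValueError("overlap fraction undefined for zero-length interval")
    inter = overlap_bp(a, b)
    return max(inter / len_a, inter / len_b)


_OVERLAP_FNS = {"reciprocal": reciprocal_overlap, "directional": directional_overlap}


def _lower_median(values: Sequence[int]) -> int:
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def _majority_type(types: Sequence[SVType]) -> Tuple[SVType, bool]:
    """Majority vote over SV types; a tied vote yields OTHER plus a flag."""
    counts = Counter(types)
    top = counts.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        return SVType.OTHER, True
    return top[0][0], False


# ---------------------------------------------------------------------------
# Within-subgroup sharing
# ---------------------------------------------------------------------------

def cluster_shared(
    calls: Sequence[SVCall],
    min_ro: float = 0.60,
    min_samples: int = 2,
    overlap_mode: str = "reciprocal",
) -> List[SVCluster]:
    """Identify regions shared by >= ``min_samples`` samples of one subgroup.

    Single-linkage clustering over the graph whose edges join two calls with
    overlap fraction >= ``min_ro`` *and* the same SV type (the convention of
    RO-graph SV-merging tools).  Clusters carried by fewer than
    ``min_samples`` distinct samples are discarded.  The representative
    interval takes the member-wise lower-median start and end and the
    majority SV type (ties -> OTHER, flagged).

    All calls must come from one caller; BND and zero-length records carry
    no usable interval and are skipped with a log message.
    """
    overlap_fn = _OVERLAP_FNS[overlap_mode]
    usable = []
    for c in calls:
        if c.svtype is SVType.BND or c.length == 0:
            logger.info("skipping %s call without interval: %s", c.svtype.value, c)
            continue
        usable.append(c)
    if not usable:
        return []
    callers = {c.caller_id for c in usable}
    if len(callers) > 1:
        raise ValueError(f"cluster_shared expects one caller, got {sorted(callers)}")

    # group by (chrom, svtype): edges require both anyway
    groups: Dict[Tuple[str, SVType], List[SVCall]] = defaultdict(list)
    for c in usable:
        groups[(normalize_chrom(c.chrom), c.svtype)].append(c)

    clusters: List[SVCluster] = []
    for (_, _), members in groups.items():
        # sweep by start so only nearby pairs are tested
        members = sorted(members, key=lambda c: (c.start, c.end))
        parent = list(range(len(members)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        max_end = 0
        active: List[int] = []
        for j, cj in enumerate(members):
            active = [i for i in active if members[i].end > cj.start]
            for i in active:
                if overlap_fn(members[i].interval, cj.interval) >= min_ro:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
            active.append(j)
            max_end = max(max_end, cj.end)

        comps: Dict[int, List[SVCall]] = defaultdict(list)
        for i, c in enumerate(members):
            comps[find(i)].append(c)
        for comp in comps.values():
            samples = {c.sample_id for c in comp}
            if len(samples) < min_samples:
                continue
            svtype, tie = _majority_type([c.svtype for c in comp])
            clusters.append(
                SVCluster(
                    member_calls=comp,
                    carrier_samples=samples,
                    chrom=comp[0].chrom,
                    start=_lower_median([c.start for c in comp]),
                    end=_lower_median([c.end for c in comp]),
                    svtype=svtype,
                    caller_id=comp[0].caller_id,
                    type_tie=tie,
                )
            )
    clusters.sort(key=lambda cl: (normalize_chrom(cl.chrom), cl.start, cl.end))
    return clusters


# ---------------------------------------------------------------------------
# Gene annotation and blacklisting
# ---------------------------------------------------------------------------

class GeneIndex:
    """Interval-tree lookup from genomic region to overlapping genes."""

    def __init__(self, genes: Iterable[GeneInterval]):
        self._trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._by_symbol: Dict[str, List[GeneInterval]] = defaultdict(list)
        for g in genes:
            if g.end > g.start:
                self._trees[normalize_chrom(g.chrom)][g.start:g.end] = g
            self._by_symbol[g.gene_symbol].append(g)

    def overlapping(self, chrom: str, start: int, end: int) -> Set[str]:
        """Symbols of genes overlapping (start, end] by >= 1 bp."""
        if end <= start:
            return set()
        tree = self._trees.get(normalize_chrom(chrom))
        if tree is None:
            return set()
        return {iv.data.gene_symbol for iv in tree.overlap(start, end)}

    def coding(self, symbol: str) -> bool:
        return any(g.coding for g in self._by_symbol.get(symbol, []))


def annotate_genes(region: Tuple[str, int, int], genes) -> Set[str]:
    """Split-style annotation: one (region, gene) row per gene overlapping
    the region by at least 1 bp.  ``genes`` may be a :class:`GeneIndex` or a
    plain list of :class:`GeneInterval`."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    return index.overlapping(*region)


def filter_gene_blacklist(
    clusters: Sequence[SVCluster],
    flags_list: Set[str],
    olfactory_list: Set[str],
) -> List[SVCluster]:
    """Remove blacklisted gene rows (FLAGS = frequently mutated genes;
    olfactory receptors).  A region is dropped entirely only when all of its
    gene rows were removed."""
    blacklist = set(flags_list) | set(olfactory_list)
    out = []
    for cl in clusters:
        kept = cl.gene_symbols - blacklist
        if cl.gene_symbols and not kept:
            continue
        cl.gene_symbols = kept
        out.append(cl)
    return out


def severe_unique_genes(
    severe_clusters: Sequence[SVCluster],
    nonsevere_gene_set: Set[str],
) -> List[SVCluster]:
    """Keep severe (region, gene) rows whose gene appears in no retained
    non-severe region; a region survives when at least one of its genes
    survives."""
    out = []
    for cl in severe_clusters:
        kept = cl.gene_symbols - nonsevere_gene_set
        if not kept:
            continue
        cl.gene_symbols = kept
        out.append(cl)
    return out


# ---------------------------------------------------------------------------
# Cross-caller consensus
# ---------------------------------------------------------------------------

def cross_caller_consensus(
    per_caller_candidates: Dict[str, Sequence[SVCluster]],
    min_callers: int = 2,
    match_ro: float = 0.60,
    breakpoint_tol: int = 200,
    overlap_mode: str = "reciprocal",
) -> List[CandidateRegion]:
    """Intersect the per-caller candidate lists: keep regions supported by at
    least ``min_callers`` callers.

    Two candidates match when their reciprocal overlap is >= ``match_ro``
    *or* both breakpoints agree within ``breakpoint_tol`` bp (this rescues
    near-identical calls whose RO is skewed by one stray breakpoint).
    Matching ignores the SV type — callers are known to disagree on DEL vs
    DUP over the same region — and any disagreement within a consensus group
    sets ``type_discordant`` with the per-caller types recorded.
    """
    overlap_fn = _OVERLAP_FNS[overlap_mode]
    items: List[SVCluster] = []
    for caller, cands in sorted(per_caller_candidates.items()):
        items.extend(cands)
    if not items:
        return []

    n = len(items)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    by_chrom: Dict[str, List[int]] = defaultdict(list)
    for i, it in enumerate(items):
        by_chrom[normalize_chrom(it.chrom)].append(i)
    for idxs in by_chrom.values():
        idxs.sort(key=lambda i: (items[i].start, items[i].end))
        for a_pos, i in enumerate(idxs):
            ai = items[i]
            for j in idxs[a_pos + 1:]:
                aj = items[j]
                if aj.start - ai.end > breakpoint_tol:
                    break
                matched = (
                    overlap_fn(ai.interval, aj.interval) >= match_ro
                    or (
                        abs(ai.start - aj.start) <= breakpoint_tol
                        and abs(ai.end - aj.end) <= breakpoint_tol
                    )
                )
                if matched:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri

    groups: Dict[int, List[SVCluster]] = defaultdict(list)
    for i in range(n):
        groups[find(i)].append(items[i])

    out: List[CandidateRegion] = []
    for members in groups.values():
        callers = {m.caller_id for m in members}
        if len(callers) < min_callers:
            continue
        svtype, _ = _majority_type([m.svtype for m in members])
        caller_types: Dict[str, SVType] = {}
        for m in sorted(members, key=lambda m: m.caller_id):
            caller_types.setdefault(m.caller_id, m.svtype)
        discordant = len({m.svtype for m in members}) > 1
        out.append(
            CandidateRegion(
                chrom=members[0].chrom,
                start=_lower_median([m.start for m in members]),
                end=_lower_median([m.end for m in members]),
                svtype=svtype,
                supporting_callers=callers,
                carrier_samples=set().union(*(m.carrier_samples for m in members)),
                gene_symbols=set().union(*(m.gene_symbols for m in members)),
                acmg_class=worst_acmg(m.acmg_class for m in members),
                type_discordant=discordant,
                caller_types=caller_types,
            )
        )
    out.sort(key=lambda c: (normalize_chrom(c.chrom), c.start, c.end))
    return out


# ---------------------------------------------------------------------------
# Full cascade over in-memory inputs
# ---------------------------------------------------------------------------

@dataclass
class PrioritizationParams:
    """Tunable thresholds of the cascade (defaults follow the standard
    rare-CNV prioritization protocol)."""

    max_sv_length: int = 100_000
    keep_acmg: frozenset = DEFAULT_KEEP_ACMG
    min_ro: float = 0.60
    min_samples: int = 2
    min_callers: int = 2
    breakpoint_tol: int = 200
    overlap_mode: str = "reciprocal"
    # "clusters": subtract genes hit by non-severe *shared clusters* (default);
    # "raw_calls": subtract genes hit by any filtered non-severe call.
    uniqueness_against: str = "clusters"


def _subgroup_stage_counts(stage: str, calls_or_clusters, report: dict) -> None:
    report[stage] = len(calls_or_clusters)


def run_prioritization(
    calls_by_caller: Dict[str, Sequence[SVCall]],
    severe_samples: Set[str],
    nonsevere_samples: Set[str],
    gene_index: GeneIndex,
    flags_list: Set[str],
    olfactory_list: Set[str],
    params: Optional[PrioritizationParams] = None,
) -> Tuple[List[CandidateRegion], dict]:
    """Execute the full cascade on in-memory call sets.

    Returns the consensus candidates for the severe subgroup and a stage
    report: per caller and subgroup, the number of variants (and genes and
    carrier individuals) surviving each filter, mirroring how per-tool
    survivor counts are reported for such pipelines.
    """
    params = params or PrioritizationParams()
    report: dict = {
        "subgroup_sizes": {
            "severe": len(severe_samples),
            "non_severe": len(nonsevere_samples),
        },
        "per_caller": {},
    }

    severe_survivors: Dict[str, List[SVCluster]] = {}
    for caller, calls in sorted(calls_by_caller.items()):
        caller_report: Dict[str, dict] = {}
        per_group_clusters: Dict[str, List[SVCluster]] = {}
        nonsevere_filtered: List[SVCall] = []
        for group_name, samples in (
            ("severe", severe_samples),
            ("non_severe", nonsevere_samples),
        ):
            g: dict = {}
            group_calls = [c for c in calls if c.sample_id in samples]
            g["raw"] = len(group_calls)
            group_calls = filter_by_length(group_calls, params.max_sv_length)
            g["after_length_filter"] = len(group_calls)
            group_calls = filter_by_acmg(group_calls, params.keep_acmg)
            g["after_acmg_filter"] = len(group_calls)
            if group_name == "non_severe":
                nonsevere_filtered = group_calls

            clusters = cluster_shared(
                group_calls,
                min_ro=params.min_ro,
                min_samples=params.min_samples,
                overlap_mode=params.overlap_mode,
            )
            g["shared_clusters"] = len(clusters)
            g["shared_carriers"] = len(
                set().union(*(c.carrier_samples for c in clusters)) if clusters else set()
            )
            for cl in clusters:
                cl.gene_symbols = gene_index.overlapping(cl.chrom, cl.start, cl.end)
            clusters = filter_gene_blacklist(clusters, flags_list, olfactory_list)
            g["after_blacklist"] = len(clusters)
            g["genes_after_blacklist"] = len(
                set().union(*(c.gene_symbols for c in clusters)) if clusters else set()
            )
            per_group_clusters[group_name] = clusters
            caller_report[group_name] = g

        if params.uniqueness_against == "raw_calls":
            nonsevere_genes: Set[str] = set()
            for c in nonsevere_filtered:
                nonsevere_genes |= gene_index.overlapping(c.chrom, c.start, c.end)
        else:
            nonsevere_genes = set().union(
                *(c.gene_symbols for c in per_group_clusters["non_severe"])
            ) if per_group_clusters["non_severe"] else set()

        unique = severe_unique_genes(per_group_clusters["severe"], nonsevere_genes)
        caller_report["severe"]["severe_unique"] = len(unique)
        caller_report["severe"]["genes_severe_unique"] = len(
            set().union(*(c.gene_symbols for c in unique)) if unique else set()
        )
        caller_report["severe"]["carriers_severe_unique"] = len(
            set().union(*(c.carrier_samples for c in unique)) if unique else set()
        )
        severe_survivors[caller] = unique
        report["per_caller"][caller] = caller_report

    candidates = cross_caller_consensus(
        severe_survivors,
        min_callers=params.min_callers,
        match_ro=params.min_ro,
        breakpoint_tol=params.breakpoint_tol,
        overlap_mode=params.overlap_mode,
    )
    report["consensus"] = {
        "candidates": len(candidates),
        "genes": len(
            set().union(*(c.gene_symbols for c in candidates)) if candidates else set()
        ),
        "carriers": len(
            set().union(*(c.carrier_samples for c in candidates)) if candidates else set()
        ),
        "type_discordant": sum(1 for c in candidates if c.type_discordant),
    }
    return candidates, report
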