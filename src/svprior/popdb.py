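"""Population-database annotation and gene-constraint lookup.

Candidates are intersected with a gnomAD-SV-style frequency database: any
same-type record overlapping a candidate by at least one base pair counts
as a match (population databases report partial overlaps, down to sub-kb
fragments of a multi-kb candidate, so no reciprocal-overlap threshold is
applied by default).  An empty match list marks the candidate as absent
from that reference population.  Gene constraint (LOEUF, pLI) is joined per
candidate gene; the most-constrained gene is the one with the lowest LOEUF,
ties broken by the highest pLI.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, Iterable, List, Optional, Sequence

from intervaltree import IntervalTree

from .model import (
    CandidateRegion,
    ConstraintRecord,
    PopDbMatch,
    PopulationSVRecord,
    normalize_chrom,
)
from .prioritize import overlap_bp, reciprocal_overlap


class PopulationDbIndex:
    """Chromosome-keyed interval index over population SV records."""

    def __init__(self, records: Iterable[PopulationSVRecord]):
        self._trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
        for r in records:
            if r.end > r.start:
                self._trees[normalize_chrom(r.chrom)][r.start:r.end] = r

    def overlapping(self, chrom: str, start: int, end: int) -> List[PopulationSVRecord]:
        tree = self._trees.get(normalize_chrom(chrom))
        if tree is None or end <= start:
            return []
        return [iv.data for iv in tree.overlap(start, end)]


def find_popdb_overlaps(
    candidate: CandidateRegion,
    db,
    min_overlap_bp: int = 1,
    require_same_type: bool = True,
    min_ro: float = 0.0,
) -> List[PopDbMatch]:
    """All database records overlapping the candidate by >= ``min_overlap_bp``
    (and of the same SV type unless ``require_same_type`` is off), sorted by
    descending reciprocal overlap.  ``db`` may be a
    :class:`PopulationDbIndex` or a plain record list."""
    index = db if isinstance(db, PopulationDbIndex) else PopulationDbIndex(db)
    matches: List[PopDbMatch] = []
    for rec in index.overlapping(candidate.chrom, candidate.start, candidate.end):
        same = rec.svtype == candidate.svtype
        if require_same_type and not same:
            continue
        ov = overlap_bp(candidate.interval, (rec.chrom, rec.start, rec.end))
        if ov < min_overlap_bp:
            continue
        ro = reciprocal_overlap(candidate.interval, (rec.chrom, rec.start, rec.end))
        if ro < min_ro:
            continue
        matches.append(PopDbMatch(record=rec, overlap_bp=ov, ro=ro, same_type=same))
    matches.sort(key=lambda m: (-m.ro, m.record.start, m.record.end))
    return matches


def annotate_popdb(
    candidates: Sequence[CandidateRegion],
    db: Iterable[PopulationSVRecord],
    min_overlap_bp: int = 1,
    require_same_type: bool = True,
) -> None:
    """Fill ``popdb_matches`` on every candidate in place."""
    index = PopulationDbIndex(db)
    for cand in candidates:
        cand.popdb_matches = find_popdb_overlaps(
            cand, index, min_overlap_bp=min_overlap_bp,
            require_same_type=require_same_type,
        )


def join_constraints(
    candidates: Sequence[CandidateRegion],
    constraints: Iterable[ConstraintRecord],
) -> None:
    """Attach per-gene (LOEUF, pLI) to each candidate in place.

    Genes absent from the constraint table carry an explicit ``None`` marker
    rather than being dropped, so downstream output distinguishes "not
    constrained" from "not scored".
    """
    table: Dict[str, ConstraintRecord] = {c.gene_symbol: c for c in constraints}
    for cand in candidates:
        cand.constraints = {g: table.get(g) for g in sorted(cand.gene_symbols)}


def most_constrained_gene(
    gene_symbols: Iterable[str],
    constraints: Iterable[ConstraintRecord],
) -> Optional[str]:
    """Convenience: lowest-LOEUF gene (ties -> highest pLI) among those
    present in the constraint table; None when none is scored."""
    table = {c.gene_symbol: c for c in constraints}
    scored = [(g, table[g]) for g in gene_symbols if g in table]
    if not scored:
        return None
    return min(scored, key=lambda gc: (gc[1].loeuf, -gc[1].pli))[0]
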