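"""Core domain types for structural-variant (SV) prioritization.

Coordinate convention
---------------------
All intervals are stored as ``(start, end]`` on a 1-based genome, i.e. the
VCF symbolic-allele convention: ``start`` is the base preceding the affected
segment (POS), ``end`` is the last affected base (INFO/END), and the length
of the event is ``end - start``.  BED input (0-based half-open) maps onto
this convention without arithmetic: internal start = BED start, internal
end = BED end, and overlap relations are preserved.

Chromosome names are compared after stripping any leading ``chr`` prefix so
both dialects ("12" and "chr12") interoperate.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


def normalize_chrom(chrom: str) -> str:
    """Strip a leading 'chr' prefix so both naming dialects compare equal."""
    if not chrom:
        raise ValueError("chromosome name must be nonempty")
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


class SVType(str, enum.Enum):
    """Structural-variant class. BND records carry no well-defined interval."""

    DEL = "DEL"
    DUP = "DUP"
    INV = "INV"
    BND = "BND"
    OTHER = "OTHER"

    @classmethod
    def from_string(cls, s: str) -> "SVType":
        s = (s or "").upper()
        aliases = {
            "DEL": cls.DEL,
            "DELETION": cls.DEL,
            "DUP": cls.DUP,
            "DUP:TANDEM": cls.DUP,
            "DUPLICATION": cls.DUP,
            "CNV": cls.OTHER,
            "INV": cls.INV,
            "INVERSION": cls.INV,
            "BND": cls.BND,
            "TRA": cls.BND,
        }
        return aliases.get(s, cls.OTHER)


class ACMGClass(str, enum.Enum):
    """Five-tier clinical pathogenicity scheme plus 'unclassified'.

    Severity order (worst first): pathogenic > likely_pathogenic > uncertain
    > likely_benign > benign > unclassified.
    """

    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    UNCERTAIN = "uncertain"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"
    UNCLASSIFIED = "unclassified"

    @property
    def severity_rank(self) -> int:
        """Lower rank = more severe (pathogenic is 0)."""
        return _ACMG_RANK[self]

    @classmethod
    def from_string(cls, s: Optional[str]) -> "ACMGClass":
        if s is None:
            return cls.UNCLASSIFIED
        key = str(s).strip().lower().replace(" ", "_").replace("-", "_")
        aliases = {
            "pathogenic": cls.PATHOGENIC,
            "likely_pathogenic": cls.LIKELY_PATHOGENIC,
            "uncertain": cls.UNCERTAIN,
            "uncertain_significance": cls.UNCERTAIN,
            "us": cls.UNCERTAIN,
            "vus": cls.UNCERTAIN,
            "likely_benign": cls.LIKELY_BENIGN,
            "benign": cls.BENIGN,
            "5": cls.PATHOGENIC,
            "4": cls.LIKELY_PATHOGENIC,
            "3": cls.UNCERTAIN,
            "2": cls.LIKELY_BENIGN,
            "1": cls.BENIGN,
        }
        return aliases.get(key, cls.UNCLASSIFIED)


_ACMG_RANK = {
    ACMGClass.PATHOGENIC: 0,
    ACMGClass.LIKELY_PATHOGENIC: 1,
    ACMGClass.UNCERTAIN: 2,
    ACMGClass.LIKELY_BENIGN: 3,
    ACMGClass.BENIGN: 4,
    ACMGClass.UNCLASSIFIED: 5,
}


def worst_acmg(classes) -> ACMGClass:
    """Most severe class in an iterable (pathogenic beats everything)."""
    classes = list(classes)
    if not classes:
        return ACMGClass.UNCLASSIFIED
    return min(classes, key=lambda c: c.severity_rank)


class Genotype(str, enum.Enum):
    HET = "het"
    HOM = "hom"
    UNKNOWN = "unknown"


class Subgroup(str, enum.Enum):
    SEVERE = "severe"
    NON_SEVERE = "non_severe"


@dataclass(frozen=True)
class SVCall:
    """One caller's call in one sample.

    ``start``/``end`` follow the (start, end] convention documented at module
    level; ``sv_length(call) == end - start``.
    """

    sample_id: str
    caller_id: str
    chrom: str
    start: int
    end: int
    svtype: SVType
    acmg_class: ACMGClass = ACMGClass.UNCLASSIFIED
    genotype: Genotype = Genotype.UNKNOWN

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if self.end < self.start:
            raise ValueError(
                f"end < start for {self.sample_id}/{self.caller_id} "
                f"{self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple:
        return (self.chrom, self.start, self.end)


def sv_length(call: SVCall) -> int:
    """Event length in bp: end − start (matches printed SV lengths)."""
    return call.end - call.start


@dataclass(frozen=True)
class GeneInterval:
    """A gene footprint on the genome; ``coding`` marks protein-coding genes."""

    gene_symbol: str
    chrom: str
    start: int
    end: int
    coding: bool = True

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"end < start for gene {self.gene_symbol}")


@dataclass(frozen=True)
class PopulationSVRecord:
    """One record of a population SV frequency database (gnomAD-SV style).

    Frequencies are consumed as given and never recomputed from carrier
    counts.  Subpopulation columns may be absent (None).
    """

    chrom: str
    start: int
    end: int
    svtype: SVType
    frequency_global: float
    carriers_global: int
    frequency_subpop: Optional[float] = None
    carriers_subpop: Optional[int] = None

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("end < start in population record")
        for f in (self.frequency_global, self.frequency_subpop):
            if f is not None and not (0.0 <= f <= 1.0):
                raise ValueError(f"frequency {f} outside [0,1]")
        if self.carriers_global < 0:
            raise ValueError("negative carrier count")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ConstraintRecord:
    """Gene-level intolerance scores: LOEUF (lower = more constrained) and pLI."""

    gene_symbol: str
    loeuf: float
    pli: float

    def __post_init__(self):
        if self.loeuf < 0:
            raise ValueError("LOEUF must be nonnegative")
        if not (0.0 <= self.pli <= 1.0):
            raise ValueError("pLI must be in [0,1]")


@dataclass
class SVCluster:
    """A set of reciprocal-overlap-linked calls from one caller within one
    subgroup, with a representative interval (member-wise median coordinates,
    majority svtype)."""

    member_calls: list  # list[SVCall], same caller and chromosome
    carrier_samples: set
    chrom: str
    start: int
    end: int
    svtype: SVType
    caller_id: str
    type_tie: bool = False  # majority-svtype vote tied -> OTHER
    gene_symbols: set = field(default_factory=set)

    @property
    def acmg_class(self) -> ACMGClass:
        return worst_acmg(c.acmg_class for c in self.member_calls)

    @property
    def interval(self) -> tuple:
        return (self.chrom, self.start, self.end)


@dataclass
class CandidateRegion:
    """A cross-caller consensus candidate.

    ``type_discordant`` is raised when supporting callers disagree on the SV
    type (e.g. one caller reports DEL, another DUP over the same region); the
    conflict is surfaced, never silently resolved beyond the majority label.
    """

    chrom: str
    start: int
    end: int
    svtype: SVType
    supporting_callers: set
    carrier_samples: set
    gene_symbols: set
    acmg_class: ACMGClass
    type_discordant: bool = False
    caller_types: dict = field(default_factory=dict)  # caller_id -> SVType
    popdb_matches: list = field(default_factory=list)  # list[PopDbMatch]
    constraints: dict = field(default_factory=dict)  # gene -> ConstraintRecord|None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple:
        return (self.chrom, self.start, self.end)

    def most_constrained_gene(self) -> Optional[str]:
        """Gene with lowest LOEUF among genes with scores; ties broken by
        highest pLI.  None when no gene has a score."""
        scored = [(g, c) for g, c in self.constraints.items() if c is not None]
        if not scored:
            return None
        return min(scored, key=lambda gc: (gc[1].loeuf, -gc[1].pli))[0]


@dataclass(frozen=True)
class PopDbMatch:
    """A population-database record overlapping a candidate region."""

    record: PopulationSVRecord
    overlap_bp: int
    ro: float
    same_type: bool

    def __post_init__(self):
        if self.overlap_bp < 1:
            raise ValueError("a match requires >= 1 bp overlap")
        if not (0.0 < self.ro <= 1.0):
            raise ValueError("match RO must be in (0,1]")


@dataclass
class CohortTable:
    """Sample -> THI score (0-100), plus the subgroup assignment filled in by
    the quartile partition."""

    entries: dict  # sample_id -> int
    subgroup: dict = field(default_factory=dict)  # sample_id -> Subgroup

    def __post_init__(self):
        for sid, score in self.entries.items():
            if not (0 <= score <= 100):
                raise ValueError(f"THI score {score} for {sid} outside [0,100]")

    @property
    def n(self) -> int:
        return len(self.entries)

    def samples_in(self, group: Subgroup) -> set:
        return {s for s, g in self.subgroup.items() if g is group}
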