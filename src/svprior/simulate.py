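"""Seeded generator of a complete synthetic input bundle.

Emulates the structure of an exome-sequenced case cohort analyzed for
structural variants: 310 samples with a skewed THI score distribution whose
third quartile sits at 68 (75 samples strictly above), three SV callers per
sample with inter-caller breakpoint jitter and occasional DEL/DUP type
disagreement, planted severe-specific shared SVs, and one decoy category
per pipeline filter (oversize, benign-ACMG, blacklisted-gene,
cross-subgroup-shared, single-caller), plus private background calls.
Every generated VCF record traces to exactly one truth entry or the
background pool, so end-to-end recovery is scorable exactly.

Coordinates live on a synthetic mini-genome (chr1/chr2, 10 Mb each) with a
dense decoy gene model; the eight genes reported in the reference tables
(ERBB3, AP4M1, COPS6, MCM7, TAF6 and the three microRNA genes) are included
as fixtures with synthetic stand-in intervals on chr7/chr12 so the fixture
constraint and expression tables have real targets.  No reference FASTA is
needed — the pipeline is sequence-free.

Determinism: one substream per draw category (scores, planted SVs,
background, ...), each seeded by (seed, crc32(category)); adding a category
never perturbs earlier draws, and a fixed seed reproduces the bundle
byte-for-byte.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .io import write_caller_vcf
from .model import (
    ACMGClass,
    CandidateRegion,
    GeneInterval,
    Genotype,
    SVCall,
    SVType,
)
from .prioritize import reciprocal_overlap

CHROM_LENGTH = 10_000_000
DEFAULT_CALLERS = ("cnvkit", "manta", "tiddit")

# Synthetic stand-in intervals for the eight fixture genes (chosen so the
# three ERBB3 deletions and the seven-gene duplication of the reference
# tables overlap them correctly; not real annotation coordinates).
FIXTURE_GENES = [
    GeneInterval("ERBB3", "12", 56_097_000, 56_101_800, coding=True),
    GeneInterval("TAF6", "7", 100_086_000, 100_091_000, coding=True),
    GeneInterval("MCM7", "7", 100_092_000, 100_101_000, coding=True),
    GeneInterval("MIR106B", "7", 100_093_300, 100_093_400, coding=False),
    GeneInterval("MIR93", "7", 100_093_700, 100_093_800, coding=False),
    GeneInterval("MIR25", "7", 100_094_000, 100_094_100, coding=False),
    GeneInterval("AP4M1", "7", 100_103_000, 100_109_000, coding=True),
    GeneInterval("COPS6", "7", 100_110_000, 100_113_500, coding=True),
]

# Constraint fixtures: gene -> (LOEUF, pLI).
FIXTURE_CONSTRAINTS = {
    "ERBB3": (0.685, 0.0),
    "AP4M1": (1.107, 0.0),
    "COPS6": (0.374, 1.0),
    "MCM7": (1.307, 0.0),
    "TAF6": (0.657, 0.55),
}

BRAIN_TISSUES = [
    "Amygdala", "Anterior_cingulate_cortex", "Caudate", "Cerebellar_Hemisphere",
    "Cerebellum", "Cortex", "Frontal_Cortex", "Hippocampus", "Hypothalamus",
    "Nucleus_accumbens", "Putamen", "Spinal_cord", "Substantia_nigra",
]


@dataclass
class SimConfig:
    """Generator parameters; defaults reproduce the study cohort shape."""

    n_samples: int = 310
    n_severe: int = 75
    thi_q3_target: int = 68
    n_severe_carrier_sets: int = 4
    n_nonsevere_shared: int = 5
    n_cross_group_shared: int = 3
    n_blacklist_decoys: int = 3
    n_oversize_decoys: int = 2
    n_benign_decoys: int = 3
    n_single_caller_decoys: int = 2
    background_mean: float = 20.0  # Poisson mean of private SVs per sample
    jitter_start: int = 5  # start offset drawn uniform in [-5, +5]
    jitter_end: int = 70  # end offset drawn uniform in [-70, +70]
    caller_dropout: float = 0.1  # never reduces a planted SV below 2 callers
    type_mislabel: float = 0.1  # one caller flips DEL<->DUP for a planted SV
    popdb_frequency: float = 8.0e-5  # frequency of planted-SV near-copies
    callers: Tuple[str, ...] = DEFAULT_CALLERS
    rng_seed: int = 1

    def validate(self) -> None:
        if self.n_samples < 8:
            raise ValueError("need at least 8 samples")
        if not (2 <= self.n_severe <= self.n_samples - 4):
            raise ValueError("n_severe out of range")
        m = self.n_samples - self.n_severe
        j = int(np.floor(0.75 * (self.n_samples - 1)))
        if m < j + 2:
            raise ValueError(
                "severe fraction too large to pin Q3 at the target score"
            )
        if len(self.callers) < 2:
            raise ValueError("planted SVs need >= 2 callers")
        if not (1 <= self.thi_q3_target <= 99):
            raise ValueError("thi_q3_target must leave room above and below")


@dataclass
class TruthEntry:
    """One planted region with its intended fate in the pipeline."""

    truth_id: str
    category: str
    chrom: str
    start: int
    end: int
    svtype: str
    genes: List[str]
    carriers: List[str]
    callers: List[str]
    mislabeled_caller: Optional[str]
    expected_flag: str  # "candidate" or a rejected_<stage> reason


@dataclass
class TruthSet:
    entries: List[TruthEntry]

    @property
    def expected_candidates(self) -> List[TruthEntry]:
        return [e for e in self.entries if e.expected_flag == "candidate"]

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([asdict(e) for e in self.entries], fh, indent=1)

    @classmethod
    def load(cls, path) -> "TruthSet":
        with open(path) as fh:
            return cls(entries=[TruthEntry(**d) for d in json.load(fh)])


@dataclass
class Bundle:
    """Paths of a generated input bundle."""

    root: Path
    manifest: Path
    phenotype: Path
    gene_bed: Path
    flags_list: Path
    olfactory_list: Path
    popdb: Path
    constraints: Path
    expression: Dict[str, Path]
    ortholog_map: Path
    truth_json: Path
    pipeline_config: Path
    truth: TruthSet


def _rng(seed: int, category: str) -> np.random.Generator:
    """Category-scoped substream: independent of draw order elsewhere."""
    return np.random.default_rng(
        np.random.SeedSequence((int(seed), zlib.crc32(category.encode())))
    )


# ---------------------------------------------------------------------------
# Phenotype
# ---------------------------------------------------------------------------

def _simulate_thi(config: SimConfig, seed: int) -> Dict[str, int]:
    """Skewed THI scores with the empirical Q3 pinned exactly at the target
    and exactly ``n_severe`` scores strictly above it."""
    rng = _rng(seed, "thi")
    n, k, q3 = config.n_samples, config.n_severe, config.thi_q3_target
    m = n - k
    # non-severe: right-skewed mass below the threshold
    low = np.floor(q3 * rng.beta(1.8, 1.1, size=m)).astype(int)
    low.sort()
    # pin the order statistics the linear-interpolation Q3 touches: in the
    # global sort the non-severe scores occupy indices 0..m-1, so setting
    # low[j:] (with j = floor(0.75*(n-1)) <= m-2) puts the threshold score
    # at both interpolation anchors
    j = int(np.floor(0.75 * (n - 1)))
    low[min(j, m - 2):] = q3
    high = rng.integers(q3 + 1, 101, size=k)
    scores = np.concatenate([low, high])
    order = rng.permutation(n)
    ids = [f"S{i + 1:04d}" for i in range(n)]
    return {ids[i]: int(scores[order[i]]) for i in range(n)}


# ---------------------------------------------------------------------------
# Gene model
# ---------------------------------------------------------------------------

def _build_gene_model(config: SimConfig, seed: int):
    """Dense decoy gene model on the mini-genome.

    Planted categories draw from dedicated, mutually exclusive gene slots in
    chr1:0-6Mb; extra decoy genes, blacklist fixtures and olfactory fixtures
    fill chr1/chr2 beyond.  Returns (genes, planted_slots, flags, olfactory).
    """
    genes: List[GeneInterval] = list(FIXTURE_GENES)
    planted_slots: List[GeneInterval] = []
    n_planted = (
        config.n_severe_carrier_sets
        + config.n_nonsevere_shared
        + config.n_cross_group_shared
        + config.n_blacklist_decoys
        + config.n_oversize_decoys
        + config.n_benign_decoys
        + config.n_single_caller_decoys
    )
    # 200 kb pitch leaves room for oversize (>100 kb) planted events
    pitch, width = 200_000, 180_000
    if n_planted * pitch > 6_000_000:
        raise ValueError("too many planted categories for the mini-genome")
    for i in range(n_planted):
        start = 50_000 + i * pitch
        g = GeneInterval(f"GENE{i + 1:03d}", "chr1", start, start + width)
        genes.append(g)
        planted_slots.append(g)

    flags = {"TTN", "MUC16", "SYNE1", "NEB", "HYDIN", "FLG", "USH2A"}
    olfactory = {f"OR{i}A1" for i in range(1, 8)}
    rng = _rng(seed, "gene_model")
    pos = 6_050_000
    for sym in sorted(flags | olfactory):
        w = int(rng.integers(5_000, 60_000))
        genes.append(GeneInterval(sym, "chr1", pos, pos + w))
        pos += w + 20_000
    # extra decoys on chr2 (coding and non-coding)
    pos = 100_000
    for i in range(40):
        w = int(rng.integers(5_000, 80_000))
        genes.append(
            GeneInterval(
                f"DEC{i + 1:03d}", "chr2", pos, pos + w,
                coding=bool(rng.integers(0, 2)),
            )
        )
        pos += w + int(rng.integers(20_000, 60_000))
    return genes, planted_slots, flags, olfactory


# ---------------------------------------------------------------------------
# Planted SVs
# ---------------------------------------------------------------------------

_CATEGORY_PLAN = [
    # (category, config field, expected_flag, acmg, subgroups, n_callers)
    ("severe_candidate", "n_severe_carrier_sets", "candidate",
     ACMGClass.UNCERTAIN, ("severe",), None),
    ("nonsevere_shared", "n_nonsevere_shared", "nonsevere_only",
     ACMGClass.UNCERTAIN, ("non_severe",), None),
    ("cross_group_shared", "n_cross_group_shared", "rejected_uniqueness",
     ACMGClass.UNCERTAIN, ("severe", "non_severe"), None),
    ("blacklist_decoy", "n_blacklist_decoys", "rejected_blacklist",
     ACMGClass.UNCERTAIN, ("severe",), None),
    ("oversize_decoy", "n_oversize_decoys", "rejected_length",
     ACMGClass.UNCERTAIN, ("severe",), None),
    ("benign_decoy", "n_benign_decoys", "rejected_acmg",
     ACMGClass.BENIGN, ("severe",), None),
    ("single_caller_decoy", "n_single_caller_decoys", "rejected_consensus",
     ACMGClass.UNCERTAIN, ("severe",), 1),
]


def _plant_svs(
    config: SimConfig,
    seed: int,
    planted_slots: Sequence[GeneInterval],
    genes: Sequence[GeneInterval],
    severe_ids: List[str],
    nonsevere_ids: List[str],
    blacklist: Set[str],
):
    """Lay out one planted SV per truth entry inside its own gene slot and
    emit the per-(carrier, caller) jittered calls."""
    rng = _rng(seed, "planted")
    truth: List[TruthEntry] = []
    calls: List[SVCall] = []
    slot_iter = iter(planted_slots)
    sev_pool = list(severe_ids)
    non_pool = list(nonsevere_ids)
    rng.shuffle(sev_pool)
    rng.shuffle(non_pool)
    sev_cursor = non_cursor = 0

    def take(pool, cursor, k):
        if cursor + k > len(pool):
            raise ValueError("not enough samples for the planted carrier sets")
        return pool[cursor:cursor + k], cursor + k

    for category, field_name, flag, acmg, subgroups, n_callers in _CATEGORY_PLAN:
        for i in range(getattr(config, field_name)):
            slot = next(slot_iter)
            if category == "blacklist_decoy":
                # re-point the slot at a blacklisted gene footprint
                target = sorted(blacklist)[i % len(blacklist)]
                slot = next(g for g in genes if g.gene_symbol == target)
            if category == "oversize_decoy":
                length = int(rng.integers(110_000, 160_000))
                start = slot.start + 1_000
            else:
                length = int(rng.integers(2_000, min(25_000, slot.end - slot.start - 200)))
                margin = slot.end - slot.start - length - 100
                start = slot.start + 50 + int(rng.integers(0, max(1, margin)))
            end = start + length
            svtype = SVType.DEL if rng.random() < 0.6 else SVType.DUP

            carriers: List[str] = []
            if "severe" in subgroups:
                picked, sev_cursor = take(sev_pool, sev_cursor, int(rng.integers(2, 4)))
                carriers += picked
            if "non_severe" in subgroups:
                picked, non_cursor = take(non_pool, non_cursor, int(rng.integers(2, 4)))
                carriers += picked

            if n_callers == 1:
                emitting = [config.callers[int(rng.integers(len(config.callers)))]]
            else:
                emitting = list(config.callers)
                for caller in list(emitting):
                    if len(emitting) <= 2:
                        break
                    if rng.random() < config.caller_dropout:
                        emitting.remove(caller)

            mislabeled = None
            if (
                len(emitting) >= 2
                and svtype in (SVType.DEL, SVType.DUP)
                and rng.random() < config.type_mislabel
            ):
                mislabeled = emitting[int(rng.integers(len(emitting)))]

            overlapped = sorted(
                g.gene_symbol for g in genes
                if g.chrom == slot.chrom and min(g.end, end) - max(g.start, start) >= 1
            )
            truth.append(
                TruthEntry(
                    truth_id=f"{category}_{i + 1}",
                    category=category,
                    chrom=slot.chrom,
                    start=start,
                    end=end,
                    svtype=svtype.value,
                    genes=overlapped,
                    carriers=sorted(carriers),
                    callers=sorted(emitting),
                    mislabeled_caller=mislabeled,
                    expected_flag=flag,
                )
            )
            flipped = SVType.DUP if svtype is SVType.DEL else SVType.DEL
            for sample in carriers:
                for caller in emitting:
                    js = int(rng.integers(-config.jitter_start, config.jitter_start + 1))
                    je = int(rng.integers(-config.jitter_end, config.jitter_end + 1))
                    calls.append(
                        SVCall(
                            sample_id=sample,
                            caller_id=caller,
                            chrom=slot.chrom,
                            start=start + js,
                            end=end + je,
                            svtype=flipped if caller == mislabeled else svtype,
                            acmg_class=acmg,
                            genotype=Genotype.HET,
                        )
                    )
    return truth, calls


def _background_calls(
    config: SimConfig, seed: int, sample_ids: List[str]
) -> List[SVCall]:
    """Private per-sample background SVs on a non-overlapping slot grid
    (chr1/chr2 beyond 6.9 Mb, clear of every gene slot used by planted
    categories), so same-caller chance clusters cannot arise."""
    rng = _rng(seed, "background")
    slots = []
    # chr1 below 8.3 Mb holds planted gene slots and the blacklist fixture
    # genes; background stays clear of every planted SV footprint
    for chrom, lo in (("chr1", 8_300_000), ("chr2", 2_600_000)):
        slots += [(chrom, s) for s in range(lo, CHROM_LENGTH - 1_000, 1_000)]
    order = rng.permutation(len(slots))
    cursor = 0
    acmg_choices = [
        ACMGClass.UNCERTAIN, ACMGClass.BENIGN,
        ACMGClass.LIKELY_BENIGN, ACMGClass.UNCLASSIFIED,
    ]
    calls: List[SVCall] = []
    counts = rng.poisson(config.background_mean, size=len(sample_ids))
    for sample, k in zip(sample_ids, counts):
        for _ in range(int(k)):
            if cursor >= len(slots):
                raise ValueError(
                    "background slot grid exhausted; lower background_mean"
                )
            chrom, base = slots[order[cursor]]
            cursor += 1
            length = int(rng.integers(50, 900))
            start = base + int(rng.integers(0, 1000 - length))
            calls.append(
                SVCall(
                    sample_id=sample,
                    caller_id=config.callers[int(rng.integers(len(config.callers)))],
                    chrom=chrom,
                    start=start,
                    end=start + length,
                    svtype=SVType.DEL if rng.random() < 0.5 else SVType.DUP,
                    acmg_class=acmg_choices[int(rng.integers(len(acmg_choices)))],
                    genotype=Genotype.HET,
                )
            )
    return calls


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------

def _write_popdb(config: SimConfig, seed: int, truth: TruthSet, path) -> None:
    """Near-copies of the planted candidate SVs at configurable frequency,
    plus random background records."""
    rng = _rng(seed, "popdb")
    rows = []
    for e in truth.expected_candidates:
        rows.append(
            {
                "chrom": e.chrom,
                "start": e.start + int(rng.integers(-4, 5)),
                "end": e.end + int(rng.integers(-4, 5)),
                "svtype": e.svtype,
                "freq_global": config.popdb_frequency,
                "n_global": int(rng.integers(1, 16)),
                "freq_subpop": config.popdb_frequency * 1.2,
                "n_subpop": int(rng.integers(1, 8)),
            }
        )
    for _ in range(30):
        start = int(rng.integers(100_000, CHROM_LENGTH - 200_000))
        rows.append(
            {
                "chrom": "chr2" if rng.random() < 0.5 else "chr1",
                "start": start,
                "end": start + int(rng.integers(100, 50_000)),
                "svtype": "DEL" if rng.random() < 0.5 else "DUP",
                "freq_global": float(np.round(rng.uniform(1e-5, 0.02), 7)),
                "n_global": int(rng.integers(1, 400)),
                "freq_subpop": float(np.round(rng.uniform(1e-5, 0.02), 7)),
                "n_subpop": int(rng.integers(0, 40)),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_constraints(seed: int, genes: Sequence[GeneInterval], path) -> None:
    rng = _rng(seed, "constraints")
    rows = [
        {"gene": g, "loeuf": l, "pli": p}
        for g, (l, p) in sorted(FIXTURE_CONSTRAINTS.items())
    ]
    for g in genes:
        if g.gene_symbol in FIXTURE_CONSTRAINTS or not g.coding:
            continue
        rows.append(
            {
                "gene": g.gene_symbol,
                "loeuf": float(np.round(rng.uniform(0.4, 1.9), 3)),
                "pli": float(np.round(rng.uniform(0, 1), 3)),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _mouse_symbol(human: str) -> str:
    return human[0].upper() + human[1:].lower()


def _write_expression(seed: int, out_dir: Path) -> Dict[str, Path]:
    """Three fixture expression tables emulating the study's sources:
    human brain RNA-seq (TPM), mouse cochlea RNA-seq (RPKM), mouse spiral
    ganglion neuron microarray — plus the human<->mouse ortholog map.

    ERBB3 is highly expressed everywhere, AP4M1 absent from the SGN set,
    and the three microRNA genes are zero in all tissues, mirroring the
    reported expression pattern of the candidate genes.
    """
    rng = _rng(seed, "expression")
    human = [g.gene_symbol for g in FIXTURE_GENES]
    noncoding = {g.gene_symbol for g in FIXTURE_GENES if not g.coding}

    def base_levels(scale):
        levels = {}
        for g in human:
            if g in noncoding:
                levels[g] = 0.0
            elif g == "ERBB3":
                levels[g] = scale  # dataset maximum
            elif g == "COPS6":
                levels[g] = 0.8 * scale
            elif g == "AP4M1":
                levels[g] = 0.08 * scale
            else:
                levels[g] = rng.uniform(0.2, 0.6) * scale
        return levels

    paths: Dict[str, Path] = {}

    levels = base_levels(240.0)  # TPM-ish
    brain = {
        t: [0.0 if g in noncoding else float(np.round(levels[g] * rng.uniform(0.55, 1.0), 2))
            for g in human]
        for t in BRAIN_TISSUES
    }
    brain_df = pd.DataFrame(brain, index=human)
    brain_df.loc["ERBB3", BRAIN_TISSUES[0]] = 240.0
    paths["gtex_brain"] = out_dir / "expression_gtex_brain.tsv"
    brain_df.to_csv(paths["gtex_brain"], sep="\t", index_label="gene")

    levels = base_levels(95.0)  # RPKM-ish, mouse symbols
    mouse_idx = [_mouse_symbol(g) for g in human]
    cochlea = {
        t: [0.0 if g in noncoding else float(np.round(levels[g] * rng.uniform(0.5, 1.0), 2))
            for g in human]
        for t in ("hair_cells", "non_hair_cells")
    }
    cochlea_df = pd.DataFrame(cochlea, index=mouse_idx)
    cochlea_df.loc[_mouse_symbol("ERBB3"), "hair_cells"] = 95.0
    paths["gear_cochlea"] = out_dir / "expression_gear_cochlea.tsv"
    cochlea_df.to_csv(paths["gear_cochlea"], sep="\t", index_label="gene")

    levels = base_levels(11_000.0)  # microarray intensity, mouse symbols
    levels["AP4M1"] = 0.0  # not expressed in SGN
    sgn = {
        "SGN": [0.0 if g in noncoding else float(np.round(levels[g] * rng.uniform(0.6, 1.0), 1))
                for g in human]
    }
    sgn_df = pd.DataFrame(sgn, index=mouse_idx)
    sgn_df.loc[_mouse_symbol("ERBB3"), "SGN"] = 11_000.0
    paths["shield_sgn"] = out_dir / "expression_shield_sgn.tsv"
    sgn_df.to_csv(paths["shield_sgn"], sep="\t", index_label="gene")

    ortho = pd.DataFrame(
        {"human_symbol": human, "mouse_symbol": mouse_idx}
    )
    paths["ortholog_map"] = out_dir / "ortholog_map.tsv"
    ortho.to_csv(paths["ortholog_map"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# Bundle assembly
# ---------------------------------------------------------------------------

def generate_cohort(config: SimConfig, out_dir, seed: Optional[int] = None) -> Bundle:
    """Write a full pipeline-ready input bundle under ``out_dir``.

    Deterministic for a fixed seed (``seed`` overrides ``config.rng_seed``).
    Returns the bundle paths plus the machine-readable truth set.
    """
    config.validate()
    seed = config.rng_seed if seed is None else int(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vcf_dir = out_dir / "vcf"
    vcf_dir.mkdir(exist_ok=True)

    scores = _simulate_thi(config, seed)
    severe_ids = sorted(s for s, v in scores.items() if v > config.thi_q3_target)
    nonsevere_ids = sorted(s for s, v in scores.items() if v <= config.thi_q3_target)
    assert len(severe_ids) == config.n_severe

    genes, planted_slots, flags, olfactory = _build_gene_model(config, seed)
    truth_entries, planted_calls = _plant_svs(
        config, seed, planted_slots, genes, severe_ids, nonsevere_ids, flags | olfactory
    )
    truth = TruthSet(entries=truth_entries)
    calls = planted_calls + _background_calls(config, seed, sorted(scores))

    # one VCF per (sample, caller); every pair listed in the manifest even
    # when a caller produced no call for a sample
    by_file: Dict[Tuple[str, str], List[SVCall]] = {
        (s, c): [] for s in sorted(scores) for c in config.callers
    }
    for call in calls:
        by_file[(call.sample_id, call.caller_id)].append(call)
    contigs = {"chr1": CHROM_LENGTH, "chr2": CHROM_LENGTH}
    manifest_rows = []
    for (sample, caller), file_calls in sorted(by_file.items()):
        path = vcf_dir / f"{sample}.{caller}.vcf"
        write_caller_vcf(file_calls, path, contigs=contigs, sample_id=sample)
        manifest_rows.append({"sample": sample, "caller": caller, "path": str(path)})
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(manifest_rows).to_csv(manifest, sep="\t", index=False)

    phenotype = out_dir / "phenotype.tsv"
    pd.DataFrame(
        {"sample_id": sorted(scores), "thi": [scores[s] for s in sorted(scores)]}
    ).to_csv(phenotype, sep="\t", index=False)

    gene_bed = out_dir / "genes.bed"
    with open(gene_bed, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.end, g.gene_symbol)):
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_symbol}\t{int(g.coding)}\n")

    flags_path = out_dir / "flags_genes.txt"
    flags_path.write_text("".join(f"{s}\n" for s in sorted(flags)))
    olfactory_path = out_dir / "olfactory_genes.txt"
    olfactory_path.write_text("".join(f"{s}\n" for s in sorted(olfactory)))

    popdb = out_dir / "population_sv.tsv"
    _write_popdb(config, seed, truth, popdb)
    constraints = out_dir / "constraints.tsv"
    _write_constraints(seed, genes, constraints)
    expr_paths = _write_expression(seed, out_dir)
    ortholog_map = expr_paths.pop("ortholog_map")

    truth_json = out_dir / "truth.json"
    truth.save(truth_json)

    pipeline_config = out_dir / "pipeline_config.yaml"
    _write_pipeline_config(
        pipeline_config, manifest, phenotype, gene_bed, flags_path,
        olfactory_path, popdb, constraints, expr_paths, ortholog_map,
        thi_threshold=config.thi_q3_target, out_dir=out_dir / "results",
    )

    return Bundle(
        root=out_dir,
        manifest=manifest,
        phenotype=phenotype,
        gene_bed=gene_bed,
        flags_list=flags_path,
        olfactory_list=olfactory_path,
        popdb=popdb,
        constraints=constraints,
        expression=expr_paths,
        ortholog_map=ortholog_map,
        truth_json=truth_json,
        pipeline_config=pipeline_config,
        truth=truth,
    )


def _write_pipeline_config(
    path, manifest, phenotype, gene_bed, flags_path, olfactory_path,
    popdb, constraints, expr_paths, ortholog_map, thi_threshold, out_dir,
) -> None:
    import yaml

    cfg = {
        "vcf_manifest": str(manifest),
        "phenotype": str(phenotype),
        "gene_bed": str(gene_bed),
        "flags_list": str(flags_path),
        "olfactory_list": str(olfactory_path),
        "population_db": str(popdb),
        "constraints": str(constraints),
        "expression": [
            {"name": name, "path": str(p)} for name, p in sorted(expr_paths.items())
        ],
        "ortholog_map": str(ortholog_map),
        "thi_threshold": int(thi_threshold),
        "out_dir": str(out_dir),
        "min_ro": 0.6,
        "min_samples": 2,
        "min_callers": 2,
        "max_sv_length": 100_000,
        "breakpoint_tol": 200,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

def score_recovery(
    candidates: Sequence[CandidateRegion],
    truth: TruthSet,
    min_ro: float = 0.6,
) -> Dict[str, float]:
    """Precision / recall of reported candidates against the planted truth.

    A candidate matches a truth entry expected to be a candidate when their
    reciprocal overlap is >= ``min_ro``.  Flag accuracy is the fraction of
    matched truths with a planted type mislabel whose candidate carries the
    ``type_discordant`` flag (1.0 when no mislabels were planted).
    """
    expected = truth.expected_candidates
    matched_truth: Dict[str, CandidateRegion] = {}
    matched_cands = set()
    for e in expected:
        for i, c in enumerate(candidates):
            if c.length == 0:
                continue
            if reciprocal_overlap((e.chrom, e.start, e.end), c.interval) >= min_ro:
                matched_truth[e.truth_id] = c
                matched_cands.add(i)
                break
    precision = len(matched_cands) / len(candidates) if candidates else (
        1.0 if not expected else 0.0
    )
    recall = len(matched_truth) / len(expected) if expected else 1.0
    mislabeled = [e for e in expected if e.mislabeled_caller]
    if mislabeled:
        flagged = sum(
            1 for e in mislabeled
            if e.truth_id in matched_truth and matched_truth[e.truth_id].type_discordant
        )
        flag_accuracy = flagged / len(mislabeled)
    else:
        flag_accuracy = 1.0
    return {
        "precision": precision,
        "recall": recall,
        "flag_accuracy": flag_accuracy,
        "n_reported": float(len(candidates)),
        "n_planted": float(len(expected)),
    }
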