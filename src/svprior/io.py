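"""Readers and writers for the standard formats the pipeline touches.

VCF call sets are read with pysam (symbolic SV alleles, INFO keys
SVTYPE/END/SVLEN); BED gene models and the various headered TSV tables go
through pandas.  Coordinates come out in the package's (start, end]
convention (see :mod:`svprior.model`): VCF POS/END are taken verbatim, BED
columns pass through unchanged.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import pandas as pd
import pysam

from .model import (
    ACMGClass,
    CandidateRegion,
    CohortTable,
    ConstraintRecord,
    GeneInterval,
    Genotype,
    PopulationSVRecord,
    SVCall,
    SVType,
)

logger = logging.getLogger("svprior")


class FormatError(RuntimeError):
    """Unreadable or malformed input file."""


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_caller_vcf(
    path,
    caller_id: str,
    sample_id: str,
    acmg_key: str = "ACMG",
) -> List[SVCall]:
    """Read one caller's SV call set for one sample.

    One :class:`SVCall` per record.  END is taken from INFO/END, or derived
    as POS + \\|SVLEN| when only SVLEN is present; records carrying neither
    are skipped with a warning.  A missing ACMG annotation (under
    ``acmg_key``) maps to ``unclassified``.  BND records are retained (with
    end = start) so callers' breakend output is not lost at parse time, but
    every downstream interval operation excludes them.
    """
    path = str(path)
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc

    calls: List[SVCall] = []
    with vcf:
        for i, rec in enumerate(vcf, start=1):
            try:
                call = _record_to_call(rec, caller_id, sample_id, acmg_key)
            except ValueError as exc:
                raise FormatError(f"{path} record {i}: {exc}") from exc
            if call is None:
                logger.warning(
                    "%s record %d (%s:%s): no END or SVLEN; skipped",
                    path, i, rec.chrom, rec.pos,
                )
                continue
            calls.append(call)
    return calls


def _info_get(rec, key):
    # pysam raises for INFO keys absent from the header; treat as missing
    try:
        return rec.info.get(key)
    except (KeyError, ValueError):
        return None


def _record_to_call(rec, caller_id, sample_id, acmg_key) -> Optional[SVCall]:
    svtype_raw = _info_get(rec, "SVTYPE")
    if svtype_raw is None:
        alt = rec.alts[0] if rec.alts else ""
        svtype_raw = alt.strip("<>") if alt.startswith("<") else ""
    svtype = SVType.from_string(str(svtype_raw))

    start = rec.pos
    if svtype is SVType.BND:
        end = start
    else:
        # pysam resolves rec.stop from INFO/END, or from SVLEN for symbolic
        # alleles; when neither is present stop collapses to pos+len(ref)-1.
        end = rec.stop
        svlen = _info_get(rec, "SVLEN")
        if isinstance(svlen, (tuple, list)):
            svlen = svlen[0] if svlen else None
        no_end_info = end <= rec.start + len(rec.ref)
        if no_end_info:
            if svlen is not None:
                end = start + abs(int(svlen))
            else:
                return None
        if end < start:
            raise ValueError(f"negative length: POS={start} END={end}")

    acmg_raw = _info_get(rec, acmg_key)
    acmg = ACMGClass.from_string(acmg_raw) if acmg_raw is not None else ACMGClass.UNCLASSIFIED

    gt = Genotype.UNKNOWN
    if rec.samples:
        alleles = next(iter(rec.samples.values())).get("GT")
        if alleles and None not in alleles:
            n_alt = sum(1 for a in alleles if a and a > 0)
            if n_alt == len([a for a in alleles if a is not None]) and n_alt > 0:
                gt = Genotype.HOM
            elif n_alt > 0:
                gt = Genotype.HET

    return SVCall(
        sample_id=sample_id,
        caller_id=caller_id,
        chrom=rec.chrom,
        start=start,
        end=end,
        svtype=svtype,
        acmg_class=acmg,
        genotype=gt,
    )


def write_caller_vcf(
    calls: Sequence[SVCall],
    path,
    contigs: Optional[dict] = None,
    acmg_key: str = "ACMG",
    sample_id: Optional[str] = None,
) -> None:
    """Write SV calls as a symbolic-allele VCF (round-trips through
    :func:`read_caller_vcf`)."""
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">')
    header.add_line(
        f'##INFO=<ID={acmg_key},Number=1,Type=String,Description="ACMG classification">'
    )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    seen = dict(contigs or {})
    for c in calls:
        seen.setdefault(c.chrom, max(c.end + 1, 2))
        seen[c.chrom] = max(seen[c.chrom], c.end + 1)
    for name, length in seen.items():
        header.contigs.add(name, length=length)
    sample_ids = sorted({c.sample_id for c in calls})
    if len(sample_ids) > 1:
        raise ValueError("write_caller_vcf writes single-sample VCFs")
    sample = sample_ids[0] if sample_ids else (sample_id or "SAMPLE")
    header.add_sample(sample)

    gt_map = {Genotype.HET: (0, 1), Genotype.HOM: (1, 1), Genotype.UNKNOWN: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in sorted(calls, key=lambda x: (x.chrom, x.start, x.end)):
            rec = out.new_record(
                contig=c.chrom,
                start=c.start - 1,  # pysam takes 0-based start
                stop=c.end,
                alleles=("N", f"<{c.svtype.value}>"),
            )
            rec.info["SVTYPE"] = c.svtype.value
            rec.info[acmg_key] = c.acmg_class.value
            rec.samples[sample]["GT"] = gt_map[c.genotype]
            out.write(rec)


# ---------------------------------------------------------------------------
# BED / TSV tables
# ---------------------------------------------------------------------------

def read_gene_bed(path) -> List[GeneInterval]:
    """Read a BED4+ gene model.

    BED is 0-based half-open; under the internal (start, end] convention the
    coordinates pass through unchanged and overlap relations are preserved.
    An optional 5th column marks coding status (1/0); absent means coding.
    """
    genes: List[GeneInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{ln}: BED needs >= 4 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: malformed coordinates") from exc
            coding = True
            if len(fields) >= 5 and fields[4] in {"0", "1"}:
                coding = fields[4] == "1"
            try:
                genes.append(
                    GeneInterval(
                        gene_symbol=fields[3], chrom=fields[0],
                        start=start, end=end, coding=coding,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
    return genes


def read_population_db(path) -> List[PopulationSVRecord]:
    """Read a population SV database as headered TSV with columns
    chrom, start, end, svtype, freq_global, n_global[, freq_subpop, n_subpop]."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    records = []
    for ln, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                PopulationSVRecord(
                    chrom=str(row.chrom),
                    start=int(row.start),
                    end=int(row.end),
                    svtype=SVType.from_string(str(row.svtype)),
                    frequency_global=float(row.freq_global),
                    carriers_global=int(row.n_global),
                    frequency_subpop=_opt_float(getattr(row, "freq_subpop", None)),
                    carriers_subpop=_opt_int(getattr(row, "n_subpop", None)),
                )
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}:{ln}: {exc}") from exc
    return records


def _opt_float(v):
    return None if v is None or pd.isna(v) else float(v)


def _opt_int(v):
    return None if v is None or pd.isna(v) else int(v)


def read_constraints(path) -> List[ConstraintRecord]:
    """Read a gene constraint table (TSV columns: gene, loeuf, pli)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    gene_col = cols.get("gene") or cols.get("gene_symbol")
    if gene_col is None or "loeuf" not in cols or "pli" not in cols:
        raise FormatError(f"{path}: expected columns gene, loeuf, pli")
    out = []
    for ln, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                ConstraintRecord(
                    gene_symbol=str(getattr(row, gene_col)),
                    loeuf=float(getattr(row, cols["loeuf"])),
                    pli=float(getattr(row, cols["pli"])),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{ln}: {exc}") from exc
    return out


def read_phenotype(path) -> CohortTable:
    """Read the phenotype TSV (columns: sample_id, thi)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    sid = cols.get("sample_id") or cols.get("sample")
    thi = cols.get("thi") or cols.get("thi_score")
    if sid is None or thi is None:
        raise FormatError(f"{path}: expected columns sample_id, thi")
    entries = {str(r[sid]): int(r[thi]) for _, r in df.iterrows()}
    return CohortTable(entries=entries)


def read_gene_list(path) -> set:
    """Read a plain-text gene symbol list (one symbol per line, # comments)."""
    symbols = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                symbols.add(line.split()[0])
    return symbols


# ---------------------------------------------------------------------------
# Candidate table output
# ---------------------------------------------------------------------------

CANDIDATE_COLUMNS = [
    "Chr", "Start", "End", "Length", "SVType", "Individuals",
    "GeneSymbols", "ACMG", "CallerSupport", "TypeDiscordant",
]


def candidates_to_frame(candidates: Iterable[CandidateRegion]) -> pd.DataFrame:
    rows = []
    for c in sorted(candidates, key=lambda c: (c.chrom, c.start, c.end)):
        rows.append(
            {
                "Chr": c.chrom,
                "Start": c.start,
                "End": c.end,
                "Length": c.length,
                "SVType": c.svtype.value,
                "Individuals": ",".join(sorted(c.carrier_samples)),
                "GeneSymbols": ",".join(sorted(c.gene_symbols)),
                "ACMG": c.acmg_class.value,
                "CallerSupport": ",".join(sorted(c.supporting_callers)),
                "TypeDiscordant": c.type_discordant,
            }
        )
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)


def write_candidate_table(candidates: Iterable[CandidateRegion], path) -> None:
    """Write the final candidate table as TSV, sorted by (chrom, start, end)."""
    df = candidates_to_frame(candidates)
    try:
        df.to_csv(path, sep="\t", index=False)
    except OSError as exc:
        raise FormatError(f"cannot write candidate table to {path}: {exc}") from exc


def write_popdb_match_table(candidates: Iterable[CandidateRegion], path) -> None:
    """Per-candidate population-database matches, one row per match."""
    rows = []
    for c in sorted(candidates, key=lambda c: (c.chrom, c.start, c.end)):
        for m in c.popdb_matches:
            r = m.record
            rows.append(
                {
                    "CandidateChr": c.chrom,
                    "CandidateStart": c.start,
                    "CandidateEnd": c.end,
                    "DbChr": r.chrom,
                    "DbStart": r.start,
                    "DbEnd": r.end,
                    "DbLength": r.length,
                    "DbSVType": r.svtype.value,
                    "FreqGlobal": r.frequency_global,
                    "NGlobal": r.carriers_global,
                    "FreqSubpop": r.frequency_subpop,
                    "NSubpop": r.carriers_subpop,
                    "OverlapBp": m.overlap_bp,
                    "RO": m.ro,
                    "SameType": m.same_type,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
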