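# svprior

Prioritization of structural variants (SVs) shared within a severity-defined
subgroup of a patient cohort, from multi-caller VCF call sets to annotated
candidate regions.

## The problem

Rare copy-number variants (deletions and duplications called from exome
sequencing) can contribute to complex inner-ear phenotypes such as severe
tinnitus in Meniere disease, but exome SV callers are noisy and disagree with
each other on breakpoints and even on variant type. A defensible candidate
set therefore needs: a phenotype-homogeneous subgroup, per-caller filtering,
evidence that a region recurs in unrelated patients of that subgroup, removal
of systematically artifact-prone genes, and agreement between independent
callers — followed by population-frequency, gene-constraint and expression
annotation to judge the survivors.

`svprior` implements that cascade as a tested, reusable pipeline, plus a
seeded synthetic-cohort generator with a machine-readable truth set so every
stage is verifiable without access-restricted patient data.

## The method

Samples are split by the Tinnitus Handicap Inventory (THI, 0–100): *severe*
iff THI > Q3 of the cohort's empirical distribution (linear-interpolation
quartile; an explicit published threshold such as 68 can be supplied
instead). Each caller's call set then passes, per subgroup:

1. **Length filter** — drop calls with length `end − start` > 100 kb
   (intervals are `(start, end]` on a 1-based genome, the VCF
   symbolic-allele convention).
2. **ACMG filter** — keep pathogenic / likely pathogenic / uncertain calls.
3. **Within-subgroup sharing** — single-linkage clusters over the graph
   whose edges join same-type calls with reciprocal overlap
   `RO(a,b) = min(|a∩b|/|a|, |a∩b|/|b|) ≥ 0.6`; clusters carried by < 2
   distinct samples are discarded.
4. **Gene annotation** — split-style: one (region, gene) row per gene
   overlapping the representative interval by ≥ 1 bp.
5. **Blacklist filter** — remove rows for FLAGS (frequently mutated) genes
   and olfactory receptors; a region is dropped only when all its gene rows
   are removed.
6. **Severe-unique genes** — keep severe rows whose gene is hit by no
   retained non-severe cluster.
7. **Cross-caller consensus** — regions from different callers match when
   RO ≥ 0.6 *or* both breakpoints agree within 200 bp; matching ignores
   SV type, and DEL/DUP disagreement between callers is surfaced as a
   `type_discordant` flag (never silently resolved beyond the majority
   label). Regions supported by < 2 of the 3 callers are dropped.

Survivors are annotated with overlapping records from a gnomAD-SV-style
population database (≥ 1 bp same-type overlap; an empty list marks absence
from the reference population), per-gene constraint scores (LOEUF, pLI; the
most-constrained gene is the lowest-LOEUF one, ties broken by higher pLI),
and a cross-database expression summary (each dataset normalized to 0–100
by its own maximum, merged by gene symbol through an ortholog map, displayed
as log10(v + 1)).

## Worked example

The published candidate table — three deletions in *ERBB3* carried by
I4-40/I4-41 and a 23 kb seven-gene duplication carried by I4-28/I4-37, all
of uncertain significance — fed through the cascade as a two-caller toy
input:

```python
from svprior import (GeneIndex, PrioritizationParams, SVCall, SVType,
                     ACMGClass, run_prioritization)
from svprior.simulate import FIXTURE_GENES

rows = [("12", 56100028, 56100172, SVType.DEL, ("I4-40", "I4-41")),
        ("12", 56100243, 56101058, SVType.DEL, ("I4-40", "I4-41")),
        ("12", 56101359, 56101526, SVType.DEL, ("I4-40", "I4-41")),
        ("7", 100089053, 100112257, SVType.DUP, ("I4-28", "I4-37"))]
calls = {caller: [SVCall(s, caller, c, a, b, t, ACMGClass.UNCERTAIN)
                  for c, a, b, t, carriers in rows for s in carriers]
         for caller in ("manta", "tiddit")}
candidates, report = run_prioritization(
    calls, severe_samples={"I4-40", "I4-41", "I4-28", "I4-37"},
    nonsevere_samples={"N1", "N2"}, gene_index=GeneIndex(FIXTURE_GENES),
    flags_list={"TTN"}, olfactory_list=set(),
    params=PrioritizationParams())
print(report["consensus"])
for c in candidates:
    print(c.chrom, c.start, c.end, c.length, c.svtype.value,
          sorted(c.gene_symbols))
```

prints

```
{'candidates': 4, 'genes': 8, 'carriers': 4, 'type_discordant': 0}
12 56100028 56100172 144 DEL ['ERBB3']
12 56100243 56101058 815 DEL ['ERBB3']
12 56101359 56101526 167 DEL ['ERBB3']
7 100089053 100112257 23204 DUP ['AP4M1', 'COPS6', 'MCM7', 'MIR106B', 'MIR25', 'MIR93', 'TAF6']
```

i.e. four consensus candidates covering eight distinct genes, each supported
by both callers and two carriers, with lengths equal to `end − start` of the
printed coordinates (144, 815, 167, 23 204 bp).

## Command line

```bash
# generate a synthetic cohort bundle (VCFs, phenotype, gene model,
# blacklists, population DB, constraints, expression, truth JSON)
svprior simulate --out bundle/ --seed 1

# run the full cascade on it
svprior run --config bundle/pipeline_config.yaml
```

The run writes `candidates.tsv`, `popdb_matches.tsv`,
`expression_matrix.tsv` and a `report.json` with per-caller, per-subgroup
survivor counts after every filter.

## Layout

- `src/svprior/model.py` — domain types and the coordinate convention
- `src/svprior/io.py` — VCF/BED/TSV readers and writers
- `src/svprior/cohort.py` — THI quartile partition
- `src/svprior/prioritize.py` — the cascade (filters, RO clustering,
  consensus)
- `src/svprior/popdb.py` — population-database and constraint annotation
- `src/svprior/expression.py` — expression normalization/merge/log display
- `src/svprior/simulate.py` — synthetic cohort generator + truth scoring
- `src/svprior/pipeline.py`, `src/svprior/cli.py` — orchestration and CLI
- `docs/methods.md` — modelling choices, parameters and limitations
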