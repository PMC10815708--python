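"""Shared fixtures: published-table call sets and a synthetic bundle."""

import pytest

from svprior import (
    ACMGClass,
    GeneInterval,
    Genotype,
    PipelineConfig,
    SimConfig,
    SVCall,
    SVType,
    generate_cohort,
    run_pipeline,
)
from svprior.simulate import FIXTURE_GENES

# The four candidate SVs as printed in the published summary table:
# (chrom, start, end, svtype, carriers)
TABLE1_ROWS = [
    ("12", 56_100_028, 56_100_172, SVType.DEL, ("I4-40", "I4-41")),
    ("12", 56_100_243, 56_101_058, SVType.DEL, ("I4-40", "I4-41")),
    ("12", 56_101_359, 56_101_526, SVType.DEL, ("I4-40", "I4-41")),
    ("7", 100_089_053, 100_112_257, SVType.DUP, ("I4-28", "I4-37")),
]

# Population-database records overlapping the candidates (chrom, start, end,
# svtype, freq_global, n_global, freq_subpop, n_subpop); the printed
# scientific-notation frequencies are garbled in the source, so plausible
# stand-in fractions are used — the pipeline treats them as opaque values.
TABLE2_ROWS = [
    ("12", 56_100_029, 56_100_167, SVType.DEL, 8.74e-5, 11, 1.02e-4, 6),
    ("12", 56_099_811, 56_101_058, SVType.DEL, 2.38e-5, 3, 1.69e-5, 1),
    ("12", 56_100_244, 56_101_058, SVType.DEL, 1.27e-4, 15, 1.36e-4, 8),
    ("12", 56_101_363, 56_101_526, SVType.DEL, 1.35e-4, 14, 1.86e-4, 11),
    ("7", 100_076_358, 100_093_492, SVType.DUP, 3.17e-5, 4, 3.39e-5, 2),
    ("7", 100_056_545, 100_214_180, SVType.DUP, 7.93e-6, 1, 0.0, 0),
    ("7", 100_095_604, 100_095_982, SVType.DUP, 7.93e-6, 1, 0.0, 0),
]

# Constraint table for the five coding candidate genes: gene -> (LOEUF, pLI)
TABLE3 = {
    "ERBB3": (0.685, 0.0),
    "AP4M1": (1.107, 0.0),
    "COPS6": (0.374, 1.0),
    "MCM7": (1.307, 0.0),
    "TAF6": (0.657, 0.55),
}


def table1_calls(caller_id: str) -> list:
    """The published candidates as one caller's call set (one call per
    carrier per region, uncertain significance)."""
    calls = []
    for chrom, start, end, svtype, carriers in TABLE1_ROWS:
        for sample in carriers:
            calls.append(
                SVCall(
                    sample_id=sample, caller_id=caller_id, chrom=chrom,
                    start=start, end=end, svtype=svtype,
                    acmg_class=ACMGClass.UNCERTAIN, genotype=Genotype.HET,
                )
            )
    return calls


@pytest.fixture(scope="session")
def fixture_gene_model() -> list:
    """Gene intervals covering the eight genes hit by the published
    candidates (synthetic stand-in coordinates)."""
    return list(FIXTURE_GENES)


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """One default synthetic cohort bundle (seed 1), generated once."""
    out = tmp_path_factory.mktemp("bundle") / "seed1"
    return generate_cohort(SimConfig(), out, seed=1)


@pytest.fixture(scope="session")
def default_bundle_run(default_bundle):
    """Pipeline output (candidates, stage report) on the default bundle."""
    config = PipelineConfig.from_yaml(default_bundle.pipeline_config)
    return run_pipeline(config)
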