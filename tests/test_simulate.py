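"""Synthetic cohort generator: determinism, truth bookkeeping, planted
caller artifacts, and recovery scoring."""

import hashlib
import json
from pathlib import Path

import pytest

from svprior import (
    ACMGClass,
    CandidateRegion,
    SimConfig,
    SVType,
    TruthSet,
    generate_cohort,
    read_caller_vcf,
    read_phenotype,
    score_recovery,
)

# A scaled-down configuration for generator-focused tests (the full-size
# default bundle is exercised by the session fixture and end-to-end tests).
SMALL = dict(
    n_samples=100, n_severe=22, n_severe_carrier_sets=2, n_nonsevere_shared=1,
    n_cross_group_shared=1, n_blacklist_decoys=1, n_oversize_decoys=1,
    n_benign_decoys=1, n_single_caller_decoys=1, background_mean=3.0,
)


def _bundle_digest(root: Path) -> str:
    """Content hash with the (run-specific) directory prefix normalized."""
    h = hashlib.sha256()
    for p in sorted(Path(root).rglob("*")):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes().replace(str(root).encode(), b"ROOT"))
    return h.hexdigest()


class TestGenerateCohort:
    def test_fixed_seed_reproduces_bundle_byte_for_byte(self, tmp_path):
        b1 = generate_cohort(SimConfig(**SMALL), tmp_path / "one", seed=9)
        b2 = generate_cohort(SimConfig(**SMALL), tmp_path / "two", seed=9)
        assert _bundle_digest(b1.root) == _bundle_digest(b2.root)
        b3 = generate_cohort(SimConfig(**SMALL), tmp_path / "three", seed=10)
        assert _bundle_digest(b3.root) != _bundle_digest(b1.root)

    def test_truth_lists_configured_candidate_count(self, default_bundle):
        truth = default_bundle.truth
        assert len(truth.expected_candidates) == 4
        by_cat = {}
        for e in truth.entries:
            by_cat[e.category] = by_cat.get(e.category, 0) + 1
        assert by_cat == {
            "severe_candidate": 4, "nonsevere_shared": 5, "cross_group_shared": 3,
            "blacklist_decoy": 3, "oversize_decoy": 2, "benign_decoy": 3,
            "single_caller_decoy": 2,
        }

    def test_truth_json_round_trips(self, default_bundle):
        loaded = TruthSet.load(default_bundle.truth_json)
        assert loaded.entries == default_bundle.truth.entries

    def test_planted_candidates_have_two_plus_carriers_and_callers(self, default_bundle):
        for e in default_bundle.truth.expected_candidates:
            assert len(e.carriers) >= 2
            assert len(e.callers) >= 2

    def test_planted_thi_scores_put_carriers_in_severe_subgroup(self, default_bundle):
        cohort = read_phenotype(default_bundle.phenotype)
        for e in default_bundle.truth.expected_candidates:
            for sample in e.carriers:
                assert cohort.entries[sample] > 68

    def test_oversize_decoys_exceed_length_cutoff(self, default_bundle):
        for e in default_bundle.truth.entries:
            if e.category == "oversize_decoy":
                assert e.end - e.start > 100_000
            elif e.category != "single_caller_decoy":
                assert e.end - e.start <= 100_000

    def test_manifest_covers_every_sample_caller_pair(self, default_bundle):
        import pandas as pd

        manifest = pd.read_csv(default_bundle.manifest, sep="\t")
        assert len(manifest) == 310 * 3
        assert set(manifest["caller"]) == {"cnvkit", "manta", "tiddit"}

    def test_type_mislabel_appears_in_that_callers_vcf(self, tmp_path):
        """With mislabelling forced on, the flagged caller's VCF reports the
        flipped type (DUP for a planted DEL) at jittered coordinates while
        the other callers keep the true type."""
        cfg = SimConfig(**{**SMALL, "type_mislabel": 1.0})
        bundle = generate_cohort(cfg, tmp_path / "mis", seed=3)
        flagged = [e for e in bundle.truth.expected_candidates if e.mislabeled_caller]
        assert flagged
        for e in flagged:
            true_type = SVType(e.svtype)
            flipped = SVType.DUP if true_type is SVType.DEL else SVType.DEL
            for caller in e.callers:
                vcf = bundle.root / "vcf" / f"{e.carriers[0]}.{caller}.vcf"
                calls = [
                    c for c in read_caller_vcf(vcf, caller, e.carriers[0])
                    if abs(c.start - e.start) <= 5 and abs(c.end - e.end) <= 70
                ]
                assert len(calls) == 1
                expected = flipped if caller == e.mislabeled_caller else true_type
                assert calls[0].svtype is expected

    def test_invalid_configs_rejected_at_generation_time(self, tmp_path):
        with pytest.raises(ValueError):
            SimConfig(n_samples=6).validate()
        with pytest.raises(ValueError):
            SimConfig(callers=("only_one",)).validate()
        with pytest.raises(ValueError, match="Q3"):
            SimConfig(n_samples=100, n_severe=40).validate()
        # carrier pools too small for the planted carrier sets
        cfg = SimConfig(**{**SMALL, "n_severe_carrier_sets": 40})
        with pytest.raises(ValueError, match="not enough samples|mini-genome"):
            generate_cohort(cfg, tmp_path / "bad", seed=1)


class TestScoreRecovery:
    def test_perfect_and_empty_recovery(self, default_bundle):
        truth = default_bundle.truth
        perfect = [
            CandidateRegion(
                chrom=e.chrom, start=e.start, end=e.end, svtype=SVType(e.svtype),
                supporting_callers=set(e.callers), carrier_samples=set(e.carriers),
                gene_symbols=set(e.genes), acmg_class=ACMGClass.UNCERTAIN,
            )
            for e in truth.expected_candidates
        ]
        scores = score_recovery(perfect, truth)
        assert scores["precision"] == 1.0 and scores["recall"] == 1.0
        empty = score_recovery([], truth)
        assert empty["recall"] == 0.0

    def test_spurious_candidate_lowers_precision(self, default_bundle):
        truth = default_bundle.truth
        spurious = CandidateRegion(
            chrom="chr2", start=1_000, end=2_000, svtype=SVType.DEL,
            supporting_callers={"a", "b"}, carrier_samples={"S1", "S2"},
            gene_symbols=set(), acmg_class=ACMGClass.UNCERTAIN,
        )
        scores = score_recovery([spurious], truth)
        assert scores["precision"] == 0.0
        assert scores["recall"] == 0.0
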