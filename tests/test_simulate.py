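import json
import math

import numpy as np
import pytest

import ribofeat as rf
from ribofeat.simulate import SENSE_CODONS, default_codon_usage


class TestCdsReference:
    def test_constructive_invariants(self):
        for s in rf.generate_cds_reference(100, seed=1):
            assert s.startswith("ATG")
            assert s[-3:] in {"TAG", "TGA", "TAA"}
            assert len(s) % 3 == 0

    def test_codon_frequencies_match_usage(self):
        usage = default_codon_usage()
        cds = rf.generate_cds_reference(5000, seed=2, length_range=(300, 600))
        counts = {}
        total = 0
        for s in cds:
            for p in range(3, len(s) - 3, 3):
                counts[s[p : p + 3]] = counts.get(s[p : p + 3], 0) + 1
                total += 1
        for codon in SENSE_CODONS:
            assert counts.get(codon, 0) / total == pytest.approx(usage[codon], abs=0.01)

    def test_seeded_determinism(self):
        assert rf.generate_cds_reference(20, seed=3) == rf.generate_cds_reference(20, seed=3)

    def test_bad_usage_rejected(self):
        usage = default_codon_usage()
        usage["AAA"] += 0.5
        with pytest.raises(ValueError):
            rf.generate_cds_reference(5, codon_usage=usage)


class TestCohort:
    def test_label_counts(self, small_cohort):
        y = list(small_cohort.labels.values())
        assert sum(y) == small_cohort.config.n_ribo
        assert len(y) - sum(y) == small_cohort.config.n_noribo

    def test_truth_lists_planted_features(self):
        cfg = rf.CohortConfig(planted_effects={"fEgc": 0.1, "fELen": -0.2})
        truth = rf.planted_truth(cfg)
        assert truth.planted_features() == {"fEgc": 1, "fELen": -1}
        mech = {p["feature"]: p["mechanism"] for p in truth.planted}
        assert mech["fEgc"] == "mechanistic"
        assert mech["fELen"] == "injected"

    def test_truth_invariant_to_seed(self):
        cfg_a = rf.CohortConfig(planted_effects={"fEgc": 0.1}, seed=1)
        cfg_b = rf.CohortConfig(planted_effects={"fEgc": 0.1}, seed=99)
        assert rf.planted_truth(cfg_a) == rf.planted_truth(cfg_b)

    def test_empty_plan_empty_truth(self):
        assert rf.planted_truth(rf.CohortConfig()).planted == []

    def test_infeasible_effect_rejected(self):
        with pytest.raises(ValueError):
            rf.CohortConfig(planted_effects={"fEgc": 1.5})

    def test_seeded_cohort_reproducible(self):
        cfg = rf.CohortConfig(n_ribo=5, n_noribo=5, seed=17)
        a = rf.generate_cohort(cfg)
        b = rf.generate_cohort(cfg)
        assert [t.seq for t in a.transcripts] == [t.seq for t in b.transcripts]

    def test_planted_first_exon_gc_shift(self):
        cfg = rf.CohortConfig(n_ribo=500, n_noribo=500, seed=23,
                              planted_effects={"fEgc": 0.1})
        coh = rf.generate_cohort(cfg)
        by_class = {0: [], 1: []}
        for t in coh.transcripts:
            by_class[coh.labels[t.id]].append(rf.splice_features(t).first_exon_gc)
        diff = np.mean(by_class[1]) - np.mean(by_class[0])
        assert diff == pytest.approx(0.1, abs=0.02)

    def test_null_cohort_has_no_significant_features(self):
        cfg = rf.CohortConfig(n_ribo=100, n_noribo=100, seed=29)
        coh = rf.generate_cohort(cfg)
        fm = rf.extract_features(coh.transcripts, coh.labels, repeats=coh.repeats,
                                 compute_structure=False)
        fm = rf.minmax_scale(rf.impute_mean(fm))
        res = rf.ks_rank(fm)
        frac_null = np.mean([r.p > 0.01 for r in res])
        assert frac_null >= 0.95

    def test_emitted_files_round_trip(self, small_cohort, tmp_path):
        small_cohort.write(tmp_path)
        ts = rf.read_transcripts(tmp_path / "transcripts.fa", tmp_path / "transcripts.bed")
        assert [t.id for t in ts] == [t.id for t in small_cohort.transcripts]
        from ribofeat.sites import read_site_table
        from ribofeat.splicing import read_repeat_bed
        m6a = read_site_table(tmp_path / "sites_m6a.tsv")
        assert set(m6a) <= set(small_cohort.labels)
        reps = read_repeat_bed(tmp_path / "repeats.bed")
        assert len(reps) == len(small_cohort.repeats)
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert truth["labels"] == {k: v for k, v in small_cohort.labels.items()}


class TestFeatureMatrixGenerator:
    def test_exact_class_shift(self):
        fm, signs = rf.synthetic_feature_matrix(
            500, 8, {"f01": 0.1, "f02": -0.1}, noise_sd=0.05, seed=31
        )
        diff = fm.X[fm.y == 1].mean() - fm.X[fm.y == 0].mean()
        assert diff["f01"] == pytest.approx(0.1, abs=0.02)
        assert diff["f02"] == pytest.approx(-0.1, abs=0.02)
        assert abs(diff["f05"]) < 0.02
        assert signs == {"f01": 1, "f02": -1}

    def test_unknown_planted_name_rejected(self):
        with pytest.raises(ValueError):
            rf.synthetic_feature_matrix(10, 4, {"f09": 0.1})
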