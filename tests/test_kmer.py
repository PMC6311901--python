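import math

import numpy as np
import pytest

from ribofeat import (
    build_reference_tables,
    context_score,
    generate_cds_reference,
    hexamer_score,
    trimer_score,
)
from ribofeat.kmer import FrequencyTable, read_tables, write_tables, _kmer_keys


def flat_table(kind, k=None, ratio=1.0, offsets=range(-6, 4)):
    """Uniform table with F/F' = ratio for every unit."""
    if kind == "context_position":
        keys = [(o, b) for o in offsets for b in "ACGT"]
    else:
        keys = _kmer_keys(k)
    base = 1.0 / len(keys)
    return FrequencyTable(kind, {u: base * ratio for u in keys}, {u: base for u in keys})


class TestReferenceTables:
    def test_seeded_build_is_reproducible(self, cds_reference):
        t1 = build_reference_tables(cds_reference[:50], seed=9)
        t2 = build_reference_tables(cds_reference[:50], seed=9)
        assert t1["hexamer"].F == t2["hexamer"].F
        assert t1["hexamer"].F_prime == t2["hexamer"].F_prime

    def test_pseudocount_keeps_all_units_positive(self, ref_tables):
        assert min(ref_tables["hexamer"].F_prime.values()) > 0
        assert min(ref_tables["trimer"].F.values()) > 0

    def test_trimer_frequencies_of_degenerate_reference(self):
        tables = build_reference_tables(["ATGAAATAG"] * 50, seed=0, pseudocount=1e-12)
        for unit in ("ATG", "AAA", "TAG"):
            assert tables["trimer"].F[unit] == pytest.approx(1 / 3, abs=1e-9)

    def test_frequencies_normalised(self, ref_tables):
        assert sum(ref_tables["trimer"].F.values()) == pytest.approx(1.0, abs=1e-9)
        ctx = ref_tables["context_position"]
        for off in range(-6, 4):
            assert sum(ctx.F[(off, b)] for b in "ACGT") == pytest.approx(1.0, abs=1e-9)

    def test_rejects_bad_cds(self):
        with pytest.raises(ValueError):
            build_reference_tables([], seed=0)
        with pytest.raises(ValueError):
            build_reference_tables(["ATGAATAG"], seed=0)  # not divisible by 3

    def test_tsv_round_trip(self, ref_tables, tmp_path):
        write_tables(ref_tables, tmp_path / "tables.tsv")
        back = read_tables(tmp_path / "tables.tsv")
        for kind in ("context_position", "trimer", "hexamer"):
            for u, v in ref_tables[kind].F.items():
                assert back[kind].F[u] == pytest.approx(v, rel=1e-12)


class TestContextScore:
    def test_identical_references_score_zero(self):
        tab = flat_table("context_position")
        s = context_score("A" * 20, 10, tab)
        assert s.value == pytest.approx(0.0)
        assert s.n_units == 10

    def test_uniform_ratio_e_scores_one(self):
        tab = flat_table("context_position", ratio=math.e)
        assert context_score("A" * 20, 10, tab).value == pytest.approx(1.0)

    def test_two_position_toy_table_cancels(self):
        # ratios e^2 and e^-2 across a 2-position window average to zero
        F = {(-1, b): math.exp(2) * 0.25 for b in "ACGT"}
        F.update({(0, b): math.exp(-2) * 0.25 for b in "ACGT"})
        Fp = {k: 0.25 for k in F}
        tab = FrequencyTable("context_position", F, Fp)
        s = context_score("ACGTACGT", 1, tab, offsets=(-1, 0))
        assert s.value == pytest.approx(0.0, abs=1e-12)

    def test_window_outside_sequence_is_missing(self):
        tab = flat_table("context_position")
        assert context_score("A" * 20, 3, tab) is None  # truncated upstream
        assert context_score("A" * 20, 18, tab) is None  # truncated downstream


class TestUnitScores:
    def test_identical_references_score_zero(self):
        assert trimer_score("ATGAAATAG", flat_table("trimer", 3)).value == pytest.approx(0.0)
        assert hexamer_score("ATGAAATAG", flat_table("hexamer", 6)).value == pytest.approx(0.0)

    def test_worked_three_codon_example(self):
        tab = flat_table("trimer", 3)
        for u in ("ATG", "AAA", "TAG"):
            tab.F[u] = tab.F_prime[u] * math.e
        s = trimer_score("ATGAAATAG", tab)
        assert s.value == pytest.approx(1.0, abs=1e-12)
        assert s.n_units == 3

    def test_hexamer_units_step_by_three(self):
        s = hexamer_score("ATGAAATAG", flat_table("hexamer", 6))
        assert s.n_units == 2  # ATGAAA, AAATAG

    def test_units_with_n_are_skipped(self):
        s = trimer_score("ATGNNNTAG", flat_table("trimer", 3))
        assert s.n_units == 2

    def test_too_short_orf_is_missing(self):
        assert hexamer_score("ATG", flat_table("hexamer", 6)) is None
        assert trimer_score("AT", flat_table("trimer", 3)) is None


class TestScoreProperties:
    def test_antisymmetry_under_reference_swap(self, ref_tables):
        rng = np.random.default_rng(13)
        tab = ref_tables["trimer"]
        swapped = FrequencyTable("trimer", tab.F_prime, tab.F)
        for _ in range(50):
            n_codons = int(rng.integers(3, 40))
            orf = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 3 * n_codons)])
            a = trimer_score(orf, tab).value
            b = trimer_score(orf, swapped).value
            assert a == pytest.approx(-b, abs=1e-12)

    def test_cds_scores_above_their_shuffles(self, ref_tables):
        """Coding-like ORFs average a positive score, their shuffles negative."""
        rng = np.random.default_rng(14)
        cds = generate_cds_reference(200, seed=99)
        fwd, shuf = [], []
        for s in cds:
            fwd.append(trimer_score(s, ref_tables["trimer"]).value)
            sh = "".join(rng.permutation(list(s)))
            shuf.append(trimer_score(sh, ref_tables["trimer"]).value)
        assert np.mean(fwd) > 0 > np.mean(shuf)
        assert np.mean(fwd) > np.mean(shuf)
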