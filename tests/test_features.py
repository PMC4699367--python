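"""Folding proxy, PWM scores, k-mers and intron feature extraction."""

import itertools

import numpy as np
import pytest
from scipy.stats import pearsonr

from tukinetics import features as ft
from tukinetics import synthetic_data as sd
from tukinetics.io_formats import TranscriptModel


def _enumerate_fold(seq):
    """Exhaustive minimum over all nested pairings under the proxy scoring.

    Independent oracle: recursively enumerates every nested structure with
    hairpin loops >= MIN_LOOP and scores pairs + stacking directly.
    """
    n = len(seq)

    def best(i, j, closed_by_pair):
        if j - i < ft.MIN_LOOP + 1:
            return 0.0
        options = [best(i + 1, j, False)]
        for k in range(i + ft.MIN_LOOP + 1, j + 1):
            pe = ft.PAIR_ENERGY.get((seq[i], seq[k]))
            if pe is None:
                continue
            inner_open = best(i + 1, k - 1, False)
            inner_closed = (
                ft.PAIR_ENERGY.get((seq[i + 1], seq[k - 1])) is not None
                and k - 1 - (i + 1) >= ft.MIN_LOOP + 1
            )
            inner = inner_open
            if inner_closed:
                inner = min(inner, best_closed(i + 1, k - 1) + ft.STACK_BONUS)
            rest = best(k + 1, j, False) if k + 1 <= j else 0.0
            options.append(pe + inner + rest)
        return min(options)

    def best_closed(i, j):
        """Best energy of [i, j] given (i, j) is paired (pair energy incl.)."""
        pe = ft.PAIR_ENERGY[(seq[i], seq[j])]
        inner = best(i + 1, j - 1, False)
        if (
            ft.PAIR_ENERGY.get((seq[i + 1], seq[j - 1])) is not None
            and (j - 1) - (i + 1) >= ft.MIN_LOOP + 1
        ):
            inner = min(inner, best_closed(i + 1, j - 1) + ft.STACK_BONUS)
        return pe + inner

    return min(0.0, best(0, n - 1, False))


class TestFoldEnergy:
    def test_homopolymer_has_no_structure(self):
        assert ft.nussinov_energy("AAAAAAAA") == 0.0

    def test_matches_exhaustive_oracle_on_short_sequences(self):
        for seq in ["GGGGAAAACCCC", "GCAUAAAGCUAG", "AUGGCAAAUGCC", "GUGUAAAACACA"]:
            dp = ft.nussinov_energy(seq)
            assert dp == pytest.approx(_enumerate_fold(seq))
        assert ft.nussinov_energy("GGGGAAAACCCC") < 0

    def test_hairpin_beats_shuffles(self):
        """A designed stem-loop is more stable than its shuffled variants."""
        hairpin = "GGGGGGAAUACGAAAACCCCCC"
        e0 = ft.nussinov_energy(hairpin)
        rng = np.random.default_rng(5)
        wins = sum(
            e0 < ft.nussinov_energy("".join(rng.permutation(list(hairpin))))
            for _ in range(100)
        )
        assert wins >= 95

    def test_non_rna_characters_rejected_with_positions(self):
        with pytest.raises(ValueError, match="positions"):
            ft.nussinov_energy("ACGXACGU")

    def test_dna_input_transparently_converted(self):
        assert ft.nussinov_energy("GGGGAAAACCCC") == ft.nussinov_energy(
            "GGGGAAAACCCC".replace("U", "T")
        )

    def test_callable_backend(self):
        assert ft.fold_energy("ACGU", backend=lambda s: -1.5) == -1.5

    def test_unknown_backend_rejected(self):
        with pytest.raises(ValueError, match="backend"):
            ft.fold_energy("ACGU", backend="nope")


class TestPerBaseEnergy:
    def test_definition(self):
        assert ft.per_base_energy(-30, 100) == pytest.approx(-0.3)

    def test_unstructured(self):
        assert ft.per_base_energy(0, 50) == 0.0

    def test_arithmetic(self):
        assert ft.per_base_energy(-12.4, 62) == pytest.approx(-0.2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ft.per_base_energy(-3, 0)
        with pytest.raises(ValueError):
            ft.per_base_energy(1.0, 10)


class TestSiteScore:
    def test_uniform_pwm_scores_zero(self):
        pwm = np.full((4, 4), 0.25)
        assert ft.site_score("ACGU", pwm) == pytest.approx(0.0)

    def test_hand_computed_two_position_example(self):
        pwm = np.array([[0.5, 0.25, 0.125, 0.125]] * 2)
        assert ft.site_score("AA", pwm) == pytest.approx(2.0)

    def test_consensus_maximizes_score(self):
        windows = ["GUAUGU"] * 8 + ["GUACGU", "GCAUGU"]
        pwm = ft.build_pwm(windows)
        consensus = ft.site_score("GUAUGU", pwm)
        for other in itertools.islice(
            ("".join(p) for p in itertools.product("ACGU", repeat=6)), 0, 256
        ):
            assert ft.site_score(other, pwm) <= consensus + 1e-12

    def test_window_width_mismatch_rejected(self):
        with pytest.raises(ValueError, match="width"):
            ft.site_score("ACG", np.full((4, 4), 0.25))


class TestKmerFrequencies:
    def test_mononucleotide(self):
        assert ft.kmer_frequencies("AUAU", 1) == {"A": 0.5, "U": 0.5}

    def test_dinucleotide(self):
        freqs = ft.kmer_frequencies("AUAU", 2)
        assert freqs == pytest.approx({"AU": 2 / 3, "UA": 1 / 3})

    def test_frequencies_sum_to_one(self):
        for k in (1, 2, 3):
            assert sum(ft.kmer_frequencies("GUAUGUACUAAC", k).values()) == (
                pytest.approx(1.0)
            )

    def test_sequence_shorter_than_k_rejected(self):
        with pytest.raises(ValueError):
            ft.kmer_frequencies("AU", 3)


def _genome_for(model, intron_seq, rng):
    n = model.end + 50
    chrom = rng.choice(list("ACGU"), size=n)
    iv = model.intron
    seq = intron_seq if model.strand == "+" else ft.reverse_complement(intron_seq)
    chrom[iv[0] : iv[1]] = list(seq)
    return {model.chrom: "".join(chrom)}


class TestExtractIntronFeatures:
    def test_five_ss_to_bp_region_length_is_bp_position(self, toy_gene, rng):
        intron = sd.simulate_intron_sequences(1, 0.6, 40, seed=1)[0]
        genome = _genome_for(toy_gene, intron.seq, rng)
        fv = ft.extract_intron_features(toy_gene, genome, intron.bp_pos)
        assert fv.intron_length == 40
        assert fv.exon2_length == 50 and fv.transcript_length == 100
        # dG/nt of the 5'ss-BP region used exactly bp_pos bases
        region = intron.seq[: intron.bp_pos]
        assert fv.dg_per_nt_5ss_to_bp == pytest.approx(
            ft.nussinov_energy(region) / intron.bp_pos
        )

    def test_bp_outside_intron_rejected(self, toy_gene, rng):
        intron = sd.simulate_intron_sequences(1, 0.6, 40, seed=1)[0]
        genome = _genome_for(toy_gene, intron.seq, rng)
        with pytest.raises(ValueError, match="BP position"):
            ft.extract_intron_features(toy_gene, genome, 41)

    def test_monomer_frequencies_track_generator_bias(self, toy_gene, rng):
        intron = sd.simulate_intron_sequences(1, 0.7, 40, seed=3)[0]
        genome = _genome_for(toy_gene, intron.seq, rng)
        fv = ft.extract_intron_features(toy_gene, genome, intron.bp_pos)
        au = fv.kmer_freq.get("k1_A", 0) + fv.kmer_freq.get("k1_U", 0)
        assert au == pytest.approx(0.7, abs=0.2)  # single short sequence

    def test_short_transcript_window_flagged(self, rng):
        tiny = TranscriptModel("tiny", "chrT", "+", [(10, 22), (62, 74)])
        intron = sd.simulate_intron_sequences(1, 0.5, 40, seed=2)[0]
        genome = _genome_for(tiny, intron.seq, rng)
        fv = ft.extract_intron_features(tiny, genome, intron.bp_pos)
        assert "window-truncated" in fv.flags

    def test_strand_symmetry(self, rng):
        """A gene and its mirror on the opposite strand yield identical
        feature vectors."""
        plus = TranscriptModel("gp", "chrP", "+", [(100, 150), (190, 240)])
        intron = sd.simulate_intron_sequences(1, 0.6, 40, seed=7)[0]
        genome_plus = _genome_for(plus, intron.seq, rng)
        n = len(genome_plus["chrP"])
        genome_minus = {"chrM": ft.reverse_complement(genome_plus["chrP"])}
        minus = TranscriptModel(
            "gm", "chrM", "-", [(n - 240, n - 190), (n - 150, n - 100)]
        )
        fp = ft.extract_intron_features(plus, genome_plus, intron.bp_pos)
        fm = ft.extract_intron_features(minus, genome_minus, intron.bp_pos)
        for attr in (
            "dg_per_nt_intron", "dg_per_nt_5ss_to_bp", "dg_window_start",
            "dg_window_stop", "dg_window_3ss", "intron_length", "exon2_length",
        ):
            assert getattr(fp, attr) == getattr(fm, attr), attr
        assert fp.kmer_freq == fm.kmer_freq

    def test_a_and_u_frequencies_anticorrelated_in_compositional_regime(self):
        """At fixed (high) A+U content, varying the A share across introns
        makes A and U frequencies strongly negatively correlated."""
        rng = np.random.default_rng(9)
        a_freqs, u_freqs = [], []
        for i in range(80):
            a_frac = float(rng.uniform(0.25, 0.75))
            intron = sd.simulate_intron_sequences(
                1, 0.7, 120, seed=100 + i, a_fraction=a_frac
            )[0]
            f = ft.kmer_frequencies(intron.seq, 1)
            a_freqs.append(f.get("A", 0.0))
            u_freqs.append(f.get("U", 0.0))
        assert pearsonr(a_freqs, u_freqs).statistic < -0.75


class TestFeatureTable:
    def test_table_covers_intronic_genes_only(self, toy_gene, rng):
        single = TranscriptModel("nc1", "chrT", "+", [(300, 500)], tx_class="CUT")
        intron = sd.simulate_intron_sequences(1, 0.6, 40, seed=4)[0]
        genome = _genome_for(toy_gene, intron.seq, rng)
        genome["chrT"] = genome["chrT"] + "A" * 400
        table = ft.feature_table(
            [toy_gene, single], genome, {"toy1": intron.bp_pos}
        )
        assert list(table.index) == ["toy1"]
        assert table.loc["toy1", "dg_per_nt_intron"] <= 0
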