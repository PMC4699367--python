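"""Simulator: kinetic closed forms, annotations, reads, sequences, features."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.stats import binom

from tukinetics import splicing_quant as sq
from tukinetics import synthetic_data as sd


def _ode_oracle(params, t):
    """Brute-force numerical integration of the labeling chain."""
    n, r = params.n_maturation_steps, params.n_maturation_steps * params.k_splice
    tp = max(0.0, t - params.label_offset)
    if tp == 0:
        return 0.0, 0.0

    def rhs(_, x):
        d = [params.k_syn - r * x[0]]
        for i in range(1, n):
            d.append(r * x[i - 1] - r * x[i])
        d.append(r * x[n - 1] - params.k_decay * x[n])
        return d

    sol = solve_ivp(rhs, (0, tp), [0.0] * (n + 1), rtol=1e-10, atol=1e-12)
    return float(np.sum(sol.y[:n, -1])), float(sol.y[n, -1])


class TestKineticModel:
    def test_initial_condition_is_zero(self):
        p = sd.KineticParams(10, 2, 1, label_offset=0.0)
        assert sd.labeled_abundance(p, 0.0) == (0.0, 0.0)

    def test_precursor_closed_form_value(self):
        p = sd.KineticParams(10, 2, 1, label_offset=0.0)
        P, _ = sd.labeled_abundance(p, 1.0)
        assert P == pytest.approx(5 * (1 - np.exp(-2)), rel=1e-12)

    def test_steady_state_ratio_algebra(self):
        p = sd.KineticParams(7, 3, 1.5)
        truth = sd.simulate_labeled_abundances(p, [1000.0])
        assert truth.R_ss[0] == pytest.approx(3 / (3 + 1.5))
        # long-time limit of the dynamic solution approaches the SS ratio
        assert truth.R[0, -1] == pytest.approx(truth.R_ss[0], abs=1e-9)

    @pytest.mark.parametrize(
        "k_syn,k_splice,k_decay,n_steps",
        [
            (10, 2, 1, 1),
            (10, 2, 2, 1),  # degenerate k_splice == k_decay
            (5, 0.3, 4.0, 1),
            (10, 0.5, 2, 4),
            (3, 1.2, 0.05, 3),
        ],
    )
    @pytest.mark.parametrize("t", [0.7, 2.5, 5.0])
    def test_closed_form_matches_ode_integrator(self, k_syn, k_splice, k_decay,
                                                n_steps, t):
        p = sd.KineticParams(k_syn, k_splice, k_decay, n_steps, label_offset=0.5)
        P, M = sd.labeled_abundance(p, t)
        Po, Mo = _ode_oracle(p, t)
        assert P == pytest.approx(Po, rel=1e-6, abs=1e-9)
        assert M == pytest.approx(Mo, rel=1e-6, abs=1e-9)

    def test_label_offset_delays_incorporation(self):
        p = sd.KineticParams(10, 2, 1, label_offset=0.5)
        assert sd.labeled_abundance(p, 0.4) == (0.0, 0.0)
        assert sd.labeled_abundance(p, 0.6)[0] > 0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            sd.KineticParams(0, 1, 1)
        with pytest.raises(ValueError):
            sd.KineticParams(1, 1, 1, n_maturation_steps=0)
        with pytest.raises(ValueError):
            sd.KineticParams(1, 1, 1, label_offset=-1)

    def test_unsorted_times_rejected(self):
        p = sd.KineticParams(1, 1, 1)
        with pytest.raises(ValueError):
            sd.simulate_labeled_abundances(p, [5.0, 1.5])

    def test_plateau_of_delayed_maturation_vs_first_order(self):
        """Erlang-chain species hold a flat above-steady-state plateau over
        1.5-5 min under per-sample normalization; the first-order analog
        declines monotonically (its labeled pool saturates immediately)."""
        times = (1.5, 2.5, 5.0)
        bg = [sd.KineticParams(20, 5.0, 0.2, label_offset=0.5) for _ in range(30)]

        def trajectory(n_steps):
            cut = sd.KineticParams(5, 0.4, 2.0, n_maturation_steps=n_steps,
                                   label_offset=0.5)
            truth = sd.simulate_labeled_abundances(bg + [cut], times)
            return sd.labeled_fpkm_trajectory(truth).iloc[-1].to_numpy()

        erlang, first = trajectory(4), trajectory(1)
        spread = lambda r: (r.max() - r.min()) / r.mean()
        assert spread(erlang) < spread(first)
        assert erlang.min() > 1.5  # well above the steady-state level
        assert first[2] < 0.85 * first[0]  # first-order ratio erodes


class TestGenerateAnnotation:
    def test_deterministic_and_single_intron(self):
        mix = {"RP-intronic": 1.0}
        a = sd.generate_annotation(10, mix, seed=1)
        b = sd.generate_annotation(10, mix, seed=1)
        assert all(m.has_intron for m in a)
        assert [(m.gene_id, m.exons) for m in a] == [(m.gene_id, m.exons) for m in b]

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError):
            sd.generate_annotation(5, {"CUT": 0.5, "SUT": 0.4}, seed=0)

    def test_class_split_and_length_ordering(self):
        models = sd.generate_annotation(100, {"CUT": 0.5, "SUT": 0.5}, seed=7)
        n_cut = sum(m.tx_class == "CUT" for m in models)
        lo, hi = binom.ppf([0.005, 0.995], 100, 0.5)
        assert lo <= n_cut <= hi
        cut_len = np.median([m.mature_length for m in models if m.tx_class == "CUT"])
        sut_len = np.median([m.mature_length for m in models if m.tx_class == "SUT"])
        assert sut_len > cut_len

    def test_coordinates_non_overlapping(self):
        models = sd.generate_annotation(50, {"CUT": 0.5, "RP-intronic": 0.5}, seed=3)
        spans = sorted((m.start, m.end) for m in models)
        assert all(a[1] < b[0] for a, b in zip(spans, spans[1:]))


class TestSimulateReads:
    def _truth(self, models, P, M):
        P = np.asarray(P, float)[:, None]
        M = np.asarray(M, float)[:, None]
        with np.errstate(invalid="ignore"):
            R = np.where(P + M > 0, M / np.maximum(P + M, 1e-300), 0.0)
        return sd.SimTruth(
            gene_ids=[m.gene_id for m in models],
            times=np.array([1.5]),
            P=P, M=M, R=R,
            P_ss=P[:, 0], M_ss=M[:, 0], R_ss=R[:, 0],
            params=[],
        )

    def test_fully_spliced_truth_yields_no_intron_reads(self, toy_gene):
        truth = self._truth([toy_gene], [0.0], [10.0])
        table = sd.simulate_reads(truth, [toy_gene], read_len=30,
                                  frag_len_mean=30, frag_len_sd=0,
                                  n_fragments=500, seed=1)
        assert not table.category.isin(["intron", "b5", "b3"]).any()

    def test_fixed_seed_is_byte_identical(self, toy_gene):
        truth = self._truth([toy_gene], [1.0], [1.0])
        kw = dict(read_len=30, frag_len_mean=40, frag_len_sd=8,
                  n_fragments=300, seed=9)
        a = sd.simulate_reads(truth, [toy_gene], **kw).to_csv()
        b = sd.simulate_reads(truth, [toy_gene], **kw).to_csv()
        assert a == b

    def test_mature_read_fraction_matches_binomial_expectation(self, toy_gene):
        """R=0.5: the unambiguous mature fraction must match the geometry's
        closed-form expectation within 99% binomial bounds."""
        truth = self._truth([toy_gene], [5.0], [5.0])
        n = 10000
        table = sd.simulate_reads(truth, [toy_gene], read_len=30,
                                  frag_len_mean=30, frag_len_sd=0,
                                  n_fragments=n, seed=5)
        geom = sq.GeneGeometry(exon1=50, intron=40, exon2=50, read_len=30)
        probs = sq._category_probs(geom, 0.5)
        # unambiguous mature = any junction-spanning fragment; unambiguous
        # precursor = any intron-touching fragment
        p_mat = probs[0] + probs[1]
        p_pre = probs[3:8].sum()
        n_mat = (table.category == "junction").sum()
        n_pre = table.category.isin(["intron", "b5", "b3"]).sum()
        for observed, p in ((n_mat, p_mat), (n_pre, p_pre)):
            lo, hi = binom.ppf([0.005, 0.995], n, p)
            assert lo <= observed <= hi

    def test_background_reads_drawn_from_steady_state(self, toy_gene):
        truth = self._truth([toy_gene], [10.0], [0.0])
        truth.M_ss = np.array([10.0])
        truth.P_ss = np.array([0.0])  # SS fully spliced
        table = sd.simulate_reads(truth, [toy_gene], read_len=30,
                                  frag_len_mean=30, frag_len_sd=0,
                                  n_fragments=2000, background_fraction=0.3,
                                  seed=2)
        bg = table[table.origin == "background"]
        assert len(bg) > 0
        assert (bg.isoform == "mature").all()

    def test_invalid_background_fraction(self, toy_gene):
        truth = self._truth([toy_gene], [1.0], [1.0])
        with pytest.raises(ValueError):
            sd.simulate_reads(truth, [toy_gene], background_fraction=1.0)


class TestIntronSequences:
    def test_bp_motif_at_annotated_position(self):
        introns = sd.simulate_intron_sequences(20, 0.6, 120, seed=3)
        for it in introns:
            assert it.seq[it.bp_pos - 6 : it.bp_pos + 1] == "UACUAAC"
            assert it.seq[it.bp_pos - 1] == "A"  # branch adenosine, 1-based
            assert it.seq.startswith("GUAUGU")
            assert it.seq.endswith("AG")

    def test_mean_au_fraction_tracks_bias(self):
        introns = sd.simulate_intron_sequences(400, 0.5, 100, seed=11)
        au = np.mean([
            sum(b in "AU" for b in it.seq) / it.length for it in introns
        ])
        assert au == pytest.approx(0.5, abs=0.02)

    def test_deterministic(self):
        a = sd.simulate_intron_sequences(5, 0.6, 80, seed=2)
        b = sd.simulate_intron_sequences(5, 0.6, 80, seed=2)
        assert [x.seq for x in a] == [x.seq for x in b]

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="length"):
            sd.simulate_intron_sequences(1, 0.5, 20)

    def test_invalid_bias_rejected(self):
        with pytest.raises(ValueError):
            sd.simulate_intron_sequences(1, 1.2, 100)


class TestFeatureTable:
    def test_deterministic_and_balanced(self):
        a = sd.generate_feature_table(100, seed=8)
        b = sd.generate_feature_table(100, seed=8)
        assert a.equals(b)
        assert a.label.sum() == 50
        assert (a.dg_per_nt <= 0).all()

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            sd.generate_feature_table(1)
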