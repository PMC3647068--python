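"""Kinetic Monte Carlo engines, correctness classifier, empirical PMFs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pilusim import (
    builtin_table,
    classify_correct,
    conditional_mean_reaching_time,
    empirical_pmf,
    grow_pilus,
    p_star_closed_form,
    simulate_ensemble,
    simulate_reaching_times,
    simulate_records,
    transition_model,
)
from pilusim.growth import (
    read_ensemble_tsv,
    summarize_records,
    write_ensemble_fasta,
    write_ensemble_tsv,
)

from _oracles import pattern_is_correct


class TestClassifyCorrect:
    @pytest.mark.parametrize(
        "seq,want",
        [
            ("GFEKAH", True),  # minimal, i = j = 1
            ("GFKAH", False),  # no PapE
            ("GFEEEKAAAAH", True),  # i = 3, j = 4
            ("GFEKH", False),  # no PapA
            ("GFEKAHH", False),  # two terminators
            ("FGEKAH", False),  # does not start with the adhesin
            ("GFEKAAH", True),
            ("GFEKA", False),  # unterminated
        ],
    )
    def test_examples(self, seq, want):
        assert classify_correct(seq) is want

    def test_bad_symbol_rejected(self):
        with pytest.raises(ValueError, match="unknown subunit"):
            classify_correct("GFXKAH")

    @settings(max_examples=100, deadline=None)
    @given(st.text(alphabet="GFEKAH", min_size=1, max_size=20))
    def test_agrees_with_loop_reference(self, seq):
        assert classify_correct(seq) == pattern_is_correct(seq)


class _MedianRng:
    """Stub generator: zero waiting times, donor drawn at u = 0.5, which is
    the most probable donor whenever it carries more than half the mass."""

    def exponential(self, scale):
        return 0.0

    def random(self):
        return 0.5


class TestGrowPilus:
    def test_structural_invariants(self, in_vitro_model):
        rng = np.random.default_rng(11)
        for _ in range(200):
            rec = grow_pilus(in_vitro_model, rng)
            assert rec.sequence[0] == "G"
            if rec.terminated == "absorbed_H":
                assert rec.sequence.endswith("H")
                assert rec.sequence.count("H") == 1
            assert rec.assembly_time_h >= 0
            assert rec.length == len(rec.sequence)

    def test_argmax_path_follows_cognate_order(self, hypothetical_model):
        """Forcing the most probable donor at each step yields G, F, E: the
        fast/slow scheme's dominant donors from PapG then PapF (both carry
        1000/1004 of the row mass, so the median draw selects them)."""
        rec = grow_pilus(hypothetical_model, _MedianRng(), length_cap=3)
        assert rec.sequence == "GFE"

    def test_length_cap_enforced(self, equal_model):
        rng = np.random.default_rng(5)
        for _ in range(50):
            rec = grow_pilus(equal_model, rng, length_cap=3)
            assert rec.length <= 3
            assert rec.terminated in ("absorbed_H", "truncated_at_cap")


class TestEnsembles:
    def test_seed_determinism_bit_exact(self, hypothetical_model):
        a = simulate_ensemble(hypothetical_model, 5000, seed=42, length_cap=5000)
        b = simulate_ensemble(hypothetical_model, 5000, seed=42, length_cap=5000)
        assert a.count_by_length.equals(b.count_by_length)
        assert a.correct_count_by_length.equals(b.correct_count_by_length)
        assert (a.n_stalled, a.n_truncated) == (b.n_stalled, b.n_truncated)

    def test_record_engine_deterministic(self, equal_model):
        r1 = simulate_records(equal_model, 200, seed=9)
        r2 = simulate_records(equal_model, 200, seed=9)
        assert [r.sequence for r in r1] == [r.sequence for r in r2]
        assert [r.assembly_time_h for r in r1] == [r.assembly_time_h for r in r2]

    def test_empty_ensemble(self, equal_model):
        s = simulate_ensemble(equal_model, 0, seed=1)
        assert s.n_pili == 0
        assert s.count_by_length.sum() == 0

    def test_counts_partition_the_ensemble(self, in_vitro_model):
        s = simulate_ensemble(in_vitro_model, 20_000, seed=3)
        assert s.n_absorbed + s.n_stalled + s.n_truncated == 20_000
        joint = s.correct_count_by_length.reindex(
            s.count_by_length.index, fill_value=0
        )
        assert (joint <= s.count_by_length).all()

    def test_fraction_length_two_equal_model(self, equal_model):
        """P(2) = 1/5: PapH drawn at the first of five equal choices."""
        n = 100_000
        s = simulate_ensemble(equal_model, n, seed=17)
        frac = s.count_by_length[2] / n
        se = math.sqrt(0.2 * 0.8 / n)
        assert abs(frac - 0.2) < 4 * se

    def test_correct_long_fraction_matches_closed_form(self, hypothetical_model):
        """MC correct-and-long fraction within 4 SE of the exact tail."""
        n = 100_000
        s = simulate_ensemble(hypothetical_model, n, seed=23, length_cap=100_000)
        cc = s.correct_count_by_length
        frac = cc[cc.index >= 100].sum() / n
        p = p_star_closed_form(hypothetical_model, 100).p_star
        se = math.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < 4 * se

    def test_mc_pmf_within_4se_of_analytic(self, in_vitro_model):
        from pilusim import distributions

        n = 100_000
        s = simulate_ensemble(in_vitro_model, n, seed=29)
        dist = distributions(in_vitro_model, 200)
        pn = np.exp(dist.log_P_n)
        pcn = np.exp(dist.log_P_Cn)
        for i, length in enumerate(dist.n):
            for p_true, counts in ((pn[i], s.count_by_length),
                                   (pcn[i], s.correct_count_by_length)):
                if p_true * n < 5:
                    continue
                obs = counts.get(length, 0)
                se = math.sqrt(n * p_true * (1 - p_true))
                assert abs(obs - n * p_true) < 4 * se, (length, obs, n * p_true)

    def test_mean_waiting_time_at_papa_exit_rate(self):
        """A state with the PapA total exit rate (83.9e-3/h) is waited in for
        11.92 h on average; isolated with a two-state table so the engine's
        waiting-time draw is measured directly."""
        from pilusim.rate_model import RateTable

        from pilusim import StallWarning

        k = builtin_table("equal").k.copy() * 0.0
        k.at["G", "H"] = 83.9  # exit rate of acceptor PapA under in vitro rates
        with pytest.warns(StallWarning):  # unused acceptors have no exits
            model = transition_model(RateTable(k))
        records = simulate_records(model, 20_000, seed=31)
        times = np.array([r.assembly_time_h for r in records])
        se = times.std(ddof=1) / math.sqrt(len(times))
        assert times.mean() == pytest.approx(11.92, abs=3 * se)

    def test_truncation_vanishes_with_cap(self, equal_model):
        tight = simulate_ensemble(equal_model, 5000, seed=37, length_cap=5)
        loose = simulate_ensemble(equal_model, 5000, seed=37, length_cap=500)
        assert loose.n_truncated < tight.n_truncated
        assert loose.n_truncated == 0  # survival beyond 500 is ~1e-49

    def test_record_and_vector_engines_agree_statistically(self, equal_model):
        n = 20_000
        records = simulate_records(equal_model, n, seed=41)
        summary = summarize_records(records)
        vec = simulate_ensemble(equal_model, n, seed=43)
        # both length-2 fractions near 0.2 within 4 joint SE
        se = math.sqrt(2 * 0.2 * 0.8 / n)
        f1 = summary.count_by_length[2] / n
        f2 = vec.count_by_length[2] / n
        assert abs(f1 - f2) < 4 * se


class TestReachingTimes:
    def test_conditioned_sampler_matches_analytic(self, in_vitro_model):
        times = simulate_reaching_times(in_vitro_model, 100, 8000, seed=47)
        exact = conditional_mean_reaching_time(in_vitro_model, 100)
        se = times.std(ddof=1) / math.sqrt(len(times))
        assert times.mean() == pytest.approx(exact, abs=4 * se)

    def test_reach_threshold_times_recorded(self, hypothetical_model):
        s = simulate_ensemble(
            hypothetical_model, 5000, seed=53, length_cap=2000, reach_thresholds=(100,)
        )
        mean, se, count = s.mean_time_reaching[100]
        assert count > 0
        assert mean > 0 and se >= 0


class TestEmpiricalPmf:
    def test_wilson_interval_example(self, equal_model):
        """200/1000 -> Wilson 95% interval (0.176, 0.226)."""
        import pandas as pd

        from pilusim.growth import EnsembleSummary

        s = EnsembleSummary(
            n_pili=1000,
            count_by_length=pd.Series({2: 200}),
            correct_count_by_length=pd.Series(dtype=int),
            n_stalled=0,
            n_truncated=800,
        )
        pmf = empirical_pmf(s)
        row = pmf[pmf.n == 2].iloc[0]
        assert row.P_n == pytest.approx(0.2)
        # Wilson oracle, z = 1.959964
        z = 1.959963984540054
        p, n = 0.2, 1000
        centre = (p + z**2 / (2 * n)) / (1 + z**2 / n)
        half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / (1 + z**2 / n)
        assert row.P_n_lo == pytest.approx(centre - half, abs=1e-9)
        assert row.P_n_hi == pytest.approx(centre + half, abs=1e-9)
        assert row.P_n_lo == pytest.approx(0.176, abs=5e-3)
        assert row.P_n_hi == pytest.approx(0.226, abs=5e-3)

    def test_zero_count_upper_bound_only(self):
        import pandas as pd

        from pilusim.growth import EnsembleSummary

        s = EnsembleSummary(
            n_pili=1000,
            count_by_length=pd.Series({2: 0}),
            correct_count_by_length=pd.Series(dtype=int),
            n_stalled=0,
            n_truncated=1000,
        )
        row = empirical_pmf(s).iloc[0]
        z = 1.959963984540054
        want_hi = z**2 / 1000 / (1 + z**2 / 1000)
        assert row.P_n == 0
        assert row.P_n_lo == 0
        assert row.P_n_hi == pytest.approx(want_hi, abs=1e-9)

    def test_full_count_estimate_one(self, equal_model):
        s = simulate_ensemble(equal_model, 50, seed=59, length_cap=100_000)
        pmf = empirical_pmf(s)
        assert (pmf.P_n <= 1).all()
        assert pmf.P_n.sum() == pytest.approx(1.0)  # all 50 absorbed


class TestEnsembleIO:
    def test_tsv_round_trip(self, tmp_path, hypothetical_model):
        records = simulate_records(hypothetical_model, 100, seed=61, length_cap=5000)
        path = tmp_path / "ens.tsv"
        write_ensemble_tsv(records, path)
        frame = read_ensemble_tsv(path)
        assert len(frame) == 100
        assert list(frame.sequence[:1])[0].startswith("G")
        assert set(frame.terminated) <= {"absorbed_H", "stalled", "truncated_at_cap"}

    def test_fasta_export(self, tmp_path, equal_model):
        records = simulate_records(equal_model, 5, seed=67)
        path = tmp_path / "ens.fa"
        write_ensemble_fasta(records, path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith(">pilus_0 correct=")
        assert set(lines[1]) <= set("GFEKAH")
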