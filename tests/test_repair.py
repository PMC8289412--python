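import dataclasses
import math

import numpy as np
import pytest

import alkrepair as ak
from alkrepair.lesions import ADDUCT_3MA, ADDUCT_7MG, ADDUCT_O6MG
from alkrepair.repair import apply_preset


def _map(plasmid, triples):
    pos, strand, cls = zip(*triples) if triples else ((), (), ())
    return ak.LesionMap(
        plasmid, np.array(pos, dtype=np.int64), np.array(strand), np.array(cls)
    )


def _event_set(plasmid, events):
    return ak.RepairEventSet(plasmid, list(events))


def _gap(strand, start, length, open=True):
    return ak.RepairEvent("MMR_gap", strand, start, length, length, open, 0)


def _nick(strand, pos, open=True):
    return ak.RepairEvent("BER_nick", strand, pos, 0, 1, open, 0)


class TestParams:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("p_engage_base", 1.5),
            ("p_nick_open", -0.1),
            ("p_mmr_gap_open", 2.0),
            ("stimulation_factor", 0.5),
            ("track_length", 0),
            ("track_length_model", "weird"),
            ("track_placement", "weird"),
            ("ber_long_patch_mean", 0),
        ],
    )
    def test_invalid_params(self, field, value):
        with pytest.raises(ValueError):
            ak.RepairParams(**{field: value})

    def test_presets(self):
        base = ak.RepairParams()
        assert apply_preset(base, "mlh1_depleted").p_engage_base == 0.0
        assert apply_preset(base, "aag_deficient_hss").p_nick_open == 0.0
        with pytest.raises(KeyError):
            apply_preset(base, "nonsense")


class TestClassifyTopology:
    def test_ccc(self):
        assert ak.classify_topology(0, 0) == "ccc"

    def test_oc(self):
        assert ak.classify_topology(0, 2) == "oc"

    def test_linear(self):
        assert ak.classify_topology(1, 0) == "linear"
        assert ak.classify_topology(2, 5) == "linear"


class TestDetectDsb:
    def test_gap_contains_opposite_nick(self, pbr322):
        es = _event_set(pbr322, [_gap(0, 1000, 500), _nick(1, 1200)])
        assert ak.detect_dsb(es, ak.RepairParams()).count == 1

    def test_nick_outside_gap(self, pbr322):
        es = _event_set(pbr322, [_gap(0, 1000, 500), _nick(1, 1600)])
        assert ak.detect_dsb(es, ak.RepairParams()).count == 0

    def test_same_strand_nick_no_dsb(self, pbr322):
        es = _event_set(pbr322, [_gap(0, 1000, 500), _nick(0, 1200)])
        assert ak.detect_dsb(es, ak.RepairParams()).count == 0

    def test_closed_gap_no_dsb(self, pbr322):
        es = _event_set(pbr322, [_gap(0, 1000, 500, open=False), _nick(1, 1200)])
        assert ak.detect_dsb(es, ak.RepairParams()).count == 0

    def test_closed_nick_no_dsb(self, pbr322):
        es = _event_set(pbr322, [_gap(0, 1000, 500), _nick(1, 1200, open=False)])
        assert ak.detect_dsb(es, ak.RepairParams()).count == 0

    def test_one_dsb_per_gap_regardless_of_nicks(self, pbr322):
        es = _event_set(
            pbr322, [_gap(0, 1000, 500), _nick(1, 1100), _nick(1, 1200), _nick(1, 1300)]
        )
        assert ak.detect_dsb(es, ak.RepairParams()).count == 1

    def test_wraparound_gap(self, pbr322):
        es = _event_set(pbr322, [_gap(0, 4200, 500), _nick(1, 50)])
        assert ak.detect_dsb(es, ak.RepairParams()).count == 1

    def test_half_open_interval(self, pbr322):
        # gap [1000, 1500): nick at 1500 excluded, at 1000 included
        es = _event_set(pbr322, [_gap(0, 1000, 500), _nick(1, 1500)])
        assert ak.detect_dsb(es, ak.RepairParams()).count == 0
        es = _event_set(pbr322, [_gap(0, 1000, 500), _nick(1, 1000)])
        assert ak.detect_dsb(es, ak.RepairParams()).count == 1

    def test_nick_nick_mode(self, pbr322):
        params = ak.RepairParams(nick_nick_dsb_threshold=10)
        es = _event_set(pbr322, [_nick(0, 100), _nick(1, 105)])
        assert ak.detect_dsb(es, params).count == 1
        es = _event_set(pbr322, [_nick(0, 100), _nick(1, 150)])
        assert ak.detect_dsb(es, params).count == 0
        # disabled by default
        es = _event_set(pbr322, [_nick(0, 100), _nick(1, 105)])
        assert ak.detect_dsb(es, ak.RepairParams()).count == 0

    def test_oracle_equivalence_random_molecules(self, mnu, dsb_oracle):
        """detect_dsb and the simulate_repair DSB count both equal the
        brute-force per-nucleotide oracle on random molecules."""
        params = ak.RepairParams(
            p_nick_open=0.3, p_engage_base=0.5, p_mmr_gap_open=0.7, track_length=300
        )
        rng = np.random.default_rng(101)
        for _ in range(200):
            L = int(rng.integers(100, 2000))
            pl = ak.PlasmidSpec("r", L)
            m = ak.place_lesions(pl, 0.01, mnu, rng=rng)
            es, outcome = ak.simulate_repair(m, params, rng=rng)
            expected = dsb_oracle(es, params)
            assert ak.detect_dsb(es, params).count == expected
            assert outcome.dsb_count == expected


class TestSimulateRepair:
    def test_no_lesions_ccc(self, pbr322):
        m = _map(pbr322, [])
        es, out = ak.simulate_repair(m, ak.RepairParams(), seed=1)
        assert out.topology == "ccc"
        assert out.synthesized_nt == 0
        assert out.dsb_count == 0

    def test_no_dsb_when_both_pathways_closed(self, pel97, mnu):
        params = ak.RepairParams(p_nick_open=0.0, p_mmr_gap_open=0.0)
        rng = np.random.default_rng(2)
        for _ in range(50):
            m = ak.place_lesions(pel97, 0.004, mnu, rng=rng)
            _, out = ak.simulate_repair(m, params, rng=rng)
            assert out.dsb_count == 0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"p_nick_open": 0.0},
            {"p_engage_base": 0.0},
            {"p_mmr_gap_open": 0.0},
        ],
    )
    def test_no_dsb_when_either_pathway_disabled(self, pel97, mnu, kwargs):
        base = dict(p_nick_open=0.3, p_engage_base=0.5, p_mmr_gap_open=0.8)
        base.update(kwargs)
        params = ak.RepairParams(**base)
        rng = np.random.default_rng(3)
        for _ in range(30):
            m = ak.place_lesions(pel97, 0.004, mnu, rng=rng)
            _, out = ak.simulate_repair(m, params, rng=rng)
            assert out.dsb_count == 0

    def test_seed_reproducible(self, pbr322, mnu):
        m = ak.place_lesions(pbr322, 0.004, mnu, seed=9)
        es1, out1 = ak.simulate_repair(m, ak.RepairParams(), seed=4)
        es2, out2 = ak.simulate_repair(m, ak.RepairParams(), seed=4)
        assert out1 == out2
        assert es1.events == es2.events

    def test_event_invariants(self, pbr322, mnu):
        m = ak.place_lesions(pbr322, 0.01, mnu, seed=10)
        es, out = ak.simulate_repair(m, ak.RepairParams(), seed=11)
        L = pbr322.length_bp
        for e in es.events:
            if e.kind == "MMR_gap":
                origin_pos = m.positions[e.origin_lesion]
                assert (origin_pos - e.start) % L < e.length  # gap covers its O6mG
                assert e.synthesis_nt == e.length
            else:
                assert e.synthesis_nt == 1 or 2 <= e.synthesis_nt <= 8
                assert e.length == (0 if e.open else e.synthesis_nt)
        assert out.o6mg_attributed_nt == sum(
            e.synthesis_nt for e in es.events if e.kind == "MMR_gap"
        )
        assert out.synthesized_nt == sum(e.synthesis_nt for e in es.events)

    def test_centered_track_placement(self, pbr322):
        m = _map(pbr322, [(2000, 0, ADDUCT_O6MG)])
        params = ak.RepairParams(
            p_engage_base=1.0, p_mmr_gap_open=1.0, track_placement="centered"
        )
        es, _ = ak.simulate_repair(m, params, seed=1)
        gaps = [e for e in es.events if e.kind == "MMR_gap"]
        assert len(gaps) == 1
        assert gaps[0].start == 2000 - 250

    def test_stimulation_raises_engagement(self, pbr322):
        """With apply_stimulation, an open nick in the window multiplies
        engagement by stimulation_factor."""
        m = _map(pbr322, [(2000, 0, ADDUCT_O6MG), (2100, 1, ADDUCT_3MA)])
        base = dict(p_engage_base=0.2, stimulation_factor=2.9, p_nick_open=1.0)
        n = 4000
        rng = np.random.default_rng(21)
        engaged_stim = sum(
            any(e.kind == "MMR_gap" for e in ak.simulate_repair(
                m, ak.RepairParams(apply_stimulation=True, **base), rng=rng
            )[0].events)
            for _ in range(n)
        )
        rng = np.random.default_rng(21)
        engaged_base = sum(
            any(e.kind == "MMR_gap" for e in ak.simulate_repair(
                m, ak.RepairParams(apply_stimulation=False, **base), rng=rng
            )[0].events)
            for _ in range(n)
        )
        f_stim, f_base = engaged_stim / n, engaged_base / n
        assert f_base == pytest.approx(0.2, abs=3 * math.sqrt(0.2 * 0.8 / n))
        assert f_stim == pytest.approx(0.58, abs=3 * math.sqrt(0.58 * 0.42 / n))

    def test_stimulation_ignored_when_nick_far(self, pbr322):
        m = _map(pbr322, [(2000, 0, ADDUCT_O6MG), (100, 1, ADDUCT_3MA)])
        params = ak.RepairParams(
            apply_stimulation=True, p_engage_base=0.2, p_nick_open=1.0
        )
        n = 3000
        rng = np.random.default_rng(22)
        engaged = sum(
            any(e.kind == "MMR_gap" for e in ak.simulate_repair(m, params, rng=rng)[0].events)
            for _ in range(n)
        )
        assert engaged / n == pytest.approx(0.2, abs=3 * math.sqrt(0.2 * 0.8 / n))


class TestUds:
    def test_270nt_is_3_percent(self, pbr322):
        out = ak.PlasmidOutcome("ccc", 0, 0, 0, 0, 270, 270)
        assert ak.uds_signal([out], pbr322) == pytest.approx(3.09, abs=0.01)

    def test_zero(self, pbr322):
        out = ak.PlasmidOutcome("ccc", 0, 0, 0, 0, 0, 0)
        assert ak.uds_signal([out], pbr322) == 0.0

    def test_empty_batch(self, pbr322):
        with pytest.raises(ValueError):
            ak.uds_signal([], pbr322)

    def test_closed_form_matches_simulation(self, pbr322, mnu):
        """UDS percent = 100 (E[nal] x patch_mean + E[O6] x p_eng x track)/(2L)."""
        params = ak.RepairParams()
        n = 4000
        summary = ak.batch_simulate(pbr322, 1 / 500, mnu, params, n, seed=33)
        e = ak.expected_counts(pbr322, 1 / 500, mnu)
        patch_mean = 1 * 0.6 + 5.0 * 0.4  # short/long patch mix
        expected_synth = (
            e.n_alkyl * patch_mean
            + e.n_o6mg * params.p_engage_base * params.track_length
        )
        expected_pct = 100 * expected_synth / (2 * 4363)
        assert summary.uds_percent_replication == pytest.approx(expected_pct, rel=0.05)

    def test_labeled_mode_drops_7mg_short_patches(self, pbr322):
        m = _map(pbr322, [(100, 0, ADDUCT_7MG), (200, 0, ADDUCT_3MA)])
        params = ak.RepairParams(ber_long_patch_fraction=0.0, p_nick_open=0.0)
        es, out = ak.simulate_repair(m, params, seed=5)
        from alkrepair.repair import labeled_synthesis_nt

        assert out.synthesized_nt == 2  # two 1-nt patches
        assert labeled_synthesis_nt(es, m) == 1  # 7mG short patch invisible


class TestFragmentSpecificActivity:
    def test_track_inside_one_fragment(self, pbr322):
        es = _event_set(pbr322, [_gap(0, 1000, 500)])
        acts = ak.fragment_specific_activity([es], [500, 2500])
        by_start = {a.start: a for a in acts}
        assert by_start[500].signal_nt == pytest.approx(500)
        assert by_start[2500].signal_nt == 0

    def test_duplicate_cuts_rejected(self, pbr322):
        es = _event_set(pbr322, [_gap(0, 1000, 500)])
        with pytest.raises(ValueError, match="duplicate"):
            ak.fragment_specific_activity([es], [500, 500])

    def test_need_two_cuts(self, pbr322):
        es = _event_set(pbr322, [])
        with pytest.raises(ValueError):
            ak.fragment_specific_activity([es], [500])

    def test_split_track_pro_rata(self, pbr322):
        # track [300, 800) over a cut at 500: 200 nt left, 300 nt right
        es = _event_set(pbr322, [_gap(0, 300, 500)])
        acts = ak.fragment_specific_activity([es], [500, 2500])
        by_start = {a.start: a for a in acts}
        assert by_start[2500].signal_nt == pytest.approx(200)  # wraps [2500,500)
        assert by_start[500].signal_nt == pytest.approx(300)

    def test_uniform_background_equal_specific_activity(self):
        """Randomly placed events give equal specific activities (symmetry)."""
        pl = ak.PlasmidSpec("pAS200.2", 2114)
        rng = np.random.default_rng(41)
        sets = []
        for _ in range(400):
            events = [
                _gap(int(rng.integers(0, 2)), int(rng.integers(0, 2114)), 100)
                for _ in range(3)
            ]
            sets.append(_event_set(pl, events))
        acts = ak.fragment_specific_activity(sets, [0, 589])
        sa = [a.specific_activity for a in acts]
        # 1200 events of 100 nt spread over 2114 nt: ~57 nt/nt +- few %
        assert sa[0] == pytest.approx(sa[1], rel=0.10)

    @pytest.mark.parametrize("site", [200, 294, 400])
    def test_spillover_bracket(self, site):
        """500 nt track centered on an O6mG inside the 589 bp S fragment:
        spill-over into L stays within the observed 0-15% bracket for
        central site positions."""
        pl = ak.PlasmidSpec("pAS200.2", 2114)
        es = _event_set(pl, [_gap(0, (site - 250) % 2114, 500)])
        acts = ak.fragment_specific_activity([es], [0, 589])
        by_start = {a.start: a for a in acts}
        spill = by_start[589].signal_nt / 500.0
        assert 0.0 <= spill <= 0.15


class TestAnalyticAndCalibration:
    def test_zero_nick_zero_fraction(self, pel97, mnu):
        params = ak.RepairParams(p_nick_open=0.0)
        assert ak.analytic_dsb_fraction(pel97, 0.004, mnu, params) == 0.0

    def test_small_density_quadratic(self, pel97, mnu):
        params = ak.RepairParams(p_nick_open=0.01)
        f1 = ak.analytic_dsb_fraction(pel97, 0.0002, mnu, params)
        f2 = ak.analytic_dsb_fraction(pel97, 0.0004, mnu, params)
        assert f2 / f1 == pytest.approx(4.0, rel=0.01)

    def test_monotonic_in_each_parameter(self, pel97, mnu):
        base = ak.RepairParams(p_nick_open=0.01)
        grid = np.linspace(0.0005, 0.004, 5)
        vals = [ak.analytic_dsb_fraction(pel97, d, mnu, base) for d in grid]
        assert all(a <= b for a, b in zip(vals, vals[1:]))
        for field, values in [
            ("track_length", [100, 300, 500, 800]),
            ("p_nick_open", [0.001, 0.01, 0.05]),
            ("p_engage_base", [0.1, 0.3, 0.6]),
            ("p_mmr_gap_open", [0.2, 0.5, 0.9]),
        ]:
            vals = [
                ak.analytic_dsb_fraction(
                    pel97, 0.002, mnu, dataclasses.replace(base, **{field: v})
                )
                for v in values
            ]
            assert all(a <= b for a, b in zip(vals, vals[1:])), field

    def test_calibration_round_trip(self, pel97, mnu):
        params = ak.RepairParams()
        p = ak.calibrate_nick_availability(0.06, pel97, 1 / 250, mnu, params)
        back = ak.analytic_dsb_fraction(
            pel97, 1 / 250, mnu, dataclasses.replace(params, p_nick_open=p)
        )
        assert back == pytest.approx(0.06, rel=1e-4)
        assert 0.005 < p < 0.05

    def test_calibrate_zero_target(self, pel97, mnu):
        assert ak.calibrate_nick_availability(0.0, pel97, 1 / 250, mnu, ak.RepairParams()) == 0.0

    def test_calibrate_unreachable(self, pel97, mnu):
        # at low density even p_nick_open = 1 cannot reach a 50% fraction
        with pytest.raises(ValueError, match="attainable maximum"):
            ak.calibrate_nick_availability(0.5, pel97, 0.0005, mnu, ak.RepairParams())

    def test_analytic_matches_simulation_spot(self, pel97, mnu, calibrated_params):
        n = 20_000
        s = ak.batch_simulate(pel97, 1 / 250, mnu, calibrated_params, n, seed=55)
        analytic = ak.analytic_dsb_fraction(pel97, 1 / 250, mnu, calibrated_params)
        # 6% is at the edge of the rare regime; allow the P(>=1) vs E[count]
        # gap (~ lambda/2 * lambda) on top of 3 MC standard errors
        bias = analytic**2 / 2
        assert abs(s.frac_linear - analytic) < 3 * s.se_linear + bias


class TestBatchSimulate:
    def test_n_validation(self, pbr322, mnu):
        with pytest.raises(ValueError):
            ak.batch_simulate(pbr322, 0.002, mnu, ak.RepairParams(), 0, seed=1)

    def test_single_molecule_fractions(self, pbr322, mnu):
        s = ak.batch_simulate(pbr322, 0.002, mnu, ak.RepairParams(), 1, seed=1)
        assert {s.frac_ccc, s.frac_oc, s.frac_linear} <= {0.0, 1.0}

    def test_fractions_sum_to_one(self, pbr322, mnu):
        s = ak.batch_simulate(pbr322, 0.002, mnu, ak.RepairParams(), 500, seed=2)
        assert s.frac_ccc + s.frac_oc + s.frac_linear == pytest.approx(1.0, abs=1e-12)
        assert s.n_ccc + s.n_oc + s.n_linear == 500

    def test_standard_errors(self, pbr322, mnu):
        s = ak.batch_simulate(pbr322, 0.002, mnu, ak.RepairParams(), 400, seed=3)
        assert s.se_oc == pytest.approx(math.sqrt(s.frac_oc * (1 - s.frac_oc) / 400))

    def test_bit_reproducible(self, pbr322, mnu):
        a = ak.batch_simulate(pbr322, 0.002, mnu, ak.RepairParams(), 300, seed=7)
        b = ak.batch_simulate(pbr322, 0.002, mnu, ak.RepairParams(), 300, seed=7)
        assert a == b

    def test_matches_per_molecule_api(self, pbr322, mnu):
        """batch_simulate is statistically the same process as
        place_lesions + simulate_repair with a shared generator."""
        params = ak.RepairParams()
        rng = np.random.default_rng(77)
        outcomes = []
        for _ in range(300):
            m = ak.place_lesions(pbr322, 0.002, mnu, rng=rng)
            _, out = ak.simulate_repair(m, params, rng=rng)
            outcomes.append(out)
        s = ak.batch_simulate(pbr322, 0.002, mnu, params, 300, seed=77)
        frac_linear_manual = sum(o.topology == "linear" for o in outcomes) / 300
        assert s.frac_linear == frac_linear_manual
        assert s.mean_synthesized_nt == pytest.approx(
            float(np.mean([o.synthesized_nt for o in outcomes]))
        )
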