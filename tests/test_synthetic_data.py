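"""Synthetic study generator: templates, noise, bundle round-trips."""

import numpy as np
import pytest

from glucotrace.kh_turnover import KhParams, closed_form_square
from glucotrace.square_pulse import build_square_pulse
from glucotrace.synthetic_data import (NoiseModel, generate_bundle,
                                       make_cohort, make_dna_dataset,
                                       make_plasma_dataset, make_protocol,
                                       read_study_bundle, sampling_times,
                                       write_study_bundle)
from glucotrace.tracer_simulator import Subject, build_params


class TestMakeCohort:
    def test_deterministic_per_seed(self):
        assert make_cohort(5, seed=3) == make_cohort(5, seed=3)
        assert make_cohort(5, seed=3) != make_cohort(5, seed=4)

    def test_degenerate_range(self):
        cohort = make_cohort(1, seed=0, ranges={"weight": (70.0, 70.0)})
        assert cohort[0].weight == 70.0

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            make_cohort(2, seed=0, ranges={"weight": (80.0, 70.0)})


class TestMakeProtocol:
    SUBJ = Subject(weight=70.0)

    def test_sevenday_dosing_arithmetic(self):
        proto = make_protocol("sevenday", self.SUBJ, seed=0)
        seg = proto.infusions[0]
        assert seg.rate == pytest.approx(30.0 / 24.0)
        assert seg.stop == pytest.approx(168.0)
        assert seg.prime == pytest.approx(1.98)
        labeling_meals = [m for m in proto.meals if m.time < 168.0]
        assert len(labeling_meals) == 21
        assert all(m.cho == pytest.approx(15.0) for m in labeling_meals)

    def test_tigas_d_dosing_arithmetic(self):
        proto = make_protocol("tigas_D", self.SUBJ, seed=0)
        seg = proto.infusions[0]
        assert seg.prime == pytest.approx(0.4165)
        assert seg.rate == pytest.approx(0.42)
        assert seg.stop == pytest.approx(14.5)
        assert proto.meals == ()

    def test_oneday_total_dose_about_one_gram_per_kg(self):
        proto = make_protocol("oneday", self.SUBJ, seed=1)
        seg = proto.infusions[0]
        total = seg.prime + seg.rate * (seg.stop - seg.start)
        assert total == pytest.approx(70.0, rel=1e-9)

    def test_unknown_template_rejected(self):
        with pytest.raises(ValueError):
            make_protocol("twoday", self.SUBJ)


class TestMakePlasmaDataset:
    def test_zero_noise_lies_on_curve(self):
        subj = Subject(weight=70.0)
        proto = make_protocol("tigas_C", subj, seed=0)
        params = build_params(subj)
        times = sampling_times("tigas_C", proto)
        clean = make_plasma_dataset(proto, params, times,
                                    NoiseModel(plasma_cv=0.0), seed=1)
        noisy = make_plasma_dataset(proto, params, times,
                                    NoiseModel(plasma_cv=0.05), seed=1)
        from glucotrace.tracer_simulator import simulate
        grid = np.arange(0.0, proto.horizon + 0.025, 0.05)
        ref = simulate(proto, params, grid).enrichment(times)
        assert clean.e == pytest.approx(ref, rel=1e-12)
        assert not np.allclose(noisy.e, ref)

    def test_sevenday_samples_are_overnight_fasted(self):
        subj = Subject(weight=70.0)
        proto = make_protocol("sevenday", subj, seed=0)
        times = sampling_times("sevenday", proto)
        days = np.floor((times - 1e-9) / 24.0)
        assert len(np.unique(days)) == len(times)  # one per day
        meal_times = np.array([m.time for m in proto.meals])
        for t in times:
            gap = t - meal_times[meal_times < t].max()
            assert gap >= 10.0


class TestMakeDnaDataset:
    def test_zero_noise_matches_closed_form(self):
        pulse = build_square_pulse(25.0, 0.0, 24.0)
        u = pulse.render(np.linspace(0.0, 600.0, 5))
        kh = KhParams(p=0.01, d_star=0.05)
        days = np.array([1.0, 5.0, 10.0, 21.0])
        curve = make_dna_dataset(u, kh, days, NoiseModel(dna_cv=0.0), seed=2)
        assert curve.l_star == pytest.approx(
            closed_form_square(pulse, kh, days), abs=1e-12)

    def test_zero_proliferation_stays_zero(self):
        u = build_square_pulse(25.0, 0.0, 24.0).render(
            np.linspace(0.0, 600.0, 5))
        curve = make_dna_dataset(u, KhParams(p=0.0, d_star=0.1),
                                 np.array([1.0, 5.0]), NoiseModel(), seed=2)
        assert np.all(curve.l_star == 0.0)

    def test_deterministic_per_seed(self):
        u = build_square_pulse(25.0, 0.0, 24.0).render(
            np.linspace(0.0, 600.0, 5))
        kh = KhParams(p=0.01, d_star=0.05)
        days = np.array([1.0, 5.0, 10.0])
        a = make_dna_dataset(u, kh, days, NoiseModel(), seed=7)
        b = make_dna_dataset(u, kh, days, NoiseModel(), seed=7)
        assert np.array_equal(a.l_star, b.l_star)


@pytest.fixture(scope="module")
def bundle():
    return generate_bundle("tigas_D", 2, seed=5, horizon_days=1.0,
                           dna_days=np.array([0.2, 0.4, 0.6, 0.8]))


class TestBundleRoundTrip:
    def test_write_then_read_preserves_data(self, bundle, tmp_path_factory):
        directory = tmp_path_factory.mktemp("bundle")
        write_study_bundle(directory, bundle)
        back = read_study_bundle(directory)
        assert set(back.subjects) == set(bundle.subjects)
        for sid in bundle.subjects:
            assert back.subjects[sid].weight == pytest.approx(
                bundle.subjects[sid].weight)
            assert back.plasma[sid].e == pytest.approx(
                bundle.plasma[sid].e, abs=1e-12)
        for key in bundle.dna:
            assert back.dna[key].l_star == pytest.approx(
                bundle.dna[key].l_star, abs=1e-12)
            assert back.truth[key].p == pytest.approx(bundle.truth[key].p)

    def test_bundle_valid_without_dna_for_a_subject(self, bundle,
                                                    tmp_path_factory):
        directory = tmp_path_factory.mktemp("partial")
        partial = generate_bundle("tigas_D", 2, seed=5, horizon_days=1.0,
                                  dna_days=np.array([0.2, 0.4, 0.6]))
        sid = sorted(partial.subjects)[0]
        del partial.dna[(sid, "cd4")]
        del partial.dna[(sid, "cd8")]
        write_study_bundle(directory, partial)
        back = read_study_bundle(directory)
        assert (sid, "cd4") not in back.dna
        assert len(back.subjects) == 2

    def test_reproducible_generation(self):
        a = generate_bundle("tigas_A", 1, seed=9, horizon_days=0.4,
                            dna_days=np.array([0.1, 0.2, 0.3]))
        b = generate_bundle("tigas_A", 1, seed=9, horizon_days=0.4,
                            dna_days=np.array([0.1, 0.2, 0.3]))
        sid = sorted(a.subjects)[0]
        assert np.array_equal(a.plasma[sid].e, b.plasma[sid].e)
        assert np.array_equal(a.dna[(sid, "cd4")].l_star,
                              b.dna[(sid, "cd4")].l_star)
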