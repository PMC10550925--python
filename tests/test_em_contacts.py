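"""EM contact detection: constructed geometries, brute-force oracle, F-test."""

import numpy as np
import pytest
from scipy import stats

from phagoquant import synthetic
from phagoquant.em_contacts import (
    EMProfile,
    detect_contacts,
    contact_stats,
    filter_profiles,
    pooled_lengths,
    variance_f_test,
)
from oracle_utils import circle_contact_runs


def circle_boundary(radius, n=256):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return radius * np.column_stack([np.cos(th), np.sin(th)])


def arc_segment(radius, a0, arc_len, step=1.0):
    n = max(int(arc_len / step), 2)
    ang = np.linspace(a0, a0 + arc_len / radius, n)
    return radius * np.column_stack([np.cos(ang), np.sin(ang)])


class TestDetectContacts:
    def test_no_er_segments(self):
        p = EMProfile(circle_boundary(1000), [], 2000)
        assert detect_contacts(p).count == 0

    def test_constant_gap_arc(self):
        # 100 nm arc held at 25 nm from a 1 um-radius boundary
        p = EMProfile(circle_boundary(1000), [arc_segment(1025, 0.0, 100.0)], 2000)
        cs = detect_contacts(p, gap_max_nm=30, min_run_nm=10)
        assert cs.count == 1
        assert cs.contacts[0].arc_length_nm == pytest.approx(100.0, abs=2.0)
        assert cs.contacts[0].min_gap_nm == pytest.approx(25.0, abs=0.5)

    def test_two_dips_give_two_contacts(self):
        # radial profile: 25 nm for 80 nm, out to 80 nm for 100 nm, back to 25
        R = 1000.0
        pieces = []
        s = np.linspace(0, 1, 80)
        pieces.append(np.column_stack([s * 80.0, np.full(80, R + 25.0)]))
        s2 = np.linspace(0, 1, 100)
        bump = R + 25.0 + 55.0 * np.sin(np.pi * s2)  # excursion to 80 nm
        pieces.append(np.column_stack([80.0 + s2 * 100.0, bump]))
        pieces.append(np.column_stack([180.0 + s * 80.0, np.full(80, R + 25.0)]))
        # convert (arc position, radius) to xy around angle 0
        poly = []
        for piece in pieces:
            ang = piece[:, 0] / R
            poly.append(piece[:, 1][:, None] * np.column_stack([np.cos(ang), np.sin(ang)]))
        seg = np.vstack(poly)
        p = EMProfile(circle_boundary(R), [seg], 2 * R)
        cs = detect_contacts(p, gap_max_nm=30, min_run_nm=20)
        assert cs.count == 2

    def test_degenerate_polyline_skipped_with_warning(self):
        p = EMProfile(circle_boundary(1000), [np.array([[0.0, 1010.0]])], 2000)
        with pytest.warns(UserWarning):
            assert detect_contacts(p).count == 0

    def test_matches_circle_oracle_on_random_profiles(self):
        cfg = synthetic.preset("shSec22b", 42)
        profiles, _ = synthetic.gen_em_profiles(cfg, 40)
        for p in profiles:
            cs = detect_contacts(p, gap_max_nm=30, min_run_nm=20)
            radius = p.phagosome_diameter_nm / 2
            oracle = []
            for seg in p.er_segments:
                oracle += circle_contact_runs(seg, (0.0, 0.0), radius, 30.0, 20.0)
            assert cs.count == len(oracle)
            np.testing.assert_allclose(
                np.sort(cs.lengths), np.sort(oracle), atol=2.0
            )

    def test_total_length_monotone_in_gap(self):
        cfg = synthetic.preset("shCTR", 3)
        profiles, _ = synthetic.gen_em_profiles(cfg, 20)
        totals = []
        for gap in (20.0, 30.0, 45.0):
            totals.append(sum(detect_contacts(p, gap_max_nm=gap).lengths.sum()
                              for p in profiles))
        assert totals[0] <= totals[1] <= totals[2]


class TestFilterAndStats:
    def test_strict_diameter_filter(self):
        profiles = [EMProfile(circle_boundary(d * 500), [], d * 1000)
                    for d in (0.8, 1.0, 1.2)]
        kept = filter_profiles(profiles, min_diameter_um=1.0)
        assert [p.phagosome_diameter_nm for p in kept] == [1200.0]
        assert filter_profiles([]) == []

    def test_generated_profiles_all_pass_filter(self):
        profiles, _ = synthetic.gen_em_profiles(synthetic.preset("shCTR", 1), 100)
        assert len(filter_profiles(profiles)) == 100

    def test_hand_computed_stats(self):
        from phagoquant.em_contacts import Contact, ContactSet

        lengths = [90, 100, 80, 95, 93, 85, 100, 90, 96]
        sets = [
            ContactSet(0, [Contact(0, l, 10.0) for l in lengths[:4]]),
            ContactSet(1, [Contact(0, l, 10.0) for l in lengths[4:]]),
        ]
        table = contact_stats(sets)
        get = lambda m: table.loc[table.metric == m, "value"].iloc[0]
        assert get("mean_contacts_per_phagosome") == pytest.approx(4.5)
        assert get("median_contact_length") == pytest.approx(93.0)

    def test_empty_set_flags_undefined_lengths(self):
        from phagoquant.em_contacts import ContactSet

        table = contact_stats([ContactSet(0, [])])
        assert (table.metric == "length_stats_undefined").any()
        mean = table.loc[table.metric == "mean_contacts_per_phagosome", "value"].iloc[0]
        assert mean == 0.0


class TestVarianceFTest:
    def test_identical_lists(self):
        x = [80.0, 90.0, 100.0, 95.0]
        F, p = variance_f_test(x, x)
        assert F == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_against_f_distribution_oracle(self, rng):
        a = rng.normal(100, 2.0, 30)
        b = rng.normal(100, 1.0, 30)
        F, p = variance_f_test(a, b)
        expected_F = a.var(ddof=1) / b.var(ddof=1)
        assert F == pytest.approx(expected_F)
        assert p == pytest.approx(min(1.0, 2 * stats.f.sf(expected_F, 29, 29)))

    def test_insufficient_data_raises(self):
        with pytest.raises(ValueError):
            variance_f_test([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            variance_f_test([1.0, 1.0], [1.0, 2.0])

    def test_knockdown_length_variance_is_detected(self):
        # the knockdown's 3% very-large contacts inflate length variance
        ctr, _ = synthetic.gen_em_profiles(synthetic.preset("shCTR", 11), 60)
        kd, _ = synthetic.gen_em_profiles(synthetic.preset("shSec22b", 12), 60)
        la = pooled_lengths([detect_contacts(p) for p in ctr])
        lb = pooled_lengths([detect_contacts(p) for p in kd])
        F, p = variance_f_test(la, lb)
        assert F > 1.0
        assert p < 0.05


class TestRecovery:
    def test_contact_frequency_and_length_recovery(self):
        from phagoquant import pipelines

        res_a = pipelines.run_em(synthetic.preset("shCTR", 21), 120)
        res_b = pipelines.run_em(synthetic.preset("shSec22b", 22), 120)
        assert res_a["mean_contacts"] == pytest.approx(4.5, rel=0.05)
        assert res_b["mean_contacts"] == pytest.approx(3.0, rel=0.05)
        # the cohort median carries ~2.5% sampling SE at this n
        assert res_a["median_length_nm"] == pytest.approx(93.0, rel=0.08)
        assert res_b["median_length_nm"] == pytest.approx(81.0, rel=0.08)
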