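"""Ground-truth consistency of the synthetic shell generator."""

import numpy as np
import pytest

import spiroform as sf
from spiroform.errors import ValidationError
from spiroform.synthetic import (
    HelicospiralParams,
    PhaseSchedule,
    default_growth_rate,
    generate_rib_positions,
)


def finite_difference_frenet(points, s):
    """Independent dense central-difference Frenet oracle on a polyline."""
    d1 = np.gradient(points, s, axis=0)
    d2 = np.gradient(d1, s, axis=0)
    d3 = np.gradient(d2, s, axis=0)
    cross = np.cross(d1, d2)
    n1 = np.linalg.norm(d1, axis=1)
    nc = np.linalg.norm(cross, axis=1)
    kappa = nc / n1**3
    tau = np.einsum("ij,ij->i", cross, d3) / np.maximum(nc**2, 1e-300)
    return kappa, tau


class TestHelicospiral:
    def test_planar_circle_truth(self):
        _, truth = sf.generate_helicospiral(
            HelicospiralParams(r0=2.0, alpha=0.0, c=0.0, theta_max=2 * np.pi, ds=0.01)
        )
        s = np.linspace(0.5, 10.0, 7)
        assert np.allclose(truth.kappa_true(s), 0.5)
        assert np.allclose(truth.tau_true(s), 0.0)

    def test_circular_helix_closed_form(self):
        # kappa = a/(a^2+c^2) = 0.4, tau = c/(a^2+c^2) = +0.2 for the dextral helix
        _, truth = sf.generate_helicospiral(
            HelicospiralParams(r0=2.0, alpha=0.0, c=1.0, theta_max=2 * np.pi, ds=0.01)
        )
        s = np.linspace(0.5, 10.0, 7)
        assert np.allclose(truth.kappa_true(s), 0.4)
        assert np.allclose(truth.tau_true(s), 0.2)

    def test_sinistral_helix_negates_torsion(self):
        _, truth = sf.generate_helicospiral(
            HelicospiralParams(r0=2.0, alpha=0.0, c=1.0, theta_max=2 * np.pi, ds=0.01,
                               handedness="sinistral")
        )
        assert np.allclose(truth.tau_true(np.array([3.0])), -0.2)

    def test_generic_truth_matches_finite_difference_oracle(self):
        axis, truth = sf.generate_helicospiral(
            HelicospiralParams(r0=1.0, alpha=0.1, c=0.3, theta_max=12.0, ds=0.002)
        )
        kap_fd, tau_fd = finite_difference_frenet(axis.points, axis.s)
        interior = slice(50, -50)
        kt = truth.kappa_true(axis.s[interior])
        tt = truth.tau_true(axis.s[interior])
        assert np.max(np.abs(kap_fd[interior] - kt) / kt) < 1e-3
        assert np.max(np.abs(tau_fd[interior] - tt) / np.abs(tt)) < 1e-3

    def test_arc_length_resampling_step_uniform(self):
        axis, _ = sf.generate_helicospiral()
        steps = np.diff(axis.s)
        ds = HelicospiralParams().ds
        assert np.max(np.abs(steps - ds)) < 0.1 * ds

    def test_mirroring_negates_truth_torsion(self):
        _, truth = sf.generate_helicospiral()
        mirrored = truth.mirrored((0.0, 1.0, 0.0))
        s = np.linspace(1.0, 10.0, 5)
        assert np.allclose(mirrored.tau_true(s), -np.asarray(truth.tau_true(s)))
        assert np.allclose(mirrored.kappa_true(s), truth.kappa_true(s))
        assert mirrored.axis.handedness == "sinistral"

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            HelicospiralParams(r0=-1.0)
        with pytest.raises(ValidationError):
            HelicospiralParams(ds=0.0)
        with pytest.raises(ValidationError):
            HelicospiralParams(r0=np.nan)
        with pytest.raises(ValidationError):
            sf.generate_helicospiral(HelicospiralParams(r0=1.0, theta_max=1e-4, ds=1.0))


class TestPhaseSchedule:
    def test_no_reversal_keeps_geometry(self):
        axis, truth = sf.generate_helicospiral()
        sch = PhaseSchedule(tuba_rotation_reversal=False)
        axis2, _ = sf.apply_phase_schedule(axis, sch, truth)
        n = len(axis2.s)
        assert np.array_equal(axis2.points, axis.points[:n])
        assert axis2.phase_bounds == (13.0, 14.0)

    def test_reversal_flips_tuba_torsion_sign(self):
        axis, truth = sf.generate_helicospiral()
        _, truth2 = sf.apply_phase_schedule(axis, PhaseSchedule(), truth)
        assert float(truth2.tau_true(10.0)) > 0  # dextral spire
        assert float(truth2.tau_true(16.0)) < 0  # reversed tuba
        # curvature is untouched by the reversal
        s = np.linspace(1.0, 16.5, 9)
        assert np.allclose(truth2.kappa_true(s), truth.kappa_true(s))

    def test_reversal_preserves_c1_continuity(self):
        axis, truth = sf.generate_helicospiral()
        axis2, _ = sf.apply_phase_schedule(axis, PhaseSchedule(), truth)
        tangents = np.diff(axis2.points, axis=0)
        tangents /= np.linalg.norm(tangents, axis=1)[:, None]
        # no tangent kink anywhere (max turning per ~ds step stays small)
        turn = np.degrees(np.arccos(np.clip(np.einsum("ij,ij->i", tangents[:-1], tangents[1:]), -1, 1)))
        assert turn.max() < 5.0

    def test_phase_bounds_partition_without_gaps(self):
        axis, truth = sf.generate_helicospiral()
        axis2, _ = sf.apply_phase_schedule(axis, PhaseSchedule(13.0, 14.0, 17.0), truth)
        s = np.linspace(0.0, axis2.total_length, 1000)
        labels = np.array([axis2.phase_of(v) for v in s])
        assert set(labels) == {"spire", "constriction", "tuba"}
        # labels are monotone: one contiguous block per phase
        changes = np.sum(labels[:-1] != labels[1:])
        assert changes == 2

    def test_schedule_beyond_axis_rejected(self):
        axis, truth = sf.generate_helicospiral()
        with pytest.raises(ValidationError):
            sf.apply_phase_schedule(axis, PhaseSchedule(tuba_end_s=100.0,
                                                        spire_end_s=13.0,
                                                        constriction_end_s=14.0), truth)

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValidationError):
            PhaseSchedule(spire_end_s=14.0, constriction_end_s=13.0, tuba_end_s=17.0)
        with pytest.raises(ValidationError):
            PhaseSchedule(constriction_perimeter_dip=1.5)


class TestApertureSequence:
    def test_planted_perimeters_follow_spire_regression_line(self, study):
        outs, _ = sf.generate_aperture_sequence(
            study.axis, study.schedule, n_outlines=3, seed=0,
            s_positions=np.array([5.0, 10.0, 12.0]), noise_frac=0.0, truth=study.truth,
        )
        assert sf.perimeter(outs[0]) == pytest.approx(0.166 * 5 + 0.457, abs=1e-9)
        assert sf.perimeter(outs[1]) == pytest.approx(0.166 * 10 + 0.457, abs=1e-9)

    def test_perimeter_program_dips_then_regrows(self, study):
        sch = study.schedule
        p_spire_end = sch.perimeter_at(sch.spire_end_s - 1e-9)
        p_dip = sch.perimeter_at(sch.constriction_end_s)
        p_tuba = sch.perimeter_at(sch.tuba_end_s)
        assert p_dip == pytest.approx((1 - sch.constriction_perimeter_dip) * p_spire_end, rel=1e-6)
        assert p_tuba > p_dip

    def test_constant_morph_gives_similarity_transforms(self, study):
        outs, _ = sf.generate_aperture_sequence(
            study.axis, study.schedule, n_outlines=4, seed=0,
            s_positions=np.array([5.0, 7.0, 9.0, 11.0]), noise_frac=0.0,
            shape_morph=0.0, truth=study.truth,
        )
        ref = sf.normalize_harmonics(sf.efa_decompose(outs[0], K=5)).coeffs
        for o in outs[1:]:
            got = sf.normalize_harmonics(sf.efa_decompose(o, K=5)).coeffs
            assert np.allclose(got, ref, atol=1e-9)

    def test_fixed_seed_reproduces_outlines_exactly(self, study):
        kw = dict(n_outlines=5, seed=77, noise_frac=0.02, truth=study.truth)
        a, _ = sf.generate_aperture_sequence(study.axis, study.schedule, **kw)
        b, _ = sf.generate_aperture_sequence(study.axis, study.schedule, **kw)
        for oa, ob in zip(a, b):
            assert np.array_equal(oa.points, ob.points)

    def test_positions_outside_axis_rejected(self, study):
        with pytest.raises(ValidationError):
            sf.generate_aperture_sequence(
                study.axis, study.schedule, n_outlines=3, seed=0,
                s_positions=np.array([1.0, 2.0, 99.0]),
            )


class TestRibPositions:
    def flat_axis(self, length=14.0):
        t = np.linspace(0, length, int(length * 100) + 1)
        pts = np.stack([t, np.zeros_like(t), np.zeros_like(t)], axis=1)
        return sf.OntogenyAxis(points=pts, phase_bounds=(0.9 * length, 0.95 * length))

    def test_constant_trend_exact_spacings(self):
        rs = generate_rib_positions(self.flat_axis(), lambda s: 0.2, jitter_sd=0.0)
        assert np.allclose(rs.spacings, 0.2)

    def test_constant_trend_interval_count(self):
        rs = generate_rib_positions(self.flat_axis(14.0), lambda s: 0.2, jitter_sd=0.0)
        assert rs.spacings.size == 70  # floor(14 / 0.2)

    def test_unimodal_trend_gives_unimodal_spacings(self):
        g = lambda s: 0.1 + 0.05 * s if s < 7 else 0.1 + 0.05 * (14 - s)  # noqa: E731
        rs = generate_rib_positions(self.flat_axis(), g, jitter_sd=0.0)
        sp = rs.spacings
        peak = int(np.argmax(sp))
        assert np.all(np.diff(sp[: peak + 1]) >= -1e-12)
        assert np.all(np.diff(sp[peak:]) <= 1e-12)

    def test_oversized_jitter_fails_after_bounded_retries(self):
        # seed 4's first draw is negative, so with no retries allowed the
        # non-positive spacing is fatal
        with pytest.raises(ValidationError):
            generate_rib_positions(
                self.flat_axis(), lambda s: 1e-4, jitter_sd=5.0, seed=4, max_retries=0
            )

    def test_nonpositive_trend_rejected(self):
        with pytest.raises(ValidationError):
            generate_rib_positions(self.flat_axis(), lambda s: -0.1)


class TestSimulateCMR:
    def population(self, study, n=6):
        from dataclasses import replace
        from spiroform.synthetic import _truncate_axis

        marks = np.linspace(2.0, 11.0, n)
        pop = []
        for m in marks:
            ribs = study.axis.rib_positions
            idx = int(np.clip(np.searchsorted(ribs, m), 1, ribs.size - 1))
            pop.append(replace(_truncate_axis(study.axis, ribs[idx] + 1e-9),
                               phase_bounds=study.schedule.phase_bounds))
        return pop

    def test_constant_rate_exact_increment(self, study):
        recs = sf.simulate_cmr(self.population(study), lambda s: 0.5, duration=4.0, noise_sd=0.0)
        for r in recs:
            assert r.s_end - r.s_start == pytest.approx(2.0)
            assert r.rate == pytest.approx(0.5)
            assert r.phase == "spire"

    def test_monotone_rate_gives_perfect_rank_correlation(self, study):
        recs = sf.simulate_cmr(self.population(study, 10), lambda s: 0.1 + 0.05 * s,
                               duration=3.0, noise_sd=0.0)
        c = sf.spearman_correlation([r.s_start for r in recs], [r.rate for r in recs])
        assert c.r == pytest.approx(1.0)

    def test_empty_population_rejected(self):
        with pytest.raises(ValidationError):
            sf.simulate_cmr([], lambda s: 0.5, duration=1.0)

    def test_planted_rate_profile_rises_then_falls(self):
        sch = PhaseSchedule()
        v = [default_growth_rate(s, sch) for s in (2.0, 10.0, 13.5, 15.0, 16.5)]
        assert v[0] < v[1] < v[2]
        assert v[2] >= v[3] > v[4]


class TestStudyDeterminism:
    def test_same_seed_bitwise_identical(self):
        a = sf.simulate_study(seed=3)
        b = sf.simulate_study(seed=3)
        assert np.array_equal(a.axis.points, b.axis.points)
        for oa, ob in zip(a.outlines, b.outlines):
            assert np.array_equal(oa.points, ob.points)
        assert [r.s_end for r in a.growth_records] == [r.s_end for r in b.growth_records]
        for ra, rb in zip(a.rib_series, b.rib_series):
            assert np.array_equal(ra.positions, rb.positions)

    def test_different_seed_differs(self):
        a = sf.simulate_study(seed=3)
        b = sf.simulate_study(seed=4)
        assert not np.array_equal(a.outlines[0].points, b.outlines[0].points)
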