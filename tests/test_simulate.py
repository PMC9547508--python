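"""Generator correctness: trajectories, sweeps, admixture mosaics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from admixscan.simulate import (
    SimConfig,
    simulate_admixed_panel,
    simulate_sweep_panel,
    simulate_trajectory,
)


class TestTrajectory:
    @pytest.mark.parametrize(
        "nu0,s,T,expected_final",
        [
            (0.5, 0.0, 10, 0.5),  # s=0 fixes the odds
            (0.5, math.log(2), 1, 2.0 / 3.0),  # x0=1, e^s=2 forces 2/3
            # frozen oracle: per-generation odds product, independent arithmetic
            (0.18, 0.0121578, 68, 0.3341182590374038),
        ],
    )
    def test_deterministic_closed_form(self, nu0, s, T, expected_final):
        traj = simulate_trajectory(nu0, s, T)
        assert traj.frequencies[0] == nu0
        assert traj.frequencies.size == T + 1
        assert traj.final_freq == pytest.approx(expected_final, abs=1e-12)

    def test_s_zero_is_constant(self):
        traj = simulate_trajectory(0.37, 0.0, 25)
        assert np.all(traj.frequencies == 0.37)

    @given(
        nu0=st.floats(0.01, 0.99),
        s=st.floats(-0.2, 0.2),
        T=st.integers(0, 50),
    )
    @settings(deadline=None, max_examples=50)
    def test_bounds_and_start(self, nu0, s, T):
        traj = simulate_trajectory(nu0, s, T)
        assert traj.frequencies[0] == nu0
        assert np.all((traj.frequencies >= 0) & (traj.frequencies <= 1))

    @pytest.mark.parametrize("nu0", [0.0, 1.0])
    def test_boundary_frequency_rejected(self, nu0):
        with pytest.raises(ValueError):
            simulate_trajectory(nu0, 0.01, 10)

    def test_stochastic_reproducible(self):
        a = simulate_trajectory(0.3, 0.02, 30, mode="stochastic", Ne=100, seed=5)
        b = simulate_trajectory(0.3, 0.02, 30, mode="stochastic", Ne=100, seed=5)
        assert np.array_equal(a.frequencies, b.frequencies)
        c = simulate_trajectory(0.3, 0.02, 30, mode="stochastic", Ne=100, seed=6)
        assert not np.array_equal(a.frequencies, c.frequencies)

    def test_stochastic_mean_tracks_deterministic(self):
        # scaled-down version of the >=1000-replicate invariant; the full
        # Ne=10,000 check runs in the acceptance suite
        det = simulate_trajectory(0.18, 0.01, 40).frequencies
        reps = np.array(
            [
                simulate_trajectory(
                    0.18, 0.01, 40, mode="stochastic", Ne=10_000, seed=1000 + r
                ).frequencies
                for r in range(300)
            ]
        )
        mean = reps.mean(axis=0)
        se = reps.std(axis=0, ddof=1) / math.sqrt(reps.shape[0])
        inside = np.abs(mean - det) <= 3 * np.maximum(se, 1e-12)
        assert inside.all()


class TestSweepPanel:
    def test_reproducible(self):
        cfg = SimConfig(Ne=50, n_sites=40, sample_haplotypes=40, seed=3, max_generations=20)
        a = simulate_sweep_panel(cfg)
        b = simulate_sweep_panel(cfg)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert np.array_equal(a.positions_bp, b.positions_bp)

    def test_coordinates_and_polymorphism(self, neutral_panel):
        p = neutral_panel
        assert np.all(np.diff(p.positions_bp) > 0)
        assert np.all(np.diff(p.genetic_pos_cM) >= 0)
        # founding generation was polymorphic at every site by construction
        assert p.truth["synthetic"] is True

    def test_neutral_focal_frequency_unbiased(self):
        # one generation of pure drift from 0.5: mean over replicates ~ 0.5
        finals = []
        for r in range(200):
            cfg = SimConfig(
                Ne=50,
                n_sites=10,
                region_length_bp=50_000,
                sample_haplotypes=100,
                s_focal=0.0,
                init_focal_freq=0.5,
                max_generations=1,
                seed=2000 + r,
            )
            finals.append(simulate_sweep_panel(cfg).focal_freq())
        finals = np.asarray(finals)
        se = finals.std(ddof=1) / math.sqrt(finals.size)
        assert abs(finals.mean() - 0.5) < 3 * se

    def test_stop_condition_recorded(self):
        cfg = SimConfig(
            Ne=100,
            n_sites=40,
            sample_haplotypes=100,
            s_focal=0.1,
            init_focal_freq=0.2,
            stop_freq=0.5,
            max_generations=500,
            seed=9,
        )
        p = simulate_sweep_panel(cfg)
        assert p.truth["stop_condition"] in ("stop_freq", "max_generations")
        if p.truth["stop_condition"] == "stop_freq":
            assert p.truth["population_focal_freq"] >= 0.5
        # sample frequency within binomial sampling noise of the population's
        assert p.focal_freq() == pytest.approx(
            p.truth["population_focal_freq"], abs=4 * 0.5 / math.sqrt(100)
        )

    def test_sample_size_validation(self):
        with pytest.raises(ValueError):
            simulate_sweep_panel(SimConfig(Ne=10, sample_haplotypes=100, seed=1))


class TestAdmixedPanel:
    @staticmethod
    def _sources(seed=21, **kw):
        cfg = SimConfig(
            Ne=60, n_sites=120, sample_haplotypes=120, max_generations=20, seed=seed, **kw
        )
        base = simulate_sweep_panel(cfg)
        half = base.n_haplotypes // 2
        from admixscan.simulate import SimulatedPanel

        a = SimulatedPanel(
            base.haplotypes[:half], base.positions_bp, base.genetic_pos_cM, base.focal_index
        )
        b = SimulatedPanel(
            base.haplotypes[half:], base.positions_bp, base.genetic_pos_cM, base.focal_index
        )
        return a, b

    def test_f_one_all_non_african(self):
        a, b = self._sources()
        adm = simulate_admixed_panel(a, b, f=1.0, T=10, n=20, seed=4)
        assert np.all(adm.ancestry == 1)

    def test_f_zero_all_african(self):
        a, b = self._sources()
        adm = simulate_admixed_panel(a, b, f=0.0, T=10, n=20, seed=4)
        assert np.all(adm.ancestry == 0)

    def test_deterministic_under_seed(self):
        a, b = self._sources()
        x = simulate_admixed_panel(a, b, f=0.5, T=68, n=30, seed=11)
        y = simulate_admixed_panel(a, b, f=0.5, T=68, n=30, seed=11)
        assert np.array_equal(x.haplotypes, y.haplotypes)
        assert np.array_equal(x.ancestry, y.ancestry)

    def test_mean_ancestry_fraction(self):
        # law of large numbers on segment assignment (scaled-down replicate count)
        a, b = self._sources()
        fracs = [
            simulate_admixed_panel(a, b, f=0.5, T=68, n=44, seed=300 + r).ancestry.mean()
            for r in range(50)
        ]
        fracs = np.asarray(fracs)
        se = fracs.std(ddof=1) / math.sqrt(fracs.size)
        assert abs(fracs.mean() - 0.5) < 3 * se

    def test_segments_copy_source_haplotypes(self):
        a, b = self._sources()
        adm = simulate_admixed_panel(a, b, f=0.5, T=5, n=10, seed=8)
        gmorg = adm.genetic_pos_cM / 100.0
        for h in range(adm.n_haplotypes):
            seg_truth = adm.truth["segments"][h]
            seg_of_site = np.searchsorted(seg_truth["cuts_morgans"], gmorg, side="right")
            for seg in range(len(seg_truth["labels"])):
                cols = seg_of_site == seg
                if not cols.any():
                    continue
                lab = seg_truth["labels"][seg]
                donor = seg_truth["donors"][seg]
                src = (a, b)[lab]
                assert np.array_equal(adm.haplotypes[h, cols], src.haplotypes[donor, cols])
                assert np.all(adm.ancestry[h, cols] == lab)

    def test_mismatched_coordinates_rejected(self):
        a, _ = self._sources(seed=21)
        _, c = self._sources(seed=22)  # different site draw
        with pytest.raises(ValueError):
            simulate_admixed_panel(a, c, f=0.5, T=10, n=5, seed=1)
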