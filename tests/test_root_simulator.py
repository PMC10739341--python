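"""Growth engine: sampling, elongation, tropism, branching, confinement,
rendering and serialization."""

import math

import numpy as np
import pytest

from conftest import straight_primary, two_order_params
from rhizobridge import root_simulator as rs
from rhizobridge.root_simulator import (
    CylinderDomain,
    SimulationConfig,
    SlabDomain,
    axis_target_length,
    confine,
    expected_branch_sites,
    export_rsml,
    export_segments_csv,
    init_system,
    read_rsml,
    render_projection,
    sample_truncated_normal,
    simulate,
    tropism_direction,
)
from rhizobridge.trait_extraction import extract_traits_from_mask


class TestTruncatedNormal:
    def test_degenerate_sd_clamps_mean(self, rng):
        assert sample_truncated_normal(5.0, 0.0, 0.0, 10.0, rng) == 5.0
        assert sample_truncated_normal(15.0, 0.0, 0.0, 10.0, rng) == 10.0

    def test_symmetric_truncation_mean(self, rng):
        draws = np.array([
            sample_truncated_normal(0.0, 1.0, -0.5, 0.5, rng)
            for _ in range(100_000)
        ])
        assert abs(draws.mean()) < 0.01
        assert draws.min() >= -0.5 and draws.max() <= 0.5

    def test_half_open_bound(self, rng):
        draws = [
            sample_truncated_normal(5.0, 1.0, 0.0, np.inf, rng)
            for _ in range(10_000)
        ]
        assert min(draws) >= 0.0

    def test_invalid_bounds_error(self, rng):
        with pytest.raises(ValueError):
            sample_truncated_normal(0.0, 1.0, 2.0, 1.0, rng)


class TestTargetLength:
    def test_zero_age(self):
        assert axis_target_length(0.0, 1.0, 10.0) == 0.0

    def test_asymptote(self):
        assert axis_target_length(1e6, 1.0, 10.0) == pytest.approx(10.0, abs=1e-9)

    def test_closed_form(self):
        assert axis_target_length(1.0, 1.0, 10.0) == pytest.approx(
            10.0 * (1.0 - math.exp(-0.1))
        )

    def test_negative_age_errors(self):
        with pytest.raises(ValueError):
            axis_target_length(-1.0, 1.0, 10.0)


class TestTropism:
    def test_zero_sigma_keeps_heading(self, rng):
        h = np.array([0.6, 0.0, 0.8])
        out = tropism_direction(h, 0.0, 50, "gravitropism", rng)
        assert np.allclose(out, h)

    def test_zero_heading_errors(self, rng):
        with pytest.raises(ValueError):
            tropism_direction([0, 0, 0], 0.1, 5, "gravitropism", rng)

    def test_gravitropic_steering_reaches_vertical(self):
        """200 chained best-of-50 steps from horizontal end close to
        straight down."""
        rng = np.random.default_rng(7)
        h = np.array([1.0, 0.0, 0.0])
        for _ in range(200):
            h = tropism_direction(h, 0.3, 50, "gravitropism", rng)
        angle_to_down = math.degrees(math.acos(np.clip(h[2], -1, 1)))
        assert angle_to_down < 10.0

    def test_single_trial_is_half_normal_random_walk(self):
        """With N = 1 the turning angle is |N(0, σΔx)| on average."""
        rng = np.random.default_rng(11)
        sigma = 0.25
        h0 = np.array([0.0, 0.0, 1.0])
        turns = []
        for _ in range(10_000):
            h = tropism_direction(h0, sigma, 1, "gravitropism", rng)
            turns.append(math.acos(np.clip(float(h @ h0), -1, 1)))
        expected = sigma * math.sqrt(2 / math.pi)
        se = sigma * math.sqrt(1 - 2 / math.pi) / math.sqrt(len(turns))
        assert abs(np.mean(turns) - expected) < 3 * se

    def test_plagiotropism_flattens(self):
        rng = np.random.default_rng(13)
        h = np.array([0.0, 0.0, 1.0])
        for _ in range(200):
            h = tropism_direction(h, 0.3, 50, "plagiotropism", rng)
        assert abs(h[2]) < 0.2

    def test_exotropism_requires_initial_heading(self, rng):
        with pytest.raises(ValueError):
            tropism_direction([0, 0, 1], 0.1, 5, "exotropism", rng)


class TestGrowth:
    def test_zero_days_gives_zero_length_primaries(self):
        cfg = SimulationConfig(total_days=0, seed=1, n_primary_roots=4)
        system = simulate(straight_primary(), cfg)
        assert len(system.axes) == 4
        assert system.total_length_mm() == 0.0

    def test_deterministic_limit_matches_closed_form(self):
        """σ = 0 with gravitropism: one straight vertical root of exactly
        the closed-form length."""
        params = straight_primary(r=1.2, l_max=12.0)
        cfg = SimulationConfig(
            total_days=10, dt=1.0, seed=3, n_primary_roots=1, sd_frac=0.0
        )
        system = simulate(params, cfg)
        expected_mm = axis_target_length(10, 1.2, 12.0) * 10
        assert system.total_length_mm() == pytest.approx(expected_mm, abs=1e-6)
        tip = system.axes[0].nodes[-1]
        assert tip[0] == 0.0 and tip[1] == 0.0
        assert tip[2] == pytest.approx(expected_mm, abs=1e-6)

    def test_fencepost_branch_site_count(self):
        # zone of 6 cm at 1 cm spacing → 7 sites
        sites = expected_branch_sites(20.0, 20.0, 100.0, 10.0)
        assert len(sites) == 7
        assert sites[0] == 20.0 and sites[-1] == 80.0

    def test_branch_sites_match_brute_force_enumeration(self):
        """Fencepost formula against direct enumeration for random zones."""
        rng = np.random.default_rng(21)
        for _ in range(20):
            l_b = float(rng.uniform(0, 30))
            l_a = float(rng.uniform(0, 30))
            l_max = float(rng.uniform(80, 300))
            l_n = float(rng.uniform(2, 40))
            sites = expected_branch_sites(l_b, l_a, l_max, l_n)
            brute = []
            s = l_b
            while s <= l_max - l_a + 1e-9:
                brute.append(s)
                s += l_n
            assert len(sites) == len(brute)

    def test_spacing_longer_than_axis_disables_branching(self):
        assert expected_branch_sites(10.0, 10.0, 120.0, 200.0) == []

    def test_lateral_emergence(self, demo_params):
        cfg = SimulationConfig(total_days=15, dt=1.0, seed=9, n_primary_roots=1)
        system = simulate(demo_params, cfg)
        orders = {ax.order for ax in system.axes}
        assert orders == {1, 2}
        for ax in system.axes:
            if ax.parent_id is not None:
                parent = system.axis(ax.parent_id)
                # child base lies on the parent polyline
                base, _ = parent.position_at(ax.branch_arclength_mm)
                assert np.allclose(base, ax.nodes[0], atol=1e-9)

    def test_missing_higher_order_params_error(self, demo_params):
        cfg = SimulationConfig(
            total_days=5, seed=1, n_primary_roots=1, max_root_order=3
        )
        with pytest.raises(ValueError, match="order-3"):
            simulate(demo_params, cfg)

    def test_axis_lengths_capped_and_total_nondecreasing(self, demo_params):
        cfg = SimulationConfig(total_days=10, dt=1.0, seed=17, n_primary_roots=2)
        system = init_system(demo_params, cfg)
        lengths = [system.total_length_mm()]
        for _ in range(10):
            rs.grow_step(system, demo_params, cfg, 1.0)
            lengths.append(system.total_length_mm())
        assert all(b >= a for a, b in zip(lengths, lengths[1:]))
        for ax in system.axes:
            assert ax.length_mm <= ax.realized.l_max_mm + 1e-6

    def test_thin_slab_runs_stay_planar(self):
        params = straight_primary(sigma=15.0)
        cfg = SimulationConfig(
            total_days=15, dt=1.0, seed=23, n_primary_roots=3,
            domain=SlabDomain(279.4, 381.0, 3.175),
        )
        system = simulate(params, cfg)
        max_y = max(
            abs(p[1]) for ax in system.axes for p in ax.nodes
        )
        assert max_y <= 3.175 / 2 + 1e-6

    def test_gravitropism_digs_deeper_than_plagiotropism(self):
        depths = {}
        for mode in ("gravitropism", "plagiotropism"):
            final = []
            for seed in range(50):
                params = straight_primary(sigma=12.0)
                params[1].N = 5  # N = 1 is a mode-blind random walk
                cfg = SimulationConfig(
                    total_days=6, dt=1.0, seed=seed, n_primary_roots=1,
                    tropism_mode={1: mode},
                    domain=CylinderDomain(200.0, 400.0),
                )
                system = simulate(params, cfg)
                final.append(max(p[2] for p in system.axes[0].nodes))
            depths[mode] = np.asarray(final)
        from scipy import stats
        res = stats.ttest_ind(
            depths["gravitropism"], depths["plagiotropism"],
            alternative="greater",
        )
        assert res.pvalue < 0.01


class TestConfine:
    def test_interior_point_unchanged(self):
        dom = CylinderDomain(63.5, 254.0)
        p = confine([5.0, 5.0, 100.0], dom)
        assert np.allclose(p, [5.0, 5.0, 100.0])

    def test_cylinder_wall_reflection(self):
        dom = CylinderDomain(63.5, 254.0)
        # 1 mm beyond the wall along +x → 1 mm inside
        p = confine([32.75, 0.0, 100.0], dom)
        assert p[0] == pytest.approx(30.75)
        assert p[1] == 0.0 and p[2] == 100.0

    def test_cylinder_floor_reflection(self):
        dom = CylinderDomain(63.5, 254.0)
        p = confine([0.0, 0.0, 260.0], dom)
        assert p[2] == pytest.approx(248.0)

    def test_slab_reflections(self):
        dom = SlabDomain(100.0, 200.0, 4.0)
        p = confine([51.0, 3.0, -2.0], dom)
        assert p[0] == pytest.approx(49.0)
        assert p[1] == pytest.approx(1.0)
        assert p[2] == pytest.approx(2.0)


class TestRenderAndExport:
    def test_projection_cross_module_length(self):
        params = straight_primary(r=2.0, l_max=10.0, radius_cm=0.05)
        cfg = SimulationConfig(
            total_days=8, dt=1.0, seed=2, n_primary_roots=1, sd_frac=0.0
        )
        system = simulate(params, cfg)
        image = render_projection(system, scale_mm_per_px=1.0)
        rec = extract_traits_from_mask(image.mask, scale=1.0)
        assert rec.total_root_length == pytest.approx(
            system.total_length_mm(), rel=0.05
        )
        assert rec.number_of_root_tips == 2

    def test_trim_radius_limits_extent(self):
        """Roots reaching past the trim radius are removed from the image."""
        params = straight_primary(r=3.0, l_max=20.0, sigma=0.0)
        cfg = SimulationConfig(
            total_days=40, dt=1.0, seed=4, n_primary_roots=1, sd_frac=0.0,
            tropism_mode={1: "gravitropism"},
            domain=CylinderDomain(500.0, 500.0),
        )
        system = simulate(params, cfg)
        assert system.total_length_mm() > 150.0
        image = render_projection(
            system, scale_mm_per_px=1.0, trim_radius_mm=100.0, padding_mm=0.0
        )
        rows = np.nonzero(image.mask)[0]
        assert (rows.max() - rows.min()) <= 100.0 + 2  # stroke width slack

    def test_empty_system_renders_background(self):
        cfg = SimulationConfig(total_days=0, seed=1, n_primary_roots=1)
        system = simulate(straight_primary(), cfg)
        image = render_projection(system, scale_mm_per_px=0.5)
        assert not image.mask.any()
        assert image.provenance == "simulated"

    def test_rsml_round_trip(self, demo_params, tmp_path):
        cfg = SimulationConfig(total_days=12, dt=1.0, seed=31, n_primary_roots=2)
        system = simulate(demo_params, cfg)
        path = tmp_path / "system.rsml"
        export_rsml(system, path)
        roots = read_rsml(path)
        assert len(roots) == len(system.axes)
        by_id = {r["id"]: r for r in roots}
        for ax in system.axes:
            assert by_id[ax.axis_id]["polyline"].shape[0] == len(ax.nodes)
            assert by_id[ax.axis_id]["order"] == ax.order
            parent = by_id[ax.axis_id]["parent_id"]
            assert parent == ax.parent_id
            assert np.allclose(
                by_id[ax.axis_id]["polyline"], np.asarray(ax.nodes), atol=1e-6
            )

    def test_rsml_empty_system_valid(self, tmp_path):
        cfg = SimulationConfig(total_days=0, seed=1, n_primary_roots=1)
        system = simulate(straight_primary(), cfg)
        path = tmp_path / "empty.rsml"
        export_rsml(system, path)
        roots = read_rsml(path)
        assert len(roots) == 1  # one zero-length primary, no geometry steps
        assert roots[0]["polyline"].shape[0] == 1

    def test_segments_csv_row_count(self, demo_params, tmp_path):
        cfg = SimulationConfig(total_days=12, dt=1.0, seed=31, n_primary_roots=2)
        system = simulate(demo_params, cfg)
        path = tmp_path / "segments.csv"
        export_segments_csv(system, path)
        df = rs.read_segments_csv(path)
        assert len(df) == sum(len(ax.nodes) - 1 for ax in system.axes)

    def test_same_seed_bit_identical_segments(self, demo_params, tmp_path):
        cfg = SimulationConfig(total_days=10, dt=1.0, seed=77, n_primary_roots=2)
        paths = []
        for name in ("a.csv", "b.csv"):
            system = simulate(demo_params, cfg)
            p = tmp_path / name
            export_segments_csv(system, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]
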