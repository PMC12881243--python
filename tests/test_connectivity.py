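"""Gaussian-kernel wiring on toroidal grids: probabilities, degrees, structure."""

import math

import numpy as np
import pytest

from casim.connectivity import (
    AREAS, DEFAULT_LINKS, GRID, N_E, Architecture, KernelSpec, ProjectionSpec,
    build_architecture, default_kernels, expected_out_degree,
    kernel_probability, toroidal_offset, wire_projection,
)
from casim.params import preset

LOCAL = KernelSpec(sigma_x=3.2, sigma_y=3.2, k_c=0.15, half_width=9)
BETWEEN = KernelSpec(sigma_x=9.0, sigma_y=9.0, k_c=0.065, half_width=9)


def brute_force_degree(kernel, exclude_self):
    """Independent oracle: direct double-loop summation of the kernel."""
    total = 0.0
    for dx in range(-kernel.half_width, kernel.half_width + 1):
        for dy in range(-kernel.half_width, kernel.half_width + 1):
            if exclude_self and dx == 0 and dy == 0:
                continue
            expo = ((dx - kernel.mean_x) ** 2 / kernel.sigma_x ** 2
                    + (dy - kernel.mean_y) ** 2 / kernel.sigma_y ** 2
                    + 2 * kernel.q * (dx - kernel.mean_x) * (dy - kernel.mean_y)
                    / (kernel.sigma_x * kernel.sigma_y))
            total += kernel.k_c * math.exp(-expo / (2 * (1 - kernel.q ** 2)))
    return total


class TestKernelProbability:
    def test_centre_equals_amplitude(self):
        assert kernel_probability(LOCAL, 0, 0) == pytest.approx(0.15)

    def test_hand_computed_offset(self):
        # sigma 3.2 -> 2 sigma^2 = 20.48; value at (3, 0)
        assert kernel_probability(LOCAL, 3, 0) == pytest.approx(
            0.15 * math.exp(-9 / 20.48))
        assert kernel_probability(LOCAL, 3, 0) == pytest.approx(0.0966, abs=2e-4)

    def test_isotropic_symmetry(self):
        assert kernel_probability(LOCAL, 2, 1) == pytest.approx(
            kernel_probability(LOCAL, -2, -1))
        assert kernel_probability(LOCAL, 2, 1) == pytest.approx(
            kernel_probability(LOCAL, 1, 2))

    def test_bounded_by_amplitude(self, rng):
        d = rng.integers(-9, 10, size=(200, 2))
        p = kernel_probability(LOCAL, d[:, 0], d[:, 1])
        assert np.all(p <= 0.15 + 1e-15) and np.all(p >= 0)

    def test_anisotropy_validation(self):
        with pytest.raises(ValueError):
            KernelSpec(sigma_x=1, sigma_y=1, k_c=0.1, half_width=2, q=1.0)


class TestExpectedOutDegree:
    @pytest.mark.parametrize("kernel,exclude_self,target", [
        (LOCAL, True, 9.4456), (LOCAL, False, 9.5956), (BETWEEN, False, 16.6328),
    ])
    def test_frozen_values(self, kernel, exclude_self, target):
        assert expected_out_degree(kernel, exclude_self) == pytest.approx(
            target, abs=5e-4)

    @pytest.mark.parametrize("kernel,exclude_self", [
        (LOCAL, True), (BETWEEN, False),
        (KernelSpec(sigma_x=2.0, sigma_y=4.0, k_c=0.3, half_width=5,
                    mean_x=1.0, q=0.4), False),
    ])
    def test_matches_brute_force(self, kernel, exclude_self):
        assert expected_out_degree(kernel, exclude_self) == pytest.approx(
            brute_force_degree(kernel, exclude_self), rel=1e-12)

    def test_zero_amplitude(self):
        k = KernelSpec(sigma_x=3.2, sigma_y=3.2, k_c=0.0, half_width=9)
        assert expected_out_degree(k) == 0.0


def _ee_spec(kernel=LOCAL, cls="EE_local", exclude_self=True):
    src, dst = ("A1", "A1") if cls == "EE_local" else ("A1", "PB")
    return ProjectionSpec(src, dst, cls, plastic=True, kernel=kernel,
                          weight_init="uniform", delay=1.0,
                          exclude_self=exclude_self)


class TestWireProjection:
    def test_empirical_degree_matches_oracle(self):
        """Mean out-degree converges to the analytic kernel sum (3 SE)."""
        expected = expected_out_degree(LOCAL, exclude_self=True)
        n_seeds = 10
        means = [wire_projection(_ee_spec(), np.random.default_rng(s))
                 .out_degree().mean() for s in range(n_seeds)]
        # variance of a single neuron's degree is sum p(1-p) over the window
        dx = np.arange(-9, 10)
        p = kernel_probability(LOCAL, dx[:, None], dx[None, :]).ravel()
        p[p == 0.15] = 0.0  # centre excluded
        se = math.sqrt(np.sum(p * (1 - p)) / (N_E * n_seeds))
        assert abs(np.mean(means) - expected) < 3 * se

    def test_determinism_under_seed(self):
        a = wire_projection(_ee_spec(), np.random.default_rng(7))
        b = wire_projection(_ee_spec(), np.random.default_rng(7))
        assert np.array_equal(a.pre, b.pre)
        assert np.array_equal(a.post, b.post)
        assert np.array_equal(a.weight, b.weight)

    def test_ee_weights_within_init_bounds(self):
        proj = wire_projection(_ee_spec(), np.random.default_rng(3))
        assert proj.weight.min() >= 0.0 and proj.weight.max() <= 0.1

    def test_no_autapses_by_default(self):
        proj = wire_projection(_ee_spec(), np.random.default_rng(5))
        assert not np.any(proj.pre == proj.post)

    def test_autapses_when_enabled(self):
        spec = _ee_spec(exclude_self=False)
        found = any(np.any(wire_projection(spec, np.random.default_rng(s)).pre
                           == wire_projection(spec, np.random.default_rng(s)).post)
                    for s in range(5))
        assert found

    def test_translation_invariance_on_torus(self):
        """Edge and centre neurons face identical wiring statistics."""
        expected = expected_out_degree(LOCAL, exclude_self=True)
        corner, centre = 0, 12 * GRID + 12
        deg = np.zeros(2)
        n_seeds = 40
        for s in range(n_seeds):
            d = wire_projection(_ee_spec(), np.random.default_rng(100 + s)).out_degree()
            deg += [d[corner], d[centre]]
        deg /= n_seeds
        se = math.sqrt(expected / n_seeds)  # Poisson-scale bound
        assert abs(deg[0] - expected) < 3 * se
        assert abs(deg[1] - expected) < 3 * se

    def test_ei_full_neighbourhood(self):
        spec = ProjectionSpec("A1", "A1", "EI", kernel=default_kernels()["ei"],
                              weight_init="kernel")
        proj = wire_projection(spec, np.random.default_rng(0))
        assert np.all(proj.out_degree() == 25)
        # weight equals the Gaussian value at the toroidal offset
        k = default_kernels()["ei"]
        pre_rc = np.stack(divmod(proj.pre, GRID), axis=1)
        post_rc = np.stack(divmod(proj.post, GRID), axis=1)
        off = toroidal_offset(pre_rc, post_rc)
        assert np.allclose(proj.weight,
                           kernel_probability(k, off[:, 0], off[:, 1]))

    def test_deterministic_classes(self):
        rng = np.random.default_rng(0)
        ie = wire_projection(ProjectionSpec("A1", "A1", "IE"), rng)
        assert np.array_equal(ie.pre, ie.post) and np.all(ie.weight == 1)
        egi = wire_projection(ProjectionSpec("A1", "A1", "E_GI"), rng)
        assert len(egi) == N_E and np.all(egi.post == 0)
        gie = wire_projection(ProjectionSpec("A1", "A1", "GI_E"), rng)
        assert len(gie) == N_E and np.all(gie.pre == 0)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="synapse class"):
            ProjectionSpec("A1", "A1", "EE_magic")

    def test_plastic_restricted_to_ee(self):
        with pytest.raises(ValueError, match="plastic"):
            ProjectionSpec("A1", "A1", "IE", plastic=True)


class TestArchitecture:
    def test_population_counts(self, felix_net):
        assert felix_net.arch.n_excitatory == 7500
        gi = [p for p in felix_net.projections
              if p.spec.synapse_class == "GI_E"]
        assert len(gi) == 12  # one global-inhibitory unit per area

    def test_local_projection_classes_per_area(self, felix_net):
        for area in AREAS:
            classes = sorted(p.spec.synapse_class for p in felix_net.projections
                             if p.spec.source_area == area
                             and p.spec.target_area == area)
            assert classes == ["EE_local", "EI", "E_GI", "GI_E", "IE"]

    def test_between_area_reciprocity(self, felix_net):
        between = {(p.spec.source_area, p.spec.target_area): p.spec.kernel
                   for p in felix_net.projections
                   if p.spec.synapse_class == "EE_between"}
        for (a, b), kernel in between.items():
            assert (b, a) in between
            assert between[(b, a)] == kernel

    def test_link_classes_use_table_kernels(self, felix_net):
        by_pair = {(p.spec.source_area, p.spec.target_area): p.spec.kernel.k_c
                   for p in felix_net.projections
                   if p.spec.synapse_class == "EE_between"}
        for a, b, cls in DEFAULT_LINKS:
            want = 0.13 if cls == "within_system" else 0.065
            assert by_pair[(a, b)] == want and by_pair[(b, a)] == want

    def test_missing_link_area_rejected(self):
        with pytest.raises(ValueError, match="unknown area"):
            Architecture(links=(("A1", "XX", "within_system"),))

    def test_hub_secondary_primary_partition(self):
        from casim.connectivity import HUB_AREAS, SECONDARY_AREAS, PRIMARY_AREAS
        assert set(HUB_AREAS) | set(SECONDARY_AREAS) | set(PRIMARY_AREAS) == set(AREAS)

    def test_projection_child_seeds_reproducible(self):
        p = preset("felix")
        _, pa = build_architecture(p, 42)
        _, pb = build_architecture(p, 42)
        for x, y in zip(pa, pb):
            assert np.array_equal(x.weight, y.weight)
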