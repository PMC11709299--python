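"""The masked IPF engine: exactness oracles, convergence, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_dataset
from tomo3d.io import Mask3D
from tomo3d.preprocess import NormalizedGeneVectors
from tomo3d.reconstruct import (IPFConfig, ipf_fit, ipf_loss, ipf_step_axis,
                                reconstruct_batch)
from tomo3d.simulate import marginalize_volume


def vectors_from_volume(E, gene_id="g"):
    x, y, z = marginalize_volume(E)
    return NormalizedGeneVectors(gene_id=gene_id, x=x, y=y, z=z,
                                 T=float(E.sum()))


def feasible_instance(rng, shape=(5, 5, 5)):
    """A random nonnegative volume on a random mask: its own marginals are
    an exactly feasible IPF target."""
    mask_values = (rng.random(shape) < 0.6).astype(np.uint8)
    # every axis slice needs some support or its target mass is unassignable
    for ax in range(3):
        sums = mask_values.sum(axis=tuple(d for d in range(3) if d != ax))
        for i in np.nonzero(sums == 0)[0]:
            idx = [rng.integers(0, s) for s in shape]
            idx[ax] = i
            mask_values[tuple(idx)] = 1
    E = rng.random(shape) * mask_values
    E[tuple(np.argwhere(mask_values)[0])] += 0.5  # nonzero mass
    # zero-marginal slices are fine; positive mass requires support
    return E, Mask3D(mask_values)


class TestIpfStepAxis:
    def test_fixed_point_when_marginal_matches(self):
        rng = np.random.default_rng(0)
        R = rng.random((4, 3, 2))
        marginal = R.sum(axis=(1, 2))
        out, unassigned = ipf_step_axis(R, marginal, "x")
        assert np.allclose(out, R)
        assert unassigned == []

    @pytest.mark.parametrize("axis", ["x", "y", "z"])
    def test_marginal_exact_after_step(self, axis):
        rng = np.random.default_rng(1)
        R = rng.random((5, 4, 3))
        ax = "xyz".index(axis)
        target = rng.random(R.shape[ax]) * 10
        out, _ = ipf_step_axis(R, target, axis)
        got = out.sum(axis=tuple(d for d in range(3) if d != ax))
        assert np.max(np.abs(got - target)) < 1e-12 * target.sum()

    def test_empty_slice_reports_unassignable_mass(self):
        R = np.zeros((3, 2, 2))
        R[0] = 1.0
        R[2] = 1.0
        target = np.array([1.0, 2.5, 1.0])
        out, unassigned = ipf_step_axis(R, target, "x")
        assert unassigned == [(1, 2.5)]
        assert np.all(out[1] == 0)

    def test_zero_target_zeroes_slice(self):
        R = np.ones((2, 2, 2))
        out, _ = ipf_step_axis(R, np.array([0.0, 4.0]), "x")
        assert np.all(out[0] == 0) and out[1].sum() == pytest.approx(4.0)

    def test_negative_marginal_is_error(self):
        with pytest.raises(ValueError, match="negative"):
            ipf_step_axis(np.ones((2, 2, 2)), np.array([1.0, -1.0]), "x")


class TestIpfLoss:
    def test_zero_when_marginals_match(self):
        rng = np.random.default_rng(2)
        E = rng.random((4, 4, 4))
        assert ipf_loss(E, vectors_from_volume(E)) == pytest.approx(0.0)

    def test_all_zero_volume(self):
        vec = vectors_from_volume(np.ones((2, 3, 4)))
        expected = (vec.x @ vec.x + vec.y @ vec.y + vec.z @ vec.z)
        assert ipf_loss(np.zeros((2, 3, 4)), vec) == pytest.approx(expected)

    def test_matches_naive_triple_loop(self):
        rng = np.random.default_rng(3)
        R = rng.random((4, 3, 5))
        vec = vectors_from_volume(rng.random((4, 3, 5)))
        naive = 0.0
        for i in range(4):
            naive += (sum(R[i, j, k] for j in range(3) for k in range(5))
                      - vec.x[i]) ** 2
        for j in range(3):
            naive += (sum(R[i, j, k] for i in range(4) for k in range(5))
                      - vec.y[j]) ** 2
        for k in range(5):
            naive += (sum(R[i, j, k] for i in range(4) for j in range(3))
                      - vec.z[k]) ** 2
        assert ipf_loss(R, vec) == pytest.approx(naive, rel=1e-12)


class TestIpfFit:
    def test_uniform_marginals_give_uniform_volume(self):
        mask = Mask3D(np.ones((2, 2, 2)))
        vec = NormalizedGeneVectors(gene_id="g", x=[4.0, 4.0], y=[4.0, 4.0],
                                    z=[4.0, 4.0], T=8.0)
        recon = ipf_fit(vec, mask, IPFConfig(iterations=1))
        assert np.allclose(recon.values, 1.0)

    def test_separable_truth_recovered_after_one_set(self):
        """Rank-1 truths f(i)g(j)h(k) on a full mask are an IPF fixed point
        reached in one full set, matching the direct product formula."""
        rng = np.random.default_rng(4)
        f, g, h = rng.random(6) + 0.1, rng.random(5) + 0.1, rng.random(4) + 0.1
        E = np.einsum("i,j,k->ijk", f, g, h)
        vec = vectors_from_volume(E)
        recon = ipf_fit(vec, Mask3D(np.ones(E.shape)), IPFConfig(iterations=1))
        assert np.max(np.abs(recon.values - E)) < 1e-9 * E.max()

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_feasible_instances_converge(self, seed):
        """Marginals of any supported volume are feasible, so the loss after
        100 sets falls below 1e-6 * T^2."""
        rng = np.random.default_rng(seed)
        E, mask = feasible_instance(rng, shape=(5, 5, 5))
        vec = vectors_from_volume(E)
        recon = ipf_fit(vec, mask, IPFConfig(iterations=100))
        assert recon.loss_trace[-1] < 1e-6 * vec.T ** 2

    def test_support_preserved_every_iteration(self):
        rng = np.random.default_rng(5)
        E, mask = feasible_instance(rng, shape=(4, 4, 4))
        vec = vectors_from_volume(E)
        outside = ~mask.values.astype(bool)
        R = mask.values.astype(float)
        for _ in range(5):
            for axis, marginal in zip("xyz", (vec.x, vec.y, vec.z)):
                R, _ = ipf_step_axis(R, marginal, axis)
                assert np.all(R[outside] == 0)

    def test_final_z_marginal_exact_and_mass_is_T(self):
        rng = np.random.default_rng(6)
        E, mask = feasible_instance(rng)
        vec = vectors_from_volume(E)
        recon = ipf_fit(vec, mask, IPFConfig(iterations=3))
        z_marg = recon.values.sum(axis=(0, 1))
        assert np.max(np.abs(z_marg - vec.z)) < 1e-12 * vec.T
        assert recon.values.sum() == pytest.approx(vec.T)

    def test_loss_trace_non_divergent(self):
        rng = np.random.default_rng(7)
        E, mask = feasible_instance(rng)
        vec = vectors_from_volume(E)
        recon = ipf_fit(vec, mask, IPFConfig(iterations=50))
        trace = np.array(recon.loss_trace)
        assert len(trace) == 50
        assert np.all(np.isfinite(trace))
        assert trace[-1] <= trace[0] + 1e-12

    def test_all_zero_axis_vector_is_error(self, small_mask):
        lx, ly, lz = small_mask.shape
        vec = NormalizedGeneVectors(gene_id="g", x=np.zeros(lx),
                                    y=np.ones(ly), z=np.ones(lz), T=1.0,
                                    reconstructable=False)
        with pytest.raises(ValueError, match="not reconstructable"):
            ipf_fit(vec, small_mask)

    def test_dimension_mismatch_is_error(self, small_mask):
        vec = NormalizedGeneVectors(gene_id="g", x=[1.0], y=[1.0], z=[1.0],
                                    T=1.0)
        with pytest.raises(ValueError, match="mask shape"):
            ipf_fit(vec, small_mask)

    def test_determinism(self):
        rng = np.random.default_rng(8)
        E, mask = feasible_instance(rng)
        vec = vectors_from_volume(E)
        a = ipf_fit(vec, mask, IPFConfig(iterations=20))
        b = ipf_fit(vec, mask, IPFConfig(iterations=20))
        assert np.array_equal(a.values, b.values)
        assert a.loss_trace == b.loss_trace


class TestReconstructBatch:
    def test_batch_of_one_equals_single_path(self, small_mask):
        from tomo3d.preprocess import preprocess_gene
        ds = random_dataset(np.random.default_rng(9), shape=small_mask.shape)
        config = IPFConfig(iterations=10)
        batch, _ = reconstruct_batch(ds, small_mask, ["g2"], config)
        vec = preprocess_gene(ds, small_mask, "g2", normalize=True)
        single = ipf_fit(vec, small_mask, config)
        assert np.array_equal(batch["g2"].values, single.values)

    def test_gene_order_independent(self, small_mask):
        ds = random_dataset(np.random.default_rng(10), shape=small_mask.shape)
        config = IPFConfig(iterations=5)
        a, _ = reconstruct_batch(ds, small_mask, ["g1", "g3"], config)
        b, _ = reconstruct_batch(ds, small_mask, ["g3", "g1"], config)
        for g in ("g1", "g3"):
            assert np.array_equal(a[g].values, b[g].values)

    def test_non_reconstructable_gene_skipped_with_report(self, small_mask):
        ds = random_dataset(np.random.default_rng(11), shape=small_mask.shape,
                            n_zero_rows=1)
        results, report = reconstruct_batch(ds, small_mask, ["g0", "g5"],
                                            IPFConfig(iterations=3))
        assert "g0" in report["skipped"] and "g5" in results

    def test_empty_gene_list_is_error(self, small_mask, dataset_small):
        with pytest.raises(ValueError, match="empty"):
            reconstruct_batch(dataset_small, small_mask, [])

    def test_unknown_gene_is_error(self, small_mask, dataset_small):
        with pytest.raises(KeyError, match="not in dataset"):
            reconstruct_batch(dataset_small, small_mask, ["nope"])
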