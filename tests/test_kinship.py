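"""IBD-sharing estimation and the A/D/epistatic kernels."""

import numpy as np
import pytest

import cgsa
from cgsa.datatypes import MISSING, GenotypeMatrix, ValidationError
from cgsa.kinship import (
    IBDEstimates,
    KinshipMatrix,
    additive_matrix,
    dominance_matrix,
    estimate_ibd,
    hadamard_kernels,
)


def _panel(calls, **kw):
    calls = np.asarray(calls, dtype=np.int16)
    n, m = calls.shape
    return GenotypeMatrix(
        individual_ids=[f"i{k}" for k in range(n)],
        snp_ids=[f"s{k}" for k in range(m)],
        calls=calls,
        **kw,
    )


def ibd_oracle(calls, freq):
    """Brute-force method-of-moments P(IBD=0/1/2) for one pair of rows.

    Counts IBS states SNP by SNP, accumulates the expected per-state counts
    under each IBD state from the textbook drawing probabilities, then solves
    the expected-count equations state by state with sequential bounding to
    [0, 1] and renormalizes.  Deliberately written pair-at-a-time with scalar
    arithmetic, independent of the vectorized implementation.
    """
    g1, g2 = calls
    counts = np.zeros(3)
    E = np.zeros((3, 3))  # E[s, k] = expected #IBS=s given IBD=k
    for a, b, p in zip(g1, g2, freq):
        if a == MISSING or b == MISSING:
            continue
        ibs = 2 - abs(int(a) - int(b))
        counts[ibs] += 1
        q = 1 - p
        E[0, 0] += 2 * p * p * q * q
        E[1, 0] += 4 * p**3 * q + 4 * p * q**3
        E[2, 0] += p**4 + q**4 + 4 * p * p * q * q
        E[1, 1] += 2 * p * p * q + 2 * p * q * q
        E[2, 1] += p**3 + q**3 + p * p * q + p * q * q
        E[2, 2] += 1.0
    p0 = min(max(counts[0] / E[0, 0], 0.0), 1.0)
    p1 = min(max((counts[1] - p0 * E[1, 0]) / E[1, 1], 0.0), 1.0)
    p2 = min(max((counts[2] - p0 * E[2, 0] - p1 * E[2, 1]) / E[2, 2], 0.0), 1.0)
    clipped = np.array([p0, p1, p2])
    return clipped / clipped.sum()


class TestEstimateIBD:
    def test_identical_homozygotes_share_two(self):
        G = _panel([[0, 2, 0, 2, 2], [0, 2, 0, 2, 2], [2, 0, 2, 0, 0]])
        est = estimate_ibd(G, min_informative=1)
        assert est.p2[0, 1] == pytest.approx(1.0)
        assert est.p0[0, 1] == pytest.approx(0.0)
        assert est.p1[0, 1] == pytest.approx(0.0)

    def test_opposite_homozygotes_share_zero(self):
        G = _panel([[0, 2, 0, 2], [2, 0, 2, 0], [1, 1, 1, 1]])
        est = estimate_ibd(G, min_informative=1)
        assert est.p0[0, 1] == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, tiny_panel):
        est = estimate_ibd(tiny_panel, min_informative=1)
        freq = tiny_panel.allele_frequencies()
        n = tiny_panel.n_individuals
        for i in range(n):
            for j in range(i + 1, n):
                expected = ibd_oracle(tiny_panel.calls[[i, j]], freq)
                got = np.array([est.p0[i, j], est.p1[i, j], est.p2[i, j]])
                np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_oracle_agreement_with_missing_calls(self, rng):
        calls = rng.integers(0, 3, size=(5, 25)).astype(np.int16)
        calls[rng.random(calls.shape) < 0.15] = MISSING
        calls[0, :] = np.tile([0, 1], 13)[:25]  # keep columns polymorphic
        G = _panel(calls)
        sub = G.subset_snps([s for s, k in zip(G.snp_ids, G.polymorphic_mask()) if k])
        est = estimate_ibd(G, min_informative=1)
        freq = sub.allele_frequencies()
        for i in range(5):
            for j in range(i + 1, 5):
                mask = (sub.calls[i] != MISSING) & (sub.calls[j] != MISSING)
                expected = ibd_oracle(sub.calls[[i, j]], freq)
                got = np.array([est.p0[i, j], est.p1[i, j], est.p2[i, j]])
                np.testing.assert_allclose(got, expected, atol=1e-10)
                assert est.informative[i, j] == mask.sum()

    def test_simplex_constraint(self, small_panel):
        est = estimate_ibd(small_panel)
        total = est.p0 + est.p1 + est.p2
        np.testing.assert_allclose(total, 1.0, atol=1e-12)
        for arr in (est.p0, est.p1, est.p2):
            assert arr.min() >= 0.0

    def test_low_confidence_flag(self):
        calls = np.array([[0, 1], [1, 2], [2, 0]], dtype=np.int16)
        G = _panel(calls)
        with pytest.warns(UserWarning, match="informative"):
            est = estimate_ibd(G, min_informative=10)
        assert est.low_confidence[0, 1]

    def test_monomorphic_snps_skipped(self):
        calls = np.array([[0, 2, 1], [0, 0, 2], [0, 1, 0]], dtype=np.int16)
        with pytest.warns(UserWarning, match="monomorphic"):
            est = estimate_ibd(_panel(calls), min_informative=1)
        assert est.n_snps_used == 2


class TestKernels:
    @pytest.mark.parametrize(
        "p, expected_a, expected_d",
        [
            ((0.0, 0.0, 1.0), 1.0, 1.0),
            ((1.0, 0.0, 0.0), 0.0, 0.0),
            ((0.25, 0.5, 0.25), 0.5, 0.25),
            ((0.0, 1.0, 0.0), 0.5, 0.0),
        ],
    )
    def test_additive_and_dominance_elements(self, p, expected_a, expected_d):
        p0, p1, p2 = p
        est = IBDEstimates(
            individual_ids=["a", "b"],
            p0=np.array([[0.0, p0], [p0, 0.0]]),
            p1=np.array([[0.0, p1], [p1, 0.0]]),
            p2=np.array([[1.0, p2], [p2, 1.0]]),
            informative=np.full((2, 2), 50),
            low_confidence=np.zeros((2, 2), bool),
        )
        A = additive_matrix(est)
        D = dominance_matrix(est)
        assert A.values[0, 1] == pytest.approx(expected_a)
        assert D.values[0, 1] == pytest.approx(expected_d)
        assert A.values[0, 0] == 1.0 and D.values[1, 1] == 1.0

    def test_hadamard_identities(self, small_kernels):
        A, D = small_kernels["A"], small_kernels["D"]
        epi = hadamard_kernels(A, D)
        np.testing.assert_array_equal(epi["AA"].values, A.values * A.values)
        np.testing.assert_array_equal(epi["AD"].values, A.values * D.values)
        np.testing.assert_array_equal(epi["DD"].values, D.values * D.values)

    def test_hadamard_identity_matrix(self):
        ids = ["a", "b", "c"]
        A = KinshipMatrix("A", np.eye(3), ids)
        D = KinshipMatrix("D", np.eye(3), ids)
        epi = hadamard_kernels(A, D)
        np.testing.assert_array_equal(epi["AA"].values, np.eye(3))

    def test_hadamard_dimension_mismatch(self):
        A = KinshipMatrix("A", np.eye(3), ["a", "b", "c"])
        D = KinshipMatrix("D", np.eye(2), ["a", "b"])
        with pytest.raises(ValidationError):
            hadamard_kernels(A, D)

    def test_ranges_and_symmetry(self, small_kernels):
        for kind, K in small_kernels.items():
            np.testing.assert_allclose(K.values, K.values.T, atol=1e-12)
        for kind in ("A", "D"):
            v = small_kernels[kind].values
            assert v.min() >= 0.0 and v.max() <= 1.0
        # Hadamard entries never exceed their factors
        assert np.all(
            small_kernels["AA"].values <= small_kernels["A"].values + 1e-15
        )

    def test_permutation_conjugates_kernels(self, small_panel, rng):
        perm = rng.permutation(small_panel.n_individuals)
        ids = [small_panel.individual_ids[i] for i in perm]
        shuffled = small_panel.subset_individuals(ids)
        k1 = cgsa.gene_set_kernels(small_panel)
        k2 = cgsa.gene_set_kernels(shuffled)
        for kind in k1:
            np.testing.assert_allclose(
                k2[kind].values, k1[kind].values[np.ix_(perm, perm)], atol=1e-10
            )

    def test_unrelated_panel_pihat_shrinks_with_snp_count(self):
        # HWE unrelateds: pi-hat is pure estimation noise whose spread (and
        # hence the positive bias left by bounding at zero) decays ~1/sqrt(m)
        means = []
        for m in (250, 4000):
            G = cgsa.simulate_genotypes(40, m, maf_range=(0.2, 0.5), seed=21)
            A = cgsa.gene_set_kernels(G, kinds=("A",))["A"].values
            means.append(A[np.triu_indices_from(A, k=1)].mean())
        assert means[1] < means[0] / 2
        assert means[1] < 0.03


class TestPlinkGenomeImport:
    def test_round_trip_through_genome_file(self, tmp_path, tiny_panel):
        est = estimate_ibd(tiny_panel, min_informative=1)
        lines = ["FID1 IID1 FID2 IID2 Z0 Z1 Z2"]
        ids = est.individual_ids
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                lines.append(
                    f"f f {ids[i]} f {ids[j]} "[:0]
                    + f"1 {ids[i]} 1 {ids[j]} {est.p0[i, j]:.6f} "
                    f"{est.p1[i, j]:.6f} {est.p2[i, j]:.6f}"
                )
        path = tmp_path / "pairs.genome"
        path.write_text("\n".join(lines) + "\n")
        df = cgsa.read_plink_genome(path)
        assert len(df) == len(ids) * (len(ids) - 1) // 2
        row = df[(df.IID1 == ids[0]) & (df.IID2 == ids[1])].iloc[0]
        assert row.Z2 == pytest.approx(est.p2[0, 1], abs=1e-6)
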