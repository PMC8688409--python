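import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cldla.genoio import MISSING, GenotypeMatrix, HaplotypePanel
from cldla.kinship import (HapIBDMatrix, RelationshipMatrix, condition_psd,
                           diplotype_matrix, midpoint_run_ibd, vanraden_grm,
                           window_ibd)
from cldla.scan import Window, make_windows

from conftest import small_map


def brute_force_grm(dosages, freqs):
    """Double-loop VanRaden reference, missing mean-imputed per marker."""
    n, m = dosages.shape
    z = np.zeros((n, m))
    for k in range(m):
        for i in range(n):
            d = dosages[i, k]
            z[i, k] = 0.0 if d == MISSING else d - 2.0 * freqs[k]
    denom = 2.0 * sum(p * (1 - p) for p in freqs)
    G = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            G[i, j] = sum(z[i, k] * z[j, k] for k in range(m)) / denom
    return G


class TestVanRadenGrm:
    def test_single_marker_arithmetic(self):
        g = GenotypeMatrix(np.array([[0], [2]], dtype=np.int8), ["a", "b"],
                           small_map(1))
        G = vanraden_grm(g, freqs=np.array([0.5]))
        np.testing.assert_allclose(G.values, [[2, -2], [-2, 2]])

    def test_matches_brute_force(self):
        rng = np.random.default_rng(7)
        dosages = rng.integers(0, 3, size=(10, 50)).astype(np.int8)
        dosages[rng.random((10, 50)) < 0.05] = MISSING
        g = GenotypeMatrix(dosages, [f"i{k}" for k in range(10)], small_map(50))
        freqs = g.allele_freq()
        G = vanraden_grm(g)
        np.testing.assert_allclose(G.values, brute_force_grm(dosages, freqs),
                                   atol=1e-10)

    def test_duplicated_individual_rows_identical(self):
        rng = np.random.default_rng(8)
        dosages = rng.integers(0, 3, size=(5, 30)).astype(np.int8)
        dosages[4] = dosages[0]
        g = GenotypeMatrix(dosages, [f"i{k}" for k in range(5)], small_map(30))
        G = vanraden_grm(g)
        np.testing.assert_allclose(G.values[0], G.values[4])

    def test_monomorphic_without_freqs_errors(self):
        g = GenotypeMatrix(np.zeros((3, 4), dtype=np.int8),
                           ["a", "b", "c"], small_map(4))
        with pytest.raises(ValueError, match="monomorphic"):
            vanraden_grm(g)

    def test_in_sample_centering_gives_zero_column_sums(self):
        rng = np.random.default_rng(9)
        dosages = rng.integers(0, 3, size=(12, 80)).astype(np.int8)
        g = GenotypeMatrix(dosages, [f"i{k}" for k in range(12)], small_map(80))
        G = vanraden_grm(g).values
        n = 12
        off_mean = (G.sum() - np.trace(G)) / (n * (n - 1))
        assert abs(off_mean + np.trace(G) / n / (n - 1)) < 1e-8


def _panel_from_rows(rows):
    rows = np.asarray(rows, dtype=np.int8)
    n = rows.shape[0] // 2
    return HaplotypePanel(rows, [f"i{k}" for k in range(n)],
                          small_map(rows.shape[1]))


def _window(markers, W):
    return make_windows(markers, W=W, step=1)[0]


class TestWindowIbd:
    def test_identical_haplotypes_score_one(self):
        h = np.tile(np.array([0, 1, 1, 0], dtype=np.int8), (2, 1))
        panel = _panel_from_rows(h)
        ibd = window_ibd(panel, _window(panel.markers, 4))
        np.testing.assert_allclose(ibd.values, 1.0)

    def test_mismatch_at_both_midpoint_markers_scores_zero(self):
        W = 8
        a = np.zeros(W, dtype=np.int8)
        b = np.zeros(W, dtype=np.int8)
        b[W // 2 - 1] = 1   # marker W/2 (1-based)
        b[W // 2] = 1       # marker W/2+1
        panel = _panel_from_rows(np.vstack([a, b]))
        ibd = window_ibd(panel, _window(panel.markers, W))
        assert ibd.values[0, 1] == 0.0

    def test_partial_runs_arithmetic(self):
        # W=40; 10 consecutive matches scanning left of the midpoint,
        # 5 scanning right, mismatches beyond -> p = 15/40
        W = 40
        a = np.zeros(W, dtype=np.int8)
        b = np.zeros(W, dtype=np.int8)
        half = W // 2
        b[:half - 10] = 1          # ends the left run after 10 markers
        b[half + 5:] = 1           # ends the right run after 5 markers
        panel = _panel_from_rows(np.vstack([a, b]))
        ibd = window_ibd(panel, _window(panel.markers, W))
        assert ibd.values[0, 1] == pytest.approx(0.375)

    def test_missing_allele_terminates_run(self):
        W = 4
        a = np.array([0, 0, 0, 0], dtype=np.int8)
        b = np.array([0, MISSING, 0, 0], dtype=np.int8)
        panel = _panel_from_rows(np.vstack([a, b]))
        ibd = window_ibd(panel, _window(panel.markers, W))
        # left run blocked at its first marker; right run runs to the cap
        assert ibd.values[0, 1] == pytest.approx(2 / 4)

    def test_window_beyond_map_rejected(self):
        panel = _panel_from_rows(np.zeros((2, 6), dtype=np.int8))
        w = Window("1", 4, 9, 1, 1, 1.0)
        with pytest.raises(ValueError, match="beyond"):
            window_ibd(panel, w)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_symmetric_and_relabel_invariant(self, seed):
        rng = np.random.default_rng(seed)
        rows = rng.integers(0, 2, size=(6, 8)).astype(np.int8)
        panel = _panel_from_rows(rows)
        w = _window(panel.markers, 8)
        p1 = window_ibd(panel, w).values
        assert np.allclose(p1, p1.T)
        flipped = _panel_from_rows(1 - rows)
        p2 = window_ibd(flipped, w).values
        np.testing.assert_allclose(p1, p2)


class TestDiplotypeMatrix:
    @staticmethod
    def brute_force(P):
        n = P.shape[0] // 2
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i == j:
                    D[i, i] = 1.0 + P[2 * i, 2 * i + 1]
                else:
                    D[i, j] = 0.5 * (P[2 * i, 2 * j] + P[2 * i, 2 * j + 1]
                                     + P[2 * i + 1, 2 * j] + P[2 * i + 1, 2 * j + 1])
        return D

    @staticmethod
    def _ibd(P, n):
        return HapIBDMatrix(P, [f"i{k}" for k in range(n)])

    def test_full_sharing_gives_twos(self):
        P = np.ones((4, 4))
        D = diplotype_matrix(self._ibd(P, 2))
        np.testing.assert_allclose(D.values, 2.0)

    def test_no_sharing_gives_identity(self):
        P = np.eye(4)
        D = diplotype_matrix(self._ibd(P, 2))
        np.testing.assert_allclose(D.values, np.eye(2))

    def test_matches_brute_force_random(self):
        rng = np.random.default_rng(12)
        n = 6
        A = rng.random((2 * n, 2 * n))
        P = (A + A.T) / 2
        np.fill_diagonal(P, 1.0)
        D = diplotype_matrix(self._ibd(P, n))
        np.testing.assert_allclose(D.values, self.brute_force(P), atol=1e-12)

    def test_clones_have_equal_diagonal_and_cross_terms(self):
        # two individuals with identical haplotype pairs, fully IBD
        P = np.ones((4, 4))
        D = diplotype_matrix(self._ibd(P, 2)).values
        assert D[0, 0] == D[1, 1] == D[0, 1]

    def test_diplotype_range_invariants(self):
        rng = np.random.default_rng(13)
        A = rng.random((8, 8))
        P = (A + A.T) / 2
        np.fill_diagonal(P, 1.0)
        D = diplotype_matrix(self._ibd(P, 4)).values
        off = D[~np.eye(4, dtype=bool)]
        assert off.min() >= 0 and off.max() <= 2
        assert np.diag(D).min() >= 1 and np.diag(D).max() <= 2


class TestConditionPsd:
    def test_identity_unchanged(self):
        m = RelationshipMatrix(np.eye(3), ["a", "b", "c"], "genomic")
        out = condition_psd(m)
        assert out.ridge == 0.0
        np.testing.assert_array_equal(out.values, np.eye(3))

    def test_rank_deficient_matrix_conditioned(self):
        m = RelationshipMatrix(np.ones((2, 2)), ["a", "b"], "genomic")
        out = condition_psd(m)
        assert np.linalg.eigvalsh(out.values)[0] >= 1e-8

    def test_small_perturbation_stays_close(self):
        rng = np.random.default_rng(5)
        B = rng.random((6, 6))
        psd = B @ B.T + 0.5 * np.eye(6)
        lam, U = np.linalg.eigh(psd)
        lam[0] = -1e-9  # tiny negative eigen-noise
        noisy = (U * lam) @ U.T
        noisy = (noisy + noisy.T) / 2
        m = RelationshipMatrix(noisy, [f"i{k}" for k in range(6)], "genomic")
        out = condition_psd(m)
        assert np.max(np.abs(out.values - noisy)) <= out.ridge + 1e-15
        assert np.linalg.eigvalsh(out.values)[0] >= 1e-8


def test_sib_window_ibd_exceeds_founder_ibd(small_cohort):
    """Mean within-family haplotype sharing must exceed sharing between
    unrelated founders, across many windows."""
    config, ped, markers, panel, _ = small_cohort
    tab = ped.table
    sibs = tab[(tab["sire"] == "SIRE1") & (tab["dam"] == "DAM0")]["id"].tolist()[:6]
    founders = ped.founders()
    windows = make_windows(markers, W=40, step=4)
    assert len(windows) >= 20
    sib_panel = panel.subset_individuals(sibs)
    fnd_panel = panel.subset_individuals(founders)
    sib_scores, fnd_scores = [], []
    for w in windows:
        ps = window_ibd(sib_panel, w).values
        pf = window_ibd(fnd_panel, w).values
        sib_scores.append(ps[np.triu_indices_from(ps, 1)].mean())
        fnd_scores.append(pf[np.triu_indices_from(pf, 1)].mean())
    assert np.mean(sib_scores) > np.mean(fnd_scores)
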