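"""Covariance structures for the two-random-effect model.

The genome-wide genomic relationship matrix (VanRaden form) models the
polygenic effect; a per-window locus-specific diplotype relationship
matrix, converted from haplotype identity-by-descent probabilities,
models the QTL effect.

The default haplotype IBD estimator is a midpoint-anchored identity
run: scanning outward from the window midpoint, it counts consecutive
identical alleles to the left and to the right (each capped at half
the window) and divides by the window length.  It is deterministic,
parameter-free and monotone in shared-segment length; the estimator is
a plug-in so a coalescent-based alternative can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .genoio import MISSING, GenotypeMatrix, HaplotypePanel

__all__ = [
    "RelationshipMatrix",
    "HapIBDMatrix",
    "vanraden_grm",
    "window_ibd",
    "midpoint_run_ibd",
    "diplotype_matrix",
    "condition_psd",
]


@dataclass
class RelationshipMatrix:
    """Symmetric individual-by-individual covariance structure."""

    values: np.ndarray
    ids: list[str]
    kind: str                     # "genomic" | "diplotype"
    ridge: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix is not symmetric")
        if self.kind not in ("genomic", "diplotype"):
            raise ValueError(f"unknown relationship kind {self.kind!r}")


@dataclass
class HapIBDMatrix:
    """2n x 2n haplotype-pair IBD probabilities for one window.

    Haplotype order is (i_hap1, i_hap2) per individual; the diagonal is
    1 and all values lie in [0, 1].
    """

    values: np.ndarray
    ids: list[str]                # individual ids, haplotypes interleaved
    window: object = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n2 = 2 * len(self.ids)
        if self.values.shape != (n2, n2):
            raise ValueError("IBD matrix must be 2n x 2n")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("IBD matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 1.0):
            raise ValueError("IBD diagonal must be 1")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("IBD probabilities must lie in [0,1]")


def vanraden_grm(g: GenotypeMatrix, freqs: np.ndarray | None = None
                 ) -> RelationshipMatrix:
    """Genomic relationship matrix G = Z Z' / (2 Σ p_k (1 - p_k)).

    Z is the dosage matrix centered at twice the allele frequency;
    missing dosages are mean-imputed per marker before centering.
    Frequencies are estimated in-sample unless supplied.
    """
    if freqs is None:
        freqs = g.allele_freq()
        if np.isnan(freqs).any():
            freqs = np.where(np.isnan(freqs), 0.5, freqs)
    freqs = np.asarray(freqs, dtype=float)
    denom = 2.0 * np.sum(freqs * (1.0 - freqs))
    if denom <= 0:
        raise ValueError("all markers monomorphic: zero VanRaden denominator "
                         "(supply frequencies or polymorphic markers)")
    d = g.dosages.astype(float)
    d[g.dosages == MISSING] = np.nan
    col_mean = 2.0 * freqs
    z = np.where(np.isnan(d), 0.0, d - col_mean)  # mean-imputed then centered
    values = z @ z.T / denom
    return RelationshipMatrix(values, list(g.ids), "genomic")


def midpoint_run_ibd(alleles: np.ndarray) -> np.ndarray:
    """Identity-run IBD scores for all haplotype pairs in one window.

    ``alleles`` is (H, W) with W even.  For each pair, runs of
    consecutive identical alleles are counted scanning leftward from
    marker W/2 and rightward from marker W/2+1 (1-based), each capped
    at W/2; the score is (c_left + c_right) / W.  Missing alleles
    terminate runs.
    """
    H, W = alleles.shape
    if W % 2 != 0:
        raise ValueError("window length must be even")
    half = W // 2
    a = alleles
    valid = a != MISSING
    eq = (a[:, None, :] == a[None, :, :]) & valid[:, None, :] & valid[None, :, :]
    left = eq[:, :, half - 1::-1]          # scan left from midpoint
    right = eq[:, :, half:]                # scan right
    c_left = np.cumprod(left, axis=2).sum(axis=2)
    c_right = np.cumprod(right, axis=2).sum(axis=2)
    p = (c_left + c_right) / W
    np.fill_diagonal(p, 1.0)
    return p


def window_ibd(panel: HaplotypePanel, window,
               estimator: Callable[[np.ndarray], np.ndarray] = midpoint_run_ibd
               ) -> HapIBDMatrix:
    """Haplotype-pair IBD matrix for one sliding window of the panel."""
    lo, hi = window.start_index, window.end_index
    if lo < 0 or hi >= panel.markers.n_markers:
        raise ValueError("window extends beyond the marker map")
    chroms = set(panel.markers.chrom[lo:hi + 1])
    if len(chroms) > 1:
        raise ValueError("window spans more than one chromosome")
    alleles = panel.haps[:, lo:hi + 1]
    values = estimator(alleles)
    return HapIBDMatrix(values, list(panel.ids), window)


def diplotype_matrix(ibd: HapIBDMatrix) -> RelationshipMatrix:
    """Locus-specific diplotype relationship matrix from haplotype IBD.

    Off-diagonal D_ij is half the sum of the four cross-haplotype IBD
    probabilities; the diagonal is 1 + p(hap1_i, hap2_i).
    """
    P = ibd.values
    n2 = P.shape[0]
    if n2 % 2 != 0:
        raise ValueError("odd haplotype count")
    n = n2 // 2
    S = P.reshape(n, 2, n, 2).sum(axis=(1, 3))
    D = 0.5 * S
    np.fill_diagonal(D, 1.0 + P[np.arange(0, n2, 2), np.arange(1, n2, 2)])
    return RelationshipMatrix(D, list(ibd.ids), "diplotype")


def condition_psd(m: RelationshipMatrix, min_eig: float = 1e-8
                  ) -> RelationshipMatrix:
    """Add the smallest ridge εI (doubling search from 1e-10) that
    brings the minimum eigenvalue up to ``min_eig``."""
    lam_min = float(np.linalg.eigvalsh(m.values)[0])
    if lam_min >= min_eig:
        return RelationshipMatrix(m.values, list(m.ids), m.kind, ridge=0.0)
    eps = 1e-10
    while lam_min + eps < min_eig:
        eps *= 2.0
    values = m.values + eps * np.eye(len(m.ids))
    return RelationshipMatrix(values, list(m.ids), m.kind, ridge=eps)
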