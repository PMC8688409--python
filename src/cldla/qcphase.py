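"""Marker/individual quality control and trio-based phasing.

QC follows the strict boundary conventions of the mapping protocol:
markers are removed when their position is unknown, when MAF < 0.025,
or when the per-marker call rate < 0.9 (both strict); individuals are
retained only when their call rate is strictly greater than 0.95.

Phasing replaces a population HMM with a deterministic pedigree rule.
The mapping cohort is trio-complete by design, so most heterozygous
sites resolve by Mendelian deduction; the remainder are resolved by
transmission continuity — founder haplotypes are reconstructed from
the alleles they demonstrably transmitted, and each child's ambiguous
sites are assigned the parental haplotype it carries at the nearest
informative flanking site.  A frequency rule is the final fallback.
Mendelian-inconsistent sites are masked and counted, never fatal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genoio import MISSING, GenotypeMatrix, HaplotypePanel, MarkerMap
from .pedigree import UNKNOWN, Pedigree
from .rng import stream

__all__ = ["QCReport", "filter_markers", "filter_individuals", "trio_phase"]


@dataclass
class QCReport:
    """Removal tallies for one QC pass; removed + remaining reconcile
    with the input counts per axis."""

    n_markers_in: int = 0
    removed_unknown_position: int = 0
    removed_maf: int = 0
    removed_call_rate: int = 0
    n_markers_out: int = 0
    n_individuals_in: int = 0
    removed_individuals: int = 0
    n_individuals_out: int = 0

    def validate(self) -> None:
        if (self.removed_unknown_position + self.removed_maf
                + self.removed_call_rate + self.n_markers_out != self.n_markers_in):
            raise ValueError("marker QC tallies do not reconcile")
        if self.removed_individuals + self.n_individuals_out != self.n_individuals_in:
            raise ValueError("individual QC tallies do not reconcile")

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def filter_markers(g: GenotypeMatrix, markers: MarkerMap, maf_min: float = 0.025,
                   callrate_min: float = 0.9,
                   exclude_chroms: tuple[str, ...] = ("X",)
                   ) -> tuple[GenotypeMatrix, MarkerMap, QCReport]:
    """Remove markers with unknown position, MAF < ``maf_min`` or call
    rate < ``callrate_min`` (strict inequalities).

    When several criteria hit the same marker it is counted under the
    first in that order.  X-linked markers are excluded by default
    (cases are hemizygous); pass ``exclude_chroms=()`` to keep them.
    """
    unknown = markers.unknown_position
    if exclude_chroms:
        unknown = unknown | np.isin(markers.chrom.astype(str), exclude_chroms)
    callrate = g.marker_call_rate()
    maf = g.minor_allele_freq()
    low_maf = ~unknown & ~np.isnan(maf) & (maf < maf_min)
    low_call = ~unknown & ~low_maf & ((callrate < callrate_min) | np.isnan(maf))
    keep = ~(unknown | low_maf | low_call)
    if not keep.any():
        raise ValueError("marker QC removed every marker")
    report = QCReport(
        n_markers_in=markers.n_markers,
        removed_unknown_position=int(unknown.sum()),
        removed_maf=int(low_maf.sum()),
        removed_call_rate=int(low_call.sum()),
        n_markers_out=int(keep.sum()),
        n_individuals_in=g.n_individuals,
        n_individuals_out=g.n_individuals,
    )
    report.validate()
    idx = np.where(keep)[0]
    out = GenotypeMatrix(g.dosages[:, idx], list(g.ids), markers.subset(idx))
    return out, out.markers, report


def filter_individuals(g: GenotypeMatrix, callrate_min: float = 0.95
                       ) -> tuple[GenotypeMatrix, QCReport]:
    """Retain individuals whose call rate is strictly greater than
    ``callrate_min``."""
    callrate = g.individual_call_rate()
    keep = callrate > callrate_min
    if not keep.any():
        raise ValueError("individual QC removed every individual")
    report = QCReport(
        n_markers_in=g.markers.n_markers, n_markers_out=g.markers.n_markers,
        n_individuals_in=g.n_individuals,
        removed_individuals=int((~keep).sum()),
        n_individuals_out=int(keep.sum()),
    )
    report.validate()
    ids = [i for i, k in zip(g.ids, keep) if k]
    return GenotypeMatrix(g.dosages[keep], ids, g.markers), report


# ---------------------------------------------------------------------------
# trio phasing
# ---------------------------------------------------------------------------

def _feasible_range(parent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Min/max allele a parent dosage can transmit (missing -> 0..1)."""
    lo = np.where(parent == 2, 1, 0)
    hi = np.where(parent == 0, 0, 1)
    lo = np.where(parent == MISSING, 0, lo)
    hi = np.where(parent == MISSING, 1, hi)
    return lo, hi


def trio_phase(g: GenotypeMatrix, ped: Pedigree, freqs: np.ndarray | None = None,
               seed: int = 0) -> HaplotypePanel:
    """Phase and impute a genotype matrix against its pedigree.

    Homozygous sites phase trivially; a heterozygous child with at
    least one homozygous parent phases by Mendelian deduction (paternal
    haplotype first).  Remaining heterozygotes are assigned the
    arrangement that extends the locally transmitted parental
    haplotype, reconstructed by transmission clustering; unresolvable
    sites fall back to the frequency rule, ties broken by seeded draw.
    Missing child genotypes are imputed from two homozygous parents,
    otherwise as the rounded expected dosage 2p.  Mendelian-
    inconsistent trio sites are set missing and counted in the
    returned panel's ``n_mendel_conflicts`` attribute.
    """
    markers = g.markers
    m = markers.n_markers
    if freqs is None:
        freqs = g.allele_freq()
    freqs = np.where(np.isnan(freqs), 0.5, freqs)
    rng = stream(seed, "trio_phase")

    order = ped.in_order()
    ids_in_ped = [str(i) for i in order["id"] if str(i) in set(g.ids)]
    row_of = {ind: k for k, ind in enumerate(g.ids)}
    D = g.dosages.astype(np.int16).copy()

    parents = {}
    for _, rec in order.iterrows():
        ind = str(rec["id"])
        if ind not in row_of:
            continue
        s, d = str(rec["sire"]), str(rec["dam"])
        parents[ind] = (s if s in row_of else None, d if d in row_of else None)

    # ---- Mendelian conflict masking --------------------------------------
    n_conflicts = 0
    for ind in ids_in_ped:
        s, d = parents[ind]
        if s is None or d is None:
            continue
        c = D[row_of[ind]]
        slo, shi = _feasible_range(D[row_of[s]])
        dlo, dhi = _feasible_range(D[row_of[d]])
        known = c != MISSING
        bad = known & ((c < slo + dlo) | (c > shi + dhi))
        n_conflicts += int(bad.sum())
        c[bad] = MISSING

    # ---- imputation of missing dosages ------------------------------------
    exp_dosage = np.clip(np.round(2.0 * freqs), 0, 2).astype(np.int16)
    for ind in ids_in_ped:
        s, d = parents[ind]
        c = D[row_of[ind]]
        miss = c == MISSING
        if not miss.any():
            continue
        fill = exp_dosage.copy()
        if s is not None and d is not None:
            sd, dd = D[row_of[s]], D[row_of[d]]
            both_hom = np.isin(sd, (0, 2)) & np.isin(dd, (0, 2))
            fill = np.where(both_hom, (sd // 2 + dd // 2).astype(np.int16), fill)
        c[miss] = fill[miss]

    # ---- haplotype arrays --------------------------------------------------
    n = len(g.ids)
    pat = np.full((n, m), MISSING, dtype=np.int8)   # haplotype 1
    mat = np.full((n, m), MISSING, dtype=np.int8)   # haplotype 2
    resolved_pat = np.zeros((n, m), dtype=bool)     # paternal allele deduced

    for ind in ids_in_ped:
        k = row_of[ind]
        c = D[k]
        hom = np.isin(c, (0, 2))
        pat[k, hom] = mat[k, hom] = (c[hom] // 2).astype(np.int8)
        resolved_pat[k, hom] = True
        het = c == 1
        s, d = parents[ind]
        if s is not None and d is not None:
            sd, dd = D[row_of[s]], D[row_of[d]]
            by_sire = het & np.isin(sd, (0, 2))
            pat[k, by_sire] = (sd[by_sire] // 2).astype(np.int8)
            mat[k, by_sire] = 1 - pat[k, by_sire]
            by_dam = het & ~by_sire & np.isin(dd, (0, 2))
            mat[k, by_dam] = (dd[by_dam] // 2).astype(np.int8)
            pat[k, by_dam] = 1 - mat[k, by_dam]
            resolved_pat[k, by_sire | by_dam] = True

    # ---- founder haplotype reconstruction by transmission clustering -------
    children_of: dict[str, list[tuple[str, int]]] = {}
    for ind in ids_in_ped:
        s, d = parents[ind]
        if s is not None:
            children_of.setdefault(s, []).append((ind, 0))  # transmitted -> pat
        if d is not None:
            children_of.setdefault(d, []).append((ind, 1))

    chrom_index = [np.where(markers.chrom == c)[0] for c in markers.chromosomes()]

    def phase_parent_by_transmission(p: str) -> None:
        k = row_of[p]
        c = D[k]
        het = np.where(c == 1)[0]
        if len(het) == 0:
            return
        kids = children_of.get(p, [])
        trans = []  # (child row, transmitted-allele array, known mask)
        for child, which in kids:
            ck = row_of[child]
            t = pat[ck] if which == 0 else mat[ck]
            trans.append((t, resolved_pat[ck]))
        for idx in chrom_index:
            sites = idx[c[idx] == 1]
            state = [0] * len(trans)  # 0 unknown, +1 carries hap1, -1 carries hap2
            for msite in sites:
                votes = [(j, int(t[msite])) for j, (t, known) in enumerate(trans)
                         if known[msite] and t[msite] != MISSING]
                anchored = [(j, a) for j, a in votes if state[j] != 0]
                if anchored:
                    tally = sum((a if state[j] > 0 else 1 - a) for j, a in anchored)
                    h1 = 1 if 2 * tally >= len(anchored) else 0
                elif votes:
                    j0, a0 = votes[0]
                    state[j0] = 1
                    h1 = a0
                else:
                    h1 = 1 if freqs[msite] > 0.5 else (
                        0 if freqs[msite] < 0.5 else int(rng.integers(2)))
                pat[k, msite] = h1
                mat[k, msite] = 1 - h1
                for j, a in votes:
                    if state[j] == 0:
                        state[j] = 1 if a == h1 else -1
                    elif (a == h1) != (state[j] > 0):
                        state[j] = -state[j]  # crossover in child's gamete
                resolved_pat[k, msite] = True

    # transmission clustering applies only to parents without their own
    # trio (founders): a recruited dam keeps the paternal/maternal
    # orientation her own trio established
    gen_of = dict(zip(order["id"].astype(str), order["generation"]))
    for p in sorted(children_of, key=lambda q: (gen_of.get(q, 0), q)):
        ps, pd_ = parents.get(p, (None, None))
        if ps is None and pd_ is None:
            phase_parent_by_transmission(p)

    # ---- ambiguous child sites by transmission continuity ------------------
    def resolve_ambiguous(ind: str) -> None:
        k = row_of[ind]
        c = D[k]
        open_sites = np.where((c == 1) & ~resolved_pat[k])[0]
        if len(open_sites) == 0:
            return
        s, d = parents[ind]
        for idx in chrom_index:
            chrom_open = open_sites[np.isin(open_sites, idx)]
            if len(chrom_open) == 0:
                continue
            best_allele = np.full(len(chrom_open), MISSING, dtype=np.int8)
            best_dist = np.full(len(chrom_open), np.inf)
            for parent, own, other in ((s, pat, mat), (d, mat, pat)):
                if parent is None:
                    continue
                pk = row_of[parent]
                # informative sites: parent heterozygous with known phase and
                # the child's transmitted allele already resolved
                info = idx[(D[pk][idx] == 1) & resolved_pat[k][idx]
                           & (pat[pk][idx] != MISSING)
                           & (own[k][idx] != MISSING)]
                if len(info) == 0:
                    continue
                carries_h1 = own[k][info] == pat[pk][info]
                pos_info = markers.bp[info].astype(float)
                pos_open = markers.bp[chrom_open].astype(float)
                j = np.searchsorted(pos_info, pos_open)
                j_left = np.clip(j - 1, 0, len(info) - 1)
                j_right = np.clip(j, 0, len(info) - 1)
                d_left = np.abs(pos_open - pos_info[j_left])
                d_right = np.abs(pos_info[j_right] - pos_open)
                nearest = np.where(d_left <= d_right, j_left, j_right)
                dist = np.minimum(d_left, d_right)
                hap_allele = np.where(carries_h1[nearest],
                                      pat[pk][chrom_open], mat[pk][chrom_open])
                better = dist < best_dist
                if own is mat:  # translate the maternal allele into a paternal one
                    hap_allele = 1 - hap_allele
                best_allele = np.where(better, hap_allele.astype(np.int8), best_allele)
                best_dist = np.where(better, dist, best_dist)
            fallback = best_allele == MISSING
            if fallback.any():
                f = freqs[chrom_open[fallback]]
                draw = np.where(f > 0.5, 1, np.where(f < 0.5, 0,
                                                     rng.integers(2, size=fallback.sum())))
                best_allele[fallback] = draw.astype(np.int8)
            pat[k, chrom_open] = best_allele
            mat[k, chrom_open] = 1 - best_allele
            resolved_pat[k, chrom_open] = True

    for ind in ids_in_ped:
        s, d = parents[ind]
        if s is not None or d is not None:
            resolve_ambiguous(ind)

    # ---- frequency fallback for anything still open ------------------------
    still = (D == 1) & (pat == MISSING)
    if still.any():
        rows_, cols_ = np.where(still)
        f = freqs[cols_]
        draw = np.where(f > 0.5, 1, np.where(f < 0.5, 0,
                                             rng.integers(2, size=len(cols_))))
        pat[rows_, cols_] = draw.astype(np.int8)
        mat[rows_, cols_] = 1 - pat[rows_, cols_]

    haps = np.empty((2 * n, m), dtype=np.int8)
    haps[0::2] = pat
    haps[1::2] = mat
    panel = HaplotypePanel(haps, list(g.ids), markers)
    panel.n_mendel_conflicts = n_conflicts
    return panel
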