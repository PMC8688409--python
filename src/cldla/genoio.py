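"""Containers and file I/O for markers, genotypes and haplotypes.

Formats supported: PLINK text PED/MAP, phased VCF (GT with ``|``),
tab-separated phenotype and pedigree tables, and the scan output
tables.  All coordinates are 1-based inclusive.  Readers validate and
reject malformed records, naming the offending marker or line; they
never coerce.

Dosage convention: allele 1 is the reference/first-listed allele and
the dosage counts copies of allele 2 (values 0/1/2, missing ``-1``).
Haplotype alleles are 0 (reference) / 1 (alternate); for trio-phased
individuals haplotype 1 is paternal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree import UNKNOWN, Pedigree

__all__ = [
    "MarkerMap",
    "GenotypeMatrix",
    "HaplotypePanel",
    "MISSING",
    "FormatError",
    "read_plink",
    "write_plink",
    "read_vcf_phased",
    "write_vcf_phased",
    "read_phenotypes",
    "write_phenotypes",
    "read_pedigree",
    "write_pedigree",
    "write_scan_outputs",
]

MISSING = -1  # dosage / allele sentinel

_UNKNOWN_CHROMS = {"", "0", "NA", "na", "."}


class FormatError(ValueError):
    """Malformed record in an input file."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class MarkerMap:
    """Marker positions: chromosome, id, bp (1-based), optional cM.

    Sorted by (chromosome, bp) within known-position markers.  Markers
    with an unknown chromosome or non-positive bp are *flagged*, never
    silently dropped; QC removes them explicitly.
    """

    chrom: np.ndarray          # str array
    ids: np.ndarray            # str array
    bp: np.ndarray             # int64
    cm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.ids = np.asarray(self.ids, dtype=object)
        self.bp = np.asarray(self.bp, dtype=np.int64)
        if self.cm is not None:
            self.cm = np.asarray(self.cm, dtype=float)
        if not (len(self.chrom) == len(self.ids) == len(self.bp)):
            raise ValueError("marker map columns have unequal lengths")
        if pd.Series(self.ids).duplicated().any():
            raise ValueError("marker ids are not unique")
        known = ~self.unknown_position
        for c in np.unique(self.chrom[known]):
            pos = self.bp[known & (self.chrom == c)]
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"markers on chromosome {c} are not bp-sorted")

    @property
    def unknown_position(self) -> np.ndarray:
        unknown_chrom = np.array([str(c) in _UNKNOWN_CHROMS for c in self.chrom])
        return unknown_chrom | (self.bp < 1)

    @property
    def n_markers(self) -> int:
        return len(self.ids)

    def genetic_pos_cm(self) -> np.ndarray:
        """cM positions; physical-to-genetic conversion fixed at 1 cM/Mbp
        when no cM column is supplied."""
        if self.cm is not None:
            return self.cm
        return self.bp / 1e6

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        cm = self.cm[idx] if self.cm is not None else None
        return MarkerMap(self.chrom[idx], self.ids[idx], self.bp[idx], cm)

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c, unk in zip(self.chrom, self.unknown_position):
            if not unk:
                seen.setdefault(str(c), None)
        return list(seen)


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosages in {0, 1, 2, MISSING}."""

    dosages: np.ndarray        # int8, n x m
    ids: list[str]
    markers: MarkerMap

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        n, m = self.dosages.shape
        if n != len(self.ids):
            raise ValueError("dosage rows do not match individual ids")
        if m != self.markers.n_markers:
            raise ValueError("dosage columns do not match marker map")
        bad = ~np.isin(self.dosages, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosages must be 0/1/2 or the missing sentinel")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("individual ids are not unique")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    def marker_call_rate(self) -> np.ndarray:
        return (self.dosages != MISSING).mean(axis=0)

    def individual_call_rate(self) -> np.ndarray:
        return (self.dosages != MISSING).mean(axis=1)

    def minor_allele_freq(self) -> np.ndarray:
        """Per-marker MAF over non-missing dosages (NaN when no calls)."""
        obs = self.dosages != MISSING
        n_called = obs.sum(axis=0)
        alt = np.where(obs, self.dosages, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
        return np.minimum(p, 1.0 - p)

    def allele_freq(self) -> np.ndarray:
        """Per-marker frequency of allele 2 (the counted allele)."""
        obs = self.dosages != MISSING
        n_called = obs.sum(axis=0)
        alt = np.where(obs, self.dosages, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, alt / (2.0 * n_called), np.nan)

    def subset_individuals(self, keep_ids: list[str]) -> "GenotypeMatrix":
        index = {i: k for k, i in enumerate(self.ids)}
        rows = [index[i] for i in keep_ids]
        return GenotypeMatrix(self.dosages[rows], list(keep_ids), self.markers)


@dataclass
class HaplotypePanel:
    """Two ordered haplotypes per individual x markers, alleles in {0,1}.

    Row 2i is haplotype 1 of individual i (paternal for trio-phased
    individuals), row 2i+1 haplotype 2.
    """

    haps: np.ndarray           # int8, 2n x m
    ids: list[str]
    markers: MarkerMap

    def __post_init__(self) -> None:
        self.haps = np.asarray(self.haps, dtype=np.int8)
        if self.haps.shape[0] != 2 * len(self.ids):
            raise ValueError("haplotype rows must be 2 per individual")
        if self.haps.shape[1] != self.markers.n_markers:
            raise ValueError("haplotype columns do not match marker map")
        bad = ~np.isin(self.haps, [0, 1, MISSING])
        if bad.any():
            raise ValueError("haplotype alleles must be 0/1 or missing")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    def dosages(self) -> GenotypeMatrix:
        h = self.haps.reshape(self.n_individuals, 2, -1)
        miss = (h == MISSING).any(axis=1)
        d = h.sum(axis=1, dtype=np.int8)
        d[miss] = MISSING
        return GenotypeMatrix(d, list(self.ids), self.markers)

    def subset_individuals(self, keep_ids: list[str]) -> "HaplotypePanel":
        index = {i: k for k, i in enumerate(self.ids)}
        rows = []
        for i in keep_ids:
            k = index[i]
            rows.extend((2 * k, 2 * k + 1))
        return HaplotypePanel(self.haps[rows], list(keep_ids), self.markers)

    def subset_markers(self, idx: np.ndarray) -> "HaplotypePanel":
        return HaplotypePanel(self.haps[:, idx], list(self.ids), self.markers.subset(idx))


# ---------------------------------------------------------------------------
# PLINK PED/MAP
# ---------------------------------------------------------------------------

_PED_DOSAGE_TO_ALLELES = {0: ("1", "1"), 1: ("1", "2"), 2: ("2", "2"), MISSING: ("0", "0")}


def write_plink(g: GenotypeMatrix, ped: Pedigree | None, ped_path, map_path) -> None:
    """Write PLINK text PED/MAP.  Alleles coded 1/2, missing ``0 0``."""
    m = g.markers
    with open(map_path, "w") as fh:
        cm = m.genetic_pos_cm()
        for c, mid, gpos, bp in zip(m.chrom, m.ids, cm, m.bp):
            fh.write(f"{c}\t{mid}\t{gpos:g}\t{bp}\n")
    info = {}
    if ped is not None:
        for _, row in ped.table.iterrows():
            sex_code = "1" if row["sex"] == "M" else "2"
            info[str(row["id"])] = (str(row["sire"]), str(row["dam"]), sex_code)
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(g.ids):
            sire, dam, sex = info.get(ind, (UNKNOWN, UNKNOWN, "0"))
            fields = ["FAM", ind, sire, dam, sex, "-9"]
            for d in g.dosages[i]:
                fields.extend(_PED_DOSAGE_TO_ALLELES[int(d)])
            fh.write(" ".join(fields) + "\n")


def read_plink(ped_path, map_path) -> tuple[GenotypeMatrix, MarkerMap, Pedigree]:
    """Read PLINK text PED/MAP into dosages, marker map and pedigree.

    Missing allele code ``0`` maps to the missing dosage; any marker
    showing more than two distinct non-zero allele codes is rejected by
    name, ragged PED lines by line number.
    """
    chroms, ids, cms, bps = [], [], [], []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) not in (3, 4):
                raise FormatError(f"{map_path}: line {lineno}: expected 3-4 columns")
            if len(parts) == 4:
                c, mid, cm, bp = parts
            else:
                c, mid, bp = parts
                cm = "0"
            chroms.append(c)
            ids.append(mid)
            cms.append(float(cm))
            bps.append(int(bp))
    markers = MarkerMap(np.array(chroms, dtype=object), np.array(ids, dtype=object),
                        np.array(bps), np.array(cms))
    m = markers.n_markers

    rows, ind_ids, ped_rows = [], [], []
    # allele codes observed per marker, to detect non-biallelic markers
    alleles: list[set[str]] = [set() for _ in range(m)]
    raw: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise FormatError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * m} fields, "
                    f"got {len(parts)}")
            _fid, iid, sire, dam, sex_code, _pheno = parts[:6]
            ind_ids.append(iid)
            sex = {"1": "M", "2": "F"}.get(sex_code, "M")
            ped_rows.append((iid, sire, dam, sex))
            pairs = [(parts[6 + 2 * k], parts[7 + 2 * k]) for k in range(m)]
            raw.append(pairs)
            for k, (a, b) in enumerate(pairs):
                alleles[k].update(x for x in (a, b) if x != "0")

    for k, seen in enumerate(alleles):
        if len(seen) > 2:
            raise FormatError(
                f"marker {markers.ids[k]!r} is not biallelic: alleles {sorted(seen)}")

    # map the two observed codes to ref(=0 per copy)/alt(=1 per copy); the
    # canonical 1/2 coding keeps its meaning even when one code is unobserved
    code_map = []
    for seen in alleles:
        mapping = {"0": MISSING}
        if seen <= {"1", "2"}:
            mapping.update({"1": 0, "2": 1})
        else:
            for j, code in enumerate(sorted(seen)):
                mapping[code] = j if len(seen) > 1 else 0
        code_map.append(mapping)

    dos = np.full((len(ind_ids), m), MISSING, dtype=np.int8)
    for i, pairs in enumerate(raw):
        for k, (a, b) in enumerate(pairs):
            if a == "0" or b == "0":
                continue
            dos[i, k] = code_map[k][a] + code_map[k][b]

    known = set(ind_ids)
    table = pd.DataFrame(
        [{"id": i, "sire": s if s in known else UNKNOWN,
          "dam": d if d in known else UNKNOWN, "sex": sx, "generation": 0}
         for i, s, d, sx in ped_rows])
    # generation indices consistent with parent links
    for _ in range(len(table)):
        gen = dict(zip(table["id"], table["generation"]))
        changed = False
        for idx, row in table.iterrows():
            g_new = max(
                (gen[p] + 1 for p in (row["sire"], row["dam"]) if p in gen and p != UNKNOWN),
                default=0)
            if g_new > row["generation"]:
                table.at[idx, "generation"] = g_new
                changed = True
        if not changed:
            break
    pedigree = Pedigree(table)
    return GenotypeMatrix(dos, ind_ids, markers), markers, pedigree


# ---------------------------------------------------------------------------
# phased VCF
# ---------------------------------------------------------------------------

def write_vcf_phased(panel: HaplotypePanel, path) -> None:
    """Write a minimal phased VCF (GT only, ``|`` separator)."""
    m = panel.markers
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=cldla\n")
        for c in m.chromosomes():
            length = int(m.bp[m.chrom == c].max()) + 1
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.ids) + "\n")
        h = panel.haps
        for k in range(m.n_markers):
            gts = []
            for i in range(panel.n_individuals):
                a1, a2 = h[2 * i, k], h[2 * i + 1, k]
                gts.append("." if MISSING in (a1, a2) else f"{a1}|{a2}")
            fh.write(f"{m.chrom[k]}\t{m.bp[k]}\t{m.ids[k]}\tA\tG\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")


def read_vcf_phased(vcf_path) -> tuple[HaplotypePanel, MarkerMap]:
    """Read a phased VCF.  Haplotype order is preserved (left allele ->
    haplotype 1).  Unphased or multiallelic records are rejected."""
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    chroms, ids, bps, rows = [], [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise FormatError(
                f"multiallelic record at {rec.CHROM}:{rec.POS} is not supported")
        gts = rec.genotypes  # [a1, a2, phased] per sample
        alleles = np.empty(2 * len(samples), dtype=np.int8)
        for i, gt in enumerate(gts):
            a1, a2, phased = gt[0], gt[1], gt[-1]
            if a1 < 0 or a2 < 0:
                alleles[2 * i] = alleles[2 * i + 1] = MISSING
                continue
            if not phased:
                raise FormatError(
                    f"unphased genotype at {rec.CHROM}:{rec.POS} (sample "
                    f"{samples[i]}); run the phasing stage first")
            alleles[2 * i] = a1
            alleles[2 * i + 1] = a2
        chroms.append(rec.CHROM)
        ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}")
        bps.append(rec.POS)
        rows.append(alleles)
    markers = MarkerMap(np.array(chroms, dtype=object), np.array(ids, dtype=object),
                        np.array(bps))
    haps = np.array(rows, dtype=np.int8).T if rows else np.empty((2 * len(samples), 0),
                                                                 dtype=np.int8)
    return HaplotypePanel(haps, samples, markers), markers


# ---------------------------------------------------------------------------
# phenotype / pedigree tables
# ---------------------------------------------------------------------------

def write_phenotypes(phen: pd.DataFrame, path) -> None:
    phen[["individual_id", "lifespan_days"]].to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    if list(df.columns[:2]) != ["individual_id", "lifespan_days"]:
        raise FormatError(f"{path}: expected columns individual_id, lifespan_days")
    if df["individual_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate individual ids")
    if not np.all(np.isfinite(df["lifespan_days"])) or (df["lifespan_days"] < 0).any():
        raise FormatError(f"{path}: lifespans must be finite and non-negative")
    return df


def write_pedigree(ped: Pedigree, path) -> None:
    ped.table[["id", "sire", "dam", "sex", "xclass", "generation"]].to_csv(
        path, sep="\t", index=False)


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "sire": str, "dam": str})
    df["xclass"] = df["xclass"].where(pd.notna(df["xclass"]), None)
    return Pedigree(df)


# ---------------------------------------------------------------------------
# scan outputs
# ---------------------------------------------------------------------------

def write_scan_outputs(profile, peaks, out_prefix) -> dict[str, str]:
    """Write the per-window LRT table, peak table and JSON run summary.

    Returns the paths written, keyed ``profile``/``peaks``/``summary``.
    """
    if profile.records.empty:
        raise ValueError("cannot write an empty LRT profile")
    out_prefix = str(out_prefix)
    paths = {
        "profile": out_prefix + ".lrt.tsv",
        "peaks": out_prefix + ".peaks.tsv",
        "summary": out_prefix + ".summary.json",
    }
    cols = ["chrom", "window_index", "start_bp", "end_bp", "mid_bp", "n_snps",
            "logL0", "logL1", "lrt", "sig_tier"]
    profile.records[cols].to_csv(paths["profile"], sep="\t", index=False)
    pd.DataFrame(
        [{"chrom": p.chrom, "mid_bp": p.mid_bp, "lrt": p.lrt, "tier": p.tier}
         for p in peaks],
        columns=["chrom", "mid_bp", "lrt", "tier"],
    ).to_csv(paths["peaks"], sep="\t", index=False)
    with open(paths["summary"], "w") as fh:
        json.dump({"thresholds": {"chromosome_wide": profile.thresholds[0],
                                  "genome_wide": profile.thresholds[1]},
                   "n_windows": int(len(profile.records)),
                   "n_peaks": len(peaks),
                   "metadata": profile.metadata}, fh, indent=2, default=str)
    return paths
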