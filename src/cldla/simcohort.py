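"""Synthetic X-linked breeding cohorts.

The generator emulates the statistical structure of a carrier-breeding
colony segregating an X-linked null allele: one heterozygous founder
dam mated to wild-type boars, trio (sire-dam-case) family structure
with carrier daughters recruited as dams in later generations, a dense
biallelic SNP chip dropped through the pedigree with Haldane
recombination, and a lifespan trait (days) carried only by affected
hemizygous males, composed of an additive QTL, a polygenic term and a
residual.

All randomness flows from one root seed; each operation draws from its
own derived stream, so the same configuration reproduces the same
cohort bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genoio import MISSING, GenotypeMatrix, HaplotypePanel, MarkerMap
from .pedigree import (AFFECTED_MALE, CARRIER_FEMALE, NULL_FEMALE, UNKNOWN,
                       WT_FEMALE, WT_MALE, Pedigree)
from .rng import stream

__all__ = [
    "SimConfig",
    "CohortSummary",
    "simulate_pedigree",
    "transmit_x_linked",
    "simulate_haplotypes",
    "simulate_phenotype",
    "inject_missingness",
    "cohort_summary",
    "survival_tally",
    "proportion_pct",
    "make_marker_map",
]


@dataclass(frozen=True)
class QTLSpec:
    chrom: str
    bp: int
    allele_freq: float
    effect_days: float  # additive effect per copy of the causal allele


@dataclass(frozen=True)
class SimConfig:
    """Design of one synthetic cohort.

    Defaults mirror the study colony: ~11.6 piglets per litter, eleven
    founder litters, seven wild-type boars, chip-density markers
    (~1 marker / 50 kb), and a lifespan trait measured in whole days
    for affected males only.
    """

    seed: int = 0
    n_chromosomes: int = 1
    markers_per_chromosome: int = 500
    chromosome_length_bp: int = 25_000_000
    founder_allele_freq_bounds: tuple[float, float] = (0.05, 0.95)
    n_sires: int = 7
    n_litters: int = 11
    litter_size_mean: float = 11.6
    qtl: QTLSpec | None = None
    var_polygenic: float = 400.0
    var_residual: float = 625.0
    mean_lifespan: float = 60.0
    missing_rate: float = 0.0
    genotype_error_rate: float = 0.0
    # breeding-programme shape beyond the founder litters
    n_cases_target: int | None = None
    litters_per_dam: int = 2
    max_generations: int = 4
    # polygenic gene dropping: number of hidden unlinked loci
    n_polygenic_loci: int = 400
    cm_per_mbp: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.founder_allele_freq_bounds
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("founder allele-frequency bounds must lie in (0,1)")
        for name in ("missing_rate", "genotype_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("var_polygenic", "var_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.qtl is not None:
            chroms = {f"{c + 1}" for c in range(self.n_chromosomes)}
            if self.qtl.chrom not in chroms:
                raise ValueError(
                    f"QTL chromosome {self.qtl.chrom!r} is not one of the "
                    f"declared chromosomes {sorted(chroms)}")
            if not 0 < self.qtl.allele_freq < 1:
                raise ValueError("QTL allele frequency must be in (0,1)")


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def _offspring_class(rng: np.random.Generator, dam_class: str, sire_class: str) -> str:
    """Sample an offspring X-genotype class (each outcome probability 1/4).

    Carrier dam x wild-type sire: WT male / affected male / WT female /
    carrier female.  Carrier dam x affected sire: WT male / affected
    male / carrier female / homozygous-null female.
    """
    if dam_class != CARRIER_FEMALE:
        raise ValueError(f"dam class {dam_class!r} not supported (carrier required)")
    if sire_class == WT_MALE:
        classes = (WT_MALE, AFFECTED_MALE, WT_FEMALE, CARRIER_FEMALE)
    elif sire_class == AFFECTED_MALE:
        classes = (WT_MALE, AFFECTED_MALE, CARRIER_FEMALE, NULL_FEMALE)
    else:
        raise ValueError(f"sire class {sire_class!r} not supported")
    return classes[rng.integers(4)]


def transmit_x_linked(ped: Pedigree, seed: int) -> Pedigree:
    """Fill X-genotype classes of all non-founders by Mendelian draw.

    Founder classes must already be set; offspring classes are sampled
    per individual given the parents' classes (probability 1/4 each for
    the four possible outcomes of a carrier dam).
    """
    rng = stream(seed, "transmit_x_linked")
    tab = ped.table.copy()
    classes = dict(zip(tab["id"].astype(str), tab["xclass"]))
    for idx, row in tab.sort_values(["generation", "id"], kind="stable").iterrows():
        s, d = str(row["sire"]), str(row["dam"])
        if s == UNKNOWN and d == UNKNOWN:
            if classes[str(row["id"])] is None:
                raise ValueError(f"founder {row['id']!r} has no X-genotype class")
            continue
        if classes.get(s) is None or classes.get(d) is None:
            raise ValueError(f"offspring {row['id']!r} has a parent without a class")
        xc = _offspring_class(rng, classes[d], classes[s])
        classes[str(row["id"])] = xc
        tab.at[idx, "xclass"] = xc
    sex = {WT_MALE: "M", AFFECTED_MALE: "M"}
    tab["sex"] = [sex.get(c, "F") for c in tab["xclass"]]
    return Pedigree(tab)


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Breed a cohort: founder carrier dam x wild-type boars, then
    carrier daughters recruited as dams until ``n_litters`` litters (or
    ``n_cases_target`` affected males) have been produced.

    X-genotype classes are drawn during breeding because recruitment
    depends on which daughters are carriers; the transmission law is
    the same one :func:`transmit_x_linked` applies.
    """
    if config.n_litters < 1 or config.n_sires < 1:
        raise ValueError("cannot breed an empty cohort: need >=1 sire and >=1 litter")
    rng_struct = stream(config.seed, "pedigree")
    rng_class = stream(config.seed, "transmit_x_linked")

    rows: list[dict] = []
    founder_dam = "DAM0"
    rows.append({"id": founder_dam, "sire": UNKNOWN, "dam": UNKNOWN, "sex": "F",
                 "xclass": CARRIER_FEMALE, "generation": 0})
    sires = [f"SIRE{j + 1}" for j in range(config.n_sires)]
    for s in sires:
        rows.append({"id": s, "sire": UNKNOWN, "dam": UNKNOWN, "sex": "M",
                     "xclass": WT_MALE, "generation": 0})

    n_cases = 0
    n_litter_total = 0
    counter = 0
    # dams available per generation; founder carries the whole first round
    dam_pool = [(founder_dam, 0)]
    done = False
    for gen_round in range(config.max_generations):
        if done or not dam_pool:
            break
        next_pool: list[tuple[str, int]] = []
        litters_this_dam = (config.n_litters if gen_round == 0
                            else config.litters_per_dam)
        for dam, dam_gen in dam_pool:
            dam_sire = next((r["sire"] for r in rows if r["id"] == dam), UNKNOWN)
            for _ in range(litters_this_dam):
                if done:
                    break
                sire = sires[n_litter_total % len(sires)]
                if sire == dam_sire and len(sires) > 1:  # no sire-daughter mating
                    sire = sires[(n_litter_total + 1) % len(sires)]
                n_litter_total += 1
                size = max(1, rng_struct.poisson(config.litter_size_mean))
                for _ in range(size):
                    counter += 1
                    cid = f"IND{counter:05d}"
                    xc = _offspring_class(rng_class, CARRIER_FEMALE, WT_MALE)
                    rows.append({"id": cid, "sire": sire, "dam": dam,
                                 "sex": "M" if xc in (WT_MALE, AFFECTED_MALE) else "F",
                                 "xclass": xc, "generation": dam_gen + 1})
                    if xc == AFFECTED_MALE:
                        n_cases += 1
                    elif xc == CARRIER_FEMALE:
                        next_pool.append((cid, dam_gen + 1))
                    if (config.n_cases_target is not None
                            and n_cases >= config.n_cases_target):
                        done = True
                if config.n_cases_target is None and n_litter_total >= config.n_litters:
                    done = True
                    break
            if done:
                break
        dam_pool = next_pool
    if config.n_cases_target is not None and n_cases < config.n_cases_target:
        raise ValueError(
            f"breeding programme exhausted at {n_cases} cases "
            f"(target {config.n_cases_target}); increase litters or generations")
    return Pedigree(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# haplotypes
# ---------------------------------------------------------------------------

def make_marker_map(config: SimConfig) -> MarkerMap:
    """Evenly spaced chip-like marker map over the declared autosomes."""
    chroms, ids, bps = [], [], []
    spacing = config.chromosome_length_bp / config.markers_per_chromosome
    for c in range(config.n_chromosomes):
        name = f"{c + 1}"
        for k in range(config.markers_per_chromosome):
            chroms.append(name)
            ids.append(f"snp_{name}_{k + 1}")
            bps.append(int(round((k + 1) * spacing)))
    return MarkerMap(np.array(chroms, dtype=object), np.array(ids, dtype=object),
                     np.array(bps))


def _meiosis(rng: np.random.Generator, h1: np.ndarray, h2: np.ndarray,
             pos_cm: np.ndarray, length_cm: float) -> np.ndarray:
    """One gamete: crossovers as a Poisson process along the genetic map
    (Haldane model, no interference)."""
    n_x = rng.poisson(length_cm / 100.0)
    start = rng.integers(2)
    if n_x == 0:
        return h1 if start == 0 else h2
    breaks = np.sort(rng.uniform(0.0, length_cm, size=n_x))
    phase = (start + np.searchsorted(breaks, pos_cm, side="right")) % 2
    return np.where(phase == 0, h1, h2)


def simulate_haplotypes(ped: Pedigree, markers: MarkerMap,
                        config: SimConfig) -> HaplotypePanel:
    """Gene-drop chip haplotypes through the pedigree.

    Founder haplotypes are i.i.d. per marker with frequencies drawn from
    the configured uniform law (the causal QTL marker, if any, gets its
    configured frequency); non-founder haplotypes are recombinant
    parental gametes.  Haplotype 1 is always the paternal gamete.
    """
    rng_freq = stream(config.seed, "founder_freqs")
    rng_fh = stream(config.seed, "founder_haps")
    rng_drop = stream(config.seed, "gene_drop")

    m = markers.n_markers
    lo, hi = config.founder_allele_freq_bounds
    freqs = rng_freq.uniform(lo, hi, size=m)
    qtl_idx = None
    if config.qtl is not None:
        qtl_idx = qtl_marker_index(markers, config.qtl)
        freqs[qtl_idx] = config.qtl.allele_freq

    order = ped.in_order()
    ids = [str(i) for i in order["id"]]
    row_of = {ind: k for k, ind in enumerate(ids)}
    haps = np.zeros((2 * len(ids), m), dtype=np.int8)

    # per-chromosome slices and genetic positions
    chrom_slices = []
    for c in markers.chromosomes():
        idx = np.where(markers.chrom == c)[0]
        pos_cm = markers.bp[idx] / 1e6 * config.cm_per_mbp
        pos_cm = pos_cm - pos_cm[0]
        length_cm = float(pos_cm[-1]) if len(pos_cm) > 1 else 1.0
        chrom_slices.append((idx, pos_cm, length_cm))

    for _, rec in order.iterrows():
        ind = str(rec["id"])
        k = row_of[ind]
        s, d = str(rec["sire"]), str(rec["dam"])
        if s == UNKNOWN and d == UNKNOWN:
            haps[2 * k] = (rng_fh.random(m) < freqs).astype(np.int8)
            haps[2 * k + 1] = (rng_fh.random(m) < freqs).astype(np.int8)
            continue
        if s == UNKNOWN or d == UNKNOWN:
            raise ValueError(f"individual {ind!r} has exactly one known parent; "
                             "gene dropping requires both or neither")
        for parent, hap_row in ((s, 2 * k), (d, 2 * k + 1)):
            pk = row_of.get(parent)
            if pk is None or pk >= k:
                raise ValueError(f"pedigree order violation: parent {parent!r} "
                                 f"does not precede {ind!r}")
            for idx, pos_cm, length_cm in chrom_slices:
                gamete = _meiosis(rng_drop, haps[2 * pk][idx], haps[2 * pk + 1][idx],
                                  pos_cm, length_cm)
                haps[hap_row][idx] = gamete
    return HaplotypePanel(haps, ids, markers)


def qtl_marker_index(markers: MarkerMap, qtl: QTLSpec) -> int:
    """Index of the marker closest to the configured QTL position."""
    idx = np.where(markers.chrom == qtl.chrom)[0]
    if len(idx) == 0:
        raise ValueError(f"QTL chromosome {qtl.chrom!r} has no markers")
    return int(idx[np.argmin(np.abs(markers.bp[idx] - qtl.bp))])


# ---------------------------------------------------------------------------
# phenotype
# ---------------------------------------------------------------------------

def _polygenic_gene_drop(ped: Pedigree, config: SimConfig) -> dict[str, float]:
    """Polygenic deviates by gene dropping many small-effect unlinked
    loci, so pedigree and genomic kinship agree by construction.

    Each hidden locus is biallelic at frequency 1/2 with effect
    ±b chosen so the marginal variance equals ``var_polygenic``.
    """
    if config.var_polygenic == 0 or config.n_polygenic_loci == 0:
        return {str(i): 0.0 for i in ped.table["id"]}
    rng = stream(config.seed, "polygenic")
    L = config.n_polygenic_loci
    # Var(g) = sum_k b^2 * 2 p q with p = 1/2  ->  b = sqrt(2 Vg / L)
    b = math.sqrt(2.0 * config.var_polygenic / L)
    signs = np.where(np.arange(L) % 2 == 0, b, -b)
    order = ped.in_order()
    geno: dict[str, np.ndarray] = {}
    g: dict[str, float] = {}
    for _, rec in order.iterrows():
        ind = str(rec["id"])
        s, d = str(rec["sire"]), str(rec["dam"])
        if s == UNKNOWN and d == UNKNOWN:
            alleles = (rng.random((2, L)) < 0.5).astype(np.int8)
        else:
            alleles = np.empty((2, L), dtype=np.int8)
            for j, parent in enumerate((s, d)):
                ph = geno[parent]
                pick = rng.integers(2, size=L)
                alleles[j] = ph[pick, np.arange(L)]
        geno[ind] = alleles
        dosage = alleles.sum(axis=0)
        g[ind] = float(np.dot(signs, dosage - 1.0))  # centered at 2p = 1
    return g


def simulate_phenotype(ped: Pedigree, panel: HaplotypePanel, config: SimConfig,
                       return_components: bool = False):
    """Lifespans (whole days, floored at 0) for affected males only.

    lifespan_i = mean + a * x_i + g_i + e_i with x_i the causal-allele
    dosage at the QTL marker, g a gene-dropped polygenic deviate and e
    i.i.d. residual noise.
    """
    if config.var_polygenic < 0 or config.var_residual < 0:
        raise ValueError("variances must be non-negative")
    cases = [c for c in ped.cases() if c in set(panel.ids)]
    rng = stream(config.seed, "residual")
    g = _polygenic_gene_drop(ped, config)

    if config.qtl is not None:
        qi = qtl_marker_index(panel.markers, config.qtl)
        sub = panel.subset_individuals(cases)
        x = sub.haps[0::2, qi].astype(float) + sub.haps[1::2, qi].astype(float)
        a = config.qtl.effect_days
    else:
        x = np.zeros(len(cases))
        a = 0.0

    gi = np.array([g[c] for c in cases])
    e = rng.normal(0.0, math.sqrt(config.var_residual), size=len(cases))
    raw = config.mean_lifespan + a * x + gi + e
    lifespan = np.maximum(0.0, np.round(raw))
    phen = pd.DataFrame({"individual_id": cases, "lifespan_days": lifespan})
    if return_components:
        comps = pd.DataFrame({"individual_id": cases, "qtl_dosage": x,
                              "polygenic": gi, "residual": e})
        return phen, comps
    return phen


# ---------------------------------------------------------------------------
# missingness / genotyping error
# ---------------------------------------------------------------------------

def inject_missingness(panel: HaplotypePanel, config: SimConfig) -> GenotypeMatrix:
    """Collapse haplotypes to unphased dosages, then mask genotypes at
    ``missing_rate`` and perturb dosages by ±1 at ``genotype_error_rate``."""
    rng = stream(config.seed, "missingness")
    g = panel.dosages()
    d = g.dosages.astype(np.int8).copy()
    shape = d.shape
    if config.genotype_error_rate > 0:
        err = rng.random(shape) < config.genotype_error_rate
        shift = np.where(rng.random(shape) < 0.5, -1, 1).astype(np.int8)
        moved = np.clip(d + shift, 0, 2).astype(np.int8)
        # a dosage pinned at its boundary moves inward
        moved = np.where(moved == d, np.clip(d - shift, 0, 2), moved).astype(np.int8)
        d = np.where(err & (d != MISSING), moved, d).astype(np.int8)
    if config.missing_rate > 0:
        mask = rng.random(shape) < config.missing_rate
        d = np.where(mask, np.int8(MISSING), d)
    return GenotypeMatrix(d, list(panel.ids), panel.markers)


# ---------------------------------------------------------------------------
# cohort summaries
# ---------------------------------------------------------------------------

def proportion_pct(count: int, total: int) -> int:
    """Integer percentage, rounded half away from zero."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(math.floor(100.0 * count / total + 0.5))


def survival_tally(lifespans, class_edges=(7, 30, 150)) -> list[int]:
    """Counts per survival class: died before each edge, then beyond.

    Default edges 7/30/150 days: died in the first week, died within
    the first month, survived one to five months, survived longer.
    """
    edges = list(class_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("class edges must be strictly increasing")
    values = np.asarray(lifespans, dtype=float)
    if values.size == 0:
        raise ValueError("empty case set")
    bins = np.concatenate(([-np.inf], edges, [np.inf]))
    counts, _ = np.histogram(values, bins=bins)
    return [int(c) for c in counts]


@dataclass
class CohortSummary:
    """Genotype-class counts plus survival-class tallies of the cases."""

    genotype_counts: dict[str, int]
    survival_counts: list[int]
    class_edges: tuple[int, ...]
    total_cases: int

    def __post_init__(self) -> None:
        if sum(self.survival_counts) != self.total_cases:
            raise ValueError("survival tallies must sum to the case total")

    @property
    def total_offspring(self) -> int:
        return sum(self.genotype_counts.values())

    def survival_percentages(self) -> list[int]:
        return [proportion_pct(c, self.total_cases) for c in self.survival_counts]


def cohort_summary(ped: Pedigree, phen: pd.DataFrame,
                   class_edges=(7, 30, 150)) -> CohortSummary:
    """Tally cases into survival classes and offspring into X-genotype
    classes, with integer percentages rounded half away from zero."""
    if phen.empty:
        raise ValueError("empty case set")
    counts = survival_tally(phen["lifespan_days"].to_numpy(), class_edges)
    non_founder = ped.table[(ped.table["sire"].astype(str) != UNKNOWN)
                            | (ped.table["dam"].astype(str) != UNKNOWN)]
    geno = {c: int((non_founder["xclass"] == c).sum())
            for c in non_founder["xclass"].dropna().unique()}
    return CohortSummary(geno, counts, tuple(class_edges), int(len(phen)))
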