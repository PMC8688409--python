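"""End-to-end simulation experiments over the scan pipeline.

These are the study-condition runs the package's calibration claims
rest on: a no-QTL null calibration of the per-window type-I error at
the chromosome-wide critical value, and a planted-QTL localisation
experiment.  Both build each cohort from scratch (pedigree, gene-
dropped haplotypes, phenotype), construct the genomic relationship
matrix from the cohort's own chip dosages, and run the window scan.

Problem sizes are chosen to exercise the whole pipeline at desk scale:
chip-like marker density (~1 SNP / 50 kb), cohorts of 60 cases for the
null and 300 cases for localisation, windows thinned along the
chromosome so replicate cohorts (fresh seeds) rather than overlapping
windows carry the statistical weight.
"""

from __future__ import annotations

import numpy as np

from .kinship import condition_psd, vanraden_grm
from .scan import DEFAULT_THRESHOLDS, call_peaks, scan_genome
from .simcohort import (QTLSpec, SimConfig, make_marker_map, simulate_haplotypes,
                        simulate_pedigree, simulate_phenotype)

__all__ = ["simulate_and_scan", "null_calibration", "localization_experiment"]


def _derived_seed(root_seed: int, k: int) -> int:
    return (int(root_seed) * 10_007 + 17 * k + 1) % (2**31 - 1)


def simulate_and_scan(config: SimConfig, W: int = 40, step: int = 1,
                      thresholds=DEFAULT_THRESHOLDS):
    """Simulate one cohort and scan it; returns (profile, config, truth).

    The scan runs on the simulator's true phased panel (QC and phasing
    have their own dedicated checks); the polygenic G is the VanRaden
    matrix of the cases' chip dosages with in-sample frequencies.
    """
    ped = simulate_pedigree(config)
    markers = make_marker_map(config)
    panel = simulate_haplotypes(ped, markers, config)
    phen = simulate_phenotype(ped, panel, config)
    if config.n_cases_target is not None:
        phen = phen.iloc[:config.n_cases_target].reset_index(drop=True)
    cases = [str(i) for i in phen["individual_id"]]
    case_panel = panel.subset_individuals(cases)
    G = condition_psd(vanraden_grm(case_panel.dosages()))
    profile = scan_genome(case_panel, G, phen, W=W, step=step,
                          thresholds=thresholds,
                          metadata={"seed": config.seed, "n_cases": len(cases)})
    return profile, ped, panel, phen


def null_calibration(seed: int, n_cohorts: int = 48, n_cases: int = 60,
                     markers_per_chromosome: int = 2530, n_chromosomes: int = 2,
                     step: int = 10, critical_value: float = 11.0):
    """Empirical fraction of null-scan windows with LRT above the
    chromosome-wide critical value.

    Cohorts carry polygenic and residual variance but no QTL, so every
    exceedance is a false positive.  Windows are thinned (``step``) and
    exceedances accumulated over ``n_cohorts`` independently seeded
    cohorts.
    """
    n_windows = 0
    n_exceed = 0
    n_failed = 0
    values = []
    for k in range(n_cohorts):
        config = SimConfig(
            seed=_derived_seed(seed, k),
            n_chromosomes=n_chromosomes,
            markers_per_chromosome=markers_per_chromosome,
            chromosome_length_bp=int(markers_per_chromosome * 50_000),
            n_cases_target=n_cases,
            n_litters=8, litters_per_dam=2, max_generations=6,
            qtl=None,
        )
        profile, *_ = simulate_and_scan(config, W=40, step=step)
        ok = profile.records.dropna(subset=["lrt"])
        n_failed += int(profile.records["failed"].sum())
        n_windows += len(ok)
        n_exceed += int((ok["lrt"] > critical_value).sum())
        values.append(ok["lrt"].to_numpy())
    fraction = n_exceed / n_windows if n_windows else float("nan")
    return {"fraction": fraction, "n_windows": n_windows, "n_exceed": n_exceed,
            "n_failed": n_failed, "critical_value": critical_value,
            "lrt_values": np.concatenate(values) if values else np.empty(0)}


def localization_experiment(seed: int, n_reps: int = 25, n_cases: int = 300,
                            effect_sd: float = 0.5, step: int = 10,
                            markers_per_chromosome: int = 800,
                            chromosome_length_bp: int = 40_000_000,
                            qtl_freq: float = 0.5, tolerance_bp: float = 2e6):
    """Fraction of replicates whose maximum-LRT window midpoint falls
    within ``tolerance_bp`` of a planted QTL of ``effect_sd`` phenotypic
    standard deviations per allele copy.

    The planted variant is common (frequency 0.5): with i.i.d. founder
    haplotypes all mapping information is pedigree sharing, which a
    balanced allele maximises.
    """
    base = SimConfig()
    pheno_sd = float(np.sqrt(base.var_polygenic + base.var_residual))
    effect = effect_sd * pheno_sd
    qtl_bp = chromosome_length_bp // 2
    hits = 0
    errors_bp = []
    peak_lrts = []
    for k in range(n_reps):
        config = SimConfig(
            seed=_derived_seed(seed, 1000 + k),
            n_chromosomes=1,
            markers_per_chromosome=markers_per_chromosome,
            chromosome_length_bp=chromosome_length_bp,
            n_cases_target=n_cases,
            n_litters=8, litters_per_dam=2, max_generations=10,
            qtl=QTLSpec(chrom="1", bp=qtl_bp, allele_freq=qtl_freq,
                        effect_days=effect),
        )
        profile, *_ = simulate_and_scan(config, W=40, step=step)
        ok = profile.records.dropna(subset=["lrt"])
        best = ok.loc[ok["lrt"].idxmax()]
        err = abs(float(best["mid_bp"]) - qtl_bp)
        errors_bp.append(err)
        peak_lrts.append(float(best["lrt"]))
        if err <= tolerance_bp:
            hits += 1
    return {"hit_rate": hits / n_reps, "n_reps": n_reps,
            "errors_bp": errors_bp, "peak_lrts": peak_lrts,
            "qtl_bp": qtl_bp, "effect_days": effect}
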