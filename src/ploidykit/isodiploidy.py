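"""Screening 46,XX diploid embryos for recombinant maternal isodiploidy.

A recombinant isodiploid inherits two maternal sister-chromatid-derived
chromosome sets and no paternal genome: pericentromeric regions are
homozygous (sisters are identical at the centromere after an MII failure),
while crossovers during prophase I leave distal heterozygous segments. The
screen therefore looks for samples with (a) a total heterozygous-SNP
fraction (BAF in [0.1, 0.9], autosomes + X) below the cohort average and
(b) a pericentromeric het fraction (sites within 10 Mb of a centromere)
significantly below both the cohort's average rate and the sample's own
overall rate. Fingerprint similarity against the father then confirms the
loss of one parental genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calls import NO_CALL
from .genome import GenomeSpec, pericentromeric_mask

__all__ = [
    "HetFractionSummary",
    "IsodiploidyFlag",
    "het_fractions",
    "screen_isodiploidy",
    "confirm_pericentromeric_loh",
    "fingerprint_similarity",
]

HET_BAF = (0.1, 0.9)


@dataclass
class HetFractionSummary:
    """Total and pericentromeric heterozygosity of one sample."""

    sample: str
    total_het: int
    total_sites: int
    peri_het: int
    peri_sites: int

    @property
    def total_het_fraction(self) -> float:
        return self.total_het / self.total_sites if self.total_sites else np.nan

    @property
    def peri_het_fraction(self) -> float:
        return self.peri_het / self.peri_sites if self.peri_sites else np.nan


@dataclass
class IsodiploidyFlag:
    sample: str
    screened: bool
    below_cohort_mean: bool
    p_vs_cohort: float
    p_vs_self: float
    confirmed: bool | None = None
    reason: str = ""


def het_fractions(
    sample: str,
    chrom: np.ndarray,
    pos: np.ndarray,
    baf: np.ndarray,
    spec: GenomeSpec,
    radius_bp: int = 10_000_000,
    min_sites: int = 100,
    min_peri_sites: int = 10,
) -> HetFractionSummary:
    """Het fractions over all usable sites and the pericentromeric subset.

    Heterozygous means BAF in [0.1, 0.9]; the pericentromeric subset is
    within ``radius_bp`` (physical distance) of a centromere. Autosomes and
    X are both eligible — pass pre-filtered arrays.
    """
    baf = np.asarray(baf, dtype=float)
    ok = np.isfinite(baf)
    chrom, pos, baf = np.asarray(chrom)[ok], np.asarray(pos)[ok], baf[ok]
    if baf.size < min_sites:
        raise ValueError(f"{sample}: fewer than {min_sites} usable sites")
    het = (baf >= HET_BAF[0]) & (baf <= HET_BAF[1])
    peri = pericentromeric_mask(spec, chrom, pos, radius_bp, metric="bp")
    summary = HetFractionSummary(
        sample=sample,
        total_het=int(het.sum()),
        total_sites=int(baf.size),
        peri_het=int((het & peri).sum()),
        peri_sites=int(peri.sum()),
    )
    if summary.peri_sites < min_peri_sites:
        raise ValueError(f"{sample}: fewer than {min_peri_sites} pericentromeric sites")
    return summary


def screen_isodiploidy(
    summaries: list[HetFractionSummary],
    alpha: float = 0.05,
    min_cohort: int = 20,
) -> list[IsodiploidyFlag]:
    """Flag candidate recombinant isodiploids against the cohort.

    A sample screens positive when its total het fraction is below the
    cohort mean AND one-sided exact binomial tests reject (at ``alpha``)
    that its pericentromeric het count is as high as (i) the cohort's mean
    pericentromeric rate and (ii) the sample's own total het fraction.
    """
    if len(summaries) < min_cohort:
        raise ValueError(f"cohort smaller than {min_cohort} samples")
    totals = np.array([s.total_het_fraction for s in summaries])
    peris = np.array([s.peri_het_fraction for s in summaries])
    mean_total = float(np.nanmean(totals))
    mean_peri = float(np.nanmean(peris))
    if np.allclose(totals, totals[0]) and np.allclose(peris, peris[0]):
        return [
            IsodiploidyFlag(s.sample, False, False, 1.0, 1.0, reason="degenerate cohort")
            for s in summaries
        ]

    flags = []
    for s in summaries:
        below = s.total_het_fraction < mean_total
        p_cohort = stats.binomtest(
            s.peri_het, s.peri_sites, min(max(mean_peri, 0.0), 1.0), alternative="less"
        ).pvalue
        p_self = stats.binomtest(
            s.peri_het, s.peri_sites, s.total_het_fraction, alternative="less"
        ).pvalue
        flags.append(
            IsodiploidyFlag(
                sample=s.sample,
                screened=bool(below and p_cohort < alpha and p_self < alpha),
                below_cohort_mean=bool(below),
                p_vs_cohort=float(p_cohort),
                p_vs_self=float(p_self),
            )
        )
    return flags


def confirm_pericentromeric_loh(
    chrom: np.ndarray,
    pos: np.ndarray,
    baf: np.ndarray,
    spec: GenomeSpec,
    radius_bp: int = 10_000_000,
    min_run: int = 10,
    min_chromosomes: int = 20,
) -> bool:
    """Automatic stand-in for expert review of the PGT plots: require a run
    of >= ``min_run`` consecutive homozygous pericentromeric SNPs on >=
    ``min_chromosomes`` chromosomes."""
    baf = np.asarray(baf, dtype=float)
    het = (baf >= HET_BAF[0]) & (baf <= HET_BAF[1])
    peri = pericentromeric_mask(spec, chrom, pos, radius_bp, metric="bp")
    n_ok = 0
    for name in np.unique(np.asarray(chrom)):
        sel = (np.asarray(chrom) == name) & peri
        h = het[sel]
        run = best = 0
        for v in h:
            run = 0 if v else run + 1
            best = max(best, run)
        if best >= min_run:
            n_ok += 1
    return n_ok >= min_chromosomes


def fingerprint_similarity(
    calls_a: np.ndarray,
    calls_b: np.ndarray,
    min_shared: int = 100,
    parent_offspring_min: float = 0.95,
    identical_min: float = 0.99,
) -> tuple[float, str, int]:
    """Allele-sharing fingerprint between two samples.

    Inputs are diploid alt-dosage calls (0/1/2, -1 = no-call) over a shared
    panel. Similarity = fraction of co-called sites whose genotype pair
    shares at least one allele (opposite homozygotes share none; a true
    parent-offspring pair shares an allele everywhere up to call error).
    Returns (similarity, verdict, n shared sites).
    """
    a = np.asarray(calls_a)
    b = np.asarray(calls_b)
    use = (a != NO_CALL) & (b != NO_CALL)
    n = int(use.sum())
    if n < min_shared:
        raise ValueError(f"fewer than {min_shared} co-called sites")
    opposite = ((a[use] == 0) & (b[use] == 2)) | ((a[use] == 2) & (b[use] == 0))
    sim = 1.0 - float(opposite.mean())
    ident = float((a[use] == b[use]).mean())
    if ident >= identical_min:
        verdict = "identical-like"
    elif sim >= parent_offspring_min:
        verdict = "parent-offspring-like"
    else:
        verdict = "unrelated-like"
    return sim, verdict, n
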