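"""Genotype calling from read evidence, site filters, and ploidy classification.

B-allele-frequency (BAF) thresholds follow the clinical pipeline the data
emulate: diploid calls use hom-ref < 0.05, het 0.2-0.8, hom-alt > 0.95 with
explicit no-call gaps; triploid dosage calls use bands centred on the 1/3
and 2/3 allele-ratio modes. Site filters: biallelic SNP, depth strictly
greater than 20x, autosomal, and (where configured) BAF within 5-95 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeSpec, pericentromeric_mask
from .simulate import SimulatedTrio

__all__ = [
    "DiploidThresholds",
    "TriploidBands",
    "SiteFilters",
    "TrioGenotypes",
    "PloidyCall",
    "call_diploid_genotype",
    "call_triploid_dosage",
    "call_haploid_genotype",
    "build_trio_genotypes",
    "filter_sites",
    "classify_sample_ploidy",
]

NO_CALL = -1


@dataclass(frozen=True)
class DiploidThresholds:
    hom_ref_max: float = 0.05
    het_min: float = 0.2
    het_max: float = 0.8
    hom_alt_min: float = 0.95

    def __post_init__(self):
        if not (0 <= self.hom_ref_max <= self.het_min <= self.het_max <= self.hom_alt_min <= 1):
            raise ValueError("diploid BAF thresholds must be ordered within [0, 1]")


@dataclass(frozen=True)
class TriploidBands:
    """BAF bands for AAA/AAB/ABB/BBB (alt dosage 0..3); gaps -> no-call."""

    bands: tuple = ((0.0, 0.10), (0.20, 0.45), (0.55, 0.80), (0.90, 1.0))

    def __post_init__(self):
        flat = [x for b in self.bands for x in b]
        if sorted(flat) != list(flat):
            raise ValueError("triploid BAF bands overlap or are unordered")


def _check_baf(baf: np.ndarray) -> np.ndarray:
    baf = np.asarray(baf, dtype=float)
    if np.any((baf < 0) | (baf > 1) | ~np.isfinite(baf)):
        raise ValueError("BAF outside [0, 1]")
    return baf


def call_diploid_genotype(baf, thresholds: DiploidThresholds | None = None) -> np.ndarray:
    """Alt dosage (0/1/2) per site from diploid BAF; -1 = no-call gap."""
    t = thresholds or DiploidThresholds()
    baf = _check_baf(baf)
    out = np.full(baf.shape, NO_CALL, dtype=np.int8)
    out[baf < t.hom_ref_max] = 0
    out[(baf >= t.het_min) & (baf <= t.het_max)] = 1
    out[baf > t.hom_alt_min] = 2
    return out


def call_triploid_dosage(baf, bands: TriploidBands | None = None) -> np.ndarray:
    """Alt dosage (0..3 = AAA/AAB/ABB/BBB) from triploid BAF; -1 = no-call."""
    b = bands or TriploidBands()
    baf = _check_baf(baf)
    out = np.full(baf.shape, NO_CALL, dtype=np.int8)
    for dosage, (lo, hi) in enumerate(b.bands):
        if dosage == 0:
            sel = (baf >= lo) & (baf < hi)
        elif dosage == 3:
            sel = (baf > lo) & (baf <= hi)
        else:
            sel = (baf > lo) & (baf < hi)
        out[sel] = dosage
    return out


def call_haploid_genotype(baf, thresholds: DiploidThresholds | None = None) -> np.ndarray:
    """Alt dosage (0/1) for a haploid sample; heterozygous-looking BAF -> no-call."""
    t = thresholds or DiploidThresholds()
    baf = _check_baf(baf)
    out = np.full(baf.shape, NO_CALL, dtype=np.int8)
    out[baf < t.hom_ref_max] = 0
    out[baf > t.hom_alt_min] = 1
    return out


@dataclass(frozen=True)
class SiteFilters:
    """The clinical site filters; ``embryo_baf_window`` applies the 5-95 %
    embryo-BAF restriction (used for heterozygosity fractions, off for trio
    concordance where homozygous embryo calls are required evidence)."""

    min_depth: int = 20  # strict: depth must exceed this
    autosomes_only: bool = True
    biallelic_only: bool = True
    embryo_baf_window: tuple | None = None  # e.g. (0.05, 0.95)


@dataclass
class TrioGenotypes:
    """Aligned embryo/mother/father calls over the panel with filter flags."""

    sites: pd.DataFrame  # chrom,pos,ref,alt + baf_*/call_* + pass_filters + reasons
    embryo_ploidy: int
    truth: SimulatedTrio | None = None

    def passing(self) -> pd.DataFrame:
        return self.sites[self.sites["pass_filters"]]


def _baf(alt, depth) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(depth > 0, alt / np.maximum(depth, 1), np.nan)


def build_trio_genotypes(
    sim: SimulatedTrio,
    spec: GenomeSpec,
    filters: SiteFilters | None = None,
    pericentromeric_cm: float = 5.0,
) -> TrioGenotypes:
    """Call a simulated (or file-loaded) trio and attach filter flags.

    Parents are called with the diploid scheme; the embryo with the scheme
    matching its ploidy. BAF with zero depth is treated as missing.
    """
    df = sim.sites_frame().copy()
    for who in ("embryo", "mother", "father"):
        df[f"baf_{who}"] = _baf(df[f"alt_{who}"].to_numpy(), df[f"depth_{who}"].to_numpy())
    safe = {c: df[c].fillna(0.0).to_numpy() for c in ("baf_embryo", "baf_mother", "baf_father")}
    df["call_mother"] = call_diploid_genotype(safe["baf_mother"])
    df["call_father"] = call_diploid_genotype(safe["baf_father"])
    if sim.ploidy == 3:
        df["call_embryo"] = call_triploid_dosage(safe["baf_embryo"])
    elif sim.ploidy == 1:
        df["call_embryo"] = call_haploid_genotype(safe["baf_embryo"])
    else:
        df["call_embryo"] = call_diploid_genotype(safe["baf_embryo"])
    for who in ("embryo", "mother", "father"):
        df.loc[df[f"depth_{who}"] == 0, f"call_{who}"] = NO_CALL

    df["pericentromeric"] = pericentromeric_mask(
        spec, df["chrom"].to_numpy(), df["pos"].to_numpy(), pericentromeric_cm, "cM"
    )
    trio = TrioGenotypes(df, embryo_ploidy=sim.ploidy, truth=sim)
    return filter_sites(trio, spec, filters or SiteFilters())


def filter_sites(trio: TrioGenotypes, spec: GenomeSpec, filters: SiteFilters) -> TrioGenotypes:
    """Flag each site pass/fail with reason codes (semicolon-joined)."""
    df = trio.sites
    n = len(df)
    reasons = [[] for _ in range(n)]
    ok = np.ones(n, dtype=bool)

    if filters.biallelic_only and "biallelic" in df.columns:
        bad = ~df["biallelic"].to_numpy(dtype=bool)
        ok &= ~bad
        for i in np.flatnonzero(bad):
            reasons[i].append("not_biallelic")
    for who in ("embryo", "mother", "father"):
        bad = df[f"depth_{who}"].to_numpy() <= filters.min_depth
        ok &= ~bad
        for i in np.flatnonzero(bad):
            reasons[i].append(f"low_depth_{who}")
    if filters.autosomes_only:
        auto = {c.name for c in spec.autosomes}
        bad = ~df["chrom"].isin(auto).to_numpy()
        ok &= ~bad
        for i in np.flatnonzero(bad):
            reasons[i].append("not_autosome")
    if filters.embryo_baf_window is not None:
        lo, hi = filters.embryo_baf_window
        baf = df["baf_embryo"].to_numpy()
        bad = ~((baf >= lo) & (baf <= hi))
        ok &= ~bad
        for i in np.flatnonzero(bad):
            reasons[i].append("baf_window")

    df = df.copy()
    df["pass_filters"] = ok
    df["filter_reasons"] = [";".join(r) for r in reasons]
    return TrioGenotypes(df, trio.embryo_ploidy, trio.truth)


@dataclass
class PloidyCall:
    """Genome-wide ploidy classification with its evidence."""

    label: str  # diploid | triploid | haploid | uninformative
    sex_karyotype: str
    het_fraction: float
    triploid_mode_mass: float  # het-BAF mass near 1/3 & 2/3
    diploid_mode_mass: float  # het-BAF mass near 1/2
    n_sites: int


_KARYO = {(3, 0): "XXX", (2, 1): "XXY", (1, 2): "XYY", (1, 0): "X", (0, 1): "Y",
          (2, 0): "XX", (1, 1): "XY"}


def classify_sample_ploidy(
    baf: np.ndarray,
    depth: np.ndarray,
    x_cn: float,
    y_cn: float,
    min_sites: int = 200,
    haploid_het_max: float = 0.02,
    mode_halfwidth: float = 0.08,
) -> PloidyCall:
    """Classify a sample as diploid / triploid / haploid.

    Haploid: genome-wide heterozygous-BAF fraction (0.1-0.9) below
    ``haploid_het_max``. Triploid: among het-band sites, more BAF mass
    within ``mode_halfwidth`` of 1/3 or 2/3 than of 1/2. Sex karyotype is
    read off the supplied X/Y copy-number values (CN calling itself is the
    upstream platform's job).
    """
    baf = np.asarray(baf, dtype=float)
    use = np.asarray(depth) > 0
    baf = baf[use & np.isfinite(baf)]
    karyo = _KARYO.get((int(round(x_cn)), int(round(y_cn))), f"X{x_cn}Y{y_cn}")
    if baf.size < min_sites:
        return PloidyCall("uninformative", karyo, np.nan, np.nan, np.nan, int(baf.size))
    het = (baf >= 0.1) & (baf <= 0.9)
    het_frac = float(het.mean())
    hb = baf[het]
    tri = float(((np.abs(hb - 1 / 3) <= mode_halfwidth) |
                 (np.abs(hb - 2 / 3) <= mode_halfwidth)).mean()) if hb.size else 0.0
    dip = float((np.abs(hb - 0.5) <= mode_halfwidth).mean()) if hb.size else 0.0
    if het_frac < haploid_het_max:
        label = "haploid"
    elif tri > dip:
        label = "triploid"
    else:
        label = "diploid"
    return PloidyCall(label, karyo, het_frac, tri, dip, int(baf.size))
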