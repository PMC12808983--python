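"""Synthetic meiosis, trio, and cohort generator.

Emulates the data a targeted-NGS preimplantation-genetic-testing (PGT)
workflow produces: ~5,000-SNP panels at ~360x mean depth, phased parental
genotypes, female meiosis with Poisson crossovers on a genetic map, and the
whole-genome segregation failures that produce triploid, haploid, and
maternal-isodiploid embryos. Ground truth (crossover positions, per-site
BPH/SPH state, injected call errors) is carried alongside the observations
so every downstream caller can be scored exactly.

Meiosis bookkeeping: each chromosome enters meiosis as a bivalent of four
chromatids (two sisters per homolog). Chiasmata are Poisson with mean
2 * L Morgans per bivalent (so a gamete carries L crossovers on average),
placed uniformly on the genetic map, each joining one chromatid from each
homolog. Chromatid identity follows the centromere: a crossover exchanges
the segment distal to the breakpoint on its arm. Whole-genome MI failure
retains one chromatid from each homolog (pericentromeric alleles from both
homologs — BPH); MII failure retains both sisters of one homolog
(pericentromeric SPH).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import GenomeSpec

__all__ = [
    "SitePanel",
    "ParentalHaplotypes",
    "ErrorModel",
    "MeiosisOutcome",
    "SimulatedTrio",
    "CohortParams",
    "MEIOSIS_MODES",
    "TRIO_SCENARIOS",
    "simulate_panel",
    "simulate_parents",
    "simulate_meiosis",
    "simulate_embryo_trio",
    "simulate_cohort",
]

MEIOSIS_MODES = (
    "normal",
    "MI_failure",
    "MII_failure",
    "recombination_failure+MI_failure",
    "recombination_failure+MII_failure",
    "isodiploid_egg",
)

TRIO_SCENARIOS = (
    "diploid",
    "maternal_triploid_MI",
    "maternal_triploid_MII",
    "paternal_triploid",
    "haploid_paternal_missing",
    "maternal_isodiploid",
)

_BASES = np.array(list("ACGT"))


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class SitePanel:
    """Ordered SNP panel: chrom, pos (1-based), ref, alt, population alt freq."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        self._slices: dict[str, slice] = {}
        chrom = self.df["chrom"].to_numpy()
        for name, grp in self.df.groupby("chrom", sort=False):
            idx = grp.index
            self._slices[str(name)] = slice(int(idx[0]), int(idx[-1]) + 1)
        # contiguity is assumed everywhere downstream
        for name, sl in self._slices.items():
            assert (chrom[sl] == name).all()

    @property
    def n_sites(self) -> int:
        return len(self.df)

    @property
    def chroms(self) -> list[str]:
        return list(self._slices)

    def chrom_slice(self, name: str) -> slice:
        return self._slices[name]

    def positions(self, name: str) -> np.ndarray:
        return self.df["pos"].to_numpy()[self._slices[name]]


@dataclass
class ParentalHaplotypes:
    """Two phased haplotypes over the panel (0 = ref allele, 1 = alt)."""

    panel: SitePanel
    haps: np.ndarray  # (2, n_sites) uint8

    @property
    def genotype(self) -> np.ndarray:
        """Diploid alt-allele dosage per site (0, 1, 2)."""
        return self.haps.sum(axis=0)


@dataclass
class ErrorModel:
    """Observation noise for targeted-NGS genotyping.

    ``call_error_rate``: probability a site's true dosage class is replaced
    by a uniformly chosen other class before reads are drawn (the flat
    0.42 % SNP genotype-call error the concordance analysis calibrates
    against). ``depth_*`` parameterize a negative-binomial depth with mean
    360x truncated at 10,000x; ``read_error`` is the per-read allele
    mis-read rate.
    """

    call_error_rate: float = 0.0042
    depth_mean: float = 360.0
    depth_dispersion: float = 4.0
    depth_max: int = 10_000
    read_error: float = 0.002

    def __post_init__(self) -> None:
        if not 0 <= self.call_error_rate < 0.05:
            raise ValueError("call_error_rate must be in [0, 0.05)")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth parameters must be positive")

    def sample_depth(self, n: int, rng) -> np.ndarray:
        r = self.depth_dispersion
        p = r / (r + self.depth_mean)
        return np.minimum(rng.negative_binomial(r, p, size=n), self.depth_max)

    def sample_reads(self, alt_copies: np.ndarray, ploidy: int, rng):
        """Depth and alt-read counts for true per-site alt dosage."""
        n = alt_copies.size
        depth = self.sample_depth(n, rng)
        frac = alt_copies / float(ploidy)
        e = self.read_error
        alt = rng.binomial(depth, frac * (1 - e) + (1 - frac) * e)
        return depth, alt


@dataclass
class MeiosisOutcome:
    """Retained oocyte chromatids plus full ground truth.

    ``origins`` maps each retained chromatid x site to the parental homolog
    (0/1) it derives from; ``alleles`` is the corresponding allele (0/1).
    ``crossovers[chrom][k]`` lists breakpoint bp positions on retained
    chromatid ``k``; ``polar_origins`` holds the discarded chromatids.
    """

    mode: str
    panel: SitePanel
    origins: np.ndarray  # (n_retained, n_sites) int8
    alleles: np.ndarray  # (n_retained, n_sites) uint8
    crossovers: dict[str, list[np.ndarray]]
    polar_origins: np.ndarray
    truth_switches: dict[str, np.ndarray]

    @property
    def n_retained(self) -> int:
        return self.origins.shape[0]

    @property
    def bph_state(self) -> np.ndarray:
        """True per-site BPH flag (only meaningful for 2-chromatid outcomes)."""
        if self.n_retained != 2:
            raise ValueError("BPH/SPH state is defined for 2 retained chromatids")
        return self.origins[0] != self.origins[1]

    def switch_positions(self, chrom: str) -> np.ndarray:
        """bp positions where the retained ancestry state truly flips.

        For 2-chromatid outcomes this is where the pair's BPH/SPH state
        changes; for a single gamete, where its homolog-of-origin changes.
        Not every recorded chromatid breakpoint qualifies: an exchange of
        segments with identical ancestry leaves the state unchanged, so the
        flip is evaluated from the ancestry immediately left and right of
        each chiasma.
        """
        return self.truth_switches[chrom]


def simulate_panel(spec: GenomeSpec, n_sites: int, seed, freq=None) -> SitePanel:
    """Draw a targeted SNP panel across the genome.

    Sites are allocated to chromosomes proportionally to physical length and
    placed uniformly; alt-allele frequencies default to Uniform(0.1, 0.9)
    (common biallelic panel SNPs), or pass a scalar / per-site array.
    """
    rng = _rng(seed)
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    lengths = np.array([c.length_bp for c in spec], dtype=float)
    if n_sites > int(lengths.sum() // 1000):
        raise ValueError("n_sites exceeds representable panel density")
    alloc = np.maximum(1, np.round(n_sites * lengths / lengths.sum()).astype(int))
    # trim/pad to hit n_sites exactly
    while alloc.sum() > n_sites:
        alloc[np.argmax(alloc)] -= 1
    while alloc.sum() < n_sites:
        alloc[np.argmin(alloc)] += 1
    rows = []
    for c, k in zip(spec, alloc):
        pos = np.sort(rng.choice(np.arange(1, c.length_bp, 1000), size=k, replace=False))
        rows.append(pd.DataFrame({"chrom": c.name, "pos": pos}))
    df = pd.concat(rows, ignore_index=True)
    n = len(df)
    ref = rng.integers(0, 4, n)
    alt = (ref + rng.integers(1, 4, n)) % 4
    df["ref"] = _BASES[ref]
    df["alt"] = _BASES[alt]
    if freq is None:
        df["freq"] = rng.uniform(0.1, 0.9, n)
    else:
        df["freq"] = np.broadcast_to(np.asarray(freq, dtype=float), (n,)).copy()
    return SitePanel(df)


def simulate_parents(spec: GenomeSpec, n_sites: int, seed, freq=None):
    """Panel plus two Hardy–Weinberg parents phased over it."""
    rng = _rng(seed)
    panel = simulate_panel(spec, n_sites, rng, freq=freq)
    p = panel.df["freq"].to_numpy()
    mother = ParentalHaplotypes(panel, (rng.random((2, panel.n_sites)) < p).astype(np.uint8))
    father = ParentalHaplotypes(panel, (rng.random((2, panel.n_sites)) < p).astype(np.uint8))
    return mother, father, panel


def _meiose_chromosome(c, positions, n_chiasma, rng):
    """Four-strand bookkeeping for one bivalent.

    Returns per-chromatid homolog-origin arrays at the panel sites, the
    per-chromatid breakpoint lists, the chiasma bp positions, and the
    per-chromatid ancestry immediately left and right of each chiasma
    (tracked via sentinel positions so true state flips can be told apart
    from no-op exchanges of identical-ancestry segments).
    """
    m = positions.size
    if n_chiasma:
        cm = np.sort(rng.uniform(0.0, c.total_cm, n_chiasma))
        bp_pos = np.asarray(c.cm_to_bp(cm), dtype=float)
    else:
        bp_pos = np.empty(0)
    k = bp_pos.size
    ext = np.concatenate([positions.astype(float), bp_pos - 1e-3, bp_pos + 1e-3])
    origin = np.repeat(np.array([0, 0, 1, 1], dtype=np.int8)[:, None], ext.size, axis=1)
    bps: list[list[float]] = [[], [], [], []]
    for bp in bp_pos:
        i = rng.integers(0, 2)
        j = 2 + rng.integers(0, 2)
        if bp >= c.centromere_bp:
            seg = ext > bp
        else:
            seg = ext < bp
        tmp = origin[i, seg].copy()
        origin[i, seg] = origin[j, seg]
        origin[j, seg] = tmp
        # breakpoints in the exchanged segment travel with it
        lo, hi = (bp, np.inf) if bp >= c.centromere_bp else (-np.inf, bp)
        keep_i = [x for x in bps[i] if not (lo < x < hi)]
        move_i = [x for x in bps[i] if lo < x < hi]
        keep_j = [x for x in bps[j] if not (lo < x < hi)]
        move_j = [x for x in bps[j] if lo < x < hi]
        bps[i] = keep_i + move_j + [bp]
        bps[j] = keep_j + move_i + [bp]
    site_origin = origin[:, :m]
    left = origin[:, m : m + k]
    right = origin[:, m + k :]
    return site_origin, [np.sort(np.array(b)) for b in bps], bp_pos, left, right


def simulate_meiosis(
    parent: ParentalHaplotypes,
    spec: GenomeSpec,
    mode: str,
    seed,
    n_recomb_override: int | None = None,
) -> MeiosisOutcome:
    """One female meiosis over the parent's genome.

    ``n_recomb_override`` forces the chiasma count per bivalent (0 recreates
    a recombination-failure oocyte explicitly).
    """
    if mode not in MEIOSIS_MODES:
        raise ValueError(f"unknown meiosis mode {mode!r}")
    rng = _rng(seed)
    panel = parent.panel
    recomb_fail = mode.startswith("recombination_failure")
    base_mode = mode.split("+")[-1] if "+" in mode else mode
    if base_mode == "isodiploid_egg":
        base_mode = "MII_failure"
    n_ret = 1 if base_mode == "normal" else 2

    origins = np.empty((n_ret, panel.n_sites), dtype=np.int8)
    polar = np.empty((4 - n_ret, panel.n_sites), dtype=np.int8)
    crossovers: dict[str, list[np.ndarray]] = {}
    switches: dict[str, np.ndarray] = {}
    for name in panel.chroms:
        c = spec[name]
        sl = panel.chrom_slice(name)
        positions = panel.df["pos"].to_numpy()[sl]
        if recomb_fail:
            n_x = 0
        elif n_recomb_override is not None:
            n_x = int(n_recomb_override)
        else:
            n_x = rng.poisson(2.0 * c.total_cm / 100.0)
        origin4, bps, bp_pos, left, right = _meiose_chromosome(c, positions, n_x, rng)
        if base_mode == "normal":
            h = rng.integers(0, 2)
            k = 2 * h + rng.integers(0, 2)
            keep = [k]
        elif base_mode == "MI_failure":
            keep = [rng.integers(0, 2), 2 + rng.integers(0, 2)]
        else:  # MII_failure
            h = rng.integers(0, 2)
            keep = [2 * h, 2 * h + 1]
        rest = [k for k in range(4) if k not in keep]
        origins[:, sl] = origin4[keep]
        polar[:, sl] = origin4[rest]
        crossovers[name] = [bps[k] for k in keep]
        if n_ret == 2:
            a, b = keep
            flips = (left[a] != left[b]) != (right[a] != right[b])
        else:
            flips = left[keep[0]] != right[keep[0]]
        switches[name] = np.sort(bp_pos[flips])

    site_idx = np.arange(panel.n_sites)
    alleles = parent.haps[origins, site_idx[None, :]]
    return MeiosisOutcome(
        mode, panel, origins, alleles.astype(np.uint8), crossovers, polar, switches
    )


@dataclass
class SimulatedTrio:
    """Observed trio read data plus embedded ground truth."""

    panel: SitePanel
    scenario: str
    ploidy: int
    sex_karyotype: str
    mother_gt: np.ndarray  # true diploid alt dosage (0/1/2)
    father_gt: np.ndarray
    embryo_alt_copies: np.ndarray  # true alt copies out of `ploidy`
    reads: pd.DataFrame  # depth_/alt_ columns for embryo, mother, father
    maternal_meiosis: MeiosisOutcome | None
    error_mask: np.ndarray  # sites where a call error was injected (embryo)
    error_model: ErrorModel

    @property
    def truth_bph(self) -> np.ndarray | None:
        mm = self.maternal_meiosis
        if mm is not None and mm.n_retained == 2:
            return mm.bph_state
        return None

    def sites_frame(self) -> pd.DataFrame:
        """Panel + read columns in one table (analysis entry point)."""
        return pd.concat([self.panel.df, self.reads], axis=1)


def _inject_call_errors(alt_copies, ploidy, rate, rng):
    """Flat genotype-class error: re-draw among the other dosage classes."""
    out = alt_copies.copy()
    mask = rng.random(alt_copies.size) < rate
    if mask.any():
        shift = rng.integers(1, ploidy + 1, size=int(mask.sum()))
        out[mask] = (out[mask] + shift) % (ploidy + 1)
    return out, mask


def simulate_embryo_trio(
    mother: ParentalHaplotypes,
    father: ParentalHaplotypes,
    spec: GenomeSpec,
    scenario: str,
    error_model: ErrorModel | None = None,
    seed=None,
    n_recomb_override: int | None = None,
) -> SimulatedTrio:
    """Assemble one embryo + parents trio under a fertilization scenario."""
    if scenario not in TRIO_SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    em = error_model or ErrorModel()
    rng = _rng(seed)
    panel = mother.panel

    mat_mode = {
        "diploid": "normal",
        "maternal_triploid_MI": "MI_failure",
        "maternal_triploid_MII": "MII_failure",
        "paternal_triploid": "normal",
        "haploid_paternal_missing": "normal",
        "maternal_isodiploid": "isodiploid_egg",
    }[scenario]
    mat = simulate_meiosis(mother, spec, mat_mode, rng, n_recomb_override)
    copies = mat.alleles.sum(axis=0).astype(np.int64)

    n_pat = {"diploid": 1, "maternal_triploid_MI": 1, "maternal_triploid_MII": 1,
             "paternal_triploid": 2, "haploid_paternal_missing": 0,
             "maternal_isodiploid": 0}[scenario]
    for _ in range(n_pat):
        pg = simulate_meiosis(father, spec, "normal", rng)
        copies = copies + pg.alleles.sum(axis=0)

    ploidy = mat.n_retained + n_pat
    if scenario == "diploid":
        karyo = "XX" if rng.random() < 0.5 else "XY"
    elif scenario in ("maternal_triploid_MI", "maternal_triploid_MII"):
        karyo = "XXX" if rng.random() < 0.5 else "XXY"
    elif scenario == "paternal_triploid":
        # MI-failure sperm are XY; MII-failure sperm XX or YY
        if rng.random() < 1 / 3:
            karyo = "XXY"
        else:
            karyo = "XXX" if rng.random() < 0.5 else "XYY"
    elif scenario == "haploid_paternal_missing":
        karyo = "X"
    else:
        karyo = "XX"

    obs_copies, err_mask = _inject_call_errors(copies, ploidy, em.call_error_rate, rng)
    de, ae = em.sample_reads(obs_copies, ploidy, rng)
    dm, am = em.sample_reads(mother.genotype, 2, rng)
    df, af = em.sample_reads(father.genotype, 2, rng)
    reads = pd.DataFrame(
        {
            "depth_embryo": de, "alt_embryo": ae,
            "depth_mother": dm, "alt_mother": am,
            "depth_father": df, "alt_father": af,
        }
    )
    return SimulatedTrio(
        panel=panel,
        scenario=scenario,
        ploidy=ploidy,
        sex_karyotype=karyo,
        mother_gt=mother.genotype,
        father_gt=father.genotype,
        embryo_alt_copies=copies,
        reads=reads,
        maternal_meiosis=mat,
        error_mask=err_mask,
        error_model=em,
    )


@dataclass
class CohortParams:
    """Generative parameters for a PGT cohort of IVF cycles.

    Defaults mirror the clinical study conditions: ~1.1 % ploidy-abnormality
    rate at the mean maternal age of 35.65 +/- 2.9 years (range 20-47), odds
    ratio 1.046 per year of maternal age, 83 % of abnormalities triploid,
    94.6 % of triploids maternal in origin with a 1/3 MI : 2/3 MII split,
    and 98.9 % of haploids caused by a missing paternal genome.
    """

    base_rate: float = 0.0113
    or_per_year: float = 1.046
    mean_age: float = 35.65
    sd_age: float = 2.9
    age_min: float = 20.0
    age_max: float = 47.0
    paternal_offset_mean: float = 1.6
    paternal_offset_sd: float = 3.0
    embryos_per_cycle_poisson: float = 3.8  # count = 1 + Poisson
    triploid_fraction: float = 0.830
    p_female_triploid: float = 0.946
    p_mi: float = 0.333
    p_female_haploid: float = 0.011
    risk_multiplier: float = 1.0  # odds multiplier for high-risk couples
    risk_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("base_rate", "triploid_fraction", "p_female_triploid",
                     "p_mi", "p_female_haploid", "risk_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.or_per_year <= 0 or self.risk_multiplier <= 0:
            raise ValueError("odds ratios must be positive")


def _truncated_normal(mean, sd, lo, hi, n, rng):
    from scipy.stats import truncnorm

    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def simulate_cohort(params: CohortParams, n_cycles: int, seed) -> pd.DataFrame:
    """Cycle x embryo table with true ploidy labels and sex karyotypes.

    Per-embryo abnormality follows a logistic model in maternal age whose
    slope is log(or_per_year), anchored at ``base_rate`` for the mean age;
    abnormal embryos receive type, parental origin, meiotic phase, and sex
    karyotype from the same generative model the sex-karyotype moments
    estimators invert.
    """
    rng = _rng(seed)
    p = params
    ages = _truncated_normal(p.mean_age, p.sd_age, p.age_min, p.age_max, n_cycles, rng)
    pat_ages = ages + rng.normal(p.paternal_offset_mean, p.paternal_offset_sd, n_cycles)
    counts = 1 + rng.poisson(p.embryos_per_cycle_poisson, n_cycles)
    high_risk = rng.random(n_cycles) < p.risk_fraction

    cyc = np.repeat(np.arange(n_cycles), counts)
    age = np.repeat(ages, counts)
    page = np.repeat(pat_ages, counts)
    risk = np.repeat(high_risk, counts)
    n = cyc.size

    logit0 = np.log(p.base_rate / (1 - p.base_rate))
    logit = logit0 + np.log(p.or_per_year) * (age - p.mean_age)
    logit = logit + np.where(risk, np.log(p.risk_multiplier), 0.0)
    prob = 1.0 / (1.0 + np.exp(-logit))
    abnormal = rng.random(n) < prob

    label = np.full(n, "diploid", dtype=object)
    karyo = np.where(rng.random(n) < 0.5, "XX", "XY").astype(object)
    origin = np.full(n, "", dtype=object)
    phase = np.full(n, "", dtype=object)

    idx = np.flatnonzero(abnormal)
    for i in idx:
        if rng.random() < p.triploid_fraction:
            label[i] = "triploid"
            female = rng.random() < p.p_female_triploid
            mi = rng.random() < p.p_mi
            origin[i] = "maternal" if female else "paternal"
            phase[i] = "MI" if mi else "MII"
            if female:
                karyo[i] = "XXX" if rng.random() < 0.5 else "XXY"
            elif mi:
                karyo[i] = "XXY"
            else:
                karyo[i] = "XXX" if rng.random() < 0.5 else "XYY"
        else:
            label[i] = "haploid"
            female = rng.random() < p.p_female_haploid
            origin[i] = "maternal" if female else "paternal"
            if female:
                karyo[i] = "X" if rng.random() < 0.5 else "Y"
            else:
                karyo[i] = "X"

    return pd.DataFrame(
        {
            "cycle_id": cyc,
            "embryo_id": [f"c{c}e{e}" for c, e in
                          zip(cyc, np.concatenate([np.arange(k) for k in counts]))],
            "maternal_age": age,
            "paternal_age": page,
            "label": label,
            "sex_karyotype": karyo,
            "error_origin": origin,
            "meiotic_phase": phase,
            "high_risk_couple": risk,
        }
    )
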