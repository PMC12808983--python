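"""Parent-of-origin and meiotic-phase inference from trio genotypes.

Parental origin uses SNPs where the parents are opposite homozygous: in a
triploid, the parent matching the duplicated allele contributed the extra
set (mother AA x father BB with embryo AAB is a maternal error); in a
haploid the embryo's single allele identifies the surviving genome, so the
other parent's set is the missing one. The counts S_m (maternal-error) and
S_p (paternal-error) give the parental origin score log(S_m / S_p) — call
maternal when positive.

Meiotic phase uses pericentromeric SNPs (within 5 cM of the centromere,
where crossovers rarely separate alleles from the centromere) at which the
erring parent is heterozygous and the other homozygous: an embryo carrying
both of the erring parent's alleles (BPH) marks an MI error, a duplicated
single allele (SPH) an MII error. The meiotic origin score is
log(S2 / S1) over SPH count S2 and BPH count S1 — call MII when positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calls import NO_CALL, TrioGenotypes

__all__ = ["OriginScores", "parental_origin_score", "meiotic_origin_score", "score_trio"]


@dataclass
class OriginScores:
    """Informative-site tallies, log-ratio scores, and sign-based calls."""

    s_m: int = 0
    s_p: int = 0
    parental_score: float = np.nan
    parental_call: str = "indeterminate"
    s1_bph: int = 0
    s2_sph: int = 0
    meiotic_score: float = np.nan
    meiotic_call: str = "indeterminate"
    per_chrom: pd.DataFrame | None = None
    reason: str = ""


def _log_ratio(num: int, den: int, pseudocount: float = 0.0) -> float:
    """Natural-log ratio; +/-inf when one side is zero and no pseudocount."""
    a, b = num + pseudocount, den + pseudocount
    if a == 0 and b == 0:
        return np.nan
    if b == 0:
        return np.inf
    if a == 0:
        return -np.inf
    return float(np.log(a / b))


def parental_origin_score(
    trio: TrioGenotypes,
    threshold: float = 0.0,
    pseudocount: float = 0.0,
) -> OriginScores:
    """Tally maternal- vs paternal-error evidence at opposite-homozygous sites.

    Strict sign convention by default: score > ``threshold`` calls maternal,
    score < -``threshold`` paternal, otherwise indeterminate.
    """
    df = trio.passing()
    cm = df["call_mother"].to_numpy()
    cf = df["call_father"].to_numpy()
    ce = df["call_embryo"].to_numpy()
    opp = ((cm == 0) & (cf == 2)) | ((cm == 2) & (cf == 0))
    called = ce != NO_CALL

    if trio.embryo_ploidy == 3:
        # embryo dosage 1 (AAB in alt counts) duplicates the hom-ref parent
        use = opp & called & ((ce == 1) | (ce == 2))
        dup_ref_parent = ce[use] == 1
        mother_is_ref = cm[use] == 0
        maternal = dup_ref_parent == mother_is_ref
    elif trio.embryo_ploidy == 1:
        # surviving allele matches one parent; the OTHER parent's set is missing
        use = opp & called & ((ce == 0) | (ce == 1))
        emb_alt = ce[use] == 1
        mother_is_alt = cm[use] == 2
        matches_mother = emb_alt == mother_is_alt
        maternal = ~matches_mother  # embryo kept father's genome -> maternal error
    else:
        raise ValueError("parental origin is defined for triploid or haploid embryos")

    s_m = int(maternal.sum())
    s_p = int((~maternal).sum())
    out = OriginScores(s_m=s_m, s_p=s_p)
    if s_m + s_p == 0:
        out.reason = "no informative opposite-homozygous sites"
        return out
    out.parental_score = _log_ratio(s_m, s_p, pseudocount)
    if np.isfinite(threshold) and not np.isnan(out.parental_score):
        if out.parental_score > threshold:
            out.parental_call = "maternal"
        elif out.parental_score < -threshold:
            out.parental_call = "paternal"
    sub = df.loc[use]
    out.per_chrom = (
        pd.DataFrame({"chrom": sub["chrom"].to_numpy(), "maternal": maternal})
        .groupby("chrom", sort=False)["maternal"]
        .agg(s_m="sum", n="count")
        .reset_index()
    )
    return out


def meiotic_origin_score(
    trio: TrioGenotypes,
    erring_parent: str = "mother",
    threshold: float = 0.0,
    pseudocount: float = 0.0,
) -> OriginScores:
    """BPH/SPH tally over pericentromeric sites; MII when log(S2/S1) > 0.

    Requires a triploid embryo and the parental call (``erring_parent``).
    Sites: erring parent heterozygous, other parent homozygous, within the
    trio's pericentromeric mask. The embryo's two erring-parent alleles are
    the embryo dosage minus the other parent's contributed allele; one of
    each -> BPH (S1), a duplicated one -> SPH (S2).
    """
    if trio.embryo_ploidy != 3:
        raise ValueError("meiotic phase is only identifiable in triploids")
    if erring_parent not in ("mother", "father"):
        raise ValueError("erring_parent must be 'mother' or 'father'")
    df = trio.passing()
    df = df[df["pericentromeric"]]
    err, other = ("mother", "father") if erring_parent == "mother" else ("father", "mother")
    ce = df["call_embryo"].to_numpy()
    cerr = df[f"call_{err}"].to_numpy()
    coth = df[f"call_{other}"].to_numpy()
    use = (cerr == 1) & ((coth == 0) | (coth == 2)) & (ce != NO_CALL)
    # erring parent's two alleles = embryo alt dosage minus other's haploid alt
    other_alt = (coth[use] == 2).astype(int)
    pair_alt = ce[use] - other_alt
    bph = pair_alt == 1
    sph = (pair_alt == 0) | (pair_alt == 2)

    out = OriginScores(s1_bph=int(bph.sum()), s2_sph=int(sph.sum()))
    if out.s1_bph + out.s2_sph == 0:
        out.reason = "no informative pericentromeric sites"
        return out
    out.meiotic_score = _log_ratio(out.s2_sph, out.s1_bph, pseudocount)
    if not np.isnan(out.meiotic_score):
        if out.meiotic_score > threshold:
            out.meiotic_call = "MII"
        elif out.meiotic_score < -threshold:
            out.meiotic_call = "MI"
    sub = df.loc[use]
    out.per_chrom = (
        pd.DataFrame({"chrom": sub["chrom"].to_numpy(), "bph": bph, "sph": sph})
        .groupby("chrom", sort=False)
        .agg(s1_bph=("bph", "sum"), s2_sph=("sph", "sum"))
        .reset_index()
    )
    return out


def score_trio(trio: TrioGenotypes, threshold: float = 0.0) -> OriginScores:
    """Full origin workup: parental score, then (triploids, when a parent is
    called) the meiotic score for the erring parent."""
    out = parental_origin_score(trio, threshold=threshold)
    if trio.embryo_ploidy == 3 and out.parental_call in ("maternal", "paternal"):
        mei = meiotic_origin_score(
            trio, erring_parent=out.parental_call.replace("maternal", "mother").replace("paternal", "father"),
            threshold=threshold,
        )
        out.s1_bph, out.s2_sph = mei.s1_bph, mei.s2_sph
        out.meiotic_score, out.meiotic_call = mei.meiotic_score, mei.meiotic_call
    return out
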