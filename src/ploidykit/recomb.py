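"""Meiotic-recombination mapping in triploid trios.

Along a chromosome of a digynic triploid, the two maternal chromatids are
either copies of both homologs (BPH) or of a single homolog (SPH); each
crossover flips the state. At SNPs where the father is homozygous and the
mother heterozygous, the embryo dosage is consistent with exactly one of
the two states, giving a per-SNP delta score in {-1, 0, +1} (-1 = only
BPH-consistent, +1 = only SPH-consistent, 0 = uninformative or consistent
with neither — a genotyping error). A 3-SNP sliding mean that reaches +/-1
assigns a state; a switch between assigned states marks a recombination
window bounded by the last SNP of the old state and the first SNP of the
new one. Three consecutive errors would be needed to fake a switch, with
probability ~0.0042^3 = 7e-8 at the platform's 0.42 % call-error rate.

Also here: the 50-SNP moving-average segmenter used for SNP-array
validation data and the random-placement permutation test for breakpoint /
window overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calls import NO_CALL, TrioGenotypes
from .genome import GenomeSpec

__all__ = [
    "ConcordanceTrack",
    "RecombinationWindow",
    "ArraySegmentation",
    "concordance_track",
    "detect_recombination_windows",
    "estimate_genotype_error_rate",
    "consecutive_error_prob",
    "segment_array_bph_sph",
    "breakpoint_overlap_test",
]


@dataclass
class ConcordanceTrack:
    """Per-chromosome SNP positions with delta scores and usable-site counts."""

    chroms: dict[str, pd.DataFrame]  # chrom -> columns pos, delta
    usable_sites: dict[str, int]

    def __iter__(self):
        return iter(self.chroms.items())


@dataclass(frozen=True)
class RecombinationWindow:
    chrom: str
    start_pos: int
    end_pos: int
    state_before: str  # BPH | SPH
    state_after: str

    def __post_init__(self):
        if self.start_pos >= self.end_pos:
            raise ValueError("window start must precede end")
        if self.state_before == self.state_after:
            raise ValueError("window must change state")


def concordance_track(trio: TrioGenotypes, erring_parent: str = "mother") -> ConcordanceTrack:
    """Delta score per usable SNP (erring parent het, other parent hom).

    delta = score_BPH - score_SPH where each score is 0 if the embryo
    dosage is consistent with that state and 1 otherwise; dosages
    inconsistent with both states score 0 (flagged by the error-rate
    estimator, not here).
    """
    if trio.embryo_ploidy != 3:
        raise ValueError("concordance tracks are defined for triploid trios")
    err, other = ("mother", "father") if erring_parent == "mother" else ("father", "mother")
    df = trio.passing()
    ce = df["call_embryo"].to_numpy()
    cerr = df[f"call_{err}"].to_numpy()
    coth = df[f"call_{other}"].to_numpy()
    use = (cerr == 1) & ((coth == 0) | (coth == 2)) & (ce != NO_CALL)

    other_alt = np.where(coth == 2, 1, 0)
    pair_alt = ce - other_alt  # the erring parent's two allele copies (alt count)
    delta = np.zeros(len(df), dtype=np.int8)
    delta[use & (pair_alt == 1)] = -1  # BPH-consistent only
    delta[use & ((pair_alt == 0) | (pair_alt == 2))] = +1  # SPH-consistent only

    chroms: dict[str, pd.DataFrame] = {}
    usable: dict[str, int] = {}
    pos_all = df["pos"].to_numpy()
    ch_all = df["chrom"].to_numpy()
    for name in pd.unique(ch_all):
        sel = (ch_all == name) & use
        chroms[str(name)] = pd.DataFrame(
            {"pos": pos_all[sel], "delta": delta[sel]}
        ).reset_index(drop=True)
        usable[str(name)] = int(sel.sum())
    return ConcordanceTrack(chroms, usable)


def _assign_states(deltas: np.ndarray, window: int, threshold: float) -> np.ndarray:
    """Per-SNP assigned state (+1/-1) where a length-``window`` mean ending
    there reaches +/-``threshold``; 0 where unassigned."""
    n = deltas.size
    out = np.zeros(n, dtype=np.int8)
    if n < window:
        return out
    kern = np.ones(window) / window
    means = np.convolve(deltas.astype(float), kern, mode="valid")  # n-window+1
    for i, m in enumerate(means):
        j = i + window - 1  # window end index
        if m >= threshold:
            out[j] = 1
        elif m <= -threshold:
            out[j] = -1
    return out


def detect_recombination_windows(
    track: ConcordanceTrack,
    window_size: int = 3,
    threshold: float = 1.0,
    skip_zero_delta: bool = True,
) -> tuple[list[RecombinationWindow], int]:
    """Find state switches per chromosome; returns (windows, total count).

    With ``skip_zero_delta`` (default) the 3-SNP windows run over
    informative SNPs only, so three consecutive *informative* sites must
    agree before a state is assigned. Each switch yields a window from the
    last SNP carrying the previous assigned state to the first SNP carrying
    the new one.
    """
    names = {1: "SPH", -1: "BPH"}
    windows: list[RecombinationWindow] = []
    for chrom, df in track:
        d = df["delta"].to_numpy()
        p = df["pos"].to_numpy()
        if skip_zero_delta:
            keep = d != 0
            d, p = d[keep], p[keep]
        if d.size < window_size:
            continue
        states = _assign_states(d, window_size, threshold)
        assigned = np.flatnonzero(states)
        if assigned.size == 0:
            continue
        prev = assigned[0]
        for i in assigned[1:]:
            if states[i] != states[prev]:
                # the new state's run began window_size-1 SNPs before the
                # first window that certified it; the old state's last SNP
                # is the closest preceding one with the opposite mean
                windows.append(
                    RecombinationWindow(
                        chrom=chrom,
                        start_pos=int(p[prev]),
                        end_pos=int(p[i - window_size + 1]),
                        state_before=names[int(states[prev])],
                        state_after=names[int(states[i])],
                    )
                )
            prev = i
    return windows, len(windows)


def estimate_genotype_error_rate(trios: list[TrioGenotypes]) -> float:
    """Average fraction of embryo calls inconsistent with the parental
    genotypes.

    Computed over sites where both parents are called homozygous: there the
    triploid embryo dosage is fully determined (the father's allele plus two
    copies of the mother's), so any other called dosage is a genotyping
    error and every error class is detectable.
    """
    bad = 0
    total = 0
    for trio in trios:
        if trio.embryo_ploidy != 3:
            continue
        df = trio.passing()
        cm = df["call_mother"].to_numpy()
        cf = df["call_father"].to_numpy()
        ce = df["call_embryo"].to_numpy()
        use = ((cm == 0) | (cm == 2)) & ((cf == 0) | (cf == 2)) & (ce != NO_CALL)
        expected = np.where(cm == 2, 2, 0) + np.where(cf == 2, 1, 0)
        bad += int((ce[use] != expected[use]).sum())
        total += int(use.sum())
    if total == 0:
        raise ValueError("no usable sites to estimate the error rate")
    return bad / total


def consecutive_error_prob(rate: float, k: int) -> float:
    """Probability of k consecutive independent genotyping errors."""
    if not 0 <= rate <= 1 or k < 1:
        raise ValueError("need rate in [0, 1] and k >= 1")
    return rate**k


@dataclass
class ArraySegmentation:
    """Per-arm BPH/SPH segments from the 50-SNP moving-average smoother."""

    segments: pd.DataFrame  # chrom, arm, start_pos, end_pos, state, low_confidence
    breakpoints: pd.DataFrame  # chrom, arm, pos


def _segment_arm(pos: np.ndarray, val: np.ndarray, window, bph_threshold, sph_threshold):
    """Label one arm scanning away from the centromere (arrays pre-ordered
    centromere -> telomere). Returns (labels per SNP, low_confidence)."""
    n = pos.size
    labels = np.zeros(n, dtype=np.int8)  # +1 BPH, -1 SPH, 0 carries previous
    low_conf = n < window
    w = min(window, n)
    if n == 0:
        return labels, low_conf
    csum = np.concatenate([[0.0], np.cumsum(val)])
    current = 0
    for i in range(n):
        lo = max(0, i - w + 1)
        m = (csum[i + 1] - csum[lo]) / (i + 1 - lo)
        if i + 1 >= w:
            if m >= bph_threshold:
                current = 1
            elif m <= sph_threshold:
                current = -1
        labels[i] = current
    # back-fill the leading unassigned stretch with the first assigned state
    first = np.flatnonzero(labels)
    if first.size:
        labels[: first[0]] = labels[first[0]]
    # a label change is certified by a full window ending at the change
    # index; pull each change back by half a window so the breakpoint sits
    # near where the underlying state actually flipped
    shift = w // 2
    change = np.flatnonzero(np.diff(labels)) + 1
    prev_edge = 0
    for s in change:
        new = labels[s]
        back = max(prev_edge + 1, s - shift)
        labels[back:s] = new
        prev_edge = back
    return labels, low_conf


def segment_array_bph_sph(
    sites: pd.DataFrame,
    spec: GenomeSpec,
    window: int = 50,
    bph_threshold: float = 0.90,
    sph_threshold: float = 0.50,
) -> ArraySegmentation:
    """SNP-array-style BPH/SPH segmentation.

    ``sites``: columns chrom, pos, value — value 1 for a heterozygous embryo
    call at a maternally informative SNP (BPH regions are ~100 % ones, SPH
    regions ~50 %). Windows slide from the centromere toward each telomere;
    BPH needs a window het-mean >= ``bph_threshold``, SPH <=
    ``sph_threshold``; intermediate means keep the previous label.
    Breakpoints sit at the label switches.
    """
    seg_rows = []
    bp_rows = []
    for chrom, grp in sites.groupby("chrom", sort=False):
        c = spec[str(chrom)]
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        val = grp["value"].to_numpy(dtype=float)
        for arm in ("p", "q"):
            if arm == "p":
                sel = pos < c.centromere_bp
                order = np.argsort(-pos[sel])  # centromere -> p telomere
            else:
                sel = pos >= c.centromere_bp
                order = np.argsort(pos[sel])
            ap, av = pos[sel][order], val[sel][order]
            labels, low_conf = _segment_arm(ap, av, window, bph_threshold, sph_threshold)
            if ap.size == 0:
                continue
            # compress runs into segments (in scan order)
            change = np.flatnonzero(np.diff(labels)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [ap.size]])
            for s, e in zip(starts, ends):
                lab = labels[s]
                seg_rows.append(
                    {
                        "chrom": chrom,
                        "arm": arm,
                        "start_pos": int(min(ap[s], ap[e - 1])),
                        "end_pos": int(max(ap[s], ap[e - 1])),
                        "state": {1: "BPH", -1: "SPH", 0: "unassigned"}[int(lab)],
                        "low_confidence": bool(low_conf),
                    }
                )
            for s in change:
                bp_rows.append({"chrom": chrom, "arm": arm, "pos": int(ap[s])})
    return ArraySegmentation(
        pd.DataFrame(seg_rows, columns=["chrom", "arm", "start_pos", "end_pos", "state", "low_confidence"]),
        pd.DataFrame(bp_rows, columns=["chrom", "arm", "pos"]),
    )


def breakpoint_overlap_test(
    pgt_windows: list[RecombinationWindow],
    array_breakpoints: pd.DataFrame,
    spec: GenomeSpec,
    n_perm: int = 1000,
    seed=None,
) -> tuple[int, float]:
    """Permutation test of array-breakpoint / PGT-window overlap.

    Observed statistic: number of array breakpoints (columns chrom, pos)
    falling inside any PGT window. Null: each window re-placed uniformly on
    its own chromosome keeping its size; p = (1 + #{null >= observed}) /
    (n_perm + 1).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by_chrom: dict[str, np.ndarray] = {
        str(ch): grp["pos"].to_numpy() for ch, grp in array_breakpoints.groupby("chrom")
    }

    def count_overlap(windows_by_chrom):
        total = 0
        for ch, pts in by_chrom.items():
            wins = windows_by_chrom.get(ch)
            if not wins:
                continue
            hit = np.zeros(pts.size, dtype=bool)
            for s, e in wins:
                hit |= (pts >= s) & (pts <= e)
            total += int(hit.sum())
        return total

    obs_wins: dict[str, list] = {}
    for w in pgt_windows:
        c = spec[w.chrom]
        if w.end_pos - w.start_pos > c.length_bp:
            raise ValueError(f"window longer than {w.chrom}")
        obs_wins.setdefault(w.chrom, []).append((w.start_pos, w.end_pos))
    observed = count_overlap(obs_wins)

    ge = 0
    for _ in range(n_perm):
        null_wins: dict[str, list] = {}
        for w in pgt_windows:
            c = spec[w.chrom]
            size = w.end_pos - w.start_pos
            start = rng.integers(1, c.length_bp - size + 1)
            null_wins.setdefault(w.chrom, []).append((start, start + size))
        if count_overlap(null_wins) >= observed:
            ge += 1
    p = (1 + ge) / (n_perm + 1)
    return observed, p
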