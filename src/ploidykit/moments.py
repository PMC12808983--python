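"""Method-of-moments inference of parental and meiotic origin from
sex-karyotype counts.

A triploid embryo's sex chromosomes identify how the extra set arose. With
p_f the probability the extra set is maternal (p_m = 1 - p_f) and p_MI the
probability of a first-division error (p_MII = 1 - p_MI), and assuming the
meiotic split is the same in both sexes, expected karyotype counts among N
triploids are

    E[N_XXX] = N (p_f / 2 + p_m p_MII / 2)
    E[N_XXY] = N (p_f / 2 + p_m p_MI)
    E[N_XYY] = N (p_m p_MII / 2)

(an XX egg plus X/Y sperm gives XXX/XXY equally; an XY MI-failure sperm
forces XXY; an XX or YY MII-failure sperm gives XXX or XYY equally).
Inverting these moments gives closed-form estimators; haploids, which keep
a Y only when the maternal set is missing and a Y sperm remains, yield
p_f = 2 N_Y / N and p_m = (N_X - N_Y) / N but cannot separate MI from MII.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SexKaryotypeCounts",
    "OriginEstimate",
    "triploid_origin_moments",
    "haploid_origin_moments",
    "triploid_expected_counts",
    "clopper_pearson",
    "binomial_exact_test",
]


@dataclass(frozen=True)
class SexKaryotypeCounts:
    """Triploid counts (n_xxx, n_xxy, n_xyy) or haploid counts (n_x, n_y)."""

    n_xxx: int = 0
    n_xxy: int = 0
    n_xyy: int = 0
    n_x: int = 0
    n_y: int = 0

    def __post_init__(self):
        if min(self.n_xxx, self.n_xxy, self.n_xyy, self.n_x, self.n_y) < 0:
            raise ValueError("karyotype counts must be non-negative")

    @property
    def n_triploid(self) -> int:
        return self.n_xxx + self.n_xxy + self.n_xyy

    @property
    def n_haploid(self) -> int:
        return self.n_x + self.n_y


@dataclass
class OriginEstimate:
    """Raw moments estimates with validity flags and optional bootstrap CIs.

    Raw values outside [0, 1] are reported as-is with ``valid=False``
    (clamping would hide misfit of the generative model); a zero meiotic
    denominator yields NaN meiotic components with ``meiotic_defined=False``.
    """

    p_female: float
    p_male: float
    p_mi: float = np.nan
    p_mii: float = np.nan
    valid: bool = True
    meiotic_defined: bool = False
    ci: dict = field(default_factory=dict)  # component -> (lo, hi), bootstrap


def triploid_origin_moments(
    counts: SexKaryotypeCounts,
    ci_level: float | None = None,
    n_boot: int = 10_000,
    seed: int = 0,
) -> OriginEstimate:
    """Closed-form parental/meiotic origin estimates for triploids.

    p_f = 2 (N_XXX - N_XYY) / N;
    p_MI = (N - 2 N_XXX) / (N - 2 (N_XXX - N_XYY));
    p_MII = 2 N_XYY / (N - 2 (N_XXX - N_XYY)).

    ``ci_level`` turns on a seeded parametric-bootstrap CI over multinomial
    resamples of the counts (an extension beyond the simple-proportion
    intervals; flagged as such in reports).
    """
    n = counts.n_triploid
    if n <= 0:
        raise ValueError("no triploid counts")
    nxxx, nxyy = counts.n_xxx, counts.n_xyy
    p_f = 2.0 * (nxxx - nxyy) / n
    denom = n - 2.0 * (nxxx - nxyy)
    if denom == 0:
        p_mi = p_mii = np.nan
        meiotic = False
    else:
        p_mi = (n - 2.0 * nxxx) / denom
        p_mii = 2.0 * nxyy / denom
        meiotic = True
    valid = bool(0 <= p_f <= 1 and (not meiotic or 0 <= p_mi <= 1))
    est = OriginEstimate(p_f, 1.0 - p_f, p_mi, p_mii, valid, meiotic)

    if ci_level is not None:
        rng = np.random.default_rng(seed)
        probs = np.array([counts.n_xxx, counts.n_xxy, counts.n_xyy]) / n
        draws = rng.multinomial(n, probs, size=n_boot)
        pf = 2.0 * (draws[:, 0] - draws[:, 2]) / n
        dn = n - 2.0 * (draws[:, 0] - draws[:, 2])
        with np.errstate(divide="ignore", invalid="ignore"):
            pmi = np.where(dn != 0, (n - 2.0 * draws[:, 0]) / dn, np.nan)
        q = [(1 - ci_level) / 2 * 100, (1 + ci_level) / 2 * 100]
        est.ci["p_female"] = tuple(np.percentile(pf, q))
        est.ci["p_mi"] = tuple(np.nanpercentile(pmi, q))
    return est


def haploid_origin_moments(counts: SexKaryotypeCounts) -> OriginEstimate:
    """p_f = 2 N_Y / N; p_m = (N_X - N_Y) / N. MI/MII are unidentifiable
    for haploids (no genetic material from the erring parent)."""
    n = counts.n_haploid
    if n <= 0:
        raise ValueError("no haploid counts")
    p_f = 2.0 * counts.n_y / n
    p_m = (counts.n_x - counts.n_y) / n
    valid = bool(0 <= p_f <= 1 and 0 <= p_m <= 1)
    return OriginEstimate(p_f, p_m, valid=valid, meiotic_defined=False)


def triploid_expected_counts(n: int, p_female: float, p_mi: float) -> tuple:
    """Expected (N_XXX, N_XXY, N_XYY) under the generative model — the
    forward map the moments estimators invert."""
    p_m, p_mii = 1.0 - p_female, 1.0 - p_mi
    return (
        n * (p_female / 2 + p_m * p_mii / 2),
        n * (p_female / 2 + p_m * p_mi),
        n * (p_m * p_mii / 2),
    )


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial CI from Beta quantiles; (0, ub) at k=0 and
    (lb, 1) at k=n."""
    if not 0 < conf < 1:
        raise ValueError("conf must be in (0, 1)")
    if not 0 <= k <= n or n < 1:
        raise ValueError("need 0 <= k <= n, n >= 1")
    a = (1 - conf) / 2
    lo = 0.0 if k == 0 else float(stats.beta.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - a, k + 1, n - k))
    return lo, hi


def binomial_exact_test(k: int, n: int, p0: float, alternative: str = "two-sided") -> float:
    """Exact binomial tail probability of ``k`` successes in ``n`` trials
    under success probability ``p0``."""
    if not 0 <= p0 <= 1:
        raise ValueError("p0 must be in [0, 1]")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    return float(stats.binomtest(k, n, p0, alternative=alternative).pvalue)
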