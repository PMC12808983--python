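"""Cohort-level epidemiology of ploidy abnormalities.

Embryo-level logistic regression of abnormality on parental age (per-year
odds ratios with Wald CIs), SART maternal-age strata, a permutation test
for per-couple recurrence that preserves each cycle's embryo count, and the
recombination-aneuploidy association tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "AgeEffectModel",
    "sart_group",
    "SART_LABELS",
    "fit_age_model",
    "or_ratio_between_ages",
    "recurrence_permutation_test",
    "abnormal_pn_age_regression",
    "recombination_aneuploidy_association",
]

SART_LABELS = ("<35", "35-37", "38-40", "41-42", ">42")


def sart_group(maternal_age) -> np.ndarray:
    """SART maternal-age strata; each named band includes its left boundary
    (35.0 falls in '35-37')."""
    age = np.asarray(maternal_age, dtype=float)
    if np.any(age < 0):
        raise ValueError("ages must be non-negative")
    bins = [-np.inf, 35.0, 38.0, 41.0, 43.0, np.inf]
    idx = np.digitize(age, bins) - 1
    return np.array(SART_LABELS, dtype=object)[idx]


@dataclass
class AgeEffectModel:
    """Per-covariate per-year odds ratios from an embryo-level logistic fit."""

    outcome: str
    covariates: list[str]
    odds_ratios: dict[str, float]
    ci: dict[str, tuple[float, float]]
    p_values: dict[str, float]
    n: int
    model_type: str  # univariate | multivariate
    result: object = field(repr=False, default=None)


_OUTCOMES = {
    "any_ploidy_abnormality": lambda lab: lab.isin(["triploid", "haploid"]),
    "triploid": lambda lab: lab == "triploid",
    "haploid": lambda lab: lab == "haploid",
}


def fit_age_model(
    cohort: pd.DataFrame,
    outcome: str = "any_ploidy_abnormality",
    covariates: tuple = ("maternal_age",),
) -> AgeEffectModel:
    """Logistic regression of a per-embryo ploidy outcome on age covariates."""
    if outcome not in _OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    y = _OUTCOMES[outcome](cohort["label"]).to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError(f"outcome {outcome!r} has an empty class")
    X = sm.add_constant(cohort[list(covariates)].to_numpy(dtype=float))
    try:
        res = sm.Logit(y, X).fit(disp=0)
    except Exception as exc:  # separation, non-convergence
        raise RuntimeError(f"logistic fit failed for {outcome!r}: {exc}") from exc
    params = res.params[1:]
    ci = res.conf_int()[1:]
    return AgeEffectModel(
        outcome=outcome,
        covariates=list(covariates),
        odds_ratios={c: float(np.exp(b)) for c, b in zip(covariates, params)},
        ci={c: (float(np.exp(lo)), float(np.exp(hi)))
            for c, (lo, hi) in zip(covariates, ci)},
        p_values={c: float(p) for c, p in zip(covariates, res.pvalues[1:])},
        n=int(y.size),
        model_type="univariate" if len(covariates) == 1 else "multivariate",
        result=res,
    )


def or_ratio_between_ages(model: AgeEffectModel, age1: float, age2: float,
                          covariate: str = "maternal_age") -> float:
    """Fold change in abnormality odds between two ages: OR^(age2 - age1)."""
    return float(model.odds_ratios[covariate] ** (age2 - age1))


def recurrence_permutation_test(
    cohort: pd.DataFrame,
    n_perm: int = 10_000,
    seed=None,
    abnormal_labels: tuple = ("triploid", "haploid"),
) -> pd.DataFrame:
    """Per-couple recurrence test within maternal-age strata.

    Within each SART category, abnormality labels are permuted across all
    embryos while each cycle keeps its embryo count; the statistic for each
    recurrence level k is the number of cycles with >= k abnormal embryos.
    p = (1 + #{null >= observed}) / (n_perm + 1), Bonferroni-corrected over
    all populated (category, k) cells (those with at least one observed
    cycle at that recurrence level).
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives unstable p values")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = cohort.copy()
    df["abnormal"] = df["label"].isin(abnormal_labels)
    if not df["abnormal"].any():
        raise ValueError("cohort contains no abnormal embryos")
    df["age_cat"] = sart_group(df["maternal_age"])

    rows = []
    for cat in SART_LABELS:
        sub = df[df["age_cat"] == cat].sort_values("cycle_id", kind="stable")
        if sub.empty:
            continue
        labels = sub["abnormal"].to_numpy()
        sizes = sub.groupby("cycle_id").size().to_numpy()
        starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
        per_cycle = np.add.reduceat(labels.astype(int), starts)
        kmax = int(per_cycle.max())
        if kmax == 0:
            continue
        ks = np.arange(1, kmax + 1)
        observed = np.array([(per_cycle >= k).sum() for k in ks])

        ge = np.zeros(kmax, dtype=int)
        lab = labels.astype(int)
        for _ in range(n_perm):
            perm = rng.permutation(lab)
            null_counts = np.add.reduceat(perm, starts)
            for i, k in enumerate(ks):
                if (null_counts >= k).sum() >= observed[i]:
                    ge[i] += 1
        for i, k in enumerate(ks):
            rows.append(
                {
                    "age_category": cat,
                    "recurrence_k": int(k),
                    "observed_cycles": int(observed[i]),
                    "p_raw": (1 + ge[i]) / (n_perm + 1),
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    m = len(out)
    out["p_bonferroni"] = np.minimum(out["p_raw"] * m, 1.0)
    out["significant"] = out["p_bonferroni"] < 0.05
    return out


def abnormal_pn_age_regression(zygotes: pd.DataFrame) -> dict:
    """Thin count-regression utility for abnormal-fertilization analyses.

    ``zygotes``: one row per cycle with maternal_age, n_zygotes, and
    n_abnormal_pn (1PN / >2PN zygotes). Fits a negative-binomial GLM of the
    abnormal-PN count on maternal age with log(n_zygotes) as offset and
    returns the per-year rate ratio with its p value.
    """
    y = zygotes["n_abnormal_pn"].to_numpy(dtype=float)
    X = sm.add_constant(zygotes[["maternal_age"]].to_numpy(dtype=float))
    offset = np.log(np.maximum(zygotes["n_zygotes"].to_numpy(dtype=float), 1.0))
    res = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=0.5), offset=offset).fit()
    return {
        "rate_ratio_per_year": float(np.exp(res.params[1])),
        "p_value": float(res.pvalues[1]),
        "n_cycles": int(len(zygotes)),
    }


def recombination_aneuploidy_association(per_embryo: pd.DataFrame) -> dict:
    """t tests linking recombination to additional aneuploidies.

    ``per_embryo``: columns recombination_events, aneuploidy_count, and
    optionally meiotic_phase ('MI'/'MII'). Embryos are split at the cohort
    mean recombination count; the aneuploidy burden is compared between the
    low- and high-recombination groups, and (when phases are present)
    between MI- and MII-origin embryos.
    """
    ev = per_embryo["recombination_events"].to_numpy(dtype=float)
    an = per_embryo["aneuploidy_count"].to_numpy(dtype=float)
    mean_ev = float(ev.mean())
    low, high = an[ev < mean_ev], an[ev >= mean_ev]
    if low.size < 2 or high.size < 2:
        raise ValueError("need >= 2 embryos on each side of the mean split")
    t_lh = stats.ttest_ind(low, high, equal_var=False)
    out = {
        "mean_events": mean_ev,
        "low_group_mean_aneuploidy": float(low.mean()),
        "high_group_mean_aneuploidy": float(high.mean()),
        "t_low_vs_high": float(t_lh.statistic),
        "p_low_vs_high": float(t_lh.pvalue),
    }
    if "meiotic_phase" in per_embryo.columns:
        mi = an[per_embryo["meiotic_phase"].to_numpy() == "MI"]
        mii = an[per_embryo["meiotic_phase"].to_numpy() == "MII"]
        if mi.size >= 2 and mii.size >= 2:
            t_p = stats.ttest_ind(mi, mii, equal_var=False)
            out.update(
                mi_mean_aneuploidy=float(mi.mean()),
                mii_mean_aneuploidy=float(mii.mean()),
                t_mi_vs_mii=float(t_p.statistic),
                p_mi_vs_mii=float(t_p.pvalue),
            )
    return out
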