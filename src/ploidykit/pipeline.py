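"""End-to-end runner: simulation -> calling -> origin -> recombination ->
isodiploidy screen -> cohort statistics, with one root seed and TSV/JSON
outputs per stage."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calls import SiteFilters, build_trio_genotypes
from .cohort import fit_age_model, recurrence_permutation_test
from .genome import GenomeSpec, default_genome, load_genome_spec, toy_genome
from .isodiploidy import het_fractions, screen_isodiploidy
from .moments import SexKaryotypeCounts, haploid_origin_moments, triploid_origin_moments
from .recomb import concordance_track, detect_recombination_windows, estimate_genotype_error_rate
from .simulate import (
    CohortParams,
    ErrorModel,
    simulate_cohort,
    simulate_embryo_trio,
    simulate_parents,
)
from .trio_origin import score_trio

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Fully serializable run description; same config + seed -> same outputs."""

    seed: int = 0
    genome: str = "toy"  # toy | grch37 | path to a chromosome TSV
    genome_map: str | None = None
    n_sites: int = 1500
    n_trios: int = 40
    trio_scenario_mix: dict = field(
        default_factory=lambda: {
            "maternal_triploid_MI": 0.25,
            "maternal_triploid_MII": 0.55,
            "haploid_paternal_missing": 0.20,
        }
    )
    n_cycles: int = 2000
    n_screen_diploid: int = 200
    n_screen_isodiploid: int = 2
    n_perm_recurrence: int = 2000
    error_model: dict = field(default_factory=dict)
    cohort_params: dict = field(default_factory=dict)
    out_dir: str = "ploidykit_run"

    def genome_spec(self) -> GenomeSpec:
        if self.genome == "toy":
            return toy_genome()
        if self.genome == "grch37":
            return default_genome()
        return load_genome_spec(self.genome, self.genome_map)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the summary dict (also written as JSON)."""
    if config.n_trios < 1 or config.n_cycles < 1:
        raise ValueError("config must request at least one trio and one cycle")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = config.genome_spec()
    em = ErrorModel(**config.error_model)
    ss = np.random.SeedSequence(config.seed)
    rng_cohort, rng_trio, rng_screen = (np.random.default_rng(s) for s in ss.spawn(3))
    summary: dict = {"version": __version__, "seed": config.seed, "genome": config.genome}

    # --- cohort stage -----------------------------------------------------
    params = CohortParams(**config.cohort_params)
    cohort = simulate_cohort(params, config.n_cycles, rng_cohort)
    cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)
    tri = cohort[cohort["label"] == "triploid"]["sex_karyotype"].value_counts()
    hap = cohort[cohort["label"] == "haploid"]["sex_karyotype"].value_counts()
    counts = SexKaryotypeCounts(
        n_xxx=int(tri.get("XXX", 0)), n_xxy=int(tri.get("XXY", 0)), n_xyy=int(tri.get("XYY", 0)),
        n_x=int(hap.get("X", 0)), n_y=int(hap.get("Y", 0)),
    )
    if counts.n_triploid:
        est = triploid_origin_moments(counts)
        summary["moments_triploid"] = {
            "n": counts.n_triploid, "p_female": est.p_female,
            "p_mi": est.p_mi, "p_mii": est.p_mii, "valid": est.valid,
        }
    if counts.n_haploid:
        est = haploid_origin_moments(counts)
        summary["moments_haploid"] = {
            "n": counts.n_haploid, "p_female": est.p_female, "p_male": est.p_male,
        }
    model = fit_age_model(cohort, "any_ploidy_abnormality", ("maternal_age",))
    summary["maternal_age_or"] = model.odds_ratios["maternal_age"]
    summary["maternal_age_or_ci"] = list(model.ci["maternal_age"])
    rec = recurrence_permutation_test(cohort, config.n_perm_recurrence, rng_cohort)
    rec.to_csv(out / "recurrence.tsv", sep="\t", index=False)
    summary["recurrence_cells"] = int(len(rec))

    # --- trio stage -------------------------------------------------------
    scen_names = list(config.trio_scenario_mix)
    scen_p = np.array([config.trio_scenario_mix[s] for s in scen_names], dtype=float)
    scen_p /= scen_p.sum()
    rows = []
    trios = []
    for i in range(config.n_trios):
        scenario = scen_names[rng_trio.choice(len(scen_names), p=scen_p)]
        mother, father, _ = simulate_parents(spec, config.n_sites, rng_trio)
        sim = simulate_embryo_trio(mother, father, spec, scenario, em, rng_trio)
        trio = build_trio_genotypes(sim, spec)
        scores = score_trio(trio)
        n_events = np.nan
        if sim.ploidy == 3:
            trios.append(trio)
            _, n_events = detect_recombination_windows(concordance_track(trio))
        rows.append(
            {
                "trio": i, "scenario": scenario, "ploidy": sim.ploidy,
                "sex_karyotype": sim.sex_karyotype,
                "s_m": scores.s_m, "s_p": scores.s_p,
                "parental_score": scores.parental_score,
                "parental_call": scores.parental_call,
                "s1_bph": scores.s1_bph, "s2_sph": scores.s2_sph,
                "meiotic_score": scores.meiotic_score,
                "meiotic_call": scores.meiotic_call,
                "recombination_events": n_events,
            }
        )
    trio_report = pd.DataFrame(rows)
    trio_report.to_csv(out / "trio_origin.tsv", sep="\t", index=False)
    if trios:
        summary["genotype_error_rate"] = estimate_genotype_error_rate(trios)
    tri_rows = trio_report[trio_report["ploidy"] == 3]
    if len(tri_rows):
        summary["trio_parental_maternal_fraction"] = float(
            (tri_rows["parental_call"] == "maternal").mean()
        )
        summary["mean_recombination_events"] = float(tri_rows["recombination_events"].mean())

    # --- isodiploidy stage ------------------------------------------------
    summaries = []
    truth_iso = []
    for i in range(config.n_screen_diploid + config.n_screen_isodiploid):
        is_iso = i >= config.n_screen_diploid
        mother, father, _ = simulate_parents(spec, config.n_sites, rng_screen)
        sim = simulate_embryo_trio(
            mother, father, spec, "maternal_isodiploid" if is_iso else "diploid", em, rng_screen
        )
        df = sim.sites_frame()
        baf = df["alt_embryo"].to_numpy() / np.maximum(df["depth_embryo"].to_numpy(), 1)
        summaries.append(
            het_fractions(f"s{i}", df["chrom"].to_numpy(), df["pos"].to_numpy(), baf, spec)
        )
        truth_iso.append(is_iso)
    flags = screen_isodiploidy(summaries)
    screen = pd.DataFrame(
        {
            "sample": [s.sample for s in summaries],
            "total_het_fraction": [s.total_het_fraction for s in summaries],
            "peri_het_fraction": [s.peri_het_fraction for s in summaries],
            "p_vs_cohort": [f.p_vs_cohort for f in flags],
            "p_vs_self": [f.p_vs_self for f in flags],
            "screened": [f.screened for f in flags],
            "truth_isodiploid": truth_iso,
        }
    )
    screen.to_csv(out / "isodiploidy.tsv", sep="\t", index=False)
    flagged = screen["screened"].to_numpy()
    truth = np.array(truth_iso)
    summary["isodiploidy_recall"] = float(flagged[truth].mean()) if truth.any() else np.nan
    summary["isodiploidy_false_flags"] = int(flagged[~truth].sum())

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary
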