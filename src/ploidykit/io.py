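"""Reading and writing the package's file formats.

Trios travel as minimal 3-sample VCFs (FORMAT DP and AD, samples EMBRYO /
MOTHER / FATHER) plus an optional truth sidecar TSV; cohorts and reports
are plain TSV. VCF reading goes through cyvcf2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import GenomeSpec
from .simulate import ErrorModel, SimulatedTrio, SitePanel

__all__ = ["write_trio_vcf", "read_trio_vcf", "write_truth_tsv", "write_cohort_tsv", "read_cohort_tsv"]

_SAMPLES = ("EMBRYO", "MOTHER", "FATHER")


def write_trio_vcf(sim: SimulatedTrio, path, spec: GenomeSpec | None = None) -> None:
    """Write one trio as a sites-only VCF with DP and AD per sample."""
    df = sim.sites_frame()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ploidykit\n")
        if spec is not None:
            for c in spec:
                fh.write(f"##contig=<ID={c.name},length={c.length_bp}>\n")
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(_SAMPLES) + "\n")
        cols = {
            "EMBRYO": ("depth_embryo", "alt_embryo"),
            "MOTHER": ("depth_mother", "alt_mother"),
            "FATHER": ("depth_father", "alt_father"),
        }
        for row in df.itertuples(index=False):
            fields = [row.chrom, str(row.pos), ".", row.ref, row.alt, ".", ".", ".", "DP:AD"]
            for s in _SAMPLES:
                dcol, acol = cols[s]
                d = int(getattr(row, dcol))
                a = int(getattr(row, acol))
                fields.append(f"{d}:{d - a},{a}")
            fh.write("\t".join(fields) + "\n")


def read_trio_vcf(path, ploidy: int, error_model: ErrorModel | None = None) -> SimulatedTrio:
    """Load a trio VCF back into the analysis container.

    Ground-truth fields are absent for file-loaded trios; ``ploidy`` is the
    embryo's (clinically) called ploidy.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if samples != list(_SAMPLES):
        raise ValueError(f"expected samples {_SAMPLES}, found {samples}")
    rows = []
    depths = []
    alts = []
    for var in vcf:
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0] if var.ALT else "."))
        dp = var.format("DP").reshape(-1)
        ad = var.format("AD")
        depths.append(dp)
        alts.append(ad[:, 1])
    vcf.close()
    panel_df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    panel_df["freq"] = np.nan
    panel = SitePanel(panel_df)
    depths = np.asarray(depths, dtype=np.int64)
    alts = np.asarray(alts, dtype=np.int64)
    reads = pd.DataFrame(
        {
            "depth_embryo": depths[:, 0], "alt_embryo": alts[:, 0],
            "depth_mother": depths[:, 1], "alt_mother": alts[:, 1],
            "depth_father": depths[:, 2], "alt_father": alts[:, 2],
        }
    )
    n = panel.n_sites
    return SimulatedTrio(
        panel=panel,
        scenario="file",
        ploidy=ploidy,
        sex_karyotype="",
        mother_gt=np.full(n, -1),
        father_gt=np.full(n, -1),
        embryo_alt_copies=np.full(n, -1),
        reads=reads,
        maternal_meiosis=None,
        error_mask=np.zeros(n, dtype=bool),
        error_model=error_model or ErrorModel(),
    )


def write_truth_tsv(sim: SimulatedTrio, path) -> None:
    """Ground-truth sidecar: per-site true dosages, injected errors, and
    (2-chromatid outcomes) the true BPH state."""
    df = sim.panel.df[["chrom", "pos"]].copy()
    df["mother_gt"] = sim.mother_gt
    df["father_gt"] = sim.father_gt
    df["embryo_alt_copies"] = sim.embryo_alt_copies
    df["call_error"] = sim.error_mask
    bph = sim.truth_bph
    df["truth_bph"] = bph if bph is not None else ""
    df.to_csv(path, sep="\t", index=False)


def write_cohort_tsv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
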