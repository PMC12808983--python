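"""Genome coordinate conventions, genetic maps, and pericentromeric masks.

All positions in this package are 1-based inclusive (VCF convention).
A :class:`GenomeSpec` carries, per chromosome, the physical length, the
centromere position, and a monotone piecewise-linear bp -> cM genetic map.
Two specs ship with the package: a GRCh37-like table (22 autosomes + X,
female-map totals summing to ~44 Morgans) and a small 4-chromosome toy
genome with a uniform 1 cM/Mb map used throughout the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "Chromosome",
    "GenomeSpec",
    "GenomeSpecError",
    "load_genome_spec",
    "default_genome",
    "toy_genome",
    "pericentromeric_mask",
]


class GenomeSpecError(ValueError):
    """Raised when a genome specification violates its invariants."""


@dataclass(frozen=True)
class Chromosome:
    """One chromosome: physical extent, centromere, and genetic map anchors."""

    name: str
    length_bp: int
    centromere_bp: int
    map_bp: np.ndarray  # ascending anchor positions, first 0, last length_bp
    map_cm: np.ndarray  # non-decreasing cM at the anchors, first 0

    def __post_init__(self) -> None:
        bp = np.asarray(self.map_bp, dtype=float)
        cm = np.asarray(self.map_cm, dtype=float)
        if bp.size < 2 or bp.size != cm.size:
            raise GenomeSpecError(
                f"{self.name}: genetic map needs >=2 (bp, cM) anchors"
            )
        if bp[0] != 0 or cm[0] != 0:
            raise GenomeSpecError(f"{self.name}: genetic map must start at (0, 0)")
        if bp[-1] != self.length_bp:
            raise GenomeSpecError(
                f"{self.name}: last map anchor must sit at length_bp"
            )
        if np.any(np.diff(bp) <= 0) or np.any(np.diff(cm) < 0):
            raise GenomeSpecError(f"{self.name}: genetic map is not monotone")
        if not (0 < self.centromere_bp < self.length_bp):
            raise GenomeSpecError(
                f"{self.name}: centromere {self.centromere_bp} outside chromosome"
            )
        object.__setattr__(self, "map_bp", bp)
        object.__setattr__(self, "map_cm", cm)

    @property
    def total_cm(self) -> float:
        return float(self.map_cm[-1])

    @property
    def is_autosome(self) -> bool:
        return self.name.lstrip("chr") not in ("X", "Y")

    def bp_to_cm(self, pos) -> np.ndarray:
        """Interpolate genetic position (cM) for physical position(s)."""
        return np.interp(np.asarray(pos, dtype=float), self.map_bp, self.map_cm)

    def cm_to_bp(self, cm) -> np.ndarray:
        """Inverse map; on flat map segments returns the left edge."""
        return np.interp(np.asarray(cm, dtype=float), self.map_cm, self.map_bp)


@dataclass
class GenomeSpec:
    """Ordered chromosome collection with name lookup."""

    chromosomes: list[Chromosome]
    _index: dict[str, Chromosome] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise GenomeSpecError("genome spec lists no chromosomes")
        self._index = {c.name: c for c in self.chromosomes}
        if len(self._index) != len(self.chromosomes):
            raise GenomeSpecError("duplicate chromosome names")

    def __getitem__(self, name: str) -> Chromosome:
        try:
            return self._index[name]
        except KeyError:
            raise GenomeSpecError(f"unknown chromosome {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __iter__(self):
        return iter(self.chromosomes)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def autosomes(self) -> list[Chromosome]:
        return [c for c in self.chromosomes if c.is_autosome]

    @property
    def total_cm(self) -> float:
        return float(sum(c.total_cm for c in self.chromosomes))


def load_genome_spec(chrom_path, map_path=None) -> GenomeSpec:
    """Load a genome spec from TSV tables.

    ``chrom_path``: columns chrom, length_bp, centromere_bp.
    ``map_path``: columns chrom, bp, cM (>=2 anchors per chromosome). When
    omitted, a uniform 1 cM/Mb map is assumed.
    """
    chroms = pd.read_csv(chrom_path, sep="\t")
    required = {"chrom", "length_bp", "centromere_bp"}
    if not required.issubset(chroms.columns):
        raise GenomeSpecError(f"chromosome table needs columns {sorted(required)}")
    if map_path is not None:
        gmap = pd.read_csv(map_path, sep="\t")
        if not {"chrom", "bp", "cM"}.issubset(gmap.columns):
            raise GenomeSpecError("map table needs columns chrom, bp, cM")
        anchors = {name: grp.sort_values("bp") for name, grp in gmap.groupby("chrom")}
    else:
        anchors = None

    out = []
    for row in chroms.itertuples(index=False):
        name, length, cen = str(row.chrom), int(row.length_bp), int(row.centromere_bp)
        if anchors is None:
            bp = np.array([0.0, length])
            cm = np.array([0.0, length / 1e6])
        else:
            if name not in anchors:
                raise GenomeSpecError(f"{name}: no genetic-map anchors")
            bp = anchors[name]["bp"].to_numpy(dtype=float)
            cm = anchors[name]["cM"].to_numpy(dtype=float)
        out.append(Chromosome(name, length, cen, bp, cm))
    return GenomeSpec(out)


def default_genome() -> GenomeSpec:
    """The bundled GRCh37-like spec: 22 autosomes + X, female-map totals."""
    data = resources.files("ploidykit.data")
    with resources.as_file(data / "grch37_chromosomes.tsv") as cpath, resources.as_file(
        data / "grch37_map.tsv"
    ) as mpath:
        return load_genome_spec(cpath, mpath)


def toy_genome() -> GenomeSpec:
    """4-chromosome test genome: 100/80/60/40 Mb, mid-arm centromeres, 1 cM/Mb."""
    out = []
    for i, mb in enumerate((100, 80, 60, 40), start=1):
        length = mb * 1_000_000
        out.append(
            Chromosome(
                name=f"chr{i}",
                length_bp=length,
                centromere_bp=length // 2,
                map_bp=np.array([0.0, length]),
                map_cm=np.array([0.0, float(mb)]),
            )
        )
    return GenomeSpec(out)


def pericentromeric_mask(
    spec: GenomeSpec,
    chrom: np.ndarray,
    pos: np.ndarray,
    radius: float,
    metric: str = "cM",
) -> np.ndarray:
    """Flag sites within ``radius`` of their chromosome's centromere.

    ``metric`` is ``"cM"`` (genetic distance on the spec's map, the 5 cM
    convention used for meiotic-phase calls) or ``"bp"`` (physical distance,
    the 10 Mb convention used for the isodiploidy screen; pass the radius
    in base pairs).
    """
    if metric not in ("cM", "bp"):
        raise ValueError(f"metric must be 'cM' or 'bp', got {metric!r}")
    if radius < 0:
        raise ValueError("radius must be non-negative")
    chrom = np.asarray(chrom)
    pos = np.asarray(pos)
    mask = np.zeros(pos.shape, dtype=bool)
    for name in np.unique(chrom):
        c = spec[str(name)]
        sel = chrom == name
        if metric == "bp":
            dist = np.abs(pos[sel] - c.centromere_bp)
        else:
            dist = np.abs(c.bp_to_cm(pos[sel]) - c.bp_to_cm(c.centromere_bp))
        mask[sel] = dist <= radius
    return mask
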