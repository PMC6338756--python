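"""Study-design and simulator configuration.

The default configuration emulates a two-strain reciprocal mouse cross
(P1 ~ C57BL/6N, P2 ~ C3H/HeN): 6 animals per parental strain (3 sires,
3 dams) and 6 F1 hybrids per cross direction (3 male, 3 female virgins),
24 animals in total, sequenced by paired-end whole-genome bisulfite
sequencing with an unmethylated lambda spike-in for conversion QC.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

GENOTYPES = ("P1", "P2", "F1_P1xP2", "F1_P2xP1")
SEXES = ("M", "F")
PARITIES = ("sire", "dam", "virgin")
AXES = ("genotype", "sex", "parity")

#: polarity labels per axis: which group is hypermethylated inside the DMR
AXIS_POLARITIES = {
    "genotype": ("P1", "P2"),
    "sex": ("M", "F"),
    "parity": ("dam", "virgin"),
}


@dataclass(frozen=True)
class SampleSpec:
    """One study animal."""

    sample_id: str
    genotype: str  # P1 | P2 | F1_P1xP2 | F1_P2xP1
    sex: str  # M | F
    parity: str  # sire | dam | virgin

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.parity not in PARITIES:
            raise ValueError(f"unknown parity {self.parity!r}")

    @property
    def is_f1(self) -> bool:
        return self.genotype.startswith("F1")

    @property
    def haplotypes(self) -> tuple[str, str]:
        """Parental origin of the two haplotypes (homozygous for parents)."""
        if self.genotype == "P1":
            return ("P1", "P1")
        if self.genotype == "P2":
            return ("P2", "P2")
        return ("P1", "P2")


@dataclass(frozen=True)
class DMRSpec:
    """How many DMRs to plant on one axis, and their geometry."""

    axis: str
    count: int
    width_range: tuple[int, int] = (300, 900)
    delta_range: tuple[float, float] = (0.3, 0.6)
    #: fraction of planted DMRs hypermethylated in the *first* polarity
    #: group of AXIS_POLARITIES[axis]
    first_polarity_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.axis not in AXES:
            raise ValueError(f"unknown DMR axis {self.axis!r}")
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if self.width_range[0] < 100:
            raise ValueError("planted DMRs must be >= 100 bp wide")
        lo, hi = self.delta_range
        if not (0.2 < lo <= hi <= 0.8):
            raise ValueError("delta range must lie in (0.2, 0.8]")


@dataclass(frozen=True)
class PlantedDMR:
    """Ground-truth differentially methylated region."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    axis: str
    polarity: str  # hypermethylated group label (e.g. "P1", "F", "virgin")
    delta: float

    def __post_init__(self) -> None:
        if self.end - self.start < 100:
            raise ValueError("planted DMR must span >= 100 bp")
        if not (0.2 < self.delta <= 0.8):
            raise ValueError("delta must lie in (0.2, 0.8]")
        if self.polarity not in AXIS_POLARITIES[self.axis]:
            raise ValueError(
                f"polarity {self.polarity!r} invalid for axis {self.axis!r}"
            )


def default_samples() -> list[SampleSpec]:
    """The 24-animal reciprocal-cross design.

    Parental animals are the breeders (males are sires, females are dams);
    F1 offspring of both sexes are virgins.
    """
    samples: list[SampleSpec] = []
    for strain in ("P1", "P2"):
        for i in range(1, 4):
            samples.append(SampleSpec(f"{strain}_M{i}", strain, "M", "sire"))
        for i in range(1, 4):
            samples.append(SampleSpec(f"{strain}_F{i}", strain, "F", "dam"))
    for cross in ("F1_P1xP2", "F1_P2xP1"):
        tag = "F1a" if cross == "F1_P1xP2" else "F1b"
        for i in range(1, 4):
            samples.append(SampleSpec(f"{tag}_M{i}", cross, "M", "virgin"))
        for i in range(1, 4):
            samples.append(SampleSpec(f"{tag}_F{i}", cross, "F", "virgin"))
    return samples


def default_dmr_specs() -> list[DMRSpec]:
    # Polarity mixes echo the study's observed asymmetries: genotype DMRs
    # balanced, sex DMRs ~2:1 female-hyper, parity DMRs almost all
    # virgin-hyper (dams lose methylation after pregnancy/lactation).
    return [
        DMRSpec("genotype", count=16, first_polarity_fraction=0.5),
        DMRSpec("sex", count=9, first_polarity_fraction=1 / 3),
        DMRSpec("parity", count=5, first_polarity_fraction=0.2),
    ]


@dataclass(frozen=True)
class SimConfig:
    """Full simulator configuration; identical config => identical outputs."""

    seed: int = 42
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    cpg_island_count: int = 25  # per chromosome
    cpg_island_length: int = 1_000
    snv_rate: float = 1 / 900.0  # ~2.8M autosomal SNVs over ~2.5 Gb
    cpg_snv_fraction: float = 0.2  # SNVs placed to create/destroy CpGs
    dmr_specs: tuple[DMRSpec, ...] = field(
        default_factory=lambda: tuple(default_dmr_specs())
    )
    min_cpgs_per_dmr: int = 8  # planted DMRs must contain this many shared CpGs
    depth: float = 20.0  # mean fragment coverage per sample
    read_length: int = 100  # PE100 geometry
    fragment_length_mean: float = 300.0
    fragment_length_sd: float = 30.0
    conversion_rate: float = 0.995  # observed conversion > 99% in the study
    error_rate: float = 0.001
    bio_sd: float = 0.05  # replicate SD floor ~5 percentage points
    island_meth: float = 0.1
    background_meth: float = 0.85
    non_cpg_meth: float = 0.0
    variable_fraction: float = 0.0  # extra highly-variable sites (intermediate meth)
    variable_sd: float = 0.3
    lambda_length: int = 20_000
    samples: tuple[SampleSpec, ...] = field(
        default_factory=lambda: tuple(default_samples())
    )

    def __post_init__(self) -> None:
        for name in ("conversion_rate", "error_rate", "bio_sd"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        for name in (
            "n_chroms",
            "chrom_length",
            "cpg_island_length",
            "read_length",
            "lambda_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fragment_length_mean < self.read_length:
            raise ValueError("fragment_length_mean must be >= read_length")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_id values must be unique")
        if not 0.0 <= self.snv_rate < 0.1:
            raise ValueError("snv_rate must lie in [0, 0.1)")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    @property
    def genome_length(self) -> int:
        return self.n_chroms * self.chrom_length

    def with_(self, **kwargs) -> "SimConfig":
        """Return a modified copy (dataclasses.replace convenience)."""
        return replace(self, **kwargs)

    def sample_by_id(self, sample_id: str) -> SampleSpec:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)
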