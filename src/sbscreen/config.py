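"""Screen configuration for the forward simulator and pipeline defaults."""

from __future__ import annotations

from dataclasses import dataclass


class ConfigurationError(ValueError):
    """Raised when a screen configuration is internally inconsistent."""


@dataclass
class ScreenConfig:
    """Parameters of a simulated Sleeping Beauty mutagenesis screen.

    The defaults describe a two-compartment screen of 40 primary mammary
    tumors and 30 lung metastases with planted primary-specific (P),
    metastasis-specific (M) and shared (S) driver genes.  Read counts per
    insertion are negative-binomial: high-mean for clonal (selected driver)
    insertions and low-mean for subclonal passenger background, so that the
    dynamic clonal filter has a real signal to separate.  One transposon
    donor concatemer sits on ``donor_chromosome`` and inflates local
    background insertion density (local hopping); one multi-copy
    ``artifact_gene`` collects recurrent insertions in both compartments,
    emulating the Sfi1 artifact of real SB screens.
    """

    seed: int = 0
    # genome / gene models
    n_chromosomes: int = 4
    chrom_length: int = 150_000
    n_genes: int = 80
    gene_length_range: tuple[int, int] = (2_000, 6_000)
    # cohort
    n_primary_samples: int = 40
    n_met_samples: int = 30
    planted_p_drivers: tuple[str, ...] = ("Pdrv1", "Pdrv2", "Pdrv3", "Pdrv4", "Pdrv5")
    planted_m_drivers: tuple[str, ...] = ("Mdrv1", "Mdrv2", "Mdrv3", "Mdrv4", "Mdrv5")
    planted_shared_drivers: tuple[str, ...] = ("Sdrv1", "Sdrv2", "Sdrv3", "Sdrv4")
    # read-count model (negative binomial: mean, dispersion/size)
    clonal_count_mean: float = 300.0
    subclonal_count_mean: float = 10.0
    clonal_dispersion: float = 5.0
    subclonal_dispersion: float = 2.0
    # insertion landscape
    background_insertions_per_sample: int = 2000
    driver_hit_probability: float = 0.8
    donor_chromosome: str = "chr1"
    local_hop_excess: float = 5.0
    met_inherited_fraction: float = 0.5
    single_library_fraction: float = 0.1
    artifact_gene: str = "Sfi1like"
    artifact_hit_probability: float = 0.6
    # read emission
    read_length: int = 50
    chrom_end_margin: int = 200

    def validate(self) -> None:
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "chrom_length": self.chrom_length,
            "n_genes": self.n_genes,
            "n_primary_samples": self.n_primary_samples,
            "n_met_samples": self.n_met_samples,
            "background_insertions_per_sample": self.background_insertions_per_sample,
        }
        for name, value in counts.items():
            if value < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {value}")
        probs = {
            "driver_hit_probability": self.driver_hit_probability,
            "met_inherited_fraction": self.met_inherited_fraction,
            "single_library_fraction": self.single_library_fraction,
            "artifact_hit_probability": self.artifact_hit_probability,
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        lo, hi = self.gene_length_range
        if not 0 < lo <= hi:
            raise ConfigurationError(f"invalid gene_length_range {self.gene_length_range}")
        p, m, s = (
            set(self.planted_p_drivers),
            set(self.planted_m_drivers),
            set(self.planted_shared_drivers),
        )
        if p & m or p & s or m & s:
            raise ConfigurationError("planted driver sets must be pairwise disjoint")
        if self.artifact_gene in p | m | s:
            raise ConfigurationError("artifact gene cannot also be a planted driver")
        # each gene needs its span plus breathing room on its chromosome
        per_chrom = -(-self.n_genes // max(self.n_chromosomes, 1))
        if per_chrom * (hi + 2) >= self.chrom_length:
            raise ConfigurationError(
                "gene count x max gene length exceeds genome capacity: "
                f"{per_chrom} genes of up to {hi} bp per {self.chrom_length} bp chromosome"
            )
        if self.local_hop_excess < 0:
            raise ConfigurationError("local_hop_excess must be >= 0")
        n_drivers = len(p) + len(m) + len(s) + 1
        if n_drivers > self.n_genes:
            raise ConfigurationError("more planted driver names than simulated genes")

    @property
    def chromosome_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def all_driver_names(self) -> list[str]:
        return (
            list(self.planted_p_drivers)
            + list(self.planted_m_drivers)
            + list(self.planted_shared_drivers)
        )
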