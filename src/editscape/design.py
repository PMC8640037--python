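"""Study design for the synthetic editing-atlas cohort.

The generator emulates a multi-dataset postmortem-brain cohort: several
datasets of subjects, each sampled in two or more brain regions, with
per-site read depths drawn around a sequencing depth typical of bulk
RNA-seq, and with two kinds of planted signal — a regional shift in editing
level at designated sites, and a per-diagnosis-step shift at designated
disease sites (diagnosis coded 0 = control, 1 = MCI, 2 = AD; one
MAYO-like dataset carries 0/2 only).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of the synthetic cohort; a fixed seed gives byte-identical outputs.

    Parameters
    ----------
    n_subjects_per_dataset : int
        Subjects per dataset; every subject is sampled in all regions.
    n_regions : int
        Brain regions per dataset (region ``R2`` carries the planted shift).
    n_sites : int
        Editing sites placed on the toy genome.
    fraction_recoding : float
        Fraction of sites placed inside coding exons (candidate re-coding
        events); the remainder land in UTRs, introns and flanks.
    planted_region_delta : float
        Editing-level difference (proportion units) added in the designated
        region at the planted regional sites.
    planted_ad_beta : float
        Editing-level change per diagnosis step (0/1/2) at the planted
        disease sites.
    batch_factors : tuple of float
        Per-TMT-batch multiplicative scalars for the peptide matrix; the
        tuple length sets the number of batches.
    depth_mean : float
        Mean total read depth per call; depths are negative-binomial so a
        realistic tail of low-depth calls fails QC naturally.
    seed : int
        Root seed for all random streams.
    """

    n_subjects_per_dataset: int = 600
    n_regions: int = 2
    n_sites: int = 60
    fraction_recoding: float = 0.3
    planted_region_delta: float = 0.30
    planted_ad_beta: float = 0.05
    batch_factors: tuple[float, ...] = (1.0, 2.0)
    depth_mean: float = 500.0
    seed: int = 0

    # cohort structure beyond the headline knobs
    n_datasets: int = 4
    n_planted_region: int = 10
    n_planted_ad: int = 10
    fraction_reported: float = 0.5
    fraction_known_variant: float = 0.05
    subject_level_sd: float = 0.02
    depth_dispersion: float = 10.0
    peptide_noise_sd: float = 0.05
    peptide_missing_fraction: float = 0.2
    n_case_per_batch: int = 8
    mayo_like_dataset: int | None = 2  # 0-based index of the 0/2-coded dataset
    n_transcripts: int | None = None   # default: scaled to n_sites

    def __post_init__(self) -> None:
        for name in ("fraction_recoding", "fraction_reported",
                     "fraction_known_variant", "peptide_missing_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.planted_region_delta <= 1.0:
            raise ValueError("planted_region_delta must lie in [0, 1]")
        if not -1.0 <= self.planted_ad_beta <= 1.0:
            raise ValueError("planted_ad_beta must lie in [-1, 1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.n_regions < 1 or self.n_sites < 1 or self.n_subjects_per_dataset < 1:
            raise ValueError("counts must be positive")
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be positive")
        if len(self.batch_factors) < 1 or any(f <= 0 for f in self.batch_factors):
            raise ValueError("batch_factors must be positive scalars")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")

    @property
    def dataset_names(self) -> list[str]:
        return [f"ds{i + 1}" for i in range(self.n_datasets)]

    @property
    def region_names(self) -> list[str]:
        return [f"R{i + 1}" for i in range(self.n_regions)]

    def diagnosis_codes(self, dataset_index: int) -> tuple[int, ...]:
        """Diagnosis levels available in a dataset (MAYO-like omits MCI)."""
        if self.mayo_like_dataset is not None and dataset_index == self.mayo_like_dataset:
            return (0, 2)
        return (0, 1, 2)
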