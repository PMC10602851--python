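"""Shared configuration dataclasses: analysis thresholds and simulation knobs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field


@dataclass(frozen=True)
class Thresholds:
    """Significance and abundance cutoffs used throughout the pipeline.

    All comparisons against these values are strict inequalities, mirroring
    the ">" convention of the source thresholds.

    Attributes
    ----------
    fc_threshold : float
        Minimum |log2 fold change| for a differential call (log2 units).
    alpha : float
        BH-adjusted p-value cutoff.
    min_tpm : float
        RNA abundance floor (TPM) applied before multiple-testing correction.
    min_tags : float
        Normalized tag-depth floor for peak assays; also the "accessible"
        cutoff for ATAC signal.
    active_tags : float
        Normalized H3K27ac tag cutoff defining "active" loci.
    tag_norm_total : float
        Per-library total that normalized tag counts are scaled to.
    tpm_total : float
        TPM column total (1e6 by definition).
    """

    fc_threshold: float = 1.0
    alpha: float = 0.05
    min_tpm: float = 8.0
    min_tags: float = 16.0
    active_tags: float = 32.0
    tag_norm_total: float = 1e7
    tpm_total: float = 1e6

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"Thresholds.{f.name} must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic-data generator.

    The negative binomial is parameterized as var = mu + alpha * mu**2 with a
    single dispersion ``nb_dispersion`` shared across features.

    Attributes
    ----------
    genome_length : int
        Reference length in bases (single chromosome).
    snp_density : float
        Expected variants per base (Poisson).
    indel_fraction : float
        Fraction of variants that are short indels rather than SNPs.
    max_indel_len : int
        Maximum inserted/deleted length in bases.
    n_features : int
        Number of features (genes or peaks) to simulate.
    read_length : int
        Simulated read length in bases.
    mean_depth : float
        Expected reads (or NB mean count) per feature.
    nb_dispersion : float
        NB dispersion alpha.
    effect_log2fc : float
        Planted |log2 fold change| for biased contrasts.
    class_proportions : dict
        Mapping regulation-class label -> fraction; must sum to 1.
    n_replicates : int
        Biological replicates per design arm.
    error_rate : float
        Uniform substitution sequencing-error rate (0 = error-free).
    seed : int
        Seed that fully determines every output.
    """

    genome_length: int = 100_000
    snp_density: float = 1.0 / 150.0
    indel_fraction: float = 0.1
    max_indel_len: int = 6
    n_features: int = 200
    read_length: int = 40
    mean_depth: float = 500.0
    nb_dispersion: float = 0.05
    effect_log2fc: float = 2.0
    class_proportions: dict = field(
        default_factory=lambda: {
            "cis": 0.2,
            "trans_environmental": 0.2,
            "trans_cellautonomous": 0.2,
            "mixed": 0.2,
            "same": 0.2,
        }
    )
    n_replicates: int = 3
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.indel_fraction <= 1.0):
            raise ValueError("indel_fraction must be in [0, 1]")
        if not (0.0 <= self.error_rate <= 1.0):
            raise ValueError("error_rate must be in [0, 1]")
        if self.snp_density < 0:
            raise ValueError("snp_density must be non-negative")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_proportions must sum to 1, got {total}")
        if any(v < 0 for v in self.class_proportions.values()):
            raise ValueError("class_proportions must be non-negative")

    def config_hash(self) -> str:
        """Short stable hash identifying this configuration (for output headers)."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


REGULATION_CLASSES = ("cis", "trans_environmental", "trans_cellautonomous", "mixed", "same")
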