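"""Cohort configuration and shared defaults for the quantification pipeline.

The :class:`CohortConfig` dataclass controls every aspect of the synthetic
cohort generator: plate layout, protein/peptide/transition counts, the three
multiplicative noise levels, missingness, planted quality failures, and the
planted biological effects (disease signatures and sex effects).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

# Pan-cancer cohort composition: 15 cancer types, 1800 patients in total.
FULL_COHORT_COUNTS: Dict[str, int] = {
    "PIT_NET": 50,
    "LYMPHOMA": 56,
    "CLL": 50,
    "AML": 52,
    "MM": 55,
    "BRC": 164,
    "OVC": 179,
    "ENDC": 110,
    "CVX": 110,
    "PRC": 172,
    "CRC": 248,
    "SI_NET": 54,
    "LUNGC": 289,
    "MENINGIOMA": 51,
    "GLIOMA": 160,
}

# Cancers restricted to a single sex; used both when drawing patient sexes
# and when restricting the "rest" group in one-vs-rest comparisons.
SEX_RESTRICTED_CANCERS: Dict[str, str] = {
    "PRC": "male",
    "BRC": "female",
    "OVC": "female",
    "ENDC": "female",
    "CVX": "female",
}

# Planted multiple-myeloma signature.  Magnitudes are synthetic choices:
# the direction of each effect is the biological claim, the size is ours.
MM_SIGNATURE_DOWN: Tuple[str, ...] = (
    "C1QB", "C1QC", "C1R", "C1S", "JCHAIN", "CD5L", "CPN1",
)
MM_SIGNATURE_UP: Tuple[str, ...] = ("TGFBI", "CFD", "MGP")

DEFAULT_EFFECT_TABLE: Dict[str, Dict[str, float]] = {
    "MM": {**{p: -1.0 for p in MM_SIGNATURE_DOWN},
           **{p: 0.7 for p in MM_SIGNATURE_UP}},
}

# Female/male concentration fold per protein (PZP-like behaviour).
DEFAULT_SEX_EFFECTS: Dict[str, float] = {"PZP": 10.0}

# Proteins that always appear first in the synthetic panel, in this order.
CORE_PROTEINS: Tuple[str, ...] = (
    MM_SIGNATURE_DOWN + MM_SIGNATURE_UP + ("PZP", "LPA", "APOA1")
)

ANCHOR_PROTEIN = "APOA1"


class ConfigError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


@dataclass
class CohortConfig:
    """Full parameterisation of a synthetic study.

    Noise is multiplicative and lognormal at three levels: biological
    (``sigma_bio``, log2 units, patient-to-patient), plate (``sigma_plate``,
    natural-log units, shared by all samples on a plate) and injection
    (``sigma_intra``, natural-log units, per sample x peptide).  Injection
    and plate noise act on the light (endogenous) channel so that the
    light/heavy ratio carries exactly ``sigma_intra`` of injection variance;
    ``sigma_heavy`` adds independent heavy-channel noise if wanted.
    """

    cancer_counts: Dict[str, int] = field(
        default_factory=lambda: dict(FULL_COHORT_COUNTS))
    wells_per_plate: int = 96
    pool_replicates: int = 3
    n_plates: Optional[int] = None

    n_proteins: int = 60
    peptides_per_protein: int = 2
    transitions_per_peptide: int = 5

    dynamic_range_decades: float = 6.0
    log10_min_conc: float = -3.0

    sigma_bio: float = 0.5       # log2 units
    sigma_intra: float = 0.1     # natural-log units
    sigma_plate: float = 0.1     # natural-log units
    sigma_heavy: float = 0.0     # natural-log units

    channel_dropout: float = 0.02
    transition_dropout: float = 0.02
    corrupted_fraction: float = 0.01
    qc_fail_fraction: float = 0.02
    low_yield_keep_fraction: float = 0.05

    effect_table: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {c: dict(t) for c, t in DEFAULT_EFFECT_TABLE.items()})
    sex_effects: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SEX_EFFECTS))

    # Retention-time model for the anchor-peptide regression.
    rt_slope: float = 0.5
    rt_intercept: float = 10.0
    rt_noise_sd: float = 0.1
    n_anchor_peptides: int = 12

    seed: int = 0

    # ------------------------------------------------------------------
    @property
    def plate_capacity(self) -> int:
        """Patient wells per plate once pool wells are reserved."""
        return self.wells_per_plate - self.pool_replicates

    @property
    def n_patients(self) -> int:
        return sum(self.cancer_counts.values())

    @property
    def n_peptides(self) -> int:
        return self.n_proteins * self.peptides_per_protein

    def validate(self) -> None:
        """Raise :class:`ConfigError` on any invariant violation."""
        probs = {
            "channel_dropout": self.channel_dropout,
            "transition_dropout": self.transition_dropout,
            "corrupted_fraction": self.corrupted_fraction,
            "qc_fail_fraction": self.qc_fail_fraction,
            "low_yield_keep_fraction": self.low_yield_keep_fraction,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        for name, s in {
            "sigma_bio": self.sigma_bio,
            "sigma_intra": self.sigma_intra,
            "sigma_plate": self.sigma_plate,
            "sigma_heavy": self.sigma_heavy,
            "rt_noise_sd": self.rt_noise_sd,
        }.items():
            if s < 0:
                raise ConfigError(f"{name} must be >= 0, got {s}")
        for cancer, n in self.cancer_counts.items():
            if n < 0:
                raise ConfigError(f"count for {cancer} must be >= 0, got {n}")
        if self.pool_replicates < 0 or self.wells_per_plate < 1:
            raise ConfigError("invalid plate geometry")
        if self.plate_capacity < 0:
            raise ConfigError(
                "pool replicates exceed wells per plate "
                f"({self.pool_replicates} > {self.wells_per_plate})")
        if self.n_proteins < len(CORE_PROTEINS):
            raise ConfigError(
                f"n_proteins must be >= {len(CORE_PROTEINS)} to hold the "
                "core panel proteins")
        if self.peptides_per_protein < 1 or self.transitions_per_peptide < 1:
            raise ConfigError("need >= 1 peptide per protein and transition per peptide")
        if self.n_plates is not None:
            if self.n_plates < 1:
                raise ConfigError("n_plates must be >= 1")
            if self.n_patients > self.n_plates * self.plate_capacity:
                raise ConfigError(
                    f"{self.n_patients} patients exceed capacity of "
                    f"{self.n_plates} plates x {self.plate_capacity} wells")

    def required_plates(self) -> int:
        if self.n_plates is not None:
            return self.n_plates
        if self.n_patients == 0:
            return 1
        return math.ceil(self.n_patients / max(self.plate_capacity, 1))

    def with_overrides(self, **kwargs) -> "CohortConfig":
        return replace(self, **kwargs)


def noiseless(config: CohortConfig) -> CohortConfig:
    """Copy of *config* with every noise and failure mechanism disabled."""
    return config.with_overrides(
        sigma_bio=0.0, sigma_intra=0.0, sigma_plate=0.0, sigma_heavy=0.0,
        channel_dropout=0.0, transition_dropout=0.0,
        corrupted_fraction=0.0, qc_fail_fraction=0.0, rt_noise_sd=0.0,
    )


def desk_config(seed: int = 0, total_patients: int = 350) -> CohortConfig:
    """Desk-scale default: ~350 patients proportional to the full cohort,
    60 proteins x 2 peptides x 5 transitions on 4 plates."""
    scale = total_patients / sum(FULL_COHORT_COUNTS.values())
    counts = {c: max(1, round(n * scale)) for c, n in FULL_COHORT_COUNTS.items()}
    cfg = CohortConfig(cancer_counts=counts, n_plates=4, seed=seed)
    cfg.validate()
    return cfg


def full_config(seed: int = 0) -> CohortConfig:
    """Full-scale cohort: 1800 patients on 33 plates, 276-standard panel
    scale (253 target proteins)."""
    cfg = CohortConfig(
        cancer_counts=dict(FULL_COHORT_COUNTS),
        n_plates=33,
        n_proteins=253,
        peptides_per_protein=4,
        seed=seed,
    )
    cfg.validate()
    return cfg
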