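"""Run and simulation configuration objects.

All stochastic stages draw from generators seeded off a single integer so
that a given configuration reproduces bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from ecmcomm.errors import ValidationError

HABITATS = ("serpentine", "non_serpentine")

ASSEMBLY_MODELS = ("filtered", "random", "overdispersed")

NULL_MODELS = ("independent_swap", "phylogeny_shuffle", "pool_draw")


@dataclass
class RunConfig:
    """Fixed analysis settings for a pipeline run.

    Defaults encode the study's choices: a 0.95 similarity cut-off for OTU
    delimitation, 999 independent-swap null randomizations, and a genus
    accepted only when the first 20 taxonomy hits agree.
    """

    similarity_threshold: float = 0.95
    n_null_runs: int = 999
    null_model: str = "independent_swap"
    seed: int = 0
    crown_cap_beta: float = 0.9
    ordination_k: int = 2
    min_hits: int = 20

    def __post_init__(self) -> None:
        if not 0.0 < self.similarity_threshold < 1.0:
            raise ValidationError(
                f"similarity_threshold must be in (0,1), got {self.similarity_threshold}"
            )
        if self.n_null_runs < 1:
            raise ValidationError(f"n_null_runs must be >= 1, got {self.n_null_runs}")
        if not 0.0 < self.crown_cap_beta < 1.0:
            raise ValidationError(
                f"crown_cap_beta must be in (0,1), got {self.crown_cap_beta}"
            )
        if self.null_model not in NULL_MODELS:
            raise ValidationError(
                f"null_model must be one of {NULL_MODELS}, got {self.null_model!r}"
            )
        if self.ordination_k < 1:
            raise ValidationError("ordination_k must be >= 1")
        if self.min_hits < 1:
            raise ValidationError("min_hits must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic two-habitat study generator.

    The design mirrors the field layout: two habitats, ``n_forests_per_habitat``
    forests each, ``n_samples_per_forest`` soil cubes per forest, and three to
    six root tips per cube averaging four.  Sequences evolve under HKY85 on a
    shared species pool tree, with the ITS marker running ``its_rate_ratio``
    times faster than LSU.
    """

    n_species_pool: int = 64
    birth_rate: float = 1.0
    kappa: float = 2.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    lsu_rate: float = 0.1
    its_rate_ratio: float = 3.0
    seq_len_its: int = 600
    seq_len_lsu: int = 900
    n_forests_per_habitat: int = 2
    n_samples_per_forest: int = 20
    tips_per_sample_min: int = 3
    tips_per_sample_max: int = 6
    # P(richness = 3..6); mean exactly 4
    tips_per_sample_probs: tuple[float, ...] = (0.35, 0.40, 0.15, 0.10)
    assembly_model: str = "random"
    assembly_model_by_habitat: dict[str, str] | None = None
    filter_strength: float = 0.0
    genus_cut_age: float = 0.45
    outgroup_depth_factor: float = 1.5
    soil_n_reps: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species_pool < 4:
            raise ValidationError("n_species_pool must be >= 4")
        if abs(sum(self.base_freqs) - 1.0) > 1e-12:
            raise ValidationError("base_freqs must sum to 1")
        if self.its_rate_ratio <= 0:
            raise ValidationError("its_rate_ratio must be > 0")
        if self.birth_rate <= 0:
            raise ValidationError("birth_rate must be > 0")
        if self.filter_strength < 0:
            raise ValidationError("filter_strength must be >= 0")
        if self.assembly_model not in ASSEMBLY_MODELS:
            raise ValidationError(
                f"assembly_model must be one of {ASSEMBLY_MODELS}, got {self.assembly_model!r}"
            )
        if self.assembly_model_by_habitat is not None:
            for hab, model in self.assembly_model_by_habitat.items():
                if hab not in HABITATS:
                    raise ValidationError(f"unknown habitat {hab!r}")
                if model not in ASSEMBLY_MODELS:
                    raise ValidationError(f"unknown assembly model {model!r}")
        n_rich = self.tips_per_sample_max - self.tips_per_sample_min + 1
        if len(self.tips_per_sample_probs) != n_rich:
            raise ValidationError(
                "tips_per_sample_probs length must match the richness range"
            )
        if abs(sum(self.tips_per_sample_probs) - 1.0) > 1e-9:
            raise ValidationError("tips_per_sample_probs must sum to 1")
        if not 0.0 < self.genus_cut_age < 1.0:
            raise ValidationError("genus_cut_age must be in (0,1)")

    def model_for(self, habitat: str) -> str:
        if self.assembly_model_by_habitat and habitat in self.assembly_model_by_habitat:
            return self.assembly_model_by_habitat[habitat]
        return self.assembly_model

    def to_dict(self) -> dict:
        return asdict(self)
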