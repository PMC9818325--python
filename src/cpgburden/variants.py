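"""Domain types for annotated germline variants and the filter cascade.

A variant enters the pipeline already annotated (gene symbol, consequence
class, caller quality, repeat flag, super-control and population-database
allele frequencies, ClinVar interpretation, exon/intron geometry). The
cascade consumes nothing else: no sequence context or genome coordinates
are required.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Optional

from pydantic import BaseModel, Field, field_validator, model_validator

#: Consequence classes the cascade distinguishes.
Consequence = Literal[
    "frameshift",
    "stop_gained",
    "canonical_splice",
    "missense",
    "synonymous",
    "inframe_indel",
    "utr",
    "upstream_downstream_intergenic",
    "intronic",
    "cnv_deletion",
    "cnv_duplication",
]

#: ClinVar clinical-significance summary values.
ClinvarCall = Literal[
    "pathogenic",
    "likely_pathogenic",
    "vus",
    "benign",
    "likely_benign",
    "conflicting",
    "none",
]

#: Population frequency databases consulted at the population-MAF stage.
POPULATION_DATABASES = ("gnomAD", "1000Genomes", "ESP", "ExAC")

#: Sequential removal stages, in the order they are applied.
STAGE_ORDER = (
    "i_quality",
    "ii_repeat",
    "iii_noncoding_inframe",
    "iv_supercontrol_maf",
    "v_population_maf",
    "vi_clinvar_benign",
    "vii_last_exon",
    "viii_deep_intronic",
    "ix_synonymous",
    "x_sequencing_error",
)

#: Label for variants that survive all ten stages but fail the final
#: pathogenicity retention rule (not ClinVar P/LP and not truncating).
FINAL_STAGE = "final_not_pathogenic"

ALL_REMOVAL_STAGES = STAGE_ORDER + (FINAL_STAGE,)

#: Copy-number consequences: exon-geometry predicates (stages iii, vii,
#: viii, ix) are undefined for these and are skipped.
CNV_CONSEQUENCES = frozenset({"cnv_deletion", "cnv_duplication"})


class AnnotatedVariant(BaseModel):
    """One called germline variant in one sample, with its annotations."""

    model_config = {"frozen": True}

    sample_id: str = Field(min_length=1)
    gene: str = Field(min_length=1)
    variant_id: str = Field(min_length=1)
    quality: float = Field(ge=0)
    in_repeat_region: bool = False
    consequence: Consequence
    #: Signed distance in bp from the nearest exon boundary; 0 for exonic
    #: consequences, nonzero only for intronic / canonical-splice records.
    intron_offset: int = 0
    in_last_exon: bool = False
    #: Allele frequency among healthy elderly "super-controls"; None if
    #: the variant was not seen there (treated as 0 by the cascade).
    maf_supercontrols: Optional[float] = Field(default=None, ge=0, le=1)
    #: Per-database population allele frequencies; absent entries mean the
    #: variant is not recorded in that database.
    maf_population: Mapping[str, float] = Field(default_factory=dict)
    clinvar: ClinvarCall = "none"
    known_sequencing_error: bool = False
    known_pathogenic_whitelisted: bool = False

    @field_validator("maf_population")
    @classmethod
    def _check_mafs(cls, v: Mapping[str, float]) -> Mapping[str, float]:
        for db, maf in v.items():
            if db not in POPULATION_DATABASES:
                raise ValueError(
                    f"unknown population database {db!r}; "
                    f"expected one of {POPULATION_DATABASES}"
                )
            if not 0 <= maf <= 1:
                raise ValueError(f"MAF for {db} out of [0, 1]: {maf}")
        return dict(v)

    @model_validator(mode="after")
    def _check_offset(self) -> "AnnotatedVariant":
        if self.intron_offset != 0 and self.consequence not in (
            "intronic",
            "canonical_splice",
        ):
            raise ValueError(
                "intron_offset is only meaningful for intronic or "
                f"canonical_splice consequences, got {self.consequence!r}"
            )
        return self


class PrioritizationConfig(BaseModel):
    """Tunable thresholds of the cascade.

    quality_min
        Minimum caller quality score; variants strictly below are removed.
    maf_max
        Allele-frequency ceiling (default 0.4%); frequencies strictly
        above it, in super-controls or any population database, are removed.
    splice_window_bp
        Distance from an exon boundary (in bp) still considered a
        conserved splice site; intronic variants beyond it are removed.
    """

    model_config = {"frozen": True}

    quality_min: float = Field(default=150.0, ge=0)
    maf_max: float = Field(default=0.004, gt=0, lt=1)
    splice_window_bp: int = Field(default=2, ge=1)


@dataclass(frozen=True)
class FilterOutcome:
    """A variant's fate in the cascade: retained, or removed at exactly
    one named stage (the first failing one)."""

    variant: AnnotatedVariant
    status: Literal["retained", "removed"]
    removal_stage: Optional[str] = None
    stage_detail: str = ""

    def __post_init__(self) -> None:
        if (self.status == "removed") != (self.removal_stage is not None):
            raise ValueError("removal_stage must be set iff status is 'removed'")
        if self.removal_stage is not None and self.removal_stage not in ALL_REMOVAL_STAGES:
            raise ValueError(f"unknown removal stage {self.removal_stage!r}")
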