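"""Synthetic two-group cohort generator with known ground truth.

Emulates the structure of a germline screening study: cases (HCC liver
transplant candidates) and population controls, each subject carrying
planted pathogenic variants with configurable per-gene, per-group
probabilities, plus "nuisance" variants constructed to be removed at a
specific cascade stage. The ground truth indexes every planted record so
cascade recall and stage attribution are exactly checkable.

Defaults mirror the bundled reference cohort: 334 cases vs 1662
controls, per-gene carrier probabilities equal to the observed carrier
fractions, and clinical covariate prevalences equal to the reference
cohort's marginal proportions (e.g. cirrhosis 98.5%, alcoholic etiology
38.6%). Covariates are sampled independently; no correlation structure
is modeled. Survival is exponential with administrative censoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Set, Tuple

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .cascade import first_failing_stage
from .panel import GenePanel, default_panel
from .variants import (
    ALL_REMOVAL_STAGES,
    FINAL_STAGE,
    STAGE_ORDER,
    AnnotatedVariant,
    PrioritizationConfig,
)
from .clinical import PhenotypeRecord

#: Reference per-gene distinct-carrier counts (cases n=334, controls n=1662)
#: used for the default carrier probabilities.
_REFERENCE_CASE_COUNTS: Dict[str, int] = {
    "PMS2": 1, "NBN": 4, "FH": 1, "RET": 1,
    "DMBT1": 3, "RAD50": 3, "ATRIP": 2, "BLM": 2, "ERCC2": 2, "LIG3": 2,
    "MSH3": 2, "SLX4": 2, "AXIN1": 1, "ERCC5": 1, "ERCC6": 1, "EXO1": 1,
    "FANCA": 1, "FANCD2": 1, "FANCG": 1, "HOXB13": 1, "MCPH1": 1, "MDC1": 1,
    "MLH3": 1, "MMP8": 1, "NHEJ1": 1, "PIK3CG": 1, "PMS1": 1, "RAD1": 1,
    "RECQL5": 1, "SBDS": 1, "SETX": 1, "SMARCA4": 1, "TLR2": 1, "TLR4": 1,
    "XRCC1": 1,
}
_REFERENCE_CONTROL_COUNTS: Dict[str, int] = {
    "PMS2": 4, "NBN": 4, "FH": 0, "RET": 2,
    "DMBT1": 2, "RAD50": 3, "ATRIP": 3, "BLM": 7, "ERCC2": 8, "LIG3": 1,
    "MSH3": 6, "SLX4": 2, "AXIN1": 0, "ERCC5": 0, "ERCC6": 0, "EXO1": 2,
    "FANCA": 7, "FANCD2": 0, "FANCG": 2, "HOXB13": 4, "MCPH1": 10, "MDC1": 0,
    "MLH3": 1, "MMP8": 5, "NHEJ1": 0, "PIK3CG": 0, "PMS1": 2, "RAD1": 0,
    "RECQL5": 6, "SBDS": 13, "SETX": 10, "SMARCA4": 0, "TLR2": 1, "TLR4": 2,
    "XRCC1": 7,
}


class GeneCarrierProb(BaseModel):
    """Per-subject carrier probability for one gene, by group."""

    model_config = {"frozen": True}

    cases: float = Field(ge=0, le=1)
    controls: float = Field(ge=0, le=1)


class SurvivalParams(BaseModel):
    """Exponential survival with administrative censoring at the horizon."""

    model_config = {"frozen": True}

    hazard_per_month: float = Field(default=0.008, gt=0)
    censor_horizon_months: float = Field(default=264.0, gt=0)


class CovariateParams(BaseModel):
    """Marginal prevalences of the clinical covariates (defaults mirror the
    reference cohort's proportions). Etiology probabilities must sum to 1;
    cirrhosis is implied by etiology != 'none'."""

    model_config = {"frozen": True}

    male_prob: float = Field(default=0.772, ge=0, le=1)
    etiology_probs: Dict[str, float] = Field(
        default_factory=lambda: {
            "alcoholic": 0.386,
            "viral": 0.359,
            "cholestatic_autoimmune": 0.144,
            "NASH": 0.087,
            "metabolic": 0.009,
            "none": 0.015,
        }
    )
    diabetes_prob: float = Field(default=0.413, ge=0, le=1)
    obesity_prob: float = Field(default=0.281, ge=0, le=1)
    smoking_prob: float = Field(default=0.575, ge=0, le=1)
    microangioinvasion_prob: float = Field(default=0.456, ge=0, le=1)
    cholangio_differentiation_prob: float = Field(default=0.054, ge=0, le=1)
    recurrence_post_tx_prob: float = Field(default=0.10, ge=0, le=1)
    multiple_primary_tumors_prob: float = Field(default=0.171, ge=0, le=1)
    family_history_prob: float = Field(default=0.392, ge=0, le=1)
    age_mean: float = Field(default=62.0, gt=0)
    age_sd: float = Field(default=9.0, gt=0)
    age_min: float = Field(default=25.0, ge=0)
    age_max: float = Field(default=80.0, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "CovariateParams":
        total = sum(self.etiology_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"etiology probabilities must sum to 1, got {total}")
        if any(p < 0 for p in self.etiology_probs.values()):
            raise ValueError("etiology probabilities must be non-negative")
        return self


def default_carrier_probabilities() -> Dict[str, GeneCarrierProb]:
    return {
        gene: GeneCarrierProb(
            cases=_REFERENCE_CASE_COUNTS[gene] / 334,
            controls=_REFERENCE_CONTROL_COUNTS[gene] / 1662,
        )
        for gene in sorted(_REFERENCE_CASE_COUNTS)
    }


class SimulationConfig(BaseModel):
    """Full specification of a synthetic cohort."""

    model_config = {"frozen": True}

    n_cases: int = Field(default=334, ge=0)
    n_controls: int = Field(default=1662, ge=0)
    carrier_prob: Dict[str, GeneCarrierProb] = Field(
        default_factory=default_carrier_probabilities
    )
    #: Expected nuisance variants per subject per removal stage (Poisson).
    #: No pre-filter per-subject variant counts are published for the
    #: reference cohort, so the default rate is a package choice.
    nuisance_rate: Dict[str, float] = Field(
        default_factory=lambda: {stage: 0.2 for stage in ALL_REMOVAL_STAGES}
    )
    seed: int = 0
    survival_params: SurvivalParams = Field(default_factory=SurvivalParams)
    covariate_params: CovariateParams = Field(default_factory=CovariateParams)

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        unknown = [s for s in self.nuisance_rate if s not in ALL_REMOVAL_STAGES]
        if unknown:
            raise ValueError(f"unknown nuisance stages: {unknown}")
        if any(r < 0 for r in self.nuisance_rate.values()):
            raise ValueError("nuisance rates must be non-negative")
        return self


@dataclass
class GroundTruth:
    """Index of every planted record: carrier variants that must survive
    the cascade, and nuisance variants with their intended removal stage."""

    planted_carriers: Set[Tuple[str, str, str]]  # (sample_id, gene, variant_id)
    nuisance_labels: Dict[str, str]  # variant_id -> intended removal stage

    @property
    def carrier_variant_ids(self) -> Set[str]:
        return {vid for _, _, vid in self.planted_carriers}


_CARRIER_ROUTES = ("frameshift", "stop_gained", "canonical_splice", "missense_clinvar")


def make_carrier_variant(
    gene: str,
    rng: np.random.Generator,
    sample_id: str = "S1",
    variant_id: Optional[str] = None,
) -> AnnotatedVariant:
    """A variant guaranteed to pass all ten stages and the final retention
    rule, via either the truncating or the ClinVar-pathogenic route."""
    route = _CARRIER_ROUTES[rng.integers(len(_CARRIER_ROUTES))]
    if route == "missense_clinvar":
        consequence, offset = "missense", 0
        clinvar = ("pathogenic", "likely_pathogenic")[rng.integers(2)]
    elif route == "canonical_splice":
        consequence = "canonical_splice"
        offset = int(rng.choice([-2, -1, 1, 2]))
        clinvar = ("pathogenic", "likely_pathogenic", "none")[rng.integers(3)]
    else:
        consequence, offset = route, 0
        clinvar = ("pathogenic", "likely_pathogenic", "none", "vus")[rng.integers(4)]
    maf_population = {}
    if rng.random() < 0.5:
        maf_population["gnomAD"] = float(np.round(rng.uniform(0, 0.003), 6))
    return AnnotatedVariant(
        sample_id=sample_id,
        gene=gene,
        variant_id=variant_id or f"{gene}:carrier:{rng.integers(10**9)}",
        quality=float(np.round(rng.uniform(150, 1500), 1)),
        in_repeat_region=False,
        consequence=consequence,
        intron_offset=offset,
        in_last_exon=False,
        maf_supercontrols=float(np.round(rng.uniform(0, 0.003), 6))
        if rng.random() < 0.5
        else None,
        maf_population=maf_population,
        clinvar=clinvar,
        known_sequencing_error=False,
        known_pathogenic_whitelisted=False,
    )


def make_nuisance_variant(
    stage_label: str,
    gene: str,
    rng: np.random.Generator,
    sample_id: str = "S1",
    variant_id: Optional[str] = None,
) -> AnnotatedVariant:
    """A variant that fails exactly the named stage's predicate and passes
    every other stage's; attributed to ``stage_label`` by the cascade.

    ``final_not_pathogenic`` builds a clean variant that survives all ten
    stages but fails the final retention rule.
    """
    if stage_label not in ALL_REMOVAL_STAGES:
        raise ValueError(
            f"unknown cascade stage {stage_label!r}; expected one of {ALL_REMOVAL_STAGES}"
        )
    # Clean baseline: coding missense, adequate quality, rare, no flags.
    fields: Dict = dict(
        sample_id=sample_id,
        gene=gene,
        variant_id=variant_id or f"{gene}:nuisance:{rng.integers(10**9)}",
        quality=float(np.round(rng.uniform(150, 1500), 1)),
        in_repeat_region=False,
        consequence="missense",
        intron_offset=0,
        in_last_exon=False,
        maf_supercontrols=None,
        maf_population={},
        clinvar="vus",
        known_sequencing_error=False,
        known_pathogenic_whitelisted=False,
    )
    if stage_label == "i_quality":
        fields["quality"] = float(np.round(rng.uniform(0, 149.9), 1))
    elif stage_label == "ii_repeat":
        fields["in_repeat_region"] = True
    elif stage_label == "iii_noncoding_inframe":
        fields["consequence"] = str(
            rng.choice(["utr", "upstream_downstream_intergenic", "inframe_indel"])
        )
    elif stage_label == "iv_supercontrol_maf":
        fields["maf_supercontrols"] = float(np.round(rng.uniform(0.0045, 0.05), 6))
    elif stage_label == "v_population_maf":
        db = str(rng.choice(["gnomAD", "1000Genomes", "ESP", "ExAC"]))
        fields["maf_population"] = {db: float(np.round(rng.uniform(0.0045, 0.05), 6))}
    elif stage_label == "vi_clinvar_benign":
        fields["clinvar"] = ("benign", "likely_benign")[rng.integers(2)]
    elif stage_label == "vii_last_exon":
        fields["in_last_exon"] = True
    elif stage_label == "viii_deep_intronic":
        fields["consequence"] = "intronic"
        fields["intron_offset"] = int(rng.integers(3, 5000)) * int(rng.choice([-1, 1]))
    elif stage_label == "ix_synonymous":
        fields["consequence"] = "synonymous"
    elif stage_label == "x_sequencing_error":
        fields["known_sequencing_error"] = True
    # FINAL_STAGE: baseline (missense, ClinVar VUS) already fails only the
    # final retention rule.
    return AnnotatedVariant(**fields)


def _sample_phenotype(
    sample_id: str,
    group: str,
    carrier_genes: Set[str],
    panel: GenePanel,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> PhenotypeRecord:
    cov = config.covariate_params
    etiologies = sorted(cov.etiology_probs)
    probs = np.array([cov.etiology_probs[e] for e in etiologies])
    etiology = str(rng.choice(etiologies, p=probs / probs.sum()))
    age = float(
        np.clip(rng.normal(cov.age_mean, cov.age_sd), cov.age_min, cov.age_max)
    )
    surv = config.survival_params
    true_time = rng.exponential(1.0 / surv.hazard_per_month)
    event = true_time <= surv.censor_horizon_months
    set_flags = {
        name: bool(carrier_genes & set(members))
        for name, members in panel.gene_sets.items()
    }
    class_flags = {
        cls: any(panel.class_of(g) == cls for g in carrier_genes)
        for cls in ("established", "candidate")
    }
    return PhenotypeRecord(
        sample_id=sample_id,
        group=group,
        carrier_flags={
            **class_flags,
            **set_flags,
            "none": not carrier_genes,
        },
        age_at_dx=round(age, 1),
        sex="M" if rng.random() < cov.male_prob else "F",
        etiology=etiology,
        cirrhosis=etiology != "none",
        microangioinvasion=bool(rng.random() < cov.microangioinvasion_prob),
        cholangio_differentiation=bool(
            rng.random() < cov.cholangio_differentiation_prob
        ),
        recurrence_post_tx=bool(rng.random() < cov.recurrence_post_tx_prob),
        multiple_primary_tumors=bool(rng.random() < cov.multiple_primary_tumors_prob),
        diabetes=bool(rng.random() < cov.diabetes_prob),
        obesity=bool(rng.random() < cov.obesity_prob),
        smoking=bool(rng.random() < cov.smoking_prob),
        family_history=bool(rng.random() < cov.family_history_prob),
        survival_months=round(min(true_time, surv.censor_horizon_months), 2),
        event=bool(event),
    )


def simulate_cohort(
    config: SimulationConfig,
    panel: Optional[GenePanel] = None,
) -> Tuple[List[AnnotatedVariant], List[PhenotypeRecord], GroundTruth]:
    """Generate the cohort: annotated variant table, phenotype table and
    ground truth. Identical config (including seed) gives byte-identical
    output."""
    panel = panel or default_panel()
    missing = sorted(g for g in config.carrier_prob if g not in panel)
    if missing:
        raise ValueError(f"carrier_prob genes absent from the panel: {missing}")
    rng = np.random.default_rng(config.seed)
    genes = sorted(config.carrier_prob)
    nuisance_stages = sorted(config.nuisance_rate, key=ALL_REMOVAL_STAGES.index)
    panel_genes = sorted(panel.genes)
    check_cfg = PrioritizationConfig()

    variants: List[AnnotatedVariant] = []
    phenotypes: List[PhenotypeRecord] = []
    truth = GroundTruth(planted_carriers=set(), nuisance_labels={})
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"v{counter:07d}"

    for group, prefix, n in (
        ("case", "H", config.n_cases),
        ("control", "C", config.n_controls),
    ):
        for i in range(n):
            sample = f"{prefix}{i + 1:05d}"
            carrier_genes: Set[str] = set()
            for gene in genes:
                prob = config.carrier_prob[gene]
                p = prob.cases if group == "case" else prob.controls
                if rng.random() < p:
                    vid = next_id()
                    v = make_carrier_variant(gene, rng, sample_id=sample, variant_id=vid)
                    assert first_failing_stage(v, check_cfg) is None
                    variants.append(v)
                    truth.planted_carriers.add((sample, gene, vid))
                    carrier_genes.add(gene)
            for stage in nuisance_stages:
                for _ in range(rng.poisson(config.nuisance_rate[stage])):
                    gene = panel_genes[rng.integers(len(panel_genes))]
                    vid = next_id()
                    v = make_nuisance_variant(
                        stage, gene, rng, sample_id=sample, variant_id=vid
                    )
                    variants.append(v)
                    truth.nuisance_labels[vid] = stage
            phenotypes.append(
                _sample_phenotype(sample, group, carrier_genes, panel, config, rng)
            )
    return variants, phenotypes, truth
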