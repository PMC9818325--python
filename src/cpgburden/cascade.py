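"""Ten-stage sequential variant prioritization cascade.

Raw annotated calls are filtered in a fixed order; a variant is removed at
the *first* stage whose predicate it fails, giving a reproducible audit
trail. Survivors of all ten stages are then kept only if they are
clinically actionable: ClinVar pathogenic/likely-pathogenic, or truncating
(stop-gain, frameshift, canonical +/-1-2 bp splice, or a multi-exon
deletion).

Stages, in order:

    i    low caller quality (< quality_min, default 150)
    ii   repetitive / low-complexity regions
    iii  non-coding (UTR, up/downstream, intergenic) and in-frame indels
    iv   super-control allele frequency > maf_max (default 0.4%)
    v    population-database allele frequency > maf_max (any database)
    vi   ClinVar benign / likely benign
    vii  last-exon variants
    viii deep intronic (beyond the conserved splice window)
    ix   synonymous
    x    known panel sequencing errors, unless whitelisted as known
         pathogenic variants

Intronic records within the splice window survive stages iii/viii and are
eligible for the truncating retention route; copy-number records skip the
exon-geometry stages (iii, vii, viii, ix), which are undefined for them.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Set

from .panel import GenePanel
from .variants import (
    CNV_CONSEQUENCES,
    FINAL_STAGE,
    STAGE_ORDER,
    AnnotatedVariant,
    FilterOutcome,
    PrioritizationConfig,
)

_NONCODING = frozenset({"utr", "upstream_downstream_intergenic"})


def passes_stage(
    variant: AnnotatedVariant, stage: str, config: PrioritizationConfig
) -> bool:
    """Pure pass-predicate for one named stage.

    Raises ValueError for an unknown stage label.
    """
    is_cnv = variant.consequence in CNV_CONSEQUENCES
    if stage == "i_quality":
        return variant.quality >= config.quality_min
    if stage == "ii_repeat":
        return not variant.in_repeat_region
    if stage == "iii_noncoding_inframe":
        if is_cnv:
            return True
        return variant.consequence not in _NONCODING and variant.consequence != "inframe_indel"
    if stage == "iv_supercontrol_maf":
        maf = variant.maf_supercontrols
        return maf is None or maf <= config.maf_max
    if stage == "v_population_maf":
        return all(maf <= config.maf_max for maf in variant.maf_population.values())
    if stage == "vi_clinvar_benign":
        return variant.clinvar not in ("benign", "likely_benign")
    if stage == "vii_last_exon":
        if is_cnv:
            return True
        return not variant.in_last_exon
    if stage == "viii_deep_intronic":
        if is_cnv:
            return True
        return not (
            variant.consequence == "intronic"
            and abs(variant.intron_offset) > config.splice_window_bp
        )
    if stage == "ix_synonymous":
        if is_cnv:
            return True
        return variant.consequence != "synonymous"
    if stage == "x_sequencing_error":
        return not variant.known_sequencing_error or variant.known_pathogenic_whitelisted
    raise ValueError(f"unknown cascade stage {stage!r}")


def is_truncating(variant: AnnotatedVariant, config: PrioritizationConfig) -> bool:
    """Truncating retention route: premature termination, frameshift,
    aberrant splicing within the conserved window, or a multi-exon
    (copy-number) deletion."""
    if variant.consequence in ("stop_gained", "frameshift", "cnv_deletion"):
        return True
    if variant.consequence == "canonical_splice":
        return abs(variant.intron_offset) <= config.splice_window_bp
    if variant.consequence == "intronic":
        return 0 < abs(variant.intron_offset) <= config.splice_window_bp
    return False


def passes_final_rule(variant: AnnotatedVariant, config: PrioritizationConfig) -> bool:
    """Final retention rule applied after the ten stages: keep only
    ClinVar P/LP variants or truncating variants."""
    if variant.clinvar in ("pathogenic", "likely_pathogenic"):
        return True
    return is_truncating(variant, config)


def first_failing_stage(
    variant: AnnotatedVariant, config: PrioritizationConfig
) -> str | None:
    """First stage (in cascade order, then the final rule) the variant
    fails, or None if it is retained."""
    for stage in STAGE_ORDER:
        if not passes_stage(variant, stage, config):
            return stage
    if not passes_final_rule(variant, config):
        return FINAL_STAGE
    return None


_STAGE_DETAIL = {
    "i_quality": "caller quality below threshold",
    "ii_repeat": "repetitive/low-complexity region",
    "iii_noncoding_inframe": "non-coding consequence or in-frame indel",
    "iv_supercontrol_maf": "super-control MAF above threshold",
    "v_population_maf": "population-database MAF above threshold",
    "vi_clinvar_benign": "ClinVar benign/likely benign",
    "vii_last_exon": "located in last exon",
    "viii_deep_intronic": "intronic beyond conserved splice window",
    "ix_synonymous": "synonymous variant",
    "x_sequencing_error": "known panel sequencing error",
    FINAL_STAGE: "not ClinVar P/LP and not truncating",
}


def apply_filter_cascade(
    variants: Iterable[AnnotatedVariant],
    config: PrioritizationConfig | None = None,
) -> List[FilterOutcome]:
    """Run the full cascade; one FilterOutcome per input variant, input
    order preserved."""
    config = config or PrioritizationConfig()
    outcomes: List[FilterOutcome] = []
    for variant in variants:
        stage = first_failing_stage(variant, config)
        if stage is None:
            outcomes.append(FilterOutcome(variant=variant, status="retained"))
        else:
            outcomes.append(
                FilterOutcome(
                    variant=variant,
                    status="removed",
                    removal_stage=stage,
                    stage_detail=_STAGE_DETAIL[stage],
                )
            )
    return outcomes


@dataclass
class CarrierMatrix:
    """Distinct-sample carrier sets per gene, per panel class and per gene
    set. A sample with two retained variants in one gene counts once for
    that gene; a sample with retained variants in two genes appears in both
    genes' sets but once in any class or set union."""

    per_gene: Dict[str, Set[str]] = field(default_factory=dict)
    per_class: Dict[str, Set[str]] = field(default_factory=dict)
    per_set: Dict[str, Set[str]] = field(default_factory=dict)

    @property
    def all_carriers(self) -> Set[str]:
        out: Set[str] = set()
        for samples in self.per_gene.values():
            out |= samples
        return out

    def gene_count(self, gene: str) -> int:
        return len(self.per_gene.get(gene, set()))


def classify_retained(
    outcomes: Sequence[FilterOutcome], panel: GenePanel
) -> CarrierMatrix:
    """Build the carrier matrix from retained variants, grouped by the
    panel's gene classes and gene sets.

    Raises KeyError if any retained variant's gene is absent from the
    panel, naming every unknown symbol.
    """
    retained = [o.variant for o in outcomes if o.status == "retained"]
    unknown = sorted({v.gene for v in retained if v.gene not in panel})
    if unknown:
        raise KeyError(f"retained variants in genes absent from the panel: {unknown}")

    matrix = CarrierMatrix(
        per_gene={},
        per_class={"established": set(), "candidate": set()},
        per_set={name: set() for name in panel.gene_sets},
    )
    set_membership = {
        name: frozenset(members) for name, members in panel.gene_sets.items()
    }
    for v in retained:
        matrix.per_gene.setdefault(v.gene, set()).add(v.sample_id)
        matrix.per_class[panel.class_of(v.gene)].add(v.sample_id)
        for name, members in set_membership.items():
            if v.gene in members:
                matrix.per_set[name].add(v.sample_id)
    return matrix


def audit_summary(outcomes: Sequence[FilterOutcome]) -> "OrderedDict[str, int]":
    """Removed-variant count per stage (all eleven removal labels, zero
    included) plus a ``retained`` entry; counts sum to the input size."""
    counts: "OrderedDict[str, int]" = OrderedDict(
        (stage, 0) for stage in STAGE_ORDER + (FINAL_STAGE,)
    )
    retained = 0
    for o in outcomes:
        if o.status == "retained":
            retained += 1
        else:
            counts[o.removal_stage] += 1  # type: ignore[index]
    counts["retained"] = retained
    return counts
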