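"""Run the ten-stage prioritization cascade on a handful of annotated
variants and inspect the audit trail.

Each variant is removed at the first stage it fails, or retained if it is
ClinVar pathogenic/likely-pathogenic or truncating after surviving all
ten stages.
"""

from cpgburden import (
    AnnotatedVariant,
    PrioritizationConfig,
    apply_filter_cascade,
    audit_summary,
)

variants = [
    # recurrent Slavic NBN frameshift: passes everything, truncating route
    AnnotatedVariant(
        sample_id="P1", gene="NBN", variant_id="NBN:c.657del5",
        quality=812, consequence="frameshift", maf_supercontrols=0.001,
        maf_population={"gnomAD": 0.0009}, clinvar="pathogenic",
    ),
    # missense kept through the ClinVar route
    AnnotatedVariant(
        sample_id="P2", gene="FH", variant_id="FH:c.1127A>C",
        quality=521, consequence="missense", clinvar="pathogenic",
    ),
    # common variant: removed at the super-control frequency stage
    AnnotatedVariant(
        sample_id="P3", gene="BLM", variant_id="BLM:common",
        quality=600, consequence="missense", maf_supercontrols=0.02,
    ),
    # low-quality call: removed at stage i
    AnnotatedVariant(
        sample_id="P4", gene="RAD50", variant_id="RAD50:lowq",
        quality=96, consequence="stop_gained",
    ),
    # clean missense without ClinVar support: fails the final rule
    AnnotatedVariant(
        sample_id="P5", gene="MSH3", variant_id="MSH3:vus",
        quality=700, consequence="missense", clinvar="vus",
    ),
]

outcomes = apply_filter_cascade(variants, PrioritizationConfig())
for o in outcomes:
    fate = "retained" if o.status == "retained" else f"removed at {o.removal_stage}"
    print(f"{o.variant.variant_id:18s} -> {fate}")

print("\nper-stage removal counts (nonzero):")
for stage, count in audit_summary(outcomes).items():
    if count:
        print(f"  {stage}: {count}")

# The two retained variants are the clinically reportable ones: a
# truncating NBN frameshift and a ClinVar-pathogenic FH missense.
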