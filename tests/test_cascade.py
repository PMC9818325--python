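"""Unit and property tests for the ten-stage filter cascade."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cpgburden import (
    FINAL_STAGE,
    STAGE_ORDER,
    PrioritizationConfig,
    apply_filter_cascade,
    audit_summary,
    classify_retained,
    first_failing_stage,
    passes_stage,
)
from cpgburden.panel import GenePanel

from conftest import clean_variant, random_variant

# ---------------------------------------------------------------------------
# Independent re-derivation of every stage predicate and the final rule,
# used as a brute-force oracle for the cascade's attribution and membership.

_CNV = {"cnv_deletion", "cnv_duplication"}


def oracle_fail_stages(v, cfg):
    fails = []
    if v.quality < cfg.quality_min:
        fails.append("i_quality")
    if v.in_repeat_region:
        fails.append("ii_repeat")
    if v.consequence in {"utr", "upstream_downstream_intergenic", "inframe_indel"}:
        fails.append("iii_noncoding_inframe")
    if v.maf_supercontrols is not None and v.maf_supercontrols > cfg.maf_max:
        fails.append("iv_supercontrol_maf")
    if any(m > cfg.maf_max for m in v.maf_population.values()):
        fails.append("v_population_maf")
    if v.clinvar in {"benign", "likely_benign"}:
        fails.append("vi_clinvar_benign")
    if v.in_last_exon and v.consequence not in _CNV:
        fails.append("vii_last_exon")
    if v.consequence == "intronic" and abs(v.intron_offset) > cfg.splice_window_bp:
        fails.append("viii_deep_intronic")
    if v.consequence == "synonymous":
        fails.append("ix_synonymous")
    if v.known_sequencing_error and not v.known_pathogenic_whitelisted:
        fails.append("x_sequencing_error")
    truncating = v.consequence in {"stop_gained", "frameshift", "cnv_deletion"} or (
        v.consequence in {"canonical_splice", "intronic"}
        and 0 < abs(v.intron_offset) <= cfg.splice_window_bp
    ) or (v.consequence == "canonical_splice" and v.intron_offset == 0)
    if v.clinvar not in {"pathogenic", "likely_pathogenic"} and not truncating:
        fails.append(FINAL_STAGE)
    return fails


# ---------------------------------------------------------------------------
# Stage predicates

@pytest.mark.parametrize(
    "overrides, failing_stage",
    [
        ({"quality": 149.0}, "i_quality"),
        ({"quality": 149.999}, "i_quality"),
        ({"in_repeat_region": True}, "ii_repeat"),
        ({"consequence": "utr"}, "iii_noncoding_inframe"),
        ({"consequence": "upstream_downstream_intergenic"}, "iii_noncoding_inframe"),
        ({"consequence": "inframe_indel"}, "iii_noncoding_inframe"),
        ({"maf_supercontrols": 0.005}, "iv_supercontrol_maf"),
        ({"maf_population": {"gnomAD": 0.001, "ESP": 0.0041}}, "v_population_maf"),
        ({"clinvar": "benign"}, "vi_clinvar_benign"),
        ({"clinvar": "likely_benign"}, "vi_clinvar_benign"),
        ({"in_last_exon": True}, "vii_last_exon"),
        ({"consequence": "intronic", "intron_offset": 3}, "viii_deep_intronic"),
        ({"consequence": "intronic", "intron_offset": -17}, "viii_deep_intronic"),
        ({"consequence": "synonymous"}, "ix_synonymous"),
        ({"known_sequencing_error": True}, "x_sequencing_error"),
    ],
)
def test_each_stage_removes_its_target(config, overrides, failing_stage):
    """Each constructed violation is caught at exactly its intended stage."""
    v = clean_variant(**overrides)
    assert not passes_stage(v, failing_stage, config)
    before = STAGE_ORDER[: STAGE_ORDER.index(failing_stage)]
    assert all(passes_stage(v, s, config) for s in before)
    assert first_failing_stage(v, config) == failing_stage


@pytest.mark.parametrize(
    "overrides",
    [
        {},  # frameshift, clean
        {"quality": 150.0},  # boundary: quality exactly at the threshold passes
        {"maf_supercontrols": 0.004},  # boundary: MAF equal to cutoff passes
        {"maf_population": {"gnomAD": 0.004}},
        {"maf_supercontrols": None, "maf_population": {}},  # absent MAFs pass
        {"consequence": "canonical_splice", "intron_offset": -2},
        {"consequence": "intronic", "intron_offset": 2},  # within splice window
        {"consequence": "missense", "clinvar": "pathogenic"},
        {"consequence": "cnv_deletion"},
        {"known_sequencing_error": True, "known_pathogenic_whitelisted": True},
    ],
)
def test_clean_and_boundary_variants_are_retained(config, overrides):
    """Threshold boundaries are strict: quality 150 and MAF 0.4% survive;
    both retention routes (truncating, ClinVar P/LP) work."""
    v = clean_variant(**overrides)
    assert first_failing_stage(v, config) is None


def test_quality_boundary_is_strict(config):
    assert passes_stage(clean_variant(quality=150.0), "i_quality", config)
    assert not passes_stage(clean_variant(quality=149.0), "i_quality", config)


def test_unknown_stage_label_rejected(config):
    with pytest.raises(ValueError, match="unknown cascade stage"):
        passes_stage(clean_variant(), "xi_bogus", config)


def test_cnv_records_skip_exon_geometry_stages(config):
    """Copy-number deletions are exempt from the non-coding, last-exon,
    deep-intronic and synonymous stages but subject to all others."""
    cnv = clean_variant(consequence="cnv_deletion", in_last_exon=True)
    for stage in ("iii_noncoding_inframe", "vii_last_exon", "viii_deep_intronic", "ix_synonymous"):
        assert passes_stage(cnv, stage, config)
    assert first_failing_stage(cnv, config) is None  # truncating route
    assert first_failing_stage(
        clean_variant(consequence="cnv_deletion", quality=10), config
    ) == "i_quality"
    # duplications have no truncating route: ClinVar P/LP only
    dup = clean_variant(consequence="cnv_duplication")
    assert first_failing_stage(dup, config) == FINAL_STAGE
    assert first_failing_stage(
        clean_variant(consequence="cnv_duplication", clinvar="likely_pathogenic"), config
    ) is None


def test_final_rule_routes(config):
    """Survivors of the ten stages are kept iff ClinVar P/LP or truncating."""
    assert first_failing_stage(
        clean_variant(consequence="missense", clinvar="pathogenic"), config
    ) is None
    assert first_failing_stage(
        clean_variant(consequence="missense", clinvar="vus"), config
    ) == FINAL_STAGE
    assert first_failing_stage(
        clean_variant(consequence="missense", clinvar="conflicting"), config
    ) == FINAL_STAGE


# ---------------------------------------------------------------------------
# Cascade behaviour

def test_attribution_is_first_failing_stage(config):
    """A variant violating several predicates is attributed to the earliest."""
    v = clean_variant(quality=10, in_repeat_region=True, clinvar="benign")
    outcomes = apply_filter_cascade([v], config)
    assert outcomes[0].removal_stage == "i_quality"


def test_cascade_matches_brute_force_oracle_on_random_batch(config):
    """On 1000 random variants the cascade agrees with an exhaustive,
    independently coded predicate table: same retained membership, and
    attribution to the first failing predicate in stage order."""
    rng = np.random.default_rng(2024)
    variants = [random_variant(rng) for _ in range(1000)]
    outcomes = apply_filter_cascade(variants, config)
    assert len(outcomes) == len(variants)
    for v, o in zip(variants, outcomes):
        fails = oracle_fail_stages(v, config)
        if fails:
            assert o.status == "removed"
            assert o.removal_stage == fails[0]
        else:
            assert o.status == "retained"


def test_order_preserved_and_complete(config):
    rng = np.random.default_rng(7)
    variants = [random_variant(rng) for _ in range(50)]
    outcomes = apply_filter_cascade(variants, config)
    assert [o.variant for o in outcomes] == variants


def test_idempotence_on_retained_variants(config):
    """Re-running the cascade on its own retained output keeps everything."""
    rng = np.random.default_rng(11)
    variants = [random_variant(rng) for _ in range(500)]
    retained = [
        o.variant for o in apply_filter_cascade(variants, config) if o.status == "retained"
    ]
    again = apply_filter_cascade(retained, config)
    assert all(o.status == "retained" for o in again)


@given(
    maf_max=st.floats(min_value=0.0005, max_value=0.02),
    quality_min=st.floats(min_value=0, max_value=500),
    seed=st.integers(min_value=0, max_value=10_000),
)
def test_retained_set_monotone_in_thresholds(maf_max, quality_min, seed):
    """Lowering the MAF ceiling or raising the quality floor never grows
    the retained set."""
    rng = np.random.default_rng(seed)
    variants = [random_variant(rng) for _ in range(60)]
    base = PrioritizationConfig()
    tighter = PrioritizationConfig(
        quality_min=max(base.quality_min, quality_min),
        maf_max=min(base.maf_max, maf_max),
    )
    keep = lambda cfg: {
        o.variant.variant_id
        for o in apply_filter_cascade(variants, cfg)
        if o.status == "retained"
    }
    assert keep(tighter) <= keep(base)


# ---------------------------------------------------------------------------
# Carrier matrix and audit

def test_carrier_matrix_distinct_sample_semantics(panel, config):
    """Two retained variants in one gene count a sample once; variants in
    two genes put the sample in both genes but once per class union."""
    variants = [
        clean_variant(sample_id="S1", gene="NBN", variant_id="NBN:a"),
        clean_variant(sample_id="S1", gene="NBN", variant_id="NBN:b"),
        clean_variant(sample_id="S1", gene="RAD50", variant_id="RAD50:a"),
        clean_variant(sample_id="S2", gene="RAD50", variant_id="RAD50:b"),
        clean_variant(sample_id="S3", gene="RAD50", variant_id="RAD50:c"),
    ]
    matrix = classify_retained(apply_filter_cascade(variants, config), panel)
    assert matrix.per_gene["NBN"] == {"S1"}
    assert matrix.per_gene["RAD50"] == {"S1", "S2", "S3"}
    assert matrix.per_set["MRN"] == {"S1", "S2", "S3"}
    assert matrix.per_class["established"] == {"S1"}
    assert matrix.per_class["candidate"] == {"S1", "S2", "S3"}
    assert matrix.all_carriers == {"S1", "S2", "S3"}


def test_unknown_gene_symbol_raises_with_name(config):
    panel = GenePanel(genes={"NBN": "established"})
    variants = [clean_variant(gene="NOTAGENE", variant_id="x")]
    with pytest.raises(KeyError, match="NOTAGENE"):
        classify_retained(apply_filter_cascade(variants, config), panel)


def test_audit_summary_counts(config):
    """One constructed violation per stage: each stage's count is 1 and
    counts sum to the number removed."""
    per_stage = [
        clean_variant(quality=100, variant_id="q"),
        clean_variant(in_repeat_region=True, variant_id="r"),
        clean_variant(consequence="utr", variant_id="u"),
        clean_variant(maf_supercontrols=0.01, variant_id="sc"),
        clean_variant(maf_population={"ExAC": 0.02}, variant_id="pop"),
        clean_variant(clinvar="benign", variant_id="b"),
        clean_variant(in_last_exon=True, variant_id="le"),
        clean_variant(consequence="intronic", intron_offset=40, variant_id="di"),
        clean_variant(consequence="synonymous", variant_id="syn"),
        clean_variant(known_sequencing_error=True, variant_id="se"),
        clean_variant(consequence="missense", clinvar="vus", variant_id="vus"),
        clean_variant(variant_id="keep"),
    ]
    summary = audit_summary(apply_filter_cascade(per_stage, config))
    for stage in STAGE_ORDER + (FINAL_STAGE,):
        assert summary[stage] == 1, stage
    assert summary["retained"] == 1
    assert sum(summary[s] for s in STAGE_ORDER + (FINAL_STAGE,)) == len(per_stage) - 1


def test_audit_summary_empty_and_all_retained(config):
    empty = audit_summary([])
    assert all(v == 0 for v in empty.values())
    outcomes = apply_filter_cascade([clean_variant(variant_id=str(i)) for i in range(5)], config)
    summary = audit_summary(outcomes)
    assert summary["retained"] == 5
    assert sum(summary[s] for s in STAGE_ORDER + (FINAL_STAGE,)) == 0
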