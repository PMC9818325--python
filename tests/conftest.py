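import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cpgburden import AnnotatedVariant, PrioritizationConfig, default_panel

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

CONSEQUENCES = (
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
)
CLINVAR = (
    "pathogenic",
    "likely_pathogenic",
    "vus",
    "benign",
    "likely_benign",
    "conflicting",
    "none",
)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def config():
    return PrioritizationConfig()


def clean_variant(**overrides) -> AnnotatedVariant:
    """A frameshift variant that passes every cascade stage and the final
    retention rule; individual fields overridden per test."""
    fields = dict(
        sample_id="S1",
        gene="NBN",
        variant_id="NBN:test",
        quality=500.0,
        in_repeat_region=False,
        consequence="frameshift",
        intron_offset=0,
        in_last_exon=False,
        maf_supercontrols=0.001,
        maf_population={"gnomAD": 0.001},
        clinvar="none",
        known_sequencing_error=False,
        known_pathogenic_whitelisted=False,
    )
    fields.update(overrides)
    return AnnotatedVariant(**fields)


def random_variant(rng: np.random.Generator, sample_id="S1", gene="NBN") -> AnnotatedVariant:
    """A structurally valid variant with independently random annotation
    fields, for oracle-equivalence sweeps over the cascade."""
    consequence = CONSEQUENCES[rng.integers(len(CONSEQUENCES))]
    if consequence == "canonical_splice":
        offset = int(rng.choice([-2, -1, 1, 2]))
    elif consequence == "intronic":
        offset = int(rng.integers(1, 200)) * int(rng.choice([-1, 1]))
    else:
        offset = 0
    maf_population = {}
    for db in ("gnomAD", "1000Genomes", "ESP", "ExAC"):
        if rng.random() < 0.4:
            maf_population[db] = float(np.round(rng.uniform(0, 0.01), 6))
    return AnnotatedVariant(
        sample_id=sample_id,
        gene=gene,
        variant_id=f"rv{rng.integers(10**9)}",
        quality=float(np.round(rng.uniform(0, 400), 1)),
        in_repeat_region=bool(rng.random() < 0.2),
        consequence=consequence,
        intron_offset=offset,
        in_last_exon=bool(rng.random() < 0.2),
        maf_supercontrols=float(np.round(rng.uniform(0, 0.01), 6))
        if rng.random() < 0.6
        else None,
        maf_population=maf_population,
        clinvar=CLINVAR[rng.integers(len(CLINVAR))],
        known_sequencing_error=bool(rng.random() < 0.2),
        known_pathogenic_whitelisted=bool(rng.random() < 0.3),
    )
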