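"""Bundled reference cohort data.

The package ships the retained-variant table of a reference screening
study — 334 HCC liver-transplant candidates sequenced on a 226-gene
cancer-predisposition panel and compared against 1662 population-matched
controls — together with the per-gene control carrier counts. These power
the worked examples and let the full carrier-counting and burden analysis
be reproduced from in-package data.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, List

import pandas as pd

from .burden import BurdenResult, burden_from_counts
from .cascade import CarrierMatrix, apply_filter_cascade, classify_retained
from .panel import GenePanel, default_panel
from .variants import AnnotatedVariant

#: Reference cohort sizes.
REFERENCE_N_CASES = 334
REFERENCE_N_CONTROLS = 1662


def _data_path(name: str):
    return resources.files("cpgburden.data").joinpath(name)


def load_reference_variants() -> List[AnnotatedVariant]:
    """The 48 retained pathogenic variants of the reference cohort (one
    row per variant per carrier; one patient carries two)."""
    from .io import read_variant_table

    with resources.as_file(_data_path("reference_retained_variants.tsv")) as path:
        return read_variant_table(path, dialect="tsv")


def load_reference_control_counts() -> Dict[str, int]:
    """Distinct control carriers per gene among the 1662 population
    controls, for genes with at least one case carrier."""
    with resources.as_file(_data_path("reference_control_carriers.tsv")) as path:
        frame = pd.read_csv(path, sep="\t")
    return dict(zip(frame["gene"], frame["control_carriers"].astype(int)))


def reference_carrier_matrix(panel: GenePanel | None = None) -> CarrierMatrix:
    """Run the prioritization cascade on the bundled variant table and
    build the case carrier matrix (the bundled table is already retained-
    level, so the cascade must keep every record)."""
    panel = panel or default_panel()
    outcomes = apply_filter_cascade(load_reference_variants())
    return classify_retained(outcomes, panel)


def reference_burden_table(
    panel: GenePanel | None = None, method: str = "chi2"
) -> List[BurdenResult]:
    """The full case-control burden table of the reference analysis:
    per-gene, per-class and MRN-complex rows."""
    panel = panel or default_panel()
    matrix = reference_carrier_matrix(panel)
    case_counts = {g: len(s) for g, s in matrix.per_gene.items()}
    return burden_from_counts(
        case_counts,
        load_reference_control_counts(),
        REFERENCE_N_CASES,
        REFERENCE_N_CONTROLS,
        panel,
        case_class_counts={c: len(s) for c, s in matrix.per_class.items()},
        case_set_counts={n: len(s) for n, s in matrix.per_set.items()},
        method=method,
    )
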