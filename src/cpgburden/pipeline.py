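"""End-to-end orchestration: prioritization -> carrier matrix -> burden
table -> clinical comparison, with all outputs written to a run directory.

Outputs are deterministic: the same inputs and configuration produce
byte-identical files (the run log records the configuration and package
version, never wall-clock time).
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional

from pydantic import BaseModel, Field

from . import __version__
from .burden import BurdenResult, burden_table, render_burden_rows
from .cascade import (
    apply_filter_cascade,
    audit_summary,
    classify_retained,
)
from .clinical import ComparisonReport, compare_groups
from .io import (
    read_phenotype_table,
    read_variant_table,
    write_variant_table,
)
from .panel import GenePanel, default_panel
from .variants import PrioritizationConfig


class RunConfig(BaseModel):
    """Configuration of one pipeline run."""

    variants_path: str
    variants_dialect: str = "tsv"
    phenotype_path: Optional[str] = None
    panel_path: Optional[str] = None
    prioritization: PrioritizationConfig = Field(default_factory=PrioritizationConfig)
    out_dir: str = "cpgburden_run"
    carrier_flags: List[str] = Field(
        default_factory=lambda: ["established", "candidate", "MRN"]
    )
    seed: int = 0


def _comparison_to_dict(report: ComparisonReport) -> Dict:
    return {
        "flag": report.flag,
        "n_carriers": report.n_carriers,
        "n_noncarriers": report.n_noncarriers,
        "significance_threshold": report.significance_threshold,
        "comparisons": [asdict(c) for c in report.comparisons],
    }


def _burden_to_dict(r: BurdenResult) -> Dict:
    return {
        "label": r.label,
        "kind": r.kind,
        "gene_class": r.gene_class,
        "table": asdict(r.table),
        "odds_ratio": r.or_point,
        "ci_low": r.ci_low,
        "ci_high": r.ci_high,
        "p_value": r.p_value,
        "defined": r.defined,
    }


def run_pipeline(config: RunConfig) -> Dict:
    """Execute the full pipeline and write the report bundle.

    Returns a dict with the in-memory results: filter outcomes, audit
    counts, carrier matrices, burden results and clinical reports.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = (
        GenePanel.from_yaml(config.panel_path) if config.panel_path else default_panel()
    )

    variants = read_variant_table(config.variants_path, dialect=config.variants_dialect)
    outcomes = apply_filter_cascade(variants, config.prioritization)
    audit = audit_summary(outcomes)

    retained = [o.variant for o in outcomes if o.status == "retained"]
    write_variant_table(retained, out / "retained_variants.tsv")
    with open(out / "audit.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["stage", "count"])
        for stage, count in audit.items():
            writer.writerow([stage, count])

    results: Dict = {"outcomes": outcomes, "audit": audit}

    pheno = (
        read_phenotype_table(config.phenotype_path) if config.phenotype_path else None
    )

    if pheno is not None:
        case_ids = {r.sample_id for r in pheno if r.group == "case"}
        control_ids = {r.sample_id for r in pheno if r.group == "control"}
        case_outcomes = [o for o in outcomes if o.variant.sample_id in case_ids]
        control_outcomes = [o for o in outcomes if o.variant.sample_id in control_ids]
        unknown = {
            o.variant.sample_id
            for o in outcomes
            if o.variant.sample_id not in case_ids | control_ids
        }
        if unknown:
            raise ValueError(
                f"prioritization stage: {len(unknown)} variant sample ids missing "
                f"from the phenotype table (first: {sorted(unknown)[0]})"
            )
        case_matrix = classify_retained(case_outcomes, panel)
        control_matrix = classify_retained(control_outcomes, panel)
        results["case_matrix"] = case_matrix
        results["control_matrix"] = control_matrix

        if case_matrix.all_carriers or control_matrix.all_carriers:
            burden = burden_table(
                case_matrix, control_matrix, len(case_ids), len(control_ids), panel
            )
            results["burden"] = burden
            with open(out / "burden.tsv", "w", newline="") as fh:
                rows = render_burden_rows(burden)
                writer = csv.DictWriter(
                    fh, fieldnames=list(rows[0]), delimiter="\t", lineterminator="\n"
                )
                writer.writeheader()
                writer.writerows(rows)
            with open(out / "burden.json", "w") as fh:
                json.dump([_burden_to_dict(r) for r in burden], fh, indent=1)
                fh.write("\n")
        else:
            results["burden"] = []
            (out / "burden.tsv").write_text("# no carriers detected; burden table empty\n")

        cases = [r for r in pheno if r.group == "case"]
        clinical: Dict[str, Dict] = {}
        for flag in config.carrier_flags:
            if not any(flag in r.carrier_flags for r in cases):
                continue
            report = compare_groups(cases, flag)
            if report.n_carriers == 0:
                clinical[flag] = {
                    "flag": flag,
                    "skipped": "no carriers in the case group",
                }
            else:
                clinical[flag] = _comparison_to_dict(report)
        results["clinical"] = clinical
        with open(out / "clinical.json", "w") as fh:
            json.dump(clinical, fh, indent=1, sort_keys=True)
            fh.write("\n")
    else:
        # No phenotype table: carrier matrix over all samples only.
        results["case_matrix"] = classify_retained(outcomes, panel)

    matrix = results["case_matrix"]
    with open(out / "carrier_matrix.json", "w") as fh:
        json.dump(
            {
                "per_gene": {g: sorted(s) for g, s in sorted(matrix.per_gene.items())},
                "per_class": {c: sorted(s) for c, s in sorted(matrix.per_class.items())},
                "per_set": {n: sorted(s) for n, s in sorted(matrix.per_set.items())},
            },
            fh,
            indent=1,
        )
        fh.write("\n")

    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"cpgburden {__version__}\n")
        fh.write("configuration:\n")
        fh.write(config.model_dump_json(indent=1))
        fh.write("\n")
        fh.write(f"variants read: {len(variants)}\n")
        fh.write(f"retained: {audit['retained']}\n")
    return results
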