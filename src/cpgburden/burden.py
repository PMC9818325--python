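"""Case-control carrier burden statistics on 2x2 tables.

For each gene (and gene class / gene set) the carriers are compared
between cases and controls via the odds ratio

    OR = (a * d) / (b * c)

with a Woolf (logit) confidence interval

    exp( ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d) )

and a two-sided Pearson chi-square test without continuity correction,

    X^2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)),   p = P(chi2_1 >= X^2).

When any cell of the table is zero the OR and CI are undefined and
reported as "n.d."; the chi-square p is undefined only when a margin is
zero. Fisher's exact test is available as an alternative p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from scipy import stats

from .cascade import CarrierMatrix
from .panel import GenePanel


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 carrier table: a/b = case carriers/non-carriers, c/d = control
    carriers/non-carriers."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency-table cells must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def transposed(self) -> "ContingencyTable":
        """Swap the case and control groups."""
        return ContingencyTable(self.c, self.d, self.a, self.b)

    @classmethod
    def from_carriers(
        cls, case_carriers: int, control_carriers: int, n_cases: int, n_controls: int
    ) -> "ContingencyTable":
        if case_carriers > n_cases or control_carriers > n_controls:
            raise ValueError(
                "carrier count exceeds group size: "
                f"{case_carriers}/{n_cases} cases, {control_carriers}/{n_controls} controls"
            )
        return cls(
            case_carriers,
            n_cases - case_carriers,
            control_carriers,
            n_controls - control_carriers,
        )


def odds_ratio(t: ContingencyTable) -> Optional[float]:
    """Cross-product odds ratio, or None when any cell is zero
    (undefined, reported as "n.d.")."""
    if min(t.a, t.b, t.c, t.d) == 0:
        return None
    return (t.a * t.d) / (t.b * t.c)


def woolf_ci(
    t: ContingencyTable, level: float = 0.95
) -> Optional[Tuple[float, float]]:
    """Woolf (log-odds normal approximation) confidence interval for the
    odds ratio; None when any cell is zero."""
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    if min(t.a, t.b, t.c, t.d) == 0:
        return None
    log_or = math.log((t.a * t.d) / (t.b * t.c))
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    z = stats.norm.ppf(0.5 + level / 2)
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


def pearson_chi2_p(t: ContingencyTable) -> Optional[float]:
    """Two-sided Pearson chi-square p (1 df, no continuity correction);
    None when any margin of the table is zero."""
    if t.n == 0:
        raise ValueError("empty contingency table")
    margins = (t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d)
    if min(margins) == 0:
        return None
    statistic = t.n * (t.a * t.d - t.b * t.c) ** 2 / math.prod(margins)
    return float(stats.chi2.sf(statistic, df=1))


def fisher_exact_p(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p, as an alternative to the chi-square."""
    return float(stats.fisher_exact([[t.a, t.b], [t.c, t.d]])[1])


@dataclass(frozen=True)
class BurdenResult:
    """One row of the burden table: a gene, class or gene-set label with
    its 2x2 table, OR, CI and p. ``defined`` is False (OR/CI reported
    "n.d.") when any table cell is zero."""

    label: str
    kind: str  # "gene" | "class" | "set"
    gene_class: Optional[str]
    table: ContingencyTable
    or_point: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    p_value: Optional[float]
    defined: bool


def _result(
    label: str,
    kind: str,
    gene_class: Optional[str],
    table: ContingencyTable,
    method: str,
) -> BurdenResult:
    or_point = odds_ratio(table)
    ci = woolf_ci(table)
    if method == "chi2":
        p = pearson_chi2_p(table)
    elif method == "fisher":
        p = fisher_exact_p(table)
    else:
        raise ValueError(f"unknown test method {method!r}; use 'chi2' or 'fisher'")
    defined = or_point is not None
    # Convention from the bundled reference analysis: an undefined OR is
    # reported "n.d." together with its p-value.
    if not defined and method == "chi2":
        p = None
    return BurdenResult(
        label=label,
        kind=kind,
        gene_class=gene_class,
        table=table,
        or_point=or_point,
        ci_low=ci[0] if ci else None,
        ci_high=ci[1] if ci else None,
        p_value=p,
        defined=defined,
    )


def burden_from_counts(
    case_counts: Mapping[str, int],
    control_counts: Mapping[str, int],
    n_cases: int,
    n_controls: int,
    panel: GenePanel,
    case_class_counts: Optional[Mapping[str, int]] = None,
    case_set_counts: Optional[Mapping[str, int]] = None,
    method: str = "chi2",
) -> List[BurdenResult]:
    """Burden table from per-gene distinct-carrier counts.

    One row per gene with >= 1 case carrier, grouped by panel class
    (established first), sorted within class by descending case count then
    symbol; one row per configured gene set; one "all carriers" row per
    class. Control-side class/set counts are sums of the per-gene control
    counts over the listed genes (distinct-sample control unions are only
    available through :func:`burden_table`). Case-side class/set counts
    default to the same sums unless distinct counts are supplied.
    """
    genes = [g for g, k in case_counts.items() if k > 0]
    unknown = sorted(g for g in genes if g not in panel)
    if unknown:
        raise KeyError(f"genes absent from the panel: {unknown}")
    for g in genes:
        if case_counts[g] > n_cases:
            raise ValueError(f"{g}: more case carriers than cases")
        if control_counts.get(g, 0) > n_controls:
            raise ValueError(f"{g}: more control carriers than controls")

    results: List[BurdenResult] = []
    for cls in ("established", "candidate"):
        cls_genes = sorted(
            (g for g in genes if panel.class_of(g) == cls),
            key=lambda g: (-case_counts[g], g),
        )
        if not cls_genes:
            continue
        for g in cls_genes:
            table = ContingencyTable.from_carriers(
                case_counts[g], control_counts.get(g, 0), n_cases, n_controls
            )
            results.append(_result(g, "gene", cls, table, method))
        case_total = (
            case_class_counts[cls]
            if case_class_counts is not None
            else sum(case_counts[g] for g in cls_genes)
        )
        control_total = sum(control_counts.get(g, 0) for g in cls_genes)
        table = ContingencyTable.from_carriers(
            case_total, control_total, n_cases, n_controls
        )
        results.append(_result(f"all_{cls}", "class", cls, table, method))

    for set_name, members in panel.gene_sets.items():
        listed = [g for g in members if case_counts.get(g, 0) > 0]
        if not listed:
            continue
        case_total = (
            case_set_counts[set_name]
            if case_set_counts is not None and set_name in case_set_counts
            else sum(case_counts[g] for g in listed)
        )
        control_total = sum(control_counts.get(g, 0) for g in listed)
        table = ContingencyTable.from_carriers(
            case_total, control_total, n_cases, n_controls
        )
        results.append(_result(set_name, "set", None, table, method))
    return results


def burden_table(
    case_matrix: CarrierMatrix,
    control_matrix: CarrierMatrix,
    n_cases: int,
    n_controls: int,
    panel: GenePanel,
    method: str = "chi2",
) -> List[BurdenResult]:
    """Burden table from case and control carrier matrices, using true
    distinct-sample unions for the class and set rows on both sides."""
    case_counts = {g: len(s) for g, s in case_matrix.per_gene.items()}
    genes = [g for g, k in case_counts.items() if k > 0]
    control_counts = {g: control_matrix.gene_count(g) for g in genes}
    results = burden_from_counts(
        case_counts,
        control_counts,
        n_cases,
        n_controls,
        panel,
        case_class_counts={
            cls: len(samples) for cls, samples in case_matrix.per_class.items()
        },
        case_set_counts={
            name: len(samples) for name, samples in case_matrix.per_set.items()
        },
        method=method,
    )
    # Replace control-side class/set sums with distinct-sample counts,
    # restricted to genes observed in cases (a control carrying variants
    # in two listed genes counts once).
    fixed: List[BurdenResult] = []
    for r in results:
        if r.kind == "gene":
            fixed.append(r)
            continue
        if r.kind == "class":
            members = [g for g in genes if panel.class_of(g) == r.gene_class]
        else:
            members = [g for g in panel.gene_sets[r.label] if g in genes]
        control_total = len(
            set().union(*(control_matrix.per_gene.get(g, set()) for g in members))
            if members
            else set()
        )
        table = ContingencyTable.from_carriers(
            r.table.a, control_total, n_cases, n_controls
        )
        fixed.append(_result(r.label, r.kind, r.gene_class, table, method))
    return fixed


# ---------------------------------------------------------------------------
# Report rendering (half-up rounding, mirroring the reference table style)

def round_half_up(x: float, decimals: int) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_percent(k: int, n: int) -> str:
    if n == 0:
        return "0.0"
    return f"{round_half_up(100 * k / n, 1):.1f}"


def format_or(r: BurdenResult) -> str:
    if not r.defined:
        return "n.d."
    return (
        f"{round_half_up(r.or_point, 1):.1f} "
        f"({round_half_up(r.ci_low, 2):.2f}-{round_half_up(r.ci_high, 2):.2f})"
    )


def format_p(p: Optional[float]) -> str:
    """p rendered in the reference-table style: three decimals below the
    0.05 significance threshold, one decimal otherwise."""
    if p is None:
        return "n.d."
    decimals = 3 if p < 0.05 else 1
    return f"{round_half_up(p, decimals):.{decimals}f}"


def render_burden_rows(results: Sequence[BurdenResult]) -> List[Dict[str, str]]:
    """Rows for a tab-separated report: label, carrier counts with
    percentages, OR (CI) and p."""
    rows = []
    for r in results:
        rows.append(
            {
                "label": r.label,
                "kind": r.kind,
                "gene_class": r.gene_class or "",
                "case_carriers": f"{r.table.a} ({format_percent(r.table.a, r.table.n_cases)})",
                "control_carriers": f"{r.table.c} ({format_percent(r.table.c, r.table.n_controls)})",
                "odds_ratio_ci": format_or(r),
                "p_value": format_p(r.p_value),
            }
        )
    return rows
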