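"""Carrier vs non-carrier clinical comparison.

Compares demographic, etiologic and tumor characteristics between
carriers and non-carriers of retained pathogenic variants (per gene
class or gene set), and their overall survival.

Test dispatch: continuous characteristics default to the Mann-Whitney U
test for two groups (Kruskal-Wallis for more, Student's t-test by
option); categorical characteristics use the Pearson chi-square test on
the contingency table. Survival uses the Kaplan-Meier product-limit
estimator and the log-rank test. All p-values are two-sided; 0.05 is the
conventional significance threshold, reported but never asserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Literal, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from pydantic import BaseModel, Field
from scipy import stats

Etiology = Literal[
    "alcoholic", "viral", "cholestatic_autoimmune", "NASH", "metabolic", "none"
]


class PhenotypeRecord(BaseModel):
    """One subject: group membership, carrier flags, demographics, cirrhosis
    etiology, tumor features and survival."""

    model_config = {"frozen": True}

    sample_id: str = Field(min_length=1)
    group: Literal["case", "control"]
    carrier_flags: Mapping[str, bool] = Field(default_factory=dict)
    age_at_dx: float = Field(ge=0)
    sex: Literal["M", "F"]
    etiology: Etiology
    cirrhosis: bool
    microangioinvasion: bool = False
    cholangio_differentiation: bool = False
    recurrence_post_tx: bool = False
    multiple_primary_tumors: bool = False
    diabetes: bool = False
    obesity: bool = False
    smoking: bool = False
    family_history: bool = False
    survival_months: float = Field(ge=0)
    event: bool


#: (name, kind) of the characteristics compared between carrier groups.
CHARACTERISTICS: Tuple[Tuple[str, str], ...] = (
    ("age_at_dx", "continuous"),
    ("sex", "categorical"),
    ("etiology", "categorical"),
    ("cirrhosis", "categorical"),
    ("diabetes", "categorical"),
    ("obesity", "categorical"),
    ("smoking", "categorical"),
    ("microangioinvasion", "categorical"),
    ("cholangio_differentiation", "categorical"),
    ("recurrence_post_tx", "categorical"),
    ("multiple_primary_tumors", "categorical"),
    ("family_history", "categorical"),
)


@dataclass(frozen=True)
class CharacteristicComparison:
    characteristic: str
    test: str
    statistic: Optional[float]
    p_value: Optional[float]
    testable: bool
    group_summary: Dict[str, Dict]
    note: str = ""


@dataclass
class ComparisonReport:
    """Per-characteristic comparison of carriers vs non-carriers for one
    carrier flag, plus the survival log-rank comparison."""

    flag: str
    n_carriers: int
    n_noncarriers: int
    comparisons: List[CharacteristicComparison] = field(default_factory=list)
    significance_threshold: float = 0.05

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "characteristic": [c.characteristic for c in self.comparisons],
                "test": [c.test for c in self.comparisons],
                "statistic": [c.statistic for c in self.comparisons],
                "p_value": [c.p_value for c in self.comparisons],
                "testable": [c.testable for c in self.comparisons],
            }
        )


def _summarize(values: pd.Series, kind: str) -> Dict:
    if kind == "continuous":
        return {
            "n": int(values.size),
            "median": float(values.median()) if values.size else float("nan"),
            "min": float(values.min()) if values.size else float("nan"),
            "max": float(values.max()) if values.size else float("nan"),
        }
    counts = values.astype(str).value_counts().sort_index()
    return {"n": int(values.size), "counts": {k: int(v) for k, v in counts.items()}}


def _compare_one(
    name: str,
    kind: str,
    groups: Sequence[pd.Series],
    labels: Sequence[str],
    continuous_test: str,
) -> CharacteristicComparison:
    summary = {lab: _summarize(g, kind) for lab, g in zip(labels, groups)}
    if any(len(g) == 0 for g in groups):
        return CharacteristicComparison(
            name, "none", None, None, False, summary, note="empty stratum"
        )
    if kind == "continuous":
        if len(groups) == 2:
            if continuous_test == "t":
                stat, p = stats.ttest_ind(groups[0], groups[1])
                test = "t-test"
            else:
                stat, p = stats.mannwhitneyu(
                    groups[0], groups[1], alternative="two-sided"
                )
                test = "mann-whitney"
        else:
            stat, p = stats.kruskal(*groups)
            test = "kruskal-wallis"
        if np.isnan(p):  # e.g. all values identical in both groups
            return CharacteristicComparison(
                name, test, None, None, False, summary, note="degenerate data"
            )
        return CharacteristicComparison(name, test, float(stat), float(p), True, summary)
    # categorical: chi-square on the levels x groups table
    table = pd.crosstab(
        pd.concat([g.astype(str) for g in groups], ignore_index=True),
        np.repeat(labels, [len(g) for g in groups]),
    )
    if table.shape[0] < 2 or table.shape[1] < 2:
        return CharacteristicComparison(
            name, "chi-square", None, None, False, summary, note="degenerate table"
        )
    stat, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return CharacteristicComparison(name, "chi-square", float(stat), float(p), True, summary)


def compare_groups(
    pheno: Sequence[PhenotypeRecord],
    flag: str,
    continuous_test: str = "mann-whitney",
) -> ComparisonReport:
    """Compare carriers (``carrier_flags[flag]`` true) against non-carriers
    on every clinical characteristic, plus survival via the log-rank test.

    ``continuous_test`` is ``"mann-whitney"`` (default) or ``"t"``.
    """
    missing = [r.sample_id for r in pheno if flag not in r.carrier_flags]
    if missing:
        raise KeyError(
            f"carrier flag {flag!r} missing for {len(missing)} records "
            f"(first: {missing[0]})"
        )
    frame = pd.DataFrame([r.model_dump() for r in pheno])
    is_carrier = np.array([bool(r.carrier_flags[flag]) for r in pheno])
    carriers, noncarriers = frame[is_carrier], frame[~is_carrier]
    report = ComparisonReport(
        flag=flag, n_carriers=len(carriers), n_noncarriers=len(noncarriers)
    )
    labels = ("carrier", "non-carrier")
    for name, kind in CHARACTERISTICS:
        report.comparisons.append(
            _compare_one(
                name,
                kind,
                (carriers[name], noncarriers[name]),
                labels,
                continuous_test,
            )
        )
    # survival comparison
    if len(carriers) and len(noncarriers):
        p = logrank_p(
            frame["survival_months"].to_numpy(),
            frame["event"].to_numpy(dtype=bool),
            np.where(is_carrier, "carrier", "non-carrier"),
        )
        report.comparisons.append(
            CharacteristicComparison(
                "survival", "log-rank", None, p, True,
                {
                    lab: {"n": int(n), "events": int(e)}
                    for lab, n, e in (
                        ("carrier", len(carriers), carriers["event"].sum()),
                        ("non-carrier", len(noncarriers), noncarriers["event"].sum()),
                    )
                },
            )
        )
    else:
        report.comparisons.append(
            CharacteristicComparison(
                "survival", "log-rank", None, None, False, {}, note="empty stratum"
            )
        )
    return report


def kaplan_meier(
    times: Sequence[float], events: Sequence[bool]
) -> List[Tuple[float, float]]:
    """Kaplan-Meier product-limit survival estimate as a list of
    (time, survival probability) step coordinates, starting at (0, 1).

    Survival is non-increasing and changes only at observed event times;
    censored subjects at a time t remain at risk for events at t.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("kaplan_meier requires at least one observation")
    if times.size != events.size:
        raise ValueError("times and events must have equal length")
    if (times < 0).any():
        raise ValueError("times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return [(float(t), float(s)) for t, s in zip(sf.index, sf.iloc[:, 0])]


def logrank_p(
    times: Sequence[float],
    events: Sequence[bool],
    group_labels: Sequence,
) -> float:
    """Two-sided log-rank test p across >= 2 non-empty groups
    (chi-square with groups - 1 df)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(group_labels)
    if not (times.size == events.size == groups.size):
        raise ValueError("times, events and group_labels must have equal length")
    uniq, counts = np.unique(groups, return_counts=True)
    if uniq.size < 2:
        raise ValueError("log-rank test requires at least two non-empty groups")
    if counts.min() == 0:
        raise ValueError("log-rank test groups must be non-empty")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.p_value)
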