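"""Delta-notation utilities and two-group Mann-Whitney-Wilcoxon statistics.

Stable-isotope abundances are expressed in delta notation: the per-mil
deviation of the sample's heavy/light isotope-number ratio from an agreed
zero-point standard (V-PDB for carbon, air N2 for nitrogen, V-SMOW for
oxygen).  Between-year group comparisons use the non-parametric two-sided
Mann-Whitney-Wilcoxon test at alpha = 0.05, with a *directional* U: the
number of (a, b) pairs where the first group's value exceeds the second
group's, counting ties as one half.  By the package convention the first
group is the 2017 harvest, so U = 0 means every 2017 value lies strictly
below every 2018 value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "IsotopeRecord",
    "TestResult",
    "GroupSummary",
    "delta_value",
    "mww_test",
    "group_summary",
    "records_to_frame",
    "EXACT_PAIR_LIMIT",
]

#: Exact p-value enumeration is used when n_a * n_b is at most this and the
#: pooled data are tie-free; otherwise the normal approximation with tie and
#: continuity corrections applies.
EXACT_PAIR_LIMIT = 400

CULTIVARS = ("Quench", "Steffi")
YEARS = (2017, 2018)
ELEMENTS = ("d13C", "d15N", "d18O")


@dataclass(frozen=True)
class IsotopeRecord:
    """Per-sample delta values in per-mil (d13C vs V-PDB, d15N vs air N2,
    d18O vs V-SMOW)."""

    sample_id: str
    cultivar: str
    year: int
    d13C: float
    d15N: float
    d18O: float

    def __post_init__(self):
        for el in ELEMENTS:
            v = getattr(self, el)
            if not np.isfinite(v):
                raise ValueError(f"{self.sample_id}: non-finite {el}")


@dataclass(frozen=True)
class TestResult:
    """Mann-Whitney-Wilcoxon outcome for two groups (a = 2017 by convention)."""

    U: float
    p: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int
    method: str  # "exact" | "approximate"

    @property
    def significant(self) -> bool:
        """Two-sided significance at alpha = 0.05."""
        return self.p < 0.05


@dataclass(frozen=True)
class GroupSummary:
    cultivar: str
    element: str
    median_2017: float
    median_2018: float
    range_2017: tuple[float, float]
    range_2018: tuple[float, float]
    test: TestResult


def delta_value(r_sample: float, r_standard: float) -> float:
    """Delta notation in per-mil: (R_sample / R_standard - 1) * 1000."""
    if r_standard <= 0:
        raise ValueError("standard isotope-number ratio must be positive")
    if r_sample < 0:
        raise ValueError("sample isotope-number ratio must be non-negative")
    return (r_sample / r_standard - 1.0) * 1000.0


def mww_test(group_a, group_b) -> TestResult:
    """Two-sided Mann-Whitney-Wilcoxon test with a directional U statistic.

    U counts pairs where a value from ``group_a`` exceeds one from
    ``group_b``, plus half the tied pairs (equivalently the rank-sum form
    R_a - n_a(n_a+1)/2 with midranks).  The p-value is exact by enumeration
    for tie-free data with ``n_a * n_b <= EXACT_PAIR_LIMIT``, otherwise a
    normal approximation with tie and continuity corrections is used; the
    ``method`` field records which path was taken.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u = float(ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0)
    has_ties = np.unique(pooled).size < pooled.size
    if a.size * b.size <= EXACT_PAIR_LIMIT and not has_ties:
        method = "exact"
        p = float(stats.mannwhitneyu(a, b, method="exact").pvalue)
    else:
        method = "approximate"
        p = float(
            stats.mannwhitneyu(a, b, method="asymptotic", use_continuity=True).pvalue
        )
    return TestResult(
        U=u,
        p=min(p, 1.0),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        n_a=a.size,
        n_b=b.size,
        method=method,
    )


def group_summary(
    records: list[IsotopeRecord], cultivar: str, element: str
) -> GroupSummary:
    """Per-year medians, ranges and the between-year MWW test for one
    cultivar and one isotope variable (2017 group first)."""
    if element not in ELEMENTS:
        raise ValueError(f"unknown element {element!r}; expected one of {ELEMENTS}")
    by_year: dict[int, list[float]] = {y: [] for y in YEARS}
    for r in records:
        if r.cultivar == cultivar and r.year in by_year:
            by_year[r.year].append(getattr(r, element))
    missing = [y for y in YEARS if not by_year[y]]
    if missing:
        raise ValueError(f"no {cultivar} records for year(s) {missing}")
    a = np.asarray(by_year[2017])
    b = np.asarray(by_year[2018])
    test = mww_test(a, b)
    return GroupSummary(
        cultivar=cultivar,
        element=element,
        median_2017=float(np.median(a)),
        median_2018=float(np.median(b)),
        range_2017=(float(a.min()), float(a.max())),
        range_2018=(float(b.min()), float(b.max())),
        test=test,
    )


def records_to_frame(records: list[IsotopeRecord]):
    """Isotope records as a DataFrame with the package CSV schema."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "cultivar": r.cultivar,
                "year": r.year,
                "d13C": r.d13C,
                "d15N": r.d15N,
                "d18O": r.d18O,
            }
            for r in records
        ]
    )


def frame_to_records(df) -> list[IsotopeRecord]:
    return [
        IsotopeRecord(
            sample_id=str(row.sample_id),
            cultivar=str(row.cultivar),
            year=int(row.year),
            d13C=float(row.d13C),
            d15N=float(row.d15N),
            d18O=float(row.d18O),
        )
        for row in df.itertuples(index=False)
    ]
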