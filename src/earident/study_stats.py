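"""Study statistics: uncorrected chi-squared, two-proportion sample size,
and Pugh-chart weighted scoring.

These are the three statistical computations of the study design:
comparing the identification rate between the two capture arms with a
Pearson chi-squared test (no continuity correction, 1 df), planning the
cohort size for detecting a difference between two proportions with the
classical normal-approximation formula, and ranking competing design
concepts with a weighted +/0/- decision matrix against a baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats as sps


class UndefinedTestError(ValueError):
    """Contingency table has a zero margin; the test statistic is undefined."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b) = arm-1 success/failure, (c, d) = arm-2 success/failure."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total must be positive")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def margins(self) -> Tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d,
                self.a + self.c, self.b + self.d)


@dataclass(frozen=True)
class PowerDesign:
    """Two-proportion design: detect p1 vs p2 at type-I error ``alpha``
    with the given power (1 - beta)."""

    p1: float
    p2: float
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        for p in (self.p1, self.p2):
            if not 0.0 < p < 1.0:
                raise ValueError("proportions must lie in (0, 1)")
        if self.p1 == self.p2:
            raise ValueError("p1 must differ from p2")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.power < 1.0:
            raise ValueError("power must lie in (0, 1)")


@dataclass(frozen=True)
class PughChart:
    """Weighted decision matrix: ``marks[i][j]`` in {-1, 0, +1} scores
    concept j on criterion i; the baseline concept is all-zero by
    convention."""

    criteria: Tuple[Tuple[str, int], ...]   # (name, positive integer weight)
    concepts: Tuple[str, ...]
    marks: Tuple[Tuple[int, ...], ...]      # criteria x concepts

    def __post_init__(self) -> None:
        if any(w <= 0 for _, w in self.criteria):
            raise ValueError("criterion weights must be positive integers")
        if len(self.marks) != len(self.criteria):
            raise ValueError("marks rows must match criteria")
        for row in self.marks:
            if len(row) != len(self.concepts):
                raise ValueError("marks columns must match concepts")
            if any(m not in (-1, 0, 1) for m in row):
                raise ValueError("marks must be -1, 0 or +1")


def chi2_uncorrected(table: ContingencyTable2x2) -> Tuple[float, float]:
    """Pearson chi-squared on a 2x2 table, no continuity correction, 1 df.

    Uses the closed form N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); the
    p-value is the upper tail of the chi-squared(1) distribution.
    """
    r1, r2, c1, c2 = table.margins()
    if 0 in (r1, r2, c1, c2):
        raise UndefinedTestError("a zero margin leaves the test undefined")
    a, b, c, d = table.a, table.b, table.c, table.d
    stat = table.n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    p = float(sps.chi2.sf(stat, df=1))
    return float(stat), p


def two_proportion_sample_size(design: PowerDesign) -> int:
    """Per-group sample size for a two-sided two-proportion z-test.

    n = (z_{1-a/2} sqrt(2 pbar (1-pbar)) + z_{1-b} sqrt(p1(1-p1)+p2(1-p2)))^2
        / (p1 - p2)^2,  pbar = (p1+p2)/2, rounded up.
    """
    p1, p2 = design.p1, design.p2
    pbar = 0.5 * (p1 + p2)
    z_a = float(sps.norm.ppf(1.0 - design.alpha / 2.0))
    z_b = float(sps.norm.ppf(design.power))
    num = (z_a * math.sqrt(2.0 * pbar * (1.0 - pbar))
           + z_b * math.sqrt(p1 * (1.0 - p1) + p2 * (1.0 - p2))) ** 2
    return int(math.ceil(num / (p1 - p2) ** 2))


def pugh_score(chart: PughChart) -> Dict[str, int]:
    """Weighted totals per concept: sum over criteria of weight x mark."""
    totals = {name: 0 for name in chart.concepts}
    for (criterion, weight), row in zip(chart.criteria, chart.marks):
        for concept, mark in zip(chart.concepts, row):
            totals[concept] += weight * mark
    return totals


#: The study's lighting-design chart: three concepts scored against the
#: diffused-LED-plate baseline on five weighted criteria.
LIGHTING_PUGH_CHART = PughChart(
    criteria=(
        ("Shadow", 2),
        ("Power Required", 1),
        ("Shape", 1),
        ("Buy/Make", 1),
        ("Price", 1),
    ),
    concepts=("Diffused LED plate", "Electroluminescent Ribbons", "LED Strip"),
    marks=(
        (0, 0, +1),
        (0, 0, -1),
        (0, +1, +1),
        (0, 0, +1),
        (0, -1, 0),
    ),
)


def counts_from_rate(rate_percent: float, n: int) -> Tuple[int, int]:
    """Reconstruct (successes, failures) from a printed percentage and N.

    Successes are the rounded product; the raw product is available from
    the caller as ``rate_percent / 100 * n`` when needed.
    """
    k = int(round(rate_percent / 100.0 * n))
    return k, n - k


def parse_pugh_csv(text: str) -> PughChart:
    """Parse ``criterion,weight,concept1,...`` rows with cells in {+,0,-}.

    The first line is the header naming the concepts.
    """
    lines = [ln.strip() for ln in text.strip().splitlines() if ln.strip()]
    header = [c.strip() for c in lines[0].split(",")]
    if len(header) < 3 or header[0].lower() != "criterion":
        raise ValueError("header must be 'criterion,weight,<concepts...>'")
    concepts = tuple(header[2:])
    sym = {"+": 1, "0": 0, "-": -1, "−": -1}
    criteria: List[Tuple[str, int]] = []
    marks: List[Tuple[int, ...]] = []
    for ln in lines[1:]:
        cells = [c.strip() for c in ln.split(",")]
        criteria.append((cells[0], int(cells[1])))
        try:
            marks.append(tuple(sym[c] for c in cells[2:]))
        except KeyError as exc:
            raise ValueError(f"invalid mark {exc} in row {cells[0]!r}") from exc
    return PughChart(criteria=tuple(criteria), concepts=concepts,
                     marks=tuple(marks))
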