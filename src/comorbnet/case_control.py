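"""Stratified case-control analysis on population-level counts.

Population-level EHR platforms expose cohort counts, not patient-level
records, so ordinary logistic regression is unavailable.  Confounding is
instead handled by stratifying the 2x2 exposure/outcome table on the
adjustment variables (age group, sex, race, risk-factor status) and pooling
with the Cochran-Mantel-Haenszel (CMH) common odds ratio.  The 95% CI uses
the Robins-Breslow-Greenland variance of log(OR), and the two-sided p-value
comes from the Mantel-Haenszel chi-square statistic (1 df).

Such platforms also suppress small cells for de-identification (counts
below 10 are masked, the rest rounded to tens); :func:`masked_input_handling`
implements explicit policies for those cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Union

from scipy import stats

__all__ = [
    "TwoByTwo",
    "StratifiedTable",
    "CMHResult",
    "DemographicsSummary",
    "crude_or",
    "cmh_or",
    "masked_input_handling",
    "summarize_demographics",
    "read_stratified_tsv",
    "write_stratified_tsv",
]

#: value written for suppressed cells in TSV output
SUPPRESSED = "<10"

Cell = Optional[int]  # None encodes a suppressed (masked) count


@dataclass(frozen=True)
class TwoByTwo:
    """One stratum's exposure/outcome table.

    a: exposed with outcome, b: exposed without, c_: unexposed with outcome,
    d: unexposed without.  A ``None`` cell is a suppressed count and must be
    resolved by :func:`masked_input_handling` before analysis.
    """

    a: Cell
    b: Cell
    c_: Cell
    d: Cell

    def __post_init__(self) -> None:
        for name, v in zip("a b c_ d".split(), (self.a, self.b, self.c_, self.d)):
            if v is not None and v < 0:
                raise ValueError(f"negative count {name}={v}")

    @property
    def masked(self) -> bool:
        return any(v is None for v in (self.a, self.b, self.c_, self.d))

    @property
    def n(self) -> int:
        if self.masked:
            raise ValueError("table contains suppressed cells")
        return self.a + self.b + self.c_ + self.d

    def transposed_exposure(self) -> "TwoByTwo":
        """Swap the exposed/unexposed rows (odds ratio inverts exactly)."""
        return TwoByTwo(self.c_, self.d, self.a, self.b)


@dataclass
class StratifiedTable:
    """Ordered collection of labelled 2x2 strata."""

    strata: list[tuple[str, TwoByTwo]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.strata]
        if len(labels) != len(set(labels)):
            raise ValueError("stratum labels must be unique")

    def __len__(self) -> int:
        return len(self.strata)

    def __iter__(self):
        return iter(self.strata)


@dataclass(frozen=True)
class CMHResult:
    aor: float
    ci_low: float
    ci_high: float
    p_value: float
    chi2: float
    strata_used: int
    strata_skipped: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.aor <= self.ci_high):
            raise ValueError("confidence interval does not bracket the estimate")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def crude_or(t: TwoByTwo, continuity: bool = False) -> float:
    """Single-table odds ratio (a*d)/(b*c).

    With ``continuity=True`` the Haldane-Anscombe correction (0.5 added to
    every cell) is applied whenever any cell is zero, yielding a finite
    estimate; otherwise a zero denominator raises.
    """
    if t.masked:
        raise ValueError("resolve suppressed cells before computing an odds ratio")
    a, b, c, d = float(t.a), float(t.b), float(t.c_), float(t.d)
    if continuity and min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if b * c == 0.0:
        raise ZeroDivisionError(
            "odds ratio undefined: b*c == 0 (enable continuity correction)"
        )
    return (a * d) / (b * c)


_Z975 = stats.norm.ppf(0.975)


def cmh_or(
    s: StratifiedTable,
    alpha: float = 0.05,
    continuity: bool = False,
) -> CMHResult:
    """Cochran-Mantel-Haenszel common odds ratio across strata.

    Estimate: sum_i(a_i d_i / n_i) / sum_i(b_i c_i / n_i).  The CI uses the
    Robins-Breslow-Greenland variance of the log common OR; the p-value is
    the Mantel-Haenszel chi-square test of OR = 1 (1 df, two-sided, no
    continuity correction unless requested).  Strata with n = 0 are skipped
    and counted in ``strata_skipped``.
    """
    used: list[TwoByTwo] = []
    skipped = 0
    for _, t in s:
        if t.masked:
            raise ValueError(
                "stratified table contains suppressed cells; "
                "apply masked_input_handling first"
            )
        if t.n == 0:
            skipped += 1
            continue
        used.append(t)
    if not used:
        raise ValueError("no usable strata (all empty)")

    R = sum(t.a * t.d / t.n for t in used)
    S = sum(t.b * t.c_ / t.n for t in used)
    if S == 0.0 or R == 0.0:
        raise ZeroDivisionError("degenerate strata: MH numerator or denominator is 0")
    aor = R / S

    # Robins-Breslow-Greenland variance of log(OR_MH)
    sum_PR = sum((t.a + t.d) / t.n * (t.a * t.d / t.n) for t in used)
    sum_PS_QR = sum(
        (t.a + t.d) / t.n * (t.b * t.c_ / t.n)
        + (t.b + t.c_) / t.n * (t.a * t.d / t.n)
        for t in used
    )
    sum_QS = sum((t.b + t.c_) / t.n * (t.b * t.c_ / t.n) for t in used)
    var_log = sum_PR / (2 * R * R) + sum_PS_QR / (2 * R * S) + sum_QS / (2 * S * S)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * math.sqrt(var_log)
    ci_low, ci_high = aor * math.exp(-half), aor * math.exp(half)

    # Mantel-Haenszel chi-square (1 df)
    sum_a = sum(t.a for t in used)
    sum_E = sum((t.a + t.b) * (t.a + t.c_) / t.n for t in used)
    sum_V = sum(
        (t.a + t.b) * (t.c_ + t.d) * (t.a + t.c_) * (t.b + t.d)
        / (t.n**2 * (t.n - 1))
        for t in used
        if t.n > 1
    )
    if sum_V > 0:
        num = abs(sum_a - sum_E) - (0.5 if continuity else 0.0)
        chi2 = max(num, 0.0) ** 2 / sum_V
        p = float(stats.chi2.sf(chi2, df=1))
    else:
        chi2, p = float("nan"), 1.0

    return CMHResult(
        aor=aor,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p,
        chi2=chi2,
        strata_used=len(used),
        strata_skipped=skipped,
    )


def masked_input_handling(
    s: StratifiedTable,
    policy: str = "midpoint",
    mask_below: int = 10,
    constant: Optional[int] = None,
) -> StratifiedTable:
    """Resolve suppressed cells before CMH analysis.

    Policies: ``midpoint`` (cell := mask_below // 2, the centre of the
    suppressed 1..mask_below-1 range), ``drop`` (exclude the stratum),
    ``zero`` (cell := 0), ``constant`` (cell := ``constant``).  The chosen
    policy and the number of affected cells/strata are recorded in the
    returned table's provenance.
    """
    if policy == "constant" and constant is None:
        raise ValueError("policy='constant' requires a constant value")
    fill = {"midpoint": mask_below // 2, "zero": 0, "constant": constant}
    if policy not in fill and policy != "drop":
        raise ValueError(f"unknown masked-cell policy {policy!r}")

    out: list[tuple[str, TwoByTwo]] = []
    n_cells = 0
    n_dropped = 0
    for label, t in s:
        cells = (t.a, t.b, t.c_, t.d)
        masked_here = sum(v is None for v in cells)
        if masked_here == 0:
            out.append((label, t))
            continue
        n_cells += masked_here
        if policy == "drop":
            n_dropped += 1
            continue
        v = fill[policy]
        out.append(
            (label, TwoByTwo(*(v if cell is None else cell for cell in cells)))
        )
    prov = dict(s.provenance)
    prov.update(
        masked_policy=policy,
        masked_cells=n_cells,
        strata_dropped_masked=n_dropped,
    )
    return StratifiedTable(out, provenance=prov)


# ---------------------------------------------------------------------------
# Demographics summaries (Table-2-style layout)

def _round_half_up_pct(count: int, total: int) -> int:
    if total <= 0:
        raise ValueError("cohort total must be positive")
    return int(math.floor(100.0 * count / total + 0.5))


@dataclass
class DemographicsSummary:
    """Per-cohort category counts with column percentages.

    ``table[cohort][group][category] = (count, percent)`` where percent is
    of the cohort total, rounded half-up to the nearest integer.  Category
    counts may sum above the total because a patient can report several
    values of the same demographic at once.
    """

    totals: dict[str, int]
    table: dict[str, dict[str, dict[str, tuple[int, int]]]]

    def percent(self, cohort: str, group: str, category: str) -> int:
        return self.table[cohort][group][category][1]

    def to_rows(self) -> list[tuple[str, str, str, int, int]]:
        rows = []
        for cohort, groups in self.table.items():
            for group, cats in groups.items():
                for cat, (count, pct) in cats.items():
                    rows.append((cohort, group, cat, count, pct))
        return rows


CountTable = Mapping[str, Union[int, Mapping[str, int]]]


def summarize_demographics(
    cohorts: Mapping[str, Union[CountTable, Iterable]],
) -> DemographicsSummary:
    """Tabulate demographic composition per cohort.

    Each cohort is either a pre-aggregated count table
    (``{"total": N, "sex": {...}, "age": {...}, ...}``) or an iterable of
    case reports carrying ``demographics = (age_group, sex)``.
    """
    totals: dict[str, int] = {}
    table: dict[str, dict[str, dict[str, tuple[int, int]]]] = {}
    for cohort, data in cohorts.items():
        if isinstance(data, Mapping):
            total = int(data["total"])
            groups = {
                g: dict(cats)
                for g, cats in data.items()
                if g != "total"
            }
        else:
            reports = list(data)
            total = len(reports)
            groups = {"age": {}, "sex": {}}
            for rep in reports:
                demo = getattr(rep, "demographics", None)
                if demo is None:
                    continue
                age_group, sex = demo
                groups["age"][age_group] = groups["age"].get(age_group, 0) + 1
                groups["sex"][sex] = groups["sex"].get(sex, 0) + 1
        totals[cohort] = total
        table[cohort] = {
            g: {cat: (cnt, _round_half_up_pct(cnt, total)) for cat, cnt in cats.items()}
            for g, cats in groups.items()
        }
    return DemographicsSummary(totals=totals, table=table)


# ---------------------------------------------------------------------------
# TSV round-trip for stratified tables

def write_stratified_tsv(s: StratifiedTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("stratum\ta\tb\tc\td\n")
        for label, t in s:
            cells = "\t".join(
                SUPPRESSED if v is None else str(v)
                for v in (t.a, t.b, t.c_, t.d)
            )
            fh.write(f"{label}\t{cells}\n")


def read_stratified_tsv(path) -> StratifiedTable:
    strata: list[tuple[str, TwoByTwo]] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("stratum"):
            raise ValueError(f"unexpected header in {path}: {header!r}")
        for line in fh:
            if not line.strip():
                continue
            label, *cells = line.rstrip("\n").split("\t")
            if len(cells) != 4:
                raise ValueError(f"malformed stratum row: {line!r}")
            vals = [None if c == SUPPRESSED else int(c) for c in cells]
            strata.append((label, TwoByTwo(*vals)))
    return StratifiedTable(strata)
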