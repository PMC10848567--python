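"""Success metrics, failure-tracking accounting, age regressions and
assignment tables.

Percentages are computed from counts and rounded half-up to one decimal
place, so printed values are exactly reproducible from the underlying
counts.  Sequence "length" always means the number of non-N bases of the
consensus, and an *acceptable* barcode has more than 300 of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd
import statsmodels.api as sm

from .assemble import ConsensusBarcode
from .plate import DEFAULT_ANALYSIS_YEAR, SpecimenRecord

ACCEPTABLE_MIN_NONN = 301  # "> 300 bp"


def pct(count: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal; 0.0 for an empty denominator."""
    if denominator == 0:
        return 0.0
    q = Decimal(count) * 100 / Decimal(denominator)
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class SuccessSummary:
    n_total: int
    n_recovered: int  # > 0 non-N bp
    n_acceptable: int  # > 300 non-N bp
    n_flagged: int = 0
    n_genera: int = 0
    n_genera_acceptable: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_acceptable <= self.n_recovered <= self.n_total:
            raise ValueError(
                "counts must satisfy acceptable <= recovered <= total, got "
                f"{self.n_acceptable} <= {self.n_recovered} <= {self.n_total}"
            )

    @property
    def pct_recovered(self) -> float:
        return pct(self.n_recovered, self.n_total)

    @property
    def pct_acceptable(self) -> float:
        return pct(self.n_acceptable, self.n_total)

    @property
    def pct_genera(self) -> float:
        return pct(self.n_genera_acceptable, self.n_genera)

    @classmethod
    def from_counts(cls, n_total: int, n_recovered: int, n_acceptable: int,
                    n_flagged: int = 0, n_genera: int = 0,
                    n_genera_acceptable: int = 0) -> "SuccessSummary":
        return cls(n_total, n_recovered, n_acceptable, n_flagged,
                   n_genera, n_genera_acceptable)


def success_summary(barcodes: list[ConsensusBarcode],
                    records: list[SpecimenRecord]) -> SuccessSummary:
    """Summarise recovery over matched (barcode, specimen) pairs.

    A genus counts as successful when at least one of its specimens gained
    an acceptable barcode.  Records without a barcode count as failures.
    """
    ids = [str(r.sample_id) for r in records]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise ValueError(f"duplicate sample_id {dup!r}")
    by_id = {b.sample_id: b for b in barcodes}
    if len(by_id) != len(barcodes):
        raise ValueError("duplicate sample_id among barcodes")
    n_recovered = n_acceptable = n_flagged = 0
    genera: dict[str, bool] = {}
    for rec in records:
        bc = by_id.get(str(rec.sample_id))
        nonN = bc.nonN_length if bc else 0
        ok = nonN >= ACCEPTABLE_MIN_NONN
        n_recovered += nonN > 0
        n_acceptable += ok
        if bc and ("contaminated" in bc.flags or rec.flags):
            n_flagged += 1
        genus = rec.taxonomy.genus
        if genus:
            genera[genus] = genera.get(genus, False) or ok
    return SuccessSummary(
        n_total=len(records),
        n_recovered=n_recovered,
        n_acceptable=n_acceptable,
        n_flagged=n_flagged,
        n_genera=len(genera),
        n_genera_acceptable=sum(genera.values()),
    )


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("regression needs at least 3 points")
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError(f"r_squared out of range: {self.r_squared}")


def age_length_regression(
    records: list[SpecimenRecord],
    barcodes: list[ConsensusBarcode],
    exclude_flagged: bool = True,
    analysis_year: int = DEFAULT_ANALYSIS_YEAR,
) -> RegressionResult:
    """OLS of recovered non-N sequence length on specimen age (years).

    Only specimens with a recovered sequence (> 0 non-N bp) and a known
    collection year enter the fit; flagged records are excluded by default.
    """
    by_id = {b.sample_id: b for b in barcodes}
    xs, ys = [], []
    for rec in records:
        bc = by_id.get(str(rec.sample_id))
        if bc is None or bc.nonN_length == 0:
            continue
        if exclude_flagged and ("contaminated" in bc.flags or rec.flags):
            continue
        age = rec.age(analysis_year)
        if age is None:
            continue
        xs.append(age)
        ys.append(bc.nonN_length)
    if len(xs) < 3:
        raise ValueError(f"need >= 3 usable (age, length) pairs, got {len(xs)}")
    if len(set(xs)) == 1:
        raise ValueError("zero variance in specimen age")
    if len(set(ys)) == 1:
        # constant response: flat fit, nothing explained
        return RegressionResult(0.0, float(ys[0]), 0.0, 1.0, len(xs))
    model = sm.OLS(ys, sm.add_constant(xs)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
        n=len(xs),
    )


@dataclass
class StageOutcome:
    """ID-level outcome of one sequencing stage (Sanger or NGS rerun)."""

    total_ids: set[str]
    recovered_ids: set[str]
    acceptable_ids: set[str]
    flagged_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.acceptable_ids <= self.recovered_ids <= self.total_ids:
            raise ValueError("need acceptable ⊆ recovered ⊆ total")

    @property
    def pct_recovered(self) -> float:
        return pct(len(self.recovered_ids), len(self.total_ids))


@dataclass
class FailureTrackingTable:
    sanger: StageOutcome
    ngs: StageOutcome
    n_review_flagged: int = 0

    @property
    def combined_recovered(self) -> int:
        return len(self.sanger.recovered_ids) + len(self.ngs.recovered_ids)

    @property
    def combined_acceptable(self) -> int:
        return len(self.sanger.acceptable_ids) + len(self.ngs.acceptable_ids)

    @property
    def n_total(self) -> int:
        return len(self.sanger.total_ids)

    @property
    def total_flagged(self) -> int:
        return (len(self.sanger.flagged_ids) + len(self.ngs.flagged_ids)
                + self.n_review_flagged)

    @property
    def pct_combined_recovered(self) -> float:
        return pct(self.combined_recovered, self.n_total)

    @property
    def pct_combined_acceptable(self) -> float:
        return pct(self.combined_acceptable, self.n_total)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("sanger", len(self.sanger.total_ids), len(self.sanger.recovered_ids),
             len(self.sanger.acceptable_ids), len(self.sanger.flagged_ids),
             self.sanger.pct_recovered),
            ("ngs_failure_tracking", len(self.ngs.total_ids), len(self.ngs.recovered_ids),
             len(self.ngs.acceptable_ids), len(self.ngs.flagged_ids),
             self.ngs.pct_recovered),
            ("combined", self.n_total, self.combined_recovered,
             self.combined_acceptable, self.total_flagged,
             self.pct_combined_recovered),
        ]
        return pd.DataFrame(
            rows, columns=["stage", "n_total", "n_recovered", "n_acceptable",
                           "n_flagged", "pct_recovered"],
        )


def failure_tracking_summary(sanger: StageOutcome, ngs: StageOutcome,
                             n_review_flagged: int = 0) -> FailureTrackingTable:
    """Combine a first-pass stage with an NGS failure-tracking rerun.

    The rerun must target a subset of the first pass's failures, and the two
    recovered sets must be disjoint; combined counts are sums, so count
    conservation holds by construction.
    """
    failures = sanger.total_ids - sanger.recovered_ids
    if not ngs.total_ids <= failures:
        extra = sorted(ngs.total_ids - failures)[:5]
        raise ValueError(f"NGS rerun targets non-failed specimens, e.g. {extra}")
    if sanger.recovered_ids & ngs.recovered_ids:
        raise ValueError("a specimen cannot be recovered by both stages")
    return FailureTrackingTable(sanger, ngs, n_review_flagged)


def assignment_report(summary: dict) -> pd.DataFrame:
    """Method x rank table with row/column/grand totals.

    ``summary`` maps (method, rank) -> count, as produced by
    :func:`museumharvest.classify.summarize_assignments`; only genus- and
    species-level assignments enter the table.
    """
    methods = ("bin_match", "id_engine")
    ranks = ("genus", "species")
    data = {
        m: {r: int(summary.get((m, r), 0)) for r in ranks} for m in methods
    }
    df = pd.DataFrame(data).T
    df["total"] = df.sum(axis=1)
    df.loc["total"] = df.sum(axis=0)
    df.index.name = "method"
    return df


def grand_total(report: pd.DataFrame) -> int:
    return int(report.loc["total", "total"])
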