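"""Classification of predicted mutations against experimental screens.

A mutation is predicted *favorable* when its relative binding free energy is
at or below a threshold (default 0 kJ/mol, boundary inclusive) and compared
with whether the mutation was *found* in a random saturation-mutagenesis
screen.  The four-cell cross table supports the Matthews correlation
coefficient, concordance (percentage of true positives plus true negatives),
mean absolute deviation and Pearson correlation between prediction methods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats


@dataclass
class PredictionRecord:
    """One mutation's predicted free energy and experimental outcome."""

    site: str
    mutation: str
    p1prime: str
    predicted_dG: float
    found: bool

    def __post_init__(self) -> None:
        if not math.isfinite(self.predicted_dG):
            raise ValueError("predicted free energy must be finite")


@dataclass
class CrossTable:
    """Counts (or proportions) of favorable/unfavorable vs found/not found.

    tp = favorable and found, fp = favorable and not found,
    fn = unfavorable and found, tn = unfavorable and not found.
    """

    tp: float
    fp: float
    fn: float
    tn: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("cross-table cells must be non-negative")
        if self.total <= 0:
            raise ValueError("cross table must have positive total")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "CrossTable") -> "CrossTable":
        return CrossTable(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )

    def proportions(self) -> "CrossTable":
        t = self.total
        return CrossTable(100 * self.tp / t, 100 * self.fp / t, 100 * self.fn / t, 100 * self.tn / t)


def classify(predicted_dG: float, threshold: float = 0.0) -> str:
    """'favorable' iff the predicted free-energy change is <= threshold."""
    if not math.isfinite(predicted_dG):
        raise ValueError("predicted free energy must be finite")
    return "favorable" if predicted_dG <= threshold else "unfavorable"


def build_cross_table(
    records: Iterable[PredictionRecord],
    threshold: float = 0.0,
    exclude_wildtype: bool = True,
    wildtype: dict | None = None,
) -> CrossTable:
    """Count predictions into the four cells.

    ``wildtype`` maps site -> wild-type residue name; matching rows (which are
    identically zero by cycle construction) are dropped when
    ``exclude_wildtype`` is set.
    """
    wildtype = wildtype or {}
    tp = fp = fn = tn = 0
    for rec in records:
        if exclude_wildtype and wildtype.get(rec.site) == rec.mutation:
            continue
        fav = classify(rec.predicted_dG, threshold) == "favorable"
        if fav and rec.found:
            tp += 1
        elif fav:
            fp += 1
        elif rec.found:
            fn += 1
        else:
            tn += 1
    if tp + fp + fn + tn == 0:
        raise ValueError("no records left after wild-type exclusion")
    return CrossTable(tp, fp, fn, tn)


def mcc(table: CrossTable) -> float:
    """Matthews correlation coefficient in [-1, 1]; 0 when a marginal is empty.

    Invariant under uniform scaling of all four cells, so percentage tables
    work as well as raw counts.
    """
    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def concordance(table: CrossTable) -> float:
    """Percentage of true positives plus true negatives."""
    return 100.0 * (table.tp + table.tn) / table.total


def mad(a: Sequence[float], b: Sequence[float]) -> float:
    """Mean absolute deviation between two paired prediction vectors (kJ/mol)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("inputs must be non-empty and of equal length")
    return float(np.mean(np.abs(a - b)))


def pearson(a: Sequence[float], b: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient between two prediction vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("inputs must be of equal length >= 2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("undefined correlation: zero variance")
    return float(_scipy_stats.pearsonr(a, b).statistic)


def records_from_frame(frame: pd.DataFrame) -> list[PredictionRecord]:
    """Build prediction records from columns site, mutation, p1prime,
    predicted_dG, found (truthy/0-1)."""
    return [
        PredictionRecord(
            site=str(row.site),
            mutation=row.mutation,
            p1prime=row.p1prime,
            predicted_dG=float(row.predicted_dG),
            found=bool(int(row.found)),
        )
        for row in frame.itertuples(index=False)
    ]


def validation_report(
    frame: pd.DataFrame,
    threshold: float = 0.0,
    exclude_wildtype: bool = True,
    wildtype: dict | None = None,
) -> pd.DataFrame:
    """Cross table, MCC and concordance per (site, p1prime) plus the pooled set."""
    rows = []
    groups = list(frame.groupby(["site", "p1prime"])) + [(("all", "all"), frame)]
    for (site, p1), group in groups:
        table = build_cross_table(
            records_from_frame(group),
            threshold=threshold,
            exclude_wildtype=exclude_wildtype,
            wildtype=wildtype,
        )
        rows.append(
            {
                "site": site,
                "p1prime": p1,
                "tp": table.tp,
                "fp": table.fp,
                "fn": table.fn,
                "tn": table.tn,
                "mcc": mcc(table),
                "concordance_pct": concordance(table),
            }
        )
    return pd.DataFrame(rows)
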