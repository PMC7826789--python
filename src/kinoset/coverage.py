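"""Kinome-coverage accounting: family tables, chemotype redundancy, dark kinases.

Coverage is reported per kinase subfamily as the percentage of *assayed*
kinases touched by at least one selected inhibitor, rounded half-up to an
integer percent (37.5% prints as 38%). Dark-kinase accounting intersects the
covered set with the user-supplied list of understudied kinases nominated by
the NIH Illuminating the Druggable Genome (IDG) initiative — that list is an
input, never fetched.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .data_model import AssayPanel, KinosetError

TOTAL_LABEL = "Total"


def round_half_up(x: float) -> int:
    """Round to the nearest integer with exact halves going up."""
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def coverage_pct(n_covered: int, n_assays: int) -> int | None:
    """Integer coverage percentage (half-up), or None when nothing is assayed."""
    if n_assays == 0:
        return None
    return round_half_up(100.0 * n_covered / n_assays)


@dataclass
class CoverageRow:
    """One subfamily's coverage: total kinases, assayed, covered, percent."""

    family: str
    n_kinases: int
    n_assays: int
    n_covered: int
    pct: int | None

    def __post_init__(self) -> None:
        if self.n_covered > self.n_assays:
            raise KinosetError(
                f"{self.family}: covered ({self.n_covered}) exceeds assayed "
                f"({self.n_assays})"
            )


@dataclass
class RedundancyReport:
    """Kinases covered by >= 2 distinct chemotypes vs exactly one."""

    n_kinases_multi: int
    n_kinases_single: int

    @property
    def total_covered(self) -> int:
        return self.n_kinases_multi + self.n_kinases_single


def family_coverage(
    panel: AssayPanel,
    covered: Iterable[str],
    family_totals: Mapping[str, int] | None = None,
) -> list[CoverageRow]:
    """Per-family coverage rows plus a totals row.

    ``family_totals`` optionally supplies the number of human kinases per
    family (a superset of what the panel assays); without it the assayed
    count is used for both columns. Covered kinases must belong to the panel.
    """
    covered = set(covered)
    panel_kinases = set(panel.kinases)
    stray = covered - panel_kinases
    if stray:
        raise KinosetError(f"covered kinases absent from panel: {sorted(stray)}")

    assays_by_family: dict[str, set[str]] = {}
    for a in panel.assays:
        assays_by_family.setdefault(a.family, set()).add(a.kinase)

    rows: list[CoverageRow] = []
    for family in sorted(assays_by_family):
        assayed = assays_by_family[family]
        n_cov = len(covered & assayed)
        n_kin = (
            int(family_totals[family])
            if family_totals is not None and family in family_totals
            else len(assayed)
        )
        rows.append(
            CoverageRow(
                family=family,
                n_kinases=n_kin,
                n_assays=len(assayed),
                n_covered=n_cov,
                pct=coverage_pct(n_cov, len(assayed)),
            )
        )
    tot_assays = sum(r.n_assays for r in rows)
    tot_cov = sum(r.n_covered for r in rows)
    rows.append(
        CoverageRow(
            family=TOTAL_LABEL,
            n_kinases=sum(r.n_kinases for r in rows),
            n_assays=tot_assays,
            n_covered=tot_cov,
            pct=coverage_pct(tot_cov, tot_assays),
        )
    )
    return rows


def coverage_table(rows: Sequence[CoverageRow]) -> pd.DataFrame:
    """Coverage rows as a DataFrame with columns family, kinases, assays, covered, pct."""
    return pd.DataFrame(
        [
            {
                "family": r.family,
                "kinases": r.n_kinases,
                "assays": r.n_assays,
                "covered": r.n_covered,
                "pct": r.pct,
            }
            for r in rows
        ]
    )


def redundancy_report(
    depth_table: Mapping[str, tuple[int, int]]
) -> RedundancyReport:
    """Split covered kinases by distinct-chemotype depth (not inhibitor count).

    ``depth_table`` maps kinase -> (n inhibitors, n distinct chemotypes),
    as produced by :meth:`kinoset.selection.SelectedSet.depth_table`.
    """
    multi = sum(1 for _, (_, n_chem) in depth_table.items() if n_chem >= 2)
    single = sum(1 for _, (_, n_chem) in depth_table.items() if n_chem == 1)
    return RedundancyReport(n_kinases_multi=multi, n_kinases_single=single)


def dark_kinase_coverage(
    covered: Iterable[str], idg_list: Sequence[str]
) -> tuple[int, list[str]]:
    """Count and list covered dark kinases (exact symbol intersection)."""
    if not idg_list:
        raise KinosetError("IDG dark-kinase list must be non-empty")
    hit = sorted(set(covered) & set(idg_list))
    return len(hit), hit
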