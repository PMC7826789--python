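"""S10 selectivity scoring and the potency/selectivity inclusion decision.

The selectivity index S10 of a compound is the fraction of assayed kinases
whose percent-of-control (PoC) at the screening concentration falls strictly
below a cutoff (default 10%, i.e. at least 90% inhibition). A compound enters
a chemogenomic set when it is both potent (at least one follow-up K_D below
100 nM) and narrow-spectrum (S10 below 0.025). All threshold comparisons are
strict, so boundary values fail.

Denominators count only wild-type human kinases with a non-missing PoC cell;
unassayed kinases are not evidence of selectivity, so missing cells drop out
of both numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .data_model import ActivityMatrix, KdRecord, KinosetError

#: Default PoC cutoff (percent activity remaining) defining "active".
DEFAULT_CUTOFF = 10.0
#: Potency bound for inclusion: some K_D strictly below this (nM).
DEFAULT_KD_MAX_NM = 100.0
#: Selectivity bound for inclusion: S10 strictly below this fraction.
DEFAULT_S10_MAX = 0.025
#: Looser S10 bound used for initial triage before K_D follow-up.
TRIAGE_S10_MAX = 0.04


@dataclass
class SelectivityResult:
    """S10 of one compound: active kinases over assayed kinases."""

    compound: str
    s10: float
    cutoff: float
    concentration: float
    active_kinases: list[str]
    n_assayed: int

    @property
    def n_active(self) -> int:
        return len(self.active_kinases)


@dataclass
class InclusionDecision:
    """Outcome of the potency + selectivity inclusion rule for one compound."""

    compound: str
    passed: bool
    qualifying_kinases: list[str]
    s10: float
    kd_max_nM: float = DEFAULT_KD_MAX_NM
    s10_max: float = DEFAULT_S10_MAX


def _assayed_row(matrix: ActivityMatrix, compound: str) -> pd.Series:
    """Non-missing PoC cells of a compound, restricted to wild-type human assays."""
    row = matrix.row(compound)
    eligible = matrix.panel.wild_type_human
    row = row[[k for k in row.index if k in eligible]]
    row = row.dropna()
    if row.empty:
        raise KinosetError(
            f"compound {compound!r} has no assayed (non-missing) cells"
        )
    return row


def active_profile(
    matrix: ActivityMatrix, compound: str, cutoff: float = DEFAULT_CUTOFF
) -> list[str]:
    """Kinases with PoC strictly below ``cutoff``, sorted by ascending PoC then symbol."""
    row = _assayed_row(matrix, compound)
    hits = row[row < cutoff]
    return [str(k) for _, k in sorted(zip(hits.to_numpy(), hits.index))]


def compute_s10(
    matrix: ActivityMatrix, compound: str, cutoff: float = DEFAULT_CUTOFF
) -> SelectivityResult:
    """S10 = (kinases with PoC < cutoff) / (kinases assayed), on this matrix's panel.

    The denominator travels with the matrix: a compound profiled on a
    230-assay panel is scored against 230, one profiled on a 401-assay
    panel against 401 (minus any missing cells).
    """
    row = _assayed_row(matrix, compound)
    active = active_profile(matrix, compound, cutoff)
    return SelectivityResult(
        compound=compound,
        s10=len(active) / len(row),
        cutoff=cutoff,
        concentration=matrix.panel.concentration,
        active_kinases=active,
        n_assayed=len(row),
    )


def kd_followup_set(
    matrix: ActivityMatrix, compound: str, followup_cutoff: float = DEFAULT_CUTOFF
) -> list[str]:
    """Kinases to submit for K_D measurement: PoC strictly below ``followup_cutoff``.

    The follow-up cutoff defaults to 10 PoC but is configurable to 20; both
    conventions are in circulation and the caller decides.
    """
    return active_profile(matrix, compound, followup_cutoff)


def decide_inclusion(
    s10_result: SelectivityResult,
    kd: Sequence[KdRecord],
    kd_max_nM: float = DEFAULT_KD_MAX_NM,
    s10_max: float = DEFAULT_S10_MAX,
) -> InclusionDecision:
    """Apply the inclusion rule: some K_D < kd_max_nM and S10 < s10_max (both strict).

    Any kinase with a sub-threshold K_D qualifies the compound — off-target
    potency is repurposed deliberately in chemogenomic set design. An empty
    K_D list yields a failed decision, not an error.
    """
    mismatched = [r.compound for r in kd if r.compound != s10_result.compound]
    if mismatched:
        raise KinosetError(
            f"K_D records for {set(mismatched)} passed to decision for "
            f"{s10_result.compound!r}"
        )
    qualifying = sorted(
        {r.kinase for r in kd if r.kd_nM < kd_max_nM}
    )
    passed = bool(qualifying) and s10_result.s10 < s10_max
    return InclusionDecision(
        compound=s10_result.compound,
        passed=passed,
        qualifying_kinases=qualifying,
        s10=s10_result.s10,
        kd_max_nM=kd_max_nM,
        s10_max=s10_max,
    )


def score_matrix(
    matrix: ActivityMatrix, cutoff: float = DEFAULT_CUTOFF
) -> pd.DataFrame:
    """S10 for every compound in a matrix, as a tidy table (used by the CLI)."""
    rows = []
    for cid in matrix.compounds:
        res = compute_s10(matrix, cid, cutoff)
        rows.append(
            {
                "compound": cid,
                "s10": res.s10,
                "n_active": res.n_active,
                "n_assayed": res.n_assayed,
                "active_kinases": ";".join(res.active_kinases),
            }
        )
    return pd.DataFrame(
        rows, columns=["compound", "s10", "n_active", "n_assayed", "active_kinases"]
    )
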