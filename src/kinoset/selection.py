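"""Greedy assembly of a chemogenomic set maximizing kinome coverage.

Expert curation of a chemogenomic library follows three stated preferences:
maximize the number of kinases covered, aim for two distinct chemotypes per
kinase, and, between otherwise equivalent compounds, prefer the chemotype
with fewer exemplars already in the set. This module commits those
preferences to a deterministic, auditable greedy algorithm.

A kinase counts as *covered* by a compound only through a qualifying
potency record (K_D below the configured bound) — mere single-concentration
activity is not coverage. Each greedy step adds the candidate with the
largest marginal coverage gain:

    gain(c) = sum over c's qualifying kinases k of
              weight(k) * [chemotype(c) is new for k  and
                           k currently holds < depth_target chemotypes]

with ties broken by (1) fewer exemplars of the candidate's chemotype already
selected, (2) lower S10, (3) lexicographically smaller id. Selection stops
when no candidate has positive gain. Optional publication weights in [0, 1]
down-weight well-studied kinases so rare coverage wins over redundant
coverage of famous targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .chemotype import BinAssignment
from .data_model import ActivityMatrix, KdRecord, KinosetError
from .selectivity import (
    DEFAULT_CUTOFF,
    DEFAULT_KD_MAX_NM,
    DEFAULT_S10_MAX,
    InclusionDecision,
    compute_s10,
    decide_inclusion,
)


@dataclass
class SelectionConfig:
    """Thresholds and goals for candidate filtering and greedy assembly."""

    kd_max_nM: float = DEFAULT_KD_MAX_NM
    s10_max: float = DEFAULT_S10_MAX
    depth_target: int = 2
    publication_weights: Mapping[str, float] | None = None
    poc_cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        if self.depth_target < 1:
            raise KinosetError("depth_target must be >= 1")
        if self.kd_max_nM <= 0 or self.s10_max <= 0:
            raise KinosetError("thresholds must be > 0")
        if self.publication_weights is not None:
            bad = {k: w for k, w in self.publication_weights.items()
                   if not 0.0 <= w <= 1.0}
            if bad:
                raise KinosetError(f"publication weights outside [0, 1]: {bad}")

    def weight(self, kinase: str) -> float:
        if self.publication_weights is None:
            return 1.0
        return float(self.publication_weights.get(kinase, 1.0))


@dataclass
class Candidate:
    """A compound that passed inclusion, with its qualifying kinase set."""

    compound: str
    s10: float
    qualifying_kinases: frozenset[str]
    decision: InclusionDecision


@dataclass
class GreedyStep:
    """Audit record of one greedy iteration (replayable)."""

    step: int
    picked: str
    gain: float
    tie_break: str  # "gain" | "chemotype_exemplars" | "s10" | "id"
    scores: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "step": self.step,
            "picked": self.picked,
            "gain": self.gain,
            "tie_break": self.tie_break,
            "scores": self.scores,
        }


@dataclass
class SelectedSet:
    """The assembled set: ordered compound ids, per-kinase depth, audit log."""

    compounds: list[str]
    depth: dict[str, tuple[int, frozenset[str]]]  # kinase -> (n inhibitors, chemotypes)
    audit: list[GreedyStep]

    def depth_table(self) -> dict[str, tuple[int, int]]:
        """kinase -> (n inhibitors, n distinct chemotypes)."""
        return {k: (n, len(bins)) for k, (n, bins) in self.depth.items()}

    @property
    def covered_kinases(self) -> set[str]:
        return set(self.depth)


def filter_candidates(
    matrix: ActivityMatrix,
    kd: Sequence[KdRecord],
    config: SelectionConfig | None = None,
) -> list[Candidate]:
    """Run the inclusion decision for every compound; keep the passers.

    Each surviving candidate carries the kinases on which it holds a
    qualifying (sub-threshold) K_D — the set through which it can later earn
    coverage credit.
    """
    config = config or SelectionConfig()
    by_compound: dict[str, list[KdRecord]] = {}
    for rec in kd:
        by_compound.setdefault(rec.compound, []).append(rec)
    out: list[Candidate] = []
    for cid in matrix.compounds:
        res = compute_s10(matrix, cid, config.poc_cutoff)
        decision = decide_inclusion(
            res, by_compound.get(cid, []),
            kd_max_nM=config.kd_max_nM, s10_max=config.s10_max,
        )
        if decision.passed:
            out.append(
                Candidate(
                    compound=cid,
                    s10=res.s10,
                    qualifying_kinases=frozenset(decision.qualifying_kinases),
                    decision=decision,
                )
            )
    return out


def greedy_assemble(
    candidates: Sequence[Candidate],
    assignments: Sequence[BinAssignment] | Mapping[str, str],
    config: SelectionConfig | None = None,
) -> SelectedSet:
    """Assemble the set by iterated highest-marginal-gain selection.

    ``assignments`` maps each candidate to its chemotype bin (a sequence of
    :class:`~kinoset.chemotype.BinAssignment` or a plain mapping). Every
    candidate must have a bin; a missing assignment is an error.
    """
    config = config or SelectionConfig()
    if isinstance(assignments, Mapping):
        bin_of = dict(assignments)
    else:
        bin_of = {a.compound: a.bin for a in assignments}
    missing = [c.compound for c in candidates if c.compound not in bin_of]
    if missing:
        raise KinosetError(f"candidates without chemotype assignment: {missing}")

    remaining = sorted(candidates, key=lambda c: c.compound)
    selected: list[str] = []
    # kinase -> set of chemotype bins already providing coverage
    kinase_bins: dict[str, set[str]] = {}
    # kinase -> number of selected inhibitors covering it
    kinase_inhibitors: dict[str, int] = {}
    # chemotype bin -> exemplars already selected
    bin_exemplars: dict[str, int] = {}
    audit: list[GreedyStep] = []

    def gain(c: Candidate) -> float:
        b = bin_of[c.compound]
        g = 0.0
        for k in c.qualifying_kinases:
            bins = kinase_bins.get(k, set())
            if len(bins) < config.depth_target and b not in bins:
                g += config.weight(k)
        return g

    step = 0
    while remaining:
        scores = {c.compound: gain(c) for c in remaining}
        best_gain = max(scores.values())
        if best_gain <= 0:
            break
        tied = [c for c in remaining if scores[c.compound] == best_gain]
        tie_break = "gain"
        if len(tied) > 1:
            tie_break = "chemotype_exemplars"
            fewest = min(bin_exemplars.get(bin_of[c.compound], 0) for c in tied)
            tied = [c for c in tied
                    if bin_exemplars.get(bin_of[c.compound], 0) == fewest]
        if len(tied) > 1:
            tie_break = "s10"
            lowest = min(c.s10 for c in tied)
            tied = [c for c in tied if c.s10 == lowest]
        if len(tied) > 1:
            tie_break = "id"
            tied = [min(tied, key=lambda c: c.compound)]
        pick = tied[0]
        b = bin_of[pick.compound]
        selected.append(pick.compound)
        bin_exemplars[b] = bin_exemplars.get(b, 0) + 1
        for k in pick.qualifying_kinases:
            kinase_bins.setdefault(k, set()).add(b)
            kinase_inhibitors[k] = kinase_inhibitors.get(k, 0) + 1
        remaining = [c for c in remaining if c.compound != pick.compound]
        step += 1
        audit.append(
            GreedyStep(step=step, picked=pick.compound, gain=best_gain,
                       tie_break=tie_break, scores=scores)
        )

    depth = {
        k: (kinase_inhibitors[k], frozenset(kinase_bins[k])) for k in kinase_bins
    }
    return SelectedSet(compounds=selected, depth=depth, audit=audit)
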