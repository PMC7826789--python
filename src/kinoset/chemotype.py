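"""Priority-ordered SMARTS chemotype binning of kinase inhibitors.

ATP-competitive kinase inhibitors are classified by the scaffold that
hydrogen-bonds to the kinase hinge region. Each bin is a SMARTS substructure
pattern with a unique priority rank; a compound matching several bins is
assigned to the highest-priority (lowest rank number) match, and compounds
matching nothing fall into a designated "other" bin. Matching is substructure
containment with perceived aromaticity, ignoring stereochemistry — bins are
scaffolds, not whole molecules.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem

from .data_model import Compound, KinosetError

FALLBACK_NAME = "other"


@dataclass(frozen=True)
class ChemotypeBin:
    """A named hinge-binder substructure with a unique priority (lower = wins)."""

    name: str
    smarts: str
    priority: int
    is_fallback: bool = False

    def pattern(self) -> Chem.Mol:
        patt = Chem.MolFromSmarts(self.smarts)
        if patt is None:
            raise KinosetError(f"invalid SMARTS for bin {self.name!r}: {self.smarts!r}")
        return patt


@dataclass
class BinAssignment:
    """One compound's bin, with every matching bin retained for audit."""

    compound: str
    bin: str
    matched: list[str] = field(default_factory=list)


def _validate_catalog(bins: list[ChemotypeBin]) -> list[ChemotypeBin]:
    priorities = [b.priority for b in bins]
    dupes = [p for p, n in Counter(priorities).items() if n > 1]
    if dupes:
        names = [b.name for b in bins if b.priority in dupes]
        raise KinosetError(
            f"duplicate priorities {sorted(dupes)} among bins {names}; "
            "priorities must form a total order"
        )
    fallbacks = [b for b in bins if b.is_fallback]
    if len(fallbacks) != 1:
        raise KinosetError(f"catalog must have exactly one fallback bin, got {len(fallbacks)}")
    if fallbacks[0].priority != max(priorities):
        raise KinosetError("fallback bin must have the lowest priority (largest rank)")
    for b in bins:
        if not b.is_fallback:
            b.pattern()  # raises naming the bin if the SMARTS does not compile
    return sorted(bins, key=lambda b: b.priority)


def load_bin_catalog(path: str | Path) -> list[ChemotypeBin]:
    """Load a bin catalog TSV (columns name, smarts, priority[, is_fallback]).

    Bins come back sorted by priority. If no fallback bin is present an
    "other" bin is appended below the last priority. Invalid SMARTS and
    duplicate priorities are hard errors naming the offending bins.
    """
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "smarts": str})
    required = {"name", "smarts", "priority"}
    missing = required - set(df.columns)
    if missing:
        raise KinosetError(f"bin catalog missing columns: {sorted(missing)}")
    bins = [
        ChemotypeBin(
            name=row.name,
            smarts="" if pd.isna(row.smarts) else str(row.smarts),
            priority=int(row.priority),
            is_fallback=bool(int(getattr(row, "is_fallback", 0) or 0)),
        )
        for row in df.itertuples(index=False)
    ]
    if not any(b.is_fallback for b in bins):
        bins.append(
            ChemotypeBin(
                name=FALLBACK_NAME,
                smarts="",
                priority=max(b.priority for b in bins) + 1,
                is_fallback=True,
            )
        )
    return _validate_catalog(bins)


def default_catalog() -> list[ChemotypeBin]:
    """The demonstration catalog shipped with the package.

    A small curated set of classic hinge-binder scaffolds (indazoles,
    oxindoles, quinazolines, quinolines, pyrimidines, ...) standing in for a
    laboratory's full private catalog; real analyses supply their own TSV.
    """
    ref = resources.files("kinoset").joinpath("data/demo_bins.tsv")
    with resources.as_file(ref) as path:
        return load_bin_catalog(path)


def assign_chemotype(
    smiles: str, catalog: Sequence[ChemotypeBin], compound_id: str | None = None
) -> BinAssignment:
    """Assign one structure to its highest-priority matching bin.

    Deterministic in (structure, catalog): catalog order and compound order
    never matter because priorities are a total order. All matching bins are
    recorded in ``matched`` for audit.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise KinosetError(f"unparseable SMILES {smiles!r}")
    matchers = [b for b in catalog if not b.is_fallback]
    matched = [b for b in matchers if mol.HasSubstructMatch(b.pattern())]
    if matched:
        winner = min(matched, key=lambda b: b.priority)
        name = winner.name
    else:
        name = next(b.name for b in catalog if b.is_fallback)
    return BinAssignment(
        compound=compound_id or smiles,
        bin=name,
        matched=sorted((b.name for b in matched),
                       key=lambda n: next(b.priority for b in catalog if b.name == n)),
    )


def assign_all(
    compounds: Iterable[Compound], catalog: Sequence[ChemotypeBin]
) -> list[BinAssignment]:
    return [assign_chemotype(c.smiles, catalog, compound_id=c.id) for c in compounds]


@dataclass
class BinHistogram:
    """Occupancy summary: occupied bins split into singleton / 2–5 / ≥6 strata."""

    occupied: int
    n_singleton: int
    n_small: int  # 2–5 members
    n_large: int  # ≥6 members
    counts: dict[str, int] = field(default_factory=dict)


def bin_histogram(assignments: Sequence[BinAssignment]) -> BinHistogram:
    """Tally bin occupancy; strata counts always sum to the occupied-bin count."""
    counts = Counter(a.bin for a in assignments)
    sizes = list(counts.values())
    return BinHistogram(
        occupied=len(counts),
        n_singleton=sum(1 for s in sizes if s == 1),
        n_small=sum(1 for s in sizes if 2 <= s <= 5),
        n_large=sum(1 for s in sizes if s >= 6),
        counts=dict(counts),
    )
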