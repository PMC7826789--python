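"""Domain types and validated I/O for compounds, kinase panels, PoC matrices, and K_D tables.

The central container is :class:`ActivityMatrix`: a compounds x kinases table of
percent-of-control (PoC) values measured at a fixed screening concentration.
PoC is percent kinase activity remaining in a binding-displacement assay:
0 means complete inhibition, 100 means no effect, and values above 100
(apparent activation or assay noise) are legal. Missing cells are preserved
as missing — an unassayed kinase is never evidence of selectivity, so
downstream selectivity math excludes missing cells from both numerator and
denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

# silence rdkit's C++-side parse chatter; parse failures are raised as errors
RDLogger.DisableLog("rdApp.error")

#: The ten kinase subfamily labels used for panel annotation.
FAMILIES = frozenset(
    {"AGC", "Atypical", "CAMK", "CK1", "CMGC", "Lipid", "Other", "STE", "TK", "TKL"}
)


class KinosetError(ValueError):
    """Base class for validation and input errors raised by this package."""


@dataclass(frozen=True)
class Compound:
    """A screened inhibitor: unique id plus a parseable SMILES structure."""

    id: str
    smiles: str
    source: str = ""
    screen_panel: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise KinosetError("compound id must be non-empty")


@dataclass(frozen=True)
class KinaseAssay:
    """One kinase assay in a profiling panel, annotated with its subfamily."""

    kinase: str
    family: str
    is_wild_type: bool = True
    is_human: bool = True

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise KinosetError(
                f"unknown kinase family {self.family!r} for {self.kinase!r}; "
                f"expected one of {sorted(FAMILIES)}"
            )


@dataclass
class AssayPanel:
    """A named profiling panel (e.g. a 401-assay wild-type human panel).

    ``concentration`` is the screening concentration in micromolar at which
    PoC values referencing this panel were measured.
    """

    name: str
    assays: list[KinaseAssay]
    concentration: float = 1.0

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise KinosetError("screening concentration must be > 0 µM")
        if not self.assays:
            raise KinosetError("panel must contain at least one assay")
        symbols = [a.kinase for a in self.assays]
        dupes = {s for s in symbols if symbols.count(s) > 1}
        if dupes:
            raise KinosetError(f"duplicate kinase symbols in panel: {sorted(dupes)}")

    @property
    def kinases(self) -> list[str]:
        return [a.kinase for a in self.assays]

    @property
    def wild_type_human(self) -> set[str]:
        """Kinases that count toward selectivity denominators."""
        return {a.kinase for a in self.assays if a.is_wild_type and a.is_human}

    def family_of(self, kinase: str) -> str:
        for a in self.assays:
            if a.kinase == kinase:
                return a.family
        raise KinosetError(f"kinase {kinase!r} not in panel {self.name!r}")

    def __len__(self) -> int:
        return len(self.assays)


@dataclass
class ActivityMatrix:
    """Compounds x kinases PoC values bound to the panel they came from.

    ``values`` is a float DataFrame indexed by compound id with kinase gene
    symbols as columns; NaN marks a missing (unassayed) cell.
    """

    panel: AssayPanel
    values: pd.DataFrame

    def __post_init__(self) -> None:
        unknown = [c for c in self.values.columns if c not in set(self.panel.kinases)]
        if unknown:
            raise KinosetError(
                f"matrix columns not in panel {self.panel.name!r}: {unknown}"
            )
        vals = self.values.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] < 0):
            raise KinosetError("PoC values must be >= 0")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise KinosetError(f"duplicate compound ids in matrix: {dupes}")

    @property
    def compounds(self) -> list[str]:
        return list(self.values.index)

    @property
    def kinases(self) -> list[str]:
        return list(self.values.columns)

    def row(self, compound: str) -> pd.Series:
        if compound not in self.values.index:
            raise KinosetError(f"compound {compound!r} not in matrix")
        return self.values.loc[compound]

    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())


@dataclass(frozen=True)
class KdRecord:
    """A dissociation constant (nM) from a follow-up dose-response experiment."""

    compound: str
    kinase: str
    kd_nM: float

    def __post_init__(self) -> None:
        if not self.kd_nM > 0:
            raise KinosetError(
                f"K_D must be > 0 nM (got {self.kd_nM!r} for "
                f"{self.compound!r}/{self.kinase!r})"
            )


# ---------------------------------------------------------------------------
# compound I/O


def _parse_smiles(smiles: str, where: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise KinosetError(f"unparseable SMILES {smiles!r} at {where}")
    return mol


def read_compounds(path: str | Path, id_field: str = "ID") -> list[Compound]:
    """Read a compound list from a SMILES file (``SMILES<tab>id`` lines) or SDF.

    The format is chosen by extension (``.sdf`` → SDF, anything else →
    whitespace-separated SMILES lines). Every structure is parse-validated;
    duplicate ids and unparseable records are hard errors naming the
    offending line or record.
    """
    path = Path(path)
    compounds: list[Compound] = []
    seen: dict[str, int] = {}
    if path.suffix.lower() == ".sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                raise KinosetError(f"unparseable structure at SDF record {i + 1}")
            if not mol.HasProp(id_field):
                raise KinosetError(
                    f"SDF record {i + 1} lacks id property {id_field!r}"
                )
            cid = mol.GetProp(id_field)
            if cid in seen:
                raise KinosetError(
                    f"duplicate compound id {cid!r} at SDF records "
                    f"{seen[cid]} and {i + 1}"
                )
            seen[cid] = i + 1
            compounds.append(Compound(id=cid, smiles=Chem.MolToSmiles(mol)))
    else:
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 1)
                if len(parts) < 2:
                    raise KinosetError(
                        f"line {lineno}: expected 'SMILES<whitespace>id'"
                    )
                smiles, cid = parts[0], parts[1].strip()
                _parse_smiles(smiles, f"line {lineno}")
                if cid in seen:
                    raise KinosetError(
                        f"duplicate compound id {cid!r} at lines "
                        f"{seen[cid]} and {lineno}"
                    )
                seen[cid] = lineno
                compounds.append(Compound(id=cid, smiles=smiles))
    return compounds


def write_compounds(path: str | Path, compounds: Sequence[Compound]) -> None:
    """Write ``SMILES<tab>id`` lines (round-trips through :func:`read_compounds`)."""
    with open(path, "w", encoding="utf-8") as fh:
        for c in compounds:
            fh.write(f"{c.smiles}\t{c.id}\n")


# ---------------------------------------------------------------------------
# panel I/O


_TRUTHY = {"1", "true", "True", "TRUE", "yes"}


def read_panel(path: str | Path, name: str | None = None,
               concentration: float = 1.0) -> AssayPanel:
    """Read a panel TSV with columns kinase, family, is_wild_type, is_human."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"kinase", "family", "is_wild_type", "is_human"}
    missing = required - set(df.columns)
    if missing:
        raise KinosetError(f"panel file missing columns: {sorted(missing)}")
    assays = [
        KinaseAssay(
            kinase=row.kinase,
            family=row.family,
            is_wild_type=str(row.is_wild_type) in _TRUTHY,
            is_human=str(row.is_human) in _TRUTHY,
        )
        for row in df.itertuples()
    ]
    return AssayPanel(name=name or path.stem, assays=assays,
                      concentration=concentration)


def write_panel(path: str | Path, panel: AssayPanel) -> None:
    rows = [
        {
            "kinase": a.kinase,
            "family": a.family,
            "is_wild_type": int(a.is_wild_type),
            "is_human": int(a.is_human),
        }
        for a in panel.assays
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PoC matrix I/O


def read_poc_matrix(path: str | Path, panel: AssayPanel) -> ActivityMatrix:
    """Read a PoC CSV (first column ``compound_id``, one column per kinase).

    Empty cells are preserved as missing, never coerced to zero. Columns
    naming kinases absent from the panel, and negative PoC values, are
    hard errors.
    """
    df = pd.read_csv(path, dtype={0: str})
    if df.columns[0] != "compound_id":
        raise KinosetError(
            f"first column must be 'compound_id', got {df.columns[0]!r}"
        )
    df = df.set_index("compound_id")
    df.index.name = None
    unknown = [c for c in df.columns if c not in set(panel.kinases)]
    if unknown:
        raise KinosetError(f"unknown kinase columns not in panel: {unknown}")
    values = df.astype(float)
    matrix = ActivityMatrix(panel=panel, values=values)
    n_miss = matrix.n_missing()
    if n_miss:
        per_cmpd = values.isna().sum(axis=1)
        for cid, k in per_cmpd[per_cmpd > 0].items():
            logger.warning(
                "compound %s: %d missing PoC cell(s) excluded from "
                "selectivity denominators", cid, int(k)
            )
    return matrix


def write_poc_matrix(path: str | Path, matrix: ActivityMatrix) -> None:
    df = matrix.values.copy()
    df.index.name = "compound_id"
    # %g keeps integers unpadded so write→read round-trips exactly
    df.to_csv(path, float_format="%g", na_rep="")


# ---------------------------------------------------------------------------
# K_D table I/O


def read_kd_table(path: str | Path) -> list[KdRecord]:
    """Read a TSV with columns compound, kinase, kd_nM into typed records."""
    df = pd.read_csv(path, sep="\t", dtype={"compound": str, "kinase": str})
    required = {"compound", "kinase", "kd_nM"}
    missing = required - set(df.columns)
    if missing:
        raise KinosetError(f"K_D file missing columns: {sorted(missing)}")
    records: list[KdRecord] = []
    for i, row in enumerate(df.itertuples(), start=2):  # header is line 1
        try:
            kd = float(row.kd_nM)
        except (TypeError, ValueError):
            raise KinosetError(f"non-numeric kd_nM at row {i}: {row.kd_nM!r}")
        if not kd > 0:
            raise KinosetError(f"non-positive kd_nM at row {i}: {kd}")
        records.append(KdRecord(compound=row.compound, kinase=row.kinase, kd_nM=kd))
    return records


def write_kd_table(path: str | Path, records: Iterable[KdRecord]) -> None:
    rows = [
        {"compound": r.compound, "kinase": r.kinase, "kd_nM": r.kd_nM}
        for r in records
    ]
    pd.DataFrame(rows, columns=["compound", "kinase", "kd_nM"]).to_csv(
        path, sep="\t", index=False, float_format="%g"
    )
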