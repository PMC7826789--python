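"""384-well plate-map generation and compound-budget arithmetic."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .data_model import KinosetError

ROWS = "ABCDEFGHIJKLMNOP"
N_COLS = 24
N_WELLS = len(ROWS) * N_COLS  # 384


def assay_budget(
    stock_vol_uL: float, stock_mM: float, assay_uM: float, well_vol_uL: float
) -> int:
    """Whole assays supported by a stock aliquot at a given final concentration.

    Moles available over moles per well, floored — partial assays don't
    count. A 1 µL aliquot of 10 mM stock supports 100 assays at 1 µM in
    100 µL working volume, or 200 assays in 50 µL.
    """
    args = (stock_vol_uL, stock_mM, assay_uM, well_vol_uL)
    if any(a <= 0 for a in args):
        raise KinosetError(f"all budget arguments must be > 0, got {args}")
    available_nmol = stock_vol_uL * stock_mM  # µL * mmol/L = nmol
    per_well_nmol = assay_uM * well_vol_uL * 1e-3  # µmol/L * µL = pmol -> nmol
    # relative epsilon guards float representation at exact ratios
    ratio = available_nmol / per_well_nmol
    return int(math.floor(ratio + 1e-9 + ratio * 1e-12))


def well_name(index: int) -> str:
    """Row-major well label for a 0-based index (0 -> A1, 24 -> B1, ...)."""
    return f"{ROWS[index // N_COLS]}{index % N_COLS + 1}"


@dataclass
class PlateMap:
    """One 384-well plate: well coordinate -> label, with per-well volume/conc."""

    plate_id: str
    wells: dict[str, str]  # well -> compound id or control label
    volume_uL: dict[str, float] = field(default_factory=dict)
    conc_mM: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        valid = {well_name(i) for i in range(N_WELLS)}
        bad = [w for w in self.wells if w not in valid]
        if bad:
            raise KinosetError(f"invalid 384-well coordinates: {bad}")

    def to_frame(self) -> pd.DataFrame:
        order = sorted(self.wells, key=lambda w: (ROWS.index(w[0]), int(w[1:])))
        return pd.DataFrame(
            [
                {
                    "plate": self.plate_id,
                    "well": w,
                    "compound_id": self.wells[w],
                    "volume_uL": self.volume_uL.get(w, 0.0),
                    "conc_mM": self.conc_mM.get(w, 0.0),
                }
                for w in order
            ]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "PlateMap":
        df = pd.read_csv(path, dtype={"plate": str, "well": str, "compound_id": str})
        plates = df["plate"].unique()
        if len(plates) != 1:
            raise KinosetError(f"expected a single plate, found {list(plates)}")
        return cls(
            plate_id=plates[0],
            wells=dict(zip(df["well"], df["compound_id"])),
            volume_uL=dict(zip(df["well"], df["volume_uL"].astype(float))),
            conc_mM=dict(zip(df["well"], df["conc_mM"].astype(float))),
        )


def build_platemap(
    compounds: Sequence[str],
    controls: Sequence[str] = (),
    fill_order: str = "row-major",
    plate_id: str = "P1",
    volume_uL: float = 1.0,
    conc_mM: float = 10.0,
) -> PlateMap:
    """Lay out compounds (plus control wells) on one 384-well plate.

    Controls are placed first, down column 1 (A1, B1, ...). Compounds then
    fill the remaining wells in ``fill_order`` ("row-major" or
    "column-major"). The layout is a pure function of its inputs, so the
    same call always produces a byte-identical CSV. Overflow is an error
    stating how many plates the request actually needs.
    """
    if fill_order not in ("row-major", "column-major"):
        raise KinosetError(f"unknown fill_order {fill_order!r}")
    dupes = {c for c in compounds if list(compounds).count(c) > 1}
    if dupes:
        raise KinosetError(f"duplicate compound ids in plate request: {sorted(dupes)}")
    total = len(compounds) + len(controls)
    if total > N_WELLS:
        raise KinosetError(
            f"{total} wells requested exceed the 384-well format; "
            f"{math.ceil(total / N_WELLS)} plates required"
        )
    if len(controls) > len(ROWS):
        raise KinosetError(
            f"at most {len(ROWS)} control wells fit in column 1, got {len(controls)}"
        )

    wells: dict[str, str] = {}
    for i, label in enumerate(controls):
        wells[f"{ROWS[i]}1"] = label

    if fill_order == "row-major":
        coords = [well_name(i) for i in range(N_WELLS)]
    else:
        coords = [
            f"{ROWS[r]}{c + 1}" for c in range(N_COLS) for r in range(len(ROWS))
        ]
    free = [w for w in coords if w not in wells]
    for cid, w in zip(compounds, free):
        wells[w] = cid

    return PlateMap(
        plate_id=plate_id,
        wells=wells,
        volume_uL={w: volume_uL for w in wells},
        conc_mM={w: conc_mM for w in wells},
    )
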