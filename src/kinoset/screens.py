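"""Annotation of phenotypic screens run against a chemogenomic set.

Three readouts are covered:

* **Cell growth** — normalized growth-rate inhibition (GR) values, which
  correct endpoint cell counts for cell-line-specific division times:
  ``gr = 2**(log2(x/x0) / log2(x_ctrl/x0)) - 1`` where ``x0`` is the live
  count at treatment time, ``x`` the treated endpoint count and ``x_ctrl``
  the same-plate vehicle endpoint. ``gr = 1`` is vehicle-like growth, 0 is
  stasis, negative values indicate net cell loss. Compounds are classed as
  inactive, broadly growth-inhibitory, or cell-line-dependent.

* **Acute cytotoxicity** — healthy-cell fraction relative to vehicle at a
  high dose, tiered at 0.8 / 0.5 / 1/3 (the last matching a ">67% decrease"
  rule), plus a per-kinase aggregation over kinases covered by at least two
  distinct chemotypes with a one-sided test against vehicle replicates.

* **Autophagic flux** — GFP/RFP reporter ratio time series rescaled so the
  vehicle tracks 0% and a reference flux inducer 100%; a hit shows a >20%
  aberration sustained over at least five consecutive time points.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import KinosetError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# growth-rate (GR) metrics


@dataclass(frozen=True)
class GrowthRecord:
    """Endpoint live-cell counts for one compound on one cell line."""

    cell_line: str
    compound: str
    x0: float
    x: float
    x_ctrl: float

    def __post_init__(self) -> None:
        if min(self.x0, self.x, self.x_ctrl) <= 0:
            raise KinosetError(
                f"cell counts must be > 0 ({self.compound!r}/{self.cell_line!r})"
            )


@dataclass(frozen=True)
class GRResult:
    cell_line: str
    compound: str
    gr: float


def compute_gr(record: GrowthRecord) -> GRResult:
    """Normalized growth-rate inhibition for one well.

    Raises when the vehicle control did not grow (``x_ctrl == x0``): a
    non-growing line has no growth rate to normalize against and is
    excluded from analysis.
    """
    if record.x_ctrl == record.x0:
        raise KinosetError(
            f"cell line {record.cell_line!r} did not grow "
            f"(x_ctrl == x0 == {record.x0}); exclude it from GR analysis"
        )
    ratio = math.log2(record.x / record.x0) / math.log2(record.x_ctrl / record.x0)
    return GRResult(cell_line=record.cell_line, compound=record.compound,
                    gr=2.0 ** ratio - 1.0)


GROWTH_CLASSES = ("inactive", "broad", "line_dependent")


def classify_growth_response(
    gr_by_line: Mapping[str, float],
    inactive_band: float = 0.1,
    decrease: float = 0.3,
    broad_fraction: float = 0.75,
) -> str:
    """Classify a compound's growth effect across cell lines.

    * ``inactive`` — every line within ``inactive_band`` of vehicle
      (gr >= 1 - inactive_band);
    * ``broad`` — at least ``broad_fraction`` of lines show a decrease of
      ``decrease`` or more (gr <= 1 - decrease);
    * ``line_dependent`` — some line shows such a decrease, but not enough
      lines to qualify as broad.

    Compounds with mild effects that reach neither bound fall back to
    ``inactive``.
    """
    if not gr_by_line:
        raise KinosetError("classify_growth_response needs at least one line")
    if len(gr_by_line) < 2:
        raise KinosetError("growth classification needs >= 2 cell lines")
    grs = np.asarray(list(gr_by_line.values()), dtype=float)
    if np.all(grs >= 1.0 - inactive_band):
        return "inactive"
    hit = grs <= 1.0 - decrease
    if hit.mean() >= broad_fraction:
        return "broad"
    if hit.any():
        return "line_dependent"
    return "inactive"


# ---------------------------------------------------------------------------
# cytotoxicity tiers


@dataclass(frozen=True)
class ToxicityRecord:
    """Vehicle-normalized healthy-cell fraction plus apoptosis/necrosis percentages."""

    compound: str
    healthy_fraction: float
    pct_apoptotic: float = 0.0
    pct_necrotic: float = 0.0
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.healthy_fraction < 0:
            raise KinosetError("healthy_fraction must be >= 0")


TOX_TIERS = ("nontoxic", "reduced", "severe", "extreme")

#: Tier bounds on healthy fraction; inclusive on the healthier side.
_TOX_EXTREME = 1.0 / 3.0  # below this, cell count dropped by > 67%
_TOX_SEVERE = 0.5
_TOX_NONTOXIC = 0.8


def classify_toxicity(record: "ToxicityRecord | float") -> str:
    """Map a healthy-cell fraction to its (most severe applicable) tier.

    Tiers partition [0, inf): >= 0.8 nontoxic; [0.5, 0.8) reduced;
    [1/3, 0.5) severe; < 1/3 extreme (a > 67% decrease in cell count).
    Boundaries belong to the healthier tier.
    """
    hf = record.healthy_fraction if isinstance(record, ToxicityRecord) else float(record)
    if hf < 0:
        raise KinosetError("healthy_fraction must be >= 0")
    if hf < _TOX_EXTREME:
        return "extreme"
    if hf < _TOX_SEVERE:
        return "severe"
    if hf < _TOX_NONTOXIC:
        return "reduced"
    return "nontoxic"


def kinase_toxicity_aggregate(
    coverage: Mapping[str, Iterable[str]],
    chemotypes: Mapping[str, str],
    toxicity: Sequence[ToxicityRecord],
    vehicle: Sequence[float],
    min_chemotypes: int = 2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-kinase toxicity over kinases covered by >= ``min_chemotypes`` chemotypes.

    ``coverage`` maps compound -> kinases it covers; ``chemotypes`` maps
    compound -> chemotype bin; ``toxicity`` holds (replicate) healthy-fraction
    records per compound; ``vehicle`` is the vehicle replicate distribution.

    For each eligible kinase the healthy fractions of all its inhibitors'
    records are pooled, the mean reported, and a one-sided Welch t-test asks
    whether the inhibitors' values are lower than vehicle. P-values are
    Benjamini–Hochberg corrected across kinases; ``flagged`` marks q < alpha.
    Kinases below the chemotype-depth bar are excluded (logged, not an error).
    """
    vehicle = np.asarray(list(vehicle), dtype=float)
    if vehicle.size < 2:
        raise KinosetError("need >= 2 vehicle replicates for the toxicity test")
    by_compound: dict[str, list[float]] = {}
    for rec in toxicity:
        by_compound.setdefault(rec.compound, []).append(rec.healthy_fraction)

    kinase_compounds: dict[str, set[str]] = {}
    for cid, kinases in coverage.items():
        for k in kinases:
            kinase_compounds.setdefault(k, set()).add(cid)

    rows = []
    for kinase in sorted(kinase_compounds):
        cids = sorted(kinase_compounds[kinase])
        missing_tox = [c for c in cids if c not in by_compound]
        if missing_tox:
            raise KinosetError(
                f"no toxicity records for compounds {missing_tox} covering {kinase!r}"
            )
        bins = {chemotypes[c] for c in cids if c in chemotypes}
        if len(bins) < min_chemotypes:
            logger.info(
                "kinase %s excluded from toxicity aggregation: %d chemotype(s) < %d",
                kinase, len(bins), min_chemotypes,
            )
            continue
        values = np.asarray([v for c in cids for v in by_compound[c]], dtype=float)
        if values.size >= 2:
            pvalue = float(
                stats.ttest_ind(values, vehicle, equal_var=False,
                                alternative="less").pvalue
            )
        else:
            # single observation: fall back to its percentile under a normal
            # fit of the vehicle replicates
            mu, sd = vehicle.mean(), vehicle.std(ddof=1)
            pvalue = float(stats.norm.cdf(values[0], loc=mu, scale=sd))
        rows.append(
            {
                "kinase": kinase,
                "n_compounds": len(cids),
                "n_chemotypes": len(bins),
                "mean_healthy_fraction": float(values.mean()),
                "pvalue": pvalue,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["kinase", "n_compounds", "n_chemotypes",
                 "mean_healthy_fraction", "pvalue"],
    )
    if len(df):
        df["qvalue"] = stats.false_discovery_control(df["pvalue"].to_numpy())
        df["flagged"] = df["qvalue"] < alpha
    else:
        df["qvalue"] = pd.Series(dtype=float)
        df["flagged"] = pd.Series(dtype=bool)
    return df


# ---------------------------------------------------------------------------
# autophagic flux


@dataclass
class FluxSeries:
    """GFP/RFP reporter ratios over time with paired vehicle and inducer series.

    All three series share one strictly increasing time grid (hours) and are
    each pre-normalized to their own 0 h value.
    """

    compound: str
    times: np.ndarray
    ratio: np.ndarray
    vehicle: np.ndarray
    control: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        self.vehicle = np.asarray(self.vehicle, dtype=float)
        self.control = np.asarray(self.control, dtype=float)
        n = self.times.size
        if not (self.ratio.size == self.vehicle.size == self.control.size == n):
            raise KinosetError(
                f"flux series for {self.compound!r} have unequal lengths"
            )
        if n and np.any(np.diff(self.times) <= 0):
            raise KinosetError("flux time grid must be strictly increasing")


@dataclass
class AutophagyHit:
    """Hit call for one compound's percent-flux series."""

    compound: str
    is_hit: bool
    direction: str | None = None  # "induced" | "reduced"
    run: tuple[int, int] | None = None  # (start index, length)
    category: int | None = None


def autophagy_normalize(series: FluxSeries) -> np.ndarray:
    """Rescale a flux series to percent of the vehicle→inducer difference.

    ``pct(t) = 100 * (ratio(t) - vehicle(t)) / (control(t) - vehicle(t))``:
    vehicle-like behaviour maps to 0%, inducer-like to 100%. A time point at
    which the inducer and vehicle coincide leaves the scale undefined and is
    reported as an error naming the time.
    """
    denom = series.control - series.vehicle
    bad = np.nonzero(denom == 0)[0]
    if bad.size:
        raise KinosetError(
            f"degenerate flux normalization (control == vehicle) at "
            f"t = {series.times[bad[0]]} h for {series.compound!r}"
        )
    return 100.0 * (series.ratio - series.vehicle) / denom


def autophagy_hit_call(
    pct: np.ndarray,
    threshold: float = 20.0,
    min_run: int = 5,
    compound: str = "",
) -> AutophagyHit:
    """Call a flux hit: |pct| strictly above ``threshold`` for >= ``min_run``
    consecutive time points.

    The first maximal qualifying run is reported as (start index, run
    length); direction is taken from the sign of the mean percent flux over
    that run (positive = induced).
    """
    pct = np.asarray(pct, dtype=float)
    if pct.size < min_run:
        raise KinosetError(
            f"series of length {pct.size} shorter than min_run = {min_run}"
        )
    above = np.abs(pct) > threshold
    # scan maximal runs of consecutive above-threshold points
    i = 0
    n = pct.size
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        if j - i >= min_run:
            run_mean = float(pct[i:j].mean())
            return AutophagyHit(
                compound=compound,
                is_hit=True,
                direction="induced" if run_mean > 0 else "reduced",
                run=(i, j - i),
            )
        i = j
    return AutophagyHit(compound=compound, is_hit=False)


PROLIFERATION_STATES = ("reduced", "unchanged", "increased")
APPEARANCE_STATES = ("normal", "abnormal")


def autophagy_categorize(
    hit: AutophagyHit,
    proliferation_change: str,
    appearance_flag: str = "normal",
) -> int:
    """Place a flux hit into one of six categories.

    The default scheme crosses flux direction with a three-way phenotype
    severity axis:

    ========  =======================================  ========
    category  phenotype                                direction
    ========  =======================================  ========
    1         proliferation unchanged/up, cells normal  induced
    2         proliferation unchanged/up, abnormal      induced
    3         proliferation reduced                     induced
    4         proliferation unchanged/up, cells normal  reduced
    5         proliferation unchanged/up, abnormal      reduced
    6         proliferation reduced                     reduced
    ========  =======================================  ========

    This is a documented surrogate grid — six mutually exclusive, jointly
    exhaustive cells over (direction, proliferation, appearance).
    """
    if not hit.is_hit:
        raise KinosetError("cannot categorize a non-hit")
    if proliferation_change not in PROLIFERATION_STATES:
        raise KinosetError(
            f"proliferation_change must be one of {PROLIFERATION_STATES}"
        )
    if appearance_flag not in APPEARANCE_STATES:
        raise KinosetError(f"appearance_flag must be one of {APPEARANCE_STATES}")
    if proliferation_change == "reduced":
        cell = 2
    elif appearance_flag == "abnormal":
        cell = 1
    else:
        cell = 0
    category = 1 + cell + (3 if hit.direction == "reduced" else 0)
    hit.category = category
    return category


# ---------------------------------------------------------------------------
# screen file I/O


def read_growth_csv(path: str | Path) -> list[GrowthRecord]:
    """Read a growth CSV with columns line, compound, x0, x, x_ctrl."""
    df = pd.read_csv(path, dtype={"line": str, "compound": str})
    required = {"line", "compound", "x0", "x", "x_ctrl"}
    missing = required - set(df.columns)
    if missing:
        raise KinosetError(f"growth file missing columns: {sorted(missing)}")
    return [
        GrowthRecord(cell_line=r.line, compound=r.compound,
                     x0=float(r.x0), x=float(r.x), x_ctrl=float(r.x_ctrl))
        for r in df.itertuples()
    ]


def read_toxicity_csv(path: str | Path) -> list[ToxicityRecord]:
    """Read a toxicity CSV: compound, healthy_fraction[, pct_apoptotic, pct_necrotic, replicate]."""
    df = pd.read_csv(path, dtype={"compound": str})
    if not {"compound", "healthy_fraction"} <= set(df.columns):
        raise KinosetError("toxicity file needs columns compound, healthy_fraction")
    return [
        ToxicityRecord(
            compound=r.compound,
            healthy_fraction=float(r.healthy_fraction),
            pct_apoptotic=float(getattr(r, "pct_apoptotic", 0.0) or 0.0),
            pct_necrotic=float(getattr(r, "pct_necrotic", 0.0) or 0.0),
            replicate=int(getattr(r, "replicate", 1) or 1),
        )
        for r in df.itertuples()
    ]


def read_flux_csv(path: str | Path) -> dict[str, FluxSeries]:
    """Read a long-format flux CSV: compound, time_h, gfp_rfp_ratio, role.

    ``role`` is ``compound``, ``vehicle`` or ``positive_control``; the vehicle
    and positive-control series are shared across compounds and must sit on
    the same time grid as every compound series.
    """
    df = pd.read_csv(path, dtype={"compound": str, "role": str})
    required = {"compound", "time_h", "gfp_rfp_ratio", "role"}
    missing = required - set(df.columns)
    if missing:
        raise KinosetError(f"flux file missing columns: {sorted(missing)}")

    def series_for(sub: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        sub = sub.sort_values("time_h")
        return sub["time_h"].to_numpy(float), sub["gfp_rfp_ratio"].to_numpy(float)

    veh = df[df["role"] == "vehicle"]
    ctl = df[df["role"] == "positive_control"]
    if veh.empty or ctl.empty:
        raise KinosetError("flux file needs vehicle and positive_control series")
    t_veh, r_veh = series_for(veh)
    t_ctl, r_ctl = series_for(ctl)
    if not np.array_equal(t_veh, t_ctl):
        raise KinosetError("vehicle and positive-control time grids differ")

    out: dict[str, FluxSeries] = {}
    for cid, sub in df[df["role"] == "compound"].groupby("compound"):
        t, r = series_for(sub)
        if not np.array_equal(t, t_veh):
            raise KinosetError(f"time grid for {cid!r} differs from controls")
        out[cid] = FluxSeries(compound=cid, times=t, ratio=r,
                              vehicle=r_veh, control=r_ctl)
    return out
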