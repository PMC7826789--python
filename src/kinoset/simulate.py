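"""Seeded synthetic-data generators for every input the toolkit consumes.

Each generator embeds its ground truth so the full pipeline is testable
without any external data:

* :func:`gen_profiles` emulates single-concentration kinome profiling
  (PoC at 1 µM over a wild-type human panel) with a mixture of selective,
  promiscuous and inactive compounds, plus follow-up K_D records for
  sub-cutoff kinases of triage-passing compounds;
* :func:`toy_molecules` is a fixed list of structures spanning classic
  hinge-binder scaffolds with their expected chemotype bin under the
  shipped demonstration catalog;
* :func:`gen_growth_screen` emulates a multi-cell-line growth screen with
  planted broad and line-selective effects;
* :func:`gen_flux_screen` emulates an autophagic-flux reporter time course
  with planted above-threshold runs.

Noise models are deliberately simple: truncated-normal PoC noise,
log-normal count noise, clipped normal noise on percent flux. Truncation
bounds keep planted labels valid at any noise scale, and at zero noise
every label is recovered exactly by the corresponding pipeline operation.
The same spec and seed always yield byte-identical files.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (
    ActivityMatrix,
    AssayPanel,
    Compound,
    FAMILIES,
    KdRecord,
    KinaseAssay,
    KinosetError,
)
from .screens import FluxSeries, GrowthRecord


@dataclass
class FixtureSpec:
    """Parameters for all generators; defaults mirror the emulated study.

    The profiling scenario defaults to a 401-kinase wild-type human panel
    screened at 1 µM, selective compounds with 1–8 sub-cutoff kinases
    (S10 <= 0.02, inside the 0.025 inclusion bound), promiscuous compounds
    hitting 10–30% of the panel, and follow-up K_D values in a clearly
    passing 5–80 nM range. The growth scenario defaults to 17 cell lines.
    """

    seed: int = 0
    # --- profiling matrix ---
    n_compounds: int = 60
    n_kinases: int = 401
    concentration_uM: float = 1.0
    fraction_selective: float = 0.5
    fraction_promiscuous: float = 0.2
    fraction_inactive: float = 0.3
    selective_active_range: tuple[int, int] = (1, 8)
    promiscuous_active_fraction: tuple[float, float] = (0.10, 0.30)
    kd_pass_range_nM: tuple[float, float] = (5.0, 80.0)
    kd_fail_range_nM: tuple[float, float] = (150.0, 900.0)
    kd_fail_fraction: float = 0.0  # selective compounds given only weak K_Ds
    poc_noise_sd: float = 2.0
    triage_s10_max: float = 0.04
    followup_cutoff: float = 10.0
    # --- growth screen ---
    n_cell_lines: int = 17
    x0_cells: float = 1000.0
    doublings_range: tuple[float, float] = (1.5, 3.0)
    growth_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    broad_gr: float = 0.5
    dependent_gr: float = 0.2
    dependent_lines_range: tuple[int, int] = (1, 4)
    growth_noise_sd: float = 0.05  # log-normal sigma on counts
    # --- flux screen ---
    flux_n_points: int = 48
    flux_dt_h: float = 2.0
    flux_fractions: tuple[float, float, float] = (0.5, 0.3, 0.2)  # null/hit/near
    flux_hit_amplitude: float = 30.0
    flux_hit_run_range: tuple[int, int] = (5, 8)
    flux_near_run: int = 4
    flux_threshold: float = 20.0
    flux_noise_sd: float = 1.5

    def __post_init__(self) -> None:
        for name, weights in (
            ("profile", (self.fraction_selective, self.fraction_promiscuous,
                         self.fraction_inactive)),
            ("growth", self.growth_fractions),
            ("flux", self.flux_fractions),
        ):
            if any(w < 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
                raise KinosetError(
                    f"{name} mixture weights must be >= 0 and sum to 1, got {weights}"
                )
        lo, hi = self.selective_active_range
        if hi > self.n_kinases:
            raise KinosetError(
                f"active-set size {hi} exceeds panel size {self.n_kinases}"
            )
        if not 1 <= lo <= hi:
            raise KinosetError("selective_active_range must satisfy 1 <= lo <= hi")
        if self.flux_hit_run_range[0] + 2 > self.flux_n_points:
            raise KinosetError("flux run length exceeds series length")


def _rng(spec: FixtureSpec, stream: int) -> np.random.Generator:
    # independent deterministic streams per generator
    return np.random.default_rng(np.random.SeedSequence([spec.seed, stream]))


def make_panel(spec: FixtureSpec) -> AssayPanel:
    """A synthetic wild-type human panel with families assigned round-robin."""
    fams = sorted(FAMILIES)
    assays = [
        KinaseAssay(kinase=f"KIN{i + 1:03d}", family=fams[i % len(fams)])
        for i in range(spec.n_kinases)
    ]
    return AssayPanel(name=f"synthetic-{spec.n_kinases}",
                      assays=assays, concentration=spec.concentration_uM)


PROFILE_CATEGORIES = ("selective", "promiscuous", "inactive")


def gen_profiles(
    spec: FixtureSpec,
) -> tuple[ActivityMatrix, list[KdRecord], pd.DataFrame]:
    """Generate a PoC matrix, follow-up K_D records, and the ground truth.

    Active cells are drawn in [0, 9.9] and inactive cells in [15, inf)
    (truncated-normal noise around their planted means), so the planted
    active set stays exactly recoverable at the 10 PoC cutoff regardless of
    the noise scale. K_D records are emitted only for sub-cutoff kinases of
    compounds whose planted S10 passes the initial triage bound, mirroring
    the follow-up workflow. The truth table's ``expected_pass`` column is
    computed arithmetically from the planted parameters, not by running the
    selectivity pipeline.
    """
    rng = _rng(spec, 1)
    panel = make_panel(spec)
    kinases = np.array(panel.kinases)
    n = spec.n_kinases

    cats = rng.choice(
        PROFILE_CATEGORIES,
        size=spec.n_compounds,
        p=(spec.fraction_selective, spec.fraction_promiscuous,
           spec.fraction_inactive),
    )
    values = np.empty((spec.n_compounds, n))
    truth_rows = []
    kd_records: list[KdRecord] = []
    for i in range(spec.n_compounds):
        cid = f"CMPD{i + 1:04d}"
        cat = str(cats[i])
        if cat == "selective":
            lo, hi = spec.selective_active_range
            k_act = int(rng.integers(lo, hi + 1))
        elif cat == "promiscuous":
            f = rng.uniform(*spec.promiscuous_active_fraction)
            k_act = max(1, int(round(f * n)))
        else:
            k_act = 0
        active_idx = rng.choice(n, size=k_act, replace=False) if k_act else np.array([], int)

        base = rng.uniform(40.0, 110.0, size=n)
        base[active_idx] = rng.uniform(0.5, 8.0, size=k_act)
        noisy = base + rng.normal(0.0, spec.poc_noise_sd, size=n)
        row = np.clip(noisy, 15.0, None)  # inactive cells stay clear of the cutoff
        if k_act:
            row[active_idx] = np.clip(noisy[active_idx], 0.0, 9.9)
        values[i] = row

        s10_true = k_act / n
        kd_fail = bool(cat == "selective" and rng.random() < spec.kd_fail_fraction)
        has_kd = k_act > 0 and s10_true < spec.triage_s10_max
        if has_kd:
            kd_range = spec.kd_fail_range_nM if kd_fail else spec.kd_pass_range_nM
            followup = active_idx[row[active_idx] < spec.followup_cutoff]
            for j in followup:
                kd_records.append(
                    KdRecord(
                        compound=cid,
                        kinase=str(kinases[j]),
                        kd_nM=float(np.round(rng.uniform(*kd_range), 2)),
                    )
                )
        expected_pass = bool(has_kd and not kd_fail and s10_true < 0.025)
        truth_rows.append(
            {
                "compound": cid,
                "category": cat,
                "n_active": k_act,
                "s10_true": s10_true,
                "active_kinases": ";".join(sorted(kinases[active_idx])),
                "kd_fail": kd_fail,
                "expected_pass": expected_pass,
            }
        )

    matrix = ActivityMatrix(
        panel=panel,
        values=pd.DataFrame(
            np.round(values, 3),
            index=[r["compound"] for r in truth_rows],
            columns=[str(k) for k in kinases],
        ),
    )
    return matrix, kd_records, pd.DataFrame(truth_rows)


#: Fixed toy structures spanning classic hinge-binder scaffolds, with the
#: chemotype bin each is expected to land in under the shipped demonstration
#: catalog (cross-validated against an independent substructure engine).
TOY_MOLECULES: tuple[tuple[str, str, str], ...] = (
    ("TOY-ANILINOQUINAZOLINE", "COc1ccc2ncnc(Nc3ccccc3)c2c1", "4-anilino-quinazoline"),
    ("TOY-ERLOTINIB", "COCCOc1cc2ncnc(Nc3cccc(C#C)c3)c2cc1OCCOC", "4-anilino-quinazoline"),
    ("TOY-OXINDOLE", "O=C1Cc2ccccc2N1", "oxindole"),
    ("TOY-SUNITINIB", "CCN(CC)CCNC(=O)c1c(C)[nH]c(/C=C2\\C(=O)Nc3ccc(F)cc32)c1C", "oxindole"),
    ("TOY-INDAZOLE", "Cc1ccc2[nH]ncc2c1", "indazole"),
    ("TOY-AZAINDOLE", "c1cnc2[nH]ccc2c1", "7-azaindole"),
    ("TOY-BENZIMIDAZOLE", "c1ccc2[nH]cnc2c1", "benzimidazole"),
    ("TOY-INDOLE", "Cc1ccc2[nH]ccc2c1", "indole"),
    ("TOY-QUINAZOLINE", "Cc1ccc2ncncc2c1", "quinazoline"),
    ("TOY-QUINOLINE", "Cc1ccc2ncccc2c1", "quinoline"),
    ("TOY-ISOQUINOLINE", "c1ccc2cnccc2c1", "isoquinoline"),
    ("TOY-AMINOPYRIMIDINE", "Nc1nccc(-c2ccccc2)n1", "aminopyrimidine"),
    ("TOY-PYRIMIDINE", "c1cncnc1", "pyrimidine"),
    ("TOY-PYRAZOLE", "Cc1cc[nH]n1", "pyrazole"),
    ("TOY-DECOY-ALKANE", "CCCCCC", "other"),
)


def toy_molecules() -> list[tuple[Compound, str]]:
    """Deterministic toy compounds with their expected chemotype bin."""
    return [
        (Compound(id=cid, smiles=smi, source="synthetic"), bin_name)
        for cid, smi, bin_name in TOY_MOLECULES
    ]


GROWTH_CLASSES = ("inactive", "broad", "line_dependent")


def gen_growth_screen(
    spec: FixtureSpec,
) -> tuple[list[GrowthRecord], pd.DataFrame]:
    """Generate endpoint growth records with planted response classes.

    Vehicle wells grow by a per-line doubling count; planted effects set the
    treated count so the normalized growth rate hits the class target
    exactly before noise (broad: the target decrease on every line;
    line-dependent: on a small random subset of lines). Counts then get
    log-normal noise; at ``growth_noise_sd = 0`` classification recovers
    every planted label.
    """
    rng = _rng(spec, 2)
    lines = [f"LINE{i + 1:02d}" for i in range(spec.n_cell_lines)]
    doublings = rng.uniform(*spec.doublings_range, size=spec.n_cell_lines)
    x_ctrl = spec.x0_cells * 2.0 ** doublings

    cats = rng.choice(GROWTH_CLASSES, size=spec.n_compounds,
                      p=spec.growth_fractions)
    records: list[GrowthRecord] = []
    truth_rows = []
    for i in range(spec.n_compounds):
        cid = f"CMPD{i + 1:04d}"
        cat = str(cats[i])
        gr_target = np.ones(spec.n_cell_lines)
        dep_lines: list[str] = []
        if cat == "broad":
            gr_target[:] = spec.broad_gr
        elif cat == "line_dependent":
            lo, hi = spec.dependent_lines_range
            n_dep = int(rng.integers(lo, hi + 1))
            idx = rng.choice(spec.n_cell_lines, size=n_dep, replace=False)
            gr_target[idx] = spec.dependent_gr
            dep_lines = sorted(lines[j] for j in idx)
        # invert the GR definition to get the treated endpoint count
        x = spec.x0_cells * 2.0 ** (
            np.log2(1.0 + gr_target) * np.log2(x_ctrl / spec.x0_cells)
        )
        if spec.growth_noise_sd > 0:
            x = x * rng.lognormal(0.0, spec.growth_noise_sd, size=spec.n_cell_lines)
        for j, line in enumerate(lines):
            records.append(
                GrowthRecord(
                    cell_line=line, compound=cid,
                    x0=spec.x0_cells,
                    x=float(np.round(x[j], 3)),
                    x_ctrl=float(np.round(x_ctrl[j], 3)),
                )
            )
        truth_rows.append(
            {"compound": cid, "class": cat,
             "dependent_lines": ";".join(dep_lines)}
        )
    return records, pd.DataFrame(truth_rows)


FLUX_CLASSES = ("null", "hit", "near")


def gen_flux_screen(
    spec: FixtureSpec,
) -> tuple[dict[str, FluxSeries], pd.DataFrame]:
    """Generate flux reporter series with planted above-threshold runs.

    The shared vehicle series drifts slowly near its starting ratio while
    the positive control (a flux inducer) drops sharply and stays low. Each
    compound is null (baseline), a hit (a run of >= 5 points with percent
    flux beyond the threshold), or a near-miss (a 4-point run). Baseline
    noise is clipped to half the threshold and run noise keeps the planted
    excursion strictly beyond it, so labels are exact at any noise scale.
    The grid starts after time zero: both controls are ratio-normalized to
    their 0 h values, where the percent-flux scale is undefined.
    """
    rng = _rng(spec, 3)
    t = spec.flux_dt_h * np.arange(1, spec.flux_n_points + 1)
    vehicle = 1.0 - 0.0005 * t
    control = 0.3 + 0.7 * np.exp(-t / 3.0)

    cats = rng.choice(FLUX_CLASSES, size=spec.n_compounds, p=spec.flux_fractions)
    out: dict[str, FluxSeries] = {}
    truth_rows = []
    amp = spec.flux_hit_amplitude
    thr = spec.flux_threshold
    if amp <= thr:
        raise KinosetError("flux_hit_amplitude must exceed flux_threshold")
    base_clip = thr / 2.0
    run_clip = (amp - thr) / 2.0
    for i in range(spec.n_compounds):
        cid = f"FLUX{i + 1:04d}"
        cat = str(cats[i])
        pct = np.clip(
            rng.normal(0.0, spec.flux_noise_sd, size=spec.flux_n_points),
            -base_clip, base_clip,
        )
        start, length, direction = -1, 0, ""
        if cat in ("hit", "near"):
            if cat == "hit":
                lo, hi = spec.flux_hit_run_range
                length = int(rng.integers(lo, hi + 1))
            else:
                length = spec.flux_near_run
            start = int(rng.integers(0, spec.flux_n_points - length + 1))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            run = sign * amp + np.clip(
                rng.normal(0.0, spec.flux_noise_sd, size=length),
                -run_clip, run_clip,
            )
            pct[start:start + length] = run
            direction = "induced" if sign > 0 else "reduced"
        ratio = vehicle + pct / 100.0 * (control - vehicle)
        out[cid] = FluxSeries(
            compound=cid, times=t, ratio=np.round(ratio, 6),
            vehicle=vehicle, control=control,
        )
        truth_rows.append(
            {
                "compound": cid,
                "class": cat,
                "is_hit": cat == "hit",
                "direction": direction if cat == "hit" else "",
                "start": start if cat == "hit" else -1,
                "length": length if cat == "hit" else 0,
            }
        )
    return out, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# file emission (generators write the same formats the readers consume)


def write_profiles(outdir: str | Path, spec: FixtureSpec) -> dict[str, Path]:
    from .data_model import write_kd_table, write_panel, write_poc_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, kd, truth = gen_profiles(spec)
    paths = {
        "panel": outdir / "panel.tsv",
        "poc": outdir / "poc.csv",
        "kd": outdir / "kd.tsv",
        "truth": outdir / "profiles_truth.tsv",
    }
    write_panel(paths["panel"], matrix.panel)
    write_poc_matrix(paths["poc"], matrix)
    write_kd_table(paths["kd"], kd)
    truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%g")
    return paths


def write_growth(outdir: str | Path, spec: FixtureSpec) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, truth = gen_growth_screen(spec)
    paths = {"growth": outdir / "growth.csv", "truth": outdir / "growth_truth.tsv"}
    pd.DataFrame(
        [
            {"line": r.cell_line, "compound": r.compound,
             "x0": r.x0, "x": r.x, "x_ctrl": r.x_ctrl}
            for r in records
        ]
    ).to_csv(paths["growth"], index=False, float_format="%g")
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def write_flux(outdir: str | Path, spec: FixtureSpec) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    series, truth = gen_flux_screen(spec)
    rows = []
    first = next(iter(series.values()))
    for role, arr in (("vehicle", first.vehicle), ("positive_control", first.control)):
        for t, r in zip(first.times, arr):
            rows.append({"compound": role.upper(), "time_h": t,
                         "gfp_rfp_ratio": r, "role": role})
    for cid, s in series.items():
        for t, r in zip(s.times, s.ratio):
            rows.append({"compound": cid, "time_h": t,
                         "gfp_rfp_ratio": r, "role": "compound"})
    paths = {"flux": outdir / "flux.csv", "truth": outdir / "flux_truth.tsv"}
    pd.DataFrame(rows).to_csv(paths["flux"], index=False, float_format="%.6g")
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
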