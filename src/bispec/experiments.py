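"""Figure-level model predictions as scripted pipelines.

Each ``run_*`` function regenerates one model prediction of the study —
binding curves per cell type, the variant panel, the incubation-time
effect, the steady-state species composition, and the dissociation time
courses — and returns an :class:`ExperimentReport` carrying the curves,
the headline numbers, and a dictionary of named scientific checks
(orderings, regime structure) evaluated on the freshly computed results.

Experimental MFI points are not shipped: the original flow-cytometry
values exist only as digitized figures elsewhere.  A user-supplied CSV can
be overlaid for visual comparison via :func:`overlay_and_report`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ode
from .mc import MCBoxConfig, MCResult, run as mc_run
from .params import (
    AssayConfig,
    CellSurfaceModel,
    KineticConstants,
    ParameterError,
    load_parameter_fixture,
)
from .rates import cuboid_height_for_concentration
from .units import N_A

logger = logging.getLogger(__name__)

VARIANT_ORDER = ("parent", "VkY92A", "VkY91A", "VkR95A",
                 "VkR95A+VhD97A", "VkR94A+VhY99A")


@dataclass
class ExperimentReport:
    """Curves + named checks + headline values for one experiment."""

    name: str
    curves: dict
    checks: dict[str, bool] = field(default_factory=dict)
    values: dict[str, float] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(self.checks.values())

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for key, curve in self.curves.items():
            safe = str(key).replace("/", "_").replace("+", "_")
            curve.to_frame().to_csv(outdir / f"{self.name}_{safe}.csv", index=False)
        with open(outdir / f"{self.name}_summary.json", "w") as fh:
            json.dump({"checks": self.checks, "values": self.values}, fh,
                      indent=2, default=float)


def _fixture(fixture):
    return fixture if fixture is not None else load_parameter_fixture()


def _default_conc_grid(n: int = 9) -> np.ndarray:
    return np.geomspace(1e-11, 1e-7, n)


def _mc_vs_ode_check(variants, cells, assay, variant_name: str,
                     cell_type: str, A: float, t_end: float,
                     mc_cfg: MCBoxConfig, mc_result: MCResult | None = None,
                     ) -> tuple[bool, dict]:
    """Ensemble-mean bound species vs the finite-bath ODE at the same
    bath geometry and horizon, within 3 standard errors (plus one count
    of discretization allowance for near-zero species)."""
    k = variants[variant_name]
    cell = cells[cell_type]
    res = mc_result if mc_result is not None else mc_run(
        cell, k, A, t_end, mc_cfg)
    n_rep = res.counts.shape[0]
    # whole-cell-equivalent bath volume: patch volume scaled by area ratio
    vol_dm3 = (mc_cfg.patch_area_um2
               * cuboid_height_for_concentration(mc_cfg.n_antibody, A,
                                                 mc_cfg.patch_area_um2)
               * cell.surface_area_um2 / mc_cfg.patch_area_um2) * 1e-15
    tc = ode.simulate_binding(k, cell, A, t_end, constant_antibody=False,
                              solution_volume_dm3_per_cell=vol_dm3)
    to_patch = cell.surface_area_dm2 * N_A * (
        mc_cfg.patch_area_um2 / cell.surface_area_um2)
    expected = np.array([tc.AT1[-1], tc.AT2[-1], tc.AT1T2[-1]]) * to_patch
    observed = res.mean[-1, 3:6]
    se = res.std[-1, 3:6] / np.sqrt(n_rep)
    ok = bool(np.all(np.abs(observed - expected) <= 3.0 * se + 1.0))
    detail = {"expected_AT1_AT2_C": expected.tolist(),
              "observed": observed.tolist(), "se": se.tolist()}
    return ok, detail


def run_fig2(
    fixture=None,
    concentrations_M=None,
    engine: str = "ode",
    mc_cfg: MCBoxConfig | None = None,
    mc_spot_conc_M: float = 1e-8,
    mc_t_end_s: float = 300.0,
    mc_result: MCResult | None = None,
    outdir=None,
) -> ExperimentReport:
    """Parent-antibody binding curves on the three cell types (1 h, washed).

    Checks the cell-type ordering dual-positive >= CD4-only >= CD70-only at
    every grid point; with ``engine="both"`` additionally runs a particle-
    simulation spot check against the finite-bath ODE at one concentration.
    """
    variants, cells, assay = _fixture(fixture)
    conc = np.asarray(concentrations_M if concentrations_M is not None
                      else _default_conc_grid(), dtype=float)
    if conc.size == 0:
        raise ParameterError("concentration grid is empty")
    parent = variants["parent"]

    curves = {}
    for cell_type in ("dual_positive", "cd4_only", "cd70_only"):
        curves[cell_type] = ode.binding_curve(
            parent, cells[cell_type], assay, apply_wash=True,
            concentrations_M=conc)

    tol = 1e-9
    dual = curves["dual_positive"].bound_total
    cd4 = curves["cd4_only"].bound_total
    cd70 = curves["cd70_only"].bound_total
    checks = {
        "dual_ge_cd4": bool(np.all(dual >= cd4 * (1 - tol))),
        "cd4_ge_cd70": bool(np.all(cd4 >= cd70 * (1 - tol))),
        "total_monotone_in_conc": bool(
            all(np.all(np.diff(c.bound_total) >= -tol * c.bound_total.max())
                for c in curves.values())),
    }
    values = {}
    if engine in ("mc", "both"):
        cfg = mc_cfg or MCBoxConfig(dt_s=5e-5, record_every_s=30.0)
        ok, detail = _mc_vs_ode_check(
            variants, cells, assay, "parent", "dual_positive",
            mc_spot_conc_M, mc_t_end_s, cfg, mc_result=mc_result)
        checks["mc_matches_ode_spot"] = ok
        values.update({f"mc_spot_{k}": v for k, v in detail.items()})

    report = ExperimentReport("fig2", curves, checks, values)
    if outdir:
        report.write(outdir)
    return report


def run_fig3(
    fixture=None,
    concentrations_M=None,
    outdir=None,
) -> ExperimentReport:
    """Variant panel on all three cell types (1 h, washed).

    Checks that dual-positive binding at 1 nM varies by less than 2x
    across the six variants while the attenuated variants collapse toward
    zero on single-positive cells after the 240 s wash.
    """
    variants, cells, assay = _fixture(fixture)
    conc = np.asarray(concentrations_M if concentrations_M is not None
                      else _default_conc_grid(), dtype=float)

    curves = {}
    for vname in VARIANT_ORDER:
        for cell_type in ("dual_positive", "cd4_only", "cd70_only"):
            curves[(vname, cell_type)] = ode.binding_curve(
                variants[vname], cells[cell_type], assay, apply_wash=True,
                concentrations_M=conc)

    at_1nM = {v: np.interp(1e-9, conc, curves[(v, "dual_positive")].bound_total)
              for v in VARIANT_ORDER}
    spread = max(at_1nM.values()) / min(at_1nM.values())

    # wash collapse on CD4-only cells: weakest variant retains a tiny
    # fraction of the parent's washed signal
    top = max(np.max(curves[("parent", "cd4_only")].bound_total), 1e-300)
    weak = np.max(curves[("VkR94A+VhY99A", "cd4_only")].bound_total)
    collapse_ratio = weak / top

    # removing the wash restores the monovalent isotherm level
    unwashed = ode.binding_curve(
        variants["VkR94A+VhY99A"], cells["cd4_only"], assay,
        apply_wash=False, concentrations_M=conc)
    kd1 = variants["VkR94A+VhY99A"].Kd1
    langmuir = cells["cd4_only"].n_T1_per_cell * conc / (conc + kd1)
    # compare at concentrations that equilibrate well within the hour
    sel = conc >= 1e-9
    rel = np.abs(unwashed.bound_total[sel] - langmuir[sel]) / langmuir[sel]

    checks = {
        "dual_1nM_spread_below_2x": bool(spread < 2.0),
        "single_positive_wash_collapse": bool(collapse_ratio < 0.05),
        "no_wash_restores_langmuir": bool(np.max(rel) < 0.05),
    }
    values = {"dual_1nM_spread": float(spread),
              "cd4_only_weak_over_parent": float(collapse_ratio)}
    report = ExperimentReport("fig3", curves, checks, values)
    if outdir:
        report.write(outdir)
    return report


def run_fig4(
    fixture=None,
    concentrations_M=None,
    times_h=(1.0, 10.0, 100.0, 1000.0, 10000.0),
    outdir=None,
) -> ExperimentReport:
    """Effect of incubation time on parent binding to dual-positive cells.

    Bound antibody increases pointwise with incubation time, has converged
    between 10^3 h and 10^4 h, is time-insensitive at 100 nM within the
    first hour, and the 10^4 h curve matches the algebraic steady state.
    """
    variants, cells, assay = _fixture(fixture)
    conc = np.asarray(concentrations_M if concentrations_M is not None
                      else _default_conc_grid(), dtype=float)
    parent = variants["parent"]
    cell = cells["dual_positive"]

    curves = {}
    for th in times_h:
        curves[th] = ode.binding_curve(
            parent, cell, assay, apply_wash=False,
            concentrations_M=conc, t_end=th * 3600.0)

    times_sorted = sorted(times_h)
    tol = 1e-6
    monotone = all(
        np.all(curves[t2].bound_total >= curves[t1].bound_total
               * (1 - tol) - tol)
        for t1, t2 in zip(times_sorted, times_sorted[1:]))

    eq = ode.equilibrium_composition_curve(parent, cell, conc)
    longest = curves[times_sorted[-1]]
    second = curves[times_sorted[-2]]
    with np.errstate(divide="ignore", invalid="ignore"):
        conv = np.nanmax(np.abs(longest.bound_total - second.bound_total)
                         / np.maximum(longest.bound_total, 1e-300))
        eq_err = np.nanmax(np.abs(longest.bound_total - eq.bound_total)
                           / np.maximum(eq.bound_total, 1e-300))

    lowest = conc.min()
    gain_low = (np.interp(lowest, conc, curves[times_sorted[1]].bound_total)
                / max(np.interp(lowest, conc, curves[times_sorted[0]].bound_total), 1e-300))
    b1h_100nM = np.interp(1e-7, conc, curves[times_sorted[0]].bound_total)
    beq_100nM = np.interp(1e-7, conc, eq.bound_total)

    checks = {
        "binding_monotone_in_time": bool(monotone),
        "long_time_curves_converged": bool(conv < 0.01),
        "longest_matches_steady_state": bool(eq_err < 0.01),
        "low_conc_gains_with_time": bool(gain_low > 1.5),
        "100nM_equilibrated_within_1h": bool(
            abs(b1h_100nM - beq_100nM) / beq_100nM < 0.02),
    }
    values = {"low_conc_10h_over_1h": float(gain_low),
              "longest_vs_steady_state_rel_err": float(eq_err)}
    report = ExperimentReport("fig4", curves, checks, values)
    if outdir:
        report.write(outdir)
    return report


def run_fig5(
    fixture=None,
    concentrations_M=None,
    variants_used=("parent", "VkR95A", "VkR94A+VhY99A"),
    outdir=None,
) -> ExperimentReport:
    """Steady-state species composition over an extended concentration range.

    On dual-positive cells the ternary complex dominates below ~50 nM and
    binary complexes accumulate at its expense at >= 1 uM; single-positive
    cells follow plain monovalent mass action.
    """
    variants, cells, assay = _fixture(fixture)
    conc = np.asarray(concentrations_M if concentrations_M is not None
                      else np.geomspace(1e-14, 1e-5, 19), dtype=float)

    curves = {}
    for vname in variants_used:
        for cell_type in ("dual_positive", "cd4_only", "cd70_only"):
            curves[(vname, cell_type)] = ode.equilibrium_composition_curve(
                variants[vname], cells[cell_type], conc)

    parent_dual = curves[("parent", "dual_positive")]
    at_10nM = {
        "ternary": np.interp(1e-8, conc, parent_dual.bound_AT1T2),
        "monovalent": np.interp(1e-8, conc,
                                parent_dual.bound_AT1 + parent_dual.bound_AT2),
    }
    # ternary share of its own maximum falls at high concentration
    c_max = parent_dual.bound_AT1T2.max()
    ternary_1uM = np.interp(1e-6, conc, parent_dual.bound_AT1T2)
    mono_1uM = np.interp(1e-6, conc,
                         parent_dual.bound_AT1 + parent_dual.bound_AT2)

    kd2 = variants["parent"].Kd2
    cd70 = curves[("parent", "cd70_only")]
    langmuir = cells["cd70_only"].n_T2_per_cell * conc / (conc + kd2)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.nanmax(np.abs(cd70.bound_total - langmuir)
                        / np.maximum(langmuir, 1e-300))

    checks = {
        "ternary_dominates_at_10nM": bool(
            at_10nM["ternary"] > 10.0 * at_10nM["monovalent"]),
        "binary_accumulates_at_1uM": bool(
            mono_1uM > at_10nM["monovalent"] and ternary_1uM < c_max),
        "cd70_only_is_langmuir": bool(rel < 1e-3),
    }
    values = {"parent_dual_10nM_ternary_over_monovalent":
              float(at_10nM["ternary"] / max(at_10nM["monovalent"], 1e-300)),
              "ternary_1uM_over_max": float(ternary_1uM / c_max)}
    report = ExperimentReport("fig5", curves, checks, values)
    if outdir:
        report.write(outdir)
    return report


def run_fig6(
    fixture=None,
    t_end_h: float = 2e4,
    n_out: int = 600,
    outdir=None,
) -> ExperimentReport:
    """Dissociation of each variant from stoichiometrically cross-linked
    targets on dual-positive cells, with the half-life table.

    Starts from AT1T2 = min(T1_tot, T2_tot) with the remaining CD70 free
    and no antibody in solution.  Checks that half-lives order inversely
    with the monovalent CD4 off-rate and that the decay decelerates
    (non-first-order kinetics).
    """
    variants, cells, assay = _fixture(fixture)
    cell = cells["dual_positive"]
    T1 = cell.total_surface_conc("T1")
    T2 = cell.total_surface_conc("T2")
    init = ode.SurfaceState(0.0, 0.0, min(T1, T2), T1, T2, 0.0)

    curves = {}
    half_lives = {}
    for vname in VARIANT_ORDER:
        tc = ode.simulate_dissociation(variants[vname], cell, init,
                                       t_end_h * 3600.0, n_out=n_out)
        curves[vname] = tc
        hl = ode.half_life(tc)
        half_lives[vname] = hl / 3600.0 if hl is not None else float("inf")

    koffs = [variants[v].k_neg1 for v in VARIANT_ORDER]
    hls = [half_lives[v] for v in VARIANT_ORDER]
    ordering = all(
        (hls[i] > hls[j]) == (koffs[i] < koffs[j])
        for i in range(len(hls)) for j in range(len(hls))
        if koffs[i] != koffs[j])

    # deceleration: instantaneous log-slope at 80% remaining vs at 30%
    tc = curves["VkR94A+VhY99A"]
    frac = tc.total_bound / tc.total_bound[0]

    def inst_rate(level):
        i = int(np.argmin(np.abs(frac - level)))
        i = min(max(i, 1), frac.size - 2)
        return -(np.log(frac[i + 1]) - np.log(frac[i - 1])) / (
            tc.times[i + 1] - tc.times[i - 1])

    rate_early = inst_rate(0.8)
    rate_late = inst_rate(0.3)

    checks = {
        "half_life_orders_inversely_with_koff1": bool(ordering),
        "decay_decelerates": bool(rate_early > rate_late),
        "weakest_half_life_exceeds_40h": bool(
            half_lives["VkR94A+VhY99A"] > 40.0),
    }
    values = {f"half_life_h/{v}": half_lives[v] for v in VARIANT_ORDER}
    values["instantaneous_rate_at_80pct"] = float(rate_early)
    values["instantaneous_rate_at_30pct"] = float(rate_late)
    report = ExperimentReport("fig6", curves, checks, values)
    if outdir:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for vname, tc in curves.items():
            safe = vname.replace("/", "_").replace("+", "_")
            tc.to_frame().to_csv(outdir / f"fig6_{safe}.csv", index=False)
        with open(outdir / "fig6_summary.json", "w") as fh:
            json.dump({"checks": checks, "values": values}, fh, indent=2)
    return report


def run_avidity(fixture=None, outdir=None) -> ExperimentReport:
    """Effective bivalent potency on dual-positive cells, per variant."""
    variants, cells, assay = _fixture(fixture)
    cell = cells["dual_positive"]
    values = {}
    for vname in VARIANT_ORDER:
        kd_eff, enh = ode.effective_avidity(variants[vname], cell)
        values[f"kd_eff_M/{vname}"] = kd_eff
        values[f"enhancement_log10/{vname}"] = enh
    checks = {
        "parent_enhancement_about_4_logs": bool(
            abs(values["enhancement_log10/parent"] - 4.0) <= 0.5),
    }
    report = ExperimentReport("avidity", {}, checks, values)
    if outdir:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "avidity_summary.json", "w") as fh:
            json.dump({"checks": checks, "values": values}, fh, indent=2)
    return report


def overlay_and_report(
    report: ExperimentReport,
    overlay: pd.DataFrame | None,
    outdir: str | Path,
) -> pd.DataFrame:
    """Merge model curves with user-supplied experimental points.

    ``overlay`` columns: concentration_M, mfi, cell_type, variant.  Points
    whose (variant, cell_type) keys match no model curve are reported with
    a warning, never an error; the comparison is visual, no goodness-of-fit
    statistic is computed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for key, curve in report.curves.items():
        vname, cell_type = key if isinstance(key, tuple) else ("parent", key)
        df = curve.to_frame()
        df["variant"] = vname
        df["cell_type"] = cell_type
        df["source"] = "model"
        rows.append(df)
    merged = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()

    if overlay is not None and len(overlay):
        if np.any(np.asarray(overlay["concentration_M"], dtype=float) <= 0):
            raise ParameterError("overlay concentrations must be > 0")
        valid = {(r["variant"], r["cell_type"]) for _, r in merged.iterrows()} \
            if len(merged) else set()
        keep = []
        for _, row in overlay.iterrows():
            key = (row.get("variant", "parent"), row["cell_type"])
            if valid and key not in valid:
                logger.warning(
                    "overlay point with unmatched key %s; valid keys: %s",
                    key, sorted({k[1] for k in valid}))
                continue
            keep.append({
                "x_value": float(row["concentration_M"]),
                "x_kind": "concentration_M",
                "total_mfi": float(row["mfi"]),
                "variant": row.get("variant", "parent"),
                "cell_type": row["cell_type"],
                "source": "experiment",
            })
        if keep:
            merged = pd.concat([merged, pd.DataFrame(keep)], ignore_index=True)

    merged.to_csv(outdir / f"{report.name}_overlay.csv", index=False)
    return merged


RUNNERS = {
    "fig2": run_fig2,
    "fig3": run_fig3,
    "fig4": run_fig4,
    "fig5": run_fig5,
    "fig6": run_fig6,
    "avidity": run_avidity,
}
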