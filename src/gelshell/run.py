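"""End-to-end simulation driver: config in, CSV + VTU series out."""

from __future__ import annotations

import json
import logging
import os
import time

import numpy as np

from . import config as cfgmod
from .constitutive import HydrogelMaterial, OgdenMaterial
from .generators import GENERATORS
from .mesh import read_mesh
from .phasefield import PhaseFieldParams
from .shell import BendingConfig, RegionMaterial, ThicknessRule
from .solver import (
    DrivenBC,
    FixedBC,
    LoadSchedule,
    SimRecord,
    SimResult,
    Simulation,
    SolverOptions,
)
from .vtu import VtuSeries

log = logging.getLogger("gelshell")


def build_mesh(mesh_cfg: dict):
    if "file" in mesh_cfg:
        return read_mesh(mesh_cfg["file"], mesh_cfg.get("format"))
    gen = GENERATORS[mesh_cfg["generator"]]
    return gen(**mesh_cfg.get("params", {}))


def build_materials(blocks: list) -> dict:
    out = {}
    for blk in blocks:
        if blk["type"] == "hydrogel":
            mat = HydrogelMaterial(
                mu=float(blk["mu"]),
                chi=float(blk["chi"]),
                k_res=float(blk.get("k_res", 1e-4)),
            )
        else:
            mat = OgdenMaterial(
                mu_og=float(blk["mu_og"]),
                k_og=float(blk["k_og"]),
                alpha=float(blk["alpha"]),
            )
        out[blk["region"]] = RegionMaterial(mat, blk.get("phase_field"))
    return out


def build_simulation(cfg: dict, mesh=None) -> Simulation:
    """Assemble a :class:`Simulation` from a resolved config."""
    if mesh is None:
        mesh = build_mesh(cfg["mesh"])
    materials = build_materials(cfg["materials"])
    pf_cfg = cfg["phase_field"]
    pf = PhaseFieldParams(
        ell=float(pf_cfg["ell"]),
        gc=float(pf_cfg["gc"]),
        k_res=float(pf_cfg.get("k_res", 1e-4)),
    )
    sch = cfg["schedule"]
    schedule = LoadSchedule(
        driven=DrivenBC(
            node_set=sch["driven"]["set"],
            direction=sch["driven"]["direction"],
            magnitudes=list(sch["driven"]["magnitudes"]),
        ),
        fixed=[
            FixedBC(node_set=f["set"], components=tuple(f["components"]))
            for f in sch.get("fixed", [])
        ],
    )
    sv = cfg["solver"]
    options = SolverOptions(
        tol_p=float(sv["tol_p"]),
        tol_e=float(sv["tol_e"]),
        max_stagger=int(sv["max_stagger"]),
        gtol=float(sv["gtol"]),
        max_lbfgs=int(sv["max_lbfgs"]),
        abort_on_stagger=bool(sv["abort_on_stagger"]),
    )
    bend = cfg["bending"]
    return Simulation(
        mesh=mesh,
        materials=materials,
        pf_params=pf,
        schedule=schedule,
        rule=ThicknessRule(int(cfg["thickness_rule"]["n_gauss"])),
        bending=BendingConfig(bool(bend["enabled"]), float(bend["stiffness"])),
        options=options,
        clamp_phase=bool(pf_cfg.get("clamp", True)),
        clamp_negative_weights=bool(pf_cfg.get("clamp_negative_weights", False)),
    )


def run_simulation(cfg: dict, outdir=None, mesh=None) -> SimResult:
    """Execute the full load schedule described by ``cfg``.

    Writes the per-step CSV record, the resolved config, and (optionally) a
    VTU time series to the output directory.  Deterministic for a fixed
    config.  ``outdir=None`` disables all file output (in-memory run).
    """
    cfg = cfgmod.resolve_config(cfg)
    sim = build_simulation(cfg, mesh=mesh)
    out_cfg = cfg["output"]
    series = None
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        cfgmod.save_config(cfg, os.path.join(outdir, "config.yaml"))
        if out_cfg["write_vtu"]:
            series = VtuSeries(outdir, out_cfg["basename"])

    record = SimRecord()
    state = sim.initial_state()
    p_history = [state.p.copy()]
    stop = cfg["stop_when"]
    stopped_early = False
    peak_force = 0.0
    region_id = _region_ids(sim.mesh)

    try:
        for magnitude in sim.schedule.driven.magnitudes:
            t0 = time.perf_counter()
            state = sim.step_with_bisection(state, float(magnitude))
            res = sim.record_step(state, record)
            p_history.append(state.p.copy())
            if series is not None and state.step % out_cfg["vtu_every"] == 0:
                _write_vtu_step(series, sim, state, res, region_id)
            force = float(
                np.linalg.norm([record.rows[-1][c] for c in ("Rx", "Ry", "Rz")])
            )
            peak_force = max(peak_force, force)
            log.info(
                "step %d  u=%.5g  |R|=%.5g  p_min=%.4f  iters=%d  (%.2fs)",
                state.step, magnitude, force, state.p.min(), state.n_iters,
                time.perf_counter() - t0,
            )
            if stop["p_min_below"] is not None and state.p.min() < stop["p_min_below"]:
                stopped_early = True
                log.info("early stop: p_min below %.3g", stop["p_min_below"])
                break
            if (
                stop["force_drop_frac"] is not None
                and peak_force > 0
                and force < (1.0 - stop["force_drop_frac"]) * peak_force
            ):
                stopped_early = True
                log.info("early stop: force dropped %.0f%% from peak",
                         100 * stop["force_drop_frac"])
                break
    except Exception as exc:
        if outdir is not None:
            record.to_csv(os.path.join(outdir, "record.csv"))
            with open(os.path.join(outdir, "error_manifest.json"), "w") as fh:
                json.dump(
                    {"error": str(exc), "type": type(exc).__name__,
                     "completed_steps": len(record.rows)},
                    fh, indent=2,
                )
        raise

    if outdir is not None:
        record.to_csv(os.path.join(outdir, "record.csv"))
    return SimResult(
        record=record,
        final_state=state,
        p_history=p_history,
        simulation=sim,
        stopped_early=stopped_early,
    )


def _region_ids(mesh):
    labels = sorted(set(mesh.element_region))
    lut = {r: i for i, r in enumerate(labels)}
    return np.array([lut[r] for r in mesh.element_region], dtype=float)


def _write_vtu_step(series, sim, state, res, region_id):
    displacement = state.positions - sim.ref_positions
    eff = sim.model.effective_stress(state.positions, state.p)
    series.write_step(
        type("M", (), {"vertices": state.positions,
                       "triangles": sim.mesh.triangles})(),
        step=state.step,
        time=state.load,
        point_fields={"p": state.p, "displacement": displacement},
        cell_fields={
            "effective_stress": eff,
            "W_plus": res.elem_w_plus,
            "region": region_id,
        },
    )
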