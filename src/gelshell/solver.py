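"""Quasi-static load stepping with the staggered displacement/damage scheme.

Each load step prescribes displacements on the driven node set, then
alternates (a) energy minimization over the free nodal coordinates at fixed
damage and (b) a history update followed by the linear phase-field solve at
fixed displacements, until both fields stop changing.  The converged step
is appended to a record of reaction forces and energy bookkeeping.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .errors import StepError
from .graph import critical_edge_length
from .mesh import TriMesh
from .phasefield import PhaseFieldParams, PhaseFieldProblem, update_history
from .shell import BendingConfig, MembraneModel, ThicknessRule

log = logging.getLogger("gelshell")

_COMPONENT_NAMES = {"x": 0, "y": 1, "z": 2, 0: 0, 1: 1, 2: 2}


@dataclass
class FixedBC:
    node_set: str
    components: tuple = (0, 1, 2)


@dataclass
class DrivenBC:
    """Prescribed displacement u = magnitude * direction on a node set.

    ``direction`` is a 3-vector, or the string "radial_xy" for per-node
    outward unit vectors in the xy-plane.
    """

    node_set: str
    direction: object
    magnitudes: list = field(default_factory=list)

    def direction_field(self, ref_positions: np.ndarray) -> np.ndarray:
        if isinstance(self.direction, str):
            if self.direction == "radial_xy":
                d = ref_positions[:, :2].copy()
                norms = np.linalg.norm(d, axis=1)
                d /= np.maximum(norms, 1e-12)[:, None]
                out = np.zeros_like(ref_positions)
                out[:, :2] = d
                return out
            raise ValueError(f"unknown direction mode {self.direction!r}")
        v = np.asarray(self.direction, dtype=np.float64)
        return np.broadcast_to(v, ref_positions.shape)


@dataclass
class LoadSchedule:
    driven: DrivenBC
    fixed: list = field(default_factory=list)

    def validate(self, mesh: TriMesh):
        names = [self.driven.node_set] + [f.node_set for f in self.fixed]
        for name in names:
            if name not in mesh.node_sets:
                raise ValueError(f"unknown node set {name!r}")
        mags = self.driven.magnitudes
        if len(mags) == 0:
            raise ValueError("schedule has no load magnitudes")


@dataclass
class SimState:
    positions: np.ndarray
    p: np.ndarray
    H: np.ndarray
    step: int = 0
    load: float = 0.0
    converged: bool = True
    n_iters: int = 0


_CSV_COLUMNS = [
    "step",
    "load_factor",
    "u_imposed",
    "Rx",
    "Ry",
    "Rz",
    "E_total",
    "E_plus",
    "E_minus",
    "p_min",
    "n_stag_iters",
]


@dataclass
class SimRecord:
    rows: list = field(default_factory=list)

    def append(self, **kwargs):
        row = {k: kwargs[k] for k in _CSV_COLUMNS}
        if not all(np.isfinite(v) for v in row.values()):
            raise StepError(f"non-finite record entry at step {row['step']}")
        self.rows.append(row)

    def column(self, name) -> np.ndarray:
        return np.array([r[name] for r in self.rows])

    def to_csv(self, path):
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=_CSV_COLUMNS)
            w.writeheader()
            for row in self.rows:
                w.writerow({k: repr(v) for k, v in row.items()})


@dataclass
class SolverOptions:
    tol_p: float = 1e-4
    tol_e: float = 1e-8
    max_stagger: int = 50
    gtol: float = 1e-6
    max_lbfgs: int = 3000
    abort_on_stagger: bool = False


class Simulation:
    """Owns the model, phase problem, schedule and the stepping logic."""

    def __init__(
        self,
        mesh: TriMesh,
        materials: dict,
        pf_params: PhaseFieldParams,
        schedule: LoadSchedule,
        rule: ThicknessRule = ThicknessRule(3),
        bending: BendingConfig | None = None,
        options: SolverOptions | None = None,
        clamp_phase: bool = True,
        clamp_negative_weights: bool = False,
    ):
        schedule.validate(mesh)
        self.mesh = mesh
        self.schedule = schedule
        self.options = options or SolverOptions()
        self.model = MembraneModel(mesh, materials, rule, bending)
        self.pf = PhaseFieldProblem(
            mesh,
            pf_params,
            element_mask=self.model.phase_mask,
            clamp=clamp_phase,
            clamp_negative_weights=clamp_negative_weights,
        )
        self.ref_positions = mesh.vertices.copy()
        self._setup_dofs()
        h = critical_edge_length(mesh, self.model.phase_mask)
        self.h_over_ell = h / pf_params.ell if pf_params.ell > 0 else np.inf
        if self.h_over_ell > 1.0:
            log.warning(
                "mesh resolution h_ele/ell = %.3f > 1: the diffuse crack "
                "width is under-resolved",
                self.h_over_ell,
            )
        else:
            log.info("mesh resolution h_ele/ell = %.3f", self.h_over_ell)

    def _setup_dofs(self):
        n = self.mesh.n_vertices
        self.prescribed = np.zeros((n, 3), dtype=bool)
        driven_idx = self.mesh.node_sets[self.schedule.driven.node_set]
        self.prescribed[driven_idx, :] = True
        for fbc in self.schedule.fixed:
            idx = self.mesh.node_sets[fbc.node_set]
            for c in fbc.components:
                self.prescribed[idx, _COMPONENT_NAMES[c]] = True
        self.free_idx = np.flatnonzero(~self.prescribed.ravel())
        self.driven_idx = driven_idx
        self.driven_dirs = self.schedule.driven.direction_field(
            self.ref_positions[driven_idx]
        )

    # -- building blocks ----------------------------------------------

    def initial_state(self) -> SimState:
        return SimState(
            positions=self.ref_positions.copy(),
            p=np.ones(self.mesh.n_vertices),
            H=np.zeros(self.mesh.n_triangles),
        )

    def _target_positions(self, positions, magnitude):
        out = positions.copy()
        fixed_mask = self.prescribed.copy()
        fixed_mask[self.driven_idx, :] = False
        # non-driven fixed dofs stay at their reference values
        out_flat = out.ravel()
        ref_flat = self.ref_positions.ravel()
        idx = np.flatnonzero(fixed_mask.ravel())
        out_flat[idx] = ref_flat[idx]
        out[self.driven_idx] = (
            self.ref_positions[self.driven_idx] + magnitude * self.driven_dirs
        )
        return out

    def _solve_displacement(self, positions, p):
        opts = self.options
        x_full = positions.copy()
        flat = x_full.ravel()
        x0 = flat[self.free_idx].copy()

        def fun(x):
            flat[self.free_idx] = x
            res = self.model.evaluate(x_full, p, compute_forces=True)
            return res.energy, res.forces.ravel()[self.free_idx].copy()

        r = minimize(
            fun,
            x0,
            jac=True,
            method="L-BFGS-B",
            options={
                "maxiter": opts.max_lbfgs,
                "maxfun": 10 * opts.max_lbfgs,
                "ftol": 1e-16,
                "gtol": opts.gtol,
                "maxcor": 20,
            },
        )
        gmax = float(np.max(np.abs(r.jac))) if r.jac is not None else np.inf
        if not np.all(np.isfinite(r.x)) or (not r.success and gmax > 100 * opts.gtol):
            raise StepError(
                f"displacement solve failed ({r.message}); "
                "consider a smaller load increment"
            )
        flat[self.free_idx] = r.x
        return x_full

    def staggered_step(self, state: SimState, magnitude: float) -> SimState:
        """One converged load step at the given imposed magnitude."""
        opts = self.options
        positions = self._target_positions(state.positions, magnitude)
        p = state.p.copy()
        H = state.H.copy()
        e_prev = None
        n_iters = 0
        converged = False
        for it in range(1, opts.max_stagger + 1):
            n_iters = it
            positions = self._solve_displacement(positions, p)
            res = self.model.evaluate(positions, p, compute_forces=False)
            H = update_history(H, res.elem_w_plus)
            p_new = self.pf.solve(H)
            dp = float(np.max(np.abs(p_new - p)))
            p = p_new
            de_ok = True
            if e_prev is not None:
                de_ok = abs(res.energy - e_prev) <= opts.tol_e * max(
                    abs(res.energy), 1e-30
                )
            e_prev = res.energy
            if dp < opts.tol_p and de_ok:
                converged = True
                break
        if not converged:
            msg = (
                f"staggered loop hit max_stagger={opts.max_stagger} "
                f"at magnitude {magnitude:.6g}"
            )
            if opts.abort_on_stagger:
                raise StepError(msg)
            log.warning(msg)
        return SimState(
            positions=positions,
            p=p,
            H=H,
            step=state.step + 1,
            load=magnitude,
            converged=converged,
            n_iters=n_iters,
        )

    def step_with_bisection(
        self, state: SimState, magnitude: float, depth: int = 3
    ) -> SimState:
        """Retry a failed step through an intermediate half-increment."""
        try:
            return self.staggered_step(state, magnitude)
        except StepError:
            if depth <= 0:
                raise
            mid = 0.5 * (state.load + magnitude)
            log.info("bisecting load step to %.6g", mid)
            state = self.step_with_bisection(state, mid, depth - 1)
            return self.step_with_bisection(state, magnitude, depth - 1)

    def reaction_force(self, state: SimState, node_set: str) -> np.ndarray:
        """Force exerted by the structure on the constraint (3-vector)."""
        if node_set not in self.mesh.node_sets:
            raise ValueError(f"unknown node set {node_set!r}")
        res = self.model.evaluate(state.positions, state.p, compute_forces=True)
        idx = self.mesh.node_sets[node_set]
        return -res.forces[idx].sum(axis=0)

    def record_step(self, state: SimState, record: SimRecord):
        res = self.model.evaluate(state.positions, state.p, compute_forces=True)
        R = -res.forces[self.driven_idx].sum(axis=0)
        record.append(
            step=state.step,
            load_factor=state.load,
            u_imposed=state.load,
            Rx=float(R[0]),
            Ry=float(R[1]),
            Rz=float(R[2]),
            E_total=res.energy,
            E_plus=res.e_plus,
            E_minus=res.e_minus,
            p_min=float(state.p.min()),
            n_stag_iters=state.n_iters,
        )
        return res


@dataclass
class SimResult:
    record: SimRecord
    final_state: SimState
    p_history: list
    simulation: Simulation
    stopped_early: bool = False
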