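"""YAML configuration schema, validation, defaults, and bundled demos.

Validation is fail-loud: unknown keys are errors, and all schema problems
are reported at once through :class:`~gelshell.errors.ConfigError`.  All
quantities are nondimensional.
"""

from __future__ import annotations

import copy

import yaml

from .errors import ConfigError

SCHEMA_VERSION = 1

_GENERATOR_PARAMS = {
    "notched_plate": {"length", "width", "notch_length", "target_h", "growth",
                      "thickness"},
    "perforated_sphere_patch": {"R", "r_hole", "n_holes", "symmetry",
                                "target_h", "hole_colatitude", "thickness"},
    "fiber_strip": {"length", "width", "thickness", "n_fibers",
                    "n_crosslinks", "target_h"},
    "cap_with_patch": {"R_major", "R_minor", "patch_angle", "target_h",
                       "cap_angle", "thickness"},
    "icosphere": {"radius", "subdivisions"},
}

_DEFAULTS = {
    "seed": 0,
    "thickness_rule": {"n_gauss": 3},
    "bending": {"enabled": False, "stiffness": 0.0},
    "solver": {
        "tol_p": 1e-4,
        "tol_e": 1e-8,
        "max_stagger": 50,
        "gtol": 1e-6,
        "max_lbfgs": 3000,
        "abort_on_stagger": False,
    },
    "stop_when": {"p_min_below": None, "force_drop_frac": None},
    "output": {"dir": "out", "write_vtu": True, "vtu_every": 1,
               "basename": "step"},
}

_TOP_KEYS = {
    "schema_version", "seed", "mesh", "materials", "phase_field",
    "thickness_rule", "bending", "schedule", "solver", "stop_when", "output",
}


def _is_num(x):
    return isinstance(x, (int, float)) and not isinstance(x, bool)


def _check_keys(section, allowed, path, errors):
    if not isinstance(section, dict):
        errors.append(f"{path}: expected a mapping")
        return False
    for k in section:
        if k not in allowed:
            errors.append(f"{path}: unknown key {k!r}")
    return True


def validate_config(cfg) -> list:
    """Return the full list of schema error messages (empty when valid)."""
    errors: list[str] = []
    if not isinstance(cfg, dict):
        return ["config root must be a mapping"]
    for k in cfg:
        if k not in _TOP_KEYS:
            errors.append(f"unknown top-level key {k!r}")
    if cfg.get("schema_version") != SCHEMA_VERSION:
        errors.append(f"schema_version must be {SCHEMA_VERSION}")

    # mesh -------------------------------------------------------------
    mesh = cfg.get("mesh")
    if mesh is None:
        errors.append("missing required section 'mesh'")
    elif _check_keys(mesh, {"generator", "params", "file", "format"},
                     "mesh", errors):
        has_gen, has_file = "generator" in mesh, "file" in mesh
        if has_gen == has_file:
            errors.append("mesh: give exactly one of 'generator' or 'file'")
        if has_gen:
            gen = mesh["generator"]
            if gen not in _GENERATOR_PARAMS:
                errors.append(f"mesh.generator: unknown generator {gen!r}")
            else:
                params = mesh.get("params", {})
                if _check_keys(params, _GENERATOR_PARAMS[gen],
                               "mesh.params", errors):
                    pass
        if has_file and mesh.get("format") not in (None, "off", "obj"):
            errors.append("mesh.format must be 'off' or 'obj'")

    # materials --------------------------------------------------------
    mats = cfg.get("materials")
    if not isinstance(mats, list) or not mats:
        errors.append("'materials' must be a non-empty list")
    else:
        for i, blk in enumerate(mats):
            path = f"materials[{i}]"
            if not _check_keys(
                blk,
                {"region", "type", "mu", "chi", "k_res", "mu_og", "k_og",
                 "alpha", "phase_field"},
                path, errors,
            ):
                continue
            t = blk.get("type")
            if t == "hydrogel":
                for key in ("mu", "chi"):
                    if not _is_num(blk.get(key)):
                        errors.append(f"{path}.{key}: required number")
            elif t == "ogden":
                for key in ("mu_og", "k_og", "alpha"):
                    if not _is_num(blk.get(key)):
                        errors.append(f"{path}.{key}: required number")
            else:
                errors.append(f"{path}.type must be 'hydrogel' or 'ogden'")

    # phase_field ------------------------------------------------------
    pf = cfg.get("phase_field")
    if pf is None:
        errors.append("missing required section 'phase_field'")
    elif _check_keys(pf, {"ell", "gc", "k_res", "clamp",
                          "clamp_negative_weights"}, "phase_field", errors):
        for key in ("ell", "gc"):
            v = pf.get(key)
            if not _is_num(v):
                errors.append(f"phase_field.{key}: required number")
            elif v <= 0:
                errors.append(f"phase_field.{key}: must be positive")

    # schedule ---------------------------------------------------------
    sch = cfg.get("schedule")
    if sch is None:
        errors.append("missing required section 'schedule'")
    elif _check_keys(sch, {"driven", "fixed"}, "schedule", errors):
        driven = sch.get("driven")
        if driven is None:
            errors.append("schedule.driven is required")
        elif _check_keys(driven, {"set", "direction", "magnitudes"},
                         "schedule.driven", errors):
            if not isinstance(driven.get("set"), str):
                errors.append("schedule.driven.set: required string")
            d = driven.get("direction")
            if not (
                (isinstance(d, list) and len(d) == 3 and all(_is_num(x) for x in d))
                or d == "radial_xy"
            ):
                errors.append(
                    "schedule.driven.direction: 3-vector or 'radial_xy'"
                )
            mags = driven.get("magnitudes")
            if isinstance(mags, dict):
                if set(mags) != {"max", "steps"}:
                    errors.append(
                        "schedule.driven.magnitudes: need {max, steps}"
                    )
            elif isinstance(mags, list):
                if not all(_is_num(x) for x in mags) or not mags:
                    errors.append(
                        "schedule.driven.magnitudes: non-empty number list"
                    )
            else:
                errors.append(
                    "schedule.driven.magnitudes: list or {max, steps}"
                )
        for i, f in enumerate(sch.get("fixed", []) or []):
            _check_keys(f, {"set", "components"}, f"schedule.fixed[{i}]",
                        errors)
            if isinstance(f, dict) and not isinstance(f.get("set"), str):
                errors.append(f"schedule.fixed[{i}].set: required string")

    # optional sections ------------------------------------------------
    for name, allowed in (
        ("thickness_rule", {"n_gauss"}),
        ("bending", {"enabled", "stiffness"}),
        ("solver", {"tol_p", "tol_e", "max_stagger", "gtol", "max_lbfgs",
                    "abort_on_stagger"}),
        ("stop_when", {"p_min_below", "force_drop_frac"}),
        ("output", {"dir", "write_vtu", "vtu_every", "basename"}),
    ):
        if name in cfg:
            _check_keys(cfg[name], allowed, name, errors)
    return errors


def resolve_config(cfg) -> dict:
    """Validate and return a deep copy with defaults filled in."""
    errors = validate_config(cfg)
    if errors:
        raise ConfigError(errors)
    out = copy.deepcopy(cfg)
    for name, defaults in _DEFAULTS.items():
        if isinstance(defaults, dict):
            section = dict(defaults)
            section.update(out.get(name, {}) or {})
            out[name] = section
        else:
            out.setdefault(name, defaults)
    pf = out["phase_field"]
    pf.setdefault("k_res", 1e-4)
    pf.setdefault("clamp", True)
    pf.setdefault("clamp_negative_weights", False)
    for blk in out["materials"]:
        blk.setdefault("region", "default")
        if blk["type"] == "hydrogel":
            blk.setdefault("k_res", pf["k_res"])
    sch = out["schedule"]
    sch.setdefault("fixed", [])
    for f in sch["fixed"]:
        f.setdefault("components", [0, 1, 2])
    mags = sch["driven"]["magnitudes"]
    if isinstance(mags, dict):
        n = int(mags["steps"])
        mx = float(mags["max"])
        sch["driven"]["magnitudes"] = [mx * (k + 1) / n for k in range(n)]
    if "params" not in out["mesh"] and "generator" in out["mesh"]:
        out["mesh"]["params"] = {}
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(cfg, path):
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# bundled desk-scale demos
# ---------------------------------------------------------------------------


def demo_config(name: str, **overrides) -> dict:
    """Return a bundled scenario config (desk scale, minutes on one CPU).

    Recognized names: sent, sphere-compression, sphere-shear, fiber-strip,
    cap-patch.  ``overrides`` may replace the fracture energy (gc), the
    number of steps (steps), the maximum imposed displacement (u_max) and
    the mesh resolution (target_h).
    """
    builders = {
        "sent": _demo_sent,
        "sphere-compression": _demo_sphere_compression,
        "sphere-shear": _demo_sphere_shear,
        "fiber-strip": _demo_fiber_strip,
        "cap-patch": _demo_cap_patch,
    }
    if name not in builders:
        raise ConfigError([f"unknown demo {name!r}; choose from "
                           f"{sorted(builders)}"])
    cfg = builders[name]()
    if "gc" in overrides and overrides["gc"] is not None:
        cfg["phase_field"]["gc"] = float(overrides["gc"])
    if "target_h" in overrides and overrides["target_h"] is not None:
        cfg["mesh"]["params"]["target_h"] = float(overrides["target_h"])
    mags = cfg["schedule"]["driven"]["magnitudes"]
    if "u_max" in overrides and overrides["u_max"] is not None:
        mags["max"] = float(overrides["u_max"])
    if "steps" in overrides and overrides["steps"] is not None:
        mags["steps"] = int(overrides["steps"])
    return cfg


def _demo_sent() -> dict:
    return {
        "schema_version": 1,
        "mesh": {
            "generator": "notched_plate",
            "params": {"length": 1.0, "width": 1.0, "notch_length": 0.3,
                       "target_h": 0.03, "growth": 1.12},
        },
        "materials": [
            {"region": "default", "type": "hydrogel", "mu": 1.0,
             "chi": 2.17, "k_res": 1e-4},
        ],
        "phase_field": {"ell": 0.05, "gc": 2e-3},
        "schedule": {
            "driven": {"set": "top", "direction": [0.0, 1.0, 0.0],
                       "magnitudes": {"max": 0.30, "steps": 30}},
            "fixed": [{"set": "bottom", "components": [0, 1, 2]}],
        },
        "stop_when": {"force_drop_frac": 0.8},
        "output": {"dir": "out_sent"},
    }


def _demo_sphere_compression() -> dict:
    return {
        "schema_version": 1,
        "mesh": {
            "generator": "perforated_sphere_patch",
            "params": {"R": 1.0, "r_hole": 0.05, "n_holes": 3,
                       "symmetry": "octant", "target_h": 0.052,
                       "hole_colatitude": 0.7, "thickness": 0.02},
        },
        "materials": [
            {"region": "default", "type": "hydrogel", "mu": 1.0,
             "chi": 2.17, "k_res": 1e-4},
        ],
        "phase_field": {"ell": 0.06, "gc": 3e-4},
        "bending": {"enabled": True, "stiffness": 5e-6},
        "solver": {"tol_p": 1e-3, "tol_e": 1e-6, "gtol": 1e-5},
        "schedule": {
            "driven": {"set": "pole", "direction": [0.0, 0.0, -1.0],
                       "magnitudes": {"max": 0.6, "steps": 12}},
            "fixed": [
                {"set": "equator", "components": [0, 1, 2]},
                {"set": "symmetry_y0", "components": [1]},
                {"set": "symmetry_x0", "components": [0]},
            ],
        },
        "stop_when": {"p_min_below": 0.4},
        "output": {"dir": "out_sphere_compression"},
    }


def _demo_sphere_shear() -> dict:
    cfg = _demo_sphere_compression()
    cfg["mesh"]["params"]["symmetry"] = "quadrant"
    cfg["schedule"] = {
        "driven": {"set": "pole", "direction": [1.0, 0.0, 0.0],
                   "magnitudes": {"max": 0.5, "steps": 20}},
        "fixed": [
            {"set": "equator", "components": [0, 1, 2]},
            {"set": "symmetry_y0", "components": [1]},
        ],
    }
    cfg["output"] = {"dir": "out_sphere_shear"}
    return cfg


def _demo_fiber_strip() -> dict:
    return {
        "schema_version": 1,
        "mesh": {
            "generator": "fiber_strip",
            "params": {"length": 4.0, "width": 1.0, "thickness": 0.1,
                       "n_fibers": 4, "n_crosslinks": 3, "target_h": 0.06},
        },
        "materials": [
            {"region": "default", "type": "hydrogel", "mu": 1.0,
             "chi": 2.17, "k_res": 1e-4},
        ],
        "phase_field": {"ell": 0.06, "gc": 3e-4},
        "schedule": {
            "driven": {"set": "center", "direction": [0.0, 0.0, 1.0],
                       "magnitudes": {"max": 0.5, "steps": 20}},
            "fixed": [
                {"set": "left", "components": [0, 1, 2]},
                {"set": "right", "components": [0, 1, 2]},
            ],
        },
        "stop_when": {"p_min_below": 0.2},
        "output": {"dir": "out_fiber_strip"},
    }


def _demo_cap_patch() -> dict:
    return {
        "schema_version": 1,
        "mesh": {
            "generator": "cap_with_patch",
            "params": {"R_major": 1.0, "R_minor": 0.8, "patch_angle": 0.5,
                       "target_h": 0.07, "thickness": 0.02},
        },
        "materials": [
            {"region": "hydrogel", "type": "hydrogel", "mu": 1.0,
             "chi": 2.17, "k_res": 1e-4},
            {"region": "substrate", "type": "ogden", "mu_og": 0.1,
             "k_og": 1.0, "alpha": -20.0},
        ],
        "phase_field": {"ell": 0.08, "gc": 1e-3},
        "schedule": {
            "driven": {"set": "rim", "direction": "radial_xy",
                       "magnitudes": {"max": 0.4, "steps": 16}},
            "fixed": [],
        },
        "stop_when": {"p_min_below": 0.3},
        "output": {"dir": "out_cap_patch"},
    }


DEMO_NAMES = ("sent", "sphere-compression", "sphere-shear", "fiber-strip",
              "cap-patch")
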