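"""Model bundle I/O: fixture writing and loading into body frames.

A model bundle on disk consists of four mesh files (STL/PLY/OBJ, mm), a
landmark JSON, a ligament JSON and an optional parameter YAML, all expressed
in one "scanner" coordinate system.  :func:`load_model` rebuilds the femoral
and tibial anatomical frames from the landmarks and transforms every
per-body entity into its body frame, so the loaded model is independent of
how the scan was oriented.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import simulate
from .geometry import SurfaceMesh
from .jcs import (LandmarkSet, RigidState, build_femoral_frame, build_tibial_frame,
                  FEMORAL_LANDMARKS, TIBIAL_LANDMARKS)
from .model import ContactParams, KneeModel, LigamentSpec, LIGAMENT_NAMES
from .tissue_forces import DEFAULT_LIGAMENT_PARAMS

__all__ = ["write_fixture", "load_model", "load_landmarks", "load_ligaments",
           "load_parameters"]

logger = logging.getLogger(__name__)

_MESH_FILES = {
    "femur_bone": "femur_bone.stl",
    "femur_cartilage": "femur_cartilage.stl",
    "tibia_bone": "tibia_bone.stl",
    "tibia_cartilage": "tibia_cartilage.stl",
}


def load_landmarks(path) -> LandmarkSet:
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    try:
        return LandmarkSet.from_dict(d)
    except (KeyError, ValueError) as exc:
        raise ValueError(f"landmark file {path}: {exc}") from exc


def load_ligaments(path) -> list[dict]:
    with open(path, encoding="utf-8") as fh:
        entries = json.load(fh)
    names = [e.get("name") for e in entries]
    if sorted(names) != sorted(LIGAMENT_NAMES):
        raise ValueError(f"ligament file {path}: expected the 15 elements "
                         f"{sorted(LIGAMENT_NAMES)}, got {sorted(names)}")
    for e in entries:
        for key in ("femoral_mm", "tibial_mm"):
            if key not in e or len(e[key]) != 3:
                raise ValueError(f"ligament file {path}: element {e.get('name')!r} "
                                 f"missing 3-vector field {key!r}")
    return entries


def load_parameters(path=None):
    """Material/contact parameter table; defaults where the file is silent."""
    table = {name: dict(zip(("K_Q", "K_L", "e"), DEFAULT_LIGAMENT_PARAMS[name]))
             for name in LIGAMENT_NAMES}
    contact = ContactParams()
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for name, vals in raw.get("ligaments", {}).items():
            if name not in table:
                raise ValueError(f"parameter file {path}: unknown ligament {name!r}")
            table[name].update(vals)
        c = raw.get("contact", {})
        contact = ContactParams(k=c.get("k", 500.0), p=c.get("p", 1.5),
                                delta_c=c.get("delta_c", 0.01), C=c.get("C", 5.0),
                                aggregation=c.get("aggregation", "distributed"))
    return table, contact


def write_fixture(model: KneeModel, cycles, out_dir, reference_alpha_deg: float = 15.0,
                  seed=None, solver: dict | None = None) -> dict:
    """Serialize a model (plus flexion profiles) as a scanner-frame bundle.

    The scanner frame is chosen as the femoral body frame with the tibia
    placed at a seated pose at ``reference_alpha_deg`` of flexion, the way a
    scan captures a slightly flexed knee.  Returns the file map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    femur = simulate.femur_state_at(np.radians(reference_alpha_deg))
    x0 = simulate.seat_pose(model, np.radians(reference_alpha_deg))
    tibia = simulate._tibia_state(femur, np.radians(reference_alpha_deg), x0)

    states = {"femur": femur, "tibia": tibia}
    files = {}
    for key, fname in _MESH_FILES.items():
        body = key.split("_")[0]
        mesh: SurfaceMesh = getattr(model, key)
        mesh.transformed(states[body]).save(out / fname)
        files[key] = fname

    pts = {}
    for name in FEMORAL_LANDMARKS:
        pts[name] = femur.frame.to_parent(model.landmarks[name]).tolist()
    for name in TIBIAL_LANDMARKS:
        pts[name] = tibia.frame.to_parent(model.landmarks[name]).tolist()
    with open(out / "landmarks.json", "w", encoding="utf-8") as fh:
        json.dump({"side": model.side, "units": "mm", "points": pts}, fh, indent=1)
    files["landmarks"] = "landmarks.json"

    ligs = [{"name": lig.name,
             "femoral_mm": femur.frame.to_parent(lig.femoral_mm).tolist(),
             "tibial_mm": tibia.frame.to_parent(lig.tibial_mm).tolist()}
            for lig in model.ligaments]
    with open(out / "ligaments.json", "w", encoding="utf-8") as fh:
        json.dump(ligs, fh, indent=1)
    files["ligaments"] = "ligaments.json"

    params = {"ligaments": {lig.name: {"K_Q": lig.K_Q, "K_L": lig.K_L, "e": lig.e}
                            for lig in model.ligaments},
              "contact": {"k": model.contact.k, "p": model.contact.p,
                          "delta_c": model.contact.delta_c, "C": model.contact.C,
                          "aggregation": model.contact.aggregation}}
    with open(out / "parameters.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(params, fh, sort_keys=True)
    files["parameters"] = "parameters.yaml"

    with open(out / "cycles.csv", "w", encoding="utf-8") as fh:
        fh.write(f"# tibfem-cycles seed={seed if seed is not None else 'NA'}\n")
        fh.write("cycle,flexion_deg\n")
        for ci, prof in enumerate(cycles):
            for a in prof:
                fh.write(f"{ci},{a:.6f}\n")
    files["cycles"] = "cycles.csv"

    with open(out / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump({"model": {**files}, "solver": dict(solver or {}),
                        "seed": int(seed or 0)},
                       fh, sort_keys=True)
    files["config"] = "config.yaml"
    return files


def read_cycles_csv(path):
    import pandas as pd
    df = pd.read_csv(path, comment="#")
    return [g["flexion_deg"].to_numpy(float) for _, g in df.groupby("cycle")]


def load_model(config) -> KneeModel:
    """Load a model bundle and express everything in anatomical body frames.

    ``config`` is a :class:`~tibfem.config.RunConfig` (or any object with
    the same path attributes).  Meshes and attachment points, given in the
    scanner frame, are transformed so that the femoral/tibial frames built
    from the landmarks become the identity: Ofem and Otib end up at their
    body-frame origins.
    """
    landmarks = load_landmarks(config.landmarks)
    fem_frame = build_femoral_frame(landmarks)
    tib_frame = build_tibial_frame(landmarks)
    fem_state = RigidState(frame=fem_frame)
    tib_state = RigidState(frame=tib_frame)
    states = {"femur": fem_state, "tibia": tib_state}

    meshes = {}
    for key in _MESH_FILES:
        body = key.split("_")[0]
        mesh = SurfaceMesh.load(getattr(config, key), frame=body)
        meshes[key] = SurfaceMesh(vertices=states[body].frame.to_local(mesh.vertices),
                                  faces=mesh.faces, frame=body)

    # landmarks in body frames (femoral group -> femoral frame, etc.)
    pts = {}
    for name in FEMORAL_LANDMARKS:
        pts[name] = fem_frame.to_local(landmarks[name])
    for name in TIBIAL_LANDMARKS:
        pts[name] = tib_frame.to_local(landmarks[name])
    local_landmarks = LandmarkSet(points=pts, side=landmarks.side)

    table, contact = load_parameters(getattr(config, "parameters", None))
    ligaments = []
    for entry in load_ligaments(config.ligaments):
        name = entry["name"]
        ligaments.append(LigamentSpec(
            name=name,
            femoral_mm=fem_frame.to_local(np.asarray(entry["femoral_mm"], float)),
            tibial_mm=tib_frame.to_local(np.asarray(entry["tibial_mm"], float)),
            **table[name]))

    return KneeModel(landmarks=local_landmarks, contact=contact,
                     ligaments=ligaments, name=str(config.landmarks), **meshes)
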