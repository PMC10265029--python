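"""Model-definition I/O, OpenSim-style XML export, and run manifests.

The model definition is a YAML/JSON mapping with ``segments``, ``joints``,
``muscles`` and ``wrap_objects`` blocks; it round-trips losslessly through
:func:`load_model_config` / :func:`save_model_config`. Angles are degrees,
lengths metres, masses kg in every file this package reads or writes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from lxml import etree

from .errors import ModelConfigError
from .path_engine import MusculotendonUnit, PathPoint, WrapObject

__all__ = [
    "load_model_config",
    "save_model_config",
    "muscles_from_config",
    "wraps_from_config",
    "export_osim",
    "RunManifest",
]


def load_model_config(path) -> dict:
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            config = yaml.safe_load(fh)
        elif path.suffix == ".json":
            config = json.load(fh)
        else:
            raise ModelConfigError(f"unknown config format {path.suffix!r}")
    if not isinstance(config, dict):
        raise ModelConfigError("model config must be a mapping")
    return config


def save_model_config(config: dict, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix in (".yaml", ".yml"):
            yaml.safe_dump(config, fh, sort_keys=False)
        elif path.suffix == ".json":
            json.dump(config, fh, indent=2)
        else:
            raise ModelConfigError(f"unknown config format {path.suffix!r}")


def muscles_from_config(config: dict) -> list:
    """Instantiate MTUs from the ``muscles`` block of a model config."""
    mtus = []
    for m in config.get("muscles", []):
        points = [PathPoint(np.asarray(p["location"], dtype=float), p["segment"])
                  for p in m["points"]]
        wraps = m.get("wraps", {})
        if isinstance(wraps, list):
            wraps = {w: None for w in wraps}
        mtus.append(MusculotendonUnit(
            name=m["name"], points=points, wraps=wraps,
            mass=float(m.get("mass", 0.0)), groups=list(m.get("groups", []))))
    return mtus


def wraps_from_config(config: dict) -> dict:
    """Instantiate wrap objects from the ``wrap_objects`` block."""
    wraps = {}
    for w in config.get("wrap_objects", []):
        frame = np.asarray(w.get("frame", np.eye(4)), dtype=float)
        wraps[w["name"]] = WrapObject(
            name=w["name"], kind=w["kind"], segment=w["segment"],
            radius=float(w["radius"]),
            half_length=float(w.get("half_length", 0.0)),
            frame=frame, active_side=w.get("active_side"))
    return wraps


# ---------------------------------------------------------------------------
# OpenSim-style export (one-way, for cross-validation)
# ---------------------------------------------------------------------------

_COORD_SUFFIX = {"X": "abduction_adduction", "Y": "long_axis_rotation",
                 "Z": "flexion_extension"}


def _vec(v) -> str:
    return " ".join(f"{float(x):.12g}" for x in np.asarray(v).ravel())


def export_osim(model, mtus=(), wrap_objects=None, version: str = "40000") -> bytes:
    """Serialize a model as OpenSim-4-style XML (bodies, custom joints,
    path points, wrap objects). Deterministic: identical input gives
    byte-identical output (stable, declaration-order serialization).
    """
    wrap_objects = wrap_objects or {}
    root = etree.Element("OpenSimDocument", Version=version)
    osim_model = etree.SubElement(root, "Model", name=model.name)
    bodyset = etree.SubElement(etree.SubElement(osim_model, "BodySet"), "objects")
    for seg in model.segments.values():
        body = etree.SubElement(bodyset, "Body", name=seg.name)
        etree.SubElement(body, "mass").text = f"{seg.mass:.12g}"
        etree.SubElement(body, "mass_center").text = _vec(seg.com)
        inertia = seg.inertia
        etree.SubElement(body, "inertia").text = _vec(
            [inertia[0, 0], inertia[1, 1], inertia[2, 2],
             inertia[0, 1], inertia[0, 2], inertia[1, 2]])
        wset = etree.SubElement(etree.SubElement(body, "WrapObjectSet"), "objects")
        for w in wrap_objects.values():
            if w.segment != seg.name:
                continue
            tag = "WrapCylinder" if w.kind == "cylinder" else "WrapSphere"
            wrap_el = etree.SubElement(wset, tag, name=w.name)
            etree.SubElement(wrap_el, "radius").text = f"{w.radius:.12g}"
            if w.kind == "cylinder":
                etree.SubElement(wrap_el, "length").text = f"{2 * w.half_length:.12g}"
            etree.SubElement(wrap_el, "translation").text = _vec(w.frame[:3, 3])
            if w.active_side:
                etree.SubElement(wrap_el, "quadrant").text = w.active_side

    jointset = etree.SubElement(etree.SubElement(osim_model, "JointSet"), "objects")
    for j in model.joints.values():
        joint = etree.SubElement(jointset, "CustomJoint", name=j.name)
        etree.SubElement(joint, "socket_parent_frame").text = j.parent_segment
        etree.SubElement(joint, "socket_child_frame").text = j.child_segment
        etree.SubElement(joint, "location_in_parent").text = _vec(j.location)
        coords = etree.SubElement(etree.SubElement(joint, "CoordinateSet"), "objects")
        for d in j.dofs:
            coord = etree.SubElement(
                coords, "Coordinate", name=f"{j.name}_{_COORD_SUFFIX[d.axis]}")
            etree.SubElement(coord, "range").text = _vec(np.deg2rad(d.rom))
            etree.SubElement(coord, "axis").text = _vec(
                j.axes[:, "XYZ".index(d.axis)] * d.sign)

    forceset = etree.SubElement(etree.SubElement(osim_model, "ForceSet"), "objects")
    for mtu in mtus:
        for wname in mtu.wraps:
            if wname not in wrap_objects:
                raise ModelConfigError(
                    f"not exportable: {mtu.name} references undeclared wrap "
                    f"{wname!r}")
        actuator = etree.SubElement(forceset, "PathActuator", name=mtu.name)
        path = etree.SubElement(etree.SubElement(actuator, "GeometryPath"),
                                "PathPointSet")
        objects = etree.SubElement(path, "objects")
        for k, pp in enumerate(mtu.points):
            el = etree.SubElement(objects, "PathPoint", name=f"{mtu.name}_p{k}")
            etree.SubElement(el, "socket_parent_frame").text = pp.segment
            etree.SubElement(el, "location").text = _vec(pp.point)
        if mtu.wraps:
            wset = etree.SubElement(actuator, "PathWrapSet")
            wobjects = etree.SubElement(wset, "objects")
            for wname in mtu.wraps:
                pw = etree.SubElement(wobjects, "PathWrap",
                                      name=f"{mtu.name}_{wname}")
                etree.SubElement(pw, "wrap_object").text = wname
    return etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8")


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record: configs, input checksums, seeds, timings."""

    config_paths: list = field(default_factory=list)
    input_checksums: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    tool_version: str = ""
    timings_s: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    @property
    def manifest_id(self) -> str:
        blob = json.dumps({
            "configs": sorted(map(str, self.config_paths)),
            "checksums": dict(sorted(self.input_checksums.items())),
            "seeds": dict(sorted(self.seeds.items())),
            "version": self.tool_version,
        }, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def add_input(self, path) -> None:
        self.input_checksums[str(path)] = _sha256(path)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "manifest_id": self.manifest_id,
                "config_paths": [str(p) for p in self.config_paths],
                "input_checksums": self.input_checksums,
                "seeds": self.seeds,
                "tool_version": self.tool_version,
                "timings_s": self.timings_s,
                "outputs": [str(o) for o in self.outputs],
            }, fh, indent=2)
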