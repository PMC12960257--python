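"""Readers and writers for design, mesh, layout and result files.

Conventions: coordinates and lengths are nm, angles degrees; FASTA
sequences are written 5'->3' uppercase; TSV tables carry a header row
with unit-annotated column names; design JSON is schema-versioned.
Every output directory written by the command-line tools receives a
``provenance.json`` with the configuration, seed and package version.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import (DipidDesign, DomainSpec, MonomerGeometry, cone_angle,
                     predict_radius_naive, strand_groups)
from .mesh import ShellMesh
from .pores import MonomerLayout
from .wlc import WLCParams

__all__ = [
    "write_design_json", "read_design_json",
    "write_strands_fasta", "write_strands_csv",
    "write_mesh_off", "read_mesh_off", "write_xyz", "read_xyz",
    "write_results_tsv", "read_results_tsv",
    "load_config_yaml", "write_provenance",
]

SCHEMA_VERSION = 1


class FileFormatError(ValueError):
    """Malformed input file; the message names file and offending field."""


# -- design JSON ----------------------------------------------------------

def write_design_json(design: DipidDesign, path):
    doc = {
        "schema_version": SCHEMA_VERSION,
        "name": design.name,
        "geometry": asdict(design.geometry),
        "wlc": asdict(design.wlc),
        "cone_angle_naive_deg": design.cone_angle_naive,
        "radius_naive_nm": (None if np.isinf(design.radius_naive)
                            else design.radius_naive),
        "diameter_calibrated_nm": design.diameter_calibrated,
        "strands": [
            {"strand_id": i, "group": g, "face": s.face,
             "flex_len": s.flex_len, "curvature_len": s.curvature_len,
             "sticky_seq": s.sticky_seq}
            for i, (g, s) in enumerate(zip(strand_groups(), design.strands))
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_design_json(path) -> DipidDesign:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FileFormatError(f"{path}: not valid JSON ({exc})") from exc
    for field in ("schema_version", "name", "geometry", "strands"):
        if field not in doc:
            raise FileFormatError(f"{path}: missing field {field!r}")
    if doc["schema_version"] > SCHEMA_VERSION:
        raise FileFormatError(
            f"{path}: schema version {doc['schema_version']} is newer than "
            f"supported {SCHEMA_VERSION}")
    try:
        geometry = MonomerGeometry(**doc["geometry"])
        wlc = WLCParams(**doc.get("wlc", {}))
        strands = tuple(
            DomainSpec(flex_len=s["flex_len"], sticky_seq=s["sticky_seq"],
                       curvature_len=s["curvature_len"], face=s["face"])
            for s in doc["strands"]
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise FileFormatError(f"{path}: invalid field ({exc})") from exc
    radius = doc.get("radius_naive_nm")
    return DipidDesign(
        name=doc["name"], geometry=geometry, strands=strands,
        cone_angle_naive=doc.get("cone_angle_naive_deg", 0.0),
        radius_naive=np.inf if radius is None else radius,
        diameter_calibrated=doc.get("diameter_calibrated_nm"), wlc=wlc)


# -- strand export --------------------------------------------------------

def strands_table(design: DipidDesign) -> pd.DataFrame:
    rows = []
    for i, (g, s) in enumerate(zip(strand_groups(), design.strands)):
        rows.append({
            "strand_id": f"{design.name}_s{i:02d}",
            "group": g,
            "face": s.face,
            "flex_len": s.flex_len,
            "curvature_len": s.curvature_len,
            "sticky_seq": s.sticky_seq,
            "full_sequence": s.full_sequence,
        })
    return pd.DataFrame(rows)


def write_strands_csv(design: DipidDesign, path):
    strands_table(design).to_csv(path, index=False)


def write_strands_fasta(design: DipidDesign, path):
    with open(path, "w") as fh:
        for _, row in strands_table(design).iterrows():
            fh.write(f">{row.strand_id} group={row.group} face={row.face}\n")
            fh.write(row.full_sequence.upper() + "\n")


# -- meshes and layouts ---------------------------------------------------

def write_mesh_off(mesh: ShellMesh, path):
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {mesh.n_triangles} {mesh.n_edges}\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def read_mesh_off(path) -> ShellMesh:
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines or lines[0] != "OFF":
        raise FileFormatError(f"{path}: missing OFF header")
    try:
        nv, nf, _ = (int(x) for x in lines[1].split())
        verts = [[float(x) for x in ln.split()[:3]] for ln in lines[2:2 + nv]]
        faces = []
        for ln in lines[2 + nv:2 + nv + nf]:
            parts = ln.split()
            if int(parts[0]) != 3:
                raise FileFormatError(f"{path}: non-triangular face {ln!r}")
            faces.append(tuple(int(x) for x in parts[1:4]))
    except (ValueError, IndexError) as exc:
        raise FileFormatError(f"{path}: malformed OFF body ({exc})") from exc
    return ShellMesh(np.array(verts), faces)


def write_xyz(points, path, comment: str = "", labels=None):
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    labels = labels if labels is not None else ["M"] * len(pts)
    with open(path, "w") as fh:
        fh.write(f"{len(pts)}\n{comment}\n")
        for lab, p in zip(labels, pts):
            fh.write(f"{lab} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")


def read_xyz(path) -> np.ndarray:
    path = Path(path)
    lines = path.read_text().splitlines()
    try:
        n = int(lines[0])
        pts = [[float(x) for x in ln.split()[1:4]] for ln in lines[2:2 + n]]
    except (ValueError, IndexError) as exc:
        raise FileFormatError(f"{path}: malformed XYZ ({exc})") from exc
    if len(pts) != n:
        raise FileFormatError(f"{path}: header promises {n} atoms, "
                              f"found {len(pts)}")
    return np.asarray(pts)


def layout_to_xyz(layout: MonomerLayout, path, comment: str = "dipid layout"):
    write_xyz(layout.centres, path, comment=comment)


# -- tables and configs ---------------------------------------------------

def write_results_tsv(df: pd.DataFrame, path):
    df.to_csv(path, sep="\t", index=False)


def read_results_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_config_yaml(path, required=(), stochastic: bool = False) -> dict:
    path = Path(path)
    try:
        cfg = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise FileFormatError(f"{path}: invalid YAML ({exc})") from exc
    for key in required:
        if key not in cfg:
            raise FileFormatError(f"{path}: missing required key {key!r}")
    if stochastic and "seed" not in cfg:
        raise FileFormatError(
            f"{path}: a stochastic run requires an explicit 'seed'")
    return cfg


def write_provenance(outdir, config: dict, seed=None):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    doc = {"package": "dipid", "version": __version__,
           "seed": seed, "config": config}
    (outdir / "provenance.json").write_text(json.dumps(doc, indent=2,
                                                       default=str))
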