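"""Mesh and Vm-series persistence: ASCII PLY, legacy-ASCII VTK, HDF5."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .geometry import AtrialMesh
from .propagation import StimulusProtocol, VmSeries


def save_mesh_ply(mesh: AtrialMesh, path) -> None:
    path = Path(path)
    n, t = mesh.n_nodes, mesh.n_triangles
    with open(path, "w") as f:
        f.write("ply\nformat ascii 1.0\n")
        f.write(f"comment afloc atrial mesh d_long={mesh.d_long} d_trans={mesh.d_trans}\n")
        f.write(f"element vertex {n}\n")
        for prop in ("x", "y", "z", "fx", "fy", "fz"):
            f.write(f"property float {prop}\n")
        f.write("property int region_id\nproperty int fibrosis\n")
        f.write(f"element face {t}\nproperty list uchar int vertex_indices\nend_header\n")
        for i in range(n):
            x, y, z = mesh.node_coords[i]
            fx, fy, fz = mesh.fiber_dir[i]
            f.write(
                f"{x:.6f} {y:.6f} {z:.6f} {fx:.9f} {fy:.9f} {fz:.9f} "
                f"{mesh.region_id[i]} {int(mesh.fibrotic[i])}\n"
            )
        for tri in mesh.triangles:
            f.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")


def load_mesh_ply(path, d_long: float = None, d_trans: float = None) -> AtrialMesh:
    path = Path(path)
    with open(path) as f:
        line = f.readline().strip()
        if line != "ply":
            raise ValueError(f"{path} is not a PLY file")
        n = t = None
        d_long_file = d_trans_file = None
        while True:
            line = f.readline()
            if not line:
                raise ValueError("unterminated PLY header")
            line = line.strip()
            if line.startswith("comment") and "d_long=" in line:
                for tok in line.split():
                    if tok.startswith("d_long="):
                        d_long_file = float(tok.split("=")[1])
                    if tok.startswith("d_trans="):
                        d_trans_file = float(tok.split("=")[1])
            elif line.startswith("element vertex"):
                n = int(line.split()[-1])
            elif line.startswith("element face"):
                t = int(line.split()[-1])
            elif line == "end_header":
                break
        if n is None or t is None:
            raise ValueError("PLY header missing vertex/face counts")
        verts = np.loadtxt(f, max_rows=n)
        faces = np.loadtxt(f, max_rows=t, dtype=np.int64)
    if faces.ndim == 1:
        faces = faces[None, :]
    return AtrialMesh(
        node_coords=verts[:, 0:3],
        triangles=faces[:, 1:4],
        fiber_dir=verts[:, 3:6],
        region_id=verts[:, 6].astype(np.int64),
        d_long=d_long if d_long is not None else (d_long_file or 1.0),
        d_trans=d_trans if d_trans is not None else (d_trans_file or 1.0),
        fibrotic=verts[:, 7].astype(bool),
    )


def save_mesh_vtk(mesh: AtrialMesh, path) -> None:
    """Legacy ASCII VTK polydata with point-data scalars and fiber vectors."""
    path = Path(path)
    n, t = mesh.n_nodes, mesh.n_triangles
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nafloc atrial mesh\nASCII\n")
        f.write("DATASET POLYDATA\n")
        f.write(f"POINTS {n} float\n")
        for p in mesh.node_coords:
            f.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        f.write(f"POLYGONS {t} {4 * t}\n")
        for tri in mesh.triangles:
            f.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
        f.write(f"POINT_DATA {n}\n")
        f.write("SCALARS region_id int 1\nLOOKUP_TABLE default\n")
        f.write("\n".join(str(int(r)) for r in mesh.region_id) + "\n")
        f.write("SCALARS fibrosis int 1\nLOOKUP_TABLE default\n")
        f.write("\n".join(str(int(b)) for b in mesh.fibrotic) + "\n")
        f.write("VECTORS fiber_dir float\n")
        for v in mesh.fiber_dir:
            f.write(f"{v[0]:.9f} {v[1]:.9f} {v[2]:.9f}\n")


def save_vm_h5(series: VmSeries, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("vm", data=series.vm, compression="gzip", compression_opts=4)
        f.create_dataset("fs", data=float(series.fs))
        f.create_dataset("labels", data=series.ground_truth_driver)
        f.attrs["duration_s"] = series.duration_s
        if series.protocol is not None:
            f.attrs["protocol"] = series.protocol.to_json()
        f.attrs["meta"] = json.dumps(
            {k: v for k, v in series.meta.items() if k != "protocol"}, default=str
        )


def load_vm_h5(path) -> VmSeries:
    with h5py.File(path, "r") as f:
        vm = f["vm"][()]
        fs = float(f["fs"][()])
        labels = f["labels"][()]
        duration = float(f.attrs.get("duration_s", vm.shape[1] / fs))
        protocol = None
        if "protocol" in f.attrs:
            d = json.loads(f.attrs["protocol"])
            if d.get("stim_nodes") is not None:
                d["stim_nodes"] = np.asarray(d["stim_nodes"], dtype=np.int64)
            protocol = StimulusProtocol(**d)
        meta = json.loads(f.attrs.get("meta", "{}"))
    return VmSeries(
        vm=vm, fs=fs, duration_s=duration, ground_truth_driver=labels,
        protocol=protocol, meta=meta,
    )
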