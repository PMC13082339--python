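"""Line-oriented text serialization for tissues and trajectory output.

Tissue format (UTF-8, one record per line):

    # phyllidsim tissue 1
    H time=<float> phase=<int> units=um apical=<id|-> side=<left|right> next_merophyte=<int>
    V <id> <x> <y> <is_base 0|1> <constraint 0|1|2>
    C <id> <merophyte> <tissue_type> <zone> <t_diff|-> <k_par> <k_per> <v1> <v2> ...
    L <child> <parent>

Floats are written with ``repr`` so a write -> read -> write round trip is
byte-identical.  Finite elements and interior triangulation nodes are not
serialized; they are rebuilt stress-free on read (valid because the model
releases residual stresses every step).
"""

from __future__ import annotations

import csv
import os

import numpy as np

from .tissue import Cell, Tissue, Vertex, retriangulate

MAGIC = "# phyllidsim tissue 1"


class TissueFormatError(ValueError):
    pass


def _fmt(x: float) -> str:
    return repr(float(x))


def write_tissue_text(tissue: Tissue) -> str:
    lines = [MAGIC]
    apical = "-" if tissue.apical_cell_id is None else str(tissue.apical_cell_id)
    lines.append(
        f"H time={_fmt(tissue.time)} phase={tissue.phase} units=um "
        f"apical={apical} side={tissue.apical_division_side} "
        f"next_merophyte={tissue.next_merophyte_id}")
    interior = {v for c in tissue.cells.values() for v in c.interior_vertices}
    for vid in sorted(tissue.vertices):
        if vid in interior:
            continue
        v = tissue.vertices[vid]
        lines.append(f"V {vid} {_fmt(v.pos[0])} {_fmt(v.pos[1])} "
                     f"{int(v.is_base)} {v.constraint}")
    for cid in sorted(tissue.cells):
        c = tissue.cells[cid]
        t_diff = "-" if c.t_diff is None else _fmt(c.t_diff)
        ring = " ".join(str(v) for v in c.boundary)
        lines.append(f"C {cid} {c.merophyte_id} {c.tissue_type} {c.zone} "
                     f"{t_diff} {_fmt(c.k_par)} {_fmt(c.k_per)} {ring}")
    for child, parent in tissue.lineage:
        lines.append(f"L {child} {parent}")
    return "\n".join(lines) + "\n"


def write_tissue(tissue: Tissue, path):
    with open(path, "w", newline="\n") as fh:
        fh.write(write_tissue_text(tissue))


def read_tissue_text(text: str, mesh: bool = True) -> Tissue:
    tissue = Tissue()
    lines = text.splitlines()
    if not lines or lines[0].strip() != MAGIC:
        raise TissueFormatError("missing tissue format header line")
    for ln, raw in enumerate(lines[1:], start=2):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        tag = parts[0]
        try:
            if tag == "H":
                kv = dict(p.split("=", 1) for p in parts[1:])
                tissue.time = float(kv["time"])
                tissue.phase = int(kv["phase"])
                tissue.apical_cell_id = (None if kv.get("apical", "-") == "-"
                                         else int(kv["apical"]))
                tissue.apical_division_side = kv.get("side", "left")
                tissue.next_merophyte_id = int(kv.get("next_merophyte", 1))
            elif tag == "V":
                vid = int(parts[1])
                tissue.vertices[vid] = Vertex(
                    vid, np.array([float(parts[2]), float(parts[3])]),
                    bool(int(parts[4])), int(parts[5]))
                tissue._next_vertex_id = max(tissue._next_vertex_id, vid + 1)
            elif tag == "C":
                cid = int(parts[1])
                t_diff = None if parts[5] == "-" else float(parts[5])
                ring = [int(p) for p in parts[8:]]
                for v in ring:
                    if v not in tissue.vertices:
                        raise TissueFormatError(
                            f"cell {cid} references unknown vertex {v}")
                tissue.cells[cid] = Cell(
                    cid, ring, int(parts[2]), parts[3], parts[4],
                    None, float(parts[6]), float(parts[7]), float("inf"),
                    t_diff, None, [])
                tissue._next_cell_id = max(tissue._next_cell_id, cid + 1)
            elif tag == "L":
                tissue.lineage.append((int(parts[1]), int(parts[2])))
            else:
                raise TissueFormatError(f"unknown record tag {tag!r}")
        except TissueFormatError:
            raise
        except Exception as exc:
            raise TissueFormatError(f"line {ln}: malformed record: {raw!r} "
                                    f"({exc})") from exc
    tissue.validate()
    if mesh:
        retriangulate(tissue, sorted(tissue.cells))
    return tissue


def read_tissue(path, mesh: bool = True) -> Tissue:
    with open(path) as fh:
        return read_tissue_text(fh.read(), mesh=mesh)


# ------------------------------------------------------- trajectory output

def write_trajectory(traj, outdir):
    """Write snapshots, cells.csv, lineage.csv, events.csv and the resolved
    parameter copy to a directory."""
    os.makedirs(outdir, exist_ok=True)
    traj.params.to_yaml(os.path.join(outdir, "params.resolved.yaml"))
    for snap in traj.snapshots:
        write_tissue(snap.tissue,
                     os.path.join(outdir, f"tissue_t{snap.time:.2f}.txt"))
    with open(os.path.join(outdir, "cells.csv"), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time", "cell", "merophyte", "tissue_type", "zone",
                    "area", "cx", "cy", "k_par", "k_per"])
        for snap in traj.snapshots:
            tis = snap.tissue
            for cid in sorted(tis.cells):
                c = tis.cells[cid]
                cen = tis.cell_centroid(cid)
                w.writerow([snap.time, cid, c.merophyte_id, c.tissue_type,
                            c.zone, tis.cell_area(cid), cen[0], cen[1],
                            c.k_par, c.k_per])
    with open(os.path.join(outdir, "lineage.csv"), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["child", "parent"])
        for child, parent in traj.final.lineage:
            w.writerow([child, parent])
    with open(os.path.join(outdir, "events.csv"), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time", "parent", "daughter_a", "daughter_b",
                    "wall_ax", "wall_ay", "wall_bx", "wall_by",
                    "orientation", "is_apical", "angle_to_polarity_deg",
                    "merophyte"])
        for e in traj.events:
            w.writerow([e.time, e.parent, e.daughter_a, e.daughter_b,
                        e.wall_a[0], e.wall_a[1], e.wall_b[0], e.wall_b[1],
                        e.orientation, int(e.is_apical),
                        e.angle_to_polarity_deg, e.merophyte])
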