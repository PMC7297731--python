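"""File I/O: multi-frame XYZ and GRO readers, coarse-graining, CSV/JSON writers.

XYZ files carry the orthorhombic box on the comment line as ``box=Lx,Ly,Lz``
(Å).  GRO files are nm-native and fixed-column; coordinates and box vectors
are converted to Å on read.  Only orthorhombic boxes are accepted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import OSMOLYTE, WATER, Configuration
from .rips import Barcode
from .synthetic import Trajectory

__all__ = [
    "CoarseGrainRule",
    "DEFAULT_RULE",
    "read_xyz_frames",
    "write_xyz_frames",
    "read_gro_frames",
    "coarse_grain",
    "write_barcodes_json",
    "read_barcodes_json",
    "write_curve_csv",
]

NM_TO_ANGSTROM = 10.0

# symbols used when writing synthetic configurations to XYZ
_SYMBOL_OF_TYPE = {OSMOLYTE: "OSM", WATER: "WAT"}
_TYPE_OF_SYMBOL = {"OSM": OSMOLYTE, "WAT": WATER}


@dataclass
class CoarseGrainRule:
    """Mapping from (residue name, atom name) to a species label.

    One entry per kept atom; atoms not matched by any entry are dropped.  The
    atom-name pattern ``*`` matches any atom of the residue.  The default rule
    keeps the TMAO nitrogen and the urea carbon as OSMOLYTE and the water
    oxygen as WATER — one coarse-grained point per molecule.
    """

    mapping: dict = field(default_factory=dict)

    def label_for(self, resname: str, atomname: str) -> str | None:
        for key in ((resname, atomname), (resname, "*")):
            if key in self.mapping:
                return self.mapping[key]
        return None


DEFAULT_RULE = CoarseGrainRule(
    mapping={
        ("TMA", "N"): OSMOLYTE,
        ("TMAO", "N"): OSMOLYTE,
        ("URE", "C"): OSMOLYTE,
        ("UREA", "C"): OSMOLYTE,
        ("SOL", "OW"): WATER,
        ("SOL", "O"): WATER,
        ("WAT", "O"): WATER,
        ("WAT", "OW"): WATER,
    }
)


def _parse_box_comment(comment: str, frame: int) -> np.ndarray:
    for token in comment.split():
        if token.startswith("box="):
            parts = token[4:].split(",")
            if len(parts) != 3:
                raise ValueError(
                    f"frame {frame}: box= comment must have 3 lengths, got {token!r}"
                )
            return np.array([float(p) for p in parts])
    raise ValueError(
        f"frame {frame}: missing box information — the XYZ comment line must "
        "contain 'box=Lx,Ly,Lz' in Å (or pass box= to read_xyz_frames)"
    )


def read_xyz_frames(path, box=None, symbol_types: dict | None = None) -> Trajectory:
    """Read a multi-frame XYZ file into a trajectory.

    Box lengths are taken from the ``box=Lx,Ly,Lz`` comment-line key, or from
    the ``box`` argument (scalar or 3 lengths in Å) when the file has none.
    Atom symbols are retained as names; symbols found in ``symbol_types``
    (default: OSM/WAT) are mapped to species labels, everything else keeps the
    symbol itself as its label until coarse-graining.
    """
    symbol_types = {**_TYPE_OF_SYMBOL, **(symbol_types or {})}
    lines = Path(path).read_text().splitlines()
    frames = []
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError as exc:
            raise ValueError(
                f"frame {len(frames)}: malformed atom-count line {lines[pos]!r}"
            ) from exc
        if pos + 1 >= len(lines):
            raise ValueError(f"frame {len(frames)}: truncated (missing comment line)")
        comment = lines[pos + 1]
        body = lines[pos + 2 : pos + 2 + n]
        if len(body) < n:
            raise ValueError(f"frame {len(frames)}: truncated (expected {n} atoms)")
        if box is not None:
            b = np.broadcast_to(np.asarray(box, dtype=float), (3,)).copy()
        else:
            b = _parse_box_comment(comment, len(frames))
        symbols, coords = [], []
        for line in body:
            parts = line.split()
            symbols.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
        types = np.array([symbol_types.get(s, s) for s in symbols])
        frames.append(
            Configuration(
                coords=np.array(coords), box=b, types=types,
                frame_index=len(frames), names=np.array(symbols),
            )
        )
        pos += 2 + n
    if not frames:
        raise ValueError(f"no frames found in {path}")
    return Trajectory(frames=frames, metadata={"source": str(path)})


def write_xyz_frames(traj: Trajectory, path) -> None:
    """Write a trajectory as multi-frame XYZ with box metadata on comment lines."""
    with open(path, "w") as fh:
        for frame in traj:
            fh.write(f"{frame.n_points}\n")
            bx, by, bz = frame.box
            fh.write(f"box={bx:.6f},{by:.6f},{bz:.6f} frame={frame.frame_index}\n")
            for t, (x, y, z) in zip(frame.types, frame.coords):
                sym = _SYMBOL_OF_TYPE.get(str(t), str(t))
                fh.write(f"{sym} {x:.6f} {y:.6f} {z:.6f}\n")


def read_gro_frames(path) -> Trajectory:
    """Read (possibly concatenated multi-frame) GRO records, converting nm to Å.

    Residue and atom names are preserved for coarse-graining; the species
    labels are initially the atom names.  Rejects non-orthorhombic boxes
    (a box line with more than three values containing non-zero tilts).
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    frames = []
    pos = 0
    offset = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        if pos + 1 >= len(lines):
            raise ValueError(f"truncated GRO file near byte offset {offset}")
        try:
            n = int(lines[pos + 1].strip())
        except ValueError as exc:
            raise ValueError(
                f"malformed GRO atom count near byte offset {offset}: "
                f"{lines[pos + 1]!r}"
            ) from exc
        end = pos + 2 + n
        if end + 1 > len(lines):
            raise ValueError(
                f"truncated GRO frame {len(frames)} near byte offset {offset}"
            )
        resnames, names, coords = [], [], []
        for line in lines[pos + 2 : end]:
            # fixed columns: resid(5) resname(5) atomname(5) atomid(5) x y z (8.3 each)
            resnames.append(line[5:10].strip())
            names.append(line[10:15].strip())
            coords.append(
                [float(line[20:28]), float(line[28:36]), float(line[36:44])]
            )
        box_vals = [float(v) for v in lines[end].split()]
        if len(box_vals) == 3:
            b = np.array(box_vals)
        elif len(box_vals) == 9 and all(v == 0.0 for v in box_vals[3:]):
            b = np.array(box_vals[:3])
        else:
            raise ValueError(
                f"frame {len(frames)}: non-orthorhombic box line {lines[end]!r}"
            )
        frames.append(
            Configuration(
                coords=np.array(coords) * NM_TO_ANGSTROM,
                box=b * NM_TO_ANGSTROM,
                types=np.array(names),
                frame_index=len(frames),
                names=np.array(names),
                resnames=np.array(resnames),
            )
        )
        offset += sum(len(l) + 1 for l in lines[pos : end + 1])
        pos = end + 1
    if not frames:
        raise ValueError(f"no frames found in {path}")
    return Trajectory(frames=frames, metadata={"source": str(path)})


def coarse_grain(traj: Trajectory, rule: CoarseGrainRule | None = None) -> Trajectory:
    """Keep one labelled point per molecule according to the coarse-grain rule.

    Every residue present must be covered by the rule (at least one kept atom),
    otherwise an error listing the unmapped residues is raised.
    """
    rule = rule or DEFAULT_RULE
    out = []
    for frame in traj:
        if frame.resnames is None or frame.names is None:
            raise ValueError(
                f"frame {frame.frame_index} has no residue/atom names to coarse-grain"
            )
        labels = [
            rule.label_for(str(r), str(a))
            for r, a in zip(frame.resnames, frame.names)
        ]
        keep = [i for i, lab in enumerate(labels) if lab is not None]
        covered = {str(frame.resnames[i]) for i in keep}
        present = set(map(str, frame.resnames))
        missing = sorted(present - covered)
        if missing:
            raise ValueError(
                f"coarse-grain rule does not cover residues: {', '.join(missing)}"
            )
        out.append(
            Configuration(
                coords=frame.coords[keep],
                box=frame.box.copy(),
                types=np.array([labels[i] for i in keep]),
                frame_index=frame.frame_index,
            )
        )
    return Trajectory(frames=out, metadata=dict(traj.metadata))


def write_barcodes_json(barcodes, path) -> None:
    """Serialize barcodes to JSON: a list of {dim, birth, death} records.

    ``barcodes`` is one Barcode or a list of them (written as a list of lists).
    Infinite deaths are written as the string "inf".
    """

    def one(bc: Barcode):
        records = []
        for k in sorted(bc.bars):
            for birth, death in bc.get(k):
                records.append(
                    {
                        "dim": int(k),
                        "birth": float(birth),
                        "death": "inf" if math.isinf(death) else float(death),
                    }
                )
        return records

    payload = one(barcodes) if isinstance(barcodes, Barcode) else [one(b) for b in barcodes]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def _barcode_from_records(records) -> Barcode:
    by_dim: dict[int, list] = {}
    for rec in records:
        death = math.inf if rec["death"] == "inf" else float(rec["death"])
        by_dim.setdefault(int(rec["dim"]), []).append((float(rec["birth"]), death))
    if not by_dim:
        return Barcode(bars={}, max_homology_dim=0)
    return Barcode.from_pairs(by_dim)


def read_barcodes_json(path):
    """Inverse of :func:`write_barcodes_json`."""
    with open(path) as fh:
        payload = json.load(fh)
    if payload and isinstance(payload[0], list):
        return [_barcode_from_records(r) for r in payload]
    return _barcode_from_records(payload)


def write_curve_csv(curve, path) -> None:
    """Write a PBN or PRDF curve as two-column CSV (x_or_r, value)."""
    if hasattr(curve, "grid"):
        x = curve.grid
    else:
        x = curve.bin_centers
    pd.DataFrame({"x_or_r": x, "value": curve.values}).to_csv(path, index=False)
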