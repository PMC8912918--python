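"""GRO coordinate I/O for membrane frames.

Frames are serialized to the fixed-column GRO format through MDAnalysis.
Bead naming encodes the frame structure so a written file reads back into an
equivalent :class:`MembraneFrame`: the headgroup vertex is ``PO4`` when the
lipid carries a phosphate bead (``ROH`` for cholesterol, ``GL1`` otherwise),
the amine bead of zwitterionic lipids is ``NC3``, tail beads are ``C<k>A`` /
``C<k>B``, and water beads are residue ``W``. Coordinates survive the
round trip to the format's 0.001 nm precision; leaflet labels are not stored
and are re-derived from geometry on read.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda

from .frame import MembraneFrame
from .groups import head_charge, head_group, ZWITTERIONIC_HEADS

NM_TO_ANGSTROM = 10.0


def _frame_beads(frame: MembraneFrame):
    """Yield (resname, [(bead_name, position), ...]) per residue."""
    n_tails, n_beads = frame.tails.shape[1:3]
    for i in range(frame.n_lipids):
        res = frame.resnames[i]
        beads = []
        if np.isfinite(frame.phosphate_pos[i, 0]):
            beads.append(("PO4", frame.phosphate_pos[i]))
        elif res == "CHOL":
            beads.append(("ROH", frame.head_pos[i]))
        else:
            beads.append(("GL1", frame.head_pos[i]))
        if np.isfinite(frame.amine_pos[i, 0]):
            beads.append(("NC3", frame.amine_pos[i]))
        for t in range(n_tails):
            for k in range(n_beads):
                pos = frame.tails[i, t, k]
                if np.isfinite(pos[0]):
                    beads.append((f"C{k + 1}{'AB'[t]}", pos))
        yield res, beads
    for w in frame.water:
        yield "W", [("W", w)]


def write_gro(frame: MembraneFrame, path: str | Path) -> None:
    """Write one frame as a GRO file (positions nm, box vector last line)."""
    names, resnames, resindex, positions = [], [], [], []
    for ridx, (res, beads) in enumerate(_frame_beads(frame)):
        resnames.append(res)
        for name, pos in beads:
            names.append(name)
            resindex.append(ridx)
            positions.append(pos)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n_atoms=len(names), n_residues=len(resnames),
                               atom_resindex=np.asarray(resindex),
                               trajectory=True)
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", np.arange(1, len(resnames) + 1))
    u.atoms.positions = np.asarray(positions) * NM_TO_ANGSTROM
    u.dimensions = [frame.box[0] * NM_TO_ANGSTROM, frame.box[1] * NM_TO_ANGSTROM,
                    frame.box[2] * NM_TO_ANGSTROM, 90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def read_gro(path: str | Path, time: float = 0.0,
             water_resnames: tuple[str, ...] = ("W", "PW", "WN")) -> MembraneFrame:
    """Read a GRO file into a :class:`MembraneFrame`.

    Water residues are identified by resname; every other residue must be a
    known lipid (unknown names raise). The headgroup vertex is the first head
    bead of the residue; leaflet labels are re-derived from headgroup heights.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty GRO file")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as err:  # malformed fixed columns
        raise ValueError(f"{path}: malformed GRO file ({err})") from err
    if u.dimensions is None:
        raise ValueError(f"{path}: missing box vector line")
    box = np.asarray(u.dimensions[:3], dtype=float) / NM_TO_ANGSTROM

    water, lipids = [], []
    for res in u.residues:
        if res.resname in water_resnames:
            # count the central bead only of multi-bead water models
            central = res.atoms[0].position if len(res.atoms) else None
            if central is not None:
                water.append(central / NM_TO_ANGSTROM)
            continue
        lipids.append(res)
    if not lipids:
        raise ValueError(f"{path}: no lipid residues found")

    max_tail_beads = 1
    for res in lipids:
        for atom in res.atoms:
            if atom.name.startswith("C") and atom.name[-1] in "AB":
                max_tail_beads = max(max_tail_beads, int(atom.name[1:-1]))

    n = len(lipids)
    resnames = np.empty(n, dtype=object)
    head = np.full((n, 3), np.nan)
    phos = np.full((n, 3), np.nan)
    amine = np.full((n, 3), np.nan)
    tails = np.full((n, 2, max_tail_beads, 3), np.nan)
    charges = np.zeros(n)
    for i, res in enumerate(lipids):
        name = res.resname
        head_group(name)  # raises UnknownResidueError for foreign residues
        resnames[i] = name
        charges[i] = head_charge(name)
        for atom in res.atoms:
            pos = atom.position / NM_TO_ANGSTROM
            if atom.name in ("PO4",):
                phos[i] = pos
                head[i] = pos
            elif atom.name in ("GL1", "ROH", "AM1", "GM1"):
                head[i] = pos
            elif atom.name in ("NC3", "NH3"):
                amine[i] = pos
            elif atom.name.startswith("C") and atom.name[-1] in "AB":
                t = "AB".index(atom.name[-1])
                k = int(atom.name[1:-1]) - 1
                tails[i, t, k] = pos
        if not np.isfinite(head[i, 0]):
            head[i] = res.atoms[0].position / NM_TO_ANGSTROM

    frame = MembraneFrame(
        box=box, time=time, resnames=resnames,
        leaflets=np.full(n, "inner", dtype=object),
        head_pos=head, phosphate_pos=phos, amine_pos=amine, tails=tails,
        charges=charges, water=np.asarray(water).reshape(-1, 3),
    )
    from .surface import assign_leaflets
    frame.leaflets = assign_leaflets(frame)
    return frame
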