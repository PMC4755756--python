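"""Map and coordinate file boundaries (CCP4/MRC mode-2 maps, PDB sites).

All file handling is delegated to gemmi; this module only adapts between the
package's in-memory types and gemmi's. Maps are written as full-cell P1 grids
in x,y,z axis order so that write/read round trips are bit exact.

Mixed belt-chalcogen sites are written as two altloc records (A: Se at the Se
fraction, B: S at the S fraction) at the same position — the standard PDB idiom
for a two-species site — and merged back into one :class:`~femose.core.Site`
on reading.
"""

from __future__ import annotations

import os

import gemmi
import numpy as np
import pandas as pd

from .core import MapGrid, Site, UnitCell

__all__ = ["write_ccp4", "read_ccp4", "write_pdb", "read_pdb",
           "write_truth_table", "read_truth_table"]


def write_ccp4(grid: MapGrid, path: str | os.PathLike) -> None:
    """Write a map as CCP4/MRC mode 2 (32-bit float), P1, full cell."""
    nx, ny, nz = grid.dims
    g = gemmi.FloatGrid(nx, ny, nz)
    g.set_unit_cell(grid.cell.to_gemmi())
    g.spacegroup = gemmi.SpaceGroup("P1")
    arr = np.array(g, copy=False)
    arr[...] = grid.values
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = g
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))


def read_ccp4(path: str | os.PathLike) -> MapGrid:
    ccp4 = gemmi.read_ccp4_map(str(path))
    ccp4.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    g = ccp4.grid
    cell = UnitCell(g.unit_cell.a, g.unit_cell.b, g.unit_cell.c,
                    g.unit_cell.alpha, g.unit_cell.beta, g.unit_cell.gamma)
    values = np.array(g, copy=True)
    return MapGrid(cell=cell, values=values)


_CHAIN_FOR_COPY = "ABCDEFGH"


def write_pdb(sites: list[Site], cell: UnitCell, path: str | os.PathLike) -> None:
    """Write sites as HETATM records; occupancy and B columns are honored.

    Sites are grouped into one chain per ``copy_id``; every site is its own
    residue so free-text labels survive as atom names.
    """
    st = gemmi.Structure()
    st.name = "femose-fixture"
    st.cell = cell.to_gemmi()
    st.spacegroup_hm = "P 1"
    model = gemmi.Model("1")
    copies = sorted({s.copy_id for s in sites})
    for copy_id in copies:
        chain = gemmi.Chain(_CHAIN_FOR_COPY[copy_id % len(_CHAIN_FOR_COPY)])
        seq = 0
        for site in sites:
            if site.copy_id != copy_id:
                continue
            seq += 1
            res = gemmi.Residue()
            res.name = "FMS"
            res.seqid = gemmi.SeqId(seq, " ")
            res.het_flag = "H"
            atom = gemmi.Atom()
            atom.name = site.label[:4].upper()
            atom.element = gemmi.Element(site.element)
            atom.pos = gemmi.Position(*site.position)
            atom.occ = float(site.occupancy)
            atom.b_iso = float(site.b_factor)
            if site.s_occupancy > 0:
                atom.altloc = "A"
            res.add_atom(atom)
            if site.s_occupancy > 0:
                alt = gemmi.Atom()
                alt.name = site.label[:4].upper()
                alt.element = gemmi.Element("S")
                alt.pos = gemmi.Position(*site.position)
                alt.occ = float(site.s_occupancy)
                alt.b_iso = float(site.b_factor)
                alt.altloc = "B"
                res.add_atom(alt)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def read_pdb(path: str | os.PathLike) -> tuple[list[Site], UnitCell]:
    st = gemmi.read_structure(str(path))
    c = st.cell
    cell = UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
    sites: list[Site] = []
    for model in st:
        for copy_id, chain in enumerate(model, start=1):
            for res in chain:
                primary: gemmi.Atom | None = None
                s_frac = 0.0
                for atom in res:
                    if atom.altloc == "B" and atom.element.name == "S":
                        s_frac = float(atom.occ)
                    else:
                        primary = atom
                if primary is None:
                    continue
                sites.append(Site(
                    label=primary.name,
                    element=primary.element.name,
                    position=np.array([primary.pos.x, primary.pos.y, primary.pos.z]),
                    b_factor=float(primary.b_iso),
                    occupancy=float(primary.occ),
                    copy_id=copy_id,
                    s_occupancy=s_frac,
                ))
        break  # single-model files only
    return sites, cell


def write_truth_table(sites: list[Site], path: str | os.PathLike) -> None:
    """Planted-occupancy table as tidy CSV (one row per site)."""
    rows = [{
        "label": s.label, "element": s.element, "copy_id": s.copy_id,
        "x": s.position[0], "y": s.position[1], "z": s.position[2],
        "b_factor": s.b_factor, "se_occupancy": s.occupancy,
        "s_occupancy": s.s_occupancy,
    } for s in sites]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def read_truth_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)
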