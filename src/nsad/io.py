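"""File I/O: SHELX HKL reflections, CCP4/MRC maps, PDB coordinates, tables.

The reflection dialect is the classic fixed-width SHELX HKL format,
3I4 + 2F8.2 (h, k, l, I, σ), terminated by an all-zero record.  Maps and
coordinates go through gemmi, the standard crystallographic toolbox.
"""

from __future__ import annotations

from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .crystal import CrystalModel, UnitCell
from .patterson import Map3D

__all__ = [
    "read_hkl",
    "write_hkl",
    "write_ccp4",
    "write_pdb",
    "write_phase_table",
]

_HKL_WIDTH = 28  # 3*4 + 2*8


def write_hkl(obs: pd.DataFrame, path: str | Path) -> None:
    """Write observations (columns h, k, l, I, sigma) as SHELX HKL."""
    with open(path, "w") as fh:
        for h, k, l, i, s in obs[["h", "k", "l", "I", "sigma"]].itertuples(
            index=False
        ):
            fh.write(f"{int(h):4d}{int(k):4d}{int(l):4d}{i:8.2f}{s:8.2f}\n")
        fh.write(f"{0:4d}{0:4d}{0:4d}{0.0:8.2f}{0.0:8.2f}\n")


def read_hkl(path: str | Path) -> pd.DataFrame:
    """Read a SHELX HKL file; stops at the all-zero terminator record.

    Raises ValueError with the offending line number on malformed records.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped.strip():
                continue
            if len(stripped) < _HKL_WIDTH:
                raise ValueError(
                    f"{path}:{lineno}: record has width {len(stripped)}, "
                    f"expected {_HKL_WIDTH} (3I4, 2F8.2)"
                )
            try:
                h = int(stripped[0:4])
                k = int(stripped[4:8])
                l = int(stripped[8:12])
                i = float(stripped[12:20])
                s = float(stripped[20:28])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparsable record: {exc}") from None
            if h == 0 and k == 0 and l == 0:
                break
            rows.append((h, k, l, i, s))
    return pd.DataFrame(rows, columns=["h", "k", "l", "I", "sigma"])


def write_ccp4(map3d: Map3D, path: str | Path) -> None:
    """Write a σ-scaled map in CCP4/MRC format (P1 header; the grid itself
    carries the symmetry)."""
    grid = gemmi.FloatGrid(*map3d.shape)
    grid.set_unit_cell(
        gemmi.UnitCell(map3d.cell.a, map3d.cell.b, map3d.cell.c, 90, 90, 90)
    )
    grid.spacegroup = gemmi.SpaceGroup("P 1")
    arr = np.ascontiguousarray(map3d.values, dtype=np.float32)
    np.asarray(grid)[:] = arr
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header(2, True)
    ccp4.write_ccp4_map(str(path))


_ELEMENT_OF = {
    "H": "H", "D": "D", "C": "C", "N": "N", "O": "O", "S": "S", "P": "P",
    "Cd113": "Cd", "Sm149": "Sm", "Eu151": "Eu", "Gd157": "Gd",
}


def write_pdb(model: CrystalModel, path: str | Path) -> None:
    """Write the asymmetric-unit atoms as minimal PDB coordinates."""
    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(
        model.cell.a, model.cell.b, model.cell.c, 90, 90, 90
    )
    st.spacegroup_hm = "P 21 21 21"
    gmodel = gemmi.Model("1")
    chain = gemmi.Chain("A")
    res = gemmi.Residue()
    res.name = "TOY"
    res.seqid = gemmi.SeqId(1, " ")
    for i, atom in enumerate(model.atoms):
        a = gemmi.Atom()
        elem = _ELEMENT_OF.get(atom.isotope.label, "C")
        a.name = f"{elem}{i % 100}"
        a.element = gemmi.Element(elem)
        cart = model.cell.orthogonalize(np.asarray(atom.xyz))
        a.pos = gemmi.Position(*cart)
        a.occ = atom.occupancy
        a.b_iso = atom.b_iso
        res.add_atom(a)
    chain.add_residue(res)
    gmodel.add_chain(chain)
    st.add_model(gmodel)
    st.setup_entities()
    st.write_pdb(str(path))


def write_phase_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a phase set as a whitespace-aligned text table (h k l F phi fom)."""
    with open(path, "w") as fh:
        fh.write(f"{'h':>4} {'k':>4} {'l':>4} {'F':>10} {'phi':>8} {'fom':>6}\n")
        for h, k, l, f, phi, fom in table[
            ["h", "k", "l", "F", "phi", "fom"]
        ].itertuples(index=False):
            fh.write(
                f"{int(h):4d} {int(k):4d} {int(l):4d} {f:10.3f} {phi:8.4f} {fom:6.3f}\n"
            )
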