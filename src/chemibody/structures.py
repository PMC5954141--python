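"""Macromolecular structure I/O and geometric primitives.

Reads PDB/mmCIF files into a light chain/residue/atom model and provides
the measurements that conjugation-site selection and rotamer comparison
consume: Shrake-Rupley solvent-accessible surface area, heavy-atom contact
maps, and signed torsion angles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from ._constants import GXG_REFERENCE_AREA, VDW_RADII

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "SASAResult",
    "ContactTable",
    "DihedralDelta",
    "read_structure",
    "write_pdb",
    "compute_sasa",
    "contact_map",
    "dihedral_angle",
    "compare_rotamer",
    "virtual_cbeta",
]


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray  # Cartesian, Å
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if not np.all(np.isfinite(self.pos)):
            raise ValueError(f"non-finite coordinates for atom {self.name!r}")
        if self.element.upper() not in VDW_RADII:
            raise ValueError(
                f"unknown element {self.element!r} for atom {self.name!r}; "
                f"no van-der-Waals radius available"
            )


@dataclass
class Residue:
    name: str  # 3-letter code
    seqid: int  # author numbering, kept verbatim from the source file
    icode: str = ""
    hetero: bool = False
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[int, str]:
        return (self.seqid, self.icode)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.name}{self.seqid} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def heavy_coords(self) -> np.ndarray:
        pts = [a.pos for a in self.atoms if a.element.upper() != "H"]
        return np.array(pts) if pts else np.empty((0, 3))


@dataclass
class Structure:
    """Chains of ordered residues; the geometric substrate for site scoring."""

    chains: dict[str, list[Residue]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, residues in self.chains.items():
            keys = [r.key for r in residues]
            if len(keys) != len(set(keys)):
                raise ValueError(f"duplicate residue identifiers in chain {cid!r}")

    def residues(self, chain_ids=None, hetero=None):
        """Iterate residues, optionally filtered by chain and hetero flag."""
        for cid, residues in self.chains.items():
            if chain_ids is not None and cid not in chain_ids:
                continue
            for r in residues:
                if hetero is not None and r.hetero != hetero:
                    continue
                yield cid, r

    def select(self, chain_ids=None, resname=None, hetero=None) -> list[tuple[str, Residue]]:
        out = []
        for cid, r in self.residues(chain_ids=chain_ids, hetero=hetero):
            if resname is not None and r.name != resname:
                continue
            out.append((cid, r))
        return out

    def all_atoms(self) -> list[tuple[str, Residue, Atom]]:
        return [(cid, r, a) for cid, rs in self.chains.items() for r in rs for a in r.atoms]


# ---------------------------------------------------------------------------
# I/O


def _pick_altloc(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Resolve alternate locations: keep the highest-occupancy conformer,
    ties broken by first encountered."""
    by_name: dict[str, gemmi.Atom] = {}
    for a in res:
        prev = by_name.get(a.name)
        if prev is None or a.occ > prev.occ:
            by_name[a.name] = a
    return list(by_name.values())


def read_structure(path, fmt: str | None = None) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    The dialect is inferred from the file suffix unless ``fmt`` ("pdb" or
    "mmcif") is given. Only the first model is kept. Author residue
    numbering is preserved verbatim.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    try:
        if fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "pdb":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        else:
            raise ValueError(f"unknown format {fmt!r}; expected 'pdb' or 'mmcif'")
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"could not parse {path} as {fmt}: {exc}") from exc

    st.setup_entities()
    chains: dict[str, list[Residue]] = {}
    model = st[0]
    for chain in model:
        residues = []
        for res in chain:
            atoms = []
            for a in _pick_altloc(res):
                el = a.element.name if a.element.name else "?"
                if el.upper() not in VDW_RADII:
                    raise ValueError(
                        f"unknown element {el!r} for atom {a.name!r} in "
                        f"{res.name}{res.seqid.num} (chain {chain.name})"
                    )
                atoms.append(
                    Atom(
                        name=a.name,
                        element=el,
                        pos=np.array([a.pos.x, a.pos.y, a.pos.z]),
                        occupancy=a.occ,
                        b_factor=a.b_iso,
                    )
                )
            residues.append(
                Residue(
                    name=res.name,
                    seqid=res.seqid.num,
                    icode=res.seqid.icode.strip(),
                    hetero=res.het_flag == "H",
                    atoms=atoms,
                )
            )
        if chain.name in chains:
            chains[chain.name].extend(residues)
        else:
            chains[chain.name] = residues
    return Structure(chains=chains)


def write_pdb(s: Structure, path) -> None:
    """Write a :class:`Structure` as a PDB file (fixture/export use)."""
    st = gemmi.Structure()
    st.name = "chemibody"
    model = gemmi.Model("1")
    for cid, residues in s.chains.items():
        chain = gemmi.Chain(cid)
        for r in residues:
            gr = gemmi.Residue()
            gr.name = r.name
            gr.seqid = gemmi.SeqId(r.seqid, r.icode if r.icode else " ")
            gr.het_flag = "H" if r.hetero else "A"
            for a in r.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.pos)
                ga.occ = a.occupancy
                ga.b_iso = a.b_factor
                gr.add_atom(ga)
            chain.add_residue(gr)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    Path(path).write_text(doc)


# ---------------------------------------------------------------------------
# SASA


@dataclass
class SASAResult:
    """Shrake-Rupley surface areas with per-residue roll-ups."""

    per_atom: pd.DataFrame  # chain, resnum, icode, resname, atom, area
    per_residue: pd.DataFrame  # chain, resnum, icode, resname, area, rel_exposure
    probe_radius: float
    point_count: int

    def atom_area(self, chain: str, resnum: int, atom: str) -> float:
        df = self.per_atom
        m = (df["chain"] == chain) & (df["resnum"] == resnum) & (df["atom"] == atom)
        return float(df.loc[m, "area"].iloc[0])

    def residue_area(self, chain: str, resnum: int) -> float:
        df = self.per_residue
        m = (df["chain"] == chain) & (df["resnum"] == resnum)
        return float(df.loc[m, "area"].iloc[0])

    def relative_exposure(self, chain: str, resnum: int) -> float:
        df = self.per_residue
        m = (df["chain"] == chain) & (df["resnum"] == resnum)
        return float(df.loc[m, "rel_exposure"].iloc[0])

    def to_csv(self, path) -> None:
        self.per_residue.to_csv(path, index=False)


def compute_sasa(s: Structure, probe: float = 1.4, points: int = 960) -> SASAResult:
    """Solvent-accessible surface area of every atom (Shrake-Rupley).

    Numeric integration over ``points`` deterministic (Fibonacci-lattice)
    sphere points per atom with the bundled Bondi radii and a water-sized
    probe. Relative per-residue exposure divides by the extended
    Gly-X-Gly free-residue area; residues without a reference (ligands,
    non-standard names) get NaN.
    """
    import biotite.structure as struc

    records = s.all_atoms()
    if not records:
        raise ValueError("empty structure")
    n = len(records)
    arr = struc.AtomArray(n)
    radii = np.empty(n)
    for i, (cid, r, a) in enumerate(records):
        arr.coord[i] = a.pos
        arr.element[i] = a.element.upper()
        radii[i] = VDW_RADII[a.element.upper()]
    areas = struc.sasa(
        arr,
        probe_radius=probe,
        point_number=points,
        vdw_radii=radii,
        ignore_ions=False,
    )
    areas = np.nan_to_num(np.asarray(areas, dtype=float), nan=0.0)

    per_atom = pd.DataFrame(
        {
            "chain": [cid for cid, r, a in records],
            "resnum": [r.seqid for cid, r, a in records],
            "icode": [r.icode for cid, r, a in records],
            "resname": [r.name for cid, r, a in records],
            "atom": [a.name for cid, r, a in records],
            "area": areas,
        }
    )
    grouped = (
        per_atom.groupby(["chain", "resnum", "icode", "resname"], sort=False)["area"]
        .sum()
        .reset_index()
    )
    grouped["rel_exposure"] = [
        row.area / GXG_REFERENCE_AREA[row.resname]
        if row.resname in GXG_REFERENCE_AREA
        else float("nan")
        for row in grouped.itertuples()
    ]
    return SASAResult(
        per_atom=per_atom,
        per_residue=grouped,
        probe_radius=probe,
        point_count=points,
    )


# ---------------------------------------------------------------------------
# Contacts


@dataclass
class ContactTable:
    """Per-residue heavy-atom contact counts of group A against group B."""

    table: pd.DataFrame  # chain, resnum, resname, n_contacts, min_distance
    cutoff: float

    def contacts(self, chain: str, resnum: int) -> int:
        df = self.table
        m = (df["chain"] == chain) & (df["resnum"] == resnum)
        return int(df.loc[m, "n_contacts"].iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def contact_map(s: Structure, group_a, group_b, cutoff: float = 4.5) -> ContactTable:
    """Count heavy-atom pairs within ``cutoff`` Å from each residue of
    ``group_a`` to all of ``group_b`` (lists of ``(chain_id, Residue)``)."""
    from scipy.spatial import cKDTree

    if not group_a or not group_b:
        raise ValueError("contact groups must be non-empty")
    keys_a = {(cid, r.key) for cid, r in group_a}
    keys_b = {(cid, r.key) for cid, r in group_b}
    if keys_a & keys_b:
        raise ValueError("contact groups must be disjoint")

    b_coords = np.vstack([r.heavy_coords() for _, r in group_b if len(r.heavy_coords())])
    tree = cKDTree(b_coords)
    rows = []
    for cid, r in group_a:
        pts = r.heavy_coords()
        if len(pts) == 0:
            rows.append((cid, r.seqid, r.name, 0, float("inf")))
            continue
        counts = tree.query_ball_point(pts, cutoff)
        n = sum(len(c) for c in counts)
        dmin, _ = tree.query(pts, k=1)
        rows.append((cid, r.seqid, r.name, int(n), float(np.min(dmin))))
    df = pd.DataFrame(rows, columns=["chain", "resnum", "resname", "n_contacts", "min_distance"])
    return ContactTable(table=df, cutoff=cutoff)


# ---------------------------------------------------------------------------
# Dihedrals and rotamers


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed torsion angle in degrees, IUPAC convention, range (-180, 180].

    Looking down the p2->p3 axis, a clockwise rotation of p4 relative to
    p1 is positive.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if np.linalg.norm(b2) < 1e-9:
        raise ValueError("undefined torsion: central atoms coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise ValueError("undefined torsion: collinear points")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def circular_difference(a: float, b: float) -> float:
    """Smallest absolute angular difference in degrees, in [0, 180]."""
    d = abs(a - b) % 360.0
    return 360.0 - d if d > 180.0 else d


def virtual_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal Cβ position built from backbone N/Cα/C geometry.

    Used as the side-chain surrogate for glycine (framework glycines are
    legitimate conjugation-site candidates) and wherever a Cβ is missing.
    """
    n, ca, c = (np.asarray(p, dtype=float) for p in (n, ca, c))
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * cc + ca


def _residue_cbeta(r: Residue) -> np.ndarray:
    if r.has_atom("CB"):
        return r.atom("CB").pos
    for nm in ("N", "CA", "C"):
        if not r.has_atom(nm):
            raise ValueError(
                f"residue {r.name}{r.seqid}: no CB and missing backbone atom {nm} "
                f"needed to build a surrogate"
            )
    return virtual_cbeta(r.atom("N").pos, r.atom("CA").pos, r.atom("C").pos)


@dataclass
class DihedralDelta:
    """Per-angle circular differences between two residues' dihedrals."""

    angles_a: dict[str, float]
    angles_b: dict[str, float]
    deltas: dict[str, float]
    same_rotamer: bool
    threshold: float


def _backbone_dihedrals(r: Residue, prev_res: Residue | None, next_res: Residue | None):
    out = {}
    need = [nm for nm in ("N", "CA", "C") if not r.has_atom(nm)]
    if need:
        raise ValueError(f"residue {r.name}{r.seqid} missing backbone atoms: {need}")
    n, ca, c = r.atom("N").pos, r.atom("CA").pos, r.atom("C").pos
    if prev_res is not None:
        if not prev_res.has_atom("C"):
            raise ValueError(f"preceding residue of {r.name}{r.seqid} missing C")
        out["phi"] = dihedral_angle(prev_res.atom("C").pos, n, ca, c)
    if next_res is not None:
        if not next_res.has_atom("N"):
            raise ValueError(f"following residue of {r.name}{r.seqid} missing N")
        out["psi"] = dihedral_angle(n, ca, c, next_res.atom("N").pos)
    cb = _residue_cbeta(r)
    # N-Cα-Cβ orientation relative to the backbone carbonyl: captures the
    # Cα-Cβ vector rotamer state even when no χ1 heavy atom exists.
    out["ca_cb"] = dihedral_angle(c, n, ca, cb)
    sidechain_g = None
    for nm in ("SG", "OG", "OG1", "CG", "CG1", "SD"):
        if r.has_atom(nm):
            sidechain_g = r.atom(nm).pos
            break
    if sidechain_g is not None:
        out["chi1"] = dihedral_angle(n, ca, cb, sidechain_g)
    return out


def compare_rotamer(
    res_a: Residue,
    res_b: Residue,
    prev_a: Residue | None = None,
    next_a: Residue | None = None,
    prev_b: Residue | None = None,
    next_b: Residue | None = None,
    threshold: float = 40.0,
) -> DihedralDelta:
    """Compare backbone (phi/psi) and side-chain (Cα-Cβ, χ1) dihedrals of
    two residues; they are called the same rotamer when every shared angle
    agrees within ``threshold`` degrees (circular)."""
    ang_a = _backbone_dihedrals(res_a, prev_a, next_a)
    ang_b = _backbone_dihedrals(res_b, prev_b, next_b)
    shared = sorted(set(ang_a) & set(ang_b))
    if not shared:
        raise ValueError("no comparable dihedrals between the two residues")
    deltas = {k: circular_difference(ang_a[k], ang_b[k]) for k in shared}
    return DihedralDelta(
        angles_a=ang_a,
        angles_b=ang_b,
        deltas=deltas,
        same_rotamer=all(d < threshold for d in deltas.values()),
        threshold=threshold,
    )
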