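"""Molecular-graph models of the small-molecule-PEG-thioether conjugate.

Builds the linker species joining a piperazinyl-acetamide warhead head to
a cysteine thioether tail through n ethylene-oxide (PEG) repeats, and
provides the mass-spectrometry bookkeeping (monoisotopic / average mass,
protonated adduct) and a torsion-independent upper bound on how far two
atoms of the graph can be separated.

Chain architecture (head → tail)::

    [acetyl-]piperazine-N'-CH2-C(=O)-NH-CH2CH2-(O-CH2CH2)n-NH-C(=O)-CH2-S(H)

Each PEG unit adds exactly one -CH2CH2O- (2 C, 1 O, 4 H; 44.0262 Da).
The piperazine ring atoms carry the ``head`` anchor tag (the warhead is
held fixed in the bound pose during conformational searches) and the
terminal sulfur carries the ``tail`` tag (the engineered cysteine Sγ).
The full trifluorophenyl warhead can be included instead of the acetyl
cap with ``full_warhead=True``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from ._constants import (
    AVERAGE_MASS,
    IDEAL_ANGLE_SP2,
    IDEAL_ANGLE_SP3,
    IDEAL_BOND_LENGTH,
    MONOISOTOPIC_MASS,
    PROTON_MASS,
)

__all__ = [
    "MolecularGraph",
    "MassResult",
    "build_conjugate_linker",
    "molecular_mass",
    "max_extension",
    "COMPOUND_SMILES",
]

#: Published compounds used for mass checks, encoded from their chemical
#: names. "amide-analog" is the N-methylacetamide warhead analog of
#: sitagliptin; "boc-acid" is the Boc-protected piperazinyl-acetic-acid
#: conjugation intermediate.
COMPOUND_SMILES = {
    "amide-analog": "CNC(=O)CN1CCN(CC1)C(=O)C[C@@H](N)Cc1cc(F)c(F)cc1F",
    "acid-analog": "OC(=O)CN1CCN(CC1)C(=O)C[C@@H](N)Cc1cc(F)c(F)cc1F",
    "boc-acid": "OC(=O)CN1CCN(CC1)C(=O)C[C@@H](NC(=O)OC(C)(C)C)Cc1cc(F)c(F)cc1F",
    "sitagliptin": "N[C@@H](CC(=O)N1CCn2c(nnc2C(F)(F)F)C1)Cc1cc(F)c(F)cc1F",
}

_ACETYL_HEAD = "CC(=O)N1CCN(CC1)CC(=O)NCC"
_WARHEAD_HEAD = "N[C@@H](Cc1cc(F)c(F)cc1F)CC(=O)N1CCN(CC1)CC(=O)NCC"
_PEG_REPEAT = "OCC"
_TAIL = "NC(=O)CS"

_MAX_PEG = 32


@dataclass
class MolecularGraph:
    """An RDKit molecule plus anchor-atom tags and a 3D seed conformer."""

    mol: Chem.Mol
    anchor_tags: dict[str, list[int]] = field(default_factory=dict)
    n_peg: int | None = None

    @property
    def n_atoms(self) -> int:
        return self.mol.GetNumAtoms()

    @property
    def n_heavy_atoms(self) -> int:
        return sum(1 for a in self.mol.GetAtoms() if a.GetAtomicNum() > 1)

    @property
    def formula(self) -> str:
        from rdkit.Chem import rdMolDescriptors

        return rdMolDescriptors.CalcMolFormula(self.mol)

    def rotatable_torsions(self) -> list[tuple[int, int, int, int]]:
        """One heavy-atom torsion quadruple per rotatable non-ring bond."""
        patt = Chem.MolFromSmarts("[!$(*#*)&!D1]-&!@[!$(*#*)&!D1]")
        quads = []
        for i, j in self.mol.GetSubstructMatches(patt):
            ai, aj = self.mol.GetAtomWithIdx(i), self.mol.GetAtomWithIdx(j)
            ni = [b.GetIdx() for b in ai.GetNeighbors() if b.GetIdx() != j and b.GetAtomicNum() > 1]
            nj = [b.GetIdx() for b in aj.GetNeighbors() if b.GetIdx() != i and b.GetAtomicNum() > 1]
            if ni and nj:
                quads.append((min(ni), i, j, min(nj)))
        return quads

    def seed_coords(self) -> np.ndarray:
        if self.mol.GetNumConformers() == 0:
            raise ValueError("graph has no 3D seed conformer")
        return self.mol.GetConformer().GetPositions()

    def to_sdf(self, path, energy: float | None = None) -> None:
        w = Chem.SDWriter(str(path))
        if energy is not None:
            self.mol.SetProp("energy_kcal_mol", f"{energy:.4f}")
        w.write(self.mol)
        w.close()


def build_conjugate_linker(
    n_peg: int,
    full_warhead: bool = False,
    embed_seed: int = 0,
) -> MolecularGraph:
    """Build the conjugate linker graph with ``n_peg`` ethylene-oxide units.

    The default head truncates the warhead to an acetyl-capped piperazine
    (the portion held fixed in the bound pose); ``full_warhead=True``
    includes the trifluorophenyl butanoyl moiety. The returned graph
    carries an MMFF-relaxed 3D seed conformer.
    """
    if n_peg < 0:
        raise ValueError("number of PEG units must be non-negative")
    if n_peg > _MAX_PEG:
        raise ValueError(f"number of PEG units must be <= {_MAX_PEG}")
    head = _WARHEAD_HEAD if full_warhead else _ACETYL_HEAD
    smiles = head + _PEG_REPEAT * n_peg + _TAIL
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:  # pragma: no cover - builder strings are fixed
        raise ValueError("internal builder produced invalid chemistry")
    # piperazine ring in SMARTS match order N,C,C,N,C,C (nitrogens at 0 and 3,
    # matching the frozen chair geometry used for anchor placement)
    match = mol.GetSubstructMatches(Chem.MolFromSmarts("N1CCN(CC1)"))
    if not match:
        raise ValueError("head contains no piperazine ring")
    ring = list(match[0])
    sulfur = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "S"][-1]

    mol = Chem.AddHs(mol)
    if AllChem.EmbedMolecule(mol, randomSeed=embed_seed) != 0:
        AllChem.EmbedMolecule(mol, randomSeed=embed_seed, useRandomCoords=True)
    AllChem.MMFFOptimizeMolecule(mol, maxIters=2000)
    return MolecularGraph(mol=mol, anchor_tags={"head": ring, "tail": [sulfur]}, n_peg=n_peg)


# ---------------------------------------------------------------------------
# Mass bookkeeping


@dataclass
class MassResult:
    formula: str
    monoisotopic: float
    average: float
    mh_plus: float  # [M+H]+ m/z

    composition: dict[str, int] = field(default_factory=dict)


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def _parse_formula(formula: str) -> dict[str, int]:
    comp: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        pos = m.end()
        el = m.group(1)
        comp[el] = comp.get(el, 0) + (int(m.group(2)) if m.group(2) else 1)
    if pos != len(formula.replace("+", "").replace("-", "")):
        # trailing charge markers from RDKit formulas are tolerated
        rest = formula[pos:]
        if rest and not set(rest) <= set("+-0123456789"):
            raise ValueError(f"cannot parse formula {formula!r}: trailing {rest!r}")
    return comp


def molecular_mass(g) -> MassResult:
    """Monoisotopic and average mass plus protonated adduct m/z.

    Accepts a :class:`MolecularGraph`, an RDKit Mol, or a molecular
    formula string. Monoisotopic mass sums the most-abundant-isotope
    masses from the bundled table; average mass uses standard atomic
    weights; [M+H]+ adds one proton (1.00728 Da).
    """
    if isinstance(g, MolecularGraph):
        comp = _composition_from_mol(g.mol)
        formula = g.formula
    elif isinstance(g, Chem.Mol):
        comp = _composition_from_mol(g)
        from rdkit.Chem import rdMolDescriptors

        formula = rdMolDescriptors.CalcMolFormula(g)
    else:
        formula = str(g)
        comp = _parse_formula(formula)

    mono = 0.0
    avg = 0.0
    for el, count in comp.items():
        key = el.upper()
        if key not in MONOISOTOPIC_MASS:
            raise ValueError(f"element {el!r} not in bundled isotope table")
        mono += MONOISOTOPIC_MASS[key] * count
        avg += AVERAGE_MASS[key] * count
    return MassResult(
        formula=formula,
        monoisotopic=mono,
        average=avg,
        mh_plus=mono + PROTON_MASS,
        composition=comp,
    )


def _composition_from_mol(mol: Chem.Mol) -> dict[str, int]:
    comp: dict[str, int] = {}
    for a in mol.GetAtoms():
        el = a.GetSymbol()
        comp[el] = comp.get(el, 0) + 1
        h = a.GetTotalNumHs()
        if h:
            comp["H"] = comp.get("H", 0) + h
    return comp


def mass_after_conjugation(mass_a: float, mass_b: float, leaving_mass: float) -> float:
    """Mass of the coupled product A+B losing one leaving group (e.g. HBr
    for thioether formation, H2O for amide coupling)."""
    return mass_a + mass_b - leaving_mass


# ---------------------------------------------------------------------------
# Extension bound


def _ideal_length(el_a: str, el_b: str, order: float) -> float:
    key = frozenset({el_a.upper(), el_b.upper()})
    if key not in IDEAL_BOND_LENGTH:
        raise ValueError(f"no ideal bond length for pair {el_a}-{el_b}")
    length = IDEAL_BOND_LENGTH[key]
    if order > 1.0:
        length -= 0.10 * (order - 1.0)  # crude multiple-bond contraction
    return length


def max_extension(g: MolecularGraph, a1: int | None = None, a2: int | None = None) -> float:
    """Upper bound (Å) on the a1-a2 distance over all torsions.

    Follows the shortest bond path between the two atoms and lays it out
    as a planar all-trans chain with ideal bond lengths and angles (sp3
    atoms at 111°, sp2 at 120°); with fixed bond lengths and angles no
    torsion assignment can separate the endpoints further than this
    extended arrangement. Defaults to the head-anchor nitrogen nearest
    the tail and the tail sulfur.
    """
    mol = g.mol
    if a1 is None or a2 is None:
        if "head" not in g.anchor_tags or "tail" not in g.anchor_tags:
            raise ValueError("anchor atoms not given and graph carries no anchor tags")
        a2 = g.anchor_tags["tail"][0]
        # head nitrogen with the shortest path to the tail
        a1 = min(
            g.anchor_tags["head"],
            key=lambda i: len(Chem.GetShortestPath(mol, i, a2)),
        )
    path = Chem.GetShortestPath(mol, int(a1), int(a2))
    if not path:
        raise ValueError("anchor atoms are not connected in the molecular graph")
    if len(path) == 1:
        return 0.0

    lengths = []
    for i in range(len(path) - 1):
        b = mol.GetBondBetweenAtoms(path[i], path[i + 1])
        lengths.append(
            _ideal_length(
                mol.GetAtomWithIdx(path[i]).GetSymbol(),
                mol.GetAtomWithIdx(path[i + 1]).GetSymbol(),
                b.GetBondTypeAsDouble(),
            )
        )
    angles = []
    for i in range(1, len(path) - 1):
        atom = mol.GetAtomWithIdx(path[i])
        sp2 = atom.GetHybridization() in (
            Chem.HybridizationType.SP2,
            Chem.HybridizationType.SP,
        )
        angles.append(IDEAL_ANGLE_SP2 if sp2 else IDEAL_ANGLE_SP3)

    # planar all-trans layout: each bond alternates +/- half the exterior angle
    pos = np.zeros((len(path), 2))
    direction = 0.0
    pos[1] = pos[0] + lengths[0] * np.array([np.cos(direction), np.sin(direction)])
    sign = 1.0
    for i in range(1, len(path) - 1):
        exterior = np.radians(180.0 - angles[i - 1])
        direction += sign * exterior
        sign = -sign
        step = lengths[i] * np.array([np.cos(direction), np.sin(direction)])
        pos[i + 1] = pos[i] + step
    return float(np.linalg.norm(pos[-1] - pos[0]))
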