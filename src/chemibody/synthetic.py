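"""Synthetic inputs with known ground truth.

Generates every input the pipeline consumes at desk scale: anchor-pair
geometries at a controlled separation (the design case places the
warhead ~28 Å from the engineered cysteine sulfur), toy
antibody-antigen-ligand complexes with planted exposed / buried /
interface residues, and noisy dose-response and Michaelis-Menten
datasets from known generating parameters. Every generator is a pure
function of its spec and seed, and each dataset is returned together
with its ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .structures import Atom, Residue, Structure, virtual_cbeta
from .assay import DoseResponse, four_pl, michaelis_menten

__all__ = [
    "AnchorSpec",
    "ToyComplexSpec",
    "make_anchor_pair",
    "make_toy_complex",
    "simulate_dose_response",
    "simulate_mm",
]

#: MMFF-equilibrium piperazine chair, centroid at origin, atom order
#: N,C,C,N,C,C matching the head anchor tag order of the linker builder.
PIPERAZINE_CHAIR = np.array(
    [
        (1.4458, 0.3081, 0.0145),
        (0.9370, -0.9845, -0.4499),
        (-0.4308, -1.3218, 0.1736),
        (-1.4820, -0.3101, -0.1053),
        (-0.9179, 1.0607, -0.1591),
        (0.4479, 1.2476, 0.5261),
    ]
)
PIPERAZINE_CHAIR -= PIPERAZINE_CHAIR.mean(axis=0)  # centroid exactly at origin


@dataclass
class AnchorSpec:
    """Fixed-atom geometry for a constrained linker search.

    ``head_coords`` are the six piperazine ring atoms (order matches the
    builder's ``head`` tag); ``tail_coord`` is the cysteine Sγ position.
    ``separation`` is the head-centroid-to-sulfur distance.
    """

    head_coords: np.ndarray
    tail_coord: np.ndarray
    separation: float
    seed: int = 0
    head_elements: tuple = ("N", "C", "C", "N", "C", "C")
    tail_element: str = "S"

    def __post_init__(self) -> None:
        self.head_coords = np.asarray(self.head_coords, dtype=float)
        self.tail_coord = np.asarray(self.tail_coord, dtype=float)
        if self.separation <= 0:
            raise ValueError("anchor separation must be positive")

    @property
    def centroid_distance(self) -> float:
        return float(np.linalg.norm(self.head_coords.mean(axis=0) - self.tail_coord))

    def to_json(self, path) -> None:
        payload = {
            "separation": self.separation,
            "seed": self.seed,
            "atoms": [
                {"element": el, "tag": "head", "xyz": list(map(float, p))}
                for el, p in zip(self.head_elements, self.head_coords)
            ]
            + [
                {
                    "element": self.tail_element,
                    "tag": "tail",
                    "xyz": list(map(float, self.tail_coord)),
                }
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "AnchorSpec":
        with open(path) as fh:
            payload = json.load(fh)
        head = [a["xyz"] for a in payload["atoms"] if a["tag"] == "head"]
        tail = [a["xyz"] for a in payload["atoms"] if a["tag"] == "tail"][0]
        return cls(
            head_coords=np.array(head),
            tail_coord=np.array(tail),
            separation=payload["separation"],
            seed=payload.get("seed", 0),
        )


def make_anchor_pair(separation: float = 28.0, seed: int = 0) -> AnchorSpec:
    """Anchor pair at a controlled centroid separation.

    The piperazine head sits at its ideal chair coordinates with the
    centroid at the origin; the sulfur is placed ``separation`` Å away
    along a direction drawn uniformly on the hemisphere facing the
    linker-bearing ring nitrogen (randomized to avoid axis-aligned
    artifacts, but restricted to the side the linker actually exits — a
    bound pose cannot have the conjugation site behind the rigid
    warhead). Deterministic for a fixed seed. Default separation is the
    28 Å design span.
    """
    if separation <= 0:
        raise ValueError("separation must be positive")
    rng = np.random.default_rng(seed)
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    exit_axis = PIPERAZINE_CHAIR[3] / np.linalg.norm(PIPERAZINE_CHAIR[3])
    if d @ exit_axis < 0:
        d = -d  # reflect into the exit hemisphere; stays uniform there
    return AnchorSpec(
        head_coords=PIPERAZINE_CHAIR.copy(),
        tail_coord=separation * d,
        separation=float(separation),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Toy complex


@dataclass
class ToyComplexSpec:
    """Layout of a planted-truth antibody-antigen-ligand complex."""

    n_exposed: int = 1
    n_buried: int = 1
    n_interface: int = 1
    n_filler: int = 6
    pocket_depth: float = 15.0  # good-site Cβ to ligand attachment atom, Å
    seed: int = 0

    def __post_init__(self) -> None:
        for v in (self.n_exposed, self.n_buried, self.n_interface, self.n_filler):
            if v < 0:
                raise ValueError("residue counts must be non-negative")
        if self.pocket_depth <= 0:
            raise ValueError("pocket depth must be positive")


_TEMPLATE = {
    "N": np.array([-1.458, 0.0, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([0.551, 1.420, 0.0]),
    "O": np.array([1.651, 1.950, 0.0]),
}


def _rotation_to(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector u onto unit vector v."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    c = float(u @ v)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # opposite: rotate 180° about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = np.cross(u, perp)
        axis /= np.linalg.norm(axis)
        k = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        return np.eye(3) + 2.0 * (k @ k)
    axis /= s
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    ang = np.arctan2(s, c)
    return np.eye(3) + np.sin(ang) * k + (1.0 - np.cos(ang)) * (k @ k)


def _residue(name, seqid, ca_pos, cb_direction) -> Residue:
    """Place the ideal backbone template at ``ca_pos`` with the Cβ
    pointing along ``cb_direction``."""
    cb_local = virtual_cbeta(_TEMPLATE["N"], _TEMPLATE["CA"], _TEMPLATE["C"])
    rot = _rotation_to(cb_local, np.asarray(cb_direction, dtype=float))
    atoms = []
    for nm, p in _TEMPLATE.items():
        el = nm[0]
        atoms.append(Atom(name=nm, element=el, pos=rot @ p + ca_pos))
    atoms.append(Atom(name="CB", element="C", pos=rot @ cb_local + ca_pos))
    return Residue(name=name, seqid=seqid, atoms=atoms)


def _fibonacci_sphere(n: int, radius: float, center: np.ndarray) -> np.ndarray:
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    pts = np.stack([r * np.cos(phi * i), r * np.sin(phi * i), z], axis=1)
    return center + radius * pts


def make_toy_complex(spec: ToyComplexSpec | None = None):
    """Build a toy complex with planted residue classes.

    Returns ``(Structure, truth)`` where ``truth`` is a DataFrame with
    one row per antibody residue giving its planted label: ``good``
    residues satisfy all four conjugation-site criteria by construction,
    ``buried`` residues sit inside an occluding shell, ``interface``
    residues have antigen heavy atoms planted at contact range, and
    ``filler`` residues are exposed but point away from the ligand.
    Chains: L = antibody, A = antigen, B = occluding shell, X = ligand.
    """
    import pandas as pd

    spec = spec or ToyComplexSpec()
    rng = np.random.default_rng(spec.seed)
    lig_attach = np.array([6.0 + 1.5 + spec.pocket_depth, 0.0, 0.0])

    ab: list[Residue] = []
    truth_rows = []
    seq = 1

    # good sites: on the +x face, Cβ aimed at the ligand attachment atom
    for k in range(spec.n_exposed):
        ca = np.array([6.0, 7.0 * k - 3.5 * (spec.n_exposed - 1), 0.0])
        ab.append(_residue("SER", seq, ca, lig_attach - ca))
        truth_rows.append(("L", seq, "good"))
        seq += 1

    # interface residues: +y face, antigen atoms planted at contact range
    interface_cbs = []
    for k in range(spec.n_interface):
        ca = np.array([7.0 * k - 3.5 * (spec.n_interface - 1), 11.0, 0.0])
        r = _residue("ASN", seq, ca, np.array([0.0, 1.0, 0.0]))
        ab.append(r)
        interface_cbs.append(r.atom("CB").pos)
        truth_rows.append(("L", seq, "interface"))
        seq += 1

    # buried residues: enclosed by an occluding shell
    shell_centers = []
    for k in range(spec.n_buried):
        ca = np.array([-14.0 - 12.0 * k, 0.0, 0.0])
        ab.append(_residue("ALA", seq, ca, np.array([0.0, 0.0, 1.0])))
        shell_centers.append(ca)
        truth_rows.append(("L", seq, "buried"))
        seq += 1

    # filler: exposed but side chain points away from the ligand
    for k in range(spec.n_filler):
        ang = np.pi * (0.3 + 0.8 * k / max(1, spec.n_filler - 1))
        ca = np.array([0.0, -10.0 * np.cos(ang), -4.0 - 10.0 * abs(np.sin(ang))])
        ab.append(_residue("ALA", seq, ca, np.array([-1.0, 0.0, 0.0])))
        truth_rows.append(("L", seq, "filler"))
        seq += 1

    chains: dict[str, list[Residue]] = {"L": ab}

    # occluding shells (chain B)
    shell: list[Residue] = []
    snum = 1
    for center in shell_centers:
        for p in _fibonacci_sphere(110, 5.2, center + np.array([0.4, 0.0, 0.5])):
            shell.append(
                Residue(name="UNK", seqid=snum, hetero=True,
                        atoms=[Atom(name="C", element="C", pos=p)])
            )
            snum += 1
    if shell:
        chains["B"] = shell

    # antigen (chain A): pocket ring behind the ligand + planted contacts
    antigen: list[Residue] = []
    anum = 1
    ring_center = lig_attach + np.array([4.0, 0.0, 0.0])
    for k in range(6):
        ang = 2 * np.pi * k / 6
        p = ring_center + 5.0 * np.array([0.0, np.cos(ang), np.sin(ang)])
        antigen.append(
            Residue(name="GLY", seqid=anum,
                    atoms=[Atom(name="CA", element="C", pos=p)])
        )
        anum += 1
    for cb in interface_cbs:
        for j in range(4):
            ang = 2 * np.pi * j / 4
            p = cb + np.array([0.0, 3.5, 0.0]) + 0.3 * np.array(
                [np.cos(ang), 0.0, np.sin(ang)]
            )
            antigen.append(
                Residue(name="GLY", seqid=anum,
                        atoms=[Atom(name="CA", element="C", pos=p)])
            )
            anum += 1
    chains["A"] = antigen

    # ligand (chain X, hetero)
    lig = Residue(
        name="LIG", seqid=1, hetero=True,
        atoms=[
            Atom(name="C1", element="C", pos=lig_attach),
            Atom(name="C2", element="C", pos=lig_attach + np.array([1.5, 0.0, 0.0])),
            Atom(name="N1", element="N", pos=lig_attach + np.array([2.2, 1.2, 0.0])),
        ],
    )
    chains["X"] = [lig]

    truth = pd.DataFrame(truth_rows, columns=["chain", "resnum", "label"])
    return Structure(chains=chains), truth


# ---------------------------------------------------------------------------
# Assay simulators


def simulate_dose_response(
    ic50_nM: float,
    hill: float = 1.0,
    top: float = 100.0,
    bottom: float = 0.0,
    doses_nM=None,
    cv: float = 0.05,
    replicates: int = 3,
    seed: int = 0,
) -> DoseResponse:
    """Triplicate (by default) POC readings from a 4PL curve with
    multiplicative Gaussian noise: response = 4PL(dose) * (1 + eps),
    eps ~ N(0, cv). Fluorescence-assay error scales with signal, hence
    the multiplicative model. Default panel: 12-point half-log dilution
    bracketing the IC50. Truth is recorded on the result.
    """
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if doses_nM is None:
        doses_nM = ic50_nM * 10.0 ** ((np.arange(12) - 5.5) / 2.0)
    doses_nM = np.asarray(doses_nM, dtype=float)
    if np.any(doses_nM <= 0):
        raise ValueError("doses must be positive")
    rng = np.random.default_rng(seed)
    conc = np.repeat(doses_nM, replicates)
    ideal = four_pl(conc, bottom, top, ic50_nM, hill)
    resp = ideal * (1.0 + rng.normal(0.0, cv, size=conc.shape)) if cv > 0 else ideal
    return DoseResponse(
        conc_nM=conc,
        response=resp,
        replicate=np.tile(np.arange(replicates), len(doses_nM)),
        metadata={"cv": cv, "replicates": replicates, "seed": seed},
        truth={"ic50_nM": ic50_nM, "hill": hill, "top": top, "bottom": bottom},
    )


def simulate_mm(
    km_uM: float,
    vmax: float,
    s_uM=None,
    cv: float = 0.05,
    replicates: int = 3,
    seed: int = 0,
):
    """Michaelis-Menten velocities on a 2-fold substrate ladder
    (default 0.5-128 µM) with multiplicative Gaussian noise.

    Returns ``(S, v, truth)``.
    """
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if s_uM is None:
        s_uM = 0.5 * 2.0 ** np.arange(9)  # 0.5 .. 128
    s_uM = np.asarray(s_uM, dtype=float)
    rng = np.random.default_rng(seed)
    s = np.repeat(s_uM, replicates)
    v = michaelis_menten(s, vmax, km_uM)
    if cv > 0:
        v = v * (1.0 + rng.normal(0.0, cv, size=s.shape))
    return s, v, {"km_uM": km_uM, "vmax": vmax}
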