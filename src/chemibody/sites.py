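"""Cysteine-conjugation site selection on an antibody-antigen-ligand complex.

Ranks antibody residues by four structural criteria: solvent exposure,
minimal antigen contact, proximity of the side chain to the ligand
attachment atom, and orientation of the Cα→Cβ vector toward the ligand
pocket. Thresholds are package defaults, individually toggleable, and
user-overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structures import (
    Structure,
    compute_sasa,
    contact_map,
    _residue_cbeta,
)

__all__ = ["SiteCriteria", "SiteScore", "pocket_direction", "score_sites"]

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


@dataclass
class SiteCriteria:
    """Thresholds for the four conjugation-site criteria.

    Each criterion can be disabled; disabled criteria always pass.
    Defaults admit well-exposed, non-interface residues whose side chain
    points at a ligand within ~30 Å (spanning the ~28 Å design case).
    """

    min_rel_exposure: float = 0.30
    max_antigen_contacts: int = 2
    max_distance: float = 30.0  # Cβ → ligand attachment atom, Å
    max_angle: float = 90.0  # Cα→Cβ vs Cβ→attachment atom, degrees
    contact_cutoff: float = 4.5
    use_exposure: bool = True
    use_contacts: bool = True
    use_distance: bool = True
    use_angle: bool = True
    weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.max_angle > 180.0 or self.max_angle <= 0:
            raise ValueError("angle threshold must be in (0, 180]")
        for v in (self.min_rel_exposure, self.max_distance, self.contact_cutoff):
            if not np.isfinite(v):
                raise ValueError("criteria thresholds must be finite")


@dataclass
class SiteScore:
    chain: str
    resnum: int
    resname: str
    rel_exposure: float
    antigen_contacts: int
    distance: float
    angle: float
    passes: dict = field(default_factory=dict)
    pass_all: bool = False
    score: float = float("nan")
    flags: list = field(default_factory=list)


def pocket_direction(s: Structure, ligand, attachment_atom: str, origin=None):
    """Target point and unit direction toward the ligand attachment atom.

    ``ligand`` is a selection (list of ``(chain, Residue)``); the named
    atom of its first residue is the target. When ``origin`` is given the
    returned direction is the unit vector origin → target (translation
    invariant); otherwise only the target point is meaningful and the
    direction is ``None``.
    """
    if not ligand:
        raise ValueError("empty ligand selection")
    target = None
    for _, res in ligand:
        if res.has_atom(attachment_atom):
            target = res.atom(attachment_atom).pos
            break
    if target is None:
        raise ValueError(f"ligand has no atom named {attachment_atom!r}")
    if origin is None:
        return target, None
    origin = np.asarray(origin, dtype=float)
    v = target - origin
    nv = np.linalg.norm(v)
    if nv < 1e-9:
        raise ValueError("origin coincides with the attachment atom")
    return target, v / nv


def score_sites(
    s: Structure,
    antibody_chains,
    antigen_chains,
    ligand=None,
    attachment_atom: str | None = None,
    criteria: SiteCriteria | None = None,
) -> list[SiteScore]:
    """Score every antibody residue against the four site criteria.

    Returns all residues (measured quantities reported even for failures),
    candidates first, ordered by composite score; ties broken by residue
    number ascending. The composite is a weighted sum of min-max
    normalized quantities with exposure ascending and contacts, distance,
    and angle descending.
    """
    criteria = criteria or SiteCriteria()
    antibody_chains = set(antibody_chains)
    antigen_chains = set(antigen_chains)

    target = None
    if ligand:
        target, _ = pocket_direction(s, ligand, attachment_atom or "C1")
    elif criteria.use_distance or criteria.use_angle:
        raise ValueError(
            "no ligand given: disable the distance and orientation criteria "
            "or provide a ligand selection"
        )

    sasa = compute_sasa(s)
    ab_residues = [
        (cid, r)
        for cid, r in s.residues(chain_ids=antibody_chains, hetero=False)
        if r.name in AMINO_ACIDS
    ]
    if not ab_residues:
        raise ValueError("no amino-acid residues found in the antibody chains")
    ag_residues = list(s.residues(chain_ids=antigen_chains, hetero=False))
    contacts = None
    if ag_residues:
        contacts = contact_map(s, ab_residues, ag_residues, cutoff=criteria.contact_cutoff)

    scores: list[SiteScore] = []
    for cid, r in ab_residues:
        rel = sasa.relative_exposure(cid, r.seqid)
        ncon = contacts.contacts(cid, r.seqid) if contacts is not None else 0
        dist = float("nan")
        angle = float("nan")
        flags = []
        try:
            cb = _residue_cbeta(r)
            ca = r.atom("CA").pos
            if target is not None:
                v_cb = cb - ca
                v_t = target - cb
                dist = float(np.linalg.norm(v_t))
                denom = np.linalg.norm(v_cb) * np.linalg.norm(v_t)
                if denom < 1e-9:
                    angle = 0.0
                else:
                    angle = float(
                        np.degrees(np.arccos(np.clip(v_cb @ v_t / denom, -1.0, 1.0)))
                    )
        except (ValueError, KeyError) as exc:
            flags.append(f"geometry: {exc}")
        if r.name == "CYS":
            flags.append("native cysteine: thiol clash risk")
        if r.name == "GLY":
            flags.append("glycine: surrogate C-beta used")

        passes = {
            "exposure": (not criteria.use_exposure)
            or (np.isfinite(rel) and rel >= criteria.min_rel_exposure),
            "contacts": (not criteria.use_contacts) or ncon <= criteria.max_antigen_contacts,
            "distance": (not criteria.use_distance)
            or (np.isfinite(dist) and dist <= criteria.max_distance),
            "angle": (not criteria.use_angle)
            or (np.isfinite(angle) and angle <= criteria.max_angle),
        }
        scores.append(
            SiteScore(
                chain=cid,
                resnum=r.seqid,
                resname=r.name,
                rel_exposure=float(rel) if np.isfinite(rel) else float("nan"),
                antigen_contacts=ncon,
                distance=dist,
                angle=angle,
                passes=passes,
                pass_all=all(passes.values()),
                flags=flags,
            )
        )

    _composite(scores, criteria)
    scores.sort(key=lambda sc: (not sc.pass_all, -sc.score, sc.resnum))
    return scores


def _composite(scores: list[SiteScore], criteria: SiteCriteria) -> None:
    """Weighted normalized sum: exposure up; contacts, distance, angle down."""

    def norm(vals, ascending):
        vals = np.asarray(vals, dtype=float)
        finite = vals[np.isfinite(vals)]
        if len(finite) == 0:
            return np.zeros_like(vals)
        lo, hi = finite.min(), finite.max()
        span = hi - lo if hi > lo else 1.0
        out = (vals - lo) / span
        out[~np.isfinite(vals)] = 0.0
        return out if ascending else 1.0 - out

    w = criteria.weights
    e = norm([sc.rel_exposure for sc in scores], ascending=True)
    c = norm([sc.antigen_contacts for sc in scores], ascending=False)
    d = norm([sc.distance for sc in scores], ascending=False)
    a = norm([sc.angle for sc in scores], ascending=False)
    total = sum(w)
    for i, sc in enumerate(scores):
        sc.score = float((w[0] * e[i] + w[1] * c[i] + w[2] * d[i] + w[3] * a[i]) / total)


def scores_to_frame(scores: list[SiteScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chain": [s.chain for s in scores],
            "resnum": [s.resnum for s in scores],
            "resname": [s.resname for s in scores],
            "rel_exposure": [s.rel_exposure for s in scores],
            "contacts": [s.antigen_contacts for s in scores],
            "distance_A": [s.distance for s in scores],
            "angle_deg": [s.angle for s in scores],
            "pass_all": [s.pass_all for s in scores],
            "score": [s.score for s in scores],
        }
    )
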