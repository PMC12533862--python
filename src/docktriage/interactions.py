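"""Key-residue interaction analysis of a docked pose.

A binding-site residue "engages" a pose when any of its heavy atoms lies
within the close-contact cutoff (5 Å by convention for this screen) of a
ligand heavy atom, or when it hydrogen-bonds to the ligand. The triage
quantities are a weighted score over a user-supplied key-residue list and the
weight-free proportion of that list engaged (the key-residue overlap).

Hydrogen-bond geometry is configurable because docked structures vary in
whether hydrogens are present: with explicit hydrogens the donor–H···acceptor
distance/angle test applies; without them the criterion degrades to a
heavy-atom donor–acceptor distance when ``heavy_atom_fallback`` is enabled.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .struct_io import MolecularGraph, ReceptorStructure, ResidueKey

__all__ = [
    "KeyResidueSpec",
    "HBondCriteria",
    "HydrogenBond",
    "InteractionReport",
    "find_close_contacts",
    "detect_hbonds",
    "key_residue_score",
    "score_pose",
    "default_key_residues",
]

_CONTEXT_MARGIN = 2.0  # Å beyond the cutoff still reported for context
_DONOR_ACCEPTOR_ELEMENTS = {"N", "O"}  # S excluded by default
_COVALENT_H_MAX = 1.25  # Å; H within this of N/O counts as bonded (receptor side)


@dataclass(frozen=True)
class KeyResidueSpec:
    """Ordered key-residue list plus the close-contact cutoff in Å.

    Entries are (chain, residue number, residue name); chain ``None`` matches
    any chain (key residues are usually quoted without one).
    """

    residues: tuple[tuple[str | None, int, str], ...]
    contact_cutoff: float = 5.0

    def __post_init__(self):
        if not self.residues:
            raise ValueError("key-residue list must be non-empty")
        if self.contact_cutoff <= 0:
            raise ValueError("contact cutoff must be positive")

    def matches(self, entry: tuple[str | None, int, str], key: ResidueKey) -> bool:
        chain, number, name = entry
        if chain is not None and chain != key.chain:
            return False
        return number == key.number and name.upper() == key.name.upper()


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition (distances Å, angle degrees)."""

    max_da_distance: float = 3.5
    max_ha_distance: float = 2.5
    min_dha_angle: float = 120.0
    heavy_atom_fallback: bool = True

    def __post_init__(self):
        if self.max_da_distance <= 0 or self.max_ha_distance <= 0:
            raise ValueError("distance criteria must be positive")
        if not (0 < self.min_dha_angle <= 180):
            raise ValueError("angle criterion must lie in (0, 180]")


@dataclass(frozen=True)
class HydrogenBond:
    """One detected hydrogen bond between the pose and a receptor residue."""

    residue: ResidueKey
    donor_side: str  # "ligand" or "receptor"
    donor_name: str
    hydrogen_name: str | None  # None for heavy-atom fallback detections
    acceptor_name: str
    da_distance: float
    ha_distance: float | None
    dha_angle: float | None


@dataclass
class InteractionReport:
    """Per-residue engagement table plus the triage summary quantities.

    ``per_residue`` has one row per key residue: minimum heavy-atom distance,
    contact flag, hydrogen-bond flag. ``score`` is the weighted sum over key
    residues (H-bond weight dominating contact weight); ``overlap`` is the
    fraction of the key list engaged by either interaction.
    """

    per_residue: pd.DataFrame
    score: float
    overlap: float
    hbonds: list[HydrogenBond] = field(default_factory=list)


def default_key_residues(contact_cutoff: float = 5.0) -> KeyResidueSpec:
    """The packaged SGLT2 glucose-pocket key-residue list.

    The nine residues lining the gliflozin/glucose site that sit within 5 Å of
    the reference empagliflozin pose: ASN 75, HIS 80, THR 87, PHE 98, GLU 99,
    SER 287, TYR 290, LYS 321, GLN 457.
    """
    text = importlib.resources.files("docktriage.data").joinpath("key_residues.tsv").read_text()
    entries = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("chain"):
            continue
        chain, num, name = line.split("\t")
        entries.append((None if chain == "." else chain, int(num), name))
    return KeyResidueSpec(residues=tuple(entries), contact_cutoff=contact_cutoff)


def find_close_contacts(
    pose: MolecularGraph, receptor: ReceptorStructure, cutoff: float = 5.0
) -> pd.DataFrame:
    """Minimum heavy-atom distance from the pose to each nearby residue.

    Returns one row per residue with any heavy atom within ``cutoff`` + 2 Å
    (columns: residue, min_dist, contact); ``contact`` is True at
    min_dist ≤ cutoff. Pose and receptor must share a coordinate frame.
    """
    lig = pose.heavy_coords()
    if lig.shape[0] == 0:
        raise ValueError("pose has no heavy atoms")
    rows = []
    for key in receptor.residues:
        res_xyz = receptor.residue_heavy_coords(key)
        if res_xyz.shape[0] == 0:
            continue
        d = float(cdist(lig, res_xyz).min())
        if d <= cutoff + _CONTEXT_MARGIN:
            rows.append({"residue": key, "min_dist": d, "contact": d <= cutoff})
    return pd.DataFrame(rows, columns=["residue", "min_dist", "contact"])


def _attached_hydrogens(coords: np.ndarray, names: list[str], elements: list[str], idx: int):
    """Hydrogens covalently close to heavy atom ``idx`` (distance-based)."""
    out = []
    for j, el in enumerate(elements):
        if el == "H" and np.linalg.norm(coords[j] - coords[idx]) <= _COVALENT_H_MAX:
            out.append(j)
    return out


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a–b–c in degrees."""
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_hbonds(
    pose: MolecularGraph,
    receptor: ReceptorStructure,
    criteria: HBondCriteria | None = None,
) -> list[HydrogenBond]:
    """Detect pose↔receptor hydrogen bonds under the configured geometry.

    N and O atoms act as donors when carrying a bonded hydrogen and as
    acceptors always. Both directions (ligand donor → residue acceptor and
    residue donor → ligand acceptor) are searched. When neither partner atom
    carries an attached hydrogen (so no explicit geometric test is possible)
    and ``heavy_atom_fallback`` is set, a donor–acceptor heavy-atom distance
    within ``max_da_distance`` suffices.
    Each donor/acceptor heavy-atom pair is reported at most once, preferring
    the explicit-hydrogen detection.
    """
    criteria = criteria or HBondCriteria()

    lig_coords = pose.coords
    lig_elements = [a.element for a in pose.atoms]
    lig_names = [a.name for a in pose.atoms]
    adj = pose.adjacency()
    ligand_has_h = any(e == "H" for e in lig_elements)

    lig_polar = [i for i, e in enumerate(lig_elements) if e in _DONOR_ACCEPTOR_ELEMENTS]

    found: dict[tuple, HydrogenBond] = {}

    def record(pair_key, bond: HydrogenBond):
        prev = found.get(pair_key)
        if prev is None or (prev.hydrogen_name is None and bond.hydrogen_name is not None):
            found[pair_key] = bond

    for res_key in receptor.residues:
        atoms = receptor.residue_atoms(res_key)
        res_coords = np.array([a.coords for a in atoms]).reshape(-1, 3)
        res_elements = [a.element for a in atoms]
        res_names = [a.name for a in atoms]
        res_has_h = any(e == "H" for e in res_elements)
        res_polar = [i for i, e in enumerate(res_elements) if e in _DONOR_ACCEPTOR_ELEMENTS]
        if not res_polar or not lig_polar:
            continue

        for li in lig_polar:
            for ri in res_polar:
                da = float(np.linalg.norm(lig_coords[li] - res_coords[ri]))
                if da > criteria.max_da_distance:
                    continue
                pair = (li, res_key, res_names[ri])

                # ligand donor → residue acceptor
                lig_hs = [j for j in adj[li] if lig_elements[j] == "H"]
                matched = False
                for h in lig_hs:
                    ha = float(np.linalg.norm(lig_coords[h] - res_coords[ri]))
                    ang = _angle_deg(lig_coords[li], lig_coords[h], res_coords[ri])
                    if ha <= criteria.max_ha_distance and ang >= criteria.min_dha_angle:
                        record(pair, HydrogenBond(res_key, "ligand", lig_names[li],
                                                  lig_names[h], res_names[ri], da, ha, ang))
                        matched = True
                        break
                if matched:
                    continue

                # residue donor → ligand acceptor
                res_hs = _attached_hydrogens(res_coords, res_names, res_elements, ri)
                for h in res_hs:
                    ha = float(np.linalg.norm(res_coords[h] - lig_coords[li]))
                    ang = _angle_deg(res_coords[ri], res_coords[h], lig_coords[li])
                    if ha <= criteria.max_ha_distance and ang >= criteria.min_dha_angle:
                        record(pair, HydrogenBond(res_key, "receptor", res_names[ri],
                                                  res_names[h], lig_names[li], da, ha, ang))
                        matched = True
                        break
                if matched:
                    continue

                # heavy-atom fallback: only when neither partner carries an
                # attached hydrogen, so no explicit geometric test was possible
                if criteria.heavy_atom_fallback and not lig_hs and not res_hs:
                    side = "receptor" if not res_has_h else "ligand"
                    donor, acceptor = (
                        (res_names[ri], lig_names[li]) if side == "receptor"
                        else (lig_names[li], res_names[ri])
                    )
                    record(pair, HydrogenBond(res_key, side, donor, None, acceptor, da, None, None))

    return list(found.values())


def key_residue_score(
    contacts: pd.DataFrame,
    hbonds: list[HydrogenBond],
    spec: KeyResidueSpec,
    w_hbond: float = 2.0,
    w_contact: float = 1.0,
) -> InteractionReport:
    """Combine contact and H-bond passes into the key-residue score and overlap.

    Each key residue contributes ``w_hbond`` when hydrogen-bonded, else
    ``w_contact`` when in close contact, else nothing. The overlap is the
    fraction of the key list engaged either way. A key residue absent from the
    receptor triggers a warning and counts as not engaged.
    """
    contact_by_key: dict[ResidueKey, tuple[float, bool]] = {
        row.residue: (row.min_dist, bool(row.contact)) for row in contacts.itertuples()
    }
    hbond_keys = {hb.residue for hb in hbonds}
    seen_keys = set(contact_by_key) | hbond_keys

    rows = []
    score = 0.0
    engaged = 0
    for entry in spec.residues:
        matches = [k for k in seen_keys if spec.matches(entry, k)]
        min_dist = np.nan
        has_contact = False
        has_hbond = False
        if matches:
            for k in matches:
                if k in contact_by_key:
                    d, c = contact_by_key[k]
                    if np.isnan(min_dist) or d < min_dist:
                        min_dist = d
                    has_contact = has_contact or c
                has_hbond = has_hbond or (k in hbond_keys)
        # an H-bond implies engagement even if the contact pass missed the residue
        has_contact = has_contact or has_hbond
        if has_hbond:
            score += w_hbond
        elif has_contact:
            score += w_contact
        if has_contact or has_hbond:
            engaged += 1
        chain, number, name = entry
        rows.append(
            {
                "chain": chain if chain is not None else ".",
                "resnum": number,
                "resname": name,
                "min_dist": min_dist,
                "contact": has_contact,
                "hbond": has_hbond,
            }
        )

    per_residue = pd.DataFrame(rows)
    overlap = engaged / len(spec.residues)
    return InteractionReport(per_residue=per_residue, score=score, overlap=overlap, hbonds=hbonds)


def score_pose(
    pose: MolecularGraph,
    receptor: ReceptorStructure,
    spec: KeyResidueSpec | None = None,
    criteria: HBondCriteria | None = None,
    w_hbond: float = 2.0,
    w_contact: float = 1.0,
) -> InteractionReport:
    """Run the full interaction analysis of one pose against one receptor."""
    spec = spec or default_key_residues()
    receptor_keys = set(receptor.residues)
    for entry in spec.residues:
        if not any(spec.matches(entry, k) for k in receptor_keys):
            warnings.warn(f"key residue {entry} not found in receptor; counted as not engaged")
    contacts = find_close_contacts(pose, receptor, cutoff=spec.contact_cutoff)
    hbonds = detect_hbonds(pose, receptor, criteria=criteria)
    return key_residue_score(contacts, hbonds, spec, w_hbond=w_hbond, w_contact=w_contact)
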