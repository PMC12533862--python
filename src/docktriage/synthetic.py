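"""Seeded generators for every input the triage pipeline consumes.

Each generator returns a :class:`FixtureBundle` carrying the artifact together
with the ground truth planted into it, so every analysis stage can be tested
against construction-guaranteed answers without any external data:

* pocket fixtures — a synthetic receptor pocket and ligand pose with a known
  set of contacting and hydrogen-bonding key residues (geometries are planted
  well inside the default criteria: H···acceptor 1.9 Å, collinear
  donor–H···acceptor, contacts at 4.3–4.8 Å, decoys beyond 7 Å);
* small ligand graphs with known automorphism-group sizes;
* per-replicate RMSD trajectories that either stay bounded below the
  early-stop threshold ("stable") or escape through it at a chosen time
  ("escaping");
* ranked screen tables with actives planted at known positions and the
  enrichment factor recorded in closed form.

All randomness flows from the ``seed`` argument: the same (seed, parameters)
always produces byte-identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd

from .interactions import default_key_residues
from .struct_io import AtomRecord, MolecularGraph, ReceptorStructure, ResidueKey, RmsdSeries, write_mol2, write_receptor
from .triage import bin_size

__all__ = [
    "FixtureBundle",
    "make_pocket_fixture",
    "make_symmetric_ligand",
    "make_random_ligand",
    "make_trajectory",
    "make_screen",
    "constant_series",
]

_MIN_ARM_SEPARATION_DEG = 40.0  # pocket arms closer than this could cross-talk


@dataclass
class FixtureBundle:
    """A generated artifact plus the ground truth planted into it."""

    artifact: Any
    ground_truth: dict
    seed: int
    params: dict


def _fibonacci_directions(n: int) -> np.ndarray:
    """n roughly evenly spaced unit vectors on the sphere."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, sign-fixed)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def constant_series(value: float, replicate_id: str = "rep1",
                    n_frames: int = 101, t0: float = 9.0, t1: float = 10.0) -> RmsdSeries:
    """A flat RMSD series at ``value`` Å spanning the ranking window.

    Useful for turning a published window-median value into a series fixture
    whose window median is exactly that value.
    """
    times = np.linspace(t0, t1, n_frames)
    return RmsdSeries(replicate_id=replicate_id, times=times, values=np.full(n_frames, float(value)))


def make_pocket_fixture(
    n_key_contacts: int,
    n_hbonds: int,
    n_decoys: int,
    seed: int,
) -> FixtureBundle:
    """Synthetic pocket with a known engagement pattern against the key list.

    The ligand sits at the origin; each of the first ``n_hbonds`` key residues
    receives an acceptor oxygen collinear with a ligand O–H donor arm
    (H···A = 1.9 Å), the next ``n_key_contacts - n_hbonds`` key residues get a
    carbon within 4.3–4.8 Å (contact but no polar atoms, hence no hydrogen
    bond), remaining key residues and all decoy residues are placed beyond
    7 Å. The artifact is (receptor PDB text, ligand MOL2 text).
    """
    if n_hbonds > n_key_contacts:
        raise ValueError("n_hbonds cannot exceed n_key_contacts")
    spec = default_key_residues()
    if n_key_contacts > len(spec.residues):
        raise ValueError(f"at most {len(spec.residues)} key residues available")

    rng = np.random.default_rng(seed)
    n_arms = len(spec.residues) + n_decoys
    dirs = _fibonacci_directions(n_arms) @ _random_rotation(rng).T
    # feasibility: arms must stay angularly separated or planted geometry leaks
    cosmax = np.cos(np.radians(_MIN_ARM_SEPARATION_DEG))
    gram = dirs @ dirs.T
    np.fill_diagonal(gram, -1.0)
    if gram.max() > cosmax:
        raise ValueError(
            f"infeasible packing: {n_arms} pocket arms cannot keep "
            f"{_MIN_ARM_SEPARATION_DEG}° separation"
        )

    lig_atoms = [AtomRecord("C", "C1", np.zeros(3), False)]
    lig_bonds: set[tuple[int, int]] = set()
    rec_atoms: list[AtomRecord] = []

    def add_residue(key: ResidueKey, positions: list[tuple[str, str, np.ndarray]]):
        for element, name, xyz in positions:
            rec_atoms.append(AtomRecord(element, name, xyz, element == "H", residue_key=key))

    contact_residues: list[ResidueKey] = []
    hbond_residues: list[ResidueKey] = []
    for idx, (chain, resnum, resname) in enumerate(spec.residues):
        key = ResidueKey(chain or "A", resnum, "", resname)
        u = dirs[idx]
        if idx < n_hbonds:
            # ligand donor arm C-C-O-H pointing at a receptor acceptor oxygen
            c_arm = len(lig_atoms)
            lig_atoms.append(AtomRecord("C", f"C{c_arm + 1}", 1.3 * u, False))
            lig_bonds.add((0, c_arm))
            o_arm = len(lig_atoms)
            lig_atoms.append(AtomRecord("O", f"O{o_arm + 1}", 2.6 * u, False))
            lig_bonds.add((c_arm, o_arm))
            h_arm = len(lig_atoms)
            lig_atoms.append(AtomRecord("H", f"H{h_arm + 1}", 3.56 * u, True))
            lig_bonds.add((o_arm, h_arm))
            add_residue(key, [("O", "OD1", 5.46 * u), ("C", "CA", 6.86 * u)])
            hbond_residues.append(key)
            contact_residues.append(key)
        elif idx < n_key_contacts:
            d = rng.uniform(4.3, 4.8)
            add_residue(key, [("C", "CB", d * u), ("C", "CA", (d + 1.4) * u)])
            contact_residues.append(key)
        else:
            d = rng.uniform(9.5, 10.5)
            add_residue(key, [("C", "CB", d * u), ("C", "CA", (d + 1.4) * u)])

    decoy_keys = []
    for j in range(n_decoys):
        key = ResidueKey("A", 500 + j, "", "LEU")
        d = rng.uniform(9.5, 12.0)
        u = dirs[len(spec.residues) + j]
        add_residue(key, [("C", "CB", d * u), ("C", "CA", (d + 1.4) * u)])
        decoy_keys.append(key)

    ligand = MolecularGraph(atoms=lig_atoms, bonds=lig_bonds, provenance="synthetic")
    receptor = ReceptorStructure(atoms=rec_atoms)
    ground_truth = {
        "contact_residues": contact_residues,
        "hbond_residues": hbond_residues,
        "overlap": n_key_contacts / len(spec.residues),
        "score": 2.0 * n_hbonds + 1.0 * (n_key_contacts - n_hbonds),
        "n_key_residues": len(spec.residues),
        "decoy_residues": decoy_keys,
    }
    return FixtureBundle(
        artifact=(write_receptor(receptor), write_mol2(ligand, name="SYNTH")),
        ground_truth=ground_truth,
        seed=seed,
        params={"n_key_contacts": n_key_contacts, "n_hbonds": n_hbonds, "n_decoys": n_decoys},
    )


def make_symmetric_ligand(kind: str, seed: int = 0) -> FixtureBundle:
    """Small ligand graphs with known heavy-atom automorphism counts.

    ``chain`` — a C–N–O chain (asymmetric, 1 automorphism); ``ring6`` — an
    all-carbon hexagon (dihedral symmetry, 12); ``ring6_hetero`` — a hexagon
    with one nitrogen (mirror only, 2). The seed applies a rigid random
    rotation/translation, which changes coordinates but not topology.
    """
    rng = np.random.default_rng(seed)
    if kind == "chain":
        elements = ["C", "N", "O"]
        coords = np.array([[0.0, 0, 0], [1.45, 0, 0], [2.9, 0, 0]])
        bonds = {(0, 1), (1, 2)}
        n_auto = 1
    elif kind in ("ring6", "ring6_hetero"):
        angles = np.radians(60.0 * np.arange(6))
        coords = 1.39 * np.column_stack([np.cos(angles), np.sin(angles), np.zeros(6)])
        bonds = {(i, (i + 1) % 6) for i in range(6)}
        elements = ["C"] * 6
        n_auto = 12
        if kind == "ring6_hetero":
            elements[0] = "N"
            n_auto = 2
    else:
        raise ValueError(f"unknown ligand kind: {kind!r}")

    rot = _random_rotation(rng)
    shift = rng.uniform(-5, 5, size=3)
    coords = coords @ rot.T + shift
    atoms = [
        AtomRecord(el, f"{el}{i + 1}", coords[i], el == "H") for i, el in enumerate(elements)
    ]
    graph = MolecularGraph(atoms=atoms, bonds=set(bonds), provenance="synthetic")
    return FixtureBundle(
        artifact=graph,
        ground_truth={"n_automorphisms": n_auto},
        seed=seed,
        params={"kind": kind},
    )


def make_random_ligand(n_heavy: int, seed: int, elements: tuple[str, ...] = ("C", "N", "O")) -> MolecularGraph:
    """A random connected heavy-atom graph with random 3-D coordinates.

    A random spanning tree guarantees connectivity; a few extra edges add
    rings. Coordinates are arbitrary (the symmetry-RMSD statistic needs no
    chemically sensible geometry), drawn in a 6 Å box.
    """
    rng = np.random.default_rng(seed)
    if n_heavy < 1:
        raise ValueError("need at least one heavy atom")
    bonds: set[tuple[int, int]] = set()
    for i in range(1, n_heavy):
        j = int(rng.integers(0, i))
        bonds.add((j, i))
    n_extra = int(rng.integers(0, max(1, n_heavy // 3) + 1))
    for _ in range(n_extra):
        i, j = rng.choice(n_heavy, size=2, replace=False)
        bonds.add((min(i, j), max(i, j)))
    coords = rng.uniform(-3, 3, size=(n_heavy, 3))
    symbols = rng.choice(elements, size=n_heavy)
    atoms = [
        AtomRecord(str(symbols[i]), f"{symbols[i]}{i + 1}", coords[i], False)
        for i in range(n_heavy)
    ]
    return MolecularGraph(atoms=atoms, bonds=bonds, provenance="synthetic")


def make_trajectory(
    kind: str,
    mu: float = 1.5,
    sigma: float = 0.2,
    cross_time: float = 4.0,
    n_frames: int = 1000,
    dt: float = 0.01,
    seed: int = 0,
    n_replicates: int = 3,
) -> FixtureBundle:
    """Replicate RMSD trajectories with a planted bound/unbound label.

    ``stable`` — mean-reverting Gaussian fluctuation around ``mu`` Å, clipped
    into (0, 5.45] so the early-stop threshold is never crossed; requires
    ``mu + 4·sigma < 5.5``. ``escaping`` — the same baseline plus a steep
    ramp that crosses 5.5 Å at ``cross_time`` (± about one frame of noise)
    and then plateaus around 8 Å; requires ``cross_time < 9`` ns so the
    censored ranking window medians to exactly the censor value.
    """
    if kind not in ("stable", "escaping"):
        raise ValueError(f"unknown trajectory kind: {kind!r}")
    if kind == "stable" and mu + 4 * sigma >= 5.5:
        raise ValueError("stable trajectories require mu + 4*sigma < 5.5 Å")
    if kind == "escaping":
        if not (0.3 <= cross_time < 9.0):
            raise ValueError("escaping trajectories require 0.3 ns <= cross_time < 9 ns")
        if mu >= 2.5:
            raise ValueError("escaping trajectories require mu < 2.5 Å")

    times = dt * np.arange(1, n_frames + 1)
    phi = 0.95  # frame-to-frame autocorrelation of the fluctuation
    replicates = []
    child_seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    for r, ss in enumerate(child_seeds, start=1):
        rng = np.random.default_rng(ss)
        eps = rng.normal(0.0, sigma * np.sqrt(1 - phi**2), size=n_frames)
        x = np.empty(n_frames)
        x[0] = mu + rng.normal(0.0, sigma)
        for t in range(1, n_frames):
            x[t] = mu + phi * (x[t - 1] - mu) + eps[t]
        if kind == "stable":
            values = np.clip(x, 0.05, 5.45)
        else:
            ramp_start = cross_time - 0.2
            slope = (5.5 - mu) / 0.2
            ramp = np.clip((times - ramp_start) * slope, 0.0, (5.5 - mu) + 2.5)
            values = np.clip(x + ramp, 0.05, None)
        replicates.append(RmsdSeries(replicate_id=f"rep{r}", times=times.copy(), values=values))

    truth = {"label": kind, "expected_bound": kind == "stable"}
    if kind == "escaping":
        truth["cross_time"] = cross_time
        truth["expected_window_median"] = 10.0
    return FixtureBundle(
        artifact=replicates,
        ground_truth=truth,
        seed=seed,
        params={"kind": kind, "mu": mu, "sigma": sigma, "cross_time": cross_time,
                "n_frames": n_frames, "dt": dt},
    )


def make_screen(
    N: int,
    n_actives: int,
    placement: str = "top_bin",
    seed: int = 0,
    fraction: float = 0.01,
) -> FixtureBundle:
    """A scored compound library with planted actives and closed-form EF.

    ``top_bin`` places the actives inside the top-``fraction`` bin (filling
    the bin first when there are more actives than bin positions), so the
    enrichment factor is exactly ``(N/N_top) × min(1, N_top/n_actives)``;
    ``uniform`` scatters them uniformly, giving EF = 1 in expectation. The
    table also carries planted ``overlap`` and ``include`` columns: actives
    get overlap in [0.7, 1] and include = 1, inactives overlap in [0, 0.5]
    and a random include flag, so the candidate-selection gates have a known
    answer under the thresholds recorded in the ground truth.
    """
    if n_actives > N:
        raise ValueError("cannot plant more actives than compounds")
    if n_actives < 1:
        raise ValueError("need at least one active")
    if placement not in ("top_bin", "uniform"):
        raise ValueError(f"unknown placement: {placement!r}")
    rng = np.random.default_rng(seed)
    scores = np.sort(rng.uniform(-150.0, -40.0, size=N))  # lower (more negative) is better
    ids = np.array([f"CPD{i:05d}" for i in rng.permutation(N)])

    n_top = bin_size(N, fraction)
    active = np.zeros(N, dtype=int)
    if placement == "top_bin":
        k_in = min(n_actives, n_top)
        in_bin = rng.choice(n_top, size=k_in, replace=False)
        active[in_bin] = 1
        if n_actives > n_top:
            rest = rng.choice(np.arange(n_top, N), size=n_actives - n_top, replace=False)
            active[rest] = 1
        expected_ef = (N / n_top) * min(1.0, n_top / n_actives)
    else:
        pos = rng.choice(N, size=n_actives, replace=False)
        active[pos] = 1
        expected_ef = 1.0  # in expectation

    overlap = np.where(
        active == 1,
        rng.uniform(0.7, 1.0, size=N),
        rng.uniform(0.0, 0.5, size=N),
    )
    include = np.where(active == 1, 1, rng.integers(0, 2, size=N))

    table = pd.DataFrame(
        {"id": ids, "score": scores, "overlap": overlap,
         "active": active, "include": include}
    )
    # shuffle row order so nothing downstream can rely on it
    table = table.sample(frac=1.0, random_state=int(rng.integers(0, 2**31))).reset_index(drop=True)

    truth = {
        "n_top": n_top,
        "expected_ef": expected_ef,
        "ef_exact": placement == "top_bin",
        "active_ids": sorted(ids[active == 1].tolist()),
        "gate_thresholds": {
            "score_threshold": float(scores[n_top - 1]),
            "overlap_threshold": 0.6,
            "require_clinical_inclusion": True,
        },
        "expected_candidate_ids": sorted(ids[: n_top][active[:n_top] == 1].tolist())
        if placement == "top_bin"
        else None,
    }
    return FixtureBundle(
        artifact=table,
        ground_truth=truth,
        seed=seed,
        params={"N": N, "n_actives": n_actives, "placement": placement, "fraction": fraction},
    )
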