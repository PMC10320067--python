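"""Deterministic synthetic inputs with machine-readable planted truth.

Everything downstream of the structure reader is testable without any
database download: this module fabricates (a) shell structures whose
concave cavity and lining residues are known by construction, (b)
labeled pocket feature tables drawn from two Gaussian classes with a
stated mean shift, mimicking the rarity of true allosteric sites among
surface pockets, and (c) random weighted residue graphs for shortest-
path oracles.  All generators are pure functions of their parameters and
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .enm_dynamics import LigandNode
from .errors import ParameterError
from .structure_io import Atom, LigandSpec, ProteinStructure, ResidueId

_RESIDUE_CYCLE = ("ALA", "ILE", "ARG")  # standard names so hydropathy applies
_ONE_LETTER = {"ALA": "A", "ILE": "I", "ARG": "R"}


@dataclass
class ShellTruth:
    """Planted ground truth emitted alongside a shell structure."""

    lining: list[ResidueId]
    cavity_center: np.ndarray
    cavity_radius: float
    ligand: LigandSpec | None
    buried: bool  # True when the aperture is closed (interior void)

    def to_json_dict(self) -> dict:
        return {
            "lining": [
                {"chain": r.chain, "number": r.number, "name": r.name}
                for r in self.lining
            ],
            "cavity_center": self.cavity_center.tolist(),
            "cavity_radius": self.cavity_radius,
            "ligand": str(self.ligand) if self.ligand else None,
            "buried": self.buried,
        }


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors (golden-angle spiral)."""
    k = np.arange(n)
    z = 1.0 - 2.0 * (k + 0.5) / n
    phi = k * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_shell_structure(
    n_residues: int = 60,
    cavity_radius: float = 6.0,
    aperture_deg: float = 55.0,
    jitter: float = 0.3,
    seed: int = 0,
    ligand: str | None = None,  # None | "orthosteric" | "surface" | "distal"
    distal_distance: float = 30.0,
) -> tuple[ProteinStructure, ShellTruth]:
    """Pseudo-residues on a spherical shell around a cavity of known lining.

    An angular aperture around +z is left open so the cavity is a concave
    surface pocket rather than a sealed void (``aperture_deg=0`` closes it,
    and the truth marks the cavity as buried).  A ligand hetero group can
    be planted at the cavity center ("orthosteric") or ``distal_distance``
    outside the shell ("distal").  Every shell residue is a planted lining
    residue.
    """
    if cavity_radius < 3.0:
        raise ParameterError(
            f"cavity radius {cavity_radius} cannot host a probe sphere"
        )
    if n_residues < 8:
        raise ParameterError("shell needs at least 8 residues")
    rng = np.random.default_rng(seed)

    cap_cos = math.cos(math.radians(aperture_deg))
    # oversample the sphere, drop the aperture cap around +z, keep n_residues
    dirs = _fibonacci_sphere(max(int(n_residues * 2.5), n_residues + 8))
    dirs = dirs[dirs[:, 2] < cap_cos] if aperture_deg > 0 else dirs
    if len(dirs) < n_residues:
        raise ParameterError("aperture too wide for the requested residue count")
    step = len(dirs) / n_residues
    dirs = dirs[(np.arange(n_residues) * step).astype(int)]

    radii = cavity_radius + rng.normal(0.0, jitter, size=n_residues)
    positions = dirs * radii[:, None]

    residues, coords, atoms, bf = [], [], {}, []
    seq = []
    for i, pos in enumerate(positions):
        name = _RESIDUE_CYCLE[i % len(_RESIDUE_CYCLE)]
        rid = ResidueId("A", i + 1, "", name)
        ca = Atom("CA", "C", tuple(pos), 1.0, 20.0)
        cb = Atom("CB", "C", tuple(pos * (1.0 + 1.5 / np.linalg.norm(pos))), 1.0, 20.0)
        residues.append(rid)
        coords.append(pos)
        atoms[rid] = (ca, cb)
        bf.append(20.0)
        seq.append(_ONE_LETTER[name])

    lig = None
    if ligand == "orthosteric":
        center = np.zeros(3)
        lig_atoms = tuple(
            Atom(f"C{k+1}", "C", tuple(center + off), 1.0, 15.0)
            for k, off in enumerate(
                [np.zeros(3), np.array([0.8, 0, 0]), np.array([0, 0.8, 0])]
            )
        )
        lig = LigandSpec("LIG", "A", 900, lig_atoms)
    elif ligand == "surface":
        # bound on the outside wall: contacts the network but sits clear of
        # the cavity probes, so the detected pocket stays unflagged
        center = np.array([0.0, 0.0, -(cavity_radius + 6.0)])
        lig_atoms = tuple(
            Atom(f"C{k+1}", "C", tuple(center + off), 1.0, 15.0)
            for k, off in enumerate([np.zeros(3), np.array([0.8, 0, 0])])
        )
        lig = LigandSpec("LIG", "A", 900, lig_atoms)
    elif ligand == "distal":
        center = np.array([0.0, 0.0, -(cavity_radius + distal_distance)])
        lig_atoms = tuple(
            Atom(f"C{k+1}", "C", tuple(center + off), 1.0, 15.0)
            for k, off in enumerate([np.zeros(3), np.array([0.8, 0, 0])])
        )
        lig = LigandSpec("LIG", "A", 900, lig_atoms)
    elif ligand is not None:
        raise ParameterError(f"unknown ligand placement '{ligand}'")

    structure = ProteinStructure(
        residues=residues,
        coords=np.asarray(coords),
        atoms=atoms,
        bfactors=np.asarray(bf),
        chains={"A": "".join(seq)},
        ligands=[lig] if lig else [],
        source_label=f"shell(n={n_residues},seed={seed})",
    )
    truth = ShellTruth(
        lining=list(residues),
        cavity_center=np.zeros(3),
        cavity_radius=cavity_radius,
        ligand=lig,
        buried=aperture_deg <= 0,
    )
    return structure, truth


def make_dipeptide(n_residues: int = 3, spacing: float = 3.8) -> ProteinStructure:
    """Extended straight-chain peptide: no cavity anywhere (negative control)."""
    residues, coords, atoms = [], [], {}
    seq = []
    for i in range(n_residues):
        name = _RESIDUE_CYCLE[i % len(_RESIDUE_CYCLE)]
        rid = ResidueId("A", i + 1, "", name)
        pos = np.array([i * spacing, 0.0, 0.0])
        residues.append(rid)
        coords.append(pos)
        atoms[rid] = (Atom("CA", "C", tuple(pos), 1.0, 10.0),)
        seq.append(_ONE_LETTER[name])
    return ProteinStructure(
        residues=residues, coords=np.asarray(coords), atoms=atoms,
        bfactors=np.full(n_residues, 10.0), chains={"A": "".join(seq)},
        ligands=[], source_label=f"peptide(n={n_residues})",
    )


def make_feature_table(
    n: int = 500,
    positive_fraction: float = 0.09,
    effect: tuple[float, float, float] = (0.0, 0.0, 3.0),
    pockets_per_protein: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Labeled two-class pocket feature table with a planted mean shift.

    Negatives are standard normal in (hydrophobicity, flexibility, rae);
    positives are shifted by ``effect`` (in sd units, default +3 sd on the
    pocket-RAE feature only).  The default positive fraction 0.09 mirrors
    the roughly one-in-eleven rate of labeled allosteric sites among
    surface pockets in curated benchmarks.  Rows are grouped into
    pseudo-proteins of ``pockets_per_protein`` so protein-level recall is
    well defined.
    """
    rng = np.random.default_rng(seed)
    n_pos = int(round(n * positive_fraction))
    labels = np.zeros(n, dtype=int)
    labels[rng.choice(n, size=n_pos, replace=False)] = 1
    x = rng.normal(size=(n, 3))
    x[labels == 1] += np.asarray(effect)
    return pd.DataFrame(
        {
            "protein_id": [f"P{i // pockets_per_protein:03d}" for i in range(n)],
            "pocket_id": np.arange(n),
            "hydrophobicity": x[:, 0],
            "flexibility": x[:, 1],
            "rae": x[:, 2],
            "label": labels,
        }
    )


def shell_feature_table(
    seeds: range | list[int] = range(8),
    ligand: str = "surface",
    coverage_threshold: float = 0.5,
) -> pd.DataFrame:
    """Labeled feature table computed from shell fixtures end to end.

    For each seed a shell structure is generated, its pockets detected and
    featurized with the real pipeline operations, and a pocket is labeled
    allosteric when it covers at least ``coverage_threshold`` of the
    planted cavity lining.  Useful for training a test model that operates
    on the same feature scales the pipeline produces.
    """
    from .enm_dynamics import build_enm, cross_correlation, mean_square_fluctuation
    from .pocket_finder import compute_descriptors, detect_pockets, flag_orthosteric_overlap
    from .rae_profile import interaction_matrix, residue_rae

    rows = []
    for seed in seeds:
        s, truth = make_shell_structure(seed=seed, ligand=ligand)
        lig = s.ligands[0]
        pockets = flag_orthosteric_overlap(detect_pockets(s), lig)
        net_apo = build_enm(s, None)
        net_holo = build_enm(s, lig)
        c_apo, c_holo = cross_correlation(net_apo), cross_correlation(net_holo)
        flex = mean_square_fluctuation(net_holo).msf[: s.n_residues]
        planted = set(truth.lining)
        for p in pockets:
            if p.overlaps_orthosteric:
                continue
            d = compute_descriptors(p, s, flex)
            prof = residue_rae(
                interaction_matrix(c_apo, p, "apo"),
                interaction_matrix(c_holo, p, "holo"),
            )
            coverage = len(p.lining_residues & planted) / len(planted)
            rows.append(
                {
                    "protein_id": f"shell{seed}",
                    "pocket_id": p.pocket_id,
                    "hydrophobicity": d.hydrophobicity,
                    "flexibility": d.flexibility,
                    "rae": prof.pocket_rae,
                    "label": int(coverage >= coverage_threshold),
                }
            )
    return pd.DataFrame(rows)


def make_random_graph(
    n_nodes: int = 8,
    edge_prob: float = 0.4,
    seed: int = 0,
    weight_range: tuple[float, float] = (0.5, 3.0),
) -> nx.Graph:
    """Connected random residue graph with a designated ligand anchor.

    Node 0 is the anchor; the rest are residue nodes on chain A.  Edges
    are redrawn until the graph is connected, so every sink is reachable.
    """
    rng = np.random.default_rng(seed)
    anchor = LigandNode("LIG", "A", 900)
    nodes = [anchor] + [ResidueId("A", i, "", "ALA") for i in range(1, n_nodes)]
    for _ in range(1000):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for i in range(n_nodes):
            for j in range(i + 1, n_nodes):
                if rng.random() < edge_prob:
                    w = float(rng.uniform(*weight_range))
                    g.add_edge(nodes[i], nodes[j], weight=w)
        if g.number_of_edges() and nx.is_connected(g):
            g.graph["anchor"] = anchor
            return g
    raise ParameterError("could not draw a connected graph; raise edge_prob")
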