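"""Geometric detection of pocket-like surface regions and their descriptors.

Pockets are found with an alpha-sphere scheme: the Delaunay
tetrahedralization of the protein heavy atoms is computed, and each
tetrahedron whose empty circumsphere has a radius between ``probe_min``
and ``probe_max`` contributes its circumcenter as a probe center (small
spheres sit in packed interiors, huge ones in open solvent; the bracket
keeps cavity-sized ones).  Probe centers are clustered by single linkage
at ``cluster_distance``; each cluster is a pocket whose lining residues
are all residues with a heavy atom within ``lining_cutoff`` of any probe
center.  Because Delaunay circumspheres are empty by construction, probe
centers never clash with atoms, and the construction commutes with rigid
motions of the structure.

Descriptors per pocket are the mean Kyte-Doolittle hydrophobicity of the
lining residues and their mean z-scored flexibility (the per-residue
fluctuation z-scored over the whole protein before averaging).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, QhullError, cKDTree

from .structure_io import LigandSpec, ProteinStructure, ResidueId

logger = logging.getLogger(__name__)

# Kyte & Doolittle hydropathy scale
KD_SCALE = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5,
    "MET": 1.9, "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8,
    "TRP": -0.9, "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5,
    "GLN": -3.5, "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}


@dataclass(frozen=True)
class PocketParams:
    probe_min: float = 3.0       # Angstrom: smallest cavity sphere kept
    probe_max: float = 6.0       # largest; bigger spheres are open solvent
    cluster_distance: float = 4.5  # single-linkage merge distance
    lining_cutoff: float = 5.0   # residue lines a pocket within this of a probe
    min_lining: int = 4          # clusters lining fewer residues are noise


@dataclass
class Pocket:
    pocket_id: int
    lining_residues: frozenset[ResidueId]
    probe_centers: np.ndarray  # (k, 3)
    overlaps_orthosteric: bool = False

    @property
    def volume_proxy(self) -> int:
        return len(self.probe_centers)


@dataclass
class PocketDescriptors:
    hydrophobicity: float
    flexibility: float


def _circumspheres(points: np.ndarray, simplices: np.ndarray):
    """Circumcenters and radii of Delaunay tetrahedra (degenerate ones dropped)."""
    a = points[simplices[:, 0]]
    rows = np.stack([points[simplices[:, k]] - a for k in (1, 2, 3)], axis=1)
    rhs = 0.5 * np.einsum("ijk,ijk->ij", rows, rows)
    det = np.linalg.det(rows)
    good = np.abs(det) > 1e-10
    centers = np.full((len(simplices), 3), np.nan)
    if good.any():
        centers[good] = a[good] + np.linalg.solve(
            rows[good], rhs[good][..., None]
        )[..., 0]
    radii = np.linalg.norm(centers - a, axis=1)
    return centers[good], radii[good]


def detect_pockets(
    s: ProteinStructure, params: PocketParams = PocketParams()
) -> list[Pocket]:
    """Detect pocket-like regions; sorted by descending probe count.

    Deterministic for fixed input and parameters.  A structure too small
    to host a probe sphere yields an empty list.
    """
    atom_coords, owners = s.heavy_atom_coords()
    if len(atom_coords) < 5:
        return []
    try:
        tri = Delaunay(atom_coords)
    except QhullError:
        return []  # degenerate geometry (collinear/coplanar): no cavity

    centers, radii = _circumspheres(atom_coords, tri.simplices)
    keep = (radii >= params.probe_min) & (radii <= params.probe_max)
    centers = centers[keep]
    if len(centers) == 0:
        return []

    # single-linkage clustering at cluster_distance via a contact graph
    tree = cKDTree(centers)
    pairs = tree.query_pairs(params.cluster_distance, output_type="ndarray")
    m = len(centers)
    if len(pairs):
        adj = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(m, m)
        )
    else:
        adj = coo_matrix((m, m))
    n_clusters, labels = connected_components(adj, directed=False)

    atom_tree = cKDTree(atom_coords)
    pockets = []
    for cl in range(n_clusters):
        probe_pts = centers[labels == cl]
        lining: set[ResidueId] = set()
        for idx_list in atom_tree.query_ball_point(probe_pts, params.lining_cutoff):
            lining.update(owners[i] for i in idx_list)
        if len(lining) < params.min_lining:
            continue
        pockets.append((probe_pts, frozenset(lining)))

    # descending volume proxy; ties broken by the sorted lining identity
    pockets.sort(key=lambda pr: (-len(pr[0]), tuple(sorted(pr[1]))))
    return [
        Pocket(pocket_id=i, lining_residues=lining, probe_centers=probe_pts)
        for i, (probe_pts, lining) in enumerate(pockets)
    ]


def flag_orthosteric_overlap(
    pockets: list[Pocket], lig: LigandSpec, contact_cutoff: float = 4.5
) -> list[Pocket]:
    """Mark pockets whose probe centers touch the orthosteric ligand.

    Flagged pockets stay in reports but are excluded from allosteric-site
    classification (an "allosteric" call on the orthosteric site itself is
    meaningless).
    """
    lig_pts = lig.heavy_coords
    flagged = []
    for p in pockets:
        d = np.linalg.norm(
            p.probe_centers[:, None, :] - lig_pts[None, :, :], axis=-1
        )
        flagged.append(replace(p, overlaps_orthosteric=bool(d.min() <= contact_cutoff)))
    return flagged


def compute_descriptors(
    p: Pocket, s: ProteinStructure, flex: np.ndarray
) -> PocketDescriptors:
    """Mean lining hydrophobicity and mean z-scored lining flexibility.

    ``flex`` is a per-residue fluctuation vector aligned with
    ``s.residues`` (ENM mean-square fluctuations preferred;
    crystallographic B-factors are an acceptable fallback).
    """
    flex = np.asarray(flex, dtype=float)
    if flex.shape[0] != s.n_residues:
        raise ValueError(
            f"flexibility vector covers {flex.shape[0]} residues, "
            f"structure has {s.n_residues}"
        )
    sd = flex.std()
    z = (flex - flex.mean()) / sd if sd > 0 else np.zeros_like(flex)
    index = s.index_of()

    hydro_vals, flex_vals = [], []
    for rid in p.lining_residues:
        if rid.name not in KD_SCALE:
            logger.warning("unknown residue name %s; hydrophobicity 0.0", rid.name)
        hydro_vals.append(KD_SCALE.get(rid.name, 0.0))
        flex_vals.append(z[index[rid]])
    return PocketDescriptors(
        hydrophobicity=float(np.mean(hydro_vals)),
        flexibility=float(np.mean(flex_vals)),
    )


def export_pockets(pockets: list[Pocket]) -> str:
    """Tab-separated pocket table (id, size, orthosteric flag, lining)."""
    lines = ["pocket_id\tn_probes\toverlaps_orthosteric\tlining_residues"]
    for p in pockets:
        lining = ",".join(str(r) for r in sorted(p.lining_residues))
        lines.append(
            f"{p.pocket_id}\t{p.volume_proxy}\t{int(p.overlaps_orthosteric)}\t{lining}"
        )
    return "\n".join(lines) + "\n"


def viewer_selection(p: Pocket) -> str:
    """PyMOL-style selection string for a pocket's lining residues."""
    parts = sorted(
        {(r.chain, f"{r.number}{r.insertion_code}") for r in p.lining_residues}
    )
    by_chain: dict[str, list[str]] = {}
    for chain, num in parts:
        by_chain.setdefault(chain, []).append(num)
    sel = " or ".join(
        f"(chain {c} and resi {'+'.join(nums)})" for c, nums in sorted(by_chain.items())
    )
    return sel
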