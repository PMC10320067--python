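"""Elastic network models: fluctuations and motion cross-correlations.

The apo and holo states are modelled as elastic networks on residue
representative coordinates (one node per residue, plus an optional
pseudo-node at the ligand heavy-atom centroid).  The default formulation
is the isotropic Kirchhoff/GNM one: for nodes i,j within the contact
cutoff the stiffness (Laplacian) matrix gets an off-diagonal -gamma, and
the thermal covariance is its pseudo-inverse with the single rigid
(all-ones) null mode removed.  Motion correlations C_ij are the
normalized covariance; per-node mean-square fluctuations are its
diagonal.  An anisotropic (ANM) formulation is available behind a flag.

Correlations are scale-invariant in the spring constant, which therefore
defaults to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .errors import (
    DegenerateNetworkError,
    DisconnectedNetworkError,
    NumericalDegeneracyError,
)
from .structure_io import LigandSpec, ProteinStructure

DEFAULT_CUTOFF = 10.0  # Angstrom, Calpha-level contact distance


@dataclass(frozen=True, order=True)
class LigandNode:
    """Pseudo-node anchoring the orthosteric ligand in the network."""

    het_name: str
    chain: str
    number: int

    def __str__(self) -> str:
        return f"LIG:{self.het_name}:{self.chain}:{self.number}"


@dataclass
class EnmNetwork:
    nodes: list[Hashable]  # ResidueId entries, plus optional LigandNode
    coords: np.ndarray  # (n, 3) Angstrom
    cutoff: float
    spring_constant: float = 1.0
    adjacency: np.ndarray = field(default=None)  # symmetric bool, empty diagonal

    def __post_init__(self):
        n = len(self.nodes)
        if n < 2:
            raise DegenerateNetworkError(f"network needs >= 2 nodes, got {n}")
        if self.adjacency is None:
            d = squareform(pdist(self.coords))
            adj = d <= self.cutoff
            np.fill_diagonal(adj, False)
            self.adjacency = adj

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def ligand_index(self) -> int | None:
        for i, node in enumerate(self.nodes):
            if isinstance(node, LigandNode):
                return i
        return None


@dataclass
class CorrelationMatrix:
    """Normalized motion correlations C_ij in [-1, 1], unit diagonal."""

    values: np.ndarray
    nodes: list[Hashable]

    def index_of(self) -> dict[Hashable, int]:
        return {n: i for i, n in enumerate(self.nodes)}


@dataclass
class FluctuationVector:
    """Per-node mean-square fluctuations (arbitrary units, >= 0)."""

    msf: np.ndarray
    nodes: list[Hashable]


def build_enm(
    s: ProteinStructure,
    ligand: LigandSpec | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    spring_constant: float = 1.0,
) -> EnmNetwork:
    """One node per residue (representative coordinate); optionally one
    ligand pseudo-node at the heavy-atom centroid.  Edges connect every
    node pair within ``cutoff``."""
    nodes: list[Hashable] = list(s.residues)
    coords = s.coords
    if ligand is not None:
        nodes = nodes + [LigandNode(ligand.het_name, ligand.chain, ligand.number)]
        coords = np.vstack([coords, ligand.centroid()])
    return EnmNetwork(nodes=nodes, coords=coords.copy(), cutoff=cutoff,
                      spring_constant=spring_constant)


def _check_connected(net: EnmNetwork) -> int:
    """Error when residue nodes split into several components.

    An isolated ligand pseudo-node (beyond cutoff from every residue) is
    tolerated: it exerts no perturbation, its covariance row is zero and
    its correlations are reported as zero.  Returns the number of zero
    modes of the Kirchhoff matrix (= number of connected components).
    """
    n_comp, labels = connected_components(
        csr_matrix(net.adjacency.astype(int)), directed=False
    )
    if n_comp == 1:
        return 1
    sizes = np.bincount(labels).tolist()
    lig = net.ligand_index()
    if (
        n_comp == 2
        and lig is not None
        and not net.adjacency[lig].any()
    ):
        return 2  # residues form one component; the ligand floats free
    raise DisconnectedNetworkError(
        f"network has {n_comp} components with sizes {sizes}"
    )


def compute_modes(net: EnmNetwork, anisotropic: bool = False) -> np.ndarray:
    """Covariance of node motions: pseudo-inverse of the stiffness matrix.

    Exactly the rigid-body null modes are removed — 1 in the isotropic
    (Kirchhoff) formulation, 6 in the anisotropic one — by dropping the
    corresponding smallest eigenvalues rather than thresholding, so the
    result is the exact Moore-Penrose inverse for a connected network.
    Returns an (n, n) covariance; in the anisotropic case the 3x3 blocks
    are traced down to one scalar per node pair.
    """
    n_comp = _check_connected(net)
    n = net.n_nodes
    gamma = net.spring_constant
    if not anisotropic:
        kirchhoff = -net.adjacency.astype(float)
        np.fill_diagonal(kirchhoff, net.adjacency.sum(axis=1))
        kirchhoff *= gamma
        cov = _pinv_drop_modes(kirchhoff, n_zero=n_comp)
    else:
        hessian = _anm_hessian(net, gamma)
        cov3 = _pinv_drop_modes(hessian, n_zero=6 * n_comp - 3 * (n_comp - 1))
        cov = np.einsum("ikjk->ij", cov3.reshape(n, 3, n, 3))
    # enforce exact symmetry against round-off
    return (cov + cov.T) / 2.0


def _pinv_drop_modes(mat: np.ndarray, n_zero: int) -> np.ndarray:
    w, v = np.linalg.eigh(mat)
    if n_zero and w[n_zero - 1] > 1e-6 * max(w[-1], 1.0):
        raise NumericalDegeneracyError(
            f"expected {n_zero} rigid modes; smallest eigenvalues {w[:n_zero]}"
        )
    w_inv = np.zeros_like(w)
    w_inv[n_zero:] = 1.0 / w[n_zero:]
    return (v * w_inv) @ v.T


def _anm_hessian(net: EnmNetwork, gamma: float) -> np.ndarray:
    n = net.n_nodes
    hess = np.zeros((3 * n, 3 * n))
    idx_i, idx_j = np.nonzero(np.triu(net.adjacency))
    for i, j in zip(idx_i, idx_j):
        d = net.coords[j] - net.coords[i]
        r2 = float(d @ d)
        if r2 == 0.0:
            raise NumericalDegeneracyError(f"coincident nodes {i} and {j}")
        block = gamma * np.outer(d, d) / r2
        hess[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] -= block
        hess[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] -= block
        hess[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] += block
        hess[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] += block
    return hess


def cross_correlation(
    net: EnmNetwork, anisotropic: bool = False, covariance: np.ndarray | None = None
) -> CorrelationMatrix:
    """C_ij = cov_ij / sqrt(cov_ii cov_jj); diagonal exactly 1."""
    cov = compute_modes(net, anisotropic=anisotropic) if covariance is None else covariance
    diag = np.diag(cov).copy()
    lig = net.ligand_index()
    zero_ok = lig is not None and not net.adjacency[lig].any()
    tol = 1e-12 * max(diag.max(), 1.0)
    degenerate = diag <= tol
    if degenerate.any() and not (zero_ok and degenerate.sum() == 1 and degenerate[lig]):
        raise NumericalDegeneracyError("zero or negative diagonal covariance")
    norm = np.sqrt(np.where(degenerate, 1.0, diag))
    c = cov / np.outer(norm, norm)
    c[degenerate, :] = 0.0  # an uncoupled ligand node correlates with nothing
    c[:, degenerate] = 0.0
    np.fill_diagonal(c, 1.0)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    return CorrelationMatrix(values=c, nodes=list(net.nodes))


def mean_square_fluctuation(
    net: EnmNetwork, anisotropic: bool = False, covariance: np.ndarray | None = None
) -> FluctuationVector:
    """msf_i = cov_ii of the mode covariance."""
    cov = compute_modes(net, anisotropic=anisotropic) if covariance is None else covariance
    return FluctuationVector(msf=np.diag(cov).copy(), nodes=list(net.nodes))


def export_correlation(c: CorrelationMatrix) -> str:
    """Dense matrix as tab-separated text with a node-label header row."""
    header = "\t".join(str(n) for n in c.nodes)
    lines = [header]
    for i, node in enumerate(c.nodes):
        row = "\t".join(f"{v:.6f}" for v in c.values[i])
        lines.append(f"{node}\t{row}")
    return "\n".join(lines) + "\n"
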