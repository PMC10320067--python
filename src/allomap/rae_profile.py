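"""Reversed allosteric effect (RAE) per residue and per pocket.

The reversed-allosteric premise: perturbation at the orthosteric site
propagates outward, so a residue's response to orthosteric ligand
binding is measured as the change of its residue-residue interactions
inside a pocket between the apo and holo states,

    RAE_i = sum_{j in pocket, j != i} | I_holo,ij - I_apo,ij |,

with the pocket-level RAE the sum of RAE_i over lining residues.  The
interaction measure I_ij is the absolute elastic-network motion
correlation between lining residues; it is isolated behind
:func:`interaction_matrix` so alternative measures (contact energies,
raw covariances) can be swapped in.  Both network states share the holo
protein coordinates and differ only by the ligand pseudo-node.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .enm_dynamics import CorrelationMatrix
from .errors import EmptyProfileError, MappingError
from .pocket_finder import Pocket
from .structure_io import ResidueId


@dataclass
class InteractionMatrix:
    """|C_ij| restricted to a pocket's lining residues; zero diagonal."""

    values: np.ndarray
    residues: list[ResidueId]  # sorted ascending, defines the index order
    state_label: str
    pocket_id: int


@dataclass
class RaeProfile:
    pocket_id: int
    residues: list[ResidueId]
    rae: np.ndarray  # per-residue RAE_i >= 0, aligned with ``residues``

    @property
    def pocket_rae(self) -> float:
        """Pocket-level RAE: the sum of its residues' RAEs."""
        return float(self.rae.sum())


def interaction_matrix(
    c: CorrelationMatrix, pocket: Pocket, state_label: str
) -> InteractionMatrix:
    """Restrict |C| to the pocket's lining-residue pairs."""
    index = c.index_of()
    residues = sorted(pocket.lining_residues)
    missing = [r for r in residues if r not in index]
    if missing:
        raise MappingError(
            f"lining residues missing from correlation matrix: "
            f"{', '.join(str(r) for r in missing)}"
        )
    idx = [index[r] for r in residues]
    vals = np.abs(c.values[np.ix_(idx, idx)])
    np.fill_diagonal(vals, 0.0)
    return InteractionMatrix(
        values=vals, residues=residues, state_label=state_label,
        pocket_id=pocket.pocket_id,
    )


def residue_rae(i_apo: InteractionMatrix, i_holo: InteractionMatrix) -> RaeProfile:
    """Per-residue L1 change of in-pocket interactions between states."""
    if i_apo.pocket_id != i_holo.pocket_id or i_apo.residues != i_holo.residues:
        raise MappingError(
            "apo and holo interaction matrices cover different pockets/residues"
        )
    delta = np.abs(i_holo.values - i_apo.values)
    rae = delta.sum(axis=1)  # diagonal is zero in both states
    return RaeProfile(pocket_id=i_holo.pocket_id, residues=list(i_holo.residues),
                      rae=rae)


def top_rae_residue(profile: RaeProfile) -> ResidueId:
    """Lining residue with maximal RAE; ties go to the lowest ResidueId.

    This residue is the sink of the site's regulation pathway.
    """
    if len(profile.residues) == 0:
        raise EmptyProfileError(f"pocket {profile.pocket_id} has an empty profile")
    # residues are sorted ascending, so the first argmax is the tie-winner
    return profile.residues[int(np.argmax(profile.rae))]


def export_rae_table(profiles: list[RaeProfile]) -> str:
    """TSV (pocket_id, chain, number, name, RAE), descending RAE per pocket."""
    lines = ["pocket_id\tchain\tresidue_number\tresidue_name\trae"]
    for prof in profiles:
        order = np.argsort(-prof.rae, kind="stable")
        for k in order:
            r = prof.residues[k]
            lines.append(
                f"{prof.pocket_id}\t{r.chain}\t{r.number}{r.insertion_code}"
                f"\t{r.name}\t{prof.rae[k]:.6f}"
            )
    return "\n".join(lines) + "\n"
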