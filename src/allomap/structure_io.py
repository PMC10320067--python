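"""Read, validate and manipulate ligand-bound protein structures.

The analysis starts from a single holo structure in PDB format: the
protein with its orthosteric ligand bound.  This module parses that file
(via gemmi), enforces the size limit, optionally collapses redundant
(near-identical) chains, resolves which hetero group is the orthosteric
ligand, and derives the apo form by deleting that ligand.

Residues are identified throughout by author numbering
(chain, residue number, insertion code), as printed in the PDB file.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from Bio import Align

from .errors import (
    AmbiguousLigandError,
    EmptyStructureError,
    LigandNotFoundError,
    PdbParseError,
    StructureSizeError,
)

DEFAULT_MAX_BYTES = 5 * 1024 * 1024  # mirrors the 5 MB upload limit
DEFAULT_MAX_RESIDUES = 6000

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass(frozen=True, order=True)
class ResidueId:
    """Author-numbered residue identity: (chain, number, insertion code).

    ``name`` (three-letter residue name) rides along for reporting but does
    not participate in ordering or equality.
    """

    chain: str
    number: int
    insertion_code: str = ""
    name: str = field(default="", compare=False)

    def __str__(self) -> str:
        return f"{self.chain}:{self.name}{self.number}{self.insertion_code}"


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: tuple[float, float, float]
    occupancy: float = 1.0
    b_factor: float = 0.0

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass(frozen=True)
class LigandSpec:
    """A non-water hetero group: candidate orthosteric ligand."""

    het_name: str
    chain: str
    number: int
    atoms: tuple[Atom, ...]

    def __str__(self) -> str:
        return f"{self.het_name}:{self.chain}:{self.number}"

    @property
    def heavy_coords(self) -> np.ndarray:
        pts = [a.coord for a in self.atoms if not a.is_hydrogen]
        if not pts:  # all-hydrogen group should not occur; fall back to all atoms
            pts = [a.coord for a in self.atoms]
        return np.asarray(pts, dtype=float)

    def centroid(self) -> np.ndarray:
        return self.heavy_coords.mean(axis=0)


@dataclass
class ProteinStructure:
    """Parsed structure: ordered residues with coordinates plus ligands.

    ``coords`` holds one representative point per residue (C-alpha when
    present, else the heavy-atom centroid), in Angstrom, aligned with
    ``residues``.  ``chains`` maps chain id to its one-letter sequence.
    """

    residues: list[ResidueId]
    coords: np.ndarray
    atoms: dict[ResidueId, tuple[Atom, ...]]
    bfactors: np.ndarray
    chains: dict[str, str]
    ligands: list[LigandSpec]
    source_label: str = ""

    def __post_init__(self):
        if len(self.residues) == 0:
            raise EmptyStructureError(
                f"no protein residues in '{self.source_label}'"
            )
        if len({(r.chain, r.number, r.insertion_code) for r in self.residues}) != len(
            self.residues
        ):
            raise PdbParseError("duplicate residue identifiers in structure")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def index_of(self) -> dict[ResidueId, int]:
        return {r: i for i, r in enumerate(self.residues)}

    def heavy_atom_coords(self) -> tuple[np.ndarray, list[ResidueId]]:
        """All protein heavy-atom coordinates with their owning residue."""
        pts, owners = [], []
        for rid in self.residues:
            for a in self.atoms[rid]:
                if not a.is_hydrogen:
                    pts.append(a.coord)
                    owners.append(rid)
        return np.asarray(pts, dtype=float), owners


def _is_amino_acid(name: str) -> bool:
    info = gemmi.find_tabulated_residue(name)
    return info is not None and info.is_amino_acid()


def _one_letter(name: str) -> str:
    info = gemmi.find_tabulated_residue(name)
    if info is not None and info.is_amino_acid():
        code = info.one_letter_code.upper()
        if code.isalpha():
            return code
    return "X"


def _resolve_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per atom name: highest occupancy, ties by altloc letter."""
    best: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = best.get(atom.name)
        if prev is None:
            best[atom.name] = atom
            continue
        # higher occupancy wins; on a tie the earlier altloc letter wins
        if (atom.occ, prev.altloc or "~") > (prev.occ, atom.altloc or "~"):
            best[atom.name] = atom
    # preserve file order of first appearance
    seen, ordered = set(), []
    for atom in res:
        if atom.name not in seen:
            seen.add(atom.name)
            ordered.append(best[atom.name])
    return ordered


def load_structure(
    source: str | os.PathLike,
    max_size: int = DEFAULT_MAX_BYTES,
    max_residues: int = DEFAULT_MAX_RESIDUES,
) -> ProteinStructure:
    """Parse a PDB file or PDB-format text into a :class:`ProteinStructure`.

    Waters are discarded; every other hetero group becomes a
    :class:`LigandSpec`.  Only the first model of a multi-model file is
    kept, and alternate locations collapse to the highest-occupancy
    conformer.

    Raises
    ------
    StructureSizeError
        If the file exceeds ``max_size`` bytes or ``max_residues`` residues.
    PdbParseError, EmptyStructureError
    """
    if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
        n_bytes = os.path.getsize(source)
        if n_bytes > max_size:
            raise StructureSizeError(
                f"'{source}' is {n_bytes} bytes; the limit is {max_size} bytes"
            )
        with open(source) as fh:
            text = fh.read()
        label = os.path.basename(str(source))
    else:
        text = str(source)
        if len(text.encode()) > max_size:
            raise StructureSizeError(
                f"input text exceeds the {max_size}-byte limit"
            )
        label = "<text>"

    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # gemmi reports the line number
        raise PdbParseError(f"cannot parse '{label}': {exc}") from exc

    if len(st) == 0:
        raise EmptyStructureError(f"no models in '{label}'")
    model = st[0]  # multi-model (NMR-style) input: keep model 1

    residues: list[ResidueId] = []
    coords: list[np.ndarray] = []
    atoms: dict[ResidueId, tuple[Atom, ...]] = {}
    bfactors: list[float] = []
    chains: dict[str, str] = {}
    ligands: list[LigandSpec] = []

    for chain in model:
        for res in chain:
            if res.name in _WATER_NAMES or res.is_water():
                continue
            picked = [
                Atom(
                    name=a.name,
                    element=a.element.name,
                    coord=(a.pos.x, a.pos.y, a.pos.z),
                    occupancy=a.occ,
                    b_factor=a.b_iso,
                )
                for a in _resolve_altlocs(res)
            ]
            if not picked:
                continue
            icode = res.seqid.icode.strip()
            if _is_amino_acid(res.name):
                rid = ResidueId(chain.name, res.seqid.num, icode, res.name)
                if rid in atoms:
                    continue  # duplicated record; keep first occurrence
                heavy = [a for a in picked if not a.is_hydrogen] or picked
                ca = next((a for a in heavy if a.name == "CA"), None)
                rep = (
                    np.asarray(ca.coord)
                    if ca is not None
                    else np.mean([a.coord for a in heavy], axis=0)
                )
                residues.append(rid)
                coords.append(rep)
                atoms[rid] = tuple(picked)
                bfactors.append(float(np.mean([a.b_factor for a in heavy])))
                chains[chain.name] = chains.get(chain.name, "") + _one_letter(res.name)
            else:
                ligands.append(
                    LigandSpec(res.name, chain.name, res.seqid.num, tuple(picked))
                )

    if not residues:
        raise EmptyStructureError(f"no protein residues in '{label}'")
    if len(residues) > max_residues:
        raise StructureSizeError(
            f"{len(residues)} residues exceed the limit of {max_residues}"
        )

    return ProteinStructure(
        residues=residues,
        coords=np.asarray(coords, dtype=float),
        atoms=atoms,
        bfactors=np.asarray(bfactors, dtype=float),
        chains=chains,
        ligands=ligands,
        source_label=label,
    )


def _sequence_identity(a: str, b: str) -> float:
    """Global-alignment identity: matched columns / alignment length."""
    if not a or not b:
        return 0.0
    if a == b:
        return 1.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aln = aligner.align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(s1, s2) if x == y and x != "-")
    return matches / len(s1)


def _chain_contacts_ligand(
    s: ProteinStructure, chain_id: str, cutoff: float = 4.5
) -> bool:
    chain_pts = []
    for rid in s.residues:
        if rid.chain == chain_id:
            chain_pts.extend(a.coord for a in s.atoms[rid] if not a.is_hydrogen)
    if not chain_pts or not s.ligands:
        return False
    chain_pts = np.asarray(chain_pts)
    for lig in s.ligands:
        d = np.linalg.norm(chain_pts[:, None, :] - lig.heavy_coords[None], axis=-1)
        if d.min() <= cutoff:
            return True
    return False


def remove_redundant_chains(
    s: ProteinStructure, identity_threshold: float = 0.95
) -> ProteinStructure:
    """Collapse groups of near-identical chains to a single representative.

    Chains whose pairwise global sequence identity reaches
    ``identity_threshold`` form a redundancy group; one chain per group is
    kept, preferring (1) a chain contacting any ligand, (2) the longest
    chain, (3) the first chain identifier.  Ligands on removed chains are
    dropped.  Idempotent; single-chain input is returned unchanged.
    """
    chain_ids = list(s.chains)
    if len(chain_ids) <= 1:
        return s

    # union-find over chains with identity >= threshold
    parent = {c: c for c in chain_ids}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for i, ci in enumerate(chain_ids):
        for cj in chain_ids[i + 1 :]:
            if _sequence_identity(s.chains[ci], s.chains[cj]) >= identity_threshold:
                parent[find(ci)] = find(cj)

    groups: dict[str, list[str]] = {}
    for c in chain_ids:
        groups.setdefault(find(c), []).append(c)

    kept: set[str] = set()
    for members in groups.values():
        members.sort(
            key=lambda c: (
                not _chain_contacts_ligand(s, c),
                -len(s.chains[c]),
                c,
            )
        )
        kept.add(members[0])

    if kept == set(chain_ids):
        return s

    residues = [r for r in s.residues if r.chain in kept]
    mask = np.array([r.chain in kept for r in s.residues])
    return ProteinStructure(
        residues=residues,
        coords=s.coords[mask],
        atoms={r: s.atoms[r] for r in residues},
        bfactors=s.bfactors[mask],
        chains={c: seq for c, seq in s.chains.items() if c in kept},
        ligands=[l for l in s.ligands if l.chain in kept],
        source_label=s.source_label,
    )


def ligand_candidates(s: ProteinStructure) -> list[LigandSpec]:
    """Hetero groups eligible as the orthosteric ligand.

    Waters never reach the ligand list; single-atom groups (ions) are
    additionally excluded here.
    """
    return [l for l in s.ligands if len(l.atoms) > 1]


def select_orthosteric_ligand(s: ProteinStructure, spec: str = "") -> LigandSpec:
    """Resolve the orthosteric ligand from a "NAME:CHAIN:NUMBER" spec.

    With an empty spec the unique candidate is returned; several
    candidates raise :class:`AmbiguousLigandError` listing them.
    """
    if spec:
        parts = spec.split(":")
        if len(parts) != 3:
            raise LigandNotFoundError(
                f"ligand spec '{spec}' is not of the form NAME:CHAIN:NUMBER"
            )
        name, chain, number = parts[0], parts[1], parts[2]
        try:
            num = int(number)
        except ValueError as exc:
            raise LigandNotFoundError(f"bad residue number in '{spec}'") from exc
        for lig in s.ligands:
            if lig.het_name == name and lig.chain == chain and lig.number == num:
                return lig
        raise LigandNotFoundError(
            f"no hetero group matches '{spec}' in '{s.source_label}'"
        )
    cands = ligand_candidates(s)
    if not cands:
        raise LigandNotFoundError(f"no ligand candidates in '{s.source_label}'")
    if len(cands) > 1:
        raise AmbiguousLigandError(cands)
    return cands[0]


def make_apo(s: ProteinStructure, lig: LigandSpec) -> ProteinStructure:
    """Delete exactly the orthosteric ligand, leaving the protein untouched.

    The apo state used for the reversed-allosteric comparison is the holo
    structure minus the ligand: identical protein coordinates.
    """
    if lig not in s.ligands:
        raise LigandNotFoundError(f"ligand {lig} is not part of the structure")
    remaining = [l for l in s.ligands if l != lig]
    return replace(s, ligands=remaining)


def to_pdb_string(s: ProteinStructure) -> str:
    """Serialize back to PDB text (round-trips the residue/ligand inventory)."""
    st = gemmi.Structure()
    st.name = s.source_label or "allomap"
    model = gemmi.Model("1")
    chain_order: dict[str, gemmi.Chain] = {}

    def get_chain(cid: str) -> gemmi.Chain:
        if cid not in chain_order:
            chain_order[cid] = gemmi.Chain(cid)
        return chain_order[cid]

    def add_residue(cid, name, number, icode, atom_list, het):
        res = gemmi.Residue()
        res.name = name
        res.seqid = gemmi.SeqId(number, icode or " ")
        res.het_flag = "H" if het else "A"
        for a in atom_list:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.coord)
            ga.occ = a.occupancy
            ga.b_iso = a.b_factor
            res.add_atom(ga)
        get_chain(cid).add_residue(res)

    for rid in s.residues:
        add_residue(rid.chain, rid.name, rid.number, rid.insertion_code,
                    s.atoms[rid], het=False)
    for lig in s.ligands:
        add_residue(lig.chain, lig.het_name, lig.number, "", lig.atoms, het=True)

    for chain in chain_order.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()
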