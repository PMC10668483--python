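"""Fragment-mapped differential reaction fingerprint (DRFP).

A reaction is encoded by taking, on each side of the arrow, the set of
circular substructures ("shingles") of every molecule up to a bond radius,
serialising each as one canonical SMILES, and keeping the symmetric
difference of the two sets.  Each surviving fragment is hashed to a 32-bit
integer and folded modulo the fingerprint length to set a bit.

Unlike a plain hashed fingerprint, every bit remembers which fragment
SMILES set it and which atoms each fragment covers — the mapping that later
lets additive feature attributions be painted back onto the molecules.

Conventions follow the explainability-oriented DRFP variant: hydrogens are
explicit in fragment SMILES by default (``[H]C([H])([H])OC([H])([H])[H]``
rather than ``COC``) and each fragment is serialised as a single canonical,
non-rooted SMILES, both of which reduce the number of distinct strings
competing for bits.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from rdkit import Chem

from .chem_io import ReactionRecord, parse_reaction_smiles
from .errors import InputError

__all__ = [
    "FingerprintParams",
    "FragmentOccurrence",
    "MappedFingerprint",
    "CorpusIndex",
    "extract_shingles",
    "hash32",
    "encode_reaction",
    "encode_corpus",
    "nearest_neighbors",
]


@dataclass(frozen=True)
class FingerprintParams:
    """DRFP parameters: folded length, shingle radius, SMILES conventions."""

    dim: int = 10240
    radius: int = 2
    include_hydrogens: bool = True
    root_central_atom: bool = False
    include_rings: bool = False  # ring-system shingles of the original DRFP

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise InputError("fingerprint dim must be >= 1")
        if self.radius < 0:
            raise InputError("radius must be >= 0")

    def to_dict(self) -> dict:
        return {
            "dim": self.dim,
            "radius": self.radius,
            "include_hydrogens": self.include_hydrogens,
            "root_central_atom": self.root_central_atom,
            "include_rings": self.include_rings,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FingerprintParams":
        return cls(**d)


@dataclass(frozen=True)
class FragmentOccurrence:
    """One placement of a fragment inside a parent molecule.

    ``atom_indices`` refer to heavy atoms of the parent molecule as written
    in the reaction SMILES (explicit-H shingle atoms are projected onto the
    heavy atom that carries them, so occurrences stay valid for depiction).
    """

    smiles: str
    molecule_index: int
    atom_indices: frozenset[int]
    side: str  # "reactant" | "product"


@dataclass
class MappedFingerprint:
    bits: np.ndarray  # uint8 vector of length dim
    on_bits: frozenset[int]
    bit_to_fragments: dict[int, set[str]]
    fragment_to_occurrences: dict[str, list[FragmentOccurrence]]
    params: FingerprintParams


@dataclass
class CorpusIndex:
    matrix: np.ndarray  # n_reactions x dim, uint8
    global_bit_to_fragments: dict[int, set[str]]
    records: list[ReactionRecord]
    params: FingerprintParams
    fingerprints: list[MappedFingerprint] = field(default_factory=list)

    def save(self, path) -> None:
        meta = {
            "params": self.params.to_dict(),
            "bit_to_fragments": {str(k): sorted(v) for k, v in self.global_bit_to_fragments.items()},
            "records": [
                {"rxn_smiles": r.reaction_smiles, "ec": r.ec.render(), "source": r.source}
                for r in self.records
            ],
        }
        np.savez_compressed(path, matrix=self.matrix, meta=json.dumps(meta))

    @classmethod
    def load(cls, path) -> "CorpusIndex":
        from .chem_io import parse_ec

        with np.load(path, allow_pickle=False) as data:
            matrix = data["matrix"]
            meta = json.loads(str(data["meta"]))
        params = FingerprintParams.from_dict(meta["params"])
        records = [
            ReactionRecord(r["rxn_smiles"], parse_ec(r["ec"]), r["source"])
            for r in meta["records"]
        ]
        g = {int(k): set(v) for k, v in meta["bit_to_fragments"].items()}
        return cls(matrix=matrix, global_bit_to_fragments=g, records=records, params=params)


# --------------------------------------------------------------------------
# Shingle extraction
# --------------------------------------------------------------------------

def extract_shingles(
    mol: Chem.Mol,
    params: FingerprintParams,
    molecule_index: int = 0,
    side: str = "reactant",
) -> set[FragmentOccurrence]:
    """Circular substructures of every atom at radii 0..params.radius.

    With ``include_hydrogens`` the molecule graph gets explicit hydrogens
    before extraction, so fragment SMILES spell them out; with
    ``root_central_atom`` off, each fragment is one canonical SMILES
    regardless of which atom it was grown from.
    """
    if mol is None:
        raise InputError("invalid molecule")
    n_heavy = mol.GetNumAtoms()
    work = Chem.AddHs(mol) if params.include_hydrogens else mol

    def project(atoms: Iterable[int]) -> frozenset[int]:
        # map explicit-H atoms back onto their heavy neighbour
        out = set()
        for a in atoms:
            if a < n_heavy:
                out.add(a)
            else:
                nbrs = work.GetAtomWithIdx(a).GetNeighbors()
                if nbrs:
                    out.add(nbrs[0].GetIdx())
        return frozenset(out)

    seen: set[tuple[str, frozenset[int]]] = set()
    occurrences: set[FragmentOccurrence] = set()

    def emit(smiles: str, atom_ids: Iterable[int]) -> None:
        if not smiles:
            return
        key = (smiles, frozenset(atom_ids))
        if key in seen:
            return
        seen.add(key)
        occurrences.add(FragmentOccurrence(smiles, molecule_index, project(atom_ids), side))

    for atom in work.GetAtoms():
        idx = atom.GetIdx()
        emit(Chem.MolFragmentToSmiles(work, atomsToUse=[idx], canonical=True), [idx])
        for radius in range(1, params.radius + 1):
            env = Chem.FindAtomEnvironmentOfRadiusN(work, radius, idx, True)
            if not env:
                continue  # molecule smaller than this radius from here
            atoms = set()
            for b in env:
                bond = work.GetBondWithIdx(b)
                atoms.add(bond.GetBeginAtomIdx())
                atoms.add(bond.GetEndAtomIdx())
            try:
                smiles = Chem.MolFragmentToSmiles(
                    work,
                    atomsToUse=sorted(atoms),
                    bondsToUse=list(env),
                    canonical=True,
                    rootedAtAtom=idx if params.root_central_atom else -1,
                )
            except Exception:  # rare sanitisation failures
                continue
            emit(smiles, atoms)

    if params.include_rings:
        ri = work.GetRingInfo()
        for ring_bonds in ri.BondRings():
            atoms = set()
            for b in ring_bonds:
                bond = work.GetBondWithIdx(b)
                atoms.add(bond.GetBeginAtomIdx())
                atoms.add(bond.GetEndAtomIdx())
            try:
                smiles = Chem.MolFragmentToSmiles(
                    work, atomsToUse=sorted(atoms), bondsToUse=list(ring_bonds), canonical=True
                )
            except Exception:
                continue
            emit(smiles, atoms)

    return occurrences


def hash32(fragment_smiles: str) -> int:
    """Deterministic, platform-independent 32-bit hash (CRC-32 of UTF-8)."""
    if not fragment_smiles:
        raise InputError("cannot hash an empty fragment SMILES")
    return zlib.crc32(fragment_smiles.encode("utf-8")) & 0xFFFFFFFF


# --------------------------------------------------------------------------
# Reaction / corpus encoding
# --------------------------------------------------------------------------

def encode_reaction(
    record: ReactionRecord | str,
    params: Optional[FingerprintParams] = None,
) -> MappedFingerprint:
    """Encode one reaction into a mapped differential fingerprint.

    Agents (the middle reaction-SMILES field) are merged into the reactant
    side; the differential fingerprint is defined on two sides only.  A
    reaction whose two shingle sets coincide legally encodes to the all-zero
    vector with empty maps.
    """
    if params is None:
        params = FingerprintParams()
    smiles = record if isinstance(record, str) else record.reaction_smiles
    reactants, agents, products = parse_reaction_smiles(smiles)
    reactant_mols = reactants + agents

    occurrences: list[FragmentOccurrence] = []
    side_sets: dict[str, set[str]] = {"reactant": set(), "product": set()}
    mol_index = 0
    for side, mols in (("reactant", reactant_mols), ("product", products)):
        for mol in mols:
            occ = extract_shingles(mol, params, molecule_index=mol_index, side=side)
            occurrences.extend(occ)
            side_sets[side].update(o.smiles for o in occ)
            mol_index += 1

    diff = side_sets["reactant"] ^ side_sets["product"]

    bits = np.zeros(params.dim, dtype=np.uint8)
    bit_to_fragments: dict[int, set[str]] = {}
    fragment_to_occurrences: dict[str, list[FragmentOccurrence]] = {}
    for frag in diff:
        bit = hash32(frag) % params.dim
        bits[bit] = 1
        bit_to_fragments.setdefault(bit, set()).add(frag)
        fragment_to_occurrences[frag] = sorted(
            (o for o in occurrences if o.smiles == frag),
            key=lambda o: (o.side, o.molecule_index, sorted(o.atom_indices)),
        )
    return MappedFingerprint(
        bits=bits,
        on_bits=frozenset(bit_to_fragments),
        bit_to_fragments=bit_to_fragments,
        fragment_to_occurrences=fragment_to_occurrences,
        params=params,
    )


def encode_corpus(
    records: Sequence[ReactionRecord],
    params: Optional[FingerprintParams] = None,
    *,
    keep_fingerprints: bool = True,
) -> CorpusIndex:
    """Encode every record; accumulate the corpus-wide bit -> fragment map."""
    if not records:
        raise InputError("cannot encode an empty corpus")
    if params is None:
        params = FingerprintParams()
    rows = []
    global_map: dict[int, set[str]] = {}
    fingerprints: list[MappedFingerprint] = []
    kept: list[ReactionRecord] = []
    for rec in records:
        fp = encode_reaction(rec, params)
        rows.append(fp.bits)
        for bit, frags in fp.bit_to_fragments.items():
            global_map.setdefault(bit, set()).update(frags)
        if keep_fingerprints:
            fingerprints.append(fp)
        kept.append(rec)
    return CorpusIndex(
        matrix=np.vstack(rows),
        global_bit_to_fragments=global_map,
        records=kept,
        params=params,
        fingerprints=fingerprints,
    )


def nearest_neighbors(
    index: CorpusIndex,
    query: MappedFingerprint | np.ndarray,
    k: int = 5,
) -> list[tuple[int, float]]:
    """Exact Jaccard (Tanimoto) search over on-bit sets, descending.

    Ties broken by record id ascending.  Convention: Jaccard(0, anything)
    is 0 (empty union counts as similarity 0).
    """
    if k < 1:
        raise InputError("k must be >= 1")
    if index.matrix.size == 0 or len(index.records) == 0:
        raise InputError("empty corpus index")
    q = query.bits if isinstance(query, MappedFingerprint) else np.asarray(query)
    if q.shape[0] != index.matrix.shape[1]:
        raise InputError(
            f"query dim {q.shape[0]} != corpus dim {index.matrix.shape[1]}"
        )
    q = q.astype(np.int64)
    m = index.matrix.astype(np.int64)
    inter = m @ q
    union = m.sum(axis=1) + q.sum() - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    order = sorted(range(len(sim)), key=lambda i: (-sim[i], i))
    return [(i, float(sim[i])) for i in order[:k]]
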