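"""Molecular graphs and fragment-pair structural descriptors.

A molecule is reduced to a set of *descriptor keys* with four slots:

* ``sd1`` — a structure token for an atom environment or a ring,
* ``ld``  — the topological length (shortest-path bond count) between the
  two sites, with 0 reserved for a site paired with itself,
* ``sd2`` — the structure token of the second site,
* ``bd``  — a bond-path code classifying the bonds along one canonical
  shortest path between the sites.

Any non-empty subset of the four slots is itself a descriptor (a
*projection* of the full quadruple), so a molecule contributes bare tokens,
token–distance pairs, token–token pairs, and full quadruples to its
profile.  Descriptor profiles are the raw material for class-frequency
enrichment: a descriptor over-represented among active compounds is a
candidate pharmacophore.

Atom environments are tokenized by element, charge, aromaticity, hydrogen
count and bond-order pattern into a small printed vocabulary (``-CH3``,
``>C(<)``, ``>C=``, ``-C(Ar)<``, ``-N<``, ``-N=``, ``>N+=``, ``=NH``,
``-OH``, ``>O``, ``=O``, ``>S``, ``-Cl``, ``>PH<``, ...); environments
outside the vocabulary fall back to a generated ``El(pattern)`` token
rather than failing.  Rings are tokenized as ``CycNN`` / ``CycArNN``
(e.g. ``Cyc06``, ``CycAr06``).

The bond-path code dialect used here (documented in docs/methods.md):

* ``...`` — every bond on the path is a single bond and no path atom is
  aromatic;
* ``.A.`` — every bond on the path is aromatic (path runs through an
  aromatic ring);
* ``.a.`` — the path mixes aromatic and non-aromatic bonds, or is all
  single bonds but touches an aromatic atom;
* ``p..`` — the path contains a non-aromatic double/triple bond and no
  aromatic atom;
* ``pA.`` — the path contains a non-aromatic double/triple bond and an
  aromatic atom (pi bond adjacent to an aromatic system).
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # rdkit parse errors are re-raised as ValueError

# Bond-path codes of the documented dialect.
BD_SINGLE = "..."
BD_AROMATIC_TOUCH = ".a."
BD_AROMATIC_THROUGH = ".A."
BD_PI = "p.."
BD_PI_AROMATIC = "pA."

#: Slot names of the descriptor quadruple, in canonical order.
SLOTS = ("sd1", "ld", "sd2", "bd")

#: The full set of non-empty slot subsets, largest first.
ALL_FAMILIES: tuple[frozenset[str], ...] = tuple(
    sorted(
        (
            frozenset(s)
            for s in (
                {"sd1"}, {"ld"}, {"sd2"}, {"bd"},
                {"sd1", "ld"}, {"sd1", "sd2"}, {"sd1", "bd"},
                {"ld", "sd2"}, {"ld", "bd"}, {"sd2", "bd"},
                {"sd1", "ld", "sd2"}, {"sd1", "ld", "bd"},
                {"sd1", "sd2", "bd"}, {"ld", "sd2", "bd"},
                {"sd1", "ld", "sd2", "bd"},
            )
        ),
        key=lambda s: (-len(s), sorted(s)),
    )
)


# ---------------------------------------------------------------------------
# Molecule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom: element, formal charge, aromaticity, hydrogens, rings."""

    symbol: str
    charge: int
    aromatic: bool
    n_hydrogens: int
    rings: frozenset[int]


@dataclass(frozen=True)
class BondRecord:
    """One bond between heavy atoms; order is 1, 2 or 3 (aromatic flagged)."""

    atoms: tuple[int, int]
    order: int
    aromatic: bool


@dataclass(frozen=True)
class Molecule:
    """A connected molecular graph with perceived aromaticity and rings.

    Ring perception is RDKit's symmetrized smallest set of smallest rings,
    which is deterministic for a given input graph.
    """

    id: str
    atoms: tuple[AtomRecord, ...]
    bonds: tuple[BondRecord, ...]
    rings: tuple[frozenset[int], ...]
    provenance: str = ""

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for b in self.bonds:
            if i == b.atoms[0]:
                out.append(b.atoms[1])
            elif i == b.atoms[1]:
                out.append(b.atoms[0])
        return sorted(out)


def _bond_order(bond: Chem.Bond) -> int:
    if bond.GetIsAromatic():
        return 1
    t = bond.GetBondType()
    if t == Chem.BondType.SINGLE:
        return 1
    if t == Chem.BondType.DOUBLE:
        return 2
    if t == Chem.BondType.TRIPLE:
        return 3
    raise ValueError(f"unsupported bond type {t}")


def _from_rdkit(mol: Chem.Mol, mol_id: str, provenance: str) -> Molecule:
    if mol.GetNumAtoms() == 0:
        raise ValueError(f"{mol_id}: empty molecule")
    frags = Chem.GetMolFrags(mol)
    if len(frags) > 1:
        raise ValueError(
            f"{mol_id}: multi-fragment input ({len(frags)} components) is rejected"
        )
    ring_info = mol.GetRingInfo()
    rings = tuple(frozenset(r) for r in ring_info.AtomRings())
    atom_rings: list[set[int]] = [set() for _ in range(mol.GetNumAtoms())]
    for ri, ring in enumerate(rings):
        for ai in ring:
            atom_rings[ai].add(ri)
    atoms = tuple(
        AtomRecord(
            symbol=a.GetSymbol(),
            charge=a.GetFormalCharge(),
            aromatic=a.GetIsAromatic(),
            n_hydrogens=a.GetTotalNumHs(),
            rings=frozenset(atom_rings[a.GetIdx()]),
        )
        for a in mol.GetAtoms()
    )
    bonds = tuple(
        BondRecord(
            atoms=(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
            order=_bond_order(b),
            aromatic=b.GetIsAromatic(),
        )
        for b in mol.GetBonds()
    )
    return Molecule(id=mol_id, atoms=atoms, bonds=bonds, rings=rings,
                    provenance=provenance)


def parse_structure(record: str, mol_id: str = "", provenance: str = "") -> Molecule:
    """Parse a SMILES string into a connected :class:`Molecule`.

    Raises ``ValueError`` with the record id on parse failure or
    multi-fragment input.
    """
    mol = Chem.MolFromSmiles(record)
    if mol is None:
        raise ValueError(f"{mol_id or record!r}: SMILES parse failure")
    return _from_rdkit(mol, mol_id or Chem.MolToSmiles(mol), provenance or record)


def parse_sdf(path) -> list[Molecule]:
    """Read an SDF (V2000) file into a list of molecules."""
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    out = []
    for i, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"{path}: record {i} failed to parse")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"sdf_{i}"
        out.append(_from_rdkit(mol, name, f"{path}:{i}"))
    return out


def parse_smiles_file(path) -> list[Molecule]:
    """Read a SMILES file: one record per line, ``smiles[<tab>id]``."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0].strip()
            mol_id = parts[1].strip() if len(parts) > 1 else f"line_{i + 1}"
            out.append(parse_structure(smiles, mol_id, f"{path}:{i + 1}"))
    return out


# ---------------------------------------------------------------------------
# Structure tokens
# ---------------------------------------------------------------------------

def atom_token(mol: Molecule, atom: int) -> str:
    """Assign the structure token of one heavy atom.

    The rules run in order; the first match wins.  Environments that match
    no rule yield a generated ``El(...)`` fallback so tokenization is total.
    """
    a = mol.atoms[atom]
    orders = sorted(b.order for b in mol.bonds if atom in b.atoms)
    has_multiple = any(o > 1 for o in orders)
    el, q, h = a.symbol, a.charge, a.n_hydrogens

    if el in ("F", "Cl", "Br", "I") and q == 0:
        return f"-{el}"
    if el == "C" and q == 0:
        if a.aromatic:
            return "-C(Ar)<"
        if h == 3:
            return "-CH3"
        if has_multiple:
            return ">C="
        return ">C(<)"
    if el == "N":
        if q > 0:
            return ">N+="
        if q == 0:
            if a.aromatic or has_multiple:
                return "=NH" if h >= 1 else "-N="
            return "-N<"
    if el == "O" and q == 0:
        if h >= 1:
            return "-OH"
        if has_multiple or a.aromatic:
            return "=O"
        return ">O"
    if el == "S" and q == 0 and not has_multiple and h == 0:
        return ">S"
    if el == "P" and q == 0 and h >= 1:
        return ">PH<"
    pattern = f"{''.join(map(str, orders))},h{h},{q:+d}" + (",ar" if a.aromatic else "")
    return f"{el}({pattern})"


def ring_token(mol: Molecule, ring_index: int) -> str:
    """``CycNN`` / ``CycArNN`` token for one perceived ring."""
    ring = mol.rings[ring_index]
    aromatic = all(mol.atoms[i].aromatic for i in ring)
    return f"Cyc{'Ar' if aromatic else ''}{len(ring):02d}"


# ---------------------------------------------------------------------------
# Paths and bond codes
# ---------------------------------------------------------------------------

def _adjacency(mol: Molecule) -> list[list[int]]:
    adj: list[list[int]] = [[] for _ in range(mol.n_atoms)]
    for b in mol.bonds:
        i, j = b.atoms
        adj[i].append(j)
        adj[j].append(i)
    for nbrs in adj:
        nbrs.sort()
    return adj


def _bfs_distances(adj: Sequence[Sequence[int]], src: int) -> list[int]:
    dist = [-1] * len(adj)
    dist[src] = 0
    queue = deque([src])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if dist[v] < 0:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


class _MolGraph:
    """Per-molecule cache: adjacency, all-pairs BFS distances, bond lookup."""

    def __init__(self, mol: Molecule):
        self.mol = mol
        self.adj = _adjacency(mol)
        self.dist = [_bfs_distances(self.adj, s) for s in range(mol.n_atoms)]
        self.bond_by_pair = {frozenset(b.atoms): b for b in mol.bonds}

    def shortest_path(self, i: int, j: int) -> list[int]:
        if i == j:
            return [i]
        dist_j = self.dist[j]
        if dist_j[i] < 0:
            raise ValueError(f"{self.mol.id}: atoms {i} and {j} are disconnected")
        path = [i]
        cur = i
        while cur != j:
            # smallest-index neighbor that stays on a shortest path
            cur = min(v for v in self.adj[cur] if dist_j[v] == dist_j[cur] - 1)
            path.append(cur)
        return path

    def path_bond_code(self, i: int, j: int) -> str:
        if i == j:
            raise ValueError("path_bond_code requires two distinct atoms")
        path = self.shortest_path(i, j)
        atoms = self.mol.atoms
        bonds = [self.bond_by_pair[frozenset((a, b))]
                 for a, b in zip(path, path[1:])]
        any_aromatic_bond = any(b.aromatic for b in bonds)
        all_aromatic = all(b.aromatic for b in bonds)
        any_pi = any(b.order > 1 and not b.aromatic for b in bonds)
        any_aromatic_atom = any(atoms[a].aromatic for a in path)
        if any_aromatic_bond:
            return BD_AROMATIC_THROUGH if all_aromatic else BD_AROMATIC_TOUCH
        if any_pi:
            return BD_PI_AROMATIC if any_aromatic_atom else BD_PI
        return BD_AROMATIC_TOUCH if any_aromatic_atom else BD_SINGLE


def shortest_path(mol: Molecule, i: int, j: int) -> list[int]:
    """The lexicographically smallest shortest atom-index path from i to j."""
    return _MolGraph(mol).shortest_path(i, j)


def path_bond_code(mol: Molecule, i: int, j: int) -> str:
    """Classify the bonds along the canonical shortest path from i to j."""
    return _MolGraph(mol).path_bond_code(i, j)


# ---------------------------------------------------------------------------
# Descriptor keys and enumeration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DescriptorKey:
    """A fragment-pair descriptor: any non-empty subset of the four slots.

    Empty slots are ``None``; the key is stored in canonical form (the
    lexicographically smaller structure token first; a lone second token is
    moved into the first slot).
    """

    sd1: str | None = None
    ld: int | None = None
    sd2: str | None = None
    bd: str | None = None

    def __post_init__(self):
        if self.sd1 is None and self.ld is None and self.sd2 is None and self.bd is None:
            raise ValueError("descriptor key must have at least one non-empty slot")

    @staticmethod
    def canonical(sd1=None, ld=None, sd2=None, bd=None) -> "DescriptorKey":
        if sd1 is None and sd2 is not None:
            sd1, sd2 = sd2, None
        if sd1 is not None and sd2 is not None and sd2 < sd1:
            sd1, sd2 = sd2, sd1
        return DescriptorKey(sd1=sd1, ld=ld, sd2=sd2, bd=bd)

    def project(self, family: frozenset[str]) -> "DescriptorKey | None":
        """Project onto a slot subset and re-canonicalize.

        Returns ``None`` when every retained slot is empty (e.g. the bond
        code of a zero-length pair projected onto ``{bd}``).
        """
        slots = dict(
            sd1=self.sd1 if "sd1" in family else None,
            ld=self.ld if "ld" in family else None,
            sd2=self.sd2 if "sd2" in family else None,
            bd=self.bd if "bd" in family else None,
        )
        if all(v is None for v in slots.values()):
            return None
        return DescriptorKey.canonical(**slots)

    def as_tuple(self) -> tuple:
        return (self.sd1 or "", "" if self.ld is None else self.ld,
                self.sd2 or "", self.bd or "")

    @property
    def sort_key(self) -> tuple[str, str, str, str]:
        """All-string tuple usable as a deterministic ordering key."""
        return tuple(str(v) for v in self.as_tuple())

    def __str__(self) -> str:
        ld = "" if self.ld is None else str(self.ld)
        return f"[{self.sd1 or ''}|{ld}|{self.sd2 or ''}|{self.bd or ''}]"


@dataclass
class DescriptorProfile:
    """Per-molecule descriptor counts."""

    molecule_id: str
    counts: Counter = field(default_factory=Counter)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _sites(mol: Molecule) -> list[tuple[str, frozenset[int]]]:
    """Tokenized sites: every heavy atom, then every perceived ring.

    A ring site occupies its full atom set; its distance to another site is
    the minimum over its atoms.
    """
    sites = [(atom_token(mol, i), frozenset((i,))) for i in range(mol.n_atoms)]
    sites += [(ring_token(mol, r), mol.rings[r]) for r in range(len(mol.rings))]
    return sites


def _site_pair_geometry(mol, dist, a_atoms: frozenset[int], b_atoms: frozenset[int]):
    """(distance, endpoint atom pair) between two sites.

    The representative endpoints are the smallest-index atom pair realizing
    the minimum distance, which keeps the bond code deterministic.
    """
    best = None
    for u in sorted(a_atoms):
        for v in sorted(b_atoms):
            d = dist[u][v]
            if best is None or d < best[0]:
                best = (d, u, v)
    return best


def enumerate_descriptors(
    mol: Molecule,
    max_length: int = 5,
    families: Iterable[frozenset[str]] = ALL_FAMILIES,
) -> DescriptorProfile:
    """Enumerate fragment-pair descriptors of a molecule.

    The full quadruple is emitted for every unordered pair of distinct
    sites (atoms and rings) at topological distance ``<= max_length``;
    every requested slot-subset family then receives the projection of each
    quadruple.  The single-token family ``{sd1}`` is special-cased to one
    bare token per site, so its total equals the heavy-atom count plus the
    ring count.
    """
    families = [frozenset(f) for f in families]
    if not families:
        raise ValueError("families must be non-empty")
    if max_length < 0:
        raise ValueError("max_length must be >= 0")
    profile = DescriptorProfile(molecule_id=mol.id)
    sites = _sites(mol)
    graph = _MolGraph(mol)
    dist = graph.dist

    sd1_only = frozenset(("sd1",))
    if sd1_only in families:
        for token, _atoms in sites:
            profile.counts[DescriptorKey(sd1=token)] += 1
    pair_families = [f for f in families if f != sd1_only]
    if not pair_families:
        return profile

    for ai in range(len(sites)):
        tok_a, atoms_a = sites[ai]
        for bi in range(ai + 1, len(sites)):
            tok_b, atoms_b = sites[bi]
            overlap = bool(atoms_a & atoms_b)
            d, u, v = _site_pair_geometry(mol, dist, atoms_a, atoms_b)
            if overlap:
                d = 0  # an atom inside its own ring
            if d > max_length:
                continue
            if d == 0:
                bd = None
            else:
                bd = graph.path_bond_code(u, v)
            full = DescriptorKey.canonical(sd1=tok_a, ld=d, sd2=tok_b, bd=bd)
            for fam in pair_families:
                key = full.project(fam)
                if key is not None:
                    profile.counts[key] += 1
    return profile


def profiles_for(
    molecules: Sequence[Molecule],
    max_length: int = 5,
    families: Iterable[frozenset[str]] = ALL_FAMILIES,
) -> list[DescriptorProfile]:
    fams = [frozenset(f) for f in families]
    return [enumerate_descriptors(m, max_length, fams) for m in molecules]
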