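"""Molecule parsing, tokenization, bond-path codes and descriptor
enumeration, including equivalence with an independent brute-force
enumerator on small molecules."""

from collections import Counter

import networkx as nx
import pytest
from rdkit import Chem

import iopqsar as q
from iopqsar.chem import (
    BD_AROMATIC_THROUGH,
    BD_AROMATIC_TOUCH,
    BD_PI,
    BD_PI_AROMATIC,
    BD_SINGLE,
    DescriptorKey,
    ring_token,
)

FULL = frozenset({"sd1", "ld", "sd2", "bd"})


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def test_parse_benzene_perceives_aromatic_ring():
    m = q.parse_structure("c1ccccc1", "benzene")
    assert m.n_atoms == 6
    assert all(a.aromatic and a.symbol == "C" for a in m.atoms)
    assert len(m.rings) == 1 and len(m.rings[0]) == 6


def test_parse_ethane():
    m = q.parse_structure("CC")
    assert m.n_atoms == 2
    assert len(m.bonds) == 1 and m.bonds[0].order == 1


@pytest.mark.parametrize("bad", ["C1CC", "not_a_smiles", ""])
def test_parse_failure_raises(bad):
    with pytest.raises(ValueError):
        q.parse_structure(bad, "badrec")


def test_multifragment_rejected():
    with pytest.raises(ValueError, match="multi-fragment"):
        q.parse_structure("CC.CC", "salt")


def test_bond_atom_indices_valid(small_library):
    for m in small_library[0]:
        for b in m.bonds:
            assert all(0 <= i < m.n_atoms for i in b.atoms)
            if b.aromatic:
                assert m.atoms[b.atoms[0]].aromatic
                assert m.atoms[b.atoms[1]].aromatic


# ---------------------------------------------------------------------------
# tokens
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "smiles, atom, token",
    [
        ("Cc1ccccc1", 0, "-CH3"),          # terminal sp3 carbon, 3 H
        ("Cc1ccccc1", 1, "-C(Ar)<"),       # aromatic carbon
        ("Clc1ccccc1", 0, "-Cl"),          # chlorine substituent
        ("CN(C)C", 1, "-N<"),              # sp3 amine
        ("CC=N", 2, "=NH"),                # imine NH
        ("CC#N", 2, "-N="),                # nitrile N (multiple bond, no H)
        ("CO", 1, "-OH"),                  # hydroxyl
        ("COC", 1, ">O"),                  # ether
        ("CC=O", 2, "=O"),                 # carbonyl
        ("CSC", 1, ">S"),                  # thioether
        ("CC(C)(C)C", 1, ">C(<)"),         # quaternary carbon
        ("C=CC", 1, ">C="),                # sp2 carbon
    ],
)
def test_atom_token_vocabulary(smiles, atom, token):
    assert q.atom_token(q.parse_structure(smiles), atom) == token


def test_charged_aromatic_nitrogen_token():
    m = q.parse_structure("C[n+]1ccn(C)c1")  # quaternized imidazolium N
    charged = [i for i, a in enumerate(m.atoms) if a.charge > 0]
    assert charged and all(q.atom_token(m, i) == ">N+=" for i in charged)


def test_unknown_environment_fallback_token():
    m = q.parse_structure("C[Si](C)(C)C")  # silicon: outside the vocabulary
    tok = q.atom_token(m, 1)
    assert tok.startswith("Si(")


def test_every_heavy_atom_gets_exactly_one_token(small_library):
    for m in small_library[0]:
        for i in range(m.n_atoms):
            assert isinstance(q.atom_token(m, i), str)


def test_ring_tokens():
    m = q.parse_structure("C1CCCCC1c1ccccc1")  # cyclohexyl-benzene
    tokens = sorted(ring_token(m, r) for r in range(len(m.rings)))
    assert tokens == ["Cyc06", "CycAr06"]
    m5 = q.parse_structure("C1CCC1")
    assert ring_token(m5, 0) == "Cyc04"


# ---------------------------------------------------------------------------
# bond-path codes
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "smiles, i, j, code",
    [
        ("CC", 0, 1, BD_SINGLE),            # one single bond
        ("CCCC", 0, 3, BD_SINGLE),          # pure single-bond chain
        ("Cc1ccccc1", 1, 4, BD_AROMATIC_THROUGH),  # through the ring
        ("Cc1ccccc1", 0, 3, BD_AROMATIC_TOUCH),    # methyl into the ring
        ("C=CC", 0, 2, BD_PI),              # path containing a double bond
        ("C=Cc1ccccc1", 0, 2, BD_PI_AROMATIC),     # pi bond beside the ring
    ],
)
def test_path_bond_code_dialect(smiles, i, j, code):
    assert q.path_bond_code(q.parse_structure(smiles), i, j) == code


def test_shortest_path_lexicographic_tiebreak():
    # benzene: two 3-bond paths between para atoms; the smallest-index one wins
    m = q.parse_structure("c1ccccc1")
    assert q.shortest_path(m, 0, 3) == [0, 1, 2, 3]


def test_path_bond_code_same_atom_rejected():
    with pytest.raises(ValueError):
        q.path_bond_code(q.parse_structure("CC"), 0, 0)


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def test_ethane_full_family():
    m = q.parse_structure("CC")
    prof = q.enumerate_descriptors(m, max_length=1, families=[FULL])
    assert dict(prof.counts) == {
        DescriptorKey(sd1="-CH3", ld=1, sd2="-CH3", bd=BD_SINGLE): 1
    }


def test_benzene_sd1_family_counts_sites():
    m = q.parse_structure("c1ccccc1")
    prof = q.enumerate_descriptors(m, families=[frozenset({"sd1"})])
    assert prof.counts[DescriptorKey(sd1="-C(Ar)<")] == 6
    assert prof.counts[DescriptorKey(sd1="CycAr06")] == 1


def test_sd1_total_is_heavy_atoms_plus_rings(small_library):
    for m in small_library[0]:
        prof = q.enumerate_descriptors(m, families=[frozenset({"sd1"})])
        assert prof.total == m.n_atoms + len(m.rings)


def test_total_count_at_least_heavy_atoms(small_library):
    for m in small_library[0][:5]:
        prof = q.enumerate_descriptors(m)
        assert prof.total >= m.n_atoms


def test_monotone_in_max_length():
    m = q.parse_structure("CCOc1ccc2[nH]cnc2c1")
    totals = [q.enumerate_descriptors(m, max_length=L).total for L in range(7)]
    assert totals == sorted(totals)


def test_projection_consistency():
    m = q.parse_structure("CCOc1ccc2[nH]cnc2c1")
    full = q.enumerate_descriptors(m, families=[FULL])
    for fam in [frozenset({"sd1", "sd2"}), frozenset({"ld"}),
                frozenset({"sd1", "ld", "bd"}), frozenset({"bd"})]:
        proj = q.enumerate_descriptors(m, families=[fam])
        expected = Counter()
        for key, n in full.counts.items():
            p = key.project(fam)
            if p is not None:
                expected[p] += n
        assert proj.counts == expected


@pytest.mark.parametrize(
    "a, b",
    [
        ("c1ccccc1C", "Cc1ccccc1"),
        ("OC(=O)c1ccccc1", "c1ccccc1C(O)=O"),
        ("c1ccc2[nH]cnc2c1", "c1cc2nc[nH]c2cc1"),
    ],
)
def test_isomorphism_invariance_alternative_smiles(a, b):
    pa = q.enumerate_descriptors(q.parse_structure(a, "x"))
    pb = q.enumerate_descriptors(q.parse_structure(b, "x"))
    assert pa.counts == pb.counts


def test_isomorphism_invariance_atom_renumbering(small_library):
    for m_src in small_library[0][:5]:
        mol = Chem.MolFromSmiles(m_src.provenance)
        order = list(reversed(range(mol.GetNumAtoms())))
        renum = Chem.MolToSmiles(Chem.RenumberAtoms(mol, order), canonical=False)
        assert (q.enumerate_descriptors(q.parse_structure(renum, "x")).counts
                == q.enumerate_descriptors(m_src).counts)


# ---------------------------------------------------------------------------
# brute-force oracle on small molecules
# ---------------------------------------------------------------------------

def _oracle_profile(smiles: str, max_length: int) -> Counter:
    """Independent pair enumerator: networkx shortest paths, dialect table
    re-derived from its definition."""
    m = q.parse_structure(smiles, "oracle")
    g = nx.Graph()
    g.add_nodes_from(range(m.n_atoms))
    bond = {}
    for b in m.bonds:
        g.add_edge(*b.atoms)
        bond[frozenset(b.atoms)] = b

    def code(path):
        bonds = [bond[frozenset((u, v))] for u, v in zip(path, path[1:])]
        if any(b.aromatic for b in bonds):
            return ".A." if all(b.aromatic for b in bonds) else ".a."
        if any(b.order > 1 for b in bonds):
            return "pA." if any(m.atoms[a].aromatic for a in path) else "p.."
        return ".a." if any(m.atoms[a].aromatic for a in path) else "..."

    sites = [(q.atom_token(m, i), {i}) for i in range(m.n_atoms)]
    sites += [(ring_token(m, r), set(m.rings[r])) for r in range(len(m.rings))]
    out = Counter()
    for ai in range(len(sites)):
        for bi in range(ai + 1, len(sites)):
            (ta, aa), (tb, ab) = sites[ai], sites[bi]
            if aa & ab:
                d, bd = 0, None
            else:
                pairs = sorted((nx.shortest_path_length(g, u, v), u, v)
                               for u in aa for v in ab)
                d, u, v = pairs[0]
                if d == 0:
                    bd = None
                else:
                    best = min(nx.all_shortest_paths(g, u, v))
                    bd = code(best)
            if d > max_length:
                continue
            out[DescriptorKey.canonical(sd1=ta, ld=d, sd2=tb, bd=bd)] += 1
    return out


@pytest.mark.parametrize(
    "smiles",
    [
        "CC", "C=CC", "CC(C)=O", "c1ccccc1", "Cc1ccccc1", "C1CCOC1",
        "c1ccncc1", "CC(N)C(O)=O", "ClCC=C", "C1CC1CC",
    ],
)
def test_full_family_matches_bruteforce_oracle(smiles):
    got = q.enumerate_descriptors(q.parse_structure(smiles, "x"),
                                  max_length=8, families=[FULL])
    assert got.counts == _oracle_profile(smiles, 8)
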