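"""Synthetic benchmark data with known, controllable structure.

Real structures and raw IOP indicator values for the studied chemical
series are not machine-readable, so every pipeline stage is exercised on
generated data whose ground truth is planted:

* :func:`gen_library` — benzimidazole-like scaffolds decorated from a
  small substituent grammar, with *planted fragments* attached at
  different rates in the active and inactive classes (the signal the
  enrichment screen must recover);
* :func:`gen_iop_matrix` — a compounds x 6 matrix of IOP-lowering
  indicators with a class-shifted mean (the signal 2-means clustering must
  recover);
* :func:`gen_hypotensive` — ED20/Index/Level activity tables whose
  association with the IOP class is controlled by a monotone link strength
  (the signal the perceptron ensemble must recover).

Everything is deterministic given the seed.  Molecular weights in the
hypotensive tables are drawn, not computed from a generated structure, so
this generator is independent of the chemistry module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .activity import ActivityProfile, index_from_ed20
from .chem import Molecule, atom_token, parse_structure

#: Benzimidazole / fused azolo-benzimidazole cores of the scaffold grammar.
SCAFFOLDS = (
    "c1ccc2[nH]cnc2c1",              # 1H-benzimidazole
    "c1ccc2c(c1)nc1[nH]ccn12",       # imidazo-fused benzimidazole
    "c1ccc2c(c1)nc1ncccn12",         # pyrimido-fused benzimidazole
    "C1=CC2=NC3=CC=CC=C3N2C=N1",     # isomeric fused tricycle
)

#: Class-neutral decorations (attached via their first atom).
SUBSTITUENTS = ("C", "CC", "OC", "N(C)C", "Cl", "c1ccccc1", "CCO", "C(C)C")


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic benchmark."""

    seed: int
    n_active: int = 30
    n_inactive: int = 30
    planted_fragments: tuple[tuple[str, float, float], ...] = (("SC", 0.8, 0.1),)
    iop_effect_size: float = 3.0
    iop_noise_sd: float = 1.0
    link_strength: float = 3.0
    max_decorations: int = 2

    def validate(self) -> None:
        if self.n_active < 1 or self.n_inactive < 1:
            raise ValueError("each class needs at least one compound")
        for frag, p_act, p_inact in self.planted_fragments:
            if Chem.MolFromSmiles(frag) is None:
                raise ValueError(f"planted fragment {frag!r} does not parse")
            if not (0 <= p_act <= 1 and 0 <= p_inact <= 1):
                raise ValueError(f"planting probabilities for {frag!r} outside [0,1]")
        if self.iop_noise_sd <= 0:
            raise ValueError("iop_noise_sd must be positive")


def _attach(mol: Chem.Mol, frag_smiles: str, rng: np.random.Generator) -> Chem.Mol:
    """Attach a fragment (by its first atom) at a random aromatic CH site."""
    frag = Chem.MolFromSmiles(frag_smiles)
    if frag is None:
        raise ValueError(f"fragment {frag_smiles!r} does not parse")
    sites = [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetIsAromatic() and a.GetSymbol() == "C" and a.GetTotalNumHs() > 0
    ]
    if not sites:
        raise ValueError("no free aromatic CH attachment site left")
    site = int(rng.choice(sites))
    combo = Chem.RWMol(Chem.CombineMols(mol, frag))
    combo.AddBond(site, mol.GetNumAtoms(), Chem.BondType.SINGLE)
    out = combo.GetMol()
    Chem.SanitizeMol(out)
    return out


def _assemble(spec: SimulationSpec, label: int, rng: np.random.Generator,
              max_retries: int = 20) -> str:
    for _ in range(max_retries):
        try:
            mol = Chem.MolFromSmiles(str(rng.choice(SCAFFOLDS)))
            n_dec = int(rng.integers(0, spec.max_decorations + 1))
            for _ in range(n_dec):
                mol = _attach(mol, str(rng.choice(SUBSTITUENTS)), rng)
            for frag, p_act, p_inact in spec.planted_fragments:
                p = p_act if label == 1 else p_inact
                if rng.random() < p:
                    mol = _attach(mol, frag, rng)
            return Chem.MolToSmiles(mol)
        except (ValueError, Chem.rdchem.KekulizeException,
                Chem.rdchem.AtomValenceException):
            continue
    raise RuntimeError("could not assemble a valid molecule after retries")


def gen_library(spec: SimulationSpec) -> tuple[list[Molecule], np.ndarray]:
    """Generate a decorated scaffold library with planted class signal.

    Returns the molecules (actives first) and their binary labels.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    molecules, labels = [], []
    for i in range(spec.n_active + spec.n_inactive):
        label = 1 if i < spec.n_active else 0
        smiles = _assemble(spec, label, rng)
        molecules.append(parse_structure(smiles, mol_id=f"SYN{i:04d}"))
        labels.append(label)
    return molecules, np.array(labels, dtype=int)


def fragment_tokens(fragment_smiles: str) -> set[str]:
    """Structure tokens a planted fragment contributes once attached.

    The fragment is capped with a methyl carbon standing in for the
    scaffold attachment point; the cap atom's own token is excluded.
    """
    capped = parse_structure("C" + fragment_smiles, mol_id="capped_fragment")
    return {atom_token(capped, i) for i in range(1, capped.n_atoms)}


#: Baseline (inactive-class) mean of each of the 6 IOP-lowering indicators.
_IOP_BASELINE = np.array([0.5, 0.5, 0.5, 0.5, 0.5, 0.5])


def gen_iop_matrix(
    labels,
    effect_size: float = 3.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """6 IOP-lowering indicators with a standardized class-mean shift.

    Active compounds' columns are shifted by ``effect_size * noise_sd``
    relative to the inactive baseline; noise is i.i.d. normal.
    """
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary (0/1)")
    rng = np.random.default_rng(seed)
    n = len(labels)
    means = _IOP_BASELINE + np.outer(labels, np.full(6, effect_size * noise_sd))
    X = rng.normal(loc=means, scale=noise_sd, size=(n, 6))
    return pd.DataFrame(X, columns=[f"ind_{j + 1}" for j in range(6)])


def gen_hypotensive(
    labels,
    link_strength: float = 3.0,
    seed: int = 0,
    codes=None,
) -> list[ActivityProfile]:
    """Hypotensive activity tables with a monotone class link.

    log(ED20 mg/kg) is normal with sd 0.6 around a median of 12 mg/kg for
    inactives, shifted down by ``link_strength`` standard deviations for
    actives (stronger hypotensives).  Index is derived from ED20; the
    umol/kg dose uses a molecular weight drawn uniformly from 200-550
    g/mol; Level in {0,1,2} is drawn with class-tilted weights whose tilt
    scales with the link strength.
    """
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary (0/1)")
    rng = np.random.default_rng(seed)
    n = len(labels)
    log_sd = 0.6
    mu = np.log(12.0) - link_strength * log_sd * labels
    ed20 = np.exp(rng.normal(mu, log_sd, size=n))
    mw = rng.uniform(200.0, 550.0, size=n)
    base = np.array([0.2, 0.6, 0.2])
    out = []
    for i in range(n):
        tilt = np.exp(0.3 * link_strength * (2 * labels[i] - 1) * np.array([-1.0, 0.0, 1.0]))
        w = base * tilt
        level = int(rng.choice(3, p=w / w.sum()))
        e = float(ed20[i])
        out.append(
            ActivityProfile(
                code=codes[i] if codes is not None else f"SYN{i:04d}",
                ed20_mg_kg=e,
                index_points=index_from_ed20(e),
                ed20_umol_kg=e / mw[i] * 1000.0,
                level=level,
                iop_cluster=int(labels[i]),
            )
        )
    return out


def profiles_to_xy(profiles) -> tuple[np.ndarray, np.ndarray]:
    """Stack activity profiles into the 4-column predictor matrix + labels."""
    X = np.array(
        [
            [p.ed20_mg_kg, p.index_points, p.ed20_umol_kg, p.level]
            for p in profiles
        ],
        dtype=float,
    )
    y = np.array([p.iop_cluster for p in profiles], dtype=int)
    return X, y
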