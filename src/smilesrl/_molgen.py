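"""Deterministic random small-molecule SMILES builders.

Shared backend for the desk-scale toy corpus (a stand-in for a large
drug-like training corpus) and the synthetic activity dataset. Molecules are
assembled from fragments that concatenate into valid SMILES (chains with
branches only where valence allows, one ring template per molecule), then
checked with RDKit; the few rejects are retried.
"""

from __future__ import annotations

import numpy as np

from .chem import contains_sulphur, is_valid, mol_from_smiles

CHAIN_ATOMS = ["C", "C", "C", "C", "N", "O"]

RINGS_PLAIN = [
    "c1ccccc1",
    "c1ccncc1",
    "c1ccc(C)cc1",
    "c1ccc(N)cc1",
    "C1CCCCC1",
    "C1CCNCC1",
    "C1CCOCC1",
]
RINGS_SULPHUR = ["c1ccsc1", "C1CCSCC1"]

#: Suffixes that introduce sulphur: thioethers and sulfonyl groups.
SULPHUR_SUFFIXES = ["SC", "SCC", "S(=O)(=O)C", "S(=O)(=O)N"]

FAMILIES = ("chain", "ether_amine", "aromatic", "alicyclic")


def random_chain(rng: np.random.Generator, lo: int, hi: int,
                 atoms=None) -> str:
    """Random linear chain with occasional (C)/(=O) branches on carbons."""
    atoms = atoms or CHAIN_ATOMS
    n = int(rng.integers(lo, hi + 1))
    out = []
    for _ in range(n):
        a = atoms[rng.integers(0, len(atoms))]
        out.append(a)
        if a == "C":
            u = rng.random()
            if u < 0.12:
                out.append("(C)")
            elif u < 0.20:
                out.append("(=O)")
        elif a == "N" and rng.random() < 0.15:
            out.append("(C)")
    return "".join(out)


def _n_heavy(fragment: str) -> int:
    # every alphabetic character in these fragments is one heavy atom
    return sum(c.isalpha() for c in fragment)


def random_molecule(rng: np.random.Generator, sulphur: bool,
                    family: str | None = None, max_heavy: int = 25,
                    min_heavy: int = 10) -> str:
    """One valid SMILES with a heavy-atom count in [min_heavy, max_heavy];
    contains sulphur iff ``sulphur``.

    ``family`` restricts the shape: plain/heteroatom-rich chains, or ring
    systems (aromatic / saturated) joined by linkers. None picks a family
    at random. Fragments are appended until a per-molecule target size is
    reached, so sizes spread over the whole allowed range.
    """
    while True:
        fam = family or FAMILIES[rng.integers(0, len(FAMILIES))]
        atoms = CHAIN_ATOMS
        if fam == "ether_amine":
            atoms = ["C", "C", "N", "O", "N", "O"]
        use_rings = fam in ("aromatic", "alicyclic")
        if fam == "aromatic":
            rings = [r for r in RINGS_PLAIN if r[0] == "c"]
            s_ring = RINGS_SULPHUR[0]
        else:
            rings = [r for r in RINGS_PLAIN if r[0] == "C"]
            s_ring = RINGS_SULPHUR[1]
        target = int(rng.integers(min_heavy, max_heavy + 1))
        parts = [random_chain(rng, 1, 4, atoms)]
        heavy = _n_heavy(parts[0])
        need_sulphur = sulphur
        want_chain = False
        while heavy < target:
            if use_rings and not want_chain:
                if need_sulphur and rng.random() < 0.4:
                    ring = s_ring
                    need_sulphur = False
                else:
                    ring = rings[rng.integers(0, len(rings))]
                parts.append(ring)
            else:
                parts.append(random_chain(rng, 1, 4, atoms))
            heavy += _n_heavy(parts[-1])
            want_chain = use_rings and not want_chain
        if need_sulphur:
            parts.append(SULPHUR_SUFFIXES[rng.integers(0, len(SULPHUR_SUFFIXES))])
        smiles = "".join(parts)
        if not is_valid(smiles):
            continue
        mol = mol_from_smiles(smiles)
        if not (min_heavy <= mol.GetNumHeavyAtoms() <= max_heavy):
            continue
        if contains_sulphur(smiles) != sulphur:
            continue
        return smiles


def random_scaffold(rng: np.random.Generator) -> str:
    """Ring-bearing core used to seed a structural family."""
    ring = RINGS_PLAIN[rng.integers(0, len(RINGS_PLAIN))]
    return random_chain(rng, 1, 3) + ring
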