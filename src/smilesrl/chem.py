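"""Chemistry substrate: SMILES tokenization, vocabularies, validity,
fingerprints, descriptors and similarity.

Everything molecular in the package funnels through here. Tokenization is
character-based with two exceptions: the two-character halogens ``Cl`` and
``Br``, and square-bracket atom environments such as ``[nH]``, each of which
is a single token. Parsing, canonicalization, fingerprints and descriptors
delegate to RDKit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, rdFingerprintGenerator, rdMolDescriptors

RDLogger.DisableLog("rdApp.*")

GO = "GO"
EOS = "EOS"

#: Marketed Celecoxib structure, the query molecule for similarity tasks.
CELECOXIB = "Cc1ccc(-c2cc(C(F)(F)F)nn2-c2ccc(S(N)(=O)=O)cc2)cc1"

#: Celecoxib with the tolyl methyl removed; its FCFP4 similarity to Celecoxib
#: is a reference value for the capped-similarity scoring function.
DESMETHYL_CELECOXIB = "c1ccc(-c2cc(C(F)(F)F)nn2-c2ccc(S(N)(=O)=O)cc2)cc1"

#: Two-character bare atom tokens; all other multi-character atom symbols only
#: occur inside square brackets.
TWO_CHAR_TOKENS = ("Cl", "Br")


class TokenizationError(ValueError):
    """Raised when a SMILES string cannot be tokenized."""


def _check_smiles_text(s: str) -> None:
    if not s:
        raise ValueError("SMILES string must be non-empty")
    if any(c.isspace() for c in s):
        raise ValueError(f"SMILES string must not contain whitespace: {s!r}")


def tokenize(s: str) -> list[str]:
    """Split a SMILES string into tokens.

    ``Cl``/``Br`` and bracket environments (``[`` greedily to the next ``]``)
    are single tokens; every other character is its own token. Concatenating
    the result reproduces the input exactly.
    """
    _check_smiles_text(s)
    tokens: list[str] = []
    i = 0
    n = len(s)
    while i < n:
        c = s[i]
        if c == "[":
            j = s.find("]", i + 1)
            if j < 0:
                raise TokenizationError(f"unclosed '[' at position {i} in {s!r}")
            inner = s[i + 1 : j]
            if "[" in inner:
                raise TokenizationError(f"nested '[' at position {i} in {s!r}")
            tokens.append(s[i : j + 1])
            i = j + 1
        elif s[i : i + 2] in TWO_CHAR_TOKENS:
            tokens.append(s[i : i + 2])
            i += 2
        else:
            tokens.append(c)
            i += 1
    return tokens


def detokenize(tokens: Iterable[str]) -> str:
    return "".join(tokens)


class Vocabulary:
    """Ordered token set with reserved GO and EOS control tokens.

    Regular tokens are sorted lexicographically; GO sits at index ``n - 2``
    and EOS at index ``n - 1`` so a vocabulary built from the same corpus is
    always identical, independent of corpus order.
    """

    def __init__(self, tokens: Iterable[str]):
        regular = sorted(set(tokens) - {GO, EOS})
        self.tokens: list[str] = regular + [GO, EOS]
        self.index_of: dict[str, int] = {t: i for i, t in enumerate(self.tokens)}
        self.go_index = self.index_of[GO]
        self.eos_index = self.index_of[EOS]

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index_of

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Vocabulary) and self.tokens == other.tokens

    def encode(self, tokens: Sequence[str]) -> np.ndarray:
        """Map tokens to integer indices."""
        try:
            return np.array([self.index_of[t] for t in tokens], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"token {exc.args[0]!r} not in vocabulary") from None

    def decode(self, indices: Iterable[int]) -> list[str]:
        return [self.tokens[int(i)] for i in indices]

    def encode_smiles(self, s: str, add_eos: bool = True) -> np.ndarray:
        toks = tokenize(s)
        if add_eos:
            toks = toks + [EOS]
        return self.encode(toks)

    def decode_to_smiles(self, indices: Iterable[int]) -> str:
        """Indices back to a SMILES string, dropping GO/EOS."""
        return "".join(
            t for t in self.decode(indices) if t not in (GO, EOS)
        )

    def to_json(self) -> str:
        return json.dumps({"tokens": self.tokens})

    @classmethod
    def from_json(cls, text: str) -> "Vocabulary":
        tokens = json.loads(text)["tokens"]
        v = cls(tokens)
        if v.tokens != tokens:
            # preserve a serialized ordering verbatim
            v.tokens = list(tokens)
            v.index_of = {t: i for i, t in enumerate(tokens)}
            v.go_index = v.index_of[GO]
            v.eos_index = v.index_of[EOS]
        return v


def build_vocabulary(corpus: Iterable[str]) -> Vocabulary:
    """Collect every token present in the corpus, plus GO and EOS."""
    seen: set[str] = set()
    empty = True
    for s in corpus:
        empty = False
        try:
            seen.update(tokenize(s))
        except (ValueError, TokenizationError) as exc:
            raise TokenizationError(f"cannot tokenize corpus entry {s!r}: {exc}") from exc
    if empty:
        raise ValueError("corpus must be non-empty")
    return Vocabulary(seen)


def one_hot(indices: Sequence[int] | np.ndarray, vocabulary: Vocabulary) -> np.ndarray:
    """T x |X| binary matrix with one 1 per row."""
    idx = np.asarray(indices, dtype=np.int64)
    mat = np.zeros((len(idx), len(vocabulary)), dtype=np.float32)
    mat[np.arange(len(idx)), idx] = 1.0
    return mat


# ---------------------------------------------------------------------------
# RDKit-backed structure handling


def mol_from_smiles(s: str) -> Chem.Mol | None:
    _check_smiles_text(s)
    return Chem.MolFromSmiles(s)


def is_valid(s: str) -> bool:
    """RDKit parser's verdict on whether ``s`` encodes a molecule."""
    try:
        return mol_from_smiles(s) is not None
    except ValueError:
        return False


def canonicalize(s: str) -> str:
    mol = mol_from_smiles(s)
    if mol is None:
        raise ValueError(f"cannot canonicalize invalid SMILES: {s!r}")
    return Chem.MolToSmiles(mol)


def contains_sulphur(s: str) -> bool:
    """True iff the parsed molecule has at least one sulphur atom.

    Decided on atoms, not text, so 'Cl' or aromatic 'c' can never be
    mistaken for sulphur.
    """
    mol = mol_from_smiles(s)
    if mol is None:
        raise ValueError(f"contains_sulphur undefined for invalid SMILES: {s!r}")
    return any(atom.GetAtomicNum() == 16 for atom in mol.GetAtoms())


@dataclass(frozen=True)
class DescriptorSet:
    mol_weight: float
    clogp: float
    n_rot_bonds: int
    n_arom_rings: int


def descriptors(s: str) -> DescriptorSet:
    """Molecular weight, cLogP, rotatable-bond and aromatic-ring counts."""
    mol = mol_from_smiles(s)
    if mol is None:
        raise ValueError(f"descriptors undefined for invalid SMILES: {s!r}")
    return DescriptorSet(
        mol_weight=float(Descriptors.MolWt(mol)),
        clogp=float(Crippen.MolLogP(mol)),
        n_rot_bonds=int(rdMolDescriptors.CalcNumRotatableBonds(mol)),
        n_arom_rings=int(rdMolDescriptors.CalcNumAromaticRings(mol)),
    )


# ---------------------------------------------------------------------------
# Fingerprints

_FP_GENERATORS = {}


def _fp_generator(kind: str):
    # ECFP6: diameter 6 (radius 3), atom-type invariants.
    # FCFP4: diameter 4 (radius 2), feature invariants — fuzzier.
    if kind not in _FP_GENERATORS:
        if kind == "ECFP6":
            gen = rdFingerprintGenerator.GetMorganGenerator(radius=3)
        elif kind == "FCFP4":
            gen = rdFingerprintGenerator.GetMorganGenerator(
                radius=2,
                atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen(),
            )
        else:
            raise ValueError(f"unknown fingerprint kind: {kind!r}")
        _FP_GENERATORS[kind] = gen
    return _FP_GENERATORS[kind]


@dataclass(frozen=True)
class Fingerprint:
    """Sparse circular (Morgan) fingerprint: identifier -> count.

    Identifiers are kept unhashed; :func:`jaccard` operates on the multiset,
    and :meth:`folded` produces a fixed-width binary vector for estimators
    that need dense input.
    """

    kind: str
    counts: Mapping[int, int]

    @property
    def bits(self) -> frozenset[int]:
        return frozenset(self.counts)

    def folded(self, n_bits: int = 2048) -> np.ndarray:
        vec = np.zeros(n_bits, dtype=np.float64)
        for ident in self.counts:
            vec[ident % n_bits] = 1.0
        return vec


def fingerprint(s: str, kind: str = "ECFP6") -> Fingerprint:
    mol = mol_from_smiles(s)
    if mol is None:
        raise ValueError(f"fingerprint undefined for invalid SMILES: {s!r}")
    sparse = _fp_generator(kind).GetSparseCountFingerprint(mol)
    return Fingerprint(kind=kind, counts=dict(sparse.GetNonzeroElements()))


def jaccard(f1: Fingerprint, f2: Fingerprint) -> float:
    """Multiset Jaccard (Tanimoto) index: sum of min counts over sum of max.

    Reduces to |intersection| / |union| of on-bits when all counts are one.
    """
    if f1.kind != f2.kind:
        raise ValueError(f"fingerprint kind mismatch: {f1.kind} vs {f2.kind}")
    keys = set(f1.counts) | set(f2.counts)
    if not keys:
        return 0.0
    num = sum(min(f1.counts.get(k, 0), f2.counts.get(k, 0)) for k in keys)
    den = sum(max(f1.counts.get(k, 0), f2.counts.get(k, 0)) for k in keys)
    return num / den


# ---------------------------------------------------------------------------
# Corpus I/O


def read_smiles_file(path) -> list[str]:
    """Plain-text corpus, one SMILES per line; '#' lines and blanks ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line.split()[0])
    return out


def write_smiles_file(path, smiles: Iterable[str]) -> None:
    with open(path, "w") as fh:
        for s in smiles:
            fh.write(s + "\n")
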