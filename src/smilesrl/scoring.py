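"""Task scoring functions S(A) in [-1, 1].

Scorers are total on every string a sampler can emit: invalid SMILES are
scored, not rejected (0 for the sulphur task, -1 elsewhere), so the score
itself pressures the agent toward syntactic validity.
"""

from __future__ import annotations

from . import chem


class Scorer:
    """Callable mapping a SMILES string to a score in [-1, 1]."""

    name: str = "scorer"

    def __call__(self, smiles: str) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def score_many(self, smiles_list) -> list[float]:
        return [self(s) for s in smiles_list]


class SulphurFreeScorer(Scorer):
    """+1 for a valid sulphur-free molecule, 0 for an invalid string,
    -1 for a valid molecule containing sulphur."""

    name = "sulphur_free"

    def __call__(self, smiles: str) -> float:
        if not chem.is_valid(smiles):
            return 0.0
        return -1.0 if chem.contains_sulphur(smiles) else 1.0


class SimilarityScorer(Scorer):
    """Capped fingerprint similarity to a query structure.

    S = -1 + 2 * min(J, k) / k with J the FCFP4 Jaccard index to the query:
    -1 at no fingerprint overlap, +1 at similarity k or above, so gains in
    similarity beyond k are not rewarded. Invalid SMILES score -1.
    """

    name = "similarity"

    def __init__(self, query: str, k: float = 0.7, fp_kind: str = "FCFP4"):
        if not 0.0 < k <= 1.0:
            raise ValueError(f"k must be in (0, 1], got {k}")
        if not chem.is_valid(query):
            raise ValueError(f"query is not a valid SMILES: {query!r}")
        self.query = query
        self.k = k
        self.fp_kind = fp_kind
        self._query_fp = chem.fingerprint(query, fp_kind)  # cached once

    def similarity(self, smiles: str) -> float:
        return chem.jaccard(chem.fingerprint(smiles, self.fp_kind),
                            self._query_fp)

    def __call__(self, smiles: str) -> float:
        if not chem.is_valid(smiles):
            return -1.0
        j = self.similarity(smiles)
        return -1.0 + 2.0 * min(j, self.k) / self.k


class ActivityScorer(Scorer):
    """S = -1 + 2 * P_active from a trained activity model's (uncalibrated)
    predicted probability of activity. Invalid SMILES score -1."""

    name = "activity"

    def __init__(self, model):
        self.model = model

    def __call__(self, smiles: str) -> float:
        if not chem.is_valid(smiles):
            return -1.0
        p = float(self.model.predict_proba_smiles(smiles))
        return -1.0 + 2.0 * p


_REGISTRY = {
    "sulphur_free": SulphurFreeScorer,
    "similarity": SimilarityScorer,
    "activity": ActivityScorer,
}


def get_scorer(name: str, **params) -> Scorer:
    """Build a scorer by registry name, e.g.
    ``get_scorer("similarity", query="...", k=0.7)``."""
    try:
        cls = _REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown scorer {name!r}; available: {sorted(_REGISTRY)}") from None
    return cls(**params)


def make_scorer(config: dict) -> Scorer:
    """Build a scorer from a config mapping: {"name": ..., <params>}."""
    params = dict(config)
    name = params.pop("name")
    return get_scorer(name, **params)
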