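"""Evaluation of sampled molecule sets, learning curves, and the toy corpus.

``evaluate_sample`` condenses a sample of generated SMILES into the metrics
used to compare priors and agents: validity, novelty, physchem descriptor
distributions, task fractions (sulphur-free / predicted active), and
recovery statistics against a reference active set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _molgen, chem


@dataclass
class SampleReport:
    """Metrics over one sampled set. Descriptor statistics and task metrics
    are computed on the valid unique canonical structures; recovery
    probability is per sampled episode (duplicates count)."""

    n_sampled: int
    fraction_valid: float
    n_valid_unique: int = 0
    fraction_unique: float = 0.0
    fraction_novel: float | None = None
    descriptor_means: dict = field(default_factory=dict)
    descriptor_sds: dict = field(default_factory=dict)
    fraction_sulphur_free: float | None = None
    fraction_predicted_active: float | None = None
    fraction_predicted_active_all: float | None = None
    mean_similarity: float | None = None
    fraction_similar_to_reference: float | None = None
    fraction_reference_recovered: float | None = None
    prob_generating_reference: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), default=float, **kwargs)


def evaluate_sample(smiles_list, reference=None, activity_model=None,
                    training_corpus=None, similarity_scorer=None,
                    similarity_threshold: float = 0.4,
                    active_threshold: float = 0.5) -> SampleReport:
    """Score a sampled set of SMILES strings.

    Parameters
    ----------
    smiles_list : list of str
        The raw sample (one entry per episode; may contain duplicates and
        invalid strings).
    reference : list of str, optional
        Reference active set; enables similarity/recovery metrics (ECFP6
        Jaccard > ``similarity_threshold`` to any reference member, exact
        canonical recovery, and per-episode probability of generating a
        reference structure).
    activity_model : ActivityModel, optional
        Enables predicted-active fractions (P_active > ``active_threshold``),
        reported both over valid unique structures and over all episodes.
    training_corpus : list of str, optional
        Enables novelty (canonical structure not in the corpus).
    similarity_scorer : SimilarityScorer, optional
        Enables mean fingerprint similarity to the scorer's query.
    """
    if not smiles_list:
        raise ValueError("sample must be non-empty")
    n = len(smiles_list)
    canon_all = []
    for s in smiles_list:
        try:
            canon_all.append(chem.canonicalize(s))
        except ValueError:
            canon_all.append(None)
    valid_canon = [c for c in canon_all if c is not None]
    report = SampleReport(n_sampled=n, fraction_valid=len(valid_canon) / n)
    if not valid_canon:
        return report
    unique = sorted(set(valid_canon))
    report.n_valid_unique = len(unique)
    report.fraction_unique = len(unique) / len(valid_canon)

    desc = [chem.descriptors(s) for s in unique]
    for name in ("mol_weight", "clogp", "n_rot_bonds", "n_arom_rings"):
        vals = np.array([getattr(d, name) for d in desc], dtype=float)
        report.descriptor_means[name] = float(vals.mean())
        report.descriptor_sds[name] = float(vals.std())
    report.fraction_sulphur_free = float(
        np.mean([not chem.contains_sulphur(s) for s in unique]))

    if training_corpus is not None:
        known = {chem.canonicalize(s) for s in training_corpus}
        report.fraction_novel = float(
            np.mean([c not in known for c in unique]))

    if similarity_scorer is not None:
        report.mean_similarity = float(
            np.mean([similarity_scorer.similarity(s) for s in unique]))

    if activity_model is not None:
        p_unique = {s: activity_model.predict_proba_smiles(s) for s in unique}
        report.fraction_predicted_active = float(
            np.mean([p > active_threshold for p in p_unique.values()]))
        # over all episodes: invalid entries count as not-active
        report.fraction_predicted_active_all = float(
            sum(p_unique[c] > active_threshold
                for c in canon_all if c is not None) / n)

    if reference is not None:
        ref_canon = {chem.canonicalize(s) for s in reference}
        ref_fps = [chem.fingerprint(s, "ECFP6") for s in ref_canon]
        def similar(s):
            f = chem.fingerprint(s, "ECFP6")
            return any(chem.jaccard(f, rf) > similarity_threshold
                       for rf in ref_fps)
        report.fraction_similar_to_reference = float(
            np.mean([similar(s) for s in unique]))
        recovered = ref_canon & set(unique)
        report.fraction_reference_recovered = len(recovered) / len(ref_canon)
        report.prob_generating_reference = float(
            sum(c in ref_canon for c in canon_all if c is not None) / n)
    return report


def learning_curve(trace, score_column: str = "mean_score",
                   threshold: float | None = None, window: int = 50) -> dict:
    """Summarise a training trace: first step whose rolling-mean score
    reaches ``threshold`` (None if never), and the final-window mean/SD.

    ``trace`` is a DataFrame or a path to the CSV written during training.
    """
    if not isinstance(trace, pd.DataFrame):
        trace = pd.read_csv(trace)
    if len(trace) < 2:
        raise ValueError("trace must have at least 2 rows")
    if score_column not in trace.columns:
        raise ValueError(f"trace has no column {score_column!r}")
    scores = trace[score_column].to_numpy(dtype=float)
    window = min(window, len(scores))
    rolling = pd.Series(scores).rolling(window, min_periods=1).mean().to_numpy()
    steps_to_threshold = None
    if threshold is not None:
        hits = np.nonzero(rolling >= threshold)[0]
        if len(hits):
            steps_to_threshold = int(trace["step"].iloc[hits[0]]
                                     if "step" in trace.columns else hits[0])
    tail = scores[-window:]
    return {
        "steps_to_threshold": steps_to_threshold,
        "plateau_mean": float(tail.mean()),
        "plateau_sd": float(tail.std()),
        "n_steps": len(scores),
    }


def make_toy_corpus(n: int, seed: int = 0, families=None,
                    sulphur_fraction: float = 0.30,
                    max_heavy: int = 25, min_heavy: int = 10) -> list[str]:
    """Desk-scale training corpus of valid, diverse small molecules.

    Molecules come from template families (chains, ether/amine-rich chains,
    aromatics, saturated rings) with 10-25 heavy atoms (the floor the
    full-scale corpus uses, with a halved ceiling); a ``sulphur_fraction``
    share contains at least one sulphur atom, emulating organosulphur
    prevalence for the sulphur-avoidance task. Deterministic per seed.
    """
    if n < 100:
        raise ValueError("toy corpus needs n >= 100")
    families = list(families) if families else list(_molgen.FAMILIES)
    for f in families:
        if f not in _molgen.FAMILIES:
            raise ValueError(f"unknown family {f!r}; choose from {_molgen.FAMILIES}")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        fam = families[rng.integers(0, len(families))]
        sulphur = bool(rng.random() < sulphur_fraction)
        out.append(_molgen.random_molecule(rng, sulphur=sulphur, family=fam,
                                           max_heavy=max_heavy,
                                           min_heavy=min_heavy))
    return out
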