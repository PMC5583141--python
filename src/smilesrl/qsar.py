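"""Activity-model protocol: fingerprint clustering, cluster-based
train/validation/test splitting, and a grid-searched Gaussian-kernel SVM.

The protocol mirrors common QSAR practice for building a target-activity
classifier whose test set is structurally dissimilar from its training set:
actives are Butina-clustered on ECFP6 similarity and whole clusters are
assigned to sets, so no test active has a close training analogue. A
synthetic planted-substructure dataset generator makes the whole protocol
testable without any external bioactivity database.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.ML.Cluster import Butina
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from . import _molgen
from .chem import Fingerprint, canonicalize, fingerprint, jaccard, mol_from_smiles

SET_NAMES = ("train", "validation", "test")


# ---------------------------------------------------------------------------
# Clustering and splitting


def butina_cluster(fingerprints: list[Fingerprint],
                   cutoff: float = 0.4) -> list[tuple[int, ...]]:
    """Sphere-exclusion (Butina) clustering on fingerprint similarity.

    ``cutoff`` is a *similarity* threshold: members lie at Jaccard
    similarity > cutoff from their cluster centroid. Returns clusters as
    tuples of input indices (centroid first), a partition of the input.
    """
    if not fingerprints:
        raise ValueError("cannot cluster an empty fingerprint list")
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must be in (0, 1)")
    kinds = {f.kind for f in fingerprints}
    if len(kinds) > 1:
        raise ValueError(f"mixed fingerprint kinds: {sorted(kinds)}")
    n = len(fingerprints)
    # flat lower-triangle distance matrix in RDKit's expected order
    dists = []
    for i in range(1, n):
        fi = fingerprints[i]
        for j in range(i):
            dists.append(1.0 - jaccard(fi, fingerprints[j]))
    clusters = Butina.ClusterData(dists, n, 1.0 - cutoff, isDistData=True)
    return [tuple(c) for c in clusters]


def split_by_clusters(clusters: list[tuple[int, ...]],
                      ratios: tuple[float, float, float] = (4 / 6, 1 / 6, 1 / 6),
                      block: int = 4) -> dict[int, str]:
    """Assign whole clusters to train/validation/test.

    Clusters are sorted by descending size and handed out in cycles: per
    cycle, ``block`` clusters go to test, ``block`` to validation, and
    proportionally more (``block * r_train / r_test``) to train, realising
    the requested cluster-count ratios (train, validation, test). Returns
    {cluster index -> set name}.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    if len(clusters) < block:
        warnings.warn("fewer clusters than one block; assigning all to train")
        return {i: "train" for i in range(len(clusters))}
    r_train, r_val, r_test = ratios
    nonzero = [r for r in ratios if r > 0]
    unit = min(nonzero)
    counts = {name: int(round(block * r / unit))
              for name, r in zip(SET_NAMES, ratios)}
    order = sorted(range(len(clusters)),
                   key=lambda i: (-len(clusters[i]), i))
    assignment: dict[int, str] = {}
    pos = 0
    while pos < len(order):
        # assignment order within a cycle: test, then validation, then train
        for name in ("test", "validation", "train"):
            take = counts[name]
            for i in order[pos: pos + take]:
                assignment[i] = name
            pos += take
            if pos >= len(order):
                break
    return assignment


def split_activity_dataset(data: pd.DataFrame, cutoff: float = 0.4,
                           ratios=(4 / 6, 1 / 6, 1 / 6), block: int = 4,
                           seed: int = 0, fp_kind: str = "ECFP6") -> pd.DataFrame:
    """Full split manifest for a (smiles, label) activity dataset.

    Actives are clustered and split by cluster; inactives are split randomly
    with the same ratios. Returns a DataFrame with columns
    smiles, label, set, cluster_id (-1 for inactives).
    """
    df = data.reset_index(drop=True)
    actives = df.index[df["label"] == 1].to_numpy()
    inactives = df.index[df["label"] == 0].to_numpy()
    fps = [fingerprint(df.loc[i, "smiles"], fp_kind) for i in actives]
    clusters = butina_cluster(fps, cutoff)
    assignment = split_by_clusters(clusters, ratios, block)
    set_col = np.empty(len(df), dtype=object)
    cluster_col = np.full(len(df), -1, dtype=np.int64)
    for ci, members in enumerate(clusters):
        for m in members:
            set_col[actives[m]] = assignment[ci]
            cluster_col[actives[m]] = ci
    rng = np.random.default_rng(seed)
    perm = rng.permutation(inactives)
    n = len(perm)
    n_train = int(round(ratios[0] * n))
    n_val = int(round(ratios[1] * n))
    set_col[perm[:n_train]] = "train"
    set_col[perm[n_train:n_train + n_val]] = "validation"
    set_col[perm[n_train + n_val:]] = "test"
    out = df.copy()
    out["set"] = set_col
    out["cluster_id"] = cluster_col
    return out


def inactive_contamination(manifest: pd.DataFrame, cutoff: float = 0.4,
                           fp_kind: str = "ECFP6") -> float:
    """Fraction of inactives within ``cutoff`` similarity of any active
    cluster centroid (a diagnostic, not a filter)."""
    actives = manifest[manifest["label"] == 1]
    centroid_smiles = (actives.groupby("cluster_id")["smiles"].first())
    centroid_fps = [fingerprint(s, fp_kind) for s in centroid_smiles]
    inact = manifest[manifest["label"] == 0]["smiles"]
    if len(inact) == 0:
        return 0.0
    hits = 0
    for s in inact:
        f = fingerprint(s, fp_kind)
        if any(jaccard(f, c) > cutoff for c in centroid_fps):
            hits += 1
    return hits / len(inact)


# ---------------------------------------------------------------------------
# The SVM activity model


class ActivityModel(BaseEstimator, ClassifierMixin):
    """Gaussian-kernel SVM over folded binary ECFP6 fingerprints.

    ``predict_proba_smiles`` exposes the (uncalibrated, in the Platt sense
    of being a secondary fit) predicted probability of activity used by the
    activity scoring function.
    """

    def __init__(self, C: float = 1.0, gamma: float = 0.015625,
                 n_bits: int = 2048, fp_kind: str = "ECFP6",
                 random_state: int = 0):
        self.C = C
        self.gamma = gamma
        self.n_bits = n_bits
        self.fp_kind = fp_kind
        self.random_state = random_state

    def featurize(self, smiles_list) -> np.ndarray:
        return np.array([fingerprint(s, self.fp_kind).folded(self.n_bits)
                         for s in smiles_list])

    def fit(self, smiles_list, y):
        smiles_list = list(smiles_list)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        # canonical row order: probability calibration uses internal CV, so
        # without this, predictions would depend on training-row order
        order = np.argsort(np.asarray(smiles_list, dtype=object))
        smiles_list = [smiles_list[i] for i in order]
        y = y[order]
        X = self.featurize(smiles_list)
        self.svc_ = SVC(kernel="rbf", C=self.C, gamma=self.gamma,
                        probability=True, random_state=self.random_state)
        self.svc_.fit(X, y)
        self.classes_ = self.svc_.classes_
        return self

    def predict_proba(self, smiles_list) -> np.ndarray:
        return self.svc_.predict_proba(self.featurize(smiles_list))

    def predict_proba_smiles(self, smiles: str) -> float:
        """P_active for one molecule."""
        proba = self.predict_proba([smiles])
        return float(proba[0, list(self.classes_).index(1)])

    def predict(self, smiles_list) -> np.ndarray:
        return self.svc_.predict(self.featurize(smiles_list))


def train_svm(train_smiles, y_train, val_smiles, y_val,
              C_grid=None, gamma_grid=None, n_bits: int = 2048,
              fp_kind: str = "ECFP6", random_state: int = 0) -> ActivityModel:
    """Grid search (C, gamma) for best validation ROC-AUC, then refit.

    Grids default to powers of two, 2^-8 .. 2^8. Ties break toward smaller
    C, then smaller gamma. The search scores with the SVM decision function
    (ROC-AUC needs only a ranking); the winning model is refit with
    probability estimates enabled. The fitted model carries
    ``validation_auc_`` and the full ``grid_scores_`` table.
    """
    C_grid = np.asarray(C_grid if C_grid is not None
                        else 2.0 ** np.arange(-8, 9), dtype=float)
    gamma_grid = np.asarray(gamma_grid if gamma_grid is not None
                            else 2.0 ** np.arange(-8, 9), dtype=float)
    y_train, y_val = np.asarray(y_train), np.asarray(y_val)
    for name, y in (("training", y_train), ("validation", y_val)):
        if len(np.unique(y)) < 2:
            raise ValueError(f"{name} set must contain both classes")
    proto = ActivityModel(n_bits=n_bits, fp_kind=fp_kind)
    X_tr = proto.featurize(train_smiles)
    X_val = proto.featurize(val_smiles)
    # precompute squared distances once; the RBF kernel for every gamma is
    # then a single exp, which keeps the full grid affordable
    sq_tr = (X_tr * X_tr).sum(1)
    sq_val = (X_val * X_val).sum(1)
    D_tt = sq_tr[:, None] + sq_tr[None, :] - 2.0 * X_tr @ X_tr.T
    D_vt = sq_val[:, None] + sq_tr[None, :] - 2.0 * X_val @ X_tr.T
    np.maximum(D_tt, 0.0, out=D_tt)
    np.maximum(D_vt, 0.0, out=D_vt)
    best = (-np.inf, None, None)
    records = []
    for g in sorted(gamma_grid):
        K_tt = np.exp(-g * D_tt)
        K_vt = np.exp(-g * D_vt)
        for C in sorted(C_grid):
            svc = SVC(kernel="precomputed", C=C)
            svc.fit(K_tt, y_train)
            auc = roc_auc_score(y_val, svc.decision_function(K_vt))
            records.append({"C": C, "gamma": g, "roc_auc": auc})
            # strict improvement only: first-seen (smallest C, gamma) wins ties
            if auc > best[0] + 1e-12:
                best = (auc, C, g)
    # re-sort tie-break across gammas: smaller C first, then smaller gamma
    table = pd.DataFrame(records)
    top = table[np.isclose(table["roc_auc"], table["roc_auc"].max())]
    top = top.sort_values(["C", "gamma"]).iloc[0]
    model = ActivityModel(C=float(top["C"]), gamma=float(top["gamma"]),
                          n_bits=n_bits, fp_kind=fp_kind,
                          random_state=random_state)
    model.fit(train_smiles, y_train)
    model.validation_auc_ = float(top["roc_auc"])
    model.grid_scores_ = table
    return model


# ---------------------------------------------------------------------------
# Synthetic activity data

#: Planted pharmacophore-like fragments; every active carries one of these,
#: no inactive carries any.
PHARMACOPHORES = ["S(=O)(=O)N", "C(=O)Nc1ccncc1", "N1CCN(C)CC1"]

_PHARM_MOLS = None


def _pharm_queries():
    global _PHARM_MOLS
    if _PHARM_MOLS is None:
        _PHARM_MOLS = [Chem.MolFromSmiles(p) for p in PHARMACOPHORES]
    return _PHARM_MOLS


def _has_pharmacophore(smiles: str) -> bool:
    mol = mol_from_smiles(smiles)
    return mol is not None and any(mol.HasSubstructMatch(q)
                                   for q in _pharm_queries())


def make_synthetic_activity_dataset(n_active: int = 300,
                                    n_inactive: int = 900,
                                    seed: int = 0,
                                    n_families: int = 25) -> pd.DataFrame:
    """Labelled synthetic dataset with a planted structure-activity rule.

    Actives are decorated members of ``n_families`` scaffold families, each
    carrying one planted pharmacophore fragment; inactives are random
    molecules verified to carry none. Canonical-SMILES duplicates within a
    label are removed, so clustering and splitting see distinct structures.
    Deterministic per seed. Columns: smiles, label (1 = active).
    """
    if n_active < 10 or n_inactive < 10:
        raise ValueError("need at least 10 molecules per class")
    rng = np.random.default_rng(seed)
    scaffolds = [_molgen.random_scaffold(rng) for _ in range(n_families)]
    actives: dict[str, None] = {}
    while len(actives) < n_active:
        scaf = scaffolds[rng.integers(0, n_families)]
        deco = _molgen.random_chain(rng, 0, 3)
        pharm = PHARMACOPHORES[rng.integers(0, len(PHARMACOPHORES))]
        smiles = deco + scaf + pharm
        try:
            can = canonicalize(smiles)
        except ValueError:
            continue
        if _has_pharmacophore(can):
            actives.setdefault(can, None)
    inactives: dict[str, None] = {}
    while len(inactives) < n_inactive:
        smiles = _molgen.random_molecule(rng, sulphur=False)
        can = canonicalize(smiles)
        if not _has_pharmacophore(can):
            inactives.setdefault(can, None)
    df = pd.DataFrame({
        "smiles": list(actives) + list(inactives),
        "label": [1] * len(actives) + [0] * len(inactives),
    })
    df.attrs["provenance"] = (
        f"synthetic planted-substructure dataset, seed={seed}")
    return df
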