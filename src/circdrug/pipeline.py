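"""End-to-end cross-validated association prediction.

Per fold: test-fold positives are masked out of the working copy of the
association matrix (leakage guard, default on); GIP similarities and
node features are recomputed from the masked matrix; the comprehensive
similarity graphs are rebuilt and binarized; one auto-encoder per side
produces embeddings; the pair classifier is trained on the fold's
training positives plus uniformly sampled negatives and scored on the
held-out pairs.  Negatives are drawn once globally (1:1 by default) and
folded together with the positives, stratified by label.

Also provides threshold grid search, per-drug candidate ranking from a
model trained on all known associations, and de-novo drug prediction
where a structure-only drug joins the graph with randomly assigned
features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .classifier import (
    ClassifierConfig,
    build_pair_features,
    predict_scores,
    train_classifier,
)
from .data_io import AssociationMatrix, Dataset, DrugRecord
from .errors import ValidationError
from .gate import Embedding, GateConfig, NodeFeatures, train_gate
from .similarity import (
    BinaryGraph,
    SimilarityMatrix,
    binarize,
    drug_structure_similarity,
    fuse,
    gip_kernel,
    sequence_similarity,
    smiles_to_fingerprint,
)

__all__ = [
    "CVConfig",
    "MetricsReport",
    "sample_negatives",
    "masked_associations",
    "kfold_split",
    "compute_metrics",
    "run_cv",
    "grid_search_thresholds",
    "rank_for_drug",
    "predict_de_novo_drug",
]

METRIC_NAMES = ("auc", "aupr", "f1", "accuracy", "recall", "specificity", "precision")


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation settings; cth/dth are the binarization cutoffs."""

    k: int = 5
    neg_ratio: float = 1.0
    cth: float = 0.7
    dth: float = 0.6
    seed: int = 0
    leakage_guard: bool = True

    def __post_init__(self):
        if self.k < 2:
            raise ValidationError("k must be >= 2")
        if self.neg_ratio <= 0:
            raise ValidationError("neg_ratio must be positive")
        for name in ("cth", "dth"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} outside [0, 1]")


@dataclass
class MetricsReport:
    """Per-fold and mean evaluation metrics."""

    folds: list[dict] = field(default_factory=list)
    mean: dict = field(default_factory=dict)

    def finalize(self) -> "MetricsReport":
        self.mean = {
            m: float(np.mean([f[m] for f in self.folds])) for m in METRIC_NAMES
        }
        return self

    def to_dict(self) -> dict:
        return {"folds": self.folds, "mean": self.mean}


def sample_negatives(
    A: AssociationMatrix, ratio: float, seed: int
) -> list[tuple[int, int]]:
    """Uniform sample (without replacement) of zero cells of A."""
    zeros = np.argwhere(A.values == 0)
    n_needed = int(round(ratio * A.n_positives))
    if n_needed > len(zeros):
        raise ValidationError(
            f"requested {n_needed} negatives but only {len(zeros)} zero cells exist"
        )
    rng = np.random.default_rng(seed)
    chosen = zeros[rng.choice(len(zeros), size=n_needed, replace=False)]
    return [(int(i), int(j)) for i, j in chosen]


def kfold_split(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Stratified fold assignment (0..k-1) per labelled pair."""
    labels = np.asarray(labels)
    if k > len(labels):
        raise ValidationError("k exceeds the number of pairs")
    counts = np.bincount(labels.astype(int))
    if (counts[counts > 0] < k).any():
        raise ValidationError("k exceeds the size of the smallest class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignment[test_idx] = f
    return assignment


def compute_metrics(labels, scores, threshold: float = 0.5) -> dict:
    """AUC (trapezoidal ROC), AUPR, and thresholded confusion metrics."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValidationError("metrics need both classes present")
    pred = scores > threshold
    pos, neg = labels == 1, labels == 0
    tp = int((pred & pos).sum())
    fp = int((pred & neg).sum())
    tn = int((~pred & neg).sum())
    fn = int((~pred & pos).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {
        "auc": float(roc_auc_score(labels, scores)),
        "aupr": float(average_precision_score(labels, scores)),
        "f1": f1,
        "accuracy": (tp + tn) / len(labels),
        "recall": recall,
        "specificity": specificity,
        "precision": precision,
    }


def _child_seed(*entropy: int) -> int:
    return int(np.random.SeedSequence(list(entropy)).generate_state(1)[0] % (2**31))


def masked_associations(A: AssociationMatrix, positive_pairs) -> np.ndarray:
    """Copy of A.values with the given positive cells zeroed (leakage guard)."""
    out = A.values.astype(np.int8).copy()
    for i, j in positive_pairs:
        if out[i, j] != 1:
            raise ValidationError(f"cell ({i},{j}) is not a known positive")
        out[i, j] = 0
    return out


def _dataset_fingerprints(dataset: Dataset, n_bits: int = 2048) -> np.ndarray:
    if dataset.fingerprints is not None:
        return dataset.fingerprints
    return np.stack(
        [smiles_to_fingerprint(d.smiles, n_bits, d.id) for d in dataset.drugs]
    )


def _primary_similarities(dataset: Dataset) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    css = sequence_similarity(dataset.sequences)
    dss = drug_structure_similarity(_dataset_fingerprints(dataset), dataset.drug_ids)
    return css, dss


def _build_graphs(
    A_work: np.ndarray,
    css: SimilarityMatrix,
    dss: SimilarityMatrix,
    cv_cfg: CVConfig,
) -> tuple[BinaryGraph, BinaryGraph]:
    cgs = gip_kernel(A_work, css.ids)
    dgs = gip_kernel(A_work.T, dss.ids)
    cs = fuse(css, cgs)
    ds = fuse(dss, dgs)
    return binarize(cs, cv_cfg.cth), binarize(ds, cv_cfg.dth)


def _embed_sides(
    A_work: np.ndarray,
    g_circ: BinaryGraph,
    g_drug: BinaryGraph,
    gate_cfg: GateConfig,
    seed_c: int,
    seed_d: int,
) -> tuple[Embedding, Embedding]:
    xc = NodeFeatures(g_circ.ids, A_work.astype(np.float64))
    xd = NodeFeatures(g_drug.ids, A_work.T.astype(np.float64))
    _, emb_c, _ = train_gate(xc, g_circ, replace(gate_cfg, seed=seed_c))
    _, emb_d, _ = train_gate(xd, g_drug, replace(gate_cfg, seed=seed_d))
    return emb_c, emb_d


def run_cv(
    dataset: Dataset,
    gate_cfg: GateConfig | None = None,
    clf_cfg: ClassifierConfig | None = None,
    cv_cfg: CVConfig | None = None,
) -> MetricsReport:
    """k-fold cross-validated evaluation of the full pipeline."""
    gate_cfg = gate_cfg or GateConfig()
    clf_cfg = clf_cfg or ClassifierConfig()
    cv_cfg = cv_cfg or CVConfig()

    A = dataset.associations
    positives = [(int(i), int(j)) for i, j in np.argwhere(A.values == 1)]
    negatives = sample_negatives(A, cv_cfg.neg_ratio, _child_seed(cv_cfg.seed, 10))
    pairs = positives + negatives
    labels = np.array([1] * len(positives) + [0] * len(negatives))
    fold_of = kfold_split(labels, cv_cfg.k, _child_seed(cv_cfg.seed, 11))

    css, dss = _primary_similarities(dataset)
    report = MetricsReport()
    for f in range(cv_cfg.k):
        test_mask = fold_of == f
        train_idx = np.flatnonzero(~test_mask)
        test_idx = np.flatnonzero(test_mask)

        if cv_cfg.leakage_guard:
            A_work = masked_associations(
                A, [pairs[t] for t in test_idx if labels[t] == 1]
            )
        else:
            A_work = A.values.astype(np.int8).copy()

        g_circ, g_drug = _build_graphs(A_work, css, dss, cv_cfg)
        emb_c, emb_d = _embed_sides(
            A_work, g_circ, g_drug, gate_cfg,
            _child_seed(cv_cfg.seed, f, 0), _child_seed(cv_cfg.seed, f, 1),
        )

        train_feats = build_pair_features(
            emb_c, emb_d, [pairs[t] for t in train_idx], labels[train_idx]
        )
        head = train_classifier(
            train_feats, replace(clf_cfg, seed=_child_seed(cv_cfg.seed, f, 2))
        )
        test_feats = build_pair_features(emb_c, emb_d, [pairs[t] for t in test_idx])
        scores = predict_scores(head, test_feats)
        entry = compute_metrics(labels[test_idx], scores)
        entry["fold"] = f
        report.folds.append(entry)
    return report.finalize()


def grid_search_thresholds(
    dataset: Dataset,
    cth_grid,
    dth_grid,
    cv_cfg: CVConfig | None = None,
    gate_cfg: GateConfig | None = None,
    clf_cfg: ClassifierConfig | None = None,
) -> list[dict]:
    """One CV run per (cth, dth) cell; rows sorted by mean AUC descending."""
    cv_cfg = cv_cfg or CVConfig()
    cth_grid = list(cth_grid)
    dth_grid = list(dth_grid)
    if not cth_grid or not dth_grid:
        raise ValidationError("threshold grids must be non-empty")
    rows = []
    for cth in cth_grid:
        for dth in dth_grid:
            rep = run_cv(dataset, gate_cfg, clf_cfg,
                         replace(cv_cfg, cth=cth, dth=dth))
            rows.append({
                "cth": float(cth), "dth": float(dth),
                "auc": rep.mean["auc"], "aupr": rep.mean["aupr"],
            })
    rows.sort(key=lambda r: (-r["auc"], r["cth"], r["dth"]))
    return rows


def _train_full(
    dataset: Dataset,
    gate_cfg: GateConfig,
    clf_cfg: ClassifierConfig,
    cv_cfg: CVConfig,
):
    """Train GATEs and classifier on all known associations (no masking)."""
    A = dataset.associations
    css, dss = _primary_similarities(dataset)
    A_work = A.values.astype(np.int8)
    g_circ, g_drug = _build_graphs(A_work, css, dss, cv_cfg)
    emb_c, emb_d = _embed_sides(
        A_work, g_circ, g_drug, gate_cfg,
        _child_seed(cv_cfg.seed, 100), _child_seed(cv_cfg.seed, 101),
    )
    positives = [(int(i), int(j)) for i, j in np.argwhere(A.values == 1)]
    negatives = sample_negatives(A, cv_cfg.neg_ratio, _child_seed(cv_cfg.seed, 102))
    labels = np.array([1] * len(positives) + [0] * len(negatives))
    feats = build_pair_features(emb_c, emb_d, positives + negatives, labels)
    head = train_classifier(feats, replace(clf_cfg, seed=_child_seed(cv_cfg.seed, 103)))
    return emb_c, emb_d, head


def _ranked(scores: np.ndarray, circ_ids, top_n: int) -> list[tuple[str, float]]:
    order = sorted(range(len(circ_ids)), key=lambda i: (-scores[i], circ_ids[i]))
    return [(circ_ids[i], float(scores[i])) for i in order[:top_n]]


def rank_for_drug(
    dataset: Dataset,
    drug_id: str,
    gate_cfg: GateConfig | None = None,
    clf_cfg: ClassifierConfig | None = None,
    cv_cfg: CVConfig | None = None,
    top_n: int = 20,
) -> list[tuple[str, float]]:
    """Top-``top_n`` circRNAs for one drug, model trained on all associations.

    Ties are broken by circRNA id (lexicographic).
    """
    gate_cfg = gate_cfg or GateConfig()
    clf_cfg = clf_cfg or ClassifierConfig()
    cv_cfg = cv_cfg or CVConfig()
    if drug_id not in dataset.drug_ids:
        raise ValidationError(f"unknown drug id {drug_id!r}")
    j = dataset.drug_ids.index(drug_id)
    emb_c, emb_d, head = _train_full(dataset, gate_cfg, clf_cfg, cv_cfg)
    pairs = [(i, j) for i in range(len(dataset.circ_ids))]
    scores = predict_scores(head, build_pair_features(emb_c, emb_d, pairs))
    return _ranked(scores, dataset.circ_ids, top_n)


def predict_de_novo_drug(
    dataset: Dataset,
    new_drug: DrugRecord | np.ndarray,
    gate_cfg: GateConfig | None = None,
    clf_cfg: ClassifierConfig | None = None,
    cv_cfg: CVConfig | None = None,
    seed: int = 0,
    top_n: int = 20,
    new_drug_id: str = "__new__",
) -> list[tuple[str, float]]:
    """Rank circRNAs for a drug with no known associations.

    ``new_drug`` is a :class:`DrugRecord` with a SMILES string, or a raw
    binary fingerprint vector.  The drug joins the drug graph through
    structure similarity only — it has no interaction profile, so its
    GIP similarity is absent and its fused row falls back to the
    structure similarity alone.  Its auto-encoder input features are
    drawn from a seeded standard uniform.
    """
    gate_cfg = gate_cfg or GateConfig()
    clf_cfg = clf_cfg or ClassifierConfig()
    cv_cfg = cv_cfg or CVConfig()

    fps = _dataset_fingerprints(dataset)
    if isinstance(new_drug, DrugRecord):
        if not new_drug.smiles:
            raise ValidationError("de novo drug needs structure information")
        new_fp = smiles_to_fingerprint(new_drug.smiles, fps.shape[1], new_drug.id)
        new_drug_id = new_drug.id
    else:
        new_fp = np.asarray(new_drug)
        if new_fp.shape != (fps.shape[1],):
            raise ValidationError(
                f"fingerprint length {new_fp.shape} != dataset length {fps.shape[1]}"
            )

    A = dataset.associations
    n_c, n_d = A.values.shape
    drug_ids_ext = A.drug_ids + (new_drug_id,)

    css = sequence_similarity(dataset.sequences)
    dss_ext = drug_structure_similarity(
        np.vstack([fps, new_fp[None, :]]), drug_ids_ext
    )
    cgs = gip_kernel(A.values, css.ids)
    # Existing drugs fuse structure and GIP as usual; the new drug has no
    # interaction profile, so its row/column falls back to structure alone.
    dgs_known = gip_kernel(A.values.T, A.drug_ids).values
    ds_vals = dss_ext.values.copy()
    ds_vals[:n_d, :n_d] = np.where(
        dss_ext.values[:n_d, :n_d] != 0,
        (dss_ext.values[:n_d, :n_d] + dgs_known) / 2.0,
        dgs_known,
    )
    ds_ext = SimilarityMatrix(drug_ids_ext, ds_vals)

    g_circ = binarize(fuse(css, cgs), cv_cfg.cth)
    g_drug = binarize(ds_ext, cv_cfg.dth)

    rng = np.random.default_rng(seed)
    A_drugside = np.vstack([A.values.T.astype(np.float64), rng.random((1, n_c))])

    xc = NodeFeatures(g_circ.ids, A.values.astype(np.float64))
    xd = NodeFeatures(g_drug.ids, A_drugside)
    _, emb_c, _ = train_gate(xc, g_circ, replace(gate_cfg, seed=_child_seed(seed, 0)))
    _, emb_d, _ = train_gate(xd, g_drug, replace(gate_cfg, seed=_child_seed(seed, 1)))

    positives = [(int(i), int(j)) for i, j in np.argwhere(A.values == 1)]
    negatives = sample_negatives(A, cv_cfg.neg_ratio, _child_seed(seed, 2))
    labels = np.array([1] * len(positives) + [0] * len(negatives))
    feats = build_pair_features(emb_c, emb_d, positives + negatives, labels)
    head = train_classifier(feats, replace(clf_cfg, seed=_child_seed(seed, 3)))

    pairs = [(i, n_d) for i in range(n_c)]
    scores = predict_scores(head, build_pair_features(emb_c, emb_d, pairs))
    return _ranked(scores, dataset.circ_ids, top_n)
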