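"""Leave-one-patient-out prediction of surgical outcome from displacement maps.

For every held-out patient the group-level ROI is re-derived from the
remaining patients only (side-stratified by default), the held-out
patient's ROI-median displacement is computed, and a single-feature
logistic regression fitted on the training patients yields the probability
of a favorable outcome.  Pooled out-of-fold probabilities give the ROC AUC
and the balanced accuracy

    BA = 1/2 * (TP / (TP + FN) + TN / (TN + FP)),

with favorable as the positive class.  A degree-preserving rewiring control
re-runs the whole pipeline on randomized networks with identical degree
sequences, probing whether prediction relies on network structure beyond
the number of resected connections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

from . import synth
from .embedding import DiskEmbedding, EmbeddingParams, align_to_reference, embed
from .geometry import hypdisp_scores
from .io import Connectome
from .raster import DiskRaster, RasterParams, interpolate
from .roi import RoiParams, pixelwise_ttest, roi_median_feature

POSITIVE = "favorable"


class UndefinedMetricError(ValueError):
    """Raised when a metric is requested for a degenerate label set."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(labels, predictions) -> ConfusionCounts:
    """Counts with ``favorable`` as the positive class."""
    labels = list(labels)
    predictions = list(predictions)
    tp = sum(1 for y, p in zip(labels, predictions) if y == POSITIVE and p == POSITIVE)
    tn = sum(1 for y, p in zip(labels, predictions) if y != POSITIVE and p != POSITIVE)
    fp = sum(1 for y, p in zip(labels, predictions) if y != POSITIVE and p == POSITIVE)
    fn = sum(1 for y, p in zip(labels, predictions) if y == POSITIVE and p != POSITIVE)
    return ConfusionCounts(tp, tn, fp, fn)


def balanced_accuracy(c: ConfusionCounts) -> float:
    """Mean of sensitivity and specificity."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise UndefinedMetricError("balanced accuracy needs both classes present")
    return 0.5 * (c.tp / (c.tp + c.fn) + c.tn / (c.tn + c.fp))


def roc_auc(labels, scores) -> float:
    """Mann-Whitney AUC: P(random favorable outranks random poor), ties 1/2."""
    labels = np.asarray([1 if y == POSITIVE else 0 for y in labels])
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2 wins
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass(frozen=True)
class PatientData:
    subject_id: str
    side: str  # left | right
    outcome: str  # favorable | poor
    pre: Connectome
    post: Connectome


@dataclass
class FoldResult:
    subject_id: str
    side: str
    outcome: str
    probability: float
    feature: float
    roi_n_pixels: int
    empty_roi: bool


@dataclass
class CohortResult:
    reference_id: str
    folds: list
    auc: float
    balanced_accuracy: float
    accuracy: float
    by_side: dict  # side -> {"auc": ..., "balanced_accuracy": ...} where defined

    @property
    def probabilities(self) -> dict:
        return {f.subject_id: f.probability for f in self.folds}


@dataclass(frozen=True)
class PatientMaps:
    """Per-patient products that do not depend on the LOPO fold."""

    patient: PatientData
    pre_embedding: DiskEmbedding  # aligned to the reference
    post_embedding: DiskEmbedding
    scores: np.ndarray
    raster: DiskRaster
    alignment_pre: object = None  # AlignmentResult for auditing
    alignment_post: object = None


def displacement_maps(
    patients,
    reference: Connectome,
    emb_params: EmbeddingParams | None = None,
    raster_params: RasterParams | None = None,
) -> list:
    """Embed, align to the reference, score and rasterize every patient.

    Pre and post embeddings are both aligned to the same healthy-control
    reference; post-surgery graphs may be disconnected or contain isolated
    nodes (placed at their pre-surgery angle).
    """
    emb_params = emb_params or EmbeddingParams()
    raster_params = raster_params or RasterParams()
    ref_emb = embed(reference, emb_params)
    out = []
    for p in patients:
        pre_emb = embed(p.pre, emb_params)
        post_emb = embed(
            p.post, emb_params, theta_fallback=pre_emb.theta, allow_disconnected=True
        )
        pre_al, t_pre = align_to_reference(pre_emb, ref_emb)
        post_al, t_post = align_to_reference(post_emb, ref_emb)
        scores = hypdisp_scores(
            pre_al.radius, pre_al.theta, post_al.radius, post_al.theta
        )
        raster = interpolate(pre_al, scores, raster_params)
        out.append(PatientMaps(p, pre_al, post_al, scores, raster, t_pre, t_post))
    return out


def _fit_probability(train_x, train_y, test_x):
    """Single-feature logistic regression; returns P(favorable) for test_x.

    Plain maximum likelihood (no regularization); on perfectly separated
    training features the fit falls back to a tiny ridge penalty.
    """
    x = np.asarray(train_x, dtype=float).reshape(-1, 1)
    y = np.asarray([1 if t == POSITIVE else 0 for t in train_y])
    pos, neg = x[y == 1, 0], x[y == 0, 0]
    separated = pos.min() > neg.max() or pos.max() < neg.min()
    if separated:
        model = LogisticRegression(C=1e6, solver="lbfgs", max_iter=2000)
    else:
        model = LogisticRegression(penalty=None, solver="lbfgs", max_iter=2000)
    with warnings.catch_warnings():
        # near-separated folds push the MLE toward infinity; the fitted
        # probabilities are still monotone in x, which is all that matters
        warnings.simplefilter("ignore")
        model.fit(x, y)
    return float(model.predict_proba([[float(test_x)]])[0, 1]), separated


def _metrics(folds):
    labels = [f.outcome for f in folds]
    probs = [f.probability for f in folds]
    preds = [POSITIVE if p >= 0.5 else "poor" for p in probs]
    c = confusion_counts(labels, preds)
    return {
        "auc": roc_auc(labels, probs),
        "balanced_accuracy": balanced_accuracy(c),
        "accuracy": (c.tp + c.tn) / c.total,
    }


def lopo_predict(
    patients,
    reference: Connectome,
    reference_id: str = "reference",
    emb_params: EmbeddingParams | None = None,
    raster_params: RasterParams | None = None,
    roi_params: RoiParams | None = None,
    stratify_by_side: bool = True,
    maps: list | None = None,
) -> CohortResult:
    """Leave-one-patient-out outcome prediction for one reference network.

    Per fold the ROI is recomputed from the training patients only — the
    held-out patient's maps contribute neither to the pixelwise test nor to
    the regression fit.  Folds whose training ROI is empty (or whose
    stratum lacks two patients per class) carry no usable feature; they are
    flagged and receive the uninformative probability 0.5.  (A training
    class-prevalence prior is deliberately not used: with one patient held
    out it is deterministically lower for held-out favorable patients than
    for held-out poor ones, which anti-correlates the probability with the
    label.)
    """
    roi_params = roi_params or RoiParams()
    patients = list(patients)
    if maps is None:
        maps = displacement_maps(patients, reference, emb_params, raster_params)
    folds = []
    for i, held in enumerate(maps):
        train = [m for j, m in enumerate(maps) if j != i]
        if stratify_by_side:
            train = [m for m in train if m.patient.side == held.patient.side]
        fav = [m.raster for m in train if m.patient.outcome == POSITIVE]
        poor = [m.raster for m in train if m.patient.outcome == "poor"]
        if len(fav) < 2 or len(poor) < 2:
            folds.append(
                FoldResult(
                    held.patient.subject_id,
                    held.patient.side,
                    held.patient.outcome,
                    probability=0.5,
                    feature=float("nan"),
                    roi_n_pixels=0,
                    empty_roi=True,
                )
            )
            continue
        roi = pixelwise_ttest(fav, poor, roi_params)
        if roi.n_pixels == 0:
            folds.append(
                FoldResult(
                    held.patient.subject_id,
                    held.patient.side,
                    held.patient.outcome,
                    probability=0.5,
                    feature=float("nan"),
                    roi_n_pixels=0,
                    empty_roi=True,
                )
            )
            continue
        train_x = [roi_median_feature(m.raster, roi) for m in train]
        train_y = [m.patient.outcome for m in train]
        test_x = roi_median_feature(held.raster, roi)
        prob, _ = _fit_probability(train_x, train_y, test_x)
        folds.append(
            FoldResult(
                held.patient.subject_id,
                held.patient.side,
                held.patient.outcome,
                probability=prob,
                feature=test_x,
                roi_n_pixels=roi.n_pixels,
                empty_roi=False,
            )
        )
    overall = _metrics(folds)
    by_side = {}
    for side in ("left", "right"):
        sub = [f for f in folds if f.side == side]
        try:
            by_side[side] = _metrics(sub)
        except (UndefinedMetricError, ZeroDivisionError):
            pass
    return CohortResult(
        reference_id=reference_id,
        folds=folds,
        auc=overall["auc"],
        balanced_accuracy=overall["balanced_accuracy"],
        accuracy=overall["accuracy"],
        by_side=by_side,
    )


def replicate_over_references(
    patients,
    controls: dict,
    n_refs: int,
    seed: int,
    **lopo_kwargs,
):
    """Repeat the LOPO prediction with several control references.

    ``controls`` maps control subject ids to their networks; ``n_refs``
    distinct references are drawn (seeded).  Returns ``(summary, results)``
    where summary holds mean and SD of AUC and balanced accuracy across
    references (SD is 0 for a single reference).
    """
    if n_refs < 1:
        raise ValueError("n_refs must be >= 1")
    ids = sorted(controls)
    if n_refs > len(ids):
        raise ValueError(f"n_refs={n_refs} exceeds number of controls {len(ids)}")
    rng = np.random.default_rng(int(seed))
    chosen = [ids[k] for k in rng.choice(len(ids), size=n_refs, replace=False)]
    results = [
        lopo_predict(patients, controls[cid], reference_id=cid, **lopo_kwargs)
        for cid in chosen
    ]
    aucs = np.array([r.auc for r in results])
    bals = np.array([r.balanced_accuracy for r in results])
    summary = {
        "n_references": n_refs,
        "reference_ids": chosen,
        "auc_mean": float(aucs.mean()),
        "auc_sd": float(aucs.std(ddof=0)) if n_refs > 1 else 0.0,
        "balanced_accuracy_mean": float(bals.mean()),
        "balanced_accuracy_sd": float(bals.std(ddof=0)) if n_refs > 1 else 0.0,
    }
    return summary, results


def degree_preserving_rewire(net: Connectome, fraction: float, seed: int) -> Connectome:
    """Randomize a graph by double-edge swaps, preserving every degree.

    Swapping continues until at least ``fraction`` of the edges differ from
    the original edge set or an attempt cap is hit (best effort on rigid
    graphs such as stars); the achieved fraction is available by comparing
    edge sets.  Self-loops and multi-edges are never created.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    if net.n_edges < 2:
        raise ValueError("rewiring needs at least 2 edges")
    if fraction == 0:
        return net
    adj = net.adjacency.copy()
    i, j = np.nonzero(np.triu(adj, k=1))
    edges = list(zip(i.tolist(), j.tolist()))
    target = int(round(fraction * len(edges)))
    rng = np.random.default_rng(int(seed))
    synth._degree_preserving_swaps(adj, edges, target, rng)
    return net.with_adjacency(adj)


def rewiring_control(
    patients,
    reference: Connectome,
    truths: dict,
    resection_fraction: float,
    rewire_fraction: float,
    seed: int,
    reference_id: str = "reference",
    **lopo_kwargs,
) -> CohortResult:
    """LOPO prediction on degree-preserving rewired patient networks.

    Each patient's pre-surgery network is rewired at ``rewire_fraction``;
    the post network is re-derived by applying the original resection mask
    (same resected nodes and resection fraction, seeded per patient) to the
    rewired graph.  At ``rewire_fraction == 0`` this reproduces the
    unperturbed cohort exactly.
    """
    rng = np.random.SeedSequence(int(seed))
    sub_seeds = rng.generate_state(2 * len(list(patients)), dtype=np.uint32) % (2**31)
    rewired = []
    for k, p in enumerate(patients):
        if rewire_fraction == 0:
            rewired.append(p)  # untouched: metrics match the baseline run exactly
            continue
        truth = truths[p.subject_id]
        pre = degree_preserving_rewire(p.pre, rewire_fraction, int(sub_seeds[2 * k]))
        post = synth.apply_resection(
            pre, truth, resection_fraction, int(sub_seeds[2 * k + 1])
        )
        rewired.append(PatientData(p.subject_id, p.side, p.outcome, pre, post))
    return lopo_predict(rewired, reference, reference_id=reference_id, **lopo_kwargs)
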