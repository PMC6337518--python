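"""Cross-validation protocols and ROC/AUC computation.

Three schemes are provided:

* **global LOOCV** — each known association is held out in turn and its score
  is ranked against all unknown (candidate) pairs of the reduced model;
* **local LOOCV** — the held-out association is ranked only against the
  unknown miRNAs of its own disease (diseases with fewer than two known
  miRNAs are skipped);
* **repeated k-fold** — the known associations are partitioned at random into
  k folds, each fold held out at once; the per-repeat AUC is reported as
  mean +/- sd over repeats.

By default every DMM-dependent quantity (functional similarity, interaction
profile kernels, inferred edges, neighbor sets) is *recomputed* on the
reduced association matrix so no information leaks from the held-out pair;
the ontology-based semantic similarity does not touch the association matrix
and is cached across folds.  ``refit=False`` scores everything from the
full-data network instead (faster, leaky).

The AUC is rank-based with midrank tie handling: for each held-out positive
the fraction of candidates scoring *worse* (larger distance; ties count one
half) is averaged over positives, which equals the probability that a random
positive outranks a random candidate when every positive faces the same
candidate set.
"""

from __future__ import annotations

from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import WINMDA, network_pipeline, score_network, score_pipeline
from .types import AssocMatrix, CvReport, RocResult


# ---------------------------------------------------------------------------
# ROC / AUC primitives
# ---------------------------------------------------------------------------

def _as_larger_better(scores: np.ndarray, polarity: str) -> np.ndarray:
    if polarity == "smaller_better":
        return -scores
    if polarity == "larger_better":
        return scores
    raise ValueError("polarity must be 'smaller_better' or 'larger_better'")


def roc_auc(
    positive_scores: Sequence[float],
    candidate_scores: Sequence[float],
    polarity: str = "smaller_better",
) -> RocResult:
    """Threshold-sweep ROC curve and rank-based AUC (midrank ties).

    The AUC equals the probability that a randomly drawn positive outranks a
    randomly drawn candidate, ties counting one half.
    """
    pos = np.asarray(list(positive_scores), dtype=float)
    neg = np.asarray(list(candidate_scores), dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    pos = _as_larger_better(pos, polarity)
    neg = _as_larger_better(neg, polarity)

    # Mann-Whitney statistic with midranks
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    auc = (greater + 0.5 * ties) / (pos.size * neg.size)

    thresholds = np.unique(np.concatenate((pos, neg)))[::-1]
    points: List[Tuple[float, float]] = [(0.0, 0.0)]
    for t in thresholds:
        tpr = float((pos >= t).mean())
        fpr = float((neg >= t).mean())
        if (fpr, tpr) != points[-1]:
            points.append((fpr, tpr))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return RocResult(points=points, auc=float(auc))


def _percentile(test_score: float, candidate_scores: np.ndarray) -> float:
    """Fraction of candidates scoring worse than the test pair (ties = 1/2).

    Scores are distances: worse = larger.  An infinite test score ranks
    behind every finite candidate and ties other infinities.
    """
    worse = (candidate_scores > test_score).sum()
    ties = (candidate_scores == test_score).sum()
    return float((worse + 0.5 * ties) / candidate_scores.size)


# ---------------------------------------------------------------------------
# Cross-validation schemes
# ---------------------------------------------------------------------------

def _reduced_assoc(assoc: AssocMatrix, remove: Iterable[Tuple[int, int]]) -> AssocMatrix:
    dmm = assoc.dmm.copy()
    for i, j in remove:
        dmm[i, j] = 0
    return AssocMatrix(list(assoc.diseases), list(assoc.mirnas), dmm)


def _fold_scores(model: WINMDA, remove: List[Tuple[int, int]], refit: bool) -> np.ndarray:
    if refit:
        reduced = _reduced_assoc(model.assoc, remove)
        state = score_pipeline(reduced, model.sdd, model.T, model.w)
        return state.scores.fpr_score
    if not hasattr(model, "_full_scores"):
        model._full_scores = score_pipeline(  # type: ignore[attr-defined]
            model.assoc, model.sdd, model.T, model.w
        ).scores.fpr_score
    return model._full_scores  # type: ignore[attr-defined]


def global_loocv(model: WINMDA, refit: bool = True) -> CvReport:
    """Leave each known association out and rank it against all unknown pairs."""
    assoc = model.assoc
    known = [tuple(p) for p in np.argwhere(assoc.dmm == 1)]
    if len(known) < 2:
        raise ValueError("global LOOCV needs at least 2 known associations")
    unknown_mask = assoc.dmm == 0
    percentiles = []
    for (i, j) in known:
        fpr = _fold_scores(model, [(i, j)], refit)
        percentiles.append(_percentile(fpr[i, j], fpr[unknown_mask]))
    return CvReport(
        scheme="global_loocv",
        auc_mean=float(np.mean(percentiles)),
        auc_sd=0.0,
        n_folds=len(known),
    )


def local_loocv(model: WINMDA, refit: bool = True) -> CvReport:
    """Per-disease LOOCV: rank each held-out miRNA against the disease's own
    unknown miRNAs.

    Diseases with fewer than two known miRNAs, or with no candidate miRNAs,
    are skipped.  The aggregate AUC is the mean of per-disease AUCs weighted
    by the number of test samples.
    """
    assoc = model.assoc
    per_disease: List[Tuple[float, int]] = []
    any_eligible = False
    for i in range(assoc.n_diseases):
        known_js = np.flatnonzero(assoc.dmm[i] == 1)
        cand_js = np.flatnonzero(assoc.dmm[i] == 0)
        if known_js.size < 2 or cand_js.size == 0:
            continue
        any_eligible = True
        us = []
        for j in known_js:
            fpr = _fold_scores(model, [(i, int(j))], refit)
            us.append(_percentile(fpr[i, j], fpr[i, cand_js]))
        per_disease.append((float(np.mean(us)), len(us)))
    if not any_eligible:
        raise ValueError("no disease has >= 2 known miRNAs and >= 1 candidate")
    aucs = np.array([a for a, _ in per_disease])
    weights = np.array([n for _, n in per_disease], dtype=float)
    mean = float(np.average(aucs, weights=weights))
    return CvReport(
        scheme="local_loocv",
        auc_mean=mean,
        auc_sd=float(aucs.std()),
        n_folds=int(weights.sum()),
    )


def kfold_cv(
    model: WINMDA,
    k: int = 5,
    repeats: int = 50,
    seed: int = 0,
    refit: bool = True,
) -> CvReport:
    """Repeated k-fold cross-validation over the known associations.

    Per repeat, the known pairs are randomly partitioned (seeded) into k
    folds; each fold is held out at once and its pairs are ranked against all
    unknown pairs of the reduced model.  Reports mean +/- sd of the
    per-repeat AUC.
    """
    assoc = model.assoc
    known = [tuple(p) for p in np.argwhere(assoc.dmm == 1)]
    n = len(known)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of known associations ({n})")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    unknown_mask = assoc.dmm == 0
    rng = np.random.default_rng(seed)
    repeat_aucs: List[float] = []
    for _ in range(repeats):
        order = rng.permutation(n)
        percentiles: List[float] = []
        for fold_idx in np.array_split(order, k):
            held = [known[t] for t in fold_idx]
            fpr = _fold_scores(model, held, refit)
            cand = fpr[unknown_mask]
            percentiles.extend(_percentile(fpr[i, j], cand) for i, j in held)
        repeat_aucs.append(float(np.mean(percentiles)))
    arr = np.array(repeat_aucs)
    sd = float(arr.std(ddof=1)) if repeats > 1 else 0.0
    return CvReport(
        scheme="kfold",
        auc_mean=float(arr.mean()),
        auc_sd=sd,
        n_folds=k,
        k=k,
        repeats=repeats,
        per_repeat_auc=repeat_aucs,
    )


def sensitivity_table(
    model: WINMDA,
    T_values: Sequence[int] = (1, 2, 5, 8, 16),
    w_values: Sequence[float] = (0.0, 0.3, 0.6, 1.0),
    refit: bool = True,
) -> pd.DataFrame:
    """Global-LOOCV AUC as a function of T (at the model's w) and of w (at the
    model's T).

    The expensive per-fold network and shortest-path computation is shared
    across all parameter settings, since only the neighbor aggregation
    depends on T and only the final convex combination depends on w.
    """
    assoc = model.assoc
    known = [tuple(p) for p in np.argwhere(assoc.dmm == 1)]
    if len(known) < 2:
        raise ValueError("need at least 2 known associations")
    unknown_mask = assoc.dmm == 0
    combos: List[Tuple[str, int, float]] = [
        ("T", int(t), model.w) for t in T_values
    ] + [("w", model.T, float(wv)) for wv in w_values]

    sums = {c: [] for c in combos}
    full_state = None if refit else network_pipeline(model.assoc, model.sdd)
    for (i, j) in known:
        if refit:
            reduced = _reduced_assoc(model.assoc, [(i, j)])
            net = network_pipeline(reduced, model.sdd)
        else:
            net = full_state
        for combo in combos:
            _, t, wv = combo
            fpr = score_network(net, t, wv).scores.fpr_score
            sums[combo].append(_percentile(fpr[i, j], fpr[unknown_mask]))
    rows = [
        {"parameter": p, "T": t, "w": wv, "auc": float(np.mean(sums[(p, t, wv)]))}
        for (p, t, wv) in combos
    ]
    return pd.DataFrame(rows)
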