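"""Chi-square nearest-neighbor classification with one-vs-rest Gaussian scoring.

Stacks are compared through the symmetric chi-square distance between their
texton histograms,

    d(a, b) = 1/2 * sum_k (a_k - b_k)^2 / (a_k + b_k),

which lies in [0, 1] for normalized histograms.  For a test stack, the
``nn`` nearest training histograms (default 10) vote with Gaussian distance
weights: the one-vs-rest confidence for class c is

    score = sum_i w_i * exp(-d_i^2 / sigma^2),   w_i = q if label_i == c else -1,

where ``sigma`` is fitted to the pairwise training distances (half-Gaussian
maximum likelihood: sigma = sqrt(mean of squared pairwise distances)) and
``q`` (~5-10, default 7) up-weights the minority positive class of the
one-vs-rest split.  Accuracy is summarized as the area under the ROC curve
of the pooled cross-validated scores, one curve per class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.model_selection import StratifiedKFold

from .exceptions import (
    ConsistencyError,
    DegenerateLibraryError,
    ParameterError,
    StratificationError,
)
from .textons import TextonDictionary, TextonHistogram, assign_and_histogram, learn_dictionary

__all__ = [
    "TrainedModel",
    "RocResult",
    "CrossValResult",
    "chi2_distance",
    "pairwise_chi2",
    "fit_sigma",
    "ovr_confidence",
    "roc_from_scores",
    "cross_validate",
    "fit_model",
]


def _freqs(h) -> np.ndarray:
    return h.freqs if isinstance(h, TextonHistogram) else np.asarray(h, dtype=np.float64)


def chi2_distance(a, b) -> float:
    """Symmetric chi-square distance between two normalized histograms.

    Bins where both histograms are empty contribute zero; the distance is in
    [0, 1] for normalized inputs and vanishes only at equality.
    """
    fa, fb = _freqs(a), _freqs(b)
    if fa.shape != fb.shape:
        raise ConsistencyError(f"histogram lengths differ: {fa.shape} vs {fb.shape}")
    s = fa + fb
    num = (fa - fb) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(s > 0, num / np.where(s > 0, s, 1.0), 0.0)
    return 0.5 * float(terms.sum())


def pairwise_chi2(histograms) -> np.ndarray:
    """Full symmetric chi-square distance matrix for a list of histograms."""
    F = np.asarray([_freqs(h) for h in histograms])
    a = F[:, None, :]
    b = F[None, :, :]
    s = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(s > 0, (a - b) ** 2 / np.where(s > 0, s, 1.0), 0.0)
    return 0.5 * terms.sum(axis=-1)


def fit_sigma(library) -> float:
    """Distance scale from a Gaussian fit to all pairwise training distances.

    Chi-square distances are nonnegative, so the natural fit is a
    zero-location half-Gaussian, whose maximum-likelihood scale is
    ``sqrt(mean(d^2))`` over all training pairs.
    """
    if isinstance(library, np.ndarray) and library.ndim == 2 and library.shape[0] == library.shape[1]:
        D = library
    else:
        D = pairwise_chi2(library)
    n = D.shape[0]
    if n < 2:
        raise ParameterError("need at least two histograms to fit sigma")
    iu = np.triu_indices(n, k=1)
    d = D[iu]
    sigma = float(np.sqrt(np.mean(d**2)))
    if sigma == 0:
        raise DegenerateLibraryError("all pairwise training distances are zero")
    return sigma


@dataclass
class TrainedModel:
    """Texton dictionary + labeled histogram library + scoring parameters."""

    dictionary: TextonDictionary
    library: list[TextonHistogram]
    sigma: float
    q: float = 7.0
    nn: int = 10
    classes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ParameterError("sigma must be positive")
        if self.nn > len(self.library):
            raise ParameterError(
                f"nn={self.nn} exceeds library size {len(self.library)}"
            )
        if not self.classes:
            self.classes = sorted({h.label for h in self.library if h.label is not None})
        missing = {h.label for h in self.library} - set(self.classes)
        if missing:
            raise ConsistencyError(f"library labels {sorted(missing)} not in class set")

    @property
    def library_freqs(self) -> np.ndarray:
        return np.asarray([h.freqs for h in self.library])

    @property
    def library_labels(self) -> np.ndarray:
        return np.asarray([h.label for h in self.library])


def _ovr_score(
    distances: np.ndarray,
    labels: np.ndarray,
    positive_class: str,
    sigma: float,
    nn: int,
    q: float,
) -> float:
    """Gaussian-weighted neighbor vote; ties broken by (distance, index)."""
    order = np.argsort(distances, kind="stable")[:nn]
    d = distances[order]
    w = np.where(labels[order] == positive_class, float(q), -1.0)
    return float(np.sum(w * np.exp(-(d**2) / sigma**2)))


def ovr_confidence(test, model: TrainedModel, positive_class: str) -> float:
    """One-vs-rest confidence of ``test`` for ``positive_class``.

    The ``model.nn`` nearest library histograms by chi-square distance
    contribute ``q * exp(-d^2/sigma^2)`` if they carry the positive label and
    ``-exp(-d^2/sigma^2)`` otherwise.
    """
    labels = model.library_labels
    if positive_class not in set(labels):
        raise ParameterError(f"positive class {positive_class!r} absent from library")
    tf = _freqs(test)
    distances = np.array([chi2_distance(tf, h) for h in model.library_freqs])
    return _ovr_score(distances, labels, positive_class, model.sigma, model.nn, model.q)


@dataclass
class RocResult:
    """ROC curve points and trapezoidal area for one one-vs-rest class."""

    points: list[tuple[float, float]]
    thresholds: np.ndarray
    auroc: float
    class_label: str | None = None


def roc_from_scores(scores, class_label: str | None = None) -> RocResult:
    """ROC curve from (confidence, is_positive) pairs.

    Sweeps all distinct score thresholds (ties step jointly); the area is the
    trapezoidal integral, identical to the normalized Mann-Whitney U
    statistic.
    """
    pairs = list(scores)
    y = np.array([bool(p[1]) for p in pairs])
    s = np.array([float(p[0]) for p in pairs])
    if y.all() or not y.any():
        raise ParameterError("ROC needs at least one positive and one negative score")
    fpr, tpr, thr = _roc_curve(y, s, drop_intermediate=False)
    return RocResult(
        points=list(zip(fpr.tolist(), tpr.tolist())),
        thresholds=thr,
        auroc=float(_auc(fpr, tpr)),
        class_label=class_label,
    )


@dataclass
class FoldRecord:
    """Training-side artifacts of one cross-validation fold."""

    fold: int
    train_indices: np.ndarray
    test_indices: np.ndarray
    dictionary: TextonDictionary
    sigma: float
    q_by_class: dict[str, float]
    train_freqs: np.ndarray


@dataclass
class CrossValResult:
    """Pooled one-vs-rest cross-validation outcome."""

    per_class: dict[str, RocResult]
    scores: pd.DataFrame
    fold_records: list[FoldRecord]
    classes: list[str]
    params: dict = field(default_factory=dict)

    def auroc(self, positive_class: str) -> float:
        return self.per_class[positive_class].auroc

    @property
    def mean_auroc(self) -> float:
        return float(np.mean([r.auroc for r in self.per_class.values()]))

    def restricted_auroc(self, positive_class: str, labels_subset) -> float:
        """AUROC of the pooled scores for ``positive_class`` restricted to
        test stacks whose true label is in ``labels_subset`` (e.g. a binary
        comparison between two morphologies)."""
        df = self.scores[self.scores.positive_class == positive_class]
        df = df[df.true_label.isin(list(labels_subset))]
        pairs = list(zip(df.score, df.true_label == positive_class))
        return roc_from_scores(pairs, class_label=positive_class).auroc


def _fold_seed(seed: int, fold: int) -> int:
    return int(np.random.SeedSequence([seed, fold]).generate_state(1)[0] % (2**31))


def _select_q(
    F: np.ndarray,
    labels: np.ndarray,
    classes,
    nn: int,
    q_grid,
    seed: int,
    inner_folds: int = 3,
) -> dict[str, float]:
    """Pick one q per class by inner cross-validation on the training fold."""
    default = {c: 7.0 for c in classes}
    counts = pd.Series(labels).value_counts()
    if counts.min() < inner_folds:
        return default
    D = pairwise_chi2(F)
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    pooled: dict[tuple[str, float], list[tuple[float, bool]]] = {
        (c, q): [] for c in classes for q in q_grid
    }
    for tr, te in skf.split(np.zeros(len(labels)), labels):
        if set(labels[tr]) != set(classes):
            return default
        sigma = fit_sigma(D[np.ix_(tr, tr)])
        for i in te:
            d = D[i, tr]
            for c in classes:
                for q in q_grid:
                    s = _ovr_score(d, labels[tr], c, sigma, min(nn, len(tr)), q)
                    pooled[(c, q)].append((s, labels[i] == c))
    chosen = {}
    for c in classes:
        best_q, best_a = None, -np.inf
        for q in q_grid:
            a = roc_from_scores(pooled[(c, q)]).auroc
            if a > best_a + 1e-12:
                best_q, best_a = float(q), a
        chosen[c] = best_q
    return chosen


def cross_validate(
    samples_per_stack,
    labels,
    folds: int = 10,
    seed: int = 0,
    K: int = 40,
    nn: int = 10,
    q="auto",
    q_grid=tuple(range(5, 11)),
    dict_algorithm: str = "minibatch",
    sources=None,
    groups=None,
) -> CrossValResult:
    """Stratified k-fold one-vs-rest evaluation with per-fold re-training.

    For every fold the texton dictionary, the training histogram library and
    the distance scale sigma are fitted on the training stacks only, so no
    held-out stack influences any training-side artifact.  Held-out scores
    are pooled across folds into one ROC per class.  ``q='auto'`` selects the
    positive-class weight per class by inner cross-validation on the training
    fold (sweeping ``q_grid``); a number fixes it globally.

    ``samples_per_stack`` holds one ``(n_vectors, n_channels)`` array per
    stack (the sampled block responses); everything is reproducible from
    ``seed``.  ``groups`` (e.g. patient identifiers) keeps all stacks of one
    group on the same side of every split, so per-patient correlation cannot
    inflate the evaluation; the default splits by stack.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if len(samples_per_stack) != n:
        raise ConsistencyError("samples_per_stack and labels length mismatch")
    if folds > n:
        raise ParameterError(f"cannot make {folds} folds from {n} stacks")
    classes = sorted(set(labels))
    if sources is None:
        sources = [f"stack_{i:03d}" for i in range(n)]
    if groups is not None:
        from sklearn.model_selection import StratifiedGroupKFold

        skf = StratifiedGroupKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = skf.split(np.zeros(n), labels, groups=np.asarray(groups))
    elif folds == n:  # leave-one-out: stratification is vacuous
        from sklearn.model_selection import KFold

        skf = KFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = skf.split(np.zeros(n))
    else:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = skf.split(np.zeros(n), labels)
    rows = []
    fold_records = []
    for f, (tr, te) in enumerate(splits):
        if set(labels[tr]) != set(classes):
            raise StratificationError(
                f"fold {f}: classes {set(classes) - set(labels[tr])} missing from training"
            )
        pooled = np.concatenate([np.asarray(samples_per_stack[i]) for i in tr], axis=0)
        dictionary = learn_dictionary(
            pooled, K=K, seed=_fold_seed(seed, f), algorithm=dict_algorithm
        )
        train_hists = [
            assign_and_histogram(samples_per_stack[i], dictionary, label=labels[i])
            for i in tr
        ]
        F_tr = np.asarray([h.freqs for h in train_hists])
        sigma = fit_sigma(F_tr)
        nn_f = min(nn, len(tr))
        if q == "auto":
            q_by_class = _select_q(F_tr, labels[tr], classes, nn_f, q_grid, _fold_seed(seed, 1000 + f))
        else:
            q_by_class = {c: float(q) for c in classes}
        for i in te:
            h = assign_and_histogram(samples_per_stack[i], dictionary)
            d = np.array([chi2_distance(h.freqs, ft) for ft in F_tr])
            for c in classes:
                s = _ovr_score(d, labels[tr], c, sigma, nn_f, q_by_class[c])
                rows.append(
                    dict(
                        stack_index=int(i),
                        source=sources[i],
                        true_label=labels[i],
                        fold=f,
                        positive_class=c,
                        score=s,
                    )
                )
        fold_records.append(
            FoldRecord(
                fold=f,
                train_indices=tr,
                test_indices=te,
                dictionary=dictionary,
                sigma=sigma,
                q_by_class=q_by_class,
                train_freqs=F_tr,
            )
        )
    scores = pd.DataFrame(rows)
    per_class = {}
    for c in classes:
        df = scores[scores.positive_class == c]
        per_class[c] = roc_from_scores(
            list(zip(df.score, df.true_label == c)), class_label=c
        )
    return CrossValResult(
        per_class=per_class,
        scores=scores,
        fold_records=fold_records,
        classes=classes,
        params=dict(folds=folds, seed=seed, K=K, nn=nn, q=q, dict_algorithm=dict_algorithm),
    )


def fit_model(
    samples_per_stack,
    labels,
    K: int = 40,
    seed: int = 0,
    nn: int = 10,
    q: float = 7.0,
    dict_algorithm: str = "lloyd",
    sources=None,
) -> TrainedModel:
    """Fit a deployable model (dictionary + library + sigma) on all stacks."""
    labels = np.asarray(labels)
    if sources is None:
        sources = [f"stack_{i:03d}" for i in range(len(labels))]
    pooled = np.concatenate([np.asarray(s) for s in samples_per_stack], axis=0)
    dictionary = learn_dictionary(pooled, K=K, seed=seed, algorithm=dict_algorithm)
    library = [
        assign_and_histogram(s, dictionary, label=l, source=src)
        for s, l, src in zip(samples_per_stack, labels, sources)
    ]
    sigma = fit_sigma(library)
    return TrainedModel(
        dictionary=dictionary,
        library=library,
        sigma=sigma,
        q=q,
        nn=min(nn, len(library)),
        classes=sorted(set(labels)),
    )
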