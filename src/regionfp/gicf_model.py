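"""Per-GO-term region scoring with a group-instance cost function (GICF).

Regions are instances, proteins are groups.  A logistic model scores each
region, a protein score is the maximum of its region scores, and the
trainable weight vector theta minimizes a four-term cost:

    J(theta) = (1/N_p)  sum_k (Yhat_k - Y_k)^2                     # protein fit
             + (w1/N_r^2) sum_i sum_j kappa(x_i, x_j) (yhat_i - yhat_j)^2
                                                                   # smoothness
             + (w2/N_r+) sum_{i in r+} (yhat_i - 1)^2              # known anchors
             + (lambda/N_p) ||theta||_2^2                          # ridge

where kappa is the thresholded cosine kernel between region feature
vectors, r+ is the (possibly empty) set of regions with known positive
labels, and the delta in every term is the square loss.  The max
aggregation is handled with a subgradient through the arg-max region
(ties to the lowest region index).  A constant intercept feature is
appended to every vector and excluded from the ridge penalty.

Training is minibatch stochastic gradient descent with momentum; a batch
is a set of whole proteins with all their regions, and every normalizer is
replaced by its in-batch counterpart so term magnitudes stay comparable.
The initial theta is seeded by an L2-regularized logistic regression on
whole-protein features, which doubles as the whole-protein baseline.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.linear_model import LogisticRegression

from .feature_space import FeatureMatrix, FeatureSpace, SimilarityKernel

logger = logging.getLogger(__name__)


@dataclass
class LabelSet:
    """Labels for one GO term: protein labels, region grouping, r+ anchors.

    ``protein_regions`` maps each protein accession to the row indices of
    its regions in the feature matrix; ``positive_regions`` holds row
    indices of regions with known positive labels (the r+ set).
    """

    protein_labels: dict[str, int]
    protein_regions: dict[str, list[int]]
    positive_regions: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if not self.protein_labels:
            raise ValueError("need at least one labelled protein")
        all_regions = {i for idxs in self.protein_regions.values() for i in idxs}
        if not all_regions:
            raise ValueError("need at least one region")
        if not set(self.positive_regions) <= all_regions:
            raise ValueError("positive_regions outside the region index set")
        if set(self.protein_regions) != set(self.protein_labels):
            raise ValueError("protein_labels and protein_regions disagree")

    @property
    def n_proteins(self) -> int:
        return len(self.protein_labels)

    @property
    def n_regions(self) -> int:
        return sum(len(v) for v in self.protein_regions.values())

    @property
    def n_positive_regions(self) -> int:
        return len(self.positive_regions)


@dataclass
class OptimizerConfig:
    """Minibatch SGD-with-momentum settings.

    ``learning_rate`` decays as lr / sqrt(epoch); ``pair_sample`` = 0 uses
    every in-batch region pair for the smoothness term, a positive value
    samples that many ordered pairs per batch.
    """

    learning_rate: float = 0.1
    momentum: float = 0.9
    batch_size: int = 32
    max_epochs: int = 200
    pair_sample: int = 0
    early_stop_patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0 <= self.momentum < 1):
            raise ValueError("momentum must be in [0, 1)")
        if min(self.batch_size, self.max_epochs) < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


@dataclass
class GICFModel:
    """Per-GO-term weight vector plus hyperparameters.

    ``theta`` has one entry per vocabulary feature plus a trailing
    intercept (excluded from the ridge penalty).
    """

    go_id: str
    space: FeatureSpace
    theta: np.ndarray
    w1: float = 1.0
    w2: float = 1.0
    lam: float = 1.0
    vocabulary_hash: str = ""
    loss_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, v in (("w1", self.w1), ("w2", self.w2), ("lam", self.lam)):
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        self.theta = np.asarray(self.theta, dtype=float)


def stable_sigmoid(z: np.ndarray | float) -> np.ndarray | float:
    """Numerically stable logistic function."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out if out.ndim else float(out)


def add_intercept(X: sp.spmatrix | np.ndarray) -> sp.csr_matrix:
    """Append a constant-1 column (the intercept feature)."""
    X = sp.csr_matrix(X)
    ones = np.ones((X.shape[0], 1))
    return sp.csr_matrix(sp.hstack([X, ones]))


def score_region(theta: np.ndarray, x: np.ndarray | sp.spmatrix) -> float:
    """Logistic score of one region: sigmoid(theta . x)."""
    x = np.asarray(x.todense()).ravel() if sp.issparse(x) else np.asarray(x).ravel()
    if x.shape[0] != theta.shape[0]:
        raise ValueError(
            f"dimension mismatch: theta {theta.shape[0]}, x {x.shape[0]}"
        )
    return float(stable_sigmoid(float(theta @ x)))


def score_regions(theta: np.ndarray, X: sp.csr_matrix) -> np.ndarray:
    if X.shape[1] != theta.shape[0]:
        raise ValueError(
            f"dimension mismatch: theta {theta.shape[0]}, X {X.shape[1]}"
        )
    return np.asarray(stable_sigmoid(X @ theta))


def aggregate_protein(region_scores: Sequence[float]) -> float:
    """Protein score = max over its region scores."""
    if len(region_scores) == 0:
        raise ValueError("protein with no region scores")
    return float(max(region_scores))


def _terms(
    theta: np.ndarray,
    X: sp.csr_matrix,
    kernel_values: sp.csr_matrix | None,
    labels: LabelSet,
    w1: float,
    w2: float,
    lam: float,
) -> tuple[float, float, float, float, np.ndarray, dict[str, int]]:
    """Shared forward pass: the four cost terms, region scores, argmaxes."""
    yhat = score_regions(theta, X)
    n_p, n_r, n_rp = labels.n_proteins, labels.n_regions, labels.n_positive_regions

    term1 = 0.0
    argmax: dict[str, int] = {}
    for acc, idxs in labels.protein_regions.items():
        scores = yhat[idxs]
        a = int(np.argmax(scores))  # first max: ties to lowest region index
        argmax[acc] = idxs[a]
        term1 += (scores[a] - labels.protein_labels[acc]) ** 2
    term1 /= n_p

    term2 = 0.0
    if w1 > 0 and kernel_values is not None:
        K = kernel_values.tocoo()
        diffs = (yhat[K.row] - yhat[K.col]) ** 2
        term2 = float(w1 * np.sum(K.data * diffs, dtype=np.longdouble) / n_r**2)

    term3 = 0.0
    if n_rp > 0 and w2 > 0:
        pos = np.fromiter(labels.positive_regions, dtype=int)
        term3 = float(w2 * np.sum((yhat[pos] - 1.0) ** 2) / n_rp)

    term4 = float(lam * np.sum(theta[:-1] ** 2) / n_p)
    return term1, term2, term3, term4, yhat, argmax


def cost(
    model: GICFModel,
    X: sp.csr_matrix,
    kernel: SimilarityKernel | None,
    labels: LabelSet,
) -> float:
    """Evaluate the four-term cost J(theta) on the full data."""
    _check_index_sets(X, labels)
    kv = kernel.values if kernel is not None else None
    t1, t2, t3, t4, _, _ = _terms(
        model.theta, X, kv, labels, model.w1, model.w2, model.lam
    )
    return t1 + t2 + t3 + t4


def _check_index_sets(X: sp.csr_matrix, labels: LabelSet) -> None:
    all_idx = sorted(i for v in labels.protein_regions.values() for i in v)
    if all_idx and (all_idx[0] < 0 or all_idx[-1] >= X.shape[0]):
        raise ValueError("region indices outside the feature matrix")


def gradient(
    model: GICFModel,
    X: sp.csr_matrix,
    kernel: SimilarityKernel | None,
    labels: LabelSet,
    batch: Sequence[str] | None = None,
    pair_sample: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Analytic gradient dJ/dtheta.

    With ``batch`` given, every normalizer (N_p, N_r^2, N_r+) is the
    in-batch count, and the smoothness term may be estimated from
    ``pair_sample`` random ordered in-batch pairs instead of all pairs.
    The max aggregation contributes only through the arg-max region of
    each protein (ties to the lowest region index).
    """
    if batch is None:
        batch = list(labels.protein_labels)
    batch_regions = [i for acc in batch for i in labels.protein_regions[acc]]
    sub = LabelSet(
        protein_labels={a: labels.protein_labels[a] for a in batch},
        protein_regions={a: labels.protein_regions[a] for a in batch},
        positive_regions=frozenset(
            i for i in labels.positive_regions if i in set(batch_regions)
        ),
    )
    theta = model.theta
    yhat = score_regions(theta, X)
    g = yhat * (1.0 - yhat)  # d sigmoid / d z
    n_p, n_r, n_rp = sub.n_proteins, sub.n_regions, sub.n_positive_regions
    grad = np.zeros_like(theta)

    # term 1: subgradient through each protein's argmax region
    for acc in batch:
        idxs = sub.protein_regions[acc]
        scores = yhat[idxs]
        a = idxs[int(np.argmax(scores))]
        coeff = 2.0 * (yhat[a] - sub.protein_labels[acc]) * g[a] / n_p
        grad += coeff * np.asarray(X[a].todense()).ravel()

    # term 2: 4 w1 / N_r^2 * sum_i [sum_j kappa_ij (yhat_i - yhat_j)] g_i x_i
    if model.w1 > 0 and kernel is not None:
        K = kernel.values[np.ix_(batch_regions, batch_regions)].tocsr()
        yb = yhat[batch_regions]
        gb = g[batch_regions]
        Xb = X[batch_regions]
        if pair_sample and rng is not None and len(batch_regions) > 1:
            # unbiased pair-sampled estimate of the all-pairs average
            nb = len(batch_regions)
            ii = rng.integers(0, nb, size=pair_sample)
            jj = rng.integers(0, nb, size=pair_sample)
            kij = np.asarray(K[ii, jj]).ravel()
            d = yb[ii] - yb[jj]
            coeff_i = 2.0 * model.w1 * kij * d * gb[ii] / pair_sample
            coeff_j = -2.0 * model.w1 * kij * d * gb[jj] / pair_sample
            grad += np.asarray(
                (sp.csr_matrix(coeff_i) @ Xb[ii]).todense()
            ).ravel()
            grad += np.asarray(
                (sp.csr_matrix(coeff_j) @ Xb[jj]).todense()
            ).ravel()
        else:
            s = yb * np.asarray(K.sum(axis=1)).ravel() - K @ yb
            coeff = 4.0 * model.w1 * s * gb / n_r**2
            grad += np.asarray((sp.csr_matrix(coeff) @ Xb).todense()).ravel()

    # term 3: anchors
    if n_rp > 0 and model.w2 > 0:
        for i in sub.positive_regions:
            coeff = 2.0 * model.w2 * (yhat[i] - 1.0) * g[i] / n_rp
            grad += coeff * np.asarray(X[i].todense()).ravel()

    # term 4: ridge, intercept excluded
    ridge = 2.0 * model.lam / n_p * theta
    ridge[-1] = 0.0
    return grad + ridge


def seed_theta(
    protein_matrix: FeatureMatrix,
    protein_labels: Mapping[str, int],
    lam_grid: Sequence[float] = (0.1, 1.0, 10.0, 100.0),
    validation: tuple[sp.csr_matrix, np.ndarray] | None = None,
) -> tuple[np.ndarray, float]:
    """Whole-protein logistic regression: seed theta and baseline weights.

    Fits an L2-regularized logistic regression on whole-protein TF-IDF
    vectors for each ridge weight in ``lam_grid`` and keeps the one with
    the best AUPR on ``validation`` (training AUPR when no validation set
    is given).  Returns ``(theta0, best_lam)`` where ``theta0`` carries a
    trailing intercept and aligns with the region vocabulary, so it doubles
    as the whole-protein baseline model.
    """
    from .evaluation import aupr  # local import to avoid a cycle

    y = np.array([protein_labels[acc] for acc in protein_matrix.item_ids])
    if len(np.unique(y)) < 2:
        raise ValueError("seed_theta needs both a positive and a negative protein")
    X = protein_matrix.weights
    best: tuple[float, np.ndarray, float] | None = None
    for lam in lam_grid:
        clf = LogisticRegression(C=1.0 / lam, solver="lbfgs", max_iter=1000)
        clf.fit(X, y)
        theta = np.concatenate([clf.coef_.ravel(), clf.intercept_])
        if validation is not None:
            Xv, yv = validation
            scores = np.asarray(stable_sigmoid(add_intercept(Xv) @ theta))
        else:
            scores = np.asarray(stable_sigmoid(add_intercept(X) @ theta))
            yv = y
        score = aupr(scores, yv)
        if best is None or score > best[0]:
            best = (score, theta, lam)
    assert best is not None
    return best[1], best[2]


@dataclass
class FitResult:
    model: GICFModel
    loss_trace: list[float]
    validation_trace: list[float]
    best_epoch: int


def fit(
    model: GICFModel,
    X: sp.csr_matrix,
    kernel: SimilarityKernel | None,
    labels: LabelSet,
    config: OptimizerConfig,
    validation: tuple[sp.csr_matrix, LabelSet] | None = None,
) -> FitResult:
    """Train theta by minibatch SGD with momentum.

    Keeps the theta with the best validation protein-level AUPR (training
    AUPR when no validation split is given) and stops after
    ``early_stop_patience`` epochs without improvement.  Raises on
    divergence (non-finite cost), naming the epoch and learning rate.
    """
    from .evaluation import aupr

    _check_index_sets(X, labels)
    rng = np.random.default_rng(config.seed)
    theta = model.theta.copy()
    velocity = np.zeros_like(theta)
    proteins = sorted(labels.protein_labels)
    trace: list[float] = []
    val_trace: list[float] = []
    best_theta, best_val, best_epoch, stale = theta.copy(), -np.inf, 0, 0

    def protein_aupr(th: np.ndarray, Xe: sp.csr_matrix, le: LabelSet) -> float:
        scores = score_regions(th, Xe)
        accs = sorted(le.protein_labels)
        agg = np.array([
            aggregate_protein(scores[le.protein_regions[a]]) for a in accs
        ])
        truth = np.array([le.protein_labels[a] for a in accs])
        if len(np.unique(truth)) < 2:
            return float("nan")
        return aupr(agg, truth)

    for epoch in range(1, config.max_epochs + 1):
        lr = config.learning_rate / np.sqrt(epoch)
        order = rng.permutation(len(proteins))
        for lo in range(0, len(proteins), config.batch_size):
            batch = [proteins[i] for i in order[lo : lo + config.batch_size]]
            work = GICFModel(
                model.go_id, model.space, theta, model.w1, model.w2, model.lam
            )
            grad = gradient(
                work, X, kernel, labels, batch=batch,
                pair_sample=config.pair_sample, rng=rng,
            )
            velocity = config.momentum * velocity - lr * grad
            theta = theta + velocity
        work = GICFModel(
            model.go_id, model.space, theta, model.w1, model.w2, model.lam
        )
        j = cost(work, X, kernel, labels)
        if not np.isfinite(j):
            raise FloatingPointError(
                f"training diverged at epoch {epoch} "
                f"(learning rate {lr:.4g}): J = {j}"
            )
        trace.append(j)
        if validation is not None:
            v = protein_aupr(theta, *validation)
        else:
            v = protein_aupr(theta, X, labels)
        val_trace.append(v)
        if np.isnan(v):
            v = -j  # fall back to cost when validation has a single class
        if v > best_val + 1e-12:
            best_val, best_theta, best_epoch, stale = v, theta.copy(), epoch, 0
        else:
            stale += 1
            if stale >= config.early_stop_patience:
                break

    fitted = GICFModel(
        go_id=model.go_id, space=model.space, theta=best_theta,
        w1=model.w1, w2=model.w2, lam=model.lam,
        vocabulary_hash=model.vocabulary_hash, loss_trace=trace,
    )
    return FitResult(fitted, trace, val_trace, best_epoch)


def predict(
    model: GICFModel,
    X: sp.csr_matrix,
    labels_or_grouping: LabelSet | Mapping[str, list[int]] | None = None,
    aggregate: bool = False,
):
    """Region scores, optionally max-aggregated to protein scores."""
    yhat = score_regions(model.theta, X)
    if not aggregate:
        return yhat
    grouping = (
        labels_or_grouping.protein_regions
        if isinstance(labels_or_grouping, LabelSet)
        else labels_or_grouping
    )
    if grouping is None:
        raise ValueError("aggregation needs the protein->regions grouping")
    return {acc: aggregate_protein(yhat[idxs]) for acc, idxs in grouping.items()}


def vocabulary_hash(vocabulary: Sequence[str]) -> str:
    return hashlib.sha256("\n".join(vocabulary).encode()).hexdigest()[:16]


def save_model(
    model: GICFModel, config: OptimizerConfig, path: str | Path
) -> None:
    """Serialize a trained model as a versioned JSON archive."""
    payload = {
        "format_version": 1,
        "go_id": model.go_id,
        "space": model.space.value,
        "vocabulary_hash": model.vocabulary_hash,
        "theta": model.theta.tolist(),
        "hyperparameters": {"w1": model.w1, "w2": model.w2, "lam": model.lam},
        "optimizer": asdict(config),
        "loss_trace": model.loss_trace,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> tuple[GICFModel, OptimizerConfig]:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != 1:
        raise ValueError(f"unsupported model archive version in {path}")
    hp = payload["hyperparameters"]
    model = GICFModel(
        go_id=payload["go_id"],
        space=FeatureSpace(payload["space"]),
        theta=np.array(payload["theta"]),
        w1=hp["w1"], w2=hp["w2"], lam=hp["lam"],
        vocabulary_hash=payload["vocabulary_hash"],
        loss_trace=payload["loss_trace"],
    )
    return model, OptimizerConfig(**payload["optimizer"])
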