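"""Ensemble pattern-network classifier with Levenberg–Marquardt training.

A single hidden layer of logistic-sigmoid units feeds two sigmoid output
units scored against one-hot targets by mean squared error, the classical
"pattern recognition" network for small tabular problems.  Training uses
Levenberg–Marquardt: each step solves

    (JᵀJ + λI) Δw = −Jᵀr

where r stacks the per-sample, per-output residuals and J is their Jacobian
in the weights.  Steps that reduce the training MSE are accepted (λ shrinks);
rejected steps grow λ and retry, interpolating between Gauss–Newton and
gradient descent.  Early stopping monitors a held-out validation partition.

Because per-tissue cohorts are small (tens of mice), a single train/test
split is noisy; the ensemble estimator repeats R random 70/15/15
train/validation/test splits, trains a freshly initialized network per
replicate, scores the test partition, and averages accuracy, sensitivity
(immunized = positive class) and specificity across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from immunosig.errors import DegenerateLabelError, TooFewSamplesError
from immunosig.panels import StandardizedMatrix


@dataclass
class NetworkSpec:
    n_inputs: int
    n_hidden: int = 12
    n_outputs: int = 2

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.n_outputs != 2:
            raise ValueError("the pattern network has exactly 2 output units")


@dataclass
class Network:
    spec: NetworkSpec
    W1: np.ndarray  # (n_hidden, n_inputs + 1), last column = bias
    W2: np.ndarray  # (n_outputs, n_hidden + 1)
    init_seed: int = 0


@dataclass
class TrainOptions:
    lambda0: float = 1e-3
    lambda_up: float = 10.0
    lambda_down: float = 0.1
    max_epochs: int = 100
    max_val_failures: int = 6
    grad_tol: float = 1e-7
    lambda_max: float = 1e10

    def __post_init__(self) -> None:
        if not (self.lambda_up > 1.0 > self.lambda_down > 0.0):
            raise ValueError("need lambda_up > 1 > lambda_down > 0")


@dataclass
class Partition:
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray


@dataclass
class ConfusionCounts:
    """Counts with immunized (label 1) as the positive class."""

    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.FP + other.FP,
                               self.TN + other.TN, self.FN + other.FN)

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @property
    def accuracy(self) -> float:
        return (self.TP + self.TN) / self.total


@dataclass
class ReplicateRecord:
    replicate: int
    seed: int
    n_train: int
    n_validation: int
    n_test: int
    confusion: ConfusionCounts
    epochs: int
    stop_reason: str


@dataclass
class EnsembleReport:
    tissue: str
    subset: str  # "all" | "F" | "M"
    R: int
    accuracy_mean: float
    accuracy_sd: float
    sensitivity_mean: float
    sensitivity_sd: float
    specificity_mean: float
    specificity_sd: float
    n_undefined_sensitivity: int
    n_undefined_specificity: int
    replicates: list[ReplicateRecord] = field(default_factory=list)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def init_network(spec: NetworkSpec, seed: int = 0) -> Network:
    """Scaled-uniform initialization: U[-0.5, 0.5] / sqrt(fan-in)."""
    rng = np.random.default_rng(seed)
    W1 = rng.uniform(-0.5, 0.5, (spec.n_hidden, spec.n_inputs + 1)) / np.sqrt(spec.n_inputs + 1)
    W2 = rng.uniform(-0.5, 0.5, (spec.n_outputs, spec.n_hidden + 1)) / np.sqrt(spec.n_hidden + 1)
    return Network(spec=spec, W1=W1, W2=W2, init_seed=seed)


def forward(net: Network, X: np.ndarray) -> np.ndarray:
    """Row-wise network outputs in (0,1)^(n×2)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != net.spec.n_inputs:
        raise ValueError(f"expected {net.spec.n_inputs} inputs, got {X.shape[1]}")
    A = np.hstack([X, np.ones((X.shape[0], 1))])
    H = _sigmoid(A @ net.W1.T)
    Hb = np.hstack([H, np.ones((H.shape[0], 1))])
    return _sigmoid(Hb @ net.W2.T)


def predict(net: Network, X: np.ndarray) -> np.ndarray:
    """Predicted class per row; ties go to class 0 (control)."""
    Y = forward(net, X)
    return (Y[:, 1] > Y[:, 0]).astype(int)


def _pack(net: Network) -> np.ndarray:
    return np.concatenate([net.W1.ravel(), net.W2.ravel()])


def _unpack(net: Network, w: np.ndarray) -> None:
    s = net.spec
    n1 = s.n_hidden * (s.n_inputs + 1)
    net.W1 = w[:n1].reshape(s.n_hidden, s.n_inputs + 1)
    net.W2 = w[n1:].reshape(s.n_outputs, s.n_hidden + 1)


def _residuals_jacobian(net: Network, X: np.ndarray, T: np.ndarray):
    """Residual vector r = vec(Y − T) and its Jacobian in the packed weights.

    Residuals are ordered sample-major: (sample 0 output 0, sample 0 output
    1, sample 1 output 0, ...).  Derivatives follow the chain through the
    two sigmoid layers; the derivative of the logistic function is y(1−y).
    """
    n = X.shape[0]
    s = net.spec
    A = np.hstack([X, np.ones((n, 1))])  # (n, I+1)
    Z1 = A @ net.W1.T
    H = _sigmoid(Z1)  # (n, Hd)
    Hb = np.hstack([H, np.ones((n, 1))])  # (n, Hd+1)
    Y = _sigmoid(Hb @ net.W2.T)  # (n, 2)
    R = Y - T

    S2 = Y * (1.0 - Y)  # dY/dZ2, (n, 2)
    S1 = H * (1.0 - H)  # dH/dZ1, (n, Hd)

    # dY[i,k]/dW1[j,l] = S2[i,k] * W2[k,j] * S1[i,j] * A[i,l]
    J1 = np.einsum("ik,kj,ij,il->ikjl", S2, net.W2[:, : s.n_hidden], S1, A)
    J1 = J1.reshape(n * s.n_outputs, s.n_hidden * (s.n_inputs + 1))
    # dY[i,k]/dW2[k,j] = S2[i,k] * Hb[i,j]  (zero for the other output unit)
    J2 = np.zeros((n, s.n_outputs, s.n_outputs, s.n_hidden + 1))
    for k in range(s.n_outputs):
        J2[:, k, k, :] = S2[:, k][:, None] * Hb
    J2 = J2.reshape(n * s.n_outputs, s.n_outputs * (s.n_hidden + 1))

    return R.ravel(), np.hstack([J1, J2])


def _mse(net: Network, X: np.ndarray, T: np.ndarray) -> float:
    R = forward(net, X) - T
    return float(np.mean(R * R))


def one_hot(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    T = np.zeros((labels.size, 2))
    T[np.arange(labels.size), labels] = 1.0
    return T


def train_lm(net: Network, train_set: tuple[np.ndarray, np.ndarray],
             val_set: tuple[np.ndarray, np.ndarray],
             opts: Optional[TrainOptions] = None,
             trace: Optional[list] = None) -> tuple[Network, int, str]:
    """Levenberg–Marquardt training with validation-based early stopping.

    Returns the network with the best validation MSE seen, the number of
    epochs run, and the stop reason (one of ``max_epochs``, ``grad_tol``,
    ``lambda_max``, ``val_failures``, ``zero_budget``).  When ``trace`` is
    a list, the training MSE after every accepted step is appended to it
    (accepted steps form a strictly decreasing sequence by construction).
    """
    opts = opts or TrainOptions()
    Xtr, Ttr = train_set
    Xval, Tval = val_set
    if Xtr.shape[0] == 0 or Xval.shape[0] == 0:
        raise ValueError("train and validation sets must be non-empty")

    w = _pack(net)
    lam = opts.lambda0
    train_mse = _mse(net, Xtr, Ttr)
    if trace is not None:
        trace.append(train_mse)
    best_val = _mse(net, Xval, Tval)
    best_w = w.copy()
    val_failures = 0
    prev_val = best_val
    stop = "zero_budget" if opts.max_epochs == 0 else "max_epochs"

    epoch = 0
    while epoch < opts.max_epochs:
        epoch += 1
        r, J = _residuals_jacobian(net, Xtr, Ttr)
        g = J.T @ r
        if np.linalg.norm(g, ord=np.inf) < opts.grad_tol:
            stop = "grad_tol"
            epoch -= 1
            break
        JtJ = J.T @ J
        eye = np.eye(JtJ.shape[0])
        accepted = False
        while lam <= opts.lambda_max:
            try:
                dw = np.linalg.solve(JtJ + lam * eye, -g)
            except np.linalg.LinAlgError:
                lam *= opts.lambda_up
                continue
            _unpack(net, w + dw)
            new_mse = _mse(net, Xtr, Ttr)
            if new_mse < train_mse:
                w = w + dw
                train_mse = new_mse
                if trace is not None:
                    trace.append(train_mse)
                lam = max(lam * opts.lambda_down, np.finfo(float).tiny)
                accepted = True
                break
            lam *= opts.lambda_up
        if not accepted:
            _unpack(net, w)
            stop = "lambda_max"
            break

        val_mse = _mse(net, Xval, Tval)
        if val_mse < best_val:
            best_val = val_mse
            best_w = w.copy()
        if val_mse > prev_val:
            val_failures += 1
            if val_failures >= opts.max_val_failures:
                stop = "val_failures"
                break
        else:
            val_failures = 0
        prev_val = val_mse

    _unpack(net, best_w if stop != "zero_budget" else w)
    return net, epoch, stop


def split_samples(n: int, seed: int) -> Partition:
    """Random 70/15/15 partition: test and validation get max(1, floor(0.15 n))."""
    if n < 7:
        raise TooFewSamplesError(f"need at least 7 samples for a 70/15/15 split, got {n}")
    n_test = max(1, int(np.floor(0.15 * n)))
    n_val = max(1, int(np.floor(0.15 * n)))
    order = np.random.default_rng(seed).permutation(n)
    return Partition(
        test=np.sort(order[:n_test]),
        validation=np.sort(order[n_test : n_test + n_val]),
        train=np.sort(order[n_test + n_val :]),
    )


def confusion_from_labels(true: np.ndarray, pred: np.ndarray) -> ConfusionCounts:
    true = np.asarray(true, dtype=int)
    pred = np.asarray(pred, dtype=int)
    return ConfusionCounts(
        TP=int(np.sum((true == 1) & (pred == 1))),
        FP=int(np.sum((true == 0) & (pred == 1))),
        TN=int(np.sum((true == 0) & (pred == 0))),
        FN=int(np.sum((true == 1) & (pred == 0))),
    )


def sensitivity(cc: ConfusionCounts) -> float:
    """TP / (TP + FN); NaN (undefined) when no positives were scored."""
    denom = cc.TP + cc.FN
    return cc.TP / denom if denom else float("nan")


def specificity(cc: ConfusionCounts) -> float:
    """TN / (TN + FP); NaN (undefined) when no negatives were scored."""
    denom = cc.TN + cc.FP
    return cc.TN / denom if denom else float("nan")


def _nan_stats(values: np.ndarray) -> tuple[float, float, int]:
    defined = values[~np.isnan(values)]
    if defined.size == 0:
        return float("nan"), float("nan"), values.size
    sd = float(defined.std(ddof=1)) if defined.size > 1 else 0.0
    return float(defined.mean()), sd, int(values.size - defined.size)


def run_ensemble(matrix: StandardizedMatrix, opts: Optional[TrainOptions] = None,
                 R: int = 2000, subset: str = "all", seed: int = 0,
                 n_hidden: Optional[int] = None, score_all: bool = False,
                 stratified: bool = False,
                 keep_replicates: bool = False) -> EnsembleReport:
    """Average test accuracy / sensitivity / specificity over R replicates.

    ``subset`` restricts rows to one sex; ``score_all`` scores every sample
    instead of the test partition only (sensitivity analysis); replicates
    whose test partition lacks a class contribute no value to the
    corresponding metric and are counted as undefined.
    """
    opts = opts or TrainOptions()
    if subset not in ("all", "F", "M"):
        raise ValueError("subset must be 'all', 'F' or 'M'")
    work = matrix if subset == "all" else matrix.subset(matrix.sex == subset)
    X, y = work.values, work.labels
    n = X.shape[0]
    if n < 7:
        raise TooFewSamplesError(f"subset {subset!r} leaves only {n} rows")
    if len(np.unique(y)) < 2:
        raise DegenerateLabelError(f"subset {subset!r} contains a single class")

    if n_hidden is None:
        n_hidden = 8 if matrix.tissue == "THY" else 12
    spec = NetworkSpec(n_inputs=X.shape[1], n_hidden=n_hidden)
    T = one_hot(y)

    root = np.random.SeedSequence(seed)
    acc = np.empty(R)
    sens = np.empty(R)
    spc = np.empty(R)
    records: list[ReplicateRecord] = []
    for r_idx, child in enumerate(root.spawn(R)):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        part = _split(n, y, rep_seed, stratified)
        net = init_network(spec, seed=rep_seed)
        net, epochs, stop = train_lm(
            net, (X[part.train], T[part.train]),
            (X[part.validation], T[part.validation]), opts,
        )
        score_idx = np.arange(n) if score_all else part.test
        cc = confusion_from_labels(y[score_idx], predict(net, X[score_idx]))
        acc[r_idx] = cc.accuracy
        sens[r_idx] = sensitivity(cc)
        spc[r_idx] = specificity(cc)
        if keep_replicates:
            records.append(ReplicateRecord(r_idx, rep_seed, part.train.size,
                                           part.validation.size, part.test.size,
                                           cc, epochs, stop))

    acc_m, acc_sd, _ = _nan_stats(acc)
    sen_m, sen_sd, sen_nan = _nan_stats(sens)
    spe_m, spe_sd, spe_nan = _nan_stats(spc)
    return EnsembleReport(
        tissue=matrix.tissue, subset=subset, R=R,
        accuracy_mean=acc_m, accuracy_sd=acc_sd,
        sensitivity_mean=sen_m, sensitivity_sd=sen_sd,
        specificity_mean=spe_m, specificity_sd=spe_sd,
        n_undefined_sensitivity=sen_nan, n_undefined_specificity=spe_nan,
        replicates=records,
    )


def _split(n: int, y: np.ndarray, seed: int, stratified: bool) -> Partition:
    if not stratified:
        return split_samples(n, seed)
    # per-class 70/15/15, recombined — keeps both classes in every part when
    # each class has >= 7 members
    rng = np.random.default_rng(seed)
    parts = {"train": [], "validation": [], "test": []}
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size < 7:
            return split_samples(n, seed)
        sub = split_samples(idx.size, int(rng.integers(2**31)))
        parts["train"].append(idx[sub.train])
        parts["validation"].append(idx[sub.validation])
        parts["test"].append(idx[sub.test])
    return Partition(train=np.sort(np.concatenate(parts["train"])),
                     validation=np.sort(np.concatenate(parts["validation"])),
                     test=np.sort(np.concatenate(parts["test"])))


def select_hidden_size(X: np.ndarray, labels: np.ndarray,
                       grid: tuple[int, ...] = (4, 8, 12, 16),
                       k_values: tuple[int, ...] = (3, 4, 5),
                       seed: int = 0,
                       opts: Optional[TrainOptions] = None) -> int:
    """Pick the hidden-layer size by k-fold cross-validation.

    For every candidate size and every k the mean fold misclassification
    rate is computed over seeded folds; the candidate minimizing the mean
    across all k values wins, ties going to the smaller network.
    """
    opts = opts or TrainOptions()
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = X.shape[0]
    if n < max(k_values):
        raise TooFewSamplesError(f"{n} rows cannot support {max(k_values)}-fold CV")
    if len(np.unique(labels)) < 2:
        raise DegenerateLabelError("constant labels: cross-validation is meaningless")
    T = one_hot(labels)

    root = np.random.SeedSequence(seed)
    scores = {h: [] for h in grid}
    for h in grid:
        for k in k_values:
            fold_seed = int(root.spawn(1)[0].generate_state(1)[0] % (2**31))
            order = np.random.default_rng(fold_seed).permutation(n)
            folds = np.array_split(order, k)
            errs = []
            for f, test_idx in enumerate(folds):
                train_idx = np.concatenate([folds[j] for j in range(k) if j != f])
                net = init_network(NetworkSpec(X.shape[1], h), seed=fold_seed + f)
                # the fold's held-out part doubles as the early-stopping monitor
                net, _, _ = train_lm(net, (X[train_idx], T[train_idx]),
                                     (X[test_idx], T[test_idx]), opts)
                errs.append(float(np.mean(predict(net, X[test_idx]) != labels[test_idx])))
            scores[h].append(float(np.mean(errs)))

    means = {h: float(np.mean(v)) for h, v in scores.items()}
    best = min(means.values())
    return min(h for h, m in means.items() if m == best)
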