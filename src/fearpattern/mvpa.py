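"""Multivoxel decoding with imbalanced-class cross-validation and permutation chance.

The analysis discriminates the two members of a sound pair from trial-wise
voxel patterns with a linear support-vector classifier, in each task condition
(context x complexity) separately.  Because half of the CS+ trials are
reinforced and discarded, the retained reinforcement-context trials are
imbalanced (twice as many CS- as CS+); fold construction assigns the i-th
chronological occurrence of each stimulus to the test set of fold i mod 3, so
training and test data are drawn from the entire experiment.  Under such
imbalance the chance level of the classifier is not 1/2, so it is estimated
empirically by re-running the identical procedure under random label
permutations; the reported quantity is the excess of the true-label accuracy
over that permutation mean.  Neutral-sound conditions, which have no
discarded trials, are randomly subsampled to the same class counts before
decoding, averaging over repetitions of the subsampling.

Cross-decoding trains on all retained CS trials of one complexity and tests
on the other, probing whether the CS+/CS- separation generalises across
stimulus families; the neutral-sound control matches labels across
complexity by the required key press.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import TrialBetaMatrix

__all__ = [
    "ClassifierSpec",
    "FoldSpec",
    "DecodingResult",
    "CrossDecodingResult",
    "zscore_across_trials",
    "make_running_index_folds",
    "decode_condition",
    "subsample_ns",
    "permutation_chance",
    "excess_accuracy",
    "evaluate_condition",
    "cross_decode",
    "decode_participant",
    "cross_decode_participant",
]

try:  # fast direct binding; the public SVC wrapper is the reference engine
    from sklearn.svm import _libsvm as _fast_libsvm

    _fast_libsvm.set_verbosity_wrap(0)
except Exception:  # pragma: no cover - depends on sklearn internals
    _fast_libsvm = None


@dataclass(frozen=True)
class ClassifierSpec:
    """Linear-kernel support-vector classifier, cost parameter C, no class weights.

    ``engine`` selects the implementation: "libsvm" calls the libsvm solver
    directly (fast, used by default); "sklearn" goes through the public
    ``sklearn.svm.SVC`` wrapper.  Both produce identical decision values.
    """

    C: float = 1.0
    engine: str = "libsvm"

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.engine not in ("libsvm", "sklearn"):
            raise ValueError("engine must be 'libsvm' or 'sklearn'")


@dataclass(frozen=True)
class FoldSpec:
    """One cross-validation fold: disjoint train and test trial indices."""

    fold: int
    train: np.ndarray
    test: np.ndarray


@dataclass
class DecodingResult:
    """Per-condition decoding outcome with its empirical chance level."""

    participant: str | None
    context: str
    complexity: str
    hemisphere: str | None
    raw_accuracy: float
    chance_mean: float
    chance_sd: float
    excess_accuracy: float
    null_distribution: np.ndarray | None = None


@dataclass
class CrossDecodingResult:
    """Cross-complexity transfer outcome for one direction and stimulus class."""

    participant: str | None
    stimulus_class: str  # "CS" or "NS"
    direction: str  # "simple_to_complex" or "complex_to_simple"
    hemisphere: str | None
    raw_accuracy: float
    chance_mean: float
    chance_sd: float
    excess_accuracy: float
    null_distribution: np.ndarray | None = None


# ---------------------------------------------------------------------------
# classifier core


def _fit_decision(
    Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray, spec: ClassifierSpec
) -> np.ndarray:
    """Decision values for the test rows; positive values favour class 1.

    Training rows are put into a canonical order (label, then feature values)
    before fitting, so the solution is a function of the training multiset
    only.  libsvm's finite termination tolerance makes its solution weakly
    order-dependent; without canonicalisation that order dependence is
    systematically different for design-ordered true labels than for permuted
    labels, biasing excess accuracy away from zero under the null.
    """
    order = np.lexsort(tuple(Xtr.T[::-1]) + (ytr,))
    Xtr = Xtr[order]
    ytr = ytr[order]
    if spec.engine == "libsvm" and _fast_libsvm is not None:
        out = _fast_libsvm.fit(
            np.ascontiguousarray(Xtr, dtype=np.float64),
            np.ascontiguousarray(ytr, dtype=np.float64),
            svm_type=0,
            kernel="linear",
            C=spec.C,
        )
        w = (out[3] @ out[1]).ravel()
        return -(Xte @ w + out[4][0])
    from sklearn.svm import SVC

    clf = SVC(kernel="linear", C=spec.C)
    clf.fit(Xtr, ytr)
    return clf.decision_function(Xte)


def _predict01(dec: np.ndarray, ytr: np.ndarray) -> np.ndarray:
    """Threshold decision values; exact ties go to the training-majority class."""
    pred = (dec > 0).astype(float)
    ties = dec == 0
    if np.any(ties):
        majority = 1.0 if np.mean(ytr) > 0.5 else 0.0
        pred[ties] = majority
    return pred


def _running_fold_ids(y01: np.ndarray, n_folds: int = 3) -> np.ndarray:
    """Fold id per trial: i-th chronological trial of each class -> i mod n_folds."""
    y01 = np.asarray(y01)
    fold_id = np.empty(len(y01), dtype=np.intp)
    for cls in (0.0, 1.0):
        idx = np.flatnonzero(y01 == cls)
        if len(idx) < n_folds:
            raise ValueError(
                f"need at least {n_folds} trials per stimulus, got {len(idx)}"
            )
        fold_id[idx] = np.arange(len(idx)) % n_folds
    return fold_id


def _pooled_cv_accuracy(X: np.ndarray, y01: np.ndarray, spec: ClassifierSpec) -> float:
    """Pooled accuracy over the three running-index folds (fast numeric path)."""
    fold_id = _running_fold_ids(y01)
    correct = 0
    for f in range(3):
        te = fold_id == f
        tr = ~te
        ytr = y01[tr]
        if ytr.min() == ytr.max():
            raise ValueError(f"fold {f} has single-class training data")
        dec = _fit_decision(X[tr], ytr, X[te], spec)
        correct += int(np.sum(_predict01(dec, ytr) == y01[te]))
    return correct / len(y01)


def _encode_labels(labels) -> tuple[np.ndarray, np.ndarray]:
    """Map arbitrary binary labels to 0/1 by sorted class order."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"labels must be binary, got classes {classes}")
    return (labels == classes[1]).astype(float), classes


# ---------------------------------------------------------------------------
# public operations


def zscore_across_trials(B):
    """z-score each voxel across all trials (mean 0, sd 1), before any fold split.

    Constant voxels are set to all zeros with a warning.  Accepts and returns
    either a :class:`TrialBetaMatrix` or a plain trials x voxels array.
    """
    if isinstance(B, TrialBetaMatrix):
        data = B.data
    else:
        data = np.asarray(B, dtype=float)
    if data.shape[0] < 2:
        raise ValueError("z-scoring requires at least 2 trials")
    mean = data.mean(axis=0)
    sd = data.std(axis=0)
    zero = sd == 0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} constant voxel(s) set to zero during z-scoring",
            RuntimeWarning,
            stacklevel=2,
        )
    safe_sd = np.where(zero, 1.0, sd)
    z = (data - mean) / safe_sd
    z[:, zero] = 0.0
    if isinstance(B, TrialBetaMatrix):
        return TrialBetaMatrix(
            data=z,
            trial_info=B.trial_info,
            participant=B.participant,
            hemisphere=B.hemisphere,
            voxel_coords=B.voxel_coords,
        )
    return z


def make_running_index_folds(stimulus_labels, n_folds: int = 3) -> list[FoldSpec]:
    """Threefold split by running index over each individual stimulus.

    Trials must be in chronological order with reinforced trials already
    removed.  The i-th occurrence of each stimulus enters the test set of fold
    i mod 3 and the training sets of the other folds.
    """
    labels = np.asarray(stimulus_labels)
    n = len(labels)
    fold_id = np.empty(n, dtype=np.intp)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < n_folds:
            raise ValueError(
                f"stimulus {cls!r} has {len(idx)} trials; at least {n_folds} required"
            )
        fold_id[idx] = np.arange(len(idx)) % n_folds
    folds = []
    for f in range(n_folds):
        te = np.flatnonzero(fold_id == f)
        tr = np.flatnonzero(fold_id != f)
        folds.append(FoldSpec(fold=f, train=tr, test=te))
    return folds


def decode_condition(B, labels, folds: list[FoldSpec], spec: ClassifierSpec | None = None) -> float:
    """Pooled cross-validated accuracy of the linear SVM over the given folds."""
    spec = spec or ClassifierSpec()
    X = B.data if isinstance(B, TrialBetaMatrix) else np.asarray(B, dtype=float)
    y01, _ = _encode_labels(labels)
    correct = 0
    total = 0
    for fs in folds:
        ytr = y01[fs.train]
        if ytr.min() == ytr.max():
            raise ValueError(f"fold {fs.fold} has single-class training data")
        dec = _fit_decision(X[fs.train], ytr, X[fs.test], spec)
        correct += int(np.sum(_predict01(dec, ytr) == y01[fs.test]))
        total += len(fs.test)
    return correct / total


def subsample_ns(
    stimulus_labels,
    rng: np.random.Generator | int | None = None,
    n_remove: int | None = None,
) -> np.ndarray:
    """Randomly drop trials of one randomly chosen NS to mirror the CS counts.

    Picks one of the two stimulus identities at random and removes
    ``n_remove`` (default: half its count) random trials of it; returns the
    retained trial indices in chronological order.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    labels = np.asarray(stimulus_labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"expected two stimulus identities, got {classes}")
    victim = classes[rng.integers(2)]
    victim_idx = np.flatnonzero(labels == victim)
    if n_remove is None:
        n_remove = len(victim_idx) // 2
    if n_remove == 0:
        return np.arange(len(labels))
    if n_remove > len(victim_idx):
        raise ValueError("cannot remove more trials than the stimulus has")
    removed = rng.choice(victim_idx, size=n_remove, replace=False)
    keep = np.setdiff1d(np.arange(len(labels)), removed)
    return keep


def permutation_chance(
    B,
    labels,
    n_perm: int,
    rng: np.random.Generator | int | None = None,
    *,
    spec: ClassifierSpec | None = None,
    subsample: bool = False,
    n_subsample_reps: int = 1,
) -> tuple[float, float, np.ndarray]:
    """Empirical chance level: the decoding procedure under label permutation.

    For each permutation the label vector is randomly permuted over the
    retained trials (multiset preserved), folds are recomputed by the same
    running-index rule, and the classifier is re-run.  With ``subsample`` the
    per-permutation value averages ``n_subsample_reps`` fresh NS subsamples.
    Returns (mean, sd, full null distribution), deterministic given the rng.
    """
    spec = spec or ClassifierSpec()
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    X = B.data if isinstance(B, TrialBetaMatrix) else np.asarray(B, dtype=float)
    X = np.ascontiguousarray(X, dtype=np.float64)
    y01, _ = _encode_labels(labels)
    null = np.empty(n_perm)
    for p in range(n_perm):
        if subsample:
            acc = 0.0
            for _ in range(n_subsample_reps):
                keep = subsample_ns(y01, rng)
                yk = y01[keep]
                perm = yk[rng.permutation(len(yk))]
                acc += _pooled_cv_accuracy(X[keep], perm, spec)
            null[p] = acc / n_subsample_reps
        else:
            perm = y01[rng.permutation(len(y01))]
            null[p] = _pooled_cv_accuracy(X, perm, spec)
    return float(null.mean()), float(null.std(ddof=1)) if n_perm > 1 else 0.0, null


def excess_accuracy(raw_accuracy: float, chance_mean: float) -> float:
    """Accuracy above the permutation-estimated chance level."""
    if not 0.0 <= raw_accuracy <= 1.0 or not 0.0 <= chance_mean <= 1.0:
        raise ValueError("accuracies must lie in [0, 1]")
    return raw_accuracy - chance_mean


def evaluate_condition(
    B,
    labels,
    *,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
    spec: ClassifierSpec | None = None,
    subsample: bool = False,
    n_subsample_reps: int = 100,
    participant: str | None = None,
    context: str = "",
    complexity: str = "",
    hemisphere: str | None = None,
    keep_null: bool = False,
) -> DecodingResult:
    """Raw accuracy, permutation chance and excess for one task condition.

    ``B``/``labels`` are the z-scored retained trials of the condition, in
    chronological order.  With ``subsample`` (NS conditions) both the raw
    accuracy and each permutation value average over ``n_subsample_reps``
    subsamples, so raw and chance are computed on identically distributed
    trial sets.
    """
    spec = spec or ClassifierSpec()
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    X = B.data if isinstance(B, TrialBetaMatrix) else np.asarray(B, dtype=float)
    X = np.ascontiguousarray(X, dtype=np.float64)
    y01, _ = _encode_labels(labels)
    if subsample:
        acc = 0.0
        for _ in range(n_subsample_reps):
            keep = subsample_ns(y01, rng)
            acc += _pooled_cv_accuracy(X[keep], y01[keep], spec)
        raw = acc / n_subsample_reps
    else:
        raw = _pooled_cv_accuracy(X, y01, spec)
    chance_mean, chance_sd, null = permutation_chance(
        X,
        y01,
        n_perm,
        rng,
        spec=spec,
        subsample=subsample,
        n_subsample_reps=n_subsample_reps,
    )
    return DecodingResult(
        participant=participant,
        context=context,
        complexity=complexity,
        hemisphere=hemisphere,
        raw_accuracy=raw,
        chance_mean=chance_mean,
        chance_sd=chance_sd,
        excess_accuracy=excess_accuracy(raw, chance_mean),
        null_distribution=null if keep_null else None,
    )


# ---------------------------------------------------------------------------
# cross-decoding


def _transfer_accuracy(Xtr, ytr, Xte, yte, spec) -> float:
    if ytr.min() == ytr.max():
        raise ValueError("training set has a single class")
    dec = _fit_decision(Xtr, ytr, Xte, spec)
    return float(np.mean(_predict01(dec, ytr) == yte))


def cross_decode(
    B_train,
    labels_train,
    B_test,
    labels_test,
    *,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
    spec: ClassifierSpec | None = None,
    subsample: bool = False,
    n_subsample_reps: int = 100,
    participant: str | None = None,
    stimulus_class: str = "CS",
    direction: str = "simple_to_complex",
    hemisphere: str | None = None,
    keep_null: bool = False,
) -> CrossDecodingResult:
    """Train on one complexity condition, test on the other (no CV folds).

    Chance is estimated by permuting the training and test label vectors
    independently (each multiset preserved) and repeating the transfer.  With
    ``subsample`` both sets are freshly subsampled to the CS-like class
    counts on every evaluation, averaging over ``n_subsample_reps``.
    """
    spec = spec or ClassifierSpec()
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    Xa = np.ascontiguousarray(
        B_train.data if isinstance(B_train, TrialBetaMatrix) else B_train, dtype=np.float64
    )
    Xb = np.ascontiguousarray(
        B_test.data if isinstance(B_test, TrialBetaMatrix) else B_test, dtype=np.float64
    )
    la = np.asarray(labels_train)
    lb = np.asarray(labels_test)
    classes = np.unique(np.concatenate([la, lb]))
    if len(classes) != 2:
        raise ValueError(f"labels must share two classes, got {classes}")
    ya = (la == classes[1]).astype(float)
    yb = (lb == classes[1]).astype(float)

    def one_eval(permute: bool) -> float:
        if subsample:
            acc = 0.0
            for _ in range(n_subsample_reps):
                ka = subsample_ns(ya, rng)
                kb = subsample_ns(yb, rng)
                ytr, yte = ya[ka], yb[kb]
                if permute:
                    ytr = ytr[rng.permutation(len(ytr))]
                    yte = yte[rng.permutation(len(yte))]
                acc += _transfer_accuracy(Xa[ka], ytr, Xb[kb], yte, spec)
            return acc / n_subsample_reps
        ytr, yte = ya, yb
        if permute:
            ytr = ytr[rng.permutation(len(ytr))]
            yte = yte[rng.permutation(len(yte))]
        return _transfer_accuracy(Xa, ytr, Xb, yte, spec)

    raw = one_eval(permute=False)
    null = np.array([one_eval(permute=True) for _ in range(n_perm)])
    chance_mean = float(null.mean())
    chance_sd = float(null.std(ddof=1)) if n_perm > 1 else 0.0
    return CrossDecodingResult(
        participant=participant,
        stimulus_class=stimulus_class,
        direction=direction,
        hemisphere=hemisphere,
        raw_accuracy=raw,
        chance_mean=chance_mean,
        chance_sd=chance_sd,
        excess_accuracy=raw - chance_mean,
        null_distribution=null if keep_null else None,
    )


# ---------------------------------------------------------------------------
# participant-level drivers


def _retained(betas: TrialBetaMatrix) -> tuple[np.ndarray, pd.DataFrame]:
    info = betas.trial_info
    if info is None:
        raise ValueError("betas.trial_info is required for condition-wise decoding")
    keep = np.flatnonzero(info["reinforced"].to_numpy() == 0)
    return keep, info.iloc[keep].reset_index(drop=True)


def decode_participant(
    betas: TrialBetaMatrix,
    *,
    n_perm: int = 1000,
    n_subsample_reps: int = 100,
    spec: ClassifierSpec | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Decode all four task conditions for one participant/hemisphere.

    Reinforced trials are discarded, the retained trials are z-scored per
    voxel across the whole experiment, and each context x complexity cell is
    decoded with its own permutation chance (NS cells with subsampling).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    keep, info = _retained(betas)
    Z = zscore_across_trials(betas.data[keep])
    rows = []
    for context in ("reinforcement", "nonreinforcement"):
        for complexity in ("simple", "complex"):
            sel = np.flatnonzero(
                (info["context"] == context).to_numpy()
                & (info["complexity"] == complexity).to_numpy()
            )
            res = evaluate_condition(
                Z[sel],
                info["trial_type"].to_numpy()[sel],
                n_perm=n_perm,
                rng=rng,
                spec=spec,
                subsample=(context == "nonreinforcement"),
                n_subsample_reps=n_subsample_reps,
                participant=betas.participant,
                context=context,
                complexity=complexity,
                hemisphere=betas.hemisphere,
            )
            rows.append(
                {
                    "participant": res.participant,
                    "hemisphere": res.hemisphere,
                    "context": res.context,
                    "complexity": res.complexity,
                    "raw_accuracy": res.raw_accuracy,
                    "chance_mean": res.chance_mean,
                    "chance_sd": res.chance_sd,
                    "excess_accuracy": res.excess_accuracy,
                }
            )
    return pd.DataFrame(rows)


def cross_decode_participant(
    betas: TrialBetaMatrix,
    *,
    n_perm: int = 1000,
    n_subsample_reps: int = 100,
    spec: ClassifierSpec | None = None,
    rng: np.random.Generator | int | None = None,
    ns_label_matching: str = "response",
) -> pd.DataFrame:
    """Cross-complexity transfer for CS and response-matched NS, both directions.

    CS transfer uses all retained reinforcement-context trials of one
    complexity as training set and the other as test set, labelled CS+/CS-.
    The NS control labels trials by the required key press, matched across
    complexity (``ns_label_matching='swapped'`` inverts the matching, which
    flips the sign of any purely motor-driven transfer), and subsamples to
    CS-like class counts.
    """
    if ns_label_matching not in ("response", "swapped"):
        raise ValueError("ns_label_matching must be 'response' or 'swapped'")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    keep, info = _retained(betas)
    Z = zscore_across_trials(betas.data[keep])
    rows = []
    for context, stim_class in (("reinforcement", "CS"), ("nonreinforcement", "NS")):
        sets = {}
        for complexity in ("simple", "complex"):
            sel = np.flatnonzero(
                (info["context"] == context).to_numpy()
                & (info["complexity"] == complexity).to_numpy()
            )
            if len(sel) == 0:
                raise ValueError(f"missing {complexity} {context} condition")
            labels = info["required_response"].to_numpy()[sel].copy()
            if stim_class == "NS" and ns_label_matching == "swapped" and complexity == "complex":
                labels = np.where(labels == "key1", "key2", "key1")
            sets[complexity] = (Z[sel], labels)
        for direction, (tr_cx, te_cx) in (
            ("simple_to_complex", ("simple", "complex")),
            ("complex_to_simple", ("complex", "simple")),
        ):
            res = cross_decode(
                sets[tr_cx][0],
                sets[tr_cx][1],
                sets[te_cx][0],
                sets[te_cx][1],
                n_perm=n_perm,
                rng=rng,
                spec=spec,
                subsample=(stim_class == "NS"),
                n_subsample_reps=n_subsample_reps,
                participant=betas.participant,
                stimulus_class=stim_class,
                direction=direction,
                hemisphere=betas.hemisphere,
            )
            rows.append(
                {
                    "participant": res.participant,
                    "hemisphere": res.hemisphere,
                    "stimulus_class": res.stimulus_class,
                    "direction": res.direction,
                    "raw_accuracy": res.raw_accuracy,
                    "chance_mean": res.chance_mean,
                    "chance_sd": res.chance_sd,
                    "excess_accuracy": res.excess_accuracy,
                }
            )
    return pd.DataFrame(rows)
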