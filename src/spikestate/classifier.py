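"""PCA and random-forest classification of cells into transcriptional states.

The three states are ``repression``, ``amplification`` and ``control_like``.
Training labels come from representative conditions (label-based route) or
from PCA gates (label-blind route); the consistency bootstrap compares the
two.  Forest "P-values" are class-vote fractions and always sum to 1; the
decided state is the argmax with ties broken in the fixed order
repression > amplification > control_like.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import cross_val_score, train_test_split

from .errors import DataError

STATE_ORDER = ("repression", "amplification", "control_like")

#: Representative condition per state for label-based training.
STATE_CONDITIONS = {"control": "control_like", "CELE16": "repression",
                    "COMBO16": "amplification"}

#: Gate constants match a specific PCA realization; on other data orient the
#: component signs first and expect to re-derive the thresholds.
DEFAULT_GATES = {
    "control_like": ["PC2 > 15"],
    "repression": ["PC1 > 15", "PC2 < 0", "PC3 > 5"],
    "amplification": ["PC1 < -15", "PC2 < 0"],
}

_PRED_RE = re.compile(r"^\s*PC(\d+)\s*([<>])\s*(-?\d+(?:\.\d+)?)\s*$")


@dataclass
class PcaResult:
    scores: pd.DataFrame               # cells x PC1..PCn
    variance_fraction: np.ndarray      # per PC, non-increasing
    signs: dict = field(default_factory=dict)


@dataclass
class StateModel:
    feature_genes: list[str]
    forest: RandomForestClassifier
    training_matrix: pd.DataFrame      # genes x training cells, control-normalized
    training_cells: list[str]
    test_cells: list[str]
    mda: pd.Series | None
    ntree: int
    cv_scores: np.ndarray | None
    seed: int


def reference_state_labels(
    annotation: pd.DataFrame, mapping: dict[str, str] | None = None
) -> pd.Series:
    """State labels for cells in the representative conditions only."""
    mapping = mapping or STATE_CONDITIONS
    cond = annotation["condition"]
    sel = cond.isin(mapping)
    return cond[sel].map(mapping).rename("state")


def select_differential_genes(
    E: pd.DataFrame,
    annotation: pd.DataFrame,
    fold: float = 1.5,
    control_condition: str = "control",
    exclude: list[str] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Genes whose mean E shifts by >= log2(fold) vs control in >= 1 treatment.

    Returns the selected gene ids and the control-normalized matrix
    (E minus the per-gene control mean) over those genes and all cells.
    """
    cond = annotation["condition"]
    cells = [c for c in E.columns if c in cond.index]
    cond = cond.loc[cells]
    ctrl = [c for c in cells if cond[c] == control_condition]
    if not ctrl:
        raise DataError(f"no cells in control condition {control_condition!r}")
    work = E[cells]
    if exclude:
        work = work.drop(index=[g for g in exclude if g in work.index])
    ctrl_mean = work[ctrl].mean(axis=1)
    t = np.log2(fold)
    selected = pd.Series(False, index=work.index)
    for c, group in cond.groupby(cond).groups.items():
        if c == control_condition:
            continue
        diff = (work[list(group)].mean(axis=1) - ctrl_mean).abs()
        selected |= diff >= t - 1e-9  # inclusive threshold, ulp-tolerant
    genes = selected.index[selected].tolist()
    norm = work.loc[genes].sub(ctrl_mean.loc[genes], axis=0)
    return genes, norm


def run_pca(
    matrix: pd.DataFrame,
    n_components: int | None = None,
    orient: dict[str, list[str]] | None = None,
) -> PcaResult:
    """PCA over cells (columns of ``matrix``) in gene-feature space.

    ``orient`` maps a PC name to cell ids whose centroid should score
    positive on that PC; the component sign is flipped when needed (principal
    axes have arbitrary sign).  Rank-deficient input is truncated to the
    non-degenerate components.
    """
    if matrix.shape[1] < 3:
        raise DataError("PCA needs at least 3 cells")
    if matrix.shape[0] < 3:
        raise DataError("PCA needs at least 3 genes")
    X = matrix.T.to_numpy(dtype=float)
    k = min(X.shape[0], X.shape[1]) if n_components is None else n_components
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    vf = pca.explained_variance_ratio_
    nz = vf > 1e-12
    scores, vf = scores[:, nz], vf[nz]
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    df = pd.DataFrame(scores, index=matrix.columns, columns=cols)
    signs = {}
    for pc, cells in (orient or {}).items():
        if pc not in df.columns:
            continue
        centroid = df.loc[[c for c in cells if c in df.index], pc].mean()
        sign = -1.0 if centroid < 0 else 1.0
        df[pc] *= sign
        signs[pc] = sign
    return PcaResult(scores=df, variance_fraction=vf, signs=signs)


def oob_condition_error(
    matrix: pd.DataFrame,
    labels: pd.Series,
    ntree: int = 600,
    seed: int = 20210617,
) -> pd.Series:
    """Per-class out-of-bag misclassification rate of a multi-class forest."""
    cells = [c for c in matrix.columns if c in labels.index]
    y = labels.loc[cells]
    counts = y.value_counts()
    if len(counts) < 2:
        raise DataError("out-of-bag analysis needs >= 2 classes")
    small = counts[counts < 5]
    if len(small):
        raise DataError(f"classes with < 5 cells: {small.index.tolist()}")
    X = matrix[cells].T.to_numpy(dtype=float)
    forest = RandomForestClassifier(
        n_estimators=ntree, oob_score=True, random_state=seed, n_jobs=1
    )
    forest.fit(X, y.to_numpy())
    votes = forest.oob_decision_function_
    # cells never out-of-bag (vanishingly rare at ntree >= 100) count as errors
    valid = ~np.isnan(votes).all(axis=1)
    pred = np.full(len(y), None, dtype=object)
    pred[valid] = forest.classes_[np.nanargmax(votes[valid], axis=1)]
    err = pd.Series(
        {cls: float(np.mean(pred[y.to_numpy() == cls] != cls)) for cls in counts.index},
        name="oob_error",
    )
    return err


def _oob_indices(estimator, n_samples: int) -> np.ndarray:
    """Out-of-bag sample indices for one bootstrap tree."""
    try:
        import inspect

        from sklearn.ensemble._forest import _generate_unsampled_indices

        kwargs = {}
        if "sample_weight" in inspect.signature(_generate_unsampled_indices).parameters:
            kwargs["sample_weight"] = None
        return _generate_unsampled_indices(estimator.random_state, n_samples,
                                           n_samples, **kwargs)
    except ImportError:  # pragma: no cover - private API moved
        rs = np.random.RandomState(estimator.random_state)
        sampled = rs.randint(0, n_samples, n_samples)
        mask = np.ones(n_samples, dtype=bool)
        mask[sampled] = False
        return np.flatnonzero(mask)


def _permutation_mda(
    forest: RandomForestClassifier,
    X: np.ndarray,
    y: np.ndarray,
    n_repeats: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-tree out-of-bag mean decrease in accuracy.

    For each tree, each feature the tree actually splits on is permuted among
    the tree's out-of-bag samples and the accuracy drop recorded; features a
    tree never touches contribute exactly zero for that tree.  The result is
    averaged over all trees — the classic forest permutation importance,
    which stays sensitive when informative features are redundant.
    """
    n, p = X.shape
    mda = np.zeros(p)
    # individual trees predict encoded class indices, not original labels
    encode = {c: i for i, c in enumerate(forest.classes_)}
    y_enc = np.array([encode[v] for v in y])
    for est in forest.estimators_:
        oob = _oob_indices(est, n)
        if len(oob) < 2:
            continue
        Xo, yo = X[oob], y_enc[oob]
        base = float(np.mean(est.predict(Xo).astype(int) == yo))
        feats = np.unique(est.tree_.feature[est.tree_.feature >= 0])
        if len(feats) == 0:
            continue
        for _ in range(n_repeats):
            stacked = np.repeat(Xo[None, :, :], len(feats), axis=0)
            for i, j in enumerate(feats):
                stacked[i, :, j] = Xo[rng.permutation(len(oob)), j]
            pred = est.predict(stacked.reshape(-1, p)).astype(int)
            acc = (pred.reshape(len(feats), len(oob)) == yo[None, :]).mean(axis=1)
            mda[feats] += (base - acc) / n_repeats
    return mda / forest.n_estimators


def train_state_classifier(
    matrix: pd.DataFrame,
    labels: pd.Series,
    ntree: int = 200,
    cv_folds: int = 5,
    train_fraction: float = 2 / 3,
    seed: int = 20210617,
    compute_mda: bool = True,
    mda_repeats: int = 1,
) -> tuple[StateModel, dict[str, float]]:
    """Train a 3-state forest on a stratified 2/3 split; report test AUCs.

    Returns the model and a per-state one-vs-rest ROC AUC computed on the
    held-out third.  MDA (mean decrease in accuracy) is the per-tree
    out-of-bag permutation importance on the training cells; genes with
    MDA > 0 contribute to the classification.  K-fold cross-validation scores on the training split are
    kept as a tuning diagnostic only — the final model is the single forest.
    """
    cells = [c for c in matrix.columns if c in labels.index]
    y = labels.loc[cells]
    counts = y.value_counts()
    if len(counts) != 3:
        raise DataError(f"expected exactly 3 state labels, got {list(counts.index)}")
    small = counts[counts < 6]
    if len(small):
        raise DataError(f"states with < 6 cells: {small.index.tolist()}")
    X = matrix[cells].T
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=train_fraction, stratify=y, random_state=seed
    )
    forest = RandomForestClassifier(n_estimators=ntree, random_state=seed, n_jobs=1)
    forest.fit(X_tr.to_numpy(), y_tr.to_numpy())

    cv_scores = None
    if cv_folds and cv_folds >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv_scores = cross_val_score(
                RandomForestClassifier(n_estimators=ntree, random_state=seed, n_jobs=1),
                X_tr.to_numpy(), y_tr.to_numpy(), cv=cv_folds,
            )

    probs = forest.predict_proba(X_te.to_numpy())
    aucs = {}
    for i, cls in enumerate(forest.classes_):
        aucs[str(cls)] = float(roc_auc_score((y_te == cls).to_numpy(), probs[:, i]))

    mda = None
    if compute_mda:
        vals = _permutation_mda(
            forest, X_tr.to_numpy(), y_tr.to_numpy(),
            n_repeats=mda_repeats, rng=np.random.default_rng(seed),
        )
        mda = pd.Series(vals, index=matrix.index, name="mda")

    model = StateModel(
        feature_genes=list(matrix.index),
        forest=forest,
        training_matrix=matrix[X_tr.index.tolist()],
        training_cells=X_tr.index.tolist(),
        test_cells=X_te.index.tolist(),
        mda=mda,
        ntree=ntree,
        cv_scores=cv_scores,
        seed=seed,
    )
    return model, aucs


def classify_cells(model: StateModel, matrix: pd.DataFrame) -> pd.DataFrame:
    """Vote fractions per state plus the decided state for every cell.

    Output columns: ``p_repression``, ``p_amplification``, ``p_control_like``,
    ``decided_state``.  The three probabilities sum to 1 per cell.
    """
    missing = [g for g in model.feature_genes if g not in matrix.index]
    if missing:
        raise DataError(f"matrix lacks model feature genes: {missing[:10]}"
                        + ("..." if len(missing) > 10 else ""))
    X = matrix.loc[model.feature_genes].T
    raw = model.forest.predict_proba(X.to_numpy())
    probs = pd.DataFrame(raw, index=X.index, columns=model.forest.classes_)
    for s in STATE_ORDER:
        if s not in probs.columns:
            probs[s] = 0.0
    probs = probs[list(STATE_ORDER)]
    decided = probs.idxmax(axis=1)  # first max wins -> documented tie order
    out = probs.rename(columns={s: f"p_{s}" for s in STATE_ORDER})
    out["decided_state"] = decided
    return out


def parse_gate(predicates: list) -> list[tuple[str, str, float]]:
    """Parse gate predicates like ``"PC1 > 15"`` into (pc, op, threshold)."""
    parsed = []
    for p in predicates:
        if isinstance(p, (tuple, list)) and len(p) == 3:
            parsed.append((str(p[0]), str(p[1]), float(p[2])))
            continue
        m = _PRED_RE.match(str(p))
        if not m:
            raise DataError(f"cannot parse gate predicate {p!r}")
        parsed.append((f"PC{m.group(1)}", m.group(2), float(m.group(3))))
    return parsed


def pca_gate_training_selection(
    pca: PcaResult,
    gates: dict[str, list] | None = None,
    n_per_group: int = 25,
    seed: int = 20210617,
    allow_small: bool = False,
) -> dict[str, list[str]]:
    """Assign cells to state pools by PC-threshold gates, sample training sets.

    Gates ignore any pre-existing condition labels.  Each pool must hold at
    least ``n_per_group`` cells unless ``allow_small``, in which case the
    whole pool is taken.
    """
    gates = gates if gates is not None else DEFAULT_GATES
    rng = np.random.default_rng(seed)
    out: dict[str, list[str]] = {}
    for state, predicates in gates.items():
        mask = pd.Series(True, index=pca.scores.index)
        for pc, op, thr in parse_gate(predicates):
            if pc not in pca.scores.columns:
                raise DataError(f"gate references unavailable component {pc}")
            col = pca.scores[pc]
            mask &= (col > thr) if op == ">" else (col < thr)
        pool = pca.scores.index[mask].tolist()
        if len(pool) < n_per_group:
            if not allow_small:
                raise DataError(
                    f"gate pool for state {state!r} has {len(pool)} cells "
                    f"(< {n_per_group}); pass allow_small to take all"
                )
            out[state] = pool
        else:
            out[state] = sorted(rng.choice(pool, size=n_per_group, replace=False))
    return out


def classification_consistency(
    matrix: pd.DataFrame,
    reference_states: pd.Series,
    gates: dict[str, list] | None = None,
    reps: int = 200,
    ci_level: float = 0.90,
    seed: int = 20210617,
    n_per_group: int = 25,
    ntree: int = 200,
    pca: PcaResult | None = None,
) -> tuple[float, tuple[float, float]]:
    """Median and equal-tail CI of gate-trained vs reference agreement.

    Each rep gate-selects a fresh training set, trains a forest with the gate
    state as label, classifies all cells and records the fraction whose
    decided state matches ``reference_states``.  Reps whose pools are too
    small are skipped with a warning; more than half skipped is an error.
    """
    if reps < 2:
        raise DataError("consistency bootstrap needs reps >= 2")
    if pca is None:
        pca = run_pca(matrix)
    root = np.random.default_rng(seed)
    fractions = []
    skipped = 0
    for rep in range(reps):
        rep_seed = int(root.integers(0, 2 ** 31 - 1))
        try:
            pools = pca_gate_training_selection(
                pca, gates, n_per_group=n_per_group, seed=rep_seed
            )
        except DataError as exc:
            warnings.warn(f"rep {rep} skipped: {exc}", stacklevel=2)
            skipped += 1
            continue
        train_cells, train_labels = [], []
        for state, cells in pools.items():
            train_cells.extend(cells)
            train_labels.extend([state] * len(cells))
        forest = RandomForestClassifier(
            n_estimators=ntree, random_state=rep_seed, n_jobs=1
        )
        forest.fit(matrix[train_cells].T.to_numpy(), np.array(train_labels))
        probs = pd.DataFrame(
            forest.predict_proba(matrix.T.to_numpy()),
            index=matrix.columns, columns=forest.classes_,
        )
        for s in STATE_ORDER:
            if s not in probs.columns:
                probs[s] = 0.0
        decided = probs[list(STATE_ORDER)].idxmax(axis=1)
        common = reference_states.index.intersection(decided.index)
        fractions.append(float((decided.loc[common] == reference_states.loc[common]).mean()))
    if skipped > reps / 2:
        raise DataError(f"{skipped}/{reps} consistency reps skipped")
    arr = np.array(fractions)
    lo, hi = np.quantile(arr, [(1 - ci_level) / 2, 1 - (1 - ci_level) / 2])
    return float(np.median(arr)), (float(lo), float(hi))
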