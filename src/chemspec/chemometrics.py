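"""Multivariate core: PCA, PC-DFA with bootstrap validation, and consensus
multi-block PCA (CPCA).

PC-DFA is the classic two-stage supervised projection used in metabolic
fingerprinting: PCA compresses the (autoscaled) data to a small number of
score dimensions, then Fisher canonical discriminant analysis is run on the
retained scores using the known class structure. Validation follows the
bootstrap scheme common in that literature: resample biological replicates
within class, refit the whole chain, and classify the out-of-bag samples,
summarising per-class percent-correct with a percentile 95% CI.

CPCA is the consensus (multi-block) PCA of Westerhuis-style multiblock
chemometrics: a NIPALS iteration that couples per-block scores through a
shared super score, with blocks weighted 1/√K_b so large blocks do not
swamp small ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .preprocess import autoscale_apply, autoscale_fit

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    pass


def _fix_signs(loadings: np.ndarray, *coupled: np.ndarray):
    """Deterministic sign convention: the largest-|.| element of each loading
    column is made positive; coupled matrices (scores) are flipped with it."""
    flips = np.ones(loadings.shape[1])
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            flips[j] = -1.0
    loadings *= flips
    for c in coupled:
        c *= flips
    return loadings, coupled


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PCAModel:
    """Column-mean-centred PCA via singular value decomposition."""

    mean_: np.ndarray
    loadings: np.ndarray            # [p, k], orthonormal columns
    scores: np.ndarray              # [n, k]
    explained_variance_ratio: np.ndarray
    singular_values: np.ndarray
    total_variance: float           # sum over all min(n-1, p) components

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.loadings


def fit_pca(X: np.ndarray, k: int | None = None) -> PCAModel:
    """Fit PCA with a deterministic sign convention.

    ``k`` defaults to the full rank ``min(n−1, p)``. Explained-variance
    fractions are relative to the total variance over all components, so
    they sum to 1 at full rank.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    n, p = X.shape
    max_k = min(n - 1, p)
    if k is None:
        k = max_k
    if not 1 <= k <= max_k:
        raise ValueError(f"k={k} outside 1..min(n-1, p)={max_k}")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, sv, Vt = np.linalg.svd(Xc, full_matrices=False)
    sv = sv[:max_k]
    U = U[:, :max_k]
    Vt = Vt[:max_k]
    var = sv**2 / (n - 1)
    total = float(var.sum())
    loadings = Vt[:k].T.copy()
    scores = U[:, :k] * sv[:k]
    loadings, (scores,) = _fix_signs(loadings, scores)
    ratio = var[:k] / total if total > 0 else np.zeros(k)
    return PCAModel(
        mean_=mean,
        loadings=loadings,
        scores=scores,
        explained_variance_ratio=ratio,
        singular_values=sv[:k].copy(),
        total_variance=total,
    )


# ---------------------------------------------------------------------------
# PC-DFA

#: Retained-PC defaults used for the two platforms in this workflow.
N_PCS_FTIR = 20
N_PCS_GCMS = 25


@dataclass
class DFAModel:
    """Canonical discriminant analysis on retained PC scores.

    ``weights`` maps PC scores to discriminant-function (DF) space; the
    canonical vectors are scaled so the pooled within-class covariance of
    the DF scores is the identity. Classification is nearest class centroid
    in DF space (Euclidean), ties broken by class sort order.
    """

    pca: PCAModel
    n_pcs: int
    classes: list
    weights: np.ndarray             # [n_pcs, n_df]
    eigenvalues: np.ndarray
    centroids: pd.DataFrame         # [n_classes, n_df]
    scores: np.ndarray              # training DF scores [n, n_df]
    ridge_used: bool = False
    bootstrap_summary: pd.DataFrame | None = None

    @property
    def n_df(self) -> int:
        return self.weights.shape[1]

    def project(self, X: np.ndarray) -> np.ndarray:
        """Map raw (preprocessed) rows into DF space."""
        return self.pca.transform(X)[:, : self.n_pcs] @ self.weights


def fit_pc_dfa(X: np.ndarray, labels, n_pcs: int = N_PCS_FTIR) -> DFAModel:
    """PCA to ``n_pcs`` scores, then Fisher DFA on those scores.

    The canonical vectors are eigenvectors of W⁻¹B where W and B are the
    pooled within-class and between-class scatter of the PC scores; at most
    ``n_classes − 1`` discriminant functions are kept. A singular W falls
    back to a small ridge (ε = 1e−8·trace(W)/n_pcs) with a logged warning.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.shape[0] != labels.shape[0]:
        raise ValueError("label count does not match row count")
    classes = sorted(pd.unique(labels).tolist())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes (no between-class scatter)")
    counts = pd.Series(labels).value_counts()
    small = counts[counts < 2].index.tolist()
    if small:
        raise ValueError(f"classes with a single sample: {small}")

    pca = fit_pca(X, k=min(n_pcs, min(X.shape[0] - 1, X.shape[1])))
    if pca.n_components < n_pcs:
        raise ValueError(
            f"n_pcs={n_pcs} exceeds available components ({pca.n_components})"
        )
    S = pca.scores[:, :n_pcs]
    grand = S.mean(axis=0)
    B = np.zeros((n_pcs, n_pcs))
    W = np.zeros((n_pcs, n_pcs))
    for g in classes:
        Sg = S[labels == g]
        mg = Sg.mean(axis=0)
        dg = (mg - grand)[:, None]
        B += len(Sg) * (dg @ dg.T)
        R = Sg - mg
        W += R.T @ R

    n, g = S.shape[0], len(classes)
    ridge_used = False
    try:
        evals, evecs = scipy.linalg.eigh(B, W)
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError):
        ridge_used = True
        eps = 1e-8 * np.trace(W) / n_pcs
        logger.warning("singular within-class scatter; adding ridge %g", eps)
        evals, evecs = scipy.linalg.eigh(B, W + eps * np.eye(n_pcs))
    order = np.argsort(evals)[::-1]
    n_df = min(g - 1, n_pcs)
    evals = np.clip(evals[order][:n_df], 0.0, None)
    A = evecs[:, order[:n_df]]
    # scale so pooled within-class covariance of canonical scores is identity
    Wpooled = W / (n - g)
    for j in range(n_df):
        s2 = float(A[:, j] @ Wpooled @ A[:, j])
        if s2 > 0:
            A[:, j] /= np.sqrt(s2)
    A, _ = _fix_signs(A)

    scores = S @ A
    cent = pd.DataFrame(
        [scores[labels == g].mean(axis=0) for g in classes],
        index=pd.Index(classes, name="class"),
        columns=[f"DF{i + 1}" for i in range(n_df)],
    )
    return DFAModel(
        pca=pca,
        n_pcs=n_pcs,
        classes=classes,
        weights=A,
        eigenvalues=evals,
        centroids=cent,
        scores=scores,
        ridge_used=ridge_used,
    )


def classify(model: DFAModel, X_new: np.ndarray) -> np.ndarray:
    """Nearest-centroid labels in DF space for already-preprocessed rows.

    Rows must be on the same scale as the training matrix (apply the
    training scaling model first). Ties go to the first class in sort
    order — ``argmin`` over the sorted centroid table is deterministic.
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.shape[1] != model.pca.mean_.shape[0]:
        raise ValueError(
            f"expected {model.pca.mean_.shape[0]} columns, got {X_new.shape[1]}"
        )
    Z = model.project(X_new)
    C = model.centroids.values
    d2 = ((Z[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
    idx = np.argmin(d2, axis=1)
    return np.asarray([model.classes[i] for i in idx])


def bootstrap_validate(
    X: np.ndarray,
    labels,
    n_pcs: int = N_PCS_FTIR,
    n_boot: int = 1000,
    seed: int | None = None,
    groups=None,
    scale: bool = True,
) -> pd.DataFrame:
    """Bootstrap cross-validation of the scaling → PCA → DFA chain.

    Each iteration resamples the replicate units (``groups``; biological
    replicates by default — pass ``design.labels`` + bio_rep ids — or one
    group per row if omitted) *within class* with replacement, refits the
    full chain on the in-bag rows, and classifies the out-of-bag rows. A
    class that ends an iteration with no out-of-bag unit contributes no
    estimate for that iteration (tracked, never fabricated).

    Returns a per-class table: mean % correct, percentile 95% CI
    (2.5th/97.5th), and the number of usable iterations.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if groups is None:
        groups = np.arange(X.shape[0])
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    classes = sorted(pd.unique(labels).tolist())
    for g in classes:
        if len(pd.unique(groups[labels == g])) < 2:
            raise ValueError(f"class {g!r} has fewer than 2 replicate units")

    per_class_acc = {g: [] for g in classes}
    for _ in range(n_boot):
        in_rows, oob_rows = [], []
        for g in classes:
            mask = labels == g
            units = pd.unique(groups[mask])
            draw = rng.choice(units, size=len(units), replace=True)
            chosen = set(draw.tolist())
            rows = np.flatnonzero(mask)
            for u in draw:  # in-bag rows with multiplicity
                in_rows.extend(rows[groups[rows] == u].tolist())
            oob_rows.extend(r for r in rows if groups[r] not in chosen)
        in_rows = np.asarray(in_rows)
        oob_rows = np.asarray(oob_rows)
        if len(oob_rows) == 0:
            continue
        Xtr, ytr = X[in_rows], labels[in_rows]
        Xte, yte = X[oob_rows], labels[oob_rows]
        if scale:
            scaler = autoscale_fit(Xtr)
            Xtr = autoscale_apply(X[in_rows], scaler)
            Xte = autoscale_apply(X[oob_rows], scaler)
        k = min(n_pcs, Xtr.shape[0] - 1, Xtr.shape[1])
        model = fit_pc_dfa(Xtr, ytr, n_pcs=k)
        pred = classify(model, Xte)
        for g in classes:
            m = yte == g
            if m.any():
                per_class_acc[g].append(100.0 * float((pred[m] == yte[m]).mean()))

    rows = []
    for g in classes:
        acc = np.asarray(per_class_acc[g])
        n_used = len(acc)
        if n_used < n_boot / 2:
            logger.warning(
                "class %r: only %d/%d bootstrap iterations usable", g, n_used, n_boot
            )
        if n_used == 0:
            rows.append((g, np.nan, np.nan, np.nan, 0))
            continue
        rows.append(
            (
                g,
                float(acc.mean()),
                float(np.percentile(acc, 2.5)),
                float(np.percentile(acc, 97.5)),
                n_used,
            )
        )
    out = pd.DataFrame(
        rows, columns=["class", "mean_correct_pct", "ci_low", "ci_high", "n_iterations"]
    ).set_index("class")
    return out


# ---------------------------------------------------------------------------
# Consensus (multi-block) PCA

@dataclass
class CPCAModel:
    """Consensus PCA over named blocks.

    In ``variables`` mode the blocks partition the columns of X (classic
    multiblock). In ``samples`` mode the blocks partition the *rows* and the
    matrix is transposed internally, so per-sample coordinates of a block
    live in that block's loadings — exposed via :meth:`sample_scores`.
    """

    mode: str
    block_names: list
    block_columns: dict             # name -> column indices (of the analysed matrix)
    block_weights: dict             # name -> 1/sqrt(K_b)
    super_scores: np.ndarray        # [n, k]
    super_weights: pd.DataFrame     # [n_blocks, k]
    block_scores: dict              # name -> [n, k]
    block_loadings: dict            # name -> [K_b, k]
    iterations: list
    residual_variance: pd.DataFrame  # per block per component

    def sample_scores(self, name: str) -> np.ndarray:
        """Per-sample coordinates of a block (sample-blocked mode)."""
        if self.mode != "samples":
            raise ValueError("sample_scores is only defined in sample-blocked mode")
        return self.block_loadings[name]


def fit_cpca(
    X: np.ndarray,
    blocks: dict,
    k: int = 2,
    mode: str = "variables",
    weighted: bool = True,
    center: bool = True,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> CPCAModel:
    """Consensus PCA by NIPALS-style iteration.

    ``blocks`` maps block name → column indices (``mode='variables'``) or
    row indices (``mode='samples'``). Per component: block loadings
    p_b = X_bᵀt/(tᵀt) (normalised), block scores t_b = X_b p_b, the score
    matrix T = [w_1 t_1 … w_B t_B] with w_b = 1/√K_b, super weights
    w = Tᵀt/(tᵀt) (normalised), new super score t = Tw; iterate until the
    super score is stable, then deflate every block by its own
    score/loading pair.
    """
    X = np.asarray(X, dtype=float)
    if mode not in ("variables", "samples"):
        raise ValueError("mode must be 'variables' or 'samples'")
    if not blocks:
        raise ValueError("no blocks given")
    work = X.T.copy() if mode == "samples" else X.copy()
    names = list(blocks)
    cols = {b: np.asarray(blocks[b], dtype=int) for b in names}
    all_cols = np.concatenate([cols[b] for b in names])
    if len(set(all_cols.tolist())) != len(all_cols) or len(all_cols) != work.shape[1]:
        raise ValueError("blocks must partition the columns exactly")
    for b in names:
        if len(cols[b]) < 2:
            raise ValueError(f"block {b!r} has fewer than 2 members")

    Xb = {b: work[:, cols[b]].copy() for b in names}
    if center:
        for b in names:
            Xb[b] = Xb[b] - Xb[b].mean(axis=0)
    wts = {b: (1.0 / np.sqrt(len(cols[b])) if weighted else 1.0) for b in names}

    n = work.shape[0]
    T_super = np.zeros((n, k))
    W_super = np.zeros((len(names), k))
    Tb = {b: np.zeros((n, k)) for b in names}
    Pb = {b: np.zeros((len(cols[b]), k)) for b in names}
    iters = []
    resid = np.zeros((len(names), k))

    for comp in range(k):
        full = np.hstack([Xb[b] for b in names])
        t = full[:, int(np.argmax(full.var(axis=0)))].copy()
        if np.linalg.norm(t) == 0:
            t = np.ones(n)
        converged = False
        for it in range(max_iter):
            tt = float(t @ t)
            if tt == 0:
                raise ConvergenceError(f"component {comp + 1}: zero super score")
            p = {}
            tb = {}
            for b in names:
                pb = Xb[b].T @ t / tt
                nrm = np.linalg.norm(pb)
                if nrm == 0:
                    raise ConvergenceError(f"component {comp + 1}: empty block {b!r}")
                pb /= nrm
                p[b] = pb
                tb[b] = Xb[b] @ pb
            T = np.column_stack([wts[b] * tb[b] for b in names])
            w = T.T @ t / tt
            w /= np.linalg.norm(w)
            t_new = T @ w
            delta = np.linalg.norm(t_new - t)
            t = t_new
            if delta <= tol * max(1.0, np.linalg.norm(t)):
                converged = True
                break
        if not converged:
            raise ConvergenceError(
                f"component {comp + 1} did not converge in {max_iter} iterations "
                f"(residual change {delta:.3e})"
            )
        iters.append(it + 1)
        # deterministic sign: largest-|.| element of the super score positive
        i = int(np.argmax(np.abs(t)))
        if t[i] < 0:
            t = -t
            w = -w
            for b in names:
                tb[b] = -tb[b]
                p[b] = -p[b]
        T_super[:, comp] = t
        W_super[:, comp] = w
        for bi, b in enumerate(names):
            Tb[b][:, comp] = tb[b]
            Pb[b][:, comp] = p[b]
            Xb[b] = Xb[b] - np.outer(tb[b], p[b])
            resid[bi, comp] = float((Xb[b] ** 2).sum())

    return CPCAModel(
        mode=mode,
        block_names=names,
        block_columns=cols,
        block_weights=wts,
        super_scores=T_super,
        super_weights=pd.DataFrame(
            W_super, index=pd.Index(names, name="block"),
            columns=[f"PC{i + 1}" for i in range(k)],
        ),
        block_scores=Tb,
        block_loadings=Pb,
        iterations=iters,
        residual_variance=pd.DataFrame(
            resid, index=pd.Index(names, name="block"),
            columns=[f"PC{i + 1}" for i in range(k)],
        ),
    )
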