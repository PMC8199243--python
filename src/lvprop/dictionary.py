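"""Fisher-discriminative dictionary learning and sparse-coding classification.

The classifier learns one sub-dictionary of unit-norm atoms per superpixel
class.  Training minimizes, over the dictionary ``D = [D_1 .. D_c]`` and the
per-class sparse codes ``X = [X_1 .. X_c]``,

    sum_i I(Y_i, D, X_i)  +  eps1 * ||X||_1  +  eps2 * f(X)

where the reconstruction/discrimination term for class ``i`` is

    I(Y_i, D, X_i) = ||Y_i - D X_i||_F^2 + ||Y_i - D_i X_i^i||_F^2
                     + sum_{j != i} ||D_j X_i^j||_F^2

(``X_i^j`` are the rows of ``X_i`` addressing sub-dictionary ``D_j``), and
the Fisher term on the codes is

    f(X) = tr(S_W(X)) - tr(S_B(X)) + ||X||_F^2

with within/between-class scatter of the code columns.  Optimization
alternates a proximal-gradient sparse-coding step per class (class means
held fixed within a step) with per-atom closed-form sub-dictionary updates;
each accepted step is guarded to keep the full objective non-increasing.

A test region ``y`` is classified by coding it on every sub-dictionary
separately,

    beta_i = argmin_b ||y - D_i b||^2 + eta1 ||b||_1 + eta2 ||b - m_i^i||^2,

and assigning the class with the smallest score
``L_i = ||y - D_i beta_i||^2 + eta1 ||beta_i||_1 + eta2 ||beta_i - m_i^i||^2``,
where ``m_i^i`` is the mean training code of class ``i`` on its own
sub-dictionary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "DiscriminativeDictionary",
    "DictionaryClassifier",
    "DivergenceError",
    "scatter_penalty",
    "objective",
    "sparse_code_class",
    "update_subdictionary",
    "train",
    "classify",
]


class DivergenceError(RuntimeError):
    """Raised when the training objective increases beyond tolerance."""


# ---------------------------------------------------------------------------
# objective pieces
# ---------------------------------------------------------------------------


def _check_finite(*arrays: np.ndarray) -> None:
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite values in input")


def _class_means(X_list: list[np.ndarray]) -> tuple[list[np.ndarray], np.ndarray]:
    means = [X.mean(axis=1) for X in X_list]
    total = sum(X.shape[1] for X in X_list)
    m = sum(X.sum(axis=1) for X in X_list) / total
    return means, m


def scatter_penalty(X_list: list[np.ndarray]) -> float:
    """Fisher code penalty f(X) = tr(S_W) - tr(S_B) + ||X||_F^2."""
    means, m = _class_means(X_list)
    sw = sum(((X - mi[:, None]) ** 2).sum() for X, mi in zip(X_list, means))
    sb = sum(
        X.shape[1] * ((mi - m) ** 2).sum() for X, mi in zip(X_list, means)
    )
    frob = sum((X**2).sum() for X in X_list)
    return float(sw - sb + frob)


def _recon_terms(
    Yi: np.ndarray, D_list: list[np.ndarray], Xi: np.ndarray, i: int
) -> float:
    D = np.hstack(D_list)
    n = D_list[0].shape[1]
    val = ((Yi - D @ Xi) ** 2).sum()
    val += ((Yi - D_list[i] @ Xi[i * n : (i + 1) * n]) ** 2).sum()
    for j, Dj in enumerate(D_list):
        if j != i:
            val += ((Dj @ Xi[j * n : (j + 1) * n]) ** 2).sum()
    return float(val)


def objective(
    Y_list: list[np.ndarray],
    D_list: list[np.ndarray],
    X_list: list[np.ndarray],
    eps1: float,
    eps2: float,
) -> float:
    """Full training objective: reconstruction + eps1*l1 + eps2*Fisher."""
    if any(Y.shape[1] == 0 for Y in Y_list):
        raise ValueError("every class must have at least one sample")
    recon = sum(
        _recon_terms(Yi, D_list, Xi, i)
        for i, (Yi, Xi) in enumerate(zip(Y_list, X_list))
    )
    l1 = sum(np.abs(X).sum() for X in X_list)
    return float(recon + eps1 * l1 + eps2 * scatter_penalty(X_list))


# ---------------------------------------------------------------------------
# proximal-gradient lasso machinery
# ---------------------------------------------------------------------------


def _soft(B: np.ndarray, t: float) -> np.ndarray:
    return np.sign(B) * np.maximum(np.abs(B) - t, 0.0)


def _ista(g_val, g_grad, B0: np.ndarray, l1: float, L0: float, n_iter: int,
          tol: float) -> np.ndarray:
    """Monotone ISTA with backtracking on the smooth majorization."""
    B = B0.copy()
    L = max(L0, 1e-8)
    gB = g_val(B)
    for _ in range(n_iter):
        G = g_grad(B)
        while True:
            Bn = _soft(B - G / L, l1 / L)
            diff = Bn - B
            gn = g_val(Bn)
            if gn <= gB + (G * diff).sum() + 0.5 * L * (diff**2).sum() + 1e-12:
                break
            L *= 2.0
            if L > 1e16:
                return B
        fold = gB + l1 * np.abs(B).sum()
        fnew = gn + l1 * np.abs(Bn).sum()
        if fnew > fold:  # numerical safety: never accept an increase
            return B
        B, gB = Bn, gn
        if fold - fnew <= tol * max(abs(fold), 1.0):
            break
        L *= 0.9
    return B


def sparse_code_class(
    Yi: np.ndarray,
    D_list: list[np.ndarray],
    i: int,
    eps1: float,
    eps2: float,
    mi: np.ndarray | None = None,
    Xi0: np.ndarray | None = None,
    n_iter: int = 60,
    tol: float = 1e-9,
) -> np.ndarray:
    """Sparse-coding step for class ``i`` with the other classes fixed.

    Minimizes ``I(Y_i, D, X_i) + eps1||X_i||_1 + eps2 f_i(X_i)`` where the
    per-class Fisher surrogate is
    ``f_i(X_i) = ||X_i - m_i||_F^2 + ||X_i||_F^2`` (the between-class part
    is constant for fixed means).  ``mi`` is the class-i code mean held
    fixed during the step (zeros if omitted).  Proximal gradient with
    backtracking guarantees the step objective does not increase.
    """
    _check_finite(Yi, *D_list)
    c = len(D_list)
    n = D_list[0].shape[1]
    cn = c * n
    ni = Yi.shape[1]
    D = np.hstack(D_list)
    if mi is None:
        mi = np.zeros(cn)
    Mi = mi[:, None]
    if Xi0 is None:
        Xi0 = np.zeros((cn, ni))

    DtD = D.T @ D
    DtY = D.T @ Yi
    grams = [Dj.T @ Dj for Dj in D_list]
    DtYi = D_list[i].T @ Yi

    def blocks(X):
        return [X[j * n : (j + 1) * n] for j in range(c)]

    def g_val(X):
        val = ((Yi - D @ X) ** 2).sum()
        Xb = blocks(X)
        val += ((Yi - D_list[i] @ Xb[i]) ** 2).sum()
        for j in range(c):
            if j != i:
                val += ((D_list[j] @ Xb[j]) ** 2).sum()
        val += eps2 * (((X - Mi) ** 2).sum() + (X**2).sum())
        return float(val)

    def g_grad(X):
        G = 2.0 * (DtD @ X - DtY)
        Xb = blocks(X)
        for j in range(c):
            add = 2.0 * (grams[j] @ Xb[j])
            if j == i:
                add -= 2.0 * DtYi
            G[j * n : (j + 1) * n] += add
        G += 2.0 * eps2 * (2.0 * X - Mi)
        return G

    smax = np.linalg.norm(D, 2) ** 2
    bmax = max(np.linalg.norm(Dj, 2) ** 2 for Dj in D_list)
    L0 = 2.0 * (smax + bmax + 2.0 * eps2)
    return _ista(g_val, g_grad, Xi0, eps1, L0, n_iter, tol)


# ---------------------------------------------------------------------------
# dictionary update
# ---------------------------------------------------------------------------


def _block_rows(X: np.ndarray, j: int, n: int) -> np.ndarray:
    return X[j * n : (j + 1) * n]


def update_subdictionary(
    Y_list: list[np.ndarray],
    D_list: list[np.ndarray],
    X_list: list[np.ndarray],
    i: int,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Per-atom closed-form update of sub-dictionary ``D_i`` with codes fixed.

    Minimizes ``||Y - D_i X^i - sum_{j!=i} D_j X^j||_F^2 +
    ||Y_i - D_i X_i^i||_F^2 + sum_{j!=i} ||D_i X_j^i||_F^2`` atom by atom
    over the residual.  Updated atoms are renormalized to unit norm and the
    corresponding block-``i`` code rows rescaled compensatorily, which keeps
    every ``D_i``-times-code product unchanged.  Dead atoms (all-zero code
    row) are re-seeded from the training column with the largest current
    reconstruction residual.

    Returns the new ``D_i`` and the (rescaled) code list.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    c = len(D_list)
    n = D_list[0].shape[1]
    Y_all = np.hstack(Y_list)
    X_all = np.hstack(X_list)
    Yi = Y_list[i]
    Di = D_list[i].copy()
    X_list = [X.copy() for X in X_list]

    # residual with the other sub-dictionaries' contribution removed
    R = Y_all - sum(
        D_list[j] @ _block_rows(X_all, j, n) for j in range(c) if j != i
    )
    # stacked least-squares targets / codes for the three Eq terms:
    # global residual fit, own-class discrimination fit, cross-class shrink
    T_parts = [R, Yi] + [
        np.zeros_like(Y_list[j]) for j in range(c) if j != i
    ]
    C_parts = [_block_rows(np.hstack(X_list), i, n),
               _block_rows(X_list[i], i, n)] + [
        _block_rows(X_list[j], i, n) for j in range(c) if j != i
    ]
    T = np.hstack(T_parts)

    def stacked_codes():
        return np.hstack(
            [_block_rows(np.hstack(X_list), i, n),
             _block_rows(X_list[i], i, n)]
            + [_block_rows(X_list[j], i, n) for j in range(c) if j != i]
        )

    for k in range(n):
        C = stacked_codes()
        ck = C[k]
        cc = float(ck @ ck)
        if cc < 1e-12:
            # dead atom: re-seed from the worst-reconstructed training column
            D_full = np.hstack(
                [Di if j == i else D_list[j] for j in range(c)]
            )
            resid = Y_all - D_full @ X_all
            col = int(np.argmax((resid**2).sum(axis=0)))
            v = Y_all[:, col]
            nv = np.linalg.norm(v)
            Di[:, k] = v / nv if nv > 1e-12 else _rand_unit(rng, Di.shape[0])
            continue
        E = T - Di @ C + np.outer(Di[:, k], ck)
        dk = E @ ck / cc
        norm = float(np.linalg.norm(dk))
        if norm < 1e-12:
            D_full = np.hstack(
                [Di if j == i else D_list[j] for j in range(c)]
            )
            resid = Y_all - D_full @ X_all
            col = int(np.argmax((resid**2).sum(axis=0)))
            v = Y_all[:, col]
            nv = np.linalg.norm(v)
            Di[:, k] = v / nv if nv > 1e-12 else _rand_unit(rng, Di.shape[0])
            continue
        Di[:, k] = dk / norm
        # compensatory rescale of block-i code row k across all classes
        for Xj in X_list:
            Xj[i * n + k] *= norm
        X_all = np.hstack(X_list)
    return Di, X_list


def _rand_unit(rng: np.random.Generator, d: int) -> np.ndarray:
    v = rng.standard_normal(d)
    return v / np.linalg.norm(v)


def eq7_value(
    Y_list: list[np.ndarray],
    D_list: list[np.ndarray],
    X_list: list[np.ndarray],
    i: int,
) -> float:
    """Value of the class-i sub-dictionary objective (used by descent tests)."""
    c = len(D_list)
    n = D_list[0].shape[1]
    Y_all = np.hstack(Y_list)
    X_all = np.hstack(X_list)
    val = ((Y_all - sum(D_list[j] @ _block_rows(X_all, j, n)
                        for j in range(c))) ** 2).sum()
    val += ((Y_list[i] - D_list[i] @ _block_rows(X_list[i], i, n)) ** 2).sum()
    for j in range(c):
        if j != i:
            val += ((D_list[i] @ _block_rows(X_list[j], i, n)) ** 2).sum()
    return float(val)


# ---------------------------------------------------------------------------
# training and classification
# ---------------------------------------------------------------------------


@dataclass
class DiscriminativeDictionary:
    """Trained model: per-class sub-dictionaries and mean own-block codes."""

    sub_dictionaries: list[np.ndarray]  # each d x n_atoms, unit-norm atoms
    class_code_means: list[np.ndarray]  # m_i^i, each length n_atoms
    eps1: float
    eps2: float
    eta1: float
    eta2: float
    objective_history: list[float] = field(default_factory=list)

    @property
    def n_classes(self) -> int:
        return len(self.sub_dictionaries)

    @property
    def n_atoms(self) -> int:
        return self.sub_dictionaries[0].shape[1]


def train(
    Y_list: list[np.ndarray],
    n_atoms: int = 32,
    eps1: float = 0.1,
    eps2: float = 0.001,
    eta1: float = 0.1,
    eta2: float = 0.005,
    max_iter: int = 50,
    tol: float = 1e-4,
    code_iter: int = 60,
    seed: int = 0,
) -> DiscriminativeDictionary:
    """Alternating training of the discriminative dictionary.

    ``Y_list`` holds one ``d x n_i`` sample matrix per class.  Atoms are
    initialized from randomly selected class samples; the loop alternates
    the per-class sparse-coding step and the per-class sub-dictionary update
    until the relative objective change drops below ``tol`` or ``max_iter``
    outer iterations.  Every step is accepted only if the full objective
    does not increase, so the recorded history is non-increasing; a genuine
    increase beyond tolerance raises :class:`DivergenceError`.
    """
    rng = np.random.default_rng(seed)
    c = len(Y_list)
    Y_list = [np.asarray(Y, dtype=float) for Y in Y_list]
    _check_finite(*Y_list)
    d = Y_list[0].shape[0]
    for i, Yi in enumerate(Y_list):
        if Yi.shape[1] < n_atoms:
            raise ValueError(
                f"class {i} has {Yi.shape[1]} samples < n_atoms={n_atoms}"
            )

    D_list = []
    for Yi in Y_list:
        cols = rng.choice(Yi.shape[1], size=n_atoms, replace=False)
        Di = Yi[:, cols].copy()
        for k in range(n_atoms):
            nv = np.linalg.norm(Di[:, k])
            Di[:, k] = Di[:, k] / nv if nv > 1e-12 else _rand_unit(rng, d)
        D_list.append(Di)
    X_list = [np.zeros((c * n_atoms, Yi.shape[1])) for Yi in Y_list]

    obj = objective(Y_list, D_list, X_list, eps1, eps2)
    history = [obj]
    for _ in range(max_iter):
        prev = obj
        # sparse-coding sweep, means refreshed before each class step
        for i in range(c):
            means, _ = _class_means(X_list)
            Xi_new = sparse_code_class(
                Y_list[i], D_list, i, eps1, eps2,
                mi=means[i], Xi0=X_list[i], n_iter=code_iter,
            )
            cand = X_list[: i] + [Xi_new] + X_list[i + 1 :]
            val = objective(Y_list, D_list, cand, eps1, eps2)
            if val <= obj + 1e-12:
                X_list, obj = cand, val
        # sub-dictionary sweep
        for i in range(c):
            Di_new, X_new = update_subdictionary(Y_list, D_list, X_list, i, rng)
            cand_D = D_list[: i] + [Di_new] + D_list[i + 1 :]
            val = objective(Y_list, cand_D, X_new, eps1, eps2)
            if val <= obj + 1e-12:
                D_list, X_list, obj = cand_D, X_new, val
        history.append(obj)
        if obj > prev + 1e-6 * max(abs(prev), 1.0):
            raise DivergenceError(
                f"objective increased {prev:.6g} -> {obj:.6g}"
            )
        if prev - obj <= tol * max(abs(prev), 1e-12):
            break

    code_means = [
        _block_rows(X_list[i], i, n_atoms).mean(axis=1) for i in range(c)
    ]
    return DiscriminativeDictionary(
        sub_dictionaries=D_list,
        class_code_means=code_means,
        eps1=eps1,
        eps2=eps2,
        eta1=eta1,
        eta2=eta2,
        objective_history=history,
    )


def _code_on_subdict(
    y: np.ndarray, Di: np.ndarray, mu: np.ndarray, eta1: float, eta2: float,
    n_iter: int = 200,
) -> np.ndarray:
    """Solve beta = argmin ||y - Di b||^2 + eta1 |b|_1 + eta2 ||b - mu||^2."""
    DtD = Di.T @ Di
    Dty = Di.T @ y

    def g_val(b):
        r = y - Di @ b[:, 0]
        return float(r @ r + eta2 * ((b[:, 0] - mu) ** 2).sum())

    def g_grad(b):
        return 2.0 * (DtD @ b - Dty[:, None]) + 2.0 * eta2 * (b - mu[:, None])

    L0 = 2.0 * (np.linalg.norm(Di, 2) ** 2 + eta2)
    b = _ista(g_val, g_grad, np.zeros((Di.shape[1], 1)), eta1, L0, n_iter,
              1e-12)
    return b[:, 0]


def classify(
    y: np.ndarray,
    model: DiscriminativeDictionary,
    eta1: float | None = None,
    eta2: float | None = None,
) -> tuple[int, np.ndarray, list[np.ndarray]]:
    """Classify one feature vector against every sub-dictionary.

    Returns ``(label, scores, codes)`` where ``label`` is the index of the
    smallest score (ties broken toward the lowest class index).
    """
    y = np.asarray(y, dtype=float)
    _check_finite(y)
    eta1 = model.eta1 if eta1 is None else eta1
    eta2 = model.eta2 if eta2 is None else eta2
    scores = np.empty(model.n_classes)
    codes = []
    for i, (Di, mu) in enumerate(
        zip(model.sub_dictionaries, model.class_code_means)
    ):
        b = _code_on_subdict(y, Di, mu, eta1, eta2)
        r = y - Di @ b
        scores[i] = (
            r @ r + eta1 * np.abs(b).sum() + eta2 * ((b - mu) ** 2).sum()
        )
        codes.append(b)
    return int(np.argmin(scores)), scores, codes


class DictionaryClassifier(BaseEstimator, ClassifierMixin):
    """sklearn-style front end for the discriminative-dictionary classifier.

    Parameters mirror the method's defaults: ``eps1``/``eps2`` weight the
    l1 and Fisher penalties during training, ``eta1``/``eta2`` the l1 and
    mean-code penalties at test time.

    Attributes (after ``fit``): ``classes_``, ``model_`` (the trained
    :class:`DiscriminativeDictionary`), ``objective_history_``.
    """

    def __init__(
        self,
        n_atoms: int = 32,
        eps1: float = 0.1,
        eps2: float = 0.001,
        eta1: float = 0.1,
        eta2: float = 0.005,
        max_iter: int = 50,
        tol: float = 1e-4,
        code_iter: int = 60,
        random_state: int = 0,
    ):
        self.n_atoms = n_atoms
        self.eps1 = eps1
        self.eps2 = eps2
        self.eta1 = eta1
        self.eta2 = eta2
        self.max_iter = max_iter
        self.tol = tol
        self.code_iter = code_iter
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "DictionaryClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_samples, n_features) aligned with y")
        _check_finite(X)
        self.classes_ = np.unique(y)
        Y_list = [X[y == cls].T for cls in self.classes_]
        self.model_ = train(
            Y_list,
            n_atoms=self.n_atoms,
            eps1=self.eps1,
            eps2=self.eps2,
            eta1=self.eta1,
            eta2=self.eta2,
            max_iter=self.max_iter,
            tol=self.tol,
            code_iter=self.code_iter,
            seed=self.random_state,
        )
        self.objective_history_ = self.model_.objective_history
        return self

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Per-class scores L_i (lower is better), shape (n_samples, c)."""
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        _check_finite(X)
        m = self.model_
        Yt = X.T  # (d, N)
        scores = np.empty((X.shape[0], m.n_classes))
        for i, (Di, mu) in enumerate(
            zip(m.sub_dictionaries, m.class_code_means)
        ):
            # batched variant of the per-sample coding problem
            DtD = Di.T @ Di
            DtY = Di.T @ Yt
            Mu = mu[:, None]

            def g_val(B):
                R = Yt - Di @ B
                return float((R**2).sum() + m.eta2 * ((B - Mu) ** 2).sum())

            def g_grad(B):
                return 2.0 * (DtD @ B - DtY) + 2.0 * m.eta2 * (B - Mu)

            L0 = 2.0 * (np.linalg.norm(Di, 2) ** 2 + m.eta2)
            B = _ista(g_val, g_grad, np.zeros((Di.shape[1], X.shape[0])),
                      m.eta1, L0, 200, 1e-12)
            R = Yt - Di @ B
            scores[:, i] = (
                (R**2).sum(axis=0)
                + m.eta1 * np.abs(B).sum(axis=0)
                + m.eta2 * ((B - Mu) ** 2).sum(axis=0)
            )
        return scores

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_scores(X)
        return self.classes_[np.argmin(scores, axis=1)]
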