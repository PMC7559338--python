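"""Scale-free-constrained k-SVD (sf k-SVD) dictionary learning.

Decomposes an expression matrix ``Y`` (n samples x p genes) as ``Y ~ D X``
where the columns of ``D`` (n x l) are unit-norm *atomic regulators* — hidden
basic regulatory signals — and ``X`` (l x p) holds sparse per-gene regulation
coefficients. Sparsity is controlled per gene: column i of ``X`` may use at
most ``t_i`` atoms, with the budgets ``t_i`` drawn from a discrete power law
``P(t) ∝ t^-lambda`` so that the implied regulator-to-gene network is
scale-free. The fit alternates orthogonal greedy pursuit (OMP) over the gene
columns with the standard k-SVD rank-1 atom update.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .utils import as_rng

__all__ = [
    "SparsityProfile",
    "FitTrace",
    "sample_sparsity_profile",
    "sparse_code",
    "update_dictionary",
    "fit_dictionary",
    "rmse",
    "ScaleFreeKSVD",
]

# atoms more coherent than this are considered duplicates and one is revived
DUPLICATE_COHERENCE = 0.999
_ZERO_NORM = 1e-12


@dataclass
class SparsityProfile:
    """Per-gene l0 budgets drawn from a truncated power law."""

    budgets: np.ndarray
    lambda_exp: float
    t_min: int
    t_max: int

    def __post_init__(self):
        self.budgets = np.asarray(self.budgets, dtype=int)
        if self.budgets.min(initial=self.t_min) < self.t_min or self.budgets.max(
            initial=self.t_max
        ) > self.t_max:
            raise ValueError("budgets outside [t_min, t_max]")

    def __len__(self) -> int:
        return len(self.budgets)


@dataclass
class FitTrace:
    """Reconstruction-error trace of an alternating fit."""

    rmse_per_iteration: np.ndarray
    iterations_run: int
    converged: bool

    def __post_init__(self):
        self.rmse_per_iteration = np.asarray(self.rmse_per_iteration, dtype=float)
        if len(self.rmse_per_iteration) != self.iterations_run:
            raise ValueError("trace length must equal iterations_run")


def power_law_pmf(t_min: int, t_max: int, lambda_exp: float) -> tuple[np.ndarray, np.ndarray]:
    """Support and probabilities of the truncated law ``P(t) ∝ t^-lambda``."""
    if t_min > t_max:
        raise ValueError(f"invalid bounds: t_min={t_min} > t_max={t_max}")
    if t_min < 1:
        raise ValueError("t_min must be >= 1")
    if lambda_exp <= 0:
        raise ValueError(f"invalid exponent: lambda_exp={lambda_exp} must be > 0")
    support = np.arange(t_min, t_max + 1)
    weights = support.astype(float) ** (-lambda_exp)
    return support, weights / weights.sum()


def sample_sparsity_profile(
    p: int,
    lambda_exp: float = 3.0,
    t_min: int = 2,
    t_max: int = 6,
    random_state=None,
) -> SparsityProfile:
    """Draw p per-gene sparsity budgets from ``P(t) ∝ t^-lambda`` on {t_min..t_max}.

    The power-law prior mirrors the in-degree distribution of real regulatory
    networks: most genes are controlled by few regulators, a heavy tail by
    many. Defaults lambda=3 and t in {2..6}.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    support, probs = power_law_pmf(t_min, t_max, lambda_exp)
    rng = as_rng(random_state)
    budgets = rng.choice(support, size=p, p=probs)
    return SparsityProfile(budgets=budgets, lambda_exp=lambda_exp, t_min=t_min, t_max=t_max)


def _column_sq_residuals(Y: np.ndarray, D: np.ndarray, X: np.ndarray) -> np.ndarray:
    R = Y - D @ X
    return np.einsum("ij,ij->j", R, R)


def _batch_omp(G: np.ndarray, A0: np.ndarray, budgets: np.ndarray) -> np.ndarray:
    """Orthogonal greedy pursuit of many columns at once, in the Gram domain.

    ``G = D.T D`` (unit-norm atoms), ``A0 = D.T Y``. At each step every
    still-active column selects the atom with maximal absolute inner product
    with its current residual, then its coefficients are re-fit by least
    squares on the selected support (batched normal-equation solves). A
    column goes inactive once its budget is exhausted or its residual is
    orthogonal to all atoms.
    """
    l, p = A0.shape
    t_max = int(budgets.max(initial=0))
    X = np.zeros((l, p))
    if t_max == 0 or p == 0:
        return X
    supports = np.zeros((p, t_max), dtype=np.int64)
    A = A0.copy()                       # correlations of atoms with residuals
    active = np.arange(p)
    coefs = None
    for step in range(t_max):
        corr = np.abs(A[:, active])
        if step:
            # residual is orthogonal to selected atoms; exclude them anyway
            # to guard against rounding
            np.put_along_axis(corr, supports[active, :step].T, -1.0, axis=0)
        best = np.argmax(corr, axis=0)
        alive = corr[best, np.arange(active.size)] > 1e-12
        if step:
            # freeze columns whose residual no longer correlates with any atom
            for_keep = active[~alive]
            if for_keep.size:
                X[supports[for_keep, :step].T, for_keep] = coefs[~alive, :step].T
        active = active[alive]
        if active.size == 0:
            break
        supports[active, step] = best[alive]
        S = supports[active, : step + 1]                    # (m, s)
        Gs = G[S[:, :, None], S[:, None, :]]                # (m, s, s)
        b = A0[S, active[:, None]]                          # (m, s)
        eye = np.eye(step + 1)
        try:
            coefs = np.linalg.solve(Gs, b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            coefs = np.linalg.solve(Gs + 1e-10 * eye, b[..., None])[..., 0]
        # updated residual correlations: A = A0 - G[:, S] @ coefs
        A[:, active] = A0[:, active] - np.einsum("msl,ms->lm", G[S], coefs)
        done = budgets[active] <= step + 1
        if done.any():
            fin = active[done]
            X[supports[fin, : step + 1].T, fin] = coefs[done].T
            active = active[~done]
            coefs = coefs[~done]
        if active.size == 0:
            break
    else:
        active = np.array([], dtype=np.int64)
    if active.size:
        X[supports[active, :t_max].T, active] = coefs.T
    return X


def sparse_code(
    Y: np.ndarray,
    D: np.ndarray,
    t: SparsityProfile | np.ndarray,
    X_prev: np.ndarray | None = None,
) -> np.ndarray:
    """Orthogonal greedy pursuit of each gene column under its own l0 budget.

    Each column y_i is approximated by at most t_i dictionary atoms: atoms are
    selected one at a time by maximal absolute inner product with the current
    residual and the coefficients re-fit by least squares on the selected
    support (orthogonal matching pursuit). Budgets are capped at the sample
    count, since more atoms than ambient dimensions cannot reduce the residual.

    If ``X_prev`` is given, a column keeps its previous code whenever that
    reconstructs it better under the current dictionary than the fresh greedy
    code; this makes the coding stage of the alternating fit non-increasing
    in reconstruction error.
    """
    Y = np.asarray(Y, dtype=float)
    D = np.asarray(D, dtype=float)
    budgets = t.budgets if isinstance(t, SparsityProfile) else np.asarray(t, dtype=int)
    n, p = Y.shape
    if D.shape[0] != n:
        raise ValueError(f"shape mismatch: Y has {n} rows but D has {D.shape[0]}")
    if len(budgets) != p:
        raise ValueError("one budget per gene column is required")
    l = D.shape[1]

    gram = D.T @ D
    Xy = D.T @ Y
    X = np.zeros((l, p))
    col_norms = np.einsum("ij,ij->j", Y, Y)
    nonzero = col_norms > _ZERO_NORM

    # budgets capped at the ambient dimension; zero columns skipped
    eff = np.where(nonzero, np.minimum(budgets, min(n, l)), 0)
    X[:, :] = _batch_omp(gram, Xy, eff)

    if X_prev is not None:
        r_new = _column_sq_residuals(Y, D, X)
        r_old = _column_sq_residuals(Y, D, X_prev)
        keep = r_old < r_new
        if keep.any():
            X[:, keep] = X_prev[:, keep]
    return X


def _revive_atom(Y: np.ndarray, D: np.ndarray, X: np.ndarray, j: int, rng) -> None:
    """Replace a dead/duplicate atom by the worst-reconstructed data column."""
    sq = _column_sq_residuals(Y, D, X)
    cand = Y[:, int(np.argmax(sq))].copy()
    nrm = np.linalg.norm(cand)
    if nrm < _ZERO_NORM:
        cand = rng.standard_normal(Y.shape[0])
        nrm = np.linalg.norm(cand)
    D[:, j] = cand / nrm


def _update_atom(Y: np.ndarray, D: np.ndarray, X: np.ndarray, j: int, rng) -> None:
    """In-place k-SVD rank-1 update of atom j and its coefficient row."""
    users = np.flatnonzero(X[j])
    if users.size == 0:
        _revive_atom(Y, D, X, j, rng)
        return
    # restricted error matrix with atom j's contribution removed
    E = Y[:, users] - D @ X[:, users] + np.outer(D[:, j], X[j, users])
    U, s, Vt = np.linalg.svd(E, full_matrices=False)
    atom = U[:, 0]
    coefs = s[0] * Vt[0]
    # fix SVD sign so the dominant coefficient is positive
    if coefs[np.argmax(np.abs(coefs))] < 0:
        atom, coefs = -atom, -coefs
    D[:, j] = atom
    X[j, users] = coefs


def update_dictionary(
    Y: np.ndarray,
    D: np.ndarray,
    X: np.ndarray,
    atom_index: int,
    random_state=None,
) -> tuple[np.ndarray, np.ndarray]:
    """k-SVD update of one atom; returns updated copies of (D, X).

    Restricted to the gene columns whose support contains ``atom_index``, the
    atom and its coefficient row are replaced by the leading singular pair of
    the reconstruction-error matrix computed with the atom removed. Supports
    never change and the total squared error never increases. An atom used by
    no column is revived as the worst-reconstructed data column, normalized.
    """
    D = np.array(D, dtype=float)
    X = np.array(X, dtype=float)
    if not 0 <= atom_index < D.shape[1]:
        raise IndexError(f"atom_index {atom_index} out of range")
    if Y.shape[0] != D.shape[0] or D.shape[1] != X.shape[0] or X.shape[1] != Y.shape[1]:
        raise ValueError("inconsistent shapes among Y, D, X")
    _update_atom(np.asarray(Y, float), D, X, atom_index, as_rng(random_state))
    return D, X


def rmse(Y: np.ndarray, D: np.ndarray, X: np.ndarray) -> float:
    """Root-mean-squared reconstruction error sqrt(||Y - DX||_F^2 / (n p))."""
    Y = np.asarray(Y, float)
    if Y.shape[0] != D.shape[0] or D.shape[1] != X.shape[0] or X.shape[1] != Y.shape[1]:
        raise ValueError("inconsistent shapes among Y, D, X")
    return float(np.sqrt(np.mean((Y - D @ X) ** 2)))


def _init_dictionary(Y: np.ndarray, l: int, rng) -> np.ndarray:
    """Seed atoms with l distinct data columns (normalized), pad randomly."""
    n, p = Y.shape
    norms = np.linalg.norm(Y, axis=0)
    usable = np.flatnonzero(norms > _ZERO_NORM)
    n_cols = min(l, usable.size)
    chosen = rng.choice(usable, size=n_cols, replace=False) if n_cols else np.array([], int)
    D = np.empty((n, l))
    if n_cols:
        D[:, :n_cols] = Y[:, chosen] / norms[chosen]
    for j in range(n_cols, l):
        v = rng.standard_normal(n)
        D[:, j] = v / np.linalg.norm(v)
    return D


def _duplicate_guard(Y: np.ndarray, D: np.ndarray, X: np.ndarray, rng) -> None:
    """Re-initialize near-duplicate atoms, folding their load onto the twin.

    If |<d_j, d_k>| exceeds the coherence threshold, atom k's coefficients are
    folded into atom j's row (supports can only shrink, so budgets still hold)
    and atom k is revived from the worst-reconstructed column.
    """
    G = D.T @ D
    l = G.shape[0]
    iu, ju = np.triu_indices(l, k=1)
    dup = np.abs(G[iu, ju]) > DUPLICATE_COHERENCE
    for j, k in zip(iu[dup], ju[dup]):
        if np.abs(G[j, k]) <= DUPLICATE_COHERENCE:  # may have been revived already
            continue
        sign = np.sign(G[j, k]) or 1.0
        X[j] += sign * X[k]
        X[k] = 0.0
        _revive_atom(Y, D, X, int(k), rng)
        G[k, :] = D[:, k] @ D
        G[:, k] = G[k, :]


def fit_dictionary(
    Y: np.ndarray,
    l: int,
    t: SparsityProfile | np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-4,
    random_state=None,
) -> tuple[np.ndarray, np.ndarray, FitTrace]:
    """Alternate sparse coding and atom updates until the RMSE stabilizes.

    Stops at the first iteration where the RMSE changes by less than ``tol``
    (compared against the zero-reconstruction RMSE before the first
    iteration), or after ``max_iter`` iterations with ``converged=False``.
    """
    Y = np.asarray(Y, dtype=float)
    n, p = Y.shape
    if l < 1 or l > n * p:
        raise ValueError(f"invalid atom count l={l}")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if tol < 0:
        raise ValueError("tol must be >= 0")
    budgets = t.budgets if isinstance(t, SparsityProfile) else np.asarray(t, int)
    rng = as_rng(random_state)

    D = _init_dictionary(Y, l, rng)
    X_prev = None
    r_prev = float(np.sqrt(np.mean(Y**2)))
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        X = sparse_code(Y, D, budgets, X_prev=X_prev)
        for j in range(l):
            _update_atom(Y, D, X, j, rng)
        r_it = rmse(Y, D, X)
        trace.append(r_it)
        if abs(r_prev - r_it) < tol:
            converged = True
            break
        r_prev = r_it
        _duplicate_guard(Y, D, X, rng)
        X_prev = X
    return D, X, FitTrace(np.array(trace), len(trace), converged)


class ScaleFreeKSVD(TransformerMixin, BaseEstimator):
    """Dictionary learning of atomic regulators under scale-free sparsity.

    Parameters
    ----------
    n_atoms : int
        Number of atomic regulators l to learn; ideally close to the number
        of real regulators underlying the data.
    lambda_exp, t_min, t_max : power-law exponent and support of the per-gene
        sparsity budgets P(t) ∝ t^-lambda.
    max_iter, tol : stopping rule on the RMSE trace.
    n_restarts : int
        Independent seeded fits to run; the one with the lowest final
        reconstruction RMSE is kept. The objective is non-convex and
        restarts are the standard guard against poor local minima.
    center : bool
        Center each gene column before fitting (the model's noise is
        zero-mean and downstream correlation scoring is location-invariant).
    budgets : array-like of int, optional
        Explicit per-gene budgets; overrides the power-law sampler.
    random_state : int, Generator or None.

    Attributes
    ----------
    dictionary_ : ndarray (n_samples, n_atoms), unit-norm columns.
    coefficients_ : ndarray (n_atoms, n_genes), per-column l0-sparse.
    budgets_ : ndarray of int, the sparsity budgets used.
    trace_ : FitTrace. n_iter_ : int. converged_ : bool.
    mean_ : per-gene means subtracted before fitting (zeros if center=False).
    """

    def __init__(
        self,
        n_atoms: int = 50,
        lambda_exp: float = 3.0,
        t_min: int = 2,
        t_max: int = 6,
        max_iter: int = 200,
        tol: float = 1e-4,
        n_restarts: int = 1,
        center: bool = True,
        budgets=None,
        random_state=None,
    ):
        self.n_atoms = n_atoms
        self.lambda_exp = lambda_exp
        self.t_min = t_min
        self.t_max = t_max
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.center = center
        self.budgets = budgets
        self.random_state = random_state

    def fit(self, X, y=None):
        """Learn the atomic-regulator dictionary from samples x genes data."""
        Y = check_array(X, dtype=float, ensure_min_samples=2)
        n, p = Y.shape
        rng = as_rng(self.random_state)
        if self.budgets is not None:
            budgets = np.asarray(self.budgets, dtype=int)
            if len(budgets) != p:
                raise ValueError("budgets length must equal the gene count")
        else:
            budgets = sample_sparsity_profile(
                p, self.lambda_exp, self.t_min, self.t_max, random_state=rng
            ).budgets
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        self.mean_ = Y.mean(axis=0) if self.center else np.zeros(p)
        best = None
        for _ in range(self.n_restarts):
            fit = fit_dictionary(
                Y - self.mean_, self.n_atoms, budgets,
                max_iter=self.max_iter, tol=self.tol, random_state=rng,
            )
            if best is None or fit[2].rmse_per_iteration[-1] < best[2].rmse_per_iteration[-1]:
                best = fit
        D, C, trace = best
        self.dictionary_ = D
        self.coefficients_ = C
        self.budgets_ = budgets
        self.trace_ = trace
        self.n_iter_ = trace.iterations_run
        self.converged_ = trace.converged
        self.n_features_in_ = p
        return self

    def transform(self, X):
        """Sparse-code gene columns against the learned dictionary.

        Returns the coefficient matrix transposed to (n_genes, n_atoms) so
        each row gives a gene's loadings on the atomic regulators.
        """
        check_is_fitted(self, "dictionary_")
        Y = check_array(X, dtype=float)
        if Y.shape[0] != self.dictionary_.shape[0]:
            raise ValueError("sample count differs from the fitted dictionary")
        budgets = sample_sparsity_profile(
            Y.shape[1], self.lambda_exp, self.t_min, self.t_max,
            random_state=self.random_state,
        ).budgets
        C = sparse_code(Y - Y.mean(axis=0) if self.center else Y, self.dictionary_, budgets)
        return C.T

    def reconstruction_rmse(self, X) -> float:
        check_is_fitted(self, "dictionary_")
        Y = check_array(X, dtype=float)
        return rmse(Y - self.mean_, self.dictionary_, self.coefficients_)
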