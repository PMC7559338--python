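"""Regulator -> target-gene edge scoring from a fitted atomic-regulator model.

Given a learned dictionary D of atomic regulators and sparse coefficients X,
the confidence that a known regulator (a TF expression profile, or a DNA
methylation profile) regulates gene g is the alpha-quantile of the absolute
correlations between the regulator's profile and the atoms associated with g
(the non-zero rows of g's coefficient column). A resampling wrapper re-runs
the whole pipeline on random sample subsets and averages the scores, which
stabilizes inference at small sample sizes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .sfksvd import ScaleFreeKSVD
from .utils import as_rng, spawn_seeds

__all__ = [
    "ARAssociation",
    "InferenceConfig",
    "associated_ars",
    "correlation_profile",
    "confidence_score",
    "score_matrix",
    "score_all",
    "resampled_inference",
    "permutation_test",
    "GRNInference",
]


@dataclass
class ARAssociation:
    """The atoms associated with one target gene (its non-zero coefficients)."""

    gene: object
    ar_indices: tuple[int, ...]

    @property
    def n_g(self) -> int:
        return len(self.ar_indices)


@dataclass
class InferenceConfig:
    """Tunables of the edge-scoring pipeline.

    alpha: quantile cutoff on |correlation| (0.9 by default; larger alpha is
    more sensitive). subsample_fraction and n_resamples drive the resampling
    wrapper (defaults: keep 75% of samples per run — i.e. hold 25% out —
    and N = 2n runs).
    """

    alpha: float = 0.9
    correlation_method: str = "pearson"
    subsample_fraction: float = 0.75
    n_resamples: int | None = None  # None -> 2 * n at run time
    seed: int | None = None

    def __post_init__(self):
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must lie in (0, 1]")
        if self.n_resamples is not None and self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if self.correlation_method not in ("pearson", "spearman"):
            raise ValueError("correlation_method must be 'pearson' or 'spearman'")


def associated_ars(X: np.ndarray, gene, gene_ids=None) -> ARAssociation:
    """Atoms with a non-zero coefficient for ``gene``, in row order.

    ``gene`` may be a column index, or an identifier if ``gene_ids`` is given.
    """
    X = np.asarray(X)
    if gene_ids is not None:
        try:
            col = list(gene_ids).index(gene)
        except ValueError:
            raise KeyError(f"unknown gene: {gene!r}") from None
    else:
        col = int(gene)
        if not 0 <= col < X.shape[1]:
            raise KeyError(f"gene column {gene} out of range")
    return ARAssociation(gene=gene, ar_indices=tuple(np.flatnonzero(X[:, col]).tolist()))


def _standardize_columns(M: np.ndarray, method: str) -> np.ndarray:
    """Z-score columns (after ranking, for Spearman); constant columns -> 0."""
    M = np.asarray(M, dtype=float)
    if method == "spearman":
        M = rankdata(M, axis=0).astype(float)
    Z = M - M.mean(axis=0)
    sd = Z.std(axis=0)
    ok = sd > 1e-12
    Z[:, ok] /= sd[ok]
    Z[:, ~ok] = 0.0  # constant profiles carry no correlation information
    return Z


def correlation_profile(
    reg_profile: np.ndarray,
    D: np.ndarray,
    assoc: ARAssociation,
    method: str = "pearson",
) -> np.ndarray:
    """|correlation| between one regulator profile and each associated atom."""
    reg_profile = np.asarray(reg_profile, dtype=float).ravel()
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if reg_profile.shape[0] != n:
        raise ValueError("profile length must equal the sample count")
    if n < 3:
        raise ValueError("insufficient samples: need n >= 3 for correlation")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    if assoc.n_g == 0:
        return np.empty(0)
    z_r = _standardize_columns(reg_profile[:, None], method)[:, 0]
    z_d = _standardize_columns(D[:, list(assoc.ar_indices)], method)
    return np.minimum(np.abs(z_r @ z_d) / n, 1.0)


def confidence_score(abs_corrs: np.ndarray, alpha: float = 0.9) -> float:
    """Empirical alpha-quantile of the |correlation| values (0 if none).

    Linear interpolation between order statistics (the type-7 convention).
    An empty vector — a gene with no associated atoms — scores 0: no atom
    evidence, no regulation signal.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    abs_corrs = np.asarray(abs_corrs, dtype=float)
    if abs_corrs.size == 0:
        return 0.0
    return float(np.quantile(abs_corrs, alpha))


def score_matrix(
    D: np.ndarray,
    X: np.ndarray,
    regs: np.ndarray,
    alpha: float = 0.9,
    method: str = "pearson",
) -> np.ndarray:
    """Confidence scores for all (regulator, gene) pairs, vectorized.

    Returns a (k regulators x p genes) array: entry (r, g) is the
    alpha-quantile of |corr(regulator r, atom)| over gene g's associated
    atoms. Genes with empty support score 0 for every regulator.
    """
    D = np.asarray(D, float)
    X = np.asarray(X)
    regs = np.asarray(regs, float)
    n, l = D.shape
    if regs.shape[0] != n:
        raise ValueError("sample-order mismatch between regulators and dictionary")
    if n < 3:
        raise ValueError("insufficient samples: need n >= 3 for correlation")
    k = regs.shape[1]
    p = X.shape[1]

    z_regs = _standardize_columns(regs, method)
    z_atoms = _standardize_columns(D, method)
    C = np.minimum(np.abs(z_regs.T @ z_atoms) / n, 1.0)  # k x l

    support_sizes = (X != 0).sum(axis=0)
    cs = np.zeros((k, p))
    for m in np.unique(support_sizes):
        if m == 0:
            continue
        genes = np.flatnonzero(support_sizes == m)
        # (genes, m) atom indices -> (k, genes, m) correlation blocks
        supports = np.argsort(X[:, genes] == 0, axis=0, kind="stable")[:m].T
        block = C[:, supports]
        cs[:, genes] = np.quantile(block, alpha, axis=2)
    return cs


def _edge_table(
    cs: np.ndarray, regulator_ids, gene_ids, n_runs: int
) -> pd.DataFrame:
    k, p = cs.shape
    table = pd.DataFrame(
        {
            "regulator": np.repeat(list(regulator_ids), p),
            "target": np.tile(list(gene_ids), k),
            "cs": cs.ravel(),
            "n_runs": n_runs,
        }
    )
    # a regulator that is also a target gene is never scored against itself
    table = table[table["regulator"] != table["target"]]
    return (
        table.sort_values(["cs", "regulator", "target"], ascending=[False, True, True])
        .reset_index(drop=True)
    )


def score_all(
    D: np.ndarray,
    X: np.ndarray,
    regs: np.ndarray,
    gene_ids=None,
    regulator_ids=None,
    cfg: InferenceConfig | None = None,
) -> pd.DataFrame:
    """Ranked edge table over all (regulator, gene) pairs (self-edges excluded)."""
    cfg = cfg or InferenceConfig()
    cs = score_matrix(D, X, regs, alpha=cfg.alpha, method=cfg.correlation_method)
    k, p = cs.shape
    if regulator_ids is None:
        regulator_ids = [f"R{i + 1}" for i in range(k)]
    if gene_ids is None:
        gene_ids = [f"G{j + 1}" for j in range(p)]
    return _edge_table(cs, regulator_ids, gene_ids, n_runs=1)


def resampled_inference(
    Y: np.ndarray,
    regs: np.ndarray,
    l: int,
    cfg: InferenceConfig | None = None,
    gene_ids=None,
    regulator_ids=None,
    t_params: dict | None = None,
    fit_params: dict | None = None,
    return_matrix: bool = False,
):
    """Subsample-and-average edge scoring (the full inference pipeline).

    N times, draw s = subsample_fraction * n samples without replacement,
    re-fit the atomic-regulator dictionary on the subset (budgets re-drawn
    from the same power law each run), score every (regulator, gene) pair,
    and return the element-wise mean of the N score tables. Defaults:
    s = 75% of n (25% of samples held out per run), N = 2n.
    """
    Y = np.asarray(Y, float)
    regs = np.asarray(regs, float)
    cfg = cfg or InferenceConfig()
    n, p = Y.shape
    if regs.shape[0] != n:
        raise ValueError("sample-order mismatch between expression and regulators")
    s = int(round(cfg.subsample_fraction * n))
    if s < 3:
        raise ValueError(
            f"insufficient subsample: s={s} < 3; raise subsample_fraction "
            f"(currently {cfg.subsample_fraction}) or provide more samples"
        )
    N = cfg.n_resamples if cfg.n_resamples is not None else 2 * n
    t_params = t_params or {}
    fit_params = fit_params or {}

    seeds = spawn_seeds(cfg.seed, 2 * N)
    total = np.zeros((regs.shape[1], p))
    for run in range(N):
        idx = as_rng(seeds[2 * run]).choice(n, size=s, replace=False)
        model = ScaleFreeKSVD(
            n_atoms=l, random_state=seeds[2 * run + 1], **t_params, **fit_params
        ).fit(Y[idx])
        total += score_matrix(
            model.dictionary_,
            model.coefficients_,
            regs[idx],
            alpha=cfg.alpha,
            method=cfg.correlation_method,
        )
    cs = total / N
    if return_matrix:
        return cs
    if regulator_ids is None:
        regulator_ids = [f"R{i + 1}" for i in range(regs.shape[1])]
    if gene_ids is None:
        gene_ids = [f"G{j + 1}" for j in range(p)]
    return _edge_table(cs, regulator_ids, gene_ids, n_runs=N)


def permutation_test(
    Y: np.ndarray,
    regs: np.ndarray,
    observed: pd.DataFrame,
    n_perm: int = 1000,
    seed=None,
    l: int | None = None,
    model: ScaleFreeKSVD | None = None,
    cfg: InferenceConfig | None = None,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-edge permutation p-values for an observed edge-score table.

    The null re-scores each regulator after independently permuting its
    sample order, against a fixed dictionary fit, and uses the add-one
    estimate p = (1 + #{permuted cs >= observed cs}) / (1 + n_perm).
    With ``fdr=True`` a Benjamini-Hochberg ``q_value`` column is added
    (p-values themselves are never adjusted by default).
    """
    if n_perm < 1:
        raise ValueError("invalid count: n_perm must be >= 1")
    Y = np.asarray(Y, float)
    regs = np.asarray(regs, float)
    cfg = cfg or InferenceConfig()
    rng = as_rng(seed)
    if model is None:
        if l is None:
            raise ValueError("provide either a fitted model or an atom count l")
        model = ScaleFreeKSVD(n_atoms=l, random_state=rng).fit(Y)
    D, X = model.dictionary_, model.coefficients_

    obs = observed.set_index(["regulator", "target"])["cs"]
    reg_ids = obs.index.get_level_values(0).unique().tolist()
    tgt_ids = obs.index.get_level_values(1).unique().tolist()
    k = regs.shape[1]
    if len(reg_ids) != k:
        raise ValueError("observed table and regulator matrix disagree on regulators")
    p = X.shape[1]
    if len(tgt_ids) != p:
        raise ValueError("observed table and coefficient matrix disagree on targets")
    obs_mat = obs.unstack().reindex(index=reg_ids, columns=tgt_ids).to_numpy()

    exceed = np.zeros_like(obs_mat)
    n = regs.shape[0]
    for _ in range(n_perm):
        permuted = np.empty_like(regs)
        for j in range(k):
            permuted[:, j] = regs[rng.permutation(n), j]
        null_cs = score_matrix(
            D, X, permuted, alpha=cfg.alpha, method=cfg.correlation_method
        )
        exceed += null_cs >= obs_mat
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    out = pd.DataFrame(pvals, index=reg_ids, columns=tgt_ids)
    out = out.stack().rename("p_value").reset_index()
    out.columns = ["regulator", "target", "p_value"]
    if fdr:
        from scipy.stats import false_discovery_control

        out["q_value"] = false_discovery_control(out["p_value"], method="bh")
    return out


class GRNInference(BaseEstimator):
    """Gene-regulatory-network inference by dictionary learning.

    Fits scale-free k-SVD dictionaries on random sample subsets, scores
    every regulator -> gene pair by the alpha-quantile of absolute
    correlations between the regulator profile and the gene's associated
    atomic regulators, and averages scores over the subsets.

    Parameters mirror :class:`InferenceConfig` plus the dictionary tunables;
    ``n_resamples=None`` means 2n and ``subsample_fraction=1.0`` with
    ``n_resamples=1`` reduces to a single fit on the full data.

    Attributes
    ----------
    edge_scores_ : DataFrame (regulator, target, cs, n_runs), cs descending.
    score_matrix_ : ndarray (k, p) of averaged confidence scores.
    """

    def __init__(
        self,
        n_atoms: int = 50,
        alpha: float = 0.9,
        method: str = "pearson",
        subsample_fraction: float = 0.75,
        n_resamples: int | None = None,
        lambda_exp: float = 3.0,
        t_min: int = 2,
        t_max: int = 6,
        max_iter: int = 200,
        tol: float = 1e-4,
        center: bool = True,
        random_state=None,
    ):
        self.n_atoms = n_atoms
        self.alpha = alpha
        self.method = method
        self.subsample_fraction = subsample_fraction
        self.n_resamples = n_resamples
        self.lambda_exp = lambda_exp
        self.t_min = t_min
        self.t_max = t_max
        self.max_iter = max_iter
        self.tol = tol
        self.center = center
        self.random_state = random_state

    def _config(self) -> InferenceConfig:
        return InferenceConfig(
            alpha=self.alpha,
            correlation_method=self.method,
            subsample_fraction=self.subsample_fraction,
            n_resamples=self.n_resamples,
            seed=self.random_state,
        )

    def fit(self, X, regulators, gene_ids=None, regulator_ids=None):
        """Infer the network from expression (samples x genes) and regulator
        profiles (same samples x regulators)."""
        if isinstance(X, pd.DataFrame):
            gene_ids = gene_ids if gene_ids is not None else list(X.columns)
            X = X.to_numpy()
        if isinstance(regulators, pd.DataFrame):
            if regulator_ids is None:
                regulator_ids = list(regulators.columns)
            regulators = regulators.to_numpy()
        Y = check_array(X, dtype=float, ensure_min_samples=2)
        R = check_array(regulators, dtype=float)
        if R.shape[0] != Y.shape[0]:
            raise ValueError("expression and regulator matrices disagree on samples")
        if gene_ids is None:
            gene_ids = [f"G{j + 1}" for j in range(Y.shape[1])]
        if regulator_ids is None:
            regulator_ids = [f"R{i + 1}" for i in range(R.shape[1])]
        cfg = self._config()
        cs = resampled_inference(
            Y,
            R,
            self.n_atoms,
            cfg=cfg,
            t_params={"lambda_exp": self.lambda_exp, "t_min": self.t_min, "t_max": self.t_max},
            fit_params={"max_iter": self.max_iter, "tol": self.tol, "center": self.center},
            return_matrix=True,
        )
        N = cfg.n_resamples if cfg.n_resamples is not None else 2 * Y.shape[0]
        self.score_matrix_ = cs
        self.edge_scores_ = _edge_table(cs, regulator_ids, gene_ids, n_runs=N)
        self.gene_ids_ = list(gene_ids)
        self.regulator_ids_ = list(regulator_ids)
        self.n_features_in_ = Y.shape[1]
        return self

    def predict(self, top_k: int | None = None) -> pd.DataFrame:
        """Return the ranked edge table (optionally its top_k rows)."""
        check_is_fitted(self, "edge_scores_")
        return self.edge_scores_ if top_k is None else self.edge_scores_.head(top_k)
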