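"""Scoring of learned dictionaries and inferred networks.

Covers four evaluation surfaces: recovery of planted regulators by learned
atoms (recovery rate / positive predictive value under one-to-one correlation
matching), ranked-edge accuracy against a gold standard (AUROC / AUPR),
cascade-motif rendering (patterns P1-P5 for each A->B->C cascade in the gold
network), and topology statistics of a predicted network (power-law degree
slope, average clustering coefficient, average correct regulators per gene).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import average_precision_score, roc_auc_score

logger = logging.getLogger(__name__)

__all__ = [
    "GoldStandard",
    "ARMatch",
    "CRSReport",
    "match_ars",
    "recovery_rate",
    "positive_predictive_value",
    "auroc",
    "aupr",
    "crs_classify",
    "power_law_slope",
    "topology_summary",
    "top_k_edges",
    "correlation_baseline",
]


@dataclass
class GoldStandard:
    """A reference edge set with its regulator and target universes."""

    edges: set
    regulator_universe: set = field(default_factory=set)
    target_universe: set = field(default_factory=set)

    def __post_init__(self):
        self.edges = {(r, t) for r, t in self.edges if r != t}
        if not self.regulator_universe:
            self.regulator_universe = {r for r, _ in self.edges}
        if not self.target_universe:
            self.target_universe = {t for _, t in self.edges}

    @classmethod
    def from_truth(cls, truth, regulator_ids, gene_ids) -> "GoldStandard":
        rows, cols = np.nonzero(truth.adjacency)
        edges = {(regulator_ids[i], gene_ids[j]) for i, j in zip(rows, cols)}
        return cls(edges, set(regulator_ids), set(gene_ids))


@dataclass
class ARMatch:
    """One-to-one matching between learned atoms and true regulators."""

    pairs: list  # (atom_index, regulator_index, abs_correlation)
    unmatched_atoms: set
    unmatched_regulators: set

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


@dataclass
class CRSReport:
    """Counts of cascade patterns P1-P5 over the background A->B->C triples."""

    counts: dict
    total_triples: int


def _abs_corr_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """|Pearson correlation| between columns of A and columns of B."""
    def z(M):
        Z = M - M.mean(axis=0)
        sd = Z.std(axis=0)
        ok = sd > 1e-12
        Z[:, ok] /= sd[ok]
        Z[:, ~ok] = 0.0
        return Z

    A = np.asarray(A, float).copy()
    B = np.asarray(B, float).copy()
    return np.minimum(np.abs(z(A).T @ z(B)) / A.shape[0], 1.0)


def match_ars(
    D_hat: np.ndarray,
    true_regs: np.ndarray,
    rho_min: float = 0.8,
    assignment: str = "greedy",
) -> ARMatch:
    """Match learned atoms to true regulator profiles by |correlation|.

    Greedy one-to-one matching on descending |Pearson correlation|, keeping
    only pairs with |correlation| >= rho_min (default 0.8). ``assignment=
    'hungarian'`` instead maximizes total correlation with the Hungarian
    algorithm before thresholding.
    """
    D_hat = np.asarray(D_hat, float)
    true_regs = np.asarray(true_regs, float)
    if D_hat.shape[0] != true_regs.shape[0]:
        raise ValueError("atoms and regulators must share the sample dimension")
    if not 0 <= rho_min <= 1:
        raise ValueError("rho_min must lie in [0, 1]")
    C = _abs_corr_matrix(D_hat, true_regs)  # atoms x regulators
    l, k = C.shape
    pairs = []
    if assignment == "hungarian":
        rows, cols = linear_sum_assignment(-C)
        for i, j in zip(rows, cols):
            if C[i, j] >= rho_min:
                pairs.append((int(i), int(j), float(C[i, j])))
    elif assignment == "greedy":
        order = np.argsort(C, axis=None)[::-1]
        used_atoms: set[int] = set()
        used_regs: set[int] = set()
        for flat in order:
            i, j = divmod(int(flat), k)
            if C[i, j] < rho_min:
                break
            if i in used_atoms or j in used_regs:
                continue
            pairs.append((i, j, float(C[i, j])))
            used_atoms.add(i)
            used_regs.add(j)
    else:
        raise ValueError("assignment must be 'greedy' or 'hungarian'")
    matched_atoms = {i for i, _, _ in pairs}
    matched_regs = {j for _, j, _ in pairs}
    return ARMatch(
        pairs=sorted(pairs, key=lambda x: -x[2]),
        unmatched_atoms=set(range(l)) - matched_atoms,
        unmatched_regulators=set(range(k)) - matched_regs,
    )


def recovery_rate(match: ARMatch, k_true: int) -> float:
    """Fraction of true regulators recovered by some learned atom."""
    if k_true <= 0:
        raise ValueError("k_true must be positive")
    return match.n_matched / k_true


def positive_predictive_value(match: ARMatch, l_learned: int) -> float:
    """Fraction of learned atoms that match some true regulator."""
    if l_learned <= 0:
        raise ValueError("l_learned must be positive")
    return match.n_matched / l_learned


def _labels_scores(scores: pd.DataFrame, gold: GoldStandard):
    in_universe = scores["regulator"].isin(gold.regulator_universe) & scores[
        "target"
    ].isin(gold.target_universe)
    dropped = int((~in_universe).sum())
    if dropped:
        logger.info("dropped %d scored pairs outside the gold universes", dropped)
    kept = scores[in_universe]
    pairs = list(zip(kept["regulator"], kept["target"]))
    y_true = np.fromiter(((r, t) in gold.edges for r, t in pairs), dtype=bool, count=len(pairs))
    y_score = kept["cs"].to_numpy()
    if y_true.all() or not y_true.any():
        raise ValueError("undefined metric: gold standard needs both positives and negatives")
    return y_true, y_score


def auroc(scores: pd.DataFrame, gold: GoldStandard) -> float:
    """Probability that a random true edge outscores a random non-edge
    (ties counted half)."""
    y_true, y_score = _labels_scores(scores, gold)
    return float(roc_auc_score(y_true, y_score))


def aupr(scores: pd.DataFrame, gold: GoldStandard) -> float:
    """Area under the precision-recall curve (step-wise integration)."""
    y_true, y_score = _labels_scores(scores, gold)
    return float(average_precision_score(y_true, y_score))


def crs_classify(predicted: set, background: GoldStandard) -> CRSReport:
    """Classify each cascade A->B->C of the gold network by how the predicted
    network renders it.

    Background triples are pairs of gold edges A->B, B->C (A != C) whose
    shortcut A->C is absent from the gold network. Patterns: P1 — the
    shortcut A->C is (wrongly) predicted, taking precedence as the error
    mode; P2 — both true edges predicted, cascade fully correct; P3 — A->B
    missed; P4 — B->C missed; P5 — both missed.
    """
    predicted = set(predicted)
    gold_edges = background.edges
    by_source: dict = {}
    for a, b in gold_edges:
        by_source.setdefault(a, set()).add(b)
    counts = {f"P{i}": 0 for i in range(1, 6)}
    total = 0
    for a, b in gold_edges:
        for c in by_source.get(b, ()):
            if c == a or (a, c) in gold_edges:
                continue
            total += 1
            if (a, c) in predicted:
                counts["P1"] += 1
            else:
                has_ab = (a, b) in predicted
                has_bc = (b, c) in predicted
                if has_ab and has_bc:
                    counts["P2"] += 1
                elif has_bc:
                    counts["P3"] += 1
                elif has_ab:
                    counts["P4"] += 1
                else:
                    counts["P5"] += 1
    return CRSReport(counts=counts, total_triples=total)


def _undirected(edges) -> nx.Graph:
    G = nx.Graph()
    G.add_edges_from((r, t) for r, t in edges)
    return G


def power_law_slope(network) -> float:
    """Least-squares slope of ln P(deg) on ln(deg) for the degree distribution.

    Degrees come from the undirected projection; P(deg) is the empirical
    frequency over degrees with non-zero count (integer binning).
    """
    G = _undirected(network)
    if G.number_of_edges() == 0:
        raise ValueError("network is empty")
    degrees = np.array([d for _, d in G.degree()])
    vals, counts = np.unique(degrees, return_counts=True)
    if len(vals) < 2:
        raise ValueError("undefined slope: a single distinct degree value")
    freq = counts / counts.sum()
    slope, _ = np.polyfit(np.log(vals), np.log(freq), 1)
    return float(slope)


def topology_summary(network, gold: GoldStandard) -> tuple[float, float]:
    """(average clustering coefficient, average correct regulators per gene).

    ACC is the mean local clustering coefficient over all nodes of the
    undirected projection (nodes of degree < 2 contribute 0). AN divides the
    number of predicted edges confirmed by the gold standard by the number of
    target genes in the gold standard.
    """
    edges = set(network)
    if not edges:
        raise ValueError("network is empty")
    acc = nx.average_clustering(_undirected(edges))
    n_targets = len(gold.target_universe)
    an = len(edges & gold.edges) / n_targets if n_targets else 0.0
    return float(acc), float(an)


def top_k_edges(scores: pd.DataFrame, k: int) -> set:
    """Top-k scored edges, ties broken by (cs desc, regulator, target)."""
    ordered = scores.sort_values(
        ["cs", "regulator", "target"], ascending=[False, True, True], kind="stable"
    )
    return set(zip(ordered["regulator"].head(k), ordered["target"].head(k)))


def correlation_baseline(
    Y: np.ndarray, regs: np.ndarray, gene_ids=None, regulator_ids=None
) -> pd.DataFrame:
    """Naive edge scores: |Pearson correlation| of regulator vs gene profiles.

    The internal comparison baseline: the same ranking task solved without
    dictionary learning.
    """
    Y = np.asarray(Y, float)
    regs = np.asarray(regs, float)
    C = _abs_corr_matrix(regs, Y)  # k x p
    k, p = C.shape
    if regulator_ids is None:
        regulator_ids = [f"R{i + 1}" for i in range(k)]
    if gene_ids is None:
        gene_ids = [f"G{j + 1}" for j in range(p)]
    table = pd.DataFrame(
        {
            "regulator": np.repeat(list(regulator_ids), p),
            "target": np.tile(list(gene_ids), k),
            "cs": C.ravel(),
        }
    )
    table = table[table["regulator"] != table["target"]]
    return table.sort_values(
        ["cs", "regulator", "target"], ascending=[False, True, True]
    ).reset_index(drop=True)
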