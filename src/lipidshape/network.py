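"""Marginal-correlation heatmap and q-order partial-correlation dependency
network with the non-rejection-rate edge criterion.

With far fewer samples than variables, full-order partial correlations are
not estimable, so limited (q-)order partial correlations are used instead:
for a pair (i, j), size-q conditioning subsets are drawn from the remaining
variables and the hypothesis of zero partial correlation is tested on each.
The non-rejection rate (NRR) is the fraction of subsets on which that null
is NOT rejected; a low NRR supports a direct dependency. Edges whose NRR
exceeds a threshold are omitted, and drawn edge width is inversely
proportional to the NRR.

Partial correlations are computed by inverting the sub-correlation matrix of
(i, j, Q); the test is Fisher's z with effective degrees of freedom
n - q - 3.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationMatrix",
    "DependencyGraph",
    "pearson_matrix",
    "partial_correlation",
    "non_rejection_rate",
    "build_graph",
]

NRR_WIDTH_FLOOR = 1e-3  # keeps edge width finite when NRR == 0


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson coefficients with the sample size they came from."""

    variables: list[str]
    values: np.ndarray
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.variables, columns=self.variables)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def pearson_matrix(data: pd.DataFrame) -> CorrelationMatrix:
    """Product-moment correlation matrix of all columns."""
    if len(data) < 3:
        raise ValueError("need at least 3 subjects")
    sds = data.std(ddof=0)
    zero = sds[sds == 0]
    if len(zero):
        raise ValueError(f"zero-variance variable: {zero.index[0]!r}")
    values = np.corrcoef(data.values, rowvar=False)
    values = np.clip(values, -1.0, 1.0)
    return CorrelationMatrix(variables=list(data.columns), values=values, n=len(data))


def partial_correlation(
    data: pd.DataFrame | np.ndarray,
    i,
    j,
    conditioning=(),
) -> tuple[float, float]:
    """Partial correlation of variables i and j given the conditioning set,
    with its two-sided Fisher-z p-value.

    ``i``, ``j`` and the members of ``conditioning`` are column labels for a
    DataFrame or integer indices for an array. Computed from the inverse of
    the (i, j, Q) sub-correlation matrix.
    """
    if isinstance(data, pd.DataFrame):
        cols = [i, j, *conditioning]
        sub = data[cols].values
    else:
        sub = np.asarray(data)[:, [i, j, *list(conditioning)]]
    n, k = sub.shape
    q = k - 2
    if i == j or i in tuple(conditioning) or j in tuple(conditioning):
        raise ValueError("i, j and the conditioning set must be disjoint")
    if q > n - 3:
        raise ValueError(f"conditioning order {q} too high for n = {n}")
    corr = np.corrcoef(sub, rowvar=False)
    if q == 0:
        r = corr[0, 1]
    else:
        # Schur complement of the conditioning block: partial covariance of
        # (i, j) given Q, normalised to a correlation. Only the Q block is
        # inverted, so a deterministic i-j dependence still yields |r| = 1.
        A = corr[:2, :2]
        B = corr[:2, 2:]
        C = corr[2:, 2:]
        try:
            part = A - B @ np.linalg.solve(C, B.T)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError("singular conditioning sub-matrix") from exc
        denom = np.sqrt(part[0, 0] * part[1, 1])
        if denom <= 0:
            raise np.linalg.LinAlgError(
                "zero partial variance: a conditioning variable determines i or j"
            )
        r = part[0, 1] / denom
    r = float(np.clip(r, -1.0, 1.0))
    df = n - q - 3
    if df <= 0:
        raise ValueError("not enough samples for the Fisher-z test")
    z = np.arctanh(min(max(r, -1 + 1e-15), 1 - 1e-15)) * np.sqrt(df)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return r, p


def non_rejection_rate(
    data: pd.DataFrame,
    i,
    j,
    q: int,
    n_sets: int | None = 100,
    alpha: float = 0.05,
    seed: int | None = 0,
) -> float:
    """Fraction of size-q conditioning subsets on which H0: pcor(i,j|Q) = 0
    is NOT rejected at level ``alpha``.

    Subsets are drawn uniformly (without replacement within a subset, with
    replacement across subsets) from all variables other than i and j;
    ``n_sets=None`` enumerates every subset instead of sampling.
    """
    others = [c for c in data.columns if c not in (i, j)]
    if q > len(others):
        raise ValueError(f"q = {q} exceeds the {len(others)} available variables")
    if q > len(data) - 3:
        raise ValueError(f"q = {q} too high for n = {len(data)}")
    if n_sets is None:
        subsets = list(combinations(others, q))
    else:
        rng = np.random.default_rng(seed)
        idx = np.arange(len(others))
        subsets = [
            tuple(others[k] for k in rng.choice(idx, size=q, replace=False))
            for _ in range(n_sets)
        ]
    not_rejected = 0
    for Q in subsets:
        _, p = partial_correlation(data, i, j, Q)
        if p >= alpha:
            not_rejected += 1
    return not_rejected / len(subsets)


@dataclass
class DependencyGraph:
    """Undirected dependency graph over lipid and image variables."""

    graph: nx.Graph
    nrr: pd.DataFrame              # symmetric matrix of non-rejection rates
    marginal: CorrelationMatrix
    q: int
    n_sets: int | None
    alpha: float
    threshold: float
    seed: int | None

    def edge_list(self) -> pd.DataFrame:
        rows = [
            dict(source=u, target=v, nrr=d["nrr"], width=d["width"])
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "nrr", "width"])

    def connected_components(self) -> list[set]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        nx.write_graphml(self.graph, outdir / "dependency_graph.graphml")
        self.edge_list().to_csv(outdir / "edges.csv", index=False)
        self.nrr.to_csv(outdir / "nrr_matrix.csv")
        self.marginal.to_csv(outdir / "pearson_matrix.csv")


def build_graph(
    data: pd.DataFrame,
    q: int = 3,
    n_sets: int | None = 100,
    alpha: float = 0.05,
    threshold: float = 0.53,
    seed: int | None = 0,
) -> DependencyGraph:
    """Estimate the NRR for every variable pair and keep edges with
    NRR <= threshold; edge width is 1 / max(NRR, floor)."""
    variables = list(data.columns)
    marginal = pearson_matrix(data)
    nrr_mat = pd.DataFrame(np.zeros((len(variables), len(variables))),
                           index=variables, columns=variables)
    graph = nx.Graph()
    graph.add_nodes_from(variables)
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    pair_seeds = ss.generate_state(len(variables) * (len(variables) - 1) // 2)
    for k, (i, j) in enumerate(combinations(variables, 2)):
        r = non_rejection_rate(data, i, j, q=q, n_sets=n_sets, alpha=alpha,
                               seed=int(pair_seeds[k]))
        nrr_mat.loc[i, j] = nrr_mat.loc[j, i] = r
        if r <= threshold:
            graph.add_edge(i, j, nrr=float(r), width=float(1.0 / max(r, NRR_WIDTH_FLOOR)))
    return DependencyGraph(graph=graph, nrr=nrr_mat, marginal=marginal, q=q,
                           n_sets=n_sets, alpha=alpha, threshold=threshold, seed=seed)
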