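"""Bootstrap-stabilized Spearman correlation networks and the density statistic.

For each anthropometric stratum the 14x14 Spearman matrix over food-group
daily grams is computed, p-values Holm-adjusted across the 91 unordered
pairs, and the matrix is submitted to a B-fold (default 100x) participant
bootstrap.  An edge enters the stratum network only if it passes a
three-part stability filter:

    adjusted p < alpha  AND  |rho_full| > rho_min  AND  support >= support_min,

where support is the fraction of bootstrap replicates in which the pair
stays (adjusted-)significant.  Each replicate also yields a network-density
sample L / (N (N-1) / 2) with L the number of significant pairs in that
replicate; density distributions are compared across strata with
Kruskal-Wallis + Dunn.  Node degree (number of included incident edges)
profiles which food groups anchor each stratum's consumption structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_stats import dunn_posthoc, holm_adjust, kruskal_wallis
from .ffq_ingest import FOOD_GROUPS

__all__ = [
    "CorrelationEdge",
    "DensitySample",
    "StratumNetwork",
    "spearman_pair",
    "spearman_matrix",
    "network_density",
    "bootstrap_network",
    "compare_density",
    "node_degree_profile",
    "network_to_graphml",
    "edges_to_frame",
    "density_samples_to_frame",
]


@dataclass(frozen=True)
class CorrelationEdge:
    """One stable correlation between two food groups (a < b canonically)."""

    a: str
    b: str
    rho_full: float
    p_adj_full: float
    support: float
    sign: str  # "positive" | "negative"


@dataclass(frozen=True)
class DensitySample:
    stratum: str
    b: int  # bootstrap replicate index, 1..B
    L: int  # significant pairs in this replicate
    N: int  # node count
    density: float


@dataclass(frozen=True)
class StratumNetwork:
    stratum: str
    nodes: tuple[str, ...]
    edges: tuple[CorrelationEdge, ...]
    n_participants: int
    B: int
    alpha: float
    rho_min: float
    support_min: float

    @property
    def node_degree(self) -> dict[str, int]:
        deg = {n: 0 for n in self.nodes}
        for e in self.edges:
            deg[e.a] += 1
            deg[e.b] += 1
        return deg

    @property
    def positive_count(self) -> int:
        return sum(1 for e in self.edges if e.sign == "positive")

    @property
    def negative_count(self) -> int:
        return sum(1 for e in self.edges if e.sign == "negative")


def spearman_pair(x, y) -> tuple[float, float]:
    """Spearman rho and two-sided p (t approximation, n-2 df).

    Rho is the Pearson correlation of average-ranked data; a zero-variance
    rank vector makes the pair not computable and returns (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("spearman_pair needs equal-length vectors of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def spearman_matrix(
    block: pd.DataFrame | np.ndarray,
    adjust: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(rho, raw p, adjusted p) matrices over the block's columns.

    Holm adjustment runs across the observed unordered pairs (91 for the 14
    food groups); pairs involving a zero-variance column are NaN and are
    excluded from the Holm family.
    """
    X = np.asarray(block, dtype=float)
    n, m = X.shape
    if n < 3:
        raise ValueError("spearman_matrix needs at least 3 rows")
    ranks = np.apply_along_axis(stats.rankdata, 0, X)
    sd = ranks.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    degenerate = sd == 0
    rho[degenerate, :] = np.nan
    rho[:, degenerate] = np.nan
    np.fill_diagonal(rho, 1.0)

    # two-sided p from t = rho * sqrt((n-2)/(1-rho^2))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)
    p[np.isnan(rho)] = np.nan
    np.fill_diagonal(p, 0.0)

    p_adj = np.full_like(p, np.nan)
    np.fill_diagonal(p_adj, 0.0)
    iu = np.triu_indices(m, k=1)
    raw = p[iu]
    ok = ~np.isnan(raw)
    if adjust and ok.any():
        adj_vals = np.full(raw.shape, np.nan)
        adj_vals[ok] = holm_adjust(raw[ok])
    else:
        adj_vals = raw.copy()
    p_adj[iu] = adj_vals
    p_adj.T[iu] = adj_vals
    return rho, p, p_adj


def network_density(L: int, N: int) -> float:
    """Density L / (N (N-1) / 2) of a graph with L edges on N nodes."""
    if N < 2:
        raise ValueError("N must be >= 2")
    max_l = N * (N - 1) // 2
    if not (0 <= L <= max_l):
        raise ValueError(f"L must be in 0..{max_l} for N={N}, got {L}")
    return L / (N * (N - 1) / 2)


def bootstrap_network(
    block: pd.DataFrame,
    stratum: str = "stratum",
    B: int = 100,
    alpha: float = 0.05,
    rho_min: float = 0.5,
    support_min: float = 0.5,
    seed: int | None = None,
    adjust_within_bootstrap: bool = True,
    min_rows: int = 20,
) -> tuple[StratumNetwork, list[DensitySample]]:
    """Build one stratum's stabilized network and its density samples.

    The full-sample Holm-adjusted Spearman matrix is computed, then B row
    resamples (participants, with replacement, at the original stratum size)
    each yield an adjusted p matrix.  Per-pair support is the fraction of
    replicates with adjusted p < alpha; an edge is included iff the
    full-sample adjusted p < alpha, |rho_full| > rho_min (strict) and
    support >= support_min.  Each replicate contributes one DensitySample
    with L = number of (adjusted-)significant pairs in that replicate —
    density's L has no rho or support filter.  Degenerate replicate columns
    make the affected pairs non-significant in that replicate.
    """
    cols = [str(c) for c in block.columns]
    X = block.to_numpy(dtype=float)
    n, m = X.shape
    if n < min_rows:
        raise ValueError(f"stratum has {n} rows; at least {min_rows} required")
    if B < 1:
        raise ValueError("B must be >= 1")

    rho_full, _, p_adj_full = spearman_matrix(X, adjust=True)

    rng = np.random.default_rng(seed)
    iu = np.triu_indices(m, k=1)
    sig_counts = np.zeros(len(iu[0]), dtype=int)
    samples: list[DensitySample] = []
    for b in range(1, B + 1):
        idx = rng.integers(0, n, n)
        _, _, p_adj_b = spearman_matrix(X[idx], adjust=adjust_within_bootstrap)
        pb = p_adj_b[iu]
        sig = (~np.isnan(pb)) & (pb < alpha)
        sig_counts += sig
        L = int(sig.sum())
        samples.append(
            DensitySample(stratum=stratum, b=b, L=L, N=m, density=network_density(L, m))
        )
    support = sig_counts / B

    edges = []
    for k, (i, j) in enumerate(zip(*iu)):
        r = rho_full[i, j]
        pa = p_adj_full[i, j]
        if np.isnan(r) or np.isnan(pa):
            continue
        if pa < alpha and abs(r) > rho_min and support[k] >= support_min:
            edges.append(
                CorrelationEdge(
                    a=cols[i],
                    b=cols[j],
                    rho_full=float(r),
                    p_adj_full=float(pa),
                    support=float(support[k]),
                    sign="positive" if r > 0 else "negative",
                )
            )
    net = StratumNetwork(
        stratum=stratum,
        nodes=tuple(cols),
        edges=tuple(edges),
        n_participants=n,
        B=B,
        alpha=alpha,
        rho_min=rho_min,
        support_min=support_min,
    )
    return net, samples


def compare_density(
    samples_by_stratum: dict[str, list[DensitySample]]
) -> tuple[float, float, pd.DataFrame]:
    """Kruskal-Wallis + Dunn comparison of per-bootstrap density vectors."""
    if len(samples_by_stratum) < 2:
        raise ValueError("compare_density needs at least 2 strata")
    groups = {}
    for name, samples in samples_by_stratum.items():
        if len(samples) < 2:
            raise ValueError(f"stratum {name!r} has fewer than 2 density samples")
        groups[name] = np.array([s.density for s in samples])
    h, p = kruskal_wallis(groups)
    dunn = dunn_posthoc(groups, adjust="holm")
    return h, p, dunn


def node_degree_profile(
    networks: StratumNetwork | dict[str, StratumNetwork]
) -> pd.DataFrame:
    """Node degrees per stratum, aligned across the 14 food groups.

    Accepts one network or a dict of them; returns a food-group x stratum
    table of included-edge degrees.
    """
    if isinstance(networks, StratumNetwork):
        networks = {networks.stratum: networks}
    out = pd.DataFrame(index=list(FOOD_GROUPS))
    for name, net in networks.items():
        deg = net.node_degree
        out[name] = [deg.get(g, 0) for g in out.index]
    out.index.name = "food_group"
    return out


def network_to_graphml(network: StratumNetwork, path) -> None:
    """Write the network as GraphML (node degree; edge rho/p/support/sign)."""
    import networkx as nx

    G = nx.Graph(stratum=network.stratum, B=network.B)
    deg = network.node_degree
    for node in network.nodes:
        G.add_node(node, label=node, degree=deg[node])
    for e in network.edges:
        G.add_edge(
            e.a,
            e.b,
            rho=e.rho_full,
            p_adj=e.p_adj_full,
            support=e.support,
            sign=e.sign,
        )
    nx.write_graphml(G, path)


def edges_to_frame(network: StratumNetwork) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "stratum": network.stratum,
                "a": e.a,
                "b": e.b,
                "rho": e.rho_full,
                "p_adj": e.p_adj_full,
                "support": e.support,
                "sign": e.sign,
            }
            for e in network.edges
        ],
        columns=["stratum", "a", "b", "rho", "p_adj", "support", "sign"],
    )


def density_samples_to_frame(samples: list[DensitySample]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"stratum": s.stratum, "b": s.b, "L": s.L, "N": s.N, "density": s.density}
            for s in samples
        ]
    )
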