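"""Random-walk-with-restart prioritization and decile evaluation.

Starting from the indicator vector P_0 of the seed disease, the walk
iterates

    P_{k+1} = (1 - c) * W P_k + c * P_0,

where W is the column-stochastic (column-normalized) adjacency operator of
the comorbidity network — restricted to the seed's connected component, so
every column sums to 1 — and c is the restart probability (default 0.15).
Because the update is a convex combination of two probability vectors,
every iterate stays on the simplex.  Iteration stops when the change
between successive vectors drops below ``tol`` (default 1e-6; L1 norm,
which is scale-free on the simplex).  The stationary vector scores each
disease's network proximity to the seed.

Ranked results are evaluated against a gold-standard comorbidity list by
splitting the ranking into 10 deciles and counting gold hits per decile.
Following the field's reporting convention, "first-decile precision" is
the share of the *gold list* found in the top decile (hits / |gold|); the
conventional hits / decile-size ratio is reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = [
    "RWRParams",
    "ConvergenceError",
    "rwr",
    "rank_diseases",
    "decile_evaluation",
    "DecileReport",
    "write_ranking",
    "read_ranking",
]


@dataclass(frozen=True)
class RWRParams:
    c: float = 0.15  # restart probability of the seed
    tol: float = 1e-6
    max_iter: int = 10_000

    def __post_init__(self):
        if not (0.0 < self.c < 1.0):
            raise ValueError("restart probability c must lie in (0, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


class ConvergenceError(RuntimeError):
    def __init__(self, residual: float, max_iter: int):
        self.residual = residual
        super().__init__(
            f"random walk did not converge within {max_iter} iterations "
            f"(last L1 residual {residual:.3e})"
        )


def rwr(
    graph: nx.Graph,
    seed: str,
    params: RWRParams = RWRParams(),
    return_iterations: bool = False,
):
    """Converged restart-walk probability over the seed's component.

    ``graph`` must be connected with every node of degree >= 1 (use
    :func:`comorbnet.comorbidity_network.seed_component`).  Returns a
    node -> probability map summing to 1.
    """
    if seed not in graph:
        raise KeyError(f"seed {seed!r} not in graph")
    nodes = sorted(graph.nodes)
    if not nx.is_connected(graph):
        raise ValueError("graph must be restricted to the seed's component")
    idx = {node: i for i, node in enumerate(nodes)}
    adj = nx.to_scipy_sparse_array(graph, nodelist=nodes, format="csr", dtype=float)
    degrees = np.asarray(adj.sum(axis=1)).ravel()
    if np.any(degrees == 0):
        raise ValueError("graph contains an isolated node; walk is ill-posed")
    # column-stochastic propagation operator A D^-1: column j of the
    # adjacency divided by deg(j).  Applying it directly keeps every
    # iterate on the probability simplex (the update is then a convex
    # combination of two distributions).
    w = adj.multiply(1.0 / degrees[None, :]).tocsr()

    p0 = np.zeros(len(nodes))
    p0[idx[seed]] = 1.0
    p = p0.copy()
    c = params.c
    for k in range(1, params.max_iter + 1):
        p_next = (1.0 - c) * (w @ p) + c * p0
        residual = float(np.abs(p_next - p).sum())
        p = p_next
        if residual < params.tol:
            logger.info("random walk converged after %d iterations", k)
            scores = {node: float(p[i]) for node, i in idx.items()}
            return (scores, k) if return_iterations else scores
    raise ConvergenceError(residual, params.max_iter)


def rank_diseases(
    scores: dict[str, float], seed: str
) -> list[tuple[str, float]]:
    """Diseases by descending score, seed excluded, ties lexicographic."""
    ranked = sorted(
        ((node, s) for node, s in scores.items() if node != seed),
        key=lambda kv: (-kv[1], kv[0]),
    )
    vals = [s for _, s in ranked]
    if len(set(vals)) < len(vals):
        logger.info("ranking contains tied scores; ties broken lexicographically")
    return ranked


@dataclass(frozen=True)
class DecileReport:
    """Gold-standard hits per decile of the ranked list."""

    bin_sizes: tuple  # 10 contiguous bin sizes, differing by at most 1
    true_positive_counts: tuple  # gold hits per bin
    gold_size: int
    first_decile_precision_pct: float  # hits in bin 1 / |gold|, in percent
    first_decile_hit_fraction: float  # hits in bin 1 / size of bin 1

    def histogram(self) -> str:
        lines = ["decile\thits\tbar"]
        for i, tp in enumerate(self.true_positive_counts, 1):
            lines.append(f"{(i-1)*10}-{i*10}%\t{tp}\t" + "#" * tp)
        return "\n".join(lines)


def _decile_boundaries(n: int) -> list[int]:
    # cumulative rank boundary of bin i is ceil(i*n/10); sizes differ by <= 1
    return [-(-i * n // 10) for i in range(11)]


def decile_evaluation(
    ranked: Sequence, gold: Iterable[str]
) -> DecileReport:
    """Count gold-standard comorbidities per decile of the ranking.

    ``ranked`` is an ordered list of diseases or (disease, score) pairs.
    The headline first-decile precision is gold hits in the top decile
    divided by the gold-list size, reported as a percentage to 1 decimal.
    """
    names = [r[0] if isinstance(r, tuple) else r for r in ranked]
    gold = set(gold)
    if not names:
        raise ValueError("ranked list is empty")
    if not gold:
        raise ValueError("gold-standard list is empty")
    bounds = _decile_boundaries(len(names))
    sizes, hits = [], []
    for i in range(10):
        members = names[bounds[i]:bounds[i + 1]]
        sizes.append(len(members))
        hits.append(sum(1 for m in members if m in gold))
    first_pct = round(100.0 * hits[0] / len(gold), 1)
    first_frac = hits[0] / sizes[0] if sizes[0] else 0.0
    return DecileReport(
        bin_sizes=tuple(sizes),
        true_positive_counts=tuple(hits),
        gold_size=len(gold),
        first_decile_precision_pct=first_pct,
        first_decile_hit_fraction=first_frac,
    )


def write_ranking(
    ranked: Sequence[tuple[str, float]], path, gold: Iterable[str] = ()
) -> None:
    gold = set(gold)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tdisease\tscore\tis_gold\n")
        for i, (disease, score) in enumerate(ranked, 1):
            fh.write(f"{i}\t{disease}\t{score!r}\t{int(disease in gold)}\n")


def read_ranking(path) -> list[tuple[str, float]]:
    out = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("rank"):
            raise ValueError(f"unexpected ranking header: {header!r}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            _, disease, score, _ = line.split("\t")
            out.append((disease, float(score)))
    return out
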