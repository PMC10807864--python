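"""Structural graph measures that predict the dynamics.

Three per-area measures — input strength (row sums), eigenvector centrality
(leading eigenvector component) and loop strength (summed products of edge
weights around directed simple cycles through the area) — each computable on
the raw simulation matrix or on a cell type-aware variant ('celltype',
'sign_only', 'noPV'; see :func:`distwm.connectome.celltype_matrix`).

Edge orientation: matrices are target-by-source, so the directed edge
j -> i carries weight ``W[i, j]``. Cycles are simple (distinct vertices),
rotation-equivalent node sequences count once, and for length >= 3 the two
traversal orientations are distinct cycles.
"""

from __future__ import annotations

import itertools
import warnings

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm

from .connectome import Connectome
from .simulator import correlate_measure

__all__ = [
    "input_strength",
    "eigenvector_centrality",
    "loop_strength",
    "predict_rate",
    "predict_binary",
    "graph_measure_table",
]

_EIG_TIE_RTOL = 1e-8


def input_strength(W: np.ndarray) -> np.ndarray:
    """Total incoming weight per target area: row sums of W."""
    W = np.asarray(W, float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("input_strength expects a square matrix")
    return W.sum(axis=1)


def eigenvector_centrality(W: np.ndarray) -> np.ndarray:
    """Component of the leading eigenvector of W, per area.

    For elementwise-nonnegative matrices this is the Perron vector,
    returned nonnegative with unit sum. For signed variants no Perron
    theory applies, so a reproducible convention is imposed: take the
    eigenvector of the eigenvalue with largest real part, keep the real
    part, flip the sign so the largest-magnitude entry is positive, and
    normalize to unit Euclidean norm. A leading eigenvalue that is tied
    (multiplicity > 1 within tolerance) is an error.
    """
    W = np.asarray(W, float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("eigenvector_centrality expects a square matrix")
    if not W.any():
        raise ValueError("all-zero matrix has no leading eigenvector")
    vals, vecs = np.linalg.eig(W)
    order = np.argsort(-vals.real)
    lead, runner = vals[order[0]], vals[order[1]]
    scale = max(1.0, abs(lead))
    if abs(lead - runner) < _EIG_TIE_RTOL * scale:
        raise ValueError(
            f"leading eigenvalue is degenerate: {lead:.6g} vs {runner:.6g}")
    v = vecs[:, order[0]].real
    if (W >= 0).all():
        v = np.abs(v)
        return v / v.sum()
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    return v / np.linalg.norm(v)


def _cycles(n: int, L: int, nonzero_edges) -> "itertools.chain":
    G = nx.DiGraph()
    G.add_nodes_from(range(n))
    G.add_edges_from(nonzero_edges)
    return (c for c in nx.simple_cycles(G, length_bound=L) if len(c) == L)


def loop_strength(W: np.ndarray, L: int = 2,
                  restrict: np.ndarray | None = None) -> np.ndarray:
    """Summed strength of the length-L directed simple cycles through each area.

    A cycle's strength is the product of its L edge weights; an area's score
    sums the strengths of every cycle containing it. ``restrict`` (boolean
    mask or index list) limits the cycle search to a subset of areas — used
    for per-attractor analyses — with zeros reported elsewhere.
    """
    W = np.asarray(W, float)
    n = W.shape[0]
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("loop_strength expects a square matrix")
    if L < 2:
        raise ValueError("loop length must be at least 2")
    if L > n:
        raise ValueError(f"loop length {L} exceeds the number of areas {n}")
    allowed = np.ones(n, bool)
    if restrict is not None:
        restrict = np.asarray(restrict)
        if restrict.dtype == bool:
            allowed = restrict.copy()
        else:
            allowed = np.zeros(n, bool)
            allowed[restrict] = True
    # edge u -> v exists when W[v, u] != 0 (target-by-source orientation)
    edges = [(u, v) for v, u in zip(*np.nonzero(W)) if allowed[u] and allowed[v]]
    scores = np.zeros(n)
    for cycle in _cycles(n, L, edges):
        strength = 1.0
        for u, v in zip(cycle, cycle[1:] + cycle[:1]):
            strength *= W[v, u]
        for node in cycle:
            scores[node] += strength
    return scores


def predict_rate(measure: np.ndarray, rates: np.ndarray,
                 subset: np.ndarray | None = None) -> tuple[float, float]:
    """Pearson correlation between a structural measure and delay rates.

    Restricted to ``subset`` (typically the persistently active areas).
    Returns (r, two-sided p).
    """
    return correlate_measure(np.asarray(measure, float),
                             np.asarray(rates, float), subset)


def predict_binary(measure: np.ndarray, labels: np.ndarray) -> tuple[float, dict]:
    """In-sample accuracy of a univariate logistic classifier.

    Fits intercept + slope on the measure, classifies by posterior > 0.5 and
    scores on the fitted sample. Perfectly separated data (where the
    unregularized likelihood has no maximizer) short-circuit to accuracy 1.0
    with ``info['separated']``; a constant measure yields the majority-class
    fraction.
    """
    x = np.asarray(measure, float)
    y = np.asarray(labels, bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    info: dict = {"separated": False, "degenerate": False}
    if np.ptp(x) == 0:
        info["degenerate"] = True
        return float(max(y.mean(), 1 - y.mean())), info
    if x[y].min() > x[~y].max() or x[y].max() < x[~y].min():
        info["separated"] = True
        return 1.0, info
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y.astype(float), X).fit(disp=0, maxiter=200)
    pred = res.predict(X) > 0.5
    info["params"] = tuple(res.params)
    return float((pred == y).mean()), info


def graph_measure_table(connectome: Connectome,
                        variants=("raw", "celltype", "sign_only", "noPV"),
                        loop_lengths=(2, 3)) -> pd.DataFrame:
    """Long-format table of every (measure, variant, loop length) combination."""
    rows = []
    for variant in variants:
        W = connectome.variant(variant)
        rows.append(pd.DataFrame({
            "area": connectome.names, "measure": "input_strength",
            "variant": variant, "loop_length": pd.NA,
            "value": input_strength(W)}))
        rows.append(pd.DataFrame({
            "area": connectome.names, "measure": "eigenvector_centrality",
            "variant": variant, "loop_length": pd.NA,
            "value": eigenvector_centrality(W)}))
        for L in loop_lengths:
            rows.append(pd.DataFrame({
                "area": connectome.names, "measure": "loop_strength",
                "variant": variant, "loop_length": L,
                "value": loop_strength(W, L)}))
    return pd.concat(rows, ignore_index=True)
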