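"""Core connectome-predictive-modelling steps.

The CPM protocol reduces a connectome to two scalar *network strengths*:

1. correlate every valid edge with the (z-scored) behavioral score over the
   training sample and keep edges with two-tailed p < 0.01;
2. split the kept edges by the sign of the correlation into a positive and
   a negative tail;
3. per participant, sum the Fisher-z values over each tail's edge set
   (a raw sum, not a mean);
4. fit an ordinary least-squares line from network strength to behavior.

Positive and negative tails are always modelled separately.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .connectome import ConnectivityProfile, count_unique_edges
from .masking import EdgeMask, _as_edge_matrix, _edgewise_pearson, pearson_r_pvalues

DEFAULT_SELECTION_ALPHA = 0.01


class CPMFitError(ValueError):
    """Raised when no usable linear model can be fit (degenerate input)."""


@dataclass
class EdgeSelection:
    """Behavior-correlated edges, partitioned by the sign of the correlation.

    ``positive_edges`` / ``negative_edges`` map (i, j) node pairs (i < j)
    to their (r, p) statistics on the training sample.
    """

    positive_edges: dict[tuple[int, int], tuple[float, float]]
    negative_edges: dict[tuple[int, int], tuple[float, float]]
    alpha: float
    n_train: int
    node_count: int

    def tail(self, which: str) -> dict[tuple[int, int], tuple[float, float]]:
        if which == "positive":
            return self.positive_edges
        if which == "negative":
            return self.negative_edges
        raise ValueError(f"tail must be 'positive' or 'negative', got {which!r}")


@dataclass
class CPMModel:
    """Affine predictor of behavior from summed network strength."""

    tail: str
    edges: list[tuple[int, int]]
    slope: float
    intercept: float
    n_train: int
    behavior_name: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {
                "tail": self.tail,
                "edges": [list(e) for e in self.edges],
                "slope": self.slope,
                "intercept": self.intercept,
                "n_train": self.n_train,
                "behavior_name": self.behavior_name,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CPMModel":
        d = json.loads(text)
        return cls(
            tail=d["tail"],
            edges=[tuple(e) for e in d["edges"]],
            slope=float(d["slope"]),
            intercept=float(d["intercept"]),
            n_train=int(d["n_train"]),
            behavior_name=d.get("behavior_name", ""),
        )


def zscore(values: Sequence[float], ddof: int = 1) -> np.ndarray:
    """Standardize to zero mean, unit (sample) SD."""
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=ddof)
    if sd == 0:
        raise ValueError("cannot z-score a constant vector")
    return (v - v.mean()) / sd


def select_edges(
    profiles,
    behavior_z: Sequence[float],
    mask: EdgeMask,
    alpha: float = DEFAULT_SELECTION_ALPHA,
    node_count: int | None = None,
) -> EdgeSelection:
    """Select valid edges significantly correlated with behavior.

    Per valid edge, Pearson r with the behavior vector (two-tailed p from
    the exact r-to-t conversion); edges with p < alpha (strict) are kept
    and partitioned by the sign of r.  The behavior vector is expected to
    be z-scored over the training sample, though selection is invariant to
    any positive affine rescaling of it.
    """
    E, nc = _as_edge_matrix(profiles, node_count)
    if mask.node_count != nc:
        raise ValueError("mask node_count does not match profiles")
    y = np.asarray(behavior_z, dtype=float)
    if y.shape != (E.shape[0],):
        raise ValueError("need one behavior value per profile")
    if E.shape[0] < 5:
        raise ValueError("need at least 5 participants for edge selection")
    if y.std() == 0:
        warnings.warn("behavior vector is constant; no edges selected", stacklevel=2)
        return EdgeSelection({}, {}, alpha, E.shape[0], nc)

    r = _edgewise_pearson(E, y)
    p = pearson_r_pvalues(r, n=E.shape[0])
    keep = (p < alpha) & mask.valid
    iu, ju = np.triu_indices(nc, k=1)
    pos: dict[tuple[int, int], tuple[float, float]] = {}
    neg: dict[tuple[int, int], tuple[float, float]] = {}
    for k in np.flatnonzero(keep):
        edge = (int(iu[k]), int(ju[k]))
        if r[k] > 0:
            pos[edge] = (float(r[k]), float(p[k]))
        elif r[k] < 0:
            neg[edge] = (float(r[k]), float(p[k]))
    return EdgeSelection(pos, neg, alpha, E.shape[0], nc)


def network_strength(profile, edges) -> float:
    """Sum of Fisher-z values over an edge set (empty set sums to 0)."""
    if isinstance(profile, ConnectivityProfile):
        z = profile.z_matrix
        return float(sum(z[i, j] for (i, j) in edges))
    raise TypeError("network_strength expects a ConnectivityProfile")


def edge_set_to_flat_indices(edges, node_count: int) -> np.ndarray:
    """Map (i, j) pairs (i < j) to flat canonical upper-triangle indices."""
    idx = []
    for (i, j) in edges:
        if not (0 <= i < j < node_count):
            raise ValueError(f"invalid edge ({i}, {j}) for {node_count} nodes")
        # row-major strict upper triangle offset
        idx.append(i * (2 * node_count - i - 1) // 2 + (j - i - 1))
    return np.asarray(idx, dtype=int)


def network_strengths_from_matrix(E: np.ndarray, flat_idx: np.ndarray) -> np.ndarray:
    """Per-participant raw sums over the selected edge columns."""
    if flat_idx.size == 0:
        return np.zeros(E.shape[0])
    return E[:, flat_idx].sum(axis=1)


def fit_cpm(
    strengths: Sequence[float],
    behavior: Sequence[float],
    tail: str,
    edges=(),
    behavior_name: str = "",
) -> CPMModel:
    """Ordinary least-squares line predicting behavior from network strength."""
    s = np.asarray(strengths, dtype=float)
    y = np.asarray(behavior, dtype=float)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("strengths and behavior must be 1-D vectors of equal length")
    if s.size < 3:
        raise ValueError("need at least 3 participants to fit the linear model")
    ss = s - s.mean()
    den = ss @ ss
    if den == 0:
        raise CPMFitError("network strengths are constant; no usable model")
    slope = (ss @ (y - y.mean())) / den
    intercept = y.mean() - slope * s.mean()
    return CPMModel(
        tail=tail,
        edges=list(edges),
        slope=float(slope),
        intercept=float(intercept),
        n_train=int(s.size),
        behavior_name=behavior_name,
    )


def predict_score(model: CPMModel, profile: ConnectivityProfile) -> float:
    """Predicted behavior: intercept + slope * network strength."""
    return model.intercept + model.slope * network_strength(profile, model.edges)
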