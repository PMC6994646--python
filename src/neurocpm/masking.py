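"""Confound masking: remove edges associated with head motion or site.

Before any modelling, every edge whose value correlates with head motion
across participants (Pearson, two-tailed p < 0.05) or differs between
acquisition sites (two-sample t-test, two-tailed p < 0.05) is marked
invalid.  Masks are computed once on the analysis sample and compose by
logical AND.  No multiple-comparison correction is applied at this step:
the point is to be aggressive about confounds, not conservative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .connectome import ConnectivityProfile, count_unique_edges, profiles_to_edge_matrix


@dataclass
class EdgeMask:
    """Validity indicator over the strict-upper-triangle edges.

    ``provenance`` maps removed edges, keyed by (i, j) node pairs with
    i < j, to the reason ("motion" or "site") that first removed them.
    """

    node_count: int
    valid: np.ndarray
    provenance: dict[tuple[int, int], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.valid = np.asarray(self.valid, dtype=bool)
        expected = count_unique_edges(self.node_count)
        if self.valid.shape != (expected,):
            raise ValueError(
                f"valid must have {expected} entries for {self.node_count} nodes, "
                f"got {self.valid.shape}"
            )

    @classmethod
    def all_valid(cls, node_count: int) -> "EdgeMask":
        return cls(node_count, np.ones(count_unique_edges(node_count), dtype=bool))

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    @property
    def n_removed(self) -> int:
        return int((~self.valid).sum())


def _as_edge_matrix(profiles, node_count=None):
    """Accept a list of ConnectivityProfile or a pre-built (n, e) matrix."""
    if isinstance(profiles, np.ndarray):
        if node_count is None:
            raise ValueError("node_count is required when passing a raw edge matrix")
        if profiles.shape[1] != count_unique_edges(node_count):
            raise ValueError("edge matrix width does not match node_count")
        return np.asarray(profiles, dtype=float), node_count
    E, nc, _ = profiles_to_edge_matrix(list(profiles))
    return E, nc


def pearson_r_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-tailed p for Pearson r at sample size n via the exact t conversion.

    t = r * sqrt((n - 2) / (1 - r^2)); |r| = 1 maps to p = 0.
    """
    r = np.asarray(r, dtype=float)
    df = n - 2
    if df <= 0:
        raise ValueError("need at least 3 observations for a correlation p-value")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return p


def _edgewise_pearson(E: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each edge column of E against the vector y."""
    Ec = E - E.mean(axis=0)
    yc = y - y.mean()
    num = Ec.T @ yc
    den = np.sqrt((Ec * Ec).sum(axis=0) * (yc @ yc))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(den > 0, num / den, 0.0)
    return np.clip(r, -1.0, 1.0)


def compute_motion_mask(
    profiles, motion_mm: Sequence[float], alpha: float = 0.05, node_count: int | None = None
) -> EdgeMask:
    """Mask out edges significantly correlated with (z-scored) head motion.

    Motion values are z-scored across participants; each edge is Pearson-
    correlated with the z-scored motion vector and removed when the
    two-tailed p < alpha (strict).  Constant motion makes the rule
    degenerate: a warning is logged and no edge is removed.
    """
    E, nc = _as_edge_matrix(profiles, node_count)
    motion = np.asarray(motion_mm, dtype=float)
    if motion.shape != (E.shape[0],):
        raise ValueError("need exactly one motion value per profile")
    if E.shape[0] < 4:
        raise ValueError("need at least 4 participants to estimate motion coupling")

    sd = motion.std(ddof=1)
    if sd == 0:
        warnings.warn(
            "motion is constant across participants; motion mask removes nothing",
            stacklevel=2,
        )
        return EdgeMask.all_valid(nc)
    z_motion = (motion - motion.mean()) / sd

    r = _edgewise_pearson(E, z_motion)
    p = pearson_r_pvalues(r, n=E.shape[0])
    removed = p < alpha
    valid = ~removed
    iu, ju = np.triu_indices(nc, k=1)
    provenance = {
        (int(iu[k]), int(ju[k])): "motion" for k in np.flatnonzero(removed)
    }
    return EdgeMask(nc, valid, provenance)


def compute_site_mask(
    profiles,
    site: Sequence[str],
    alpha: float = 0.05,
    node_count: int | None = None,
    equal_var: bool = False,
) -> EdgeMask:
    """Mask out edges that differ between the two acquisition sites.

    Per edge, a two-sample t-test (Welch by default; the site samples are
    unbalanced) between the two site groups; edges with two-tailed
    p < alpha (strict) are removed.  Exactly two site labels must be
    present, each with at least 2 participants.
    """
    E, nc = _as_edge_matrix(profiles, node_count)
    site = np.asarray(site)
    if site.shape != (E.shape[0],):
        raise ValueError("need exactly one site label per profile")
    labels = np.unique(site)
    if labels.size != 2:
        raise ValueError(f"site masking requires exactly 2 sites, got {labels.tolist()}")
    a = E[site == labels[0]]
    b = E[site == labels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each site needs at least 2 participants")

    res = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    removed = res.pvalue < alpha
    valid = ~removed
    iu, ju = np.triu_indices(nc, k=1)
    provenance = {(int(iu[k]), int(ju[k])): "site" for k in np.flatnonzero(removed)}
    return EdgeMask(nc, valid, provenance)


def foldwise_confound_valid(
    profiles,
    motion_mm: Sequence[float],
    site: Sequence[str],
    alpha: float = 0.05,
    node_count: int | None = None,
    equal_var: bool = False,
) -> np.ndarray:
    """Per-leave-one-out-fold validity matrix (strict train-only masking).

    Row i is the combined motion+site mask computed on the sample that
    excludes participant i — the stricter alternative to computing one mask
    on the full analysis sample.  Masks depend only on motion and site, so
    the matrix can be computed once and reused across permutation shuffles.
    Returns an (n_participants, n_edges) boolean array for the LOO engine.
    """
    E, nc = _as_edge_matrix(profiles, node_count)
    motion = np.asarray(motion_mm, dtype=float)
    site = np.asarray(site)
    n = E.shape[0]
    valid = np.empty((n, E.shape[1]), dtype=bool)
    for i in range(n):
        train = np.arange(n) != i
        masks = [compute_motion_mask(E[train], motion[train], alpha=alpha, node_count=nc)]
        if len(np.unique(site[train])) == 2:
            masks.append(
                compute_site_mask(
                    E[train], site[train], alpha=alpha, node_count=nc,
                    equal_var=equal_var,
                )
            )
        valid[i] = combine_masks(masks).valid
    return valid


def combine_masks(masks: Sequence[EdgeMask]) -> EdgeMask:
    """Logical AND of masks; provenance keeps the first reason recorded.

    Pass the motion mask first so that edges removed by both confounds are
    attributed to motion, matching the bookkeeping order of the protocol.
    """
    masks = list(masks)
    if not masks:
        raise ValueError("no masks to combine")
    nc = masks[0].node_count
    for m in masks[1:]:
        if m.node_count != nc:
            raise ValueError(
                f"node_count mismatch: {m.node_count} vs {nc}"
            )
    valid = np.ones_like(masks[0].valid)
    provenance: dict[tuple[int, int], str] = {}
    for m in masks:
        valid &= m.valid
        for edge, reason in m.provenance.items():
            provenance.setdefault(edge, reason)
    return EdgeMask(nc, valid, provenance)
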