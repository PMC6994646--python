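"""Functional-connectivity profile construction.

A participant's *connectome* (FC profile) is a symmetric node x node matrix
of Fisher-z transformed Pearson correlations between regional BOLD
timecourses.  Nodes come from an integer-labelled whole-brain parcellation
(268 regions by default); timecourses are the mean BOLD signal over each
region's voxels.  The diagonal is stored as NaN and is never read by any
downstream operation: every edge-wise computation in this package iterates
over the strict upper triangle with 0-based indices (i < j), in the
row-major order of ``numpy.triu_indices``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

#: Number of nodes in the default whole-brain parcellation.
DEFAULT_NODE_COUNT = 268

#: Pearson r is clamped to +/- this value before the Fisher transform so
#: that perfectly (anti)correlated timecourses still map to a finite edge.
CLIP_R = 1.0 - 1e-7


def count_unique_edges(node_count: int) -> int:
    """Number of unique undirected edges among ``node_count`` nodes.

    For a symmetric connectivity matrix only the strict upper triangle
    carries information: n * (n - 1) / 2 edges (35,778 for n = 268).
    """
    if node_count < 1:
        raise ValueError(f"node_count must be >= 1, got {node_count}")
    return node_count * (node_count - 1) // 2


def edge_index_pairs(node_count: int) -> tuple[np.ndarray, np.ndarray]:
    """(i, j) node indices of every unique edge, in canonical order."""
    return np.triu_indices(node_count, k=1)


@dataclass
class NodeTimeseries:
    """Per-participant node x timepoint matrix of (denoised) BOLD values."""

    participant_id: str
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("timeseries data must be a 2-D nodes x timepoints array")
        if self.data.shape[1] < 3:
            raise ValueError(
                f"need at least 3 timepoints for a Pearson correlation, "
                f"got {self.data.shape[1]}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("timeseries contains missing or non-finite values")

    @property
    def node_count(self) -> int:
        return self.data.shape[0]

    @property
    def timepoint_count(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectivityProfile:
    """Symmetric Fisher-z connectivity matrix for one participant.

    The diagonal holds NaN sentinels; ``edge_values`` exposes the strict
    upper triangle as a flat vector in canonical edge order.
    """

    participant_id: str
    z_matrix: np.ndarray

    def __post_init__(self) -> None:
        self.z_matrix = np.asarray(self.z_matrix, dtype=float)
        z = self.z_matrix
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError("z_matrix must be square")
        off = ~np.eye(z.shape[0], dtype=bool)
        if not np.all(np.isfinite(z[off])):
            raise ValueError("off-diagonal Fisher-z values must be finite")
        if not np.array_equal(z[off], z.T[off]):
            raise ValueError("z_matrix must be symmetric")

    @property
    def node_count(self) -> int:
        return self.z_matrix.shape[0]

    def edge_values(self) -> np.ndarray:
        """Flat vector of upper-triangle edge values (canonical order)."""
        iu, ju = np.triu_indices(self.node_count, k=1)
        return self.z_matrix[iu, ju]


def compute_fc_profile(ts: NodeTimeseries, clip_r: float = CLIP_R) -> ConnectivityProfile:
    """Pearson-correlate all node pairs and Fisher-z transform.

    For nodes i != j, ``z = atanh(clamp(r, -clip_r, +clip_r))`` where r is
    the Pearson correlation of the two timecourses.  Clamping keeps edges
    finite when |r| = 1 (downstream network strengths are sums).  A node
    with zero temporal variance has no defined correlation and raises.
    """
    X = ts.data
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(
            f"zero-variance timecourse for node(s) {bad.tolist()} of "
            f"participant {ts.participant_id!r}"
        )
    r = np.corrcoef(X)
    np.clip(r, -clip_r, clip_r, out=r)
    z = np.arctanh(r)
    # enforce exact symmetry: copy the upper triangle into the lower
    z = np.triu(z, k=1)
    z = z + z.T
    np.fill_diagonal(z, np.nan)
    return ConnectivityProfile(participant_id=ts.participant_id, z_matrix=z)


def extract_node_timeseries(volume, atlas, participant_id: str = "") -> NodeTimeseries:
    """Mean regional timecourses from a 4-D volume and an integer atlas.

    ``volume`` and ``atlas`` may be nibabel images or paths to NIfTI files.
    Atlas labels must be the integers 1..node_count (0 = background); row k
    of the result is the mean over all voxels carrying label k+1, at each
    timepoint.  A label with no voxels is an error (the parcellation does
    not cover the acquired field of view).
    """
    import nibabel as nib

    if isinstance(volume, (str, Path)):
        volume = nib.load(str(volume))
    if isinstance(atlas, (str, Path)):
        atlas = nib.load(str(atlas))

    vol = np.asanyarray(volume.dataobj, dtype=float)
    lab = np.asanyarray(atlas.dataobj)
    if vol.ndim != 4:
        raise ValueError(f"volume must be 4-D, got shape {vol.shape}")
    if lab.ndim != 3:
        raise ValueError(f"atlas must be 3-D, got shape {lab.shape}")
    if vol.shape[:3] != lab.shape:
        raise ValueError(
            f"grid mismatch: volume {vol.shape[:3]} vs atlas {lab.shape}"
        )
    if not np.all(lab == np.round(lab)):
        raise ValueError("atlas contains non-integer labels")
    lab = lab.astype(int)
    if lab.min() < 0:
        raise ValueError("atlas labels must be non-negative integers")

    node_count = int(lab.max())
    if node_count < 1:
        raise ValueError("atlas contains no labelled voxels")
    n_t = vol.shape[3]
    flat_vol = vol.reshape(-1, n_t)
    flat_lab = lab.reshape(-1)
    data = np.empty((node_count, n_t))
    for k in range(1, node_count + 1):
        sel = flat_lab == k
        if not sel.any():
            raise ValueError(f"atlas label {k} has no voxels")
        data[k - 1] = flat_vol[sel].mean(axis=0)
    return NodeTimeseries(participant_id=participant_id, data=data)


def profiles_to_edge_matrix(
    profiles: Sequence[ConnectivityProfile],
) -> tuple[np.ndarray, int, list[str]]:
    """Stack profiles into a participants x edges matrix.

    Returns ``(edge_matrix, node_count, participant_ids)``; columns follow
    the canonical upper-triangle edge order.
    """
    if len(profiles) == 0:
        raise ValueError("no profiles given")
    node_count = profiles[0].node_count
    for p in profiles:
        if p.node_count != node_count:
            raise ValueError(
                f"node_count mismatch: {p.participant_id!r} has {p.node_count}, "
                f"expected {node_count}"
            )
    E = np.vstack([p.edge_values() for p in profiles])
    ids = [p.participant_id for p in profiles]
    return E, node_count, ids


def edge_matrix_to_profile(
    edge_values: np.ndarray, node_count: int, participant_id: str = ""
) -> ConnectivityProfile:
    """Rebuild a symmetric profile from a flat edge vector."""
    edge_values = np.asarray(edge_values, dtype=float)
    if edge_values.shape != (count_unique_edges(node_count),):
        raise ValueError(
            f"expected {count_unique_edges(node_count)} edge values for "
            f"{node_count} nodes, got {edge_values.shape}"
        )
    z = np.full((node_count, node_count), np.nan)
    iu, ju = np.triu_indices(node_count, k=1)
    z[iu, ju] = edge_values
    z[ju, iu] = edge_values
    return ConnectivityProfile(participant_id=participant_id, z_matrix=z)
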