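"""Vectorised leave-one-out CPM engine.

Re-running edge selection inside every cross-validation fold (and inside
every permutation of a permutation test) is the cost centre of the whole
protocol.  This engine exploits the fact that for leave-one-out folds all
per-edge Pearson statistics differ from the full-sample statistics by one
participant's contribution: sufficient statistics (sums, squared sums,
cross-products) are computed once per behavior vector and the per-fold
correlations for *all* folds and edges fall out of a handful of broadcast
operations.  The p < alpha selection threshold is applied as an equivalent
threshold on r^2 (the t statistic is monotone in |r| at fixed df), so no
per-edge p-values are materialised on the fast path.

Per fold, the admitted edges are summed into network strengths and an OLS
line from strength to behavior predicts the held-out participant.  Because
OLS commutes exactly with affine transforms of the target, fitting raw
behavior here is identical to the protocol's "z-score on the training
fold, fit, un-standardize" sequence.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


class LOOEngine:
    """Leave-one-out CPM predictions for repeated behavior vectors.

    Parameters
    ----------
    edges:
        (n_participants, n_edges) matrix of Fisher-z edge values in
        canonical upper-triangle order.
    valid:
        boolean validity mask over edges: either one (n_edges,) vector
        (global confound masking) or an (n_participants, n_edges) matrix
        giving each leave-one-out fold its own training-sample mask.
    """

    def __init__(self, edges: np.ndarray, valid: np.ndarray):
        E = np.ascontiguousarray(edges, dtype=np.float64)
        if E.ndim != 2:
            raise ValueError("edge matrix must be 2-D")
        self.n, self.n_edges = E.shape
        if self.n < 4:
            raise ValueError("need at least 4 participants for leave-one-out folds")
        valid = np.asarray(valid, dtype=bool)
        if valid.shape not in ((self.n_edges,), (self.n, self.n_edges)):
            raise ValueError("valid mask does not match edge matrix shape")
        self.E = E
        self.ET = np.ascontiguousarray(E.T)
        self.valid = valid
        m = self.n - 1
        self.m = m
        Sx = E.sum(axis=0)
        # per-fold training sums: row i excludes participant i
        self.A = Sx[None, :] - E                       # Σ_train x
        Sxx = (E * E).sum(axis=0)
        self.denx = m * (Sxx[None, :] - E * E) - self.A**2   # m·Σx² − (Σx)²
        # edges that are constant in some training fold can never be selected
        self._admissible = (self.denx > 0) & np.atleast_2d(valid)
        # scratch buffers reused across behavior vectors (permutation loops)
        self._buf = np.empty_like(E)
        self._buf2 = np.empty_like(E)
        self._bbuf = np.empty(E.shape, dtype=bool)
        self._bbuf2 = np.empty(E.shape, dtype=bool)

    def r_critical_sq(self, alpha: float) -> float:
        """Squared Pearson-r threshold equivalent to two-tailed p < alpha."""
        df = self.m - 2
        if df <= 0:
            raise ValueError("too few participants for edge selection p-values")
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
        return tcrit * tcrit / (tcrit * tcrit + df)

    def fold_selection(self, y: np.ndarray, tail: str, alpha: float) -> np.ndarray:
        """(n_folds, n_edges) boolean selection per leave-one-out fold."""
        return self._fold_selection_into(y, tail, alpha).copy()

    def _fold_selection_into(self, y: np.ndarray, tail: str, alpha: float) -> np.ndarray:
        """Selection written into an internal buffer (invalidated by the next call)."""
        m = self.m
        y = np.asarray(y, dtype=np.float64)
        if y.shape != (self.n,):
            raise ValueError("behavior vector length mismatch")
        Sy = y.sum()
        Syy = y @ y
        Sxy = self.ET @ y
        Sy_i = Sy - y                                   # Σ_train y, per fold
        deny = m * (Syy - y * y) - Sy_i**2              # scalar per fold
        rc2 = self.r_critical_sq(alpha)
        if tail not in ("positive", "negative"):
            raise ValueError(f"tail must be 'positive' or 'negative', got {tail!r}")

        # num[i, e] = m·Σ_train(x·y) − Σ_train(x)·Σ_train(y), built in-place
        num, tmp = self._buf, self._buf2
        np.multiply(self.E, (-m * y)[:, None], out=num)
        np.multiply(self.A, Sy_i[:, None], out=tmp)
        num -= tmp
        num += (m * Sxy)[None, :]

        # p < alpha  <=>  num² > rc² · denx · deny  (with the tail's sign)
        sel = self._bbuf
        if tail == "negative":
            np.less(num, 0.0, out=sel)
        else:
            np.greater(num, 0.0, out=sel)
        np.square(num, out=num)
        np.multiply(self.denx, (rc2 * deny)[:, None], out=tmp)
        np.greater(num, tmp, out=self._bbuf2)
        sel &= self._bbuf2
        sel &= self._admissible
        return sel

    def run(
        self,
        y: np.ndarray,
        tail: str,
        alpha: float,
        selection_counts: np.ndarray | None = None,
    ):
        """LOO predictions for behavior vector ``y``.

        Returns ``(predicted, n_degenerate)``.  A fold whose selection is
        empty (or whose strengths are constant) predicts the training-fold
        mean behavior and counts as degenerate.  If ``selection_counts``
        (an int array over edges) is given, each fold's selected edges are
        tallied into it, for consensus-network reporting.
        """
        y = np.asarray(y, dtype=np.float64)
        sel = self._fold_selection_into(y, tail, alpha)
        return self.predict_from_selection(y, sel, selection_counts=selection_counts)

    def predict_from_selection(
        self,
        y: np.ndarray,
        sel: np.ndarray,
        selection_counts: np.ndarray | None = None,
    ):
        """LOO predictions given a precomputed (n_folds, n_edges) selection.

        Used by the reduced permutation mode, where the observed-data fold
        selections are held fixed and only the strength model is refit per
        shuffle.
        """
        y = np.asarray(y, dtype=np.float64)
        m = self.m
        Sy_i = y.sum() - y
        pred = np.empty(self.n)
        n_degenerate = 0
        for i in range(self.n):
            idx = np.flatnonzero(sel[i])
            if selection_counts is not None:
                selection_counts[idx] += 1
            if idx.size == 0:
                pred[i] = Sy_i[i] / m
                n_degenerate += 1
                continue
            s = self.ET[idx].sum(axis=0)              # strengths, all participants
            Ss = s.sum() - s[i]
            Sss = s @ s - s[i] * s[i]
            d = m * Sss - Ss * Ss
            if d <= 0:
                pred[i] = Sy_i[i] / m
                n_degenerate += 1
                continue
            Ssy = s @ y - s[i] * y[i]
            slope = (m * Ssy - Ss * Sy_i[i]) / d
            intercept = (Sy_i[i] - slope * Ss) / m
            pred[i] = intercept + slope * s[i]
        return pred, n_degenerate
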