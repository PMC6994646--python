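"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately naive (explicit loops, scalar scipy calls,
textbook formulas) and shares no code with the package's vectorised paths.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def pearson_loop(x, y):
    """Textbook Pearson correlation via explicit sums."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    num = float(((x - mx) * (y - my)).sum())
    den = float(np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum()))
    return num / den


def fc_matrix_loop(data, clip):
    """Per-pair Pearson + Fisher z with an explicit double loop."""
    n = data.shape[0]
    z = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            r = pearson_loop(data[i], data[j])
            r = min(max(r, -clip), clip)
            z[i, j] = z[j, i] = np.arctanh(r)
    return z


def roi_means_loop(vol, atlas, n_labels):
    """Mean regional timecourses via an explicit per-voxel accumulation."""
    n_t = vol.shape[3]
    sums = np.zeros((n_labels, n_t))
    counts = np.zeros(n_labels)
    for ix in range(vol.shape[0]):
        for iy in range(vol.shape[1]):
            for iz in range(vol.shape[2]):
                lab = int(atlas[ix, iy, iz])
                if lab > 0:
                    sums[lab - 1] += vol[ix, iy, iz]
                    counts[lab - 1] += 1
    return sums / counts[:, None]


def midranks(values):
    """Average ranks (1-based) with midrank tie handling, by hand."""
    values = np.asarray(values, float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_loop(x, y):
    """Spearman rs = Pearson correlation of midranks, all by hand."""
    return pearson_loop(midranks(x), midranks(y))


def partial_spearman_residual(x, y, c):
    """Partial rank correlation via explicit residualisation of ranks."""
    rx, ry, rc = midranks(x), midranks(y), midranks(c)

    def residualise(v, on):
        design = np.column_stack([np.ones_like(on), on])
        beta, *_ = np.linalg.lstsq(design, v, rcond=None)
        return v - design @ beta

    ex = residualise(rx, rc)
    ey = residualise(ry, rc)
    return pearson_loop(ex, ey)


def edgewise_selection_loop(E, y, valid, alpha):
    """Per-edge scalar pearsonr selection: (positive set, negative set)."""
    pos, neg = set(), set()
    for e in range(E.shape[1]):
        if not valid[e]:
            continue
        r, p = stats.pearsonr(E[:, e], y)
        if p < alpha:
            if r > 0:
                pos.add(e)
            elif r < 0:
                neg.add(e)
    return pos, neg


def motion_removal_loop(E, motion, alpha):
    """Per-edge scalar motion-correlation removals (set of flat indices)."""
    z = (motion - motion.mean()) / motion.std(ddof=1)
    removed = set()
    for e in range(E.shape[1]):
        _, p = stats.pearsonr(E[:, e], z)
        if p < alpha:
            removed.add(e)
    return removed


def naive_loo_predictions(E, y, valid, alpha, tail):
    """Leave-one-out CPM with the protocol spelled out per fold.

    Per fold: z-score the training behavior (sample SD), select edges by
    scalar pearsonr on the training rows, sum the selected columns into
    strengths, OLS-fit strength -> z-behavior, predict the held-out
    participant and map back to the original scale.
    """
    n = len(y)
    pred = np.empty(n)
    for i in range(n):
        train = np.array([k for k in range(n) if k != i])
        yt = y[train]
        mu, sd = yt.mean(), yt.std(ddof=1)
        yz = (yt - mu) / sd
        pos, neg = edgewise_selection_loop(E[train], yz, valid, alpha)
        sel = sorted(pos if tail == "positive" else neg)
        if not sel:
            pred[i] = mu
            continue
        s_train = np.array([sum(E[k, e] for e in sel) for k in train])
        if s_train.std() == 0:
            pred[i] = mu
            continue
        slope, intercept = np.polyfit(s_train, yz, 1)
        s_i = sum(E[i, e] for e in sel)
        pred[i] = mu + sd * (intercept + slope * s_i)
    return pred
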