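"""Cross-validation schemes, Spearman evaluation and permutation inference.

Model performance is always the Spearman rank correlation between observed
and cross-validated predicted scores (robust to outliers, and CPM
predictions are best read as relative rather than absolute).  The
parametric p attached to that correlation over-states significance — the
leave-one-out folds are not independent — so it is used only as a gate:
models whose LOO correlation is positive and parametrically significant at
p < 0.05 proceed to permutation testing, where the behavior vector is
shuffled and the *entire* pipeline (per-fold z-scoring, edge selection,
fit, prediction) is re-run per shuffle.

The permutation p-value is exact and one-tailed:

    p = (1 + #{null rs >= observed rs}) / (n_perm + 1)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from ._engine import LOOEngine
from .cpm import (
    DEFAULT_SELECTION_ALPHA,
    edge_set_to_flat_indices,
    fit_cpm,
    network_strengths_from_matrix,
    select_edges,
    zscore,
)
from .dataset import CPMDataset
from .masking import EdgeMask, combine_masks, compute_motion_mask, compute_site_mask

DEFAULT_N_PERM = 5000
GATE_ALPHA = 0.05
MIN_LOO_N = 10


@dataclass
class PredictionResult:
    """Observed vs cross-validated predicted scores for one model."""

    behavior_name: str
    tail: str
    participant_ids: list[str]
    observed: np.ndarray
    predicted: np.ndarray
    rs: float
    p_parametric: float
    n: int
    fold_degeneracies: int = 0
    metadata: dict = field(default_factory=dict)

    def gate_passed(self, alpha: float = GATE_ALPHA) -> bool:
        """Follow-up gate: a positive, parametrically significant rs."""
        return bool(np.isfinite(self.rs) and self.rs > 0 and self.p_parametric < alpha)


@dataclass
class PermutationResult:
    """Null distribution of rs under behavior shuffling, plus the exact p."""

    behavior_name: str
    tail: str
    observed_rs: float
    null_rs: np.ndarray
    p_perm: float
    n_perm: int
    seed: int | None = None


@dataclass
class CrossSiteDirection:
    """One train-on-site-A / predict-site-B direction."""

    source: str
    target: str
    gate: PredictionResult
    attempted: bool
    prediction: PredictionResult | None = None


def evaluate_spearman(predicted: Sequence[float], observed: Sequence[float]):
    """Spearman rs (midrank ties) with its parametric t-approximation p.

    The parametric p is advisory only (see module docstring).  A constant
    vector leaves ranks undefined: (nan, nan) is returned as the
    degenerate flag.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.ndim != 1:
        raise ValueError("predicted and observed must be 1-D vectors of equal length")
    if predicted.size < 3:
        raise ValueError("need at least 3 observations for a Spearman correlation")
    if np.ptp(predicted) == 0 or np.ptp(observed) == 0:
        return float("nan"), float("nan")
    res = stats.spearmanr(predicted, observed)
    return float(res.statistic), float(res.pvalue)


def permutation_pvalue(observed_rs: float, null_rs: Sequence[float]) -> float:
    """Exact one-tailed permutation p: (1 + #{null >= observed}) / (n + 1)."""
    null_rs = np.asarray(null_rs, dtype=float)
    if null_rs.size < 1:
        raise ValueError("need at least one permutation")
    return float((1 + np.count_nonzero(null_rs >= observed_rs)) / (null_rs.size + 1))


def _mask_valid(mask, dataset: CPMDataset) -> np.ndarray:
    """Validity array from an EdgeMask (global) or a boolean array.

    A (n_edges,) vector applies one mask to every fold; an
    (n_participants, n_edges) matrix gives each leave-one-out fold its own
    training-sample mask (see ``masking.foldwise_confound_valid``).
    """
    if isinstance(mask, EdgeMask):
        if mask.node_count != dataset.node_count:
            raise ValueError("mask node_count does not match dataset")
        return mask.valid
    return np.asarray(mask, dtype=bool)


def loo_cross_validation(
    dataset: CPMDataset,
    behavior_name: str,
    tail: str,
    mask,
    alpha: float = DEFAULT_SELECTION_ALPHA,
    consensus: bool = True,
) -> PredictionResult:
    """Leave-one-out CPM: N folds, each selecting edges and fitting afresh.

    Per fold the training behavior is z-scored, edges are selected at
    p < alpha on the training sample, strengths are summed and an OLS line
    predicts the held-out participant (folds with an empty selection
    predict the training mean and are counted in ``fold_degeneracies``).
    ``metadata['selection_frequency']`` records, per edge, the fraction of
    folds that selected it; the consensus network is the set selected in
    every fold.
    """
    if dataset.n < MIN_LOO_N:
        raise ValueError(
            f"leave-one-out needs at least {MIN_LOO_N} participants, got {dataset.n}"
        )
    y = dataset.behavior(behavior_name)
    engine = LOOEngine(dataset.edges, _mask_valid(mask, dataset))
    counts = np.zeros(dataset.edges.shape[1], dtype=int) if consensus else None
    pred, n_deg = engine.run(y, tail=tail, alpha=alpha, selection_counts=counts)
    rs, p = evaluate_spearman(pred, y)
    meta: dict = {"selection_alpha": alpha}
    if consensus:
        meta["selection_frequency"] = counts / dataset.n
    return PredictionResult(
        behavior_name=behavior_name,
        tail=tail,
        participant_ids=dataset.participant_ids,
        observed=y,
        predicted=pred,
        rs=rs,
        p_parametric=p,
        n=dataset.n,
        fold_degeneracies=n_deg,
        metadata=meta,
    )


def consensus_edges(result: PredictionResult, node_count: int, threshold: float = 1.0):
    """Edges selected in at least ``threshold`` fraction of LOO folds."""
    freq = result.metadata.get("selection_frequency")
    if freq is None:
        raise ValueError("result carries no selection frequencies")
    iu, ju = np.triu_indices(node_count, k=1)
    keep = np.flatnonzero(freq >= threshold)
    return [((int(iu[k]), int(ju[k])), float(freq[k])) for k in keep]


def permutation_test(
    dataset: CPMDataset,
    behavior_name: str,
    tail: str,
    mask,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    alpha: float = DEFAULT_SELECTION_ALPHA,
    perm_loo: str = "full",
) -> PermutationResult:
    """Full-pipeline permutation test of the LOO Spearman correlation.

    The raw behavior vector is shuffled ``n_perm`` times (seeded); with
    ``perm_loo='full'`` (the default and the faithful null) each shuffle
    re-runs the complete leave-one-out pipeline — selection, fit and
    prediction — and contributes one null rs (predicted vs shuffled
    scores).  ``perm_loo='strength_refit'`` is a cheaper approximation
    that freezes the observed-data fold selections and only refits the
    strength model per shuffle; its null is narrower because the selection
    step's overfitting is not replayed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if perm_loo not in ("full", "strength_refit"):
        raise ValueError(f"perm_loo must be 'full' or 'strength_refit', got {perm_loo!r}")
    y = dataset.behavior(behavior_name)
    engine = LOOEngine(dataset.edges, _mask_valid(mask, dataset))
    if perm_loo == "strength_refit":
        fixed_sel = engine.fold_selection(y, tail, alpha)
        pred, _ = engine.predict_from_selection(y, fixed_sel)
    else:
        fixed_sel = None
        pred, _ = engine.run(y, tail=tail, alpha=alpha)
    observed_rs, _ = evaluate_spearman(pred, y)

    rng = np.random.default_rng(seed)
    null_rs = np.empty(n_perm)
    for k in range(n_perm):
        y_perm = rng.permutation(y)
        if fixed_sel is not None:
            pred_k, _ = engine.predict_from_selection(y_perm, fixed_sel)
        else:
            pred_k, _ = engine.run(y_perm, tail=tail, alpha=alpha)
        null_rs[k], _ = evaluate_spearman(pred_k, y_perm)
    p_perm = permutation_pvalue(observed_rs, null_rs)
    return PermutationResult(
        behavior_name=behavior_name,
        tail=tail,
        observed_rs=observed_rs,
        null_rs=null_rs,
        p_perm=p_perm,
        n_perm=n_perm,
        seed=seed,
    )


def stratified_split(
    site: Sequence[str], group: Sequence[str], seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Random half split preserving site x group stratum counts.

    Each stratum is shuffled and divided as evenly as possible; strata with
    an odd count donate their extra member to the two halves alternately
    (in sorted stratum order), so the halves end up the same size whenever
    the parity of odd strata allows it.
    """
    site = np.asarray(site)
    group = np.asarray(group)
    rng = np.random.default_rng(seed)
    strata = sorted(set(zip(site.tolist(), group.tolist())))
    half_a: list[int] = []
    half_b: list[int] = []
    odd_toggle = 0
    for st in strata:
        idx = np.flatnonzero((site == st[0]) & (group == st[1]))
        if idx.size < 2:
            raise ValueError(f"stratum {st} has fewer than 2 members")
        idx = rng.permutation(idx)
        base = idx.size // 2
        if idx.size % 2 == 0:
            cut = base
        else:
            cut = base + 1 if odd_toggle == 0 else base
            odd_toggle ^= 1
        half_a.extend(idx[:cut].tolist())
        half_b.extend(idx[cut:].tolist())
    return np.asarray(sorted(half_a)), np.asarray(sorted(half_b))


def _train_and_predict(
    train: CPMDataset,
    test: CPMDataset,
    behavior_name: str,
    tail: str,
    mask: EdgeMask,
    alpha: float,
) -> PredictionResult:
    """Select + fit on the whole training set, predict every test member."""
    y_train = train.behavior(behavior_name)
    selection = select_edges(
        train.edges, zscore(y_train), mask, alpha=alpha, node_count=train.node_count
    )
    edges = sorted(selection.tail(tail))
    flat = edge_set_to_flat_indices(edges, train.node_count)
    n_deg = 0
    if flat.size == 0:
        pred = np.full(test.n, y_train.mean())
        n_deg = 1
    else:
        s_train = network_strengths_from_matrix(train.edges, flat)
        model = fit_cpm(s_train, y_train, tail=tail, edges=edges, behavior_name=behavior_name)
        s_test = network_strengths_from_matrix(test.edges, flat)
        pred = model.intercept + model.slope * s_test
    y_test = test.behavior(behavior_name)
    rs, p = evaluate_spearman(pred, y_test)
    return PredictionResult(
        behavior_name=behavior_name,
        tail=tail,
        participant_ids=test.participant_ids,
        observed=y_test,
        predicted=pred,
        rs=rs,
        p_parametric=p,
        n=test.n,
        fold_degeneracies=n_deg,
        metadata={"n_train": train.n, "n_selected_edges": len(edges)},
    )


def _masks_for(dataset: CPMDataset, mask_alpha: float, with_site: bool = True) -> EdgeMask:
    """Motion (+ optional site) confound mask computed on ``dataset``."""
    masks = [
        compute_motion_mask(
            dataset.edges,
            dataset.column("motion_mm").astype(float),
            alpha=mask_alpha,
            node_count=dataset.node_count,
        )
    ]
    if with_site:
        masks.append(
            compute_site_mask(
                dataset.edges,
                dataset.column("site"),
                alpha=mask_alpha,
                node_count=dataset.node_count,
            )
        )
    return combine_masks(masks)


def split_half_validation(
    dataset: CPMDataset,
    behavior_name: str,
    tail: str,
    seed: int | None = None,
    alpha: float = DEFAULT_SELECTION_ALPHA,
    mask_alpha: float = 0.05,
) -> tuple[PredictionResult, PredictionResult]:
    """Stratified split-half prediction: train in one half, predict the other.

    The cohort is split in half at random while preserving the number of
    participants per site and per diagnostic group.  Within each half a
    confound mask is computed and a leave-one-out gate run; the model
    (selection + fit on the whole half) then predicts every member of the
    opposite half.  Returns (half-1 -> half-2, half-2 -> half-1) results;
    each carries its training half's gate in ``metadata['gate']``.
    """
    idx_a, idx_b = stratified_split(
        dataset.column("site"), dataset.column("group"), seed=seed
    )
    halves = {"1": dataset.subset(idx_a), "2": dataset.subset(idx_b)}
    results = []
    for src, dst in (("1", "2"), ("2", "1")):
        train, test = halves[src], halves[dst]
        mask = _masks_for(train, mask_alpha)
        gate = loo_cross_validation(
            train, behavior_name, tail, mask, alpha=alpha, consensus=False
        )
        res = _train_and_predict(train, test, behavior_name, tail, mask, alpha)
        res.metadata["gate"] = {
            "rs": gate.rs,
            "p_parametric": gate.p_parametric,
            "passed": gate.gate_passed(),
        }
        res.metadata["train_half"] = src
        results.append(res)
    return results[0], results[1]


def cross_site_validation(
    dataset: CPMDataset,
    behavior_name: str,
    tail: str,
    alpha: float = DEFAULT_SELECTION_ALPHA,
    mask_alpha: float = 0.05,
) -> list[CrossSiteDirection]:
    """Site-to-site prediction with a within-site leave-one-out gate.

    For each direction, a model is considered for export only if a LOO
    analysis *within the source site* produces a positive, significant
    (parametric p < 0.05) Spearman correlation; otherwise cross-site
    prediction is flagged not-attempted.  The site mask is omitted
    (training data come from a single site); the motion mask is computed
    within the source site.
    """
    sites = sorted(set(dataset.column("site").tolist()))
    if len(sites) < 2:
        raise ValueError("cross-site validation needs two sites")
    if len(sites) > 2:
        raise ValueError(f"expected exactly 2 sites, got {sites}")
    directions = []
    for src, tgt in ((sites[0], sites[1]), (sites[1], sites[0])):
        train = dataset.subset(dataset.column("site") == src)
        test = dataset.subset(dataset.column("site") == tgt)
        mask = _masks_for(train, mask_alpha, with_site=False)
        gate = loo_cross_validation(
            train, behavior_name, tail, mask, alpha=alpha, consensus=False
        )
        if gate.gate_passed():
            res = _train_and_predict(train, test, behavior_name, tail, mask, alpha)
            directions.append(
                CrossSiteDirection(source=src, target=tgt, gate=gate, attempted=True, prediction=res)
            )
        else:
            directions.append(
                CrossSiteDirection(source=src, target=tgt, gate=gate, attempted=False)
            )
    return directions
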