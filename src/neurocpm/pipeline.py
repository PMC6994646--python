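"""End-to-end orchestration: filter -> mask -> leave-one-out -> permutation.

This is the analysis a user actually runs: apply the exclusion rules for
the chosen behavioral measure, compute motion and site confound masks on
the resulting sample, run leave-one-out CPM for the requested tail, gate on
the parametric Spearman p, and (if gated in) assess significance by
full-pipeline permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortFilterReport, filter_phenotype
from .dataset import CPMDataset
from .masking import (
    EdgeMask,
    combine_masks,
    compute_motion_mask,
    compute_site_mask,
    foldwise_confound_valid,
)
from .validation import (
    DEFAULT_N_PERM,
    PermutationResult,
    PredictionResult,
    loo_cross_validation,
    permutation_test,
)


@dataclass
class AnalysisConfig:
    """Tunable knobs of the pipeline (defaults follow the protocol)."""

    selection_alpha: float = 0.01    # edge-selection threshold, two-tailed
    mask_alpha: float = 0.05         # confound-mask threshold, two-tailed
    mask_scope: str = "global"       # "global" (protocol) or "train_only"
    welch: bool = True               # Welch t for the site mask
    n_perm: int = DEFAULT_N_PERM
    gate_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class AnalysisResult:
    """Everything one filter+mask+LOO(+permutation) run produced."""

    measure: str
    tail: str
    filter_report: CohortFilterReport
    mask: "EdgeMask | np.ndarray"   # per-fold validity matrix if train_only
    loo: PredictionResult
    permutation: PermutationResult | None = None


def compute_confound_masks(
    dataset: CPMDataset, config: AnalysisConfig | None = None
) -> EdgeMask:
    """Motion and site masks on the given sample, combined (motion first)."""
    config = config or AnalysisConfig()
    motion = compute_motion_mask(
        dataset.edges,
        dataset.column("motion_mm").astype(float),
        alpha=config.mask_alpha,
        node_count=dataset.node_count,
    )
    site = compute_site_mask(
        dataset.edges,
        dataset.column("site"),
        alpha=config.mask_alpha,
        node_count=dataset.node_count,
        equal_var=not config.welch,
    )
    return combine_masks([motion, site])


def analyze(
    dataset: CPMDataset,
    measure: str,
    tail: str = "negative",
    config: AnalysisConfig | None = None,
    seed: int | None = None,
    run_permutation: bool = True,
) -> AnalysisResult:
    """Run the full protocol for one behavioral measure and one tail.

    Exclusion rules are applied for ``measure``; confound masks are
    computed once on the filtered sample (``mask_scope='global'``, the
    protocol's published behaviour) or per training fold
    (``mask_scope='train_only'``, the stricter alternative with no
    test-sample leakage); leave-one-out CPM is evaluated by Spearman;
    permutation testing runs only when the parametric gate (positive rs,
    p < gate_alpha) passes and ``run_permutation`` is True.
    """
    config = config or AnalysisConfig()
    _, report = filter_phenotype(dataset.phenotype, measure)
    keep = np.asarray(
        [pid in set(report.retained_ids) for pid in dataset.participant_ids]
    )
    sample = dataset.subset(keep)

    if config.mask_scope == "train_only":
        mask = foldwise_confound_valid(
            sample.edges,
            sample.column("motion_mm").astype(float),
            sample.column("site"),
            alpha=config.mask_alpha,
            node_count=sample.node_count,
            equal_var=not config.welch,
        )
    elif config.mask_scope == "global":
        mask = compute_confound_masks(sample, config)
    else:
        raise ValueError(f"unknown mask_scope {config.mask_scope!r}")
    loo = loo_cross_validation(
        sample, measure, tail, mask, alpha=config.selection_alpha
    )
    perm = None
    if run_permutation and loo.gate_passed(config.gate_alpha):
        perm = permutation_test(
            sample,
            measure,
            tail,
            mask,
            n_perm=config.n_perm,
            seed=seed,
            alpha=config.selection_alpha,
        )
    return AnalysisResult(
        measure=measure,
        tail=tail,
        filter_report=report,
        mask=mask,
        loo=loo,
        permutation=perm,
    )
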