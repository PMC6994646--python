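"""Model-specificity checks.

A predictive model could look good for uninteresting reasons: it might just
separate diagnostic groups (categorical rather than dimensional signal),
track residual head motion or IQ, or capture general symptom burden rather
than the targeted behavioral domain.  These checks probe each possibility
on the *same* cross-validated predictions, with no refitting:

* per-group Spearman correlations (TD and ASD separately);
* a cross-correlation table of predicted scores against motion (before and
  after cleaning), IQ, SRS total, the other observed behavioral-regulation
  domains, and age (exploratory — T-scores are age-normed);
* a rank-based partial correlation controlling for diagnosis.

Table cells are Bonferroni-corrected for the number of comparisons per
model (7 by default, so corrected alpha = 0.05 / 7 ~ 0.007).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import MEASURE_COLUMNS, flag_behavioral_outliers
from .validation import PredictionResult, evaluate_spearman

DEFAULT_N_COMPARISONS = 7
DIAGNOSIS_CODING = {"TD": 0, "ASD": 1}


@dataclass
class SpecificityReport:
    """Cross-domain correlation table plus per-group and partial results."""

    table: pd.DataFrame
    per_group: dict[str, dict[str, tuple[float, float]]]
    alpha_corrected: float
    n_comparisons: int
    partial: dict[str, dict[str, float]] = field(default_factory=dict)


def subgroup_evaluation(
    result: PredictionResult, groups: Sequence[str]
) -> dict[str, tuple[float, float]]:
    """Spearman rs and p within each group, on the pooled model's predictions."""
    groups = np.asarray(groups)
    if groups.shape != (result.n,):
        raise ValueError("need one group label per participant in the result")
    out: dict[str, tuple[float, float]] = {}
    for g in sorted(set(groups.tolist())):
        sel = groups == g
        if sel.sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 members")
        out[g] = evaluate_spearman(result.predicted[sel], result.observed[sel])
    return out


def partial_spearman(
    x: Sequence[float], y: Sequence[float], covariate: Sequence[float]
) -> float:
    """Rank-based partial correlation of x and y controlling for a covariate.

    All three vectors are midrank-transformed; the first-order partial
    Pearson formula is applied to the rank correlations:

        (r_xy - r_xc * r_yc) / sqrt((1 - r_xc^2) (1 - r_yc^2))

    A constant covariate carries no information (both rank correlations
    with it are taken as 0), so the result reduces exactly to the plain
    Spearman correlation.  |r_xc| = 1 or |r_yc| = 1 leaves the partial
    undefined: NaN is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(covariate, dtype=float)
    if not (x.shape == y.shape == c.shape) or x.ndim != 1:
        raise ValueError("x, y and covariate must be 1-D vectors of equal length")
    if x.size < 4:
        raise ValueError("need at least 4 observations for a partial correlation")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rc = stats.rankdata(c)

    def _corr(a, b):
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    r_xy = _corr(rx, ry)
    if np.ptp(rc) == 0:
        return r_xy
    r_xc = _corr(rx, rc)
    r_yc = _corr(ry, rc)
    den_sq = (1.0 - r_xc**2) * (1.0 - r_yc**2)
    if den_sq <= 1e-12:
        warnings.warn(
            "covariate is rank-collinear with x or y; partial correlation undefined",
            stacklevel=2,
        )
        return float("nan")
    return (r_xy - r_xc * r_yc) / np.sqrt(den_sq)


#: table columns -> canonical phenotype column supplying the comparison scores
_TABLE_COLUMNS = {
    "motion_before": "motion_mm",
    "motion_after": "motion_mm_after",
    "fiq": "fiq",
    "srs_total": "srs_total_t",
    "age": "age",
}


def cross_domain_table(
    predictions: Mapping[str, PredictionResult],
    phenotype: pd.DataFrame,
    n_comparisons: int = DEFAULT_N_COMPARISONS,
) -> SpecificityReport:
    """Correlate each model's predicted scores with potential confounds.

    ``predictions`` maps behavior measures (e.g. "shift") to their pooled
    cross-validated results; ``phenotype`` supplies the comparison columns
    by participant_id.  For each model the table holds Spearman rs and
    uncorrected p against motion before/after cleaning, FIQ, SRS total,
    the *other* observed behavioral-regulation domains, and age; cells are
    flagged significant at alpha = 0.05 / n_comparisons.  The SRS cell
    drops participants who are SRS outliers (> 3 SD) or missing SRS.
    Missing phenotype columns are reported as unavailable (NaN).
    """
    if not predictions:
        raise ValueError("need predictions for at least one behavior")
    pheno = phenotype.copy()
    pheno["participant_id"] = pheno["participant_id"].astype(str)
    pheno = pheno.set_index("participant_id")
    alpha_corrected = 0.05 / n_comparisons

    rows = []
    per_group: dict[str, dict[str, tuple[float, float]]] = {}
    partial: dict[str, dict[str, float]] = {}
    for name, result in predictions.items():
        ids = [str(i) for i in result.participant_ids]
        sub = pheno.loc[ids]
        pred = np.asarray(result.predicted, dtype=float)

        def _cell(values: np.ndarray, drop_outliers: bool = False):
            vals = np.asarray(values, dtype=float)
            ok = np.isfinite(vals)
            if drop_outliers and ok.sum() >= 2:
                out = flag_behavioral_outliers(np.where(ok, vals, np.nan))
                ok &= ~np.isin(np.arange(vals.size), list(out))
            if ok.sum() < 3:
                return float("nan"), float("nan"), ok.sum()
            rs, p = evaluate_spearman(pred[ok], vals[ok])
            return rs, p, int(ok.sum())

        row: dict[str, object] = {"model": name, "tail": result.tail}
        for label, col in _TABLE_COLUMNS.items():
            if col not in sub.columns:
                row[f"{label}_rs"] = float("nan")
                row[f"{label}_p"] = float("nan")
                row[f"{label}_n"] = 0
                continue
            rs, p, n_used = _cell(
                sub[col].to_numpy(dtype=float), drop_outliers=(label == "srs_total")
            )
            row[f"{label}_rs"] = rs
            row[f"{label}_p"] = p
            row[f"{label}_n"] = n_used
            row[f"{label}_significant"] = bool(np.isfinite(p) and p < alpha_corrected)

        # predicted scores vs the *other* observed behavioral domains
        for other, col in MEASURE_COLUMNS.items():
            if other == name:
                continue
            if col not in sub.columns:
                rs, p, n_used = float("nan"), float("nan"), 0
            else:
                rs, p, n_used = _cell(sub[col].to_numpy(dtype=float))
            row[f"observed_{other}_rs"] = rs
            row[f"observed_{other}_p"] = p
            row[f"observed_{other}_n"] = n_used
            row[f"observed_{other}_significant"] = bool(
                np.isfinite(p) and p < alpha_corrected
            )
        rows.append(row)

        if "group" in sub.columns:
            per_group[name] = subgroup_evaluation(result, sub["group"].to_numpy())
            if "srs_total_t" in sub.columns:
                srs = sub["srs_total_t"].to_numpy(dtype=float)
                diag = np.array([DIAGNOSIS_CODING.get(g, np.nan) for g in sub["group"]])
                ok = np.isfinite(srs) & np.isfinite(diag)
                if ok.sum() >= 4:
                    partial[name] = {
                        "srs_controlling_diagnosis": partial_spearman(
                            pred[ok], srs[ok], diag[ok]
                        )
                    }

    table = pd.DataFrame(rows).set_index("model")
    return SpecificityReport(
        table=table,
        per_group=per_group,
        alpha_corrected=alpha_corrected,
        n_comparisons=n_comparisons,
        partial=partial,
    )
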