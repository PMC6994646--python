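"""Seeded synthetic multi-site cohorts with planted brain-behavior structure.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage can be exercised end-to-end without any imaging
download:

* two acquisition sites ("GU", "KK") with cell sizes matching a 276-child
  two-site pediatric cohort (GU: 46 TD / 36 ASD; KK: 145 TD / 49 ASD);
* two diagnostic groups whose behavioral-regulation T-scores are shifted
  (TD mean 44, ASD mean 60 by default — parent-report scores are age-normed
  to mean 50 / SD 10 in the norming population, and clinical groups score
  higher, i.e. worse);
* a planted *negative-tail* network: a set of edges whose Fisher-z value
  decreases linearly with the (z-scored) behavior score;
* a set of motion-coupled edges, and a set of edges mean-shifted at the
  second site (the confounds the masking stage must catch);
* head motion in the 0-4 mm range (maximum absolute displacement), higher
  on average in the ASD group.

Edge values are Gaussian around a per-edge baseline; the default effect
size ``beta_signal`` is calibrated so a planted edge correlates with
behavior at |r| ~ 0.25, a realistic single-edge brain-behavior effect.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .connectome import (
    ConnectivityProfile,
    NodeTimeseries,
    count_unique_edges,
    edge_matrix_to_profile,
)
from .dataset import CPMDataset

#: default acquisition length (volumes) per site
SITE_TIMEPOINTS = {"GU": 154, "KK": 128}

#: Table-1-like means/SDs used for the behavioral columns that are *not*
#: the planted measure: (TD mean, TD sd, ASD mean, ASD sd)
_OTHER_BEHAVIOR_PARAMS = {
    "brief_inhibit_t": (44.1, 6.1, 59.4, 9.2),
    "brief_shift_t": (43.7, 7.0, 67.2, 12.7),
    "brief_emocontrol_t": (43.9, 7.3, 59.5, 11.5),
}
_SRS_PARAMS = (43.4, 5.6, 74.8, 11.5)
_FIQ_PARAMS = (116.3, 11.8, 109.8, 16.6)


def _default_cells() -> dict[tuple[str, str], int]:
    return {("GU", "TD"): 46, ("GU", "ASD"): 36, ("KK", "TD"): 145, ("KK", "ASD"): 49}


@dataclass
class SimulationConfig:
    """Cohort-level generative parameters (defaults = the study conditions).

    ``beta_signal`` is the per-unit-z decrease of a signal edge's Fisher-z
    value as behavior increases; with ``noise_sd_edge`` = 0.2 the default
    0.0516 yields a planted edge-behavior correlation of about -0.25.
    ``node_count`` defaults to the 268-node whole-brain parcellation;
    tests and the acceptance analyses use 90 nodes (4005 edges) for
    runtime, which preserves every statistical property being exercised.
    """

    n_per_site_group: dict[tuple[str, str], int] = field(default_factory=_default_cells)
    node_count: int = 268
    n_signal_edges: int = 120
    beta_signal: float = 0.0516
    n_motion_edges: int = 200
    beta_motion: float = 0.115
    n_site_edges: int = 300
    delta_site: float = 0.15
    noise_sd_edge: float = 0.2
    baseline_mean: float = 0.25
    baseline_sd: float = 0.35
    signal_measure: str = "inhibit"
    behavior_mean: dict[str, float] = field(default_factory=lambda: {"TD": 44.0, "ASD": 60.0})
    behavior_sd: dict[str, float] = field(default_factory=lambda: {"TD": 7.0, "ASD": 12.0})
    rho_other_domains: float = 0.7
    rho_srs: float = 0.7
    motion_mean: dict[str, float] = field(default_factory=lambda: {"TD": 1.2, "ASD": 1.5})
    motion_sd: float = 0.9
    allow_overlap: bool = False
    seed: int = 0

    def validate(self) -> None:
        for (site, group), n in self.n_per_site_group.items():
            if n < 0:
                raise ValueError(f"negative count for {(site, group)}")
        n_edges = count_unique_edges(self.node_count)
        planted = self.n_signal_edges + self.n_motion_edges + self.n_site_edges
        if min(self.n_signal_edges, self.n_motion_edges, self.n_site_edges) < 0:
            raise ValueError("planted edge counts must be >= 0")
        if not self.allow_overlap and planted > n_edges:
            raise ValueError(
                f"{planted} disjoint planted edges do not fit in {n_edges} edges"
            )
        if self.allow_overlap and max(
            self.n_signal_edges, self.n_motion_edges, self.n_site_edges
        ) > n_edges:
            raise ValueError("a planted edge set exceeds the number of edges")
        if self.signal_measure not in ("inhibit", "shift", "emocontrol"):
            raise ValueError(f"unknown signal_measure {self.signal_measure!r}")

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["n_per_site_group"] = {
            f"{site},{group}": n for (site, group), n in self.n_per_site_group.items()
        }
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_jsonable(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class SyntheticCohort:
    """Generated phenotype + edge matrix + the planted ground truth."""

    phenotype: pd.DataFrame
    edges: np.ndarray
    node_count: int
    ground_truth: dict
    config: SimulationConfig

    def to_dataset(self) -> CPMDataset:
        return CPMDataset(
            phenotype=self.phenotype, edges=self.edges, node_count=self.node_count
        )

    def profiles(self) -> list[ConnectivityProfile]:
        ids = self.phenotype["participant_id"].tolist()
        return [
            edge_matrix_to_profile(self.edges[k], self.node_count, participant_id=pid)
            for k, pid in enumerate(ids)
        ]


def _truncated_normal(rng, mean, sd, low, high, size):
    """Rejection-sampled normal truncated to [low, high]; mean/sd/bounds may be vectors."""
    mean = np.broadcast_to(np.asarray(mean, float), (size,))
    sd = np.broadcast_to(np.asarray(sd, float), (size,))
    low = np.broadcast_to(np.asarray(low, float), (size,))
    high = np.broadcast_to(np.asarray(high, float), (size,))
    out = rng.normal(mean, sd)
    bad = (out < low) | (out > high)
    while bad.any():
        out[bad] = rng.normal(mean[bad], sd[bad])
        bad = (out < low) | (out > high)
    return out


def _flat_to_pairs(flat_idx: np.ndarray, node_count: int) -> list[tuple[int, int]]:
    iu, ju = np.triu_indices(node_count, k=1)
    return [(int(iu[k]), int(ju[k])) for k in flat_idx]


def generate_cohort(cfg: SimulationConfig) -> SyntheticCohort:
    """Draw one seeded cohort under ``cfg``.

    Per participant, each edge value is

        baseline_e + beta_signal * (-z_behavior) * [signal edge]
                   + beta_motion * z_motion      * [motion edge]
                   + delta_site  *                 [site edge & second site]
                   + Gaussian(0, noise_sd_edge)

    where z-scores are taken across the cohort.  Behavioral draws are
    truncated at 2.5 group SDs and re-drawn (deterministically, from the
    same stream) if the combined sample would flag them as > 3 SD
    outliers, so a default cohort passes the exclusion rules untouched.
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    rng_pheno, rng_edges, rng_noise = [np.random.default_rng(s) for s in ss.spawn(3)]

    cells = sorted(cfg.n_per_site_group.items())
    rows = []
    for (site, group), n_cell in cells:
        for k in range(n_cell):
            rows.append({"site": site, "group": group})
    pheno = pd.DataFrame(rows)
    n = len(pheno)
    if n < 2:
        raise ValueError("cohort must contain at least 2 participants")
    pheno["participant_id"] = [
        f"sub-{r.site}{r.group}{i:04d}" for i, r in enumerate(pheno.itertuples())
    ]
    group = pheno["group"].to_numpy()
    site = pheno["site"].to_numpy()
    is_asd = group == "ASD"

    # primary behavioral measure, truncated per group
    b_mean = np.where(is_asd, cfg.behavior_mean["ASD"], cfg.behavior_mean["TD"])
    b_sd = np.where(is_asd, cfg.behavior_sd["ASD"], cfg.behavior_sd["TD"])
    behavior = _truncated_normal(
        rng_pheno, b_mean, b_sd, b_mean - 2.5 * b_sd, b_mean + 2.5 * b_sd, n
    )
    # re-draw any combined-sample outlier so the cohort passes filtering
    from .cohort import flag_behavioral_outliers

    for _ in range(50):
        flagged = flag_behavioral_outliers(behavior)
        if not flagged:
            break
        idx = np.asarray(sorted(flagged))
        behavior[idx] = _truncated_normal(
            rng_pheno, b_mean[idx], b_sd[idx], b_mean[idx] - b_sd[idx],
            b_mean[idx] + b_sd[idx], idx.size,
        )
    zb_cohort = (behavior - behavior.mean()) / behavior.std()
    zb_group = np.zeros(n)
    for g in set(group.tolist()):
        sel = group == g
        sd = behavior[sel].std()
        if sel.sum() >= 2 and sd > 0:
            zb_group[sel] = (behavior[sel] - behavior[sel].mean()) / sd

    measure_col = {"inhibit": "brief_inhibit_t", "shift": "brief_shift_t",
                   "emocontrol": "brief_emocontrol_t"}[cfg.signal_measure]
    pheno[measure_col] = behavior

    # remaining behavioral domains: correlated with the primary within group
    rho = cfg.rho_other_domains
    for col, (m_td, s_td, m_asd, s_asd) in _OTHER_BEHAVIOR_PARAMS.items():
        if col == measure_col:
            continue
        mu = np.where(is_asd, m_asd, m_td)
        sd = np.where(is_asd, s_asd, s_td)
        eps = rng_pheno.standard_normal(n)
        pheno[col] = mu + sd * (rho * zb_group + np.sqrt(1 - rho**2) * eps)

    m_td, s_td, m_asd, s_asd = _SRS_PARAMS
    mu = np.where(is_asd, m_asd, m_td)
    sd = np.where(is_asd, s_asd, s_td)
    eps = rng_pheno.standard_normal(n)
    pheno["srs_total_t"] = mu + sd * (
        cfg.rho_srs * zb_group + np.sqrt(1 - cfg.rho_srs**2) * eps
    )

    m_td, s_td, m_asd, s_asd = _FIQ_PARAMS
    mu = np.where(is_asd, m_asd, m_td)
    sd = np.where(is_asd, s_asd, s_td)
    eps = rng_pheno.standard_normal(n)
    pheno["fiq"] = mu + sd * (-0.2 * zb_group + np.sqrt(1 - 0.04) * eps)
    pheno["viq"] = pheno["fiq"] + rng_pheno.normal(2.0, 6.0, n)
    pheno["piq"] = pheno["fiq"] + rng_pheno.normal(-3.0, 6.0, n)

    pheno["age"] = rng_pheno.uniform(8.0, 13.0, n).round(1)
    pheno["sex"] = np.where(rng_pheno.random(n) < np.where(is_asd, 0.78, 0.62), "M", "F")
    pheno["handedness"] = rng_pheno.choice(["R", "A", "L"], size=n, p=[0.85, 0.06, 0.09])
    pheno["brief_inconsistency"] = rng_pheno.integers(0, 8, n).astype(float)

    motion_mu = np.where(is_asd, cfg.motion_mean["ASD"], cfg.motion_mean["TD"])
    motion = _truncated_normal(rng_pheno, motion_mu, cfg.motion_sd, 0.05, 4.0, n)
    pheno["motion_mm"] = motion
    pheno["motion_mm_after"] = _truncated_normal(rng_pheno, 0.05, 0.07, 0.0, 0.5, n)
    z_motion = (motion - motion.mean()) / motion.std()

    # planted edge sets
    n_edges = count_unique_edges(cfg.node_count)
    if cfg.allow_overlap:
        sig_idx = rng_edges.choice(n_edges, cfg.n_signal_edges, replace=False)
        mot_idx = rng_edges.choice(n_edges, cfg.n_motion_edges, replace=False)
        site_idx = rng_edges.choice(n_edges, cfg.n_site_edges, replace=False)
    else:
        total = cfg.n_signal_edges + cfg.n_motion_edges + cfg.n_site_edges
        drawn = rng_edges.choice(n_edges, total, replace=False)
        sig_idx = drawn[: cfg.n_signal_edges]
        mot_idx = drawn[cfg.n_signal_edges : cfg.n_signal_edges + cfg.n_motion_edges]
        site_idx = drawn[cfg.n_signal_edges + cfg.n_motion_edges :]

    baseline = rng_edges.normal(cfg.baseline_mean, cfg.baseline_sd, n_edges)
    E = baseline[None, :] + cfg.noise_sd_edge * rng_noise.standard_normal((n, n_edges))
    if sig_idx.size:
        E[:, sig_idx] += cfg.beta_signal * (-zb_cohort)[:, None]
    if mot_idx.size:
        E[:, mot_idx] += cfg.beta_motion * z_motion[:, None]
    if site_idx.size:
        # the site shift lands on the lexicographically second site
        sites_present = sorted(set(site.tolist()))
        if len(sites_present) > 1:
            E[np.ix_(site == sites_present[-1], site_idx)] += cfg.delta_site

    ground_truth = {
        "signal_edges": _flat_to_pairs(sig_idx, cfg.node_count),
        "motion_edges": _flat_to_pairs(mot_idx, cfg.node_count),
        "site_edges": _flat_to_pairs(site_idx, cfg.node_count),
        "signal_flat_indices": sig_idx.tolist(),
        "motion_flat_indices": mot_idx.tolist(),
        "site_flat_indices": site_idx.tolist(),
        "beta_signal": cfg.beta_signal,
        "beta_motion": cfg.beta_motion,
        "delta_site": cfg.delta_site,
        "signal_measure": cfg.signal_measure,
        "seed": cfg.seed,
    }

    column_order = [
        "participant_id", "site", "group", "age", "sex", "handedness",
        "fiq", "viq", "piq", "srs_total_t",
        "brief_inhibit_t", "brief_shift_t", "brief_emocontrol_t",
        "brief_inconsistency", "motion_mm", "motion_mm_after",
    ]
    pheno = pheno[column_order]
    return SyntheticCohort(
        phenotype=pheno,
        edges=E,
        node_count=cfg.node_count,
        ground_truth=ground_truth,
        config=cfg,
    )


def simulate_timeseries_for_target(
    target_r: np.ndarray, timepoints: int, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian node signals whose correlation matrix approximates a target.

    The target correlation matrix is projected to the nearest positive
    semi-definite matrix (eigenvalue clipping, diagonal re-normalised) and
    sampled through its Cholesky-like factor.  Off-diagonal |r| >= 1 is
    infeasible for finite noisy data and raises.
    """
    R = np.asarray(target_r, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("target correlation matrix must be square")
    if timepoints < 30:
        raise ValueError("need at least 30 timepoints")
    off = ~np.eye(R.shape[0], dtype=bool)
    if np.any(np.abs(R[off]) >= 1.0):
        raise ValueError("target |r| >= 1 between distinct nodes is degenerate")
    if not np.allclose(R, R.T):
        raise ValueError("target correlation matrix must be symmetric")
    R = R.copy()
    np.fill_diagonal(R, 1.0)
    w, V = np.linalg.eigh(R)
    w = np.clip(w, 1e-8, None)
    R_psd = (V * w) @ V.T
    d = np.sqrt(np.diag(R_psd))
    R_psd = R_psd / np.outer(d, d)
    L = np.linalg.cholesky(R_psd + 1e-10 * np.eye(R.shape[0]))
    return L @ rng.standard_normal((R.shape[0], timepoints))


@dataclass
class TimeseriesCohort:
    """A synthetic cohort together with per-participant node timecourses."""

    cohort: SyntheticCohort
    timeseries: list[NodeTimeseries]


def generate_timeseries_cohort(
    cfg: SimulationConfig, timepoints: int | None = None
) -> TimeseriesCohort:
    """Cohort whose node timecourses induce the planted connectivity.

    Each participant's target correlation matrix is ``tanh`` of their
    planted Fisher-z profile; latent Gaussian node signals are drawn from
    its nearest PSD projection, so ``compute_fc_profile`` on the output
    recovers the planted edge effects in expectation.  When ``timepoints``
    is None, site-specific acquisition lengths are used (GU 154, KK 128
    volumes).
    """
    cohort = generate_cohort(cfg)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(4)[-1])
    iu, ju = np.triu_indices(cfg.node_count, k=1)
    series = []
    for k, pid in enumerate(cohort.phenotype["participant_id"]):
        R = np.eye(cfg.node_count)
        r_vals = np.tanh(cohort.edges[k])
        R[iu, ju] = r_vals
        R[ju, iu] = r_vals
        t = timepoints
        if t is None:
            t = SITE_TIMEPOINTS.get(cohort.phenotype["site"].iloc[k], 150)
        X = simulate_timeseries_for_target(R, t, rng)
        series.append(NodeTimeseries(participant_id=str(pid), data=X))
    return TimeseriesCohort(cohort=cohort, timeseries=series)


def write_fixture_set(
    cohort: SyntheticCohort,
    out_dir: str | Path,
    timeseries: Sequence[NodeTimeseries] | None = None,
) -> dict:
    """Write a cohort to disk as plain-text fixtures; return the manifest.

    Writes ``phenotype.csv``, one ``<participant_id>_fc.tsv`` square matrix
    per participant (and ``<participant_id>_ts.tsv`` if timecourses are
    given), ``ground_truth.json`` and ``manifest.json``.  The manifest
    records the seed and a hash of the full configuration, so fixture sets
    are traceable to their generating parameters.
    """
    from . import io as ncio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []

    pheno_path = out_dir / "phenotype.csv"
    ncio.write_phenotype(cohort.phenotype, pheno_path)
    files.append(pheno_path.name)

    for k, pid in enumerate(cohort.phenotype["participant_id"]):
        profile = edge_matrix_to_profile(
            cohort.edges[k], cohort.node_count, participant_id=str(pid)
        )
        path = out_dir / f"{pid}_fc.tsv"
        ncio.write_fc_matrix(profile.z_matrix, path)
        files.append(path.name)

    if timeseries is not None:
        for ts in timeseries:
            path = out_dir / f"{ts.participant_id}_ts.tsv"
            np.savetxt(path, ts.data, delimiter="\t", fmt="%.10g")
            files.append(path.name)

    gt_path = out_dir / "ground_truth.json"
    gt_path.write_text(json.dumps(cohort.ground_truth, indent=2))
    files.append(gt_path.name)

    manifest = {
        "seed": cohort.config.seed,
        "config": cohort.config.to_jsonable(),
        "config_hash": cohort.config.config_hash(),
        "node_count": cohort.node_count,
        "n_participants": int(len(cohort.phenotype)),
        "files": files,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
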