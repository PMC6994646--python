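"""File formats: phenotype CSV, connectivity/timecourse TSV, masks, results.

Phenotype files use ABIDE-style upper-case column names on disk (SUB_ID,
SITE_ID, DX_GROUP, ...) and canonical lower-case names in memory; the
mapping is configurable for other dialects.  Connectivity matrices are one
whitespace/tab-separated square matrix per participant in
``<participant_id>_fc.tsv`` (diagonal written as nan); node timecourses are
``<participant_id>_ts.tsv`` with nodes in rows.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import ConnectivityProfile, count_unique_edges
from .dataset import CPMDataset
from .masking import EdgeMask

#: canonical in-memory column -> default on-disk CSV column
DEFAULT_COLUMN_MAP = {
    "participant_id": "SUB_ID",
    "site": "SITE_ID",
    "group": "DX_GROUP",
    "age": "AGE_AT_SCAN",
    "sex": "SEX",
    "handedness": "HANDEDNESS",
    "fiq": "FIQ",
    "viq": "VIQ",
    "piq": "PIQ",
    "srs_total_t": "SRS_TOTAL_T",
    "brief_inhibit_t": "BRIEF_INHIBIT_T",
    "brief_shift_t": "BRIEF_SHIFT_T",
    "brief_emocontrol_t": "BRIEF_EMOCONTROL_T",
    "brief_inconsistency": "BRIEF_INCONSISTENCY",
    "motion_mm": "MOTION_MM",
    "motion_mm_after": "MOTION_MM_AFTER",
}


def read_phenotype(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a phenotype CSV into canonical column names.

    ``column_map`` maps canonical names to the file's column names;
    unmapped file columns are kept as-is (lower-cased).  Only columns
    present in the file are produced; participant_id is required.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path)
    rename = {disk: canon for canon, disk in cmap.items() if disk in df.columns}
    df = df.rename(columns=rename)
    df.columns = [c if c in cmap else c.lower() for c in df.columns]
    if "participant_id" not in df.columns:
        raise ValueError(f"phenotype file {path} lacks a participant id column")
    df["participant_id"] = df["participant_id"].astype(str)
    return df


def write_phenotype(phenotype: pd.DataFrame, path, column_map: dict[str, str] | None = None) -> None:
    """Write a canonical phenotype table using the on-disk column dialect."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    out = phenotype.rename(columns={c: cmap.get(c, c) for c in phenotype.columns})
    out.to_csv(path, index=False)


def write_fc_matrix(z_matrix: np.ndarray, path) -> None:
    np.savetxt(path, z_matrix, delimiter="\t", fmt="%.10g")


def read_fc_matrix(path) -> np.ndarray:
    z = np.loadtxt(path, delimiter="\t")
    if z.ndim != 2 or z.shape[0] != z.shape[1]:
        raise ValueError(f"{path} is not a square connectivity matrix")
    return z


def read_timeseries(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path))


def load_cohort(phenotype_path, fc_dir, column_map: dict[str, str] | None = None) -> CPMDataset:
    """Assemble a dataset from a phenotype CSV and a directory of FC TSVs.

    Every phenotype row must have a matching ``<participant_id>_fc.tsv``.
    """
    pheno = read_phenotype(phenotype_path, column_map)
    fc_dir = Path(fc_dir)
    edges = []
    node_count = None
    for pid in pheno["participant_id"]:
        path = fc_dir / f"{pid}_fc.tsv"
        if not path.exists():
            raise FileNotFoundError(f"no connectivity matrix for participant {pid!r}: {path}")
        z = read_fc_matrix(path)
        if node_count is None:
            node_count = z.shape[0]
        profile = ConnectivityProfile(participant_id=str(pid), z_matrix=z)
        edges.append(profile.edge_values())
    return CPMDataset(phenotype=pheno, edges=np.vstack(edges), node_count=node_count)


def write_mask(mask: EdgeMask, path) -> None:
    """Serialize a mask as a TSV edge list: node_i, node_j, status, reason."""
    iu, ju = np.triu_indices(mask.node_count, k=1)
    with open(path, "w") as fh:
        fh.write(f"# node_count={mask.node_count}\n")
        fh.write("node_i\tnode_j\tstatus\treason\n")
        for k in range(mask.valid.size):
            edge = (int(iu[k]), int(ju[k]))
            if mask.valid[k]:
                fh.write(f"{edge[0]}\t{edge[1]}\tvalid\t.\n")
            else:
                reason = mask.provenance.get(edge, "unknown")
                fh.write(f"{edge[0]}\t{edge[1]}\tremoved\t{reason}\n")


def read_mask(path) -> EdgeMask:
    node_count = None
    with open(path) as fh:
        first = fh.readline().strip()
        if first.startswith("# node_count="):
            node_count = int(first.split("=", 1)[1])
    if node_count is None:
        raise ValueError(f"{path} lacks the node_count header line")
    df = pd.read_csv(path, sep="\t", comment="#")
    valid = np.ones(count_unique_edges(node_count), dtype=bool)
    provenance = {}
    removed = df[df["status"] == "removed"]
    iu, ju = np.triu_indices(node_count, k=1)
    flat = {(int(i), int(j)): k for k, (i, j) in enumerate(zip(iu, ju))}
    for _, row in removed.iterrows():
        edge = (int(row["node_i"]), int(row["node_j"]))
        valid[flat[edge]] = False
        provenance[edge] = str(row["reason"])
    return EdgeMask(node_count, valid, provenance)


def write_prediction_result(result, path) -> None:
    """JSON dump of a PredictionResult (numpy arrays become lists)."""
    payload = {
        "behavior_name": result.behavior_name,
        "tail": result.tail,
        "participant_ids": list(result.participant_ids),
        "observed": np.asarray(result.observed).tolist(),
        "predicted": np.asarray(result.predicted).tolist(),
        "rs": result.rs,
        "p_parametric": result.p_parametric,
        "n": result.n,
        "fold_degeneracies": result.fold_degeneracies,
        "metadata": {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in result.metadata.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_prediction_result(path):
    from .validation import PredictionResult

    d = json.loads(Path(path).read_text())
    return PredictionResult(
        behavior_name=d["behavior_name"],
        tail=d["tail"],
        participant_ids=[str(i) for i in d["participant_ids"]],
        observed=np.asarray(d["observed"], dtype=float),
        predicted=np.asarray(d["predicted"], dtype=float),
        rs=float(d["rs"]),
        p_parametric=float(d["p_parametric"]),
        n=int(d["n"]),
        fold_degeneracies=int(d["fold_degeneracies"]),
        metadata=d.get("metadata", {}),
    )
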