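"""Table, matrix and configuration I/O.

All tabular outputs are TSV with floats written at 12 significant digits so
write-read round trips preserve values; matrix files carry a comment header
naming the vectorisation order.  Task voxel arrays are stored one ``.npy``
container per subject-region with a sidecar TSV design table.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidArgumentError, ParseError, SchemaError
from .synthetic import (Atlas, CouplingSpec, TaskDesign, TaskRegionData,
                        default_task_design)

FLOAT_FORMAT = "%.12g"
EDGE_ORDER_COMMENT = ("# edge order: row-major lower triangle "
                      "(i > j, i ascending, j ascending within i); "
                      "node ids 1-based")


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path, required_columns: Optional[Sequence[str]] = None
               ) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    except FileNotFoundError as exc:
        raise ParseError(f"{path}: file not found") from exc
    if required_columns:
        required_columns = list(required_columns)
        missing = [c for c in required_columns if c not in df.columns]
        if missing:
            raise SchemaError(
                f"{path}: missing required columns {missing}")
    # a ragged row that pandas tolerated shows up as trailing NaN in every
    # required column; flag the first such line for the user
    if required_columns:
        bad = df[required_columns].isna().all(axis=1)
        if bad.any():
            line = int(np.where(bad)[0][0]) + 2  # +1 header, +1 one-based
            raise ParseError(f"{path}: malformed row at line {line}")
    return df


def write_matrix(matrix: np.ndarray, path,
                 labels: Optional[Sequence[str]] = None,
                 comment: str = EDGE_ORDER_COMMENT) -> None:
    m = np.asarray(matrix, float)
    labels = list(labels) if labels is not None \
        else [str(i + 1) for i in range(m.shape[0])]
    df = pd.DataFrame(m, index=labels, columns=labels)
    with open(path, "w") as fh:
        fh.write(comment + "\n")
        df.to_csv(fh, sep="\t", float_format=FLOAT_FORMAT,
                  index_label="label")


def read_matrix(path) -> Tuple[np.ndarray, List[str]]:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return df.to_numpy(float), [str(c) for c in df.columns]


def write_edge_table(edges: np.ndarray, subject_ids: np.ndarray,
                     n_nodes: int, path) -> None:
    """Long-format edge table (subject, i, j, value), declared order."""
    from .restconn import edge_index_pairs
    i, j = edge_index_pairs(n_nodes)
    n_subj, E = edges.shape
    if E != len(i):
        raise InvalidArgumentError("edge count does not match n_nodes")
    df = pd.DataFrame({
        "subject_id": np.repeat(subject_ids, E),
        "i": np.tile(i + 1, n_subj),
        "j": np.tile(j + 1, n_subj),
        "value": edges.ravel()})
    with open(path, "w") as fh:
        fh.write(EDGE_ORDER_COMMENT + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_edge_table(path) -> Tuple[np.ndarray, np.ndarray, int]:
    """Returns (subject_ids, edges array, n_nodes)."""
    df = read_table(path, required_columns=("subject_id", "i", "j", "value"))
    n_nodes = int(df["i"].max())
    subjects = df["subject_id"].drop_duplicates().to_numpy()
    E = n_nodes * (n_nodes - 1) // 2
    vals = df["value"].to_numpy(float)
    if len(vals) != len(subjects) * E:
        raise SchemaError(f"{path}: edge table is not a complete grid")
    return subjects, vals.reshape(len(subjects), E), n_nodes


# ---------------------------------------------------------------------------
# Task arrays
# ---------------------------------------------------------------------------

def write_design(design: TaskDesign, path) -> None:
    df = pd.DataFrame(design.blocks, columns=["onset", "length", "category"])
    with open(path, "w") as fh:
        fh.write(f"# tr_s={design.tr_s} n_volumes={design.n_volumes} "
                 f"samples_per_block={design.samples_per_block} "
                 f"vols_per_sample={design.vols_per_sample} "
                 f"hemodynamic_delay_volumes="
                 f"{design.hemodynamic_delay_volumes}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_design(path) -> TaskDesign:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.startswith("#"):
        raise ParseError(f"{path}: missing design header at line 1")
    attrs = dict(kv.split("=") for kv in header[1:].split())
    df = read_table(path, required_columns=("onset", "length", "category"))
    blocks = tuple((int(r.onset), int(r.length), str(r.category))
                   for r in df.itertuples())
    design = TaskDesign(
        tr_s=float(attrs["tr_s"]), n_volumes=int(attrs["n_volumes"]),
        blocks=blocks,
        samples_per_block=int(attrs["samples_per_block"]),
        vols_per_sample=int(attrs["vols_per_sample"]),
        hemodynamic_delay_volumes=int(attrs["hemodynamic_delay_volumes"]))
    design.validate()
    return design


def write_task_data(data_iter: Iterable[TaskRegionData], out_dir) -> int:
    """Write one .npy per subject-region plus a single design sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = 0
    design = None
    for d in data_iter:
        np.save(out_dir / f"sub-{d.subject_id:05d}_region-{d.region_id:03d}"
                          ".npy", d.voxels_by_time)
        design = d.design
        n += 1
    if design is not None:
        write_design(design, out_dir / "design.tsv")
    return n


def read_task_data(in_dir) -> Iterator[TaskRegionData]:
    in_dir = Path(in_dir)
    design = read_design(in_dir / "design.tsv")
    for f in sorted(in_dir.glob("sub-*_region-*.npy")):
        stem = f.stem
        sid = int(stem.split("_")[0].split("-")[1])
        rid = int(stem.split("_")[1].split("-")[1])
        yield TaskRegionData(sid, rid, np.load(f), design)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_DEFAULT_STAGES = ("simulate", "phenocorr", "decode", "associate_task",
                   "associate_anat", "restconn", "associate_rest",
                   "signatures", "global_cpm")


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Per-stage seeds are derived deterministically from ``seed`` and recorded
    in the run manifest, so a manifest fully determines all outputs.
    """

    seed: int = 0
    out_dir: str = "sleepsig_run"
    n_subjects: int = 200
    n_regions: int = 20
    n_ics: int = 21
    n_voxels: int = 24
    alpha: float = 0.05
    n_phenotypes: int = 5
    n_perm: int = 200
    sel_p: float = 0.01
    cpm_folds: int = 10
    svm_backend: str = "dcd"
    stages: Dict[str, bool] = field(
        default_factory=lambda: {s: True for s in _DEFAULT_STAGES})

    def __post_init__(self) -> None:
        for s in self.stages:
            if s not in _DEFAULT_STAGES:
                raise InvalidArgumentError(f"unknown stage {s!r}")
        for s in _DEFAULT_STAGES:
            self.stages.setdefault(s, True)
        for name in ("alpha", "sel_p"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be positive")
        if self.n_perm < 1 or self.cpm_folds < 2:
            raise InvalidArgumentError("n_perm >= 1 and cpm_folds >= 2")

    def stage_seed(self, stage: str) -> int:
        if stage not in _DEFAULT_STAGES:
            raise InvalidArgumentError(f"unknown stage {stage!r}")
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31)

    def to_dict(self) -> dict:
        return asdict(self)

    def analysis_dict(self) -> dict:
        """Config without the output location (which does not affect any
        computed value)."""
        d = asdict(self)
        d.pop("out_dir")
        return d

    def hash(self) -> str:
        canon = json.dumps(self.analysis_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: config must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
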