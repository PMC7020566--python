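"""File readers/writers, run configuration, and result export.

All on-disk formats are delimited text (comma or tab, auto-detected):
per-subject time-series or connectivity matrices, three-column weighted
edge lists, two-column label files, similarity matrices with subject IDs
as header row/column, and a flat key-value run manifest sufficient to
reproduce a run exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .clustering import ClusteringResult, SimilarityMatrix
from .network import (
    TimeSeriesMatrix,
    TreeNetwork,
    WeightedNetwork,
    default_region_names,
)

logger = logging.getLogger("bnclust")

_PRECISION = 12  # significant digits on output; round-trip stable
INPUT_KINDS = ("timeseries", "matrix", "edgelist")


@dataclass
class RunConfig:
    """All parameters of a clustering run (mirrors the CLI flags)."""

    input_dir: Path
    output_dir: Path
    input_kind: str = "matrix"
    delta: float = 0.5
    h: int = 2
    d: int = 3
    ridge: float = 1e-6
    clusters: int = 2
    seed: int = 0
    labels_path: Path | None = None
    kernel_variant: str = "as_printed"
    subgraph_weights: str = "binary"
    transpose: bool = False

    def __post_init__(self) -> None:
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir)
        if self.labels_path is not None:
            self.labels_path = Path(self.labels_path)
        if self.input_kind not in INPUT_KINDS:
            raise ValueError(f"input_kind must be one of {INPUT_KINDS}")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")
        if self.h < 1 or self.d < 1:
            raise ValueError("h and d must be >= 1")
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")
        if self.clusters < 2:
            raise ValueError("clusters must be >= 2")
        if self.kernel_variant not in ("as_printed", "s_divergence"):
            raise ValueError("unknown kernel_variant")
        if self.subgraph_weights not in ("binary", "weighted"):
            raise ValueError("unknown subgraph_weights")

    @classmethod
    def from_file(cls, path: Path, **overrides) -> "RunConfig":
        """Load a flat key-value config file; keyword overrides win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} is not a flat mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _sniff_rows(path: Path) -> list[list[str]]:
    """Tokenized rows of a delimited file (comma or tab auto-detected)."""
    text = Path(path).read_text()
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "\t" in line:
            tokens = [t.strip() for t in line.split("\t")]
        elif "," in line:
            tokens = [t.strip() for t in line.split(",")]
        else:
            tokens = line.split()
        rows.append(tokens)
    return rows


def _is_float(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _parse_numeric_rows(
    rows: list[list[str]], path: Path, start_line: int
) -> np.ndarray:
    width = len(rows[0])
    out = np.empty((len(rows), width))
    for r, tokens in enumerate(rows):
        if len(tokens) != width:
            raise ValueError(
                f"{path}: line {start_line + r} has {len(tokens)} fields, "
                f"expected {width} (ragged matrix)"
            )
        for c, tok in enumerate(tokens):
            if not _is_float(tok):
                raise ValueError(
                    f"{path}: line {start_line + r}: non-numeric value {tok!r}"
                )
            out[r, c] = float(tok)
    return out


def read_matrix_file(
    path: Path,
) -> tuple[np.ndarray, tuple[str, ...] | None]:
    """Numeric matrix from delimited text, with optional header names.

    A first row containing any non-numeric token is taken as the header
    of region names.  Returns (values, names-or-None).
    """
    rows = _sniff_rows(path)
    if not rows:
        raise ValueError(f"{path}: empty file")
    header: tuple[str, ...] | None = None
    if any(not _is_float(t) for t in rows[0]):
        header = tuple(rows[0])
        rows = rows[1:]
        if not rows:
            raise ValueError(f"{path}: header but no data rows")
    values = _parse_numeric_rows(rows, Path(path), 2 if header else 1)
    return values, header


def read_timeseries_file(
    path: Path, transpose: bool = False
) -> TimeSeriesMatrix:
    """Per-subject time series: rows = time points, columns = regions.

    Set ``transpose=True`` for files stored regions-by-time.
    """
    values, header = read_matrix_file(path)
    if transpose:
        values = values.T
    names = header if header is not None else tuple(
        default_region_names(values.shape[1])
    )
    if header is not None and len(header) != values.shape[1]:
        raise ValueError(
            f"{path}: header has {len(header)} names for "
            f"{values.shape[1]} columns"
        )
    return TimeSeriesMatrix(values=values, region_names=names)


def read_connectivity_file(path: Path) -> WeightedNetwork:
    """Square symmetric connectivity matrix from delimited text."""
    values, header = read_matrix_file(path)
    if values.shape[0] != values.shape[1]:
        raise ValueError(
            f"{path}: connectivity matrix must be square, got {values.shape}"
        )
    names = header if header is not None else tuple(
        default_region_names(values.shape[0])
    )
    return WeightedNetwork(weights=values, region_names=names)


def read_edgelist_file(path: Path) -> WeightedNetwork:
    """Weighted edge list (node_a, node_b, weight) to a dense network.

    Nodes are ordered by sorted label so that subjects sharing a label
    set get identical node orderings regardless of edge order on disk.
    """
    rows = _sniff_rows(path)
    if not rows:
        raise ValueError(f"{path}: empty file")
    triples: list[tuple[str, str, float]] = []
    labels: set[str] = set()
    for lineno, tokens in enumerate(rows, start=1):
        if len(tokens) != 3:
            raise ValueError(
                f"{path}: line {lineno}: expected 3 fields, got {len(tokens)}"
            )
        a, b, w = tokens
        if not _is_float(w):
            raise ValueError(f"{path}: line {lineno}: bad weight {w!r}")
        labels.update((a, b))
        triples.append((a, b, float(w)))
    names = sorted(labels)
    index = {name: i for i, name in enumerate(names)}
    n = len(names)
    weights = np.zeros((n, n))
    for a, b, w in triples:
        weights[index[a], index[b]] = weights[index[b], index[a]] = w
    return WeightedNetwork(weights=weights, region_names=tuple(names))


def read_subject_inputs(
    config: RunConfig,
) -> list[tuple[str, TimeSeriesMatrix | WeightedNetwork]]:
    """All subject files of a cohort directory, in filename order.

    Subject IDs are the file stems; region counts must agree across
    subjects, and when headers are present the region names must match
    (headerless files get generated names, with a logged warning when
    mixed with header-bearing ones).
    """
    paths = sorted(
        p for p in config.input_dir.iterdir()
        if p.is_file() and not p.name.startswith(".")
    )
    if not paths:
        raise ValueError(f"no input files in {config.input_dir}")
    subjects: list[tuple[str, TimeSeriesMatrix | WeightedNetwork]] = []
    any_header = False
    any_headerless = False
    header_ref: tuple[tuple[str, ...], str] | None = None
    for path in paths:
        if config.input_kind == "timeseries":
            _, header = read_matrix_file(path)
            item: TimeSeriesMatrix | WeightedNetwork = read_timeseries_file(
                path, transpose=config.transpose
            )
        elif config.input_kind == "matrix":
            _, header = read_matrix_file(path)
            item = read_connectivity_file(path)
        else:
            header = None
            item = read_edgelist_file(path)
        any_header |= header is not None
        any_headerless |= header is None
        if header is not None:
            if header_ref is None:
                header_ref = (tuple(header), path.stem)
            elif tuple(header) != header_ref[0]:
                raise ValueError(
                    f"subject {path.stem!r} has region names differing from "
                    f"subject {header_ref[1]!r}"
                )
        subjects.append((path.stem, item))
    if any_header and any_headerless and config.input_kind != "edgelist":
        logger.warning(
            "mixed header/headerless files; headerless subjects use "
            "generated region names"
        )
    ref_id, ref_item = subjects[0]
    ref_n = (
        ref_item.n_regions
        if isinstance(ref_item, TimeSeriesMatrix)
        else ref_item.n_nodes
    )
    for sid, item in subjects[1:]:
        n = (
            item.n_regions
            if isinstance(item, TimeSeriesMatrix)
            else item.n_nodes
        )
        if n != ref_n:
            raise ValueError(
                f"subject {sid!r} has {n} regions, expected {ref_n} "
                f"(as in subject {ref_id!r})"
            )
    return subjects


def read_class_labels(
    path: Path, subject_ids: list[str]
) -> np.ndarray:
    """Two-column (subject_id, class) label file, matched to the cohort."""
    rows = _sniff_rows(path)
    mapping: dict[str, int] = {}
    for lineno, tokens in enumerate(rows, start=1):
        if len(tokens) != 2:
            raise ValueError(
                f"{path}: line {lineno}: expected 2 fields, got {len(tokens)}"
            )
        mapping[tokens[0]] = int(float(tokens[1]))
    missing = [s for s in subject_ids if s not in mapping]
    if missing:
        raise ValueError(f"{path}: no class label for subject(s) {missing}")
    return np.asarray([mapping[s] for s in subject_ids], dtype=int)


def _fmt(x: float) -> str:
    return f"{x:.{_PRECISION}g}"


def write_matrix(
    path: Path, values: np.ndarray, names: list[str] | tuple[str, ...]
) -> None:
    """Delimited matrix with IDs as header row and leading column."""
    with open(path, "w") as fh:
        fh.write("\t".join(["id", *names]) + "\n")
        for name, row in zip(names, values):
            fh.write("\t".join([name, *(_fmt(v) for v in row)]) + "\n")


def read_labeled_matrix(path: Path) -> tuple[np.ndarray, tuple[str, ...]]:
    """Inverse of :func:`write_matrix`."""
    rows = _sniff_rows(path)
    names = tuple(rows[0][1:])
    values = np.array(
        [[float(t) for t in row[1:]] for row in rows[1:]]
    )
    return values, names


def write_tree(path: Path, tree: TreeNetwork) -> None:
    """Tree as a tab-delimited edge list (node_a, node_b, weight)."""
    with open(path, "w") as fh:
        for i, j in sorted(tree.edges):
            w = (tree.edge_weights or {}).get((i, j), 1.0)
            fh.write(f"{tree.nodes[i]}\t{tree.nodes[j]}\t{_fmt(w)}\n")


def write_results(
    result: ClusteringResult,
    matrices: dict[str, SimilarityMatrix],
    config: RunConfig,
) -> dict[str, Path]:
    """Write labels, similarity matrices, and the run manifest.

    The manifest records every parameter plus the seed, enough to re-run
    the clustering identically.  Returns the paths written.
    """
    if result.labels.size == 0:
        raise ValueError("refusing to write results for an empty cohort")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    labels_path = out / "cluster_labels.tsv"
    with open(labels_path, "w") as fh:
        for sid, lab in zip(result.subject_ids, result.labels):
            fh.write(f"{sid}\t{lab}\n")
    written["labels"] = labels_path

    for name, matrix in matrices.items():
        mpath = out / f"similarity_{name}.tsv"
        write_matrix(mpath, matrix.values, list(matrix.subject_ids))
        written[name] = mpath

    manifest_path = out / "run_manifest.txt"
    from . import __version__

    entries = {
        "version": __version__,
        "input_dir": config.input_dir,
        "input_kind": config.input_kind,
        "delta": config.delta,
        "h": config.h,
        "d": config.d,
        "ridge": config.ridge,
        "clusters": config.clusters,
        "seed": config.seed,
        "kernel_variant": config.kernel_variant,
        "subgraph_weights": config.subgraph_weights,
        "labels_path": config.labels_path or "",
        "consistency": "" if result.consistency is None
        else _fmt(result.consistency),
    }
    with open(manifest_path, "w") as fh:
        for key, value in entries.items():
            fh.write(f"{key}: {value}\n")
    written["manifest"] = manifest_path
    return written


def write_betweenness(path: Path, bv) -> None:
    """Per-node betweenness export: one row per node (label, value)."""
    with open(path, "w") as fh:
        for name, value in zip(bv.node_names, bv.values):
            fh.write(f"{name}\t{_fmt(value)}\n")


def write_timeseries(path: Path, ts: TimeSeriesMatrix) -> None:
    """Time series with a header row of region names."""
    with open(path, "w") as fh:
        fh.write("\t".join(ts.region_names) + "\n")
        for row in ts.values:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")
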