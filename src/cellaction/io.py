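"""Readers and writers for on-disk artifacts.

Expression/velocity matrices are accepted either as dense TSV (cells in
rows, genes in columns, cell ids in the first column) or as MatrixMarket
``.mtx`` with plain-text sidecars listing row (cell) and column (gene)
names — the two dominant interchange forms for scRNA matrices.  The
velocity matrix must use the same dialect and shape as the expression
matrix.

Trajectories are stored as JSON-lines, one record per trajectory; the
run manifest (config echo plus the time-label mapping) as JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from ._errors import FormatError, ValidationError
from .datatypes import CellTable, TrajectoryEnsemble

__all__ = [
    "load_cell_table",
    "write_cell_table",
    "read_trajectories",
    "write_trajectories",
    "write_vocabulary",
    "read_vocabulary",
    "write_manifest",
]

logger = logging.getLogger(__name__)

_REQUIRED_META = ("cell_id", "time", "cell_type")


def _read_matrix(path: Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Return (matrix, row names, column names) from TSV or MTX."""
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        rows_file = path.with_suffix(".mtx.rows")
        cols_file = path.with_suffix(".mtx.cols")
        for side in (rows_file, cols_file):
            if not side.exists():
                raise FormatError(f"missing MatrixMarket sidecar {side}")
        row_names = rows_file.read_text().split()
        col_names = cols_file.read_text().split()
        if len(row_names) != mat.shape[0] or len(col_names) != mat.shape[1]:
            raise FormatError(
                f"sidecar lengths ({len(row_names)}, {len(col_names)}) do not "
                f"match matrix shape {mat.shape} for {path}"
            )
        return np.asarray(mat, dtype=float), row_names, col_names
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return (
        df.to_numpy(dtype=float),
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
    )


def load_cell_table(
    expression_path: str | Path,
    velocity_path: str | Path,
    metadata_path: str | Path,
    rank_map: bool = True,
) -> CellTable:
    """Load expression, velocity and per-cell metadata into a CellTable.

    Rows are reordered to the metadata order (matched on ``cell_id``).
    Time labels are rank-mapped to a contiguous 0-based range by default,
    with the mapping recorded on the returned table; with
    ``rank_map=False`` the labels must already be contiguous 0-based
    integers and a gap raises a validation error naming it.
    """
    expression_path = Path(expression_path)
    velocity_path = Path(velocity_path)
    if (expression_path.suffix == ".mtx") != (velocity_path.suffix == ".mtx"):
        raise FormatError("expression and velocity must use the same dialect")
    expr, expr_rows, expr_cols = _read_matrix(expression_path)
    vel, vel_rows, _ = _read_matrix(velocity_path)
    if expr.shape != vel.shape:
        raise FormatError(
            f"expression shape {expr.shape} != velocity shape {vel.shape}"
        )
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"cell_id": str})
    missing = [c for c in _REQUIRED_META if c not in meta.columns]
    if missing:
        raise FormatError(f"metadata missing required columns: {missing}")
    if len(meta) != expr.shape[0]:
        raise FormatError(
            f"{len(meta)} metadata rows for {expr.shape[0]} matrix rows"
        )
    order = {cid: i for i, cid in enumerate(expr_rows)}
    try:
        perm = np.array([order[cid] for cid in meta["cell_id"]])
    except KeyError as exc:
        raise FormatError(f"metadata cell_id {exc} not found in matrix rows")
    expr = expr[perm]
    if vel_rows != expr_rows:
        vel = vel[np.array([{c: i for i, c in enumerate(vel_rows)}[cid]
                            for cid in meta["cell_id"]])]
    else:
        vel = vel[perm]

    labels = meta["time"].to_numpy()
    mapping: dict = {}
    if rank_map:
        uniq = np.unique(labels)
        mapping = {lab: rank for rank, lab in enumerate(uniq.tolist())}
        meta = meta.assign(time=[mapping[lab] for lab in labels.tolist()])
    else:
        try:
            as_int = labels.astype(int)
        except (TypeError, ValueError):
            raise ValidationError(
                "rank_map=False requires integer time labels"
            )
        uniq = np.unique(as_int)
        expected = np.arange(uniq.size)
        if uniq.size == 0 or not np.array_equal(uniq, expected):
            gaps = sorted(set(range(int(uniq.max()) + 1)) - set(uniq.tolist()))
            raise ValidationError(
                f"time labels are not a contiguous 0-based range: missing {gaps}"
            )
        meta = meta.assign(time=as_int)
    table = CellTable(expr, vel, meta, time_mapping=mapping)
    logger.info(
        "loaded %d cells x %d genes in %d layers (sizes %s)",
        table.n_cells, table.n_genes, table.n_layers,
        table.layer_sizes.tolist(),
    )
    return table


def write_cell_table(
    table: CellTable,
    expression_path: str | Path,
    velocity_path: str | Path,
    metadata_path: str | Path,
) -> None:
    """Write a CellTable back to disk; exact inverse of load_cell_table.

    Dialect follows the expression path suffix (``.mtx`` or TSV).
    """
    expression_path = Path(expression_path)
    velocity_path = Path(velocity_path)
    ids = [str(c) for c in table.cell_ids]
    genes = [f"g{j}" for j in range(table.n_genes)]
    if expression_path.suffix == ".mtx":
        for path, mat in ((expression_path, table.expression),
                          (velocity_path, table.velocity)):
            scipy.io.mmwrite(path, scipy.sparse.coo_matrix(mat))
            path.with_suffix(".mtx.rows").write_text("\n".join(ids) + "\n")
            path.with_suffix(".mtx.cols").write_text("\n".join(genes) + "\n")
    else:
        for path, mat in ((expression_path, table.expression),
                          (velocity_path, table.velocity)):
            pd.DataFrame(mat, index=ids, columns=genes).to_csv(
                path, sep="\t", float_format="%.17g"
            )
    table.obs[list(_REQUIRED_META)].to_csv(metadata_path, sep="\t", index=False)


def write_trajectories(ensemble: TrajectoryEnsemble, path: str | Path) -> None:
    """JSON-lines, one record per trajectory."""
    if ensemble.n_trajectories == 0:
        raise ValidationError("cannot write an empty trajectory ensemble")
    with open(path, "w") as fh:
        for i, row in enumerate(ensemble.tokens):
            rec = {"traj_id": i, "tokens": [int(t) for t in row]}
            if ensemble.cell_ids is not None:
                rec["cell_ids"] = [str(c) for c in ensemble.cell_ids[i]]
            fh.write(json.dumps(rec) + "\n")


def read_trajectories(path: str | Path) -> TrajectoryEnsemble:
    """Exact inverse of :func:`write_trajectories`."""
    tokens, cell_ids = [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            tokens.append(rec["tokens"])
            if "cell_ids" in rec:
                cell_ids.append(rec["cell_ids"])
    if not tokens:
        raise ValidationError(f"no trajectories found in {path}")
    lengths = {len(t) for t in tokens}
    if len(lengths) != 1:
        raise ValidationError(f"ragged trajectory lengths in {path}: {sorted(lengths)}")
    return TrajectoryEnsemble(
        np.asarray(tokens, dtype=int),
        cell_ids if cell_ids else None,
    )


def write_vocabulary(vocab, path: str | Path) -> None:
    """Vocabulary as JSON: centroids, metadata, cell map."""
    payload = {
        "centroids": [[float(x) for x in c] for c in vocab.centroids],
        "token_layer": [int(t) for t in vocab.token_layer],
        "token_cell_type": [str(t) for t in vocab.token_cell_type],
        "cell_to_token": {k: int(v) for k, v in vocab.cell_to_token.items()},
        "token_members": [[int(r) for r in m] for m in vocab.token_members],
    }
    Path(path).write_text(json.dumps(payload) + "\n")


def read_vocabulary(path: str | Path):
    """Exact inverse of :func:`write_vocabulary`."""
    from .tokenize import Vocabulary

    raw = json.loads(Path(path).read_text())
    return Vocabulary(
        centroids=np.asarray(raw["centroids"], dtype=float),
        token_layer=np.asarray(raw["token_layer"], dtype=int),
        token_cell_type=np.asarray(raw["token_cell_type"], dtype=object),
        cell_to_token=raw["cell_to_token"],
        token_members=[np.asarray(m, dtype=int) for m in raw["token_members"]],
    )


def write_manifest(path: str | Path, config, time_mapping: dict | None = None,
                   **extra) -> None:
    """Write the run manifest (config echo, time mapping, extras) as JSON."""
    payload = {"config": config.to_dict() if hasattr(config, "to_dict") else config}
    if time_mapping:
        payload["time_mapping"] = {str(k): int(v) for k, v in time_mapping.items()}
    payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
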