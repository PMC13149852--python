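"""Readers and writers for samples, forces, and trajectories.

Samples: Matrix Market (matrix.mtx + genes.tsv + barcodes.tsv +
coords.csv), an AnnData .h5ad with ``obsm["spatial"]``, or plain CSV
(expression.csv + coords.csv). Forces: a TSV matrix pair with a JSON
sidecar, or a single HDF5 file with groups /g_inter, /g_intra, /meta.
All writes are atomic (temp file + rename) and embed provenance.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import anndata as ad
import h5py
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

from . import __version__
from .energy import GeneGeneForces
from .preprocess import SpatialSample, build_knn_graph

__all__ = [
    "read_sample",
    "write_sample",
    "read_forces",
    "write_forces",
    "write_trajectory",
    "read_trajectory",
]


def _atomic_write(path: Path, writer) -> None:
    """Write via a temp file in the same directory, then rename."""
    path = Path(path)
    # keep the suffix: some writers (Matrix Market) key behavior on it
    fd, tmp = tempfile.mkstemp(
        dir=path.parent, prefix=f".{path.stem}.", suffix=path.suffix
    )
    os.close(fd)
    try:
        writer(Path(tmp))
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.remove(tmp)
        raise


def _detect_format(path: Path) -> str:
    if path.is_dir():
        if (path / "matrix.mtx").exists():
            return "mtx"
        if (path / "expression.csv").exists():
            return "csv"
        raise ValueError(
            f"cannot auto-detect format in {path}: expected matrix.mtx or "
            "expression.csv (supported: mtx, h5ad, csv)"
        )
    if path.suffix == ".h5ad":
        return "h5ad"
    raise ValueError(
        f"unknown format for {path}; supported formats: mtx (directory), "
        "h5ad (file), csv (directory)"
    )


def read_sample(
    path,
    format: str = "auto",
    n_neighbors: int = 6,
    already_normalized: bool | None = None,
) -> SpatialSample:
    """Read a spatial sample from disk and build its kNN graph.

    If the expression rows are already unit-norm (within 1e-6) the data
    are taken as pre-normalized; otherwise log1p + spherical
    normalization is applied (override with ``already_normalized``).
    """
    path = Path(path)
    if format == "auto":
        format = _detect_format(path)
    if format == "mtx":
        mtx = path / "matrix.mtx"
        coords_f = path / "coords.csv"
        for f in (mtx, path / "genes.tsv", path / "barcodes.tsv", coords_f):
            if not f.exists():
                raise FileNotFoundError(
                    f"missing {f.name}: an mtx sample directory needs "
                    "matrix.mtx, genes.tsv, barcodes.tsv, coords.csv"
                )
        X = np.asarray(mmread(mtx).todense() if sparse.issparse(mmread(mtx)) else mmread(mtx), dtype=float)
        genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].astype(str).tolist()
        cells = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str).tolist()
        cdf = pd.read_csv(coords_f)
        coords = cdf[["x", "y"]].to_numpy(dtype=float)
        if "cell_id" in cdf.columns:
            order = {c: i for i, c in enumerate(cdf["cell_id"].astype(str))}
            coords = coords[[order[c] for c in cells]]
    elif format == "h5ad":
        adata = ad.read_h5ad(path)
        if "spatial" not in adata.obsm:
            raise ValueError("h5ad file lacks obsm['spatial'] coordinates")
        X = np.asarray(
            adata.X.todense() if sparse.issparse(adata.X) else adata.X, dtype=float
        )
        genes = adata.var_names.astype(str).tolist()
        cells = adata.obs_names.astype(str).tolist()
        coords = np.asarray(adata.obsm["spatial"], dtype=float)[:, :2]
    elif format == "csv":
        expr_f, coords_f = path / "expression.csv", path / "coords.csv"
        if not coords_f.exists():
            raise FileNotFoundError(f"missing coords file {coords_f}")
        edf = pd.read_csv(expr_f, index_col=0)
        X = edf.to_numpy(dtype=float)
        genes = edf.columns.astype(str).tolist()
        cells = edf.index.astype(str).tolist()
        coords = pd.read_csv(coords_f)[["x", "y"]].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown format {format!r}; supported: mtx, h5ad, csv")

    if coords.shape[0] != X.shape[0]:
        raise ValueError(
            f"coordinate rows ({coords.shape[0]}) do not match expression "
            f"rows ({X.shape[0]})"
        )
    norms = np.linalg.norm(X, axis=1)
    if already_normalized is None:
        already_normalized = bool(np.allclose(norms, 1.0, atol=1e-6))
    if already_normalized:
        expression = X
    else:
        from .preprocess import log_normalize

        expression = log_normalize(X)
    k = min(n_neighbors, X.shape[0] - 1)
    return SpatialSample(
        expression=expression,
        coords=coords,
        adjacency=build_knn_graph(coords, k),
        gene_names=genes,
        cell_ids=cells,
        meta={
            "source": str(path),
            "format": format,
            "n_neighbors": k,
            "normalized": "detected" if already_normalized else "log1p+spherical",
            "package_version": __version__,
        },
    )


def write_sample(sample: SpatialSample, path, format: str = "mtx") -> None:
    """Write a sample; round-trips losslessly through read_sample."""
    path = Path(path)
    if format in ("mtx", "csv"):
        path.mkdir(parents=True, exist_ok=True)
        coords_df = pd.DataFrame(
            {"cell_id": sample.cell_ids, "x": sample.coords[:, 0], "y": sample.coords[:, 1]}
        )
        _atomic_write(path / "coords.csv", lambda p: coords_df.to_csv(p, index=False))
        meta = {**sample.meta, "package_version": __version__}
        _atomic_write(
            path / "meta.json", lambda p: p.write_text(json.dumps(meta, default=str))
        )
        if format == "mtx":
            _atomic_write(
                path / "matrix.mtx",
                lambda p: mmwrite(str(p), sparse.coo_matrix(sample.expression)),
            )
            _atomic_write(
                path / "genes.tsv",
                lambda p: p.write_text("\n".join(sample.gene_names) + "\n"),
            )
            _atomic_write(
                path / "barcodes.tsv",
                lambda p: p.write_text("\n".join(sample.cell_ids) + "\n"),
            )
        else:
            edf = pd.DataFrame(
                sample.expression, index=sample.cell_ids, columns=sample.gene_names
            )
            _atomic_write(path / "expression.csv", lambda p: edf.to_csv(p))
    elif format == "h5ad":
        adata = ad.AnnData(
            X=sample.expression.copy(),
            obs=pd.DataFrame(index=sample.cell_ids),
            var=pd.DataFrame(index=sample.gene_names),
        )
        adata.obsm["spatial"] = sample.coords.copy()
        adata.uns["meta"] = {k: str(v) for k, v in sample.meta.items()}
        _atomic_write(path, lambda p: adata.write_h5ad(p))
    else:
        raise ValueError(f"unknown format {format!r}; supported: mtx, h5ad, csv")


def write_forces(
    forces: GeneGeneForces,
    path,
    meta: dict | None = None,
    loss_trajectory: np.ndarray | None = None,
    format: str = "h5",
) -> None:
    """Write forces as HDF5 (/g_inter, /g_intra, /meta) or a TSV pair + JSON."""
    path = Path(path)
    meta = dict(meta or {})
    meta["package_version"] = __version__
    if format == "h5":
        def _write(p: Path) -> None:
            with h5py.File(p, "w") as f:
                f.create_dataset("g_inter", data=forces.g_inter)
                f.create_dataset("g_intra", data=forces.g_intra)
                grp = f.create_group("meta")
                grp.attrs["gene_names"] = [str(g) for g in forces.gene_names]
                grp.attrs["config"] = json.dumps(meta, default=str)
                if loss_trajectory is not None:
                    f.create_dataset("loss_trajectory", data=np.asarray(loss_trajectory))

        _atomic_write(path, _write)
    elif format == "tsv":
        path.mkdir(parents=True, exist_ok=True)
        for name, m in (("g_inter", forces.g_inter), ("g_intra", forces.g_intra)):
            df = pd.DataFrame(m, index=forces.gene_names, columns=forces.gene_names)
            _atomic_write(path / f"{name}.tsv", lambda p, df=df: df.to_csv(p, sep="\t"))
        sidecar = {"meta": meta}
        if loss_trajectory is not None:
            sidecar["loss_trajectory"] = np.asarray(loss_trajectory).tolist()
        _atomic_write(
            path / "forces.json", lambda p: p.write_text(json.dumps(sidecar, default=str))
        )
    else:
        raise ValueError(f"unknown forces format {format!r}; supported: h5, tsv")


def read_forces(path) -> GeneGeneForces:
    path = Path(path)
    if path.is_dir():
        gi = pd.read_csv(path / "g_inter.tsv", sep="\t", index_col=0)
        gq = pd.read_csv(path / "g_intra.tsv", sep="\t", index_col=0)
        return GeneGeneForces(
            gi.to_numpy(float), gq.to_numpy(float), gi.index.astype(str).tolist()
        )
    with h5py.File(path, "r") as f:
        return GeneGeneForces(
            f["g_inter"][...],
            f["g_intra"][...],
            [g if isinstance(g, str) else g.decode() for g in f["meta"].attrs["gene_names"]],
        )


def write_trajectory(states: list[np.ndarray], loss_trajectory: np.ndarray,
                     recorded_epochs: list[int], path, meta: dict | None = None) -> None:
    """Generation trajectory to HDF5: /states (epochs x cells x genes), /loss."""
    def _write(p: Path) -> None:
        with h5py.File(p, "w") as f:
            f.create_dataset("states", data=np.stack(states))
            f.create_dataset("loss", data=np.asarray(loss_trajectory))
            f.create_dataset("recorded_epochs", data=np.asarray(recorded_epochs))
            f.attrs["config"] = json.dumps(
                {**(meta or {}), "package_version": __version__}, default=str
            )

    _atomic_write(Path(path), _write)


def read_trajectory(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    with h5py.File(path, "r") as f:
        return f["states"][...], f["loss"][...], f["recorded_epochs"][...]
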