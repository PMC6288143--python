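"""Reading and writing the pipeline's on-disk formats.

Everything on disk is plain text: voxel-by-timepoint matrices as TSV
with a commented metadata header, edge lists as sorted two-column
0-based vertex-index TSV, atlases and cohort manifests as TSV tables,
region matrices as TSV with region-id header row/column, and metric
reports as flat key-value TSV.  4D NIfTI volumes are read with
nibabel; voxel order is the mask scan order with x varying fastest.
"""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .decomposition import BandSignals, BoldMatrix, FrequencyBand
from .metrics import RegionAtlas, RegionConnectivityMatrix
from .network import MultiGraph, VoxelGraph

__all__ = [
    "read_nifti_series",
    "write_bold_text",
    "read_bold_text",
    "write_band_signals",
    "write_edge_list",
    "read_edge_list",
    "write_multigraph",
    "read_multigraph",
    "write_atlas",
    "read_atlas",
    "write_region_matrix",
    "write_metrics_report",
    "write_cohort_manifest",
    "read_cohort_manifest",
]

logger = logging.getLogger(__name__)


def read_nifti_series(
    path_4d: str | Path, path_mask: str | Path, tr_override: float | None = None
) -> BoldMatrix:
    """Extract a voxel-by-timepoint matrix from a 4D NIfTI and a 3D mask.

    Voxels are the nonzero mask positions in scan order (x fastest);
    coordinates are recorded in voxel indices.  TR is read from the
    header (4th zoom, seconds) unless ``tr_override`` is given.
    """
    img = nib.load(str(path_4d))
    mask_img = nib.load(str(path_mask))
    data = np.asanyarray(img.dataobj)
    mask = np.asanyarray(mask_img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"expected 4D image, got {data.ndim}D")
    if mask.shape != data.shape[:3]:
        raise ValueError(
            f"grid mismatch: image {data.shape[:3]} vs mask {mask.shape}"
        )
    if not np.any(mask):
        raise ValueError("empty mask")
    tr = tr_override
    if tr is None:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) >= 4 else 0.0
        if not tr or tr <= 0:
            raise ValueError("TR missing from header; pass tr_override")
    # x-fastest scan order = Fortran raveling of the (x, y, z) grid
    flat_mask = mask.reshape(-1, order="F") != 0
    xs, ys, zs = np.unravel_index(
        np.flatnonzero(flat_mask), mask.shape, order="F"
    )
    coords = np.column_stack([xs, ys, zs]).astype(float)
    series = data.reshape(-1, data.shape[3], order="F")[flat_mask].astype(float)
    return BoldMatrix(values=series, tr_seconds=tr, voxel_coords=coords)


# --- text matrices ----------------------------------------------------------


def write_bold_text(bold: BoldMatrix, path: str | Path) -> None:
    """TSV: columns x, y, z then timepoints; TR in a commented header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# tr_seconds={bold.tr_seconds}\n")
        fh.write(f"# n_voxels={bold.n_voxels} n_timepoints={bold.n_timepoints}\n")
        fh.write("# columns: x y z t0 t1 ... (voxel order = mask scan order, x fastest)\n")
        body = np.column_stack([bold.voxel_coords, bold.values])
        np.savetxt(fh, body, delimiter="\t", fmt="%.10g")


def read_bold_text(path: str | Path) -> BoldMatrix:
    path = Path(path)
    tr = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "tr_seconds=" in line:
                tr = float(line.split("tr_seconds=")[1].split()[0])
                break
    if tr is None:
        raise ValueError(f"{path}: no tr_seconds header")
    body = np.loadtxt(path, delimiter="\t", comments="#", ndmin=2)
    return BoldMatrix(values=body[:, 3:], tr_seconds=tr, voxel_coords=body[:, :3])


def write_band_signals(
    signals: list[BandSignals], out_dir: str | Path, stem: str = "band"
) -> list[Path]:
    """One TSV per band plus a YAML sidecar with band edges, TR, counts."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    meta = {"tr_seconds": signals[0].tr_seconds, "bands": {}}
    for sig in signals:
        p = out_dir / f"{stem}_{sig.band.name}.tsv"
        np.savetxt(p, sig.values, delimiter="\t", fmt="%.10g")
        meta["bands"][sig.band.name] = {
            "f_low_hz": sig.band.f_low_hz,
            "f_high_hz": sig.band.f_high_hz,
            "n_voxels": int(sig.n_voxels),
            "path": p.name,
        }
        paths.append(p)
    with open(out_dir / f"{stem}_meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return paths


# --- edge lists -------------------------------------------------------------


def write_edge_list(g: VoxelGraph, path: str | Path, threshold: float | None = None,
                    normalized: bool | None = None) -> None:
    """Sorted two-column 0-based edge list with a descriptive header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# band={g.band_label or 'unknown'}")
        if threshold is not None:
            fh.write(f" threshold={threshold!r}")
        if normalized is not None:
            fh.write(f" normalized={normalized}")
        fh.write(f" n_vertices={g.n_vertices}\n")
        fh.write("# i\tj (0-based vertex indices, i < j)\n")
        for i, j in sorted(g.edges):
            fh.write(f"{i}\t{j}\n")


def read_edge_list(path: str | Path, vertex_coords: np.ndarray | None = None) -> VoxelGraph:
    path = Path(path)
    band = ""
    n_vertices = None
    edges = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("band="):
                        band = tok[5:]
                    elif tok.startswith("n_vertices="):
                        n_vertices = int(tok.split("=")[1])
                continue
            if line.strip():
                i, j = map(int, line.split())
                edges.append((i, j))
    if n_vertices is None:
        n_vertices = max((max(e) for e in edges), default=-1) + 1
    if vertex_coords is None:
        from .network import scan_order_coords

        vertex_coords = scan_order_coords(n_vertices)
    return VoxelGraph(
        n_vertices=n_vertices,
        vertex_coords=vertex_coords,
        edges=frozenset(edges),
        band_label=band,
    )


def write_multigraph(mg: MultiGraph, out_dir: str | Path, stem: str = "edges") -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for band in mg.edge_sets:
        p = out_dir / f"{stem}_{band}.tsv"
        write_edge_list(mg.band_graph(band), p)
        paths[band] = p
    np.savetxt(
        out_dir / f"{stem}_coords.tsv", mg.vertex_coords, delimiter="\t", fmt="%.10g",
        header="x\ty\tz (row = vertex index)",
    )
    return paths


def read_multigraph(out_dir: str | Path, stem: str = "edges") -> MultiGraph:
    out_dir = Path(out_dir)
    coords = np.loadtxt(out_dir / f"{stem}_coords.tsv", delimiter="\t", ndmin=2)
    mg = MultiGraph(n_vertices=coords.shape[0], vertex_coords=coords)
    for p in sorted(out_dir.glob(f"{stem}_*.tsv")):
        band = p.stem[len(stem) + 1 :]
        if band == "coords":
            continue
        mg.edge_sets[band] = read_edge_list(p, coords).edges
    return mg


# --- atlas, matrices, reports ----------------------------------------------


def write_atlas(atlas: RegionAtlas, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "region_id": atlas.region_ids,
            "x": atlas.centers[:, 0],
            "y": atlas.centers[:, 1],
            "z": atlas.centers[:, 2],
            "name": atlas.names,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_atlas(path: str | Path) -> RegionAtlas:
    df = pd.read_csv(path, sep="\t")
    df = df.sort_values("region_id")
    return RegionAtlas(
        centers=df[["x", "y", "z"]].to_numpy(float), names=[str(n) for n in df["name"]]
    )


def write_region_matrix(rcm: RegionConnectivityMatrix, path: str | Path) -> None:
    df = pd.DataFrame(rcm.counts, index=rcm.region_ids, columns=rcm.region_ids)
    df.to_csv(path, sep="\t", index_label="region_id")


def write_metrics_report(metrics: dict[str, float], path: str | Path) -> None:
    """Flat key-value TSV report."""
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for k, v in metrics.items():
            fh.write(f"{k}\t{v!r}\n")


def write_kernel_matrix(K, path: str | Path) -> None:
    """Square delimited kernel with the subject order as header row."""
    df = pd.DataFrame(K.values, index=K.subject_order, columns=K.subject_order)
    df.to_csv(path, sep="\t", index_label="subject_id", float_format="%.12g")


def read_kernel_matrix(path: str | Path):
    from .classify import KernelMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    return KernelMatrix(values=df.to_numpy(float), subject_order=[str(c) for c in df.columns])


def write_roc_points(result, path: str | Path) -> None:
    """Two-column text (false positive rate, true positive rate)."""
    fpr, tpr = result.roc_points()
    np.savetxt(
        path, np.column_stack([fpr, tpr]), delimiter="\t",
        header="fpr\ttpr", fmt="%.10g",
    )


def write_cohort_manifest(
    rows: list[dict], path: str | Path
) -> None:
    """TSV manifest: subject_id, label, seed, path (one row per subject)."""
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_cohort_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
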