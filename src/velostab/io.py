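"""Readers and writers for layered count containers and TSV/JSON reports.

Two input routes are supported: a layered ``.h5ad`` single-cell container
(via anndata) with count layers named ``"spliced"``/``"unspliced"``, and
MatrixMarket triplets (one ``.mtx`` per layer) with plain-text gene and
barcode lists.  Count layers are validated as integer-valued at load time.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix, CoherenceVector, VelocityResult
from .synthdata import SyntheticDataset

__all__ = [
    "read_layered",
    "read_mtx_layers",
    "write_layered",
    "write_tsv_report",
    "dataset_to_anndata",
]

NA_STRING = "NA"
INF_STRING = "inf"


def read_layered(path: str | Path, required_layers=("spliced", "unspliced")) -> dict[str, CountMatrix]:
    """Load the requested count layers from a layered ``.h5ad`` container."""
    import anndata as ad

    adata = ad.read_h5ad(str(path))
    available = sorted(adata.layers.keys())
    out: dict[str, CountMatrix] = {}
    for layer in required_layers:
        if layer not in adata.layers:
            raise KeyError(
                f"layer {layer!r} not found; available layers: {available}"
            )
        out[layer] = CountMatrix(
            adata.layers[layer],
            gene_ids=pd.Index(adata.var_names),
            cell_ids=pd.Index(adata.obs_names),
            layer_name=layer,
        )
    return out


def read_mtx_layers(
    mtx_paths: dict[str, str | Path],
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> dict[str, CountMatrix]:
    """Load layers from MatrixMarket files plus gene/barcode text lists.

    Matrices are expected cells x genes; a genes x cells matrix whose shape
    matches only when transposed is transposed with a note in the container.
    """
    genes = pd.Index(
        pd.read_csv(genes_path, header=None, sep="\t").iloc[:, 0].astype(str)
    )
    cells = pd.Index(
        pd.read_csv(barcodes_path, header=None, sep="\t").iloc[:, 0].astype(str)
    )
    out = {}
    for layer, p in mtx_paths.items():
        M = scipy.io.mmread(str(p))
        M = sp.csr_matrix(M)
        if M.shape == (len(genes), len(cells)) and M.shape != (len(cells), len(genes)):
            M = M.T.tocsr()
        out[layer] = CountMatrix(M, genes, cells, layer)
    return out


def dataset_to_anndata(ds: SyntheticDataset):
    """Pack a synthetic dataset into an AnnData with layered counts."""
    import anndata as ad

    adata = ad.AnnData(
        X=sp.csr_matrix(ds.spliced.counts),
        obs=pd.DataFrame(
            {"stage": ds.cell_stage_labels.values}, index=ds.spliced.cell_ids
        ),
        var=pd.DataFrame(index=ds.spliced.gene_ids),
    )
    adata.layers["spliced"] = sp.csr_matrix(ds.spliced.counts)
    adata.layers["unspliced"] = sp.csr_matrix(ds.unspliced.counts)
    tv = np.zeros(adata.shape)
    tv[:, : ds.params.kinetic_genes] = ds.true_velocity
    adata.layers["true_velocity"] = tv
    return adata


def write_layered(
    path: str | Path,
    layers: dict[str, CountMatrix],
    obs: pd.DataFrame | None = None,
    provenance: dict | None = None,
) -> None:
    """Write count layers to ``.h5ad``; provenance goes in ``.uns``."""
    import anndata as ad

    first = next(iter(layers.values()))
    adata = ad.AnnData(
        X=sp.csr_matrix(first.counts),
        obs=obs if obs is not None else pd.DataFrame(index=first.cell_ids),
        var=pd.DataFrame(index=first.gene_ids),
    )
    for name, cm in layers.items():
        if not cm.cell_ids.equals(first.cell_ids) or not cm.gene_ids.equals(first.gene_ids):
            raise ValueError("all layers must share identifiers")
        adata.layers[name] = sp.csr_matrix(cm.counts)
    if provenance:
        adata.uns["velostab"] = {k: v for k, v in provenance.items()}
    adata.write_h5ad(str(path))


def _fmt(v) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return NA_STRING
    if isinstance(v, float) and np.isinf(v):
        return INF_STRING
    if isinstance(v, float):
        return format(v, ".10g")
    return str(v)


def write_tsv_report(records: list[dict], path: str | Path) -> None:
    """Write records as a deterministic TSV (header from the first record).

    Floats use ``%.10g``; missing values are spelled ``NA`` and infinities
    ``inf``, so re-writing identical records yields a byte-identical file.
    """
    if not records:
        raise ValueError("no records to write")
    columns = list(records[0].keys())
    lines = ["\t".join(columns)]
    for rec in records:
        lines.append("\t".join(_fmt(rec.get(c)) for c in columns))
    Path(path).write_text("\n".join(lines) + "\n")


def coherence_records(theta: CoherenceVector, column: str = "theta") -> list[dict]:
    return [
        {"cell_id": c, column: (None if np.isnan(v) else float(v))}
        for c, v in zip(theta.cell_ids, theta.values)
    ]


def write_velocity(path: str | Path, V: VelocityResult, provenance: dict | None = None) -> None:
    """Store a velocity result as an ``.h5ad`` with a ``velocity`` layer."""
    import anndata as ad

    adata = ad.AnnData(
        X=np.asarray(V.velocities),
        obs=pd.DataFrame(index=V.cell_ids),
        var=pd.DataFrame(index=V.gene_ids),
    )
    adata.layers["velocity"] = np.asarray(V.velocities)
    adata.uns["space_tag"] = V.space_tag
    if provenance:
        adata.uns["velostab"] = provenance
    adata.write_h5ad(str(path))


def read_velocity(path: str | Path) -> VelocityResult:
    import anndata as ad

    adata = ad.read_h5ad(str(path))
    layer = adata.layers["velocity"] if "velocity" in adata.layers else adata.X
    if sp.issparse(layer):
        layer = np.asarray(layer.todense())
    return VelocityResult(
        np.asarray(layer),
        gene_ids=pd.Index(adata.var_names),
        cell_ids=pd.Index(adata.obs_names),
        space_tag=str(adata.uns.get("space_tag", "gene")),
    )


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
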