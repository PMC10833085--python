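"""Dataset containers, panel merging, and quality filtering.

Reference datasets carry RNA counts, an optional surface-protein panel, and
cell-type labels; a query carries RNA only.  Multiple references with
heterogeneous antibody panels are merged on the gene intersection and the
protein union, with a boolean mask recording which protein entries were
actually measured (the censoring structure consumed by the protein loss).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when a dataset violates a structural invariant."""


def _as_count_matrix(x, name: str) -> np.ndarray:
    arr = np.asarray(x)
    if hasattr(x, "toarray"):  # scipy sparse
        arr = x.toarray()
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValidationError(f"{name} must be 2-D, got shape {arr.shape}")
    if np.any(arr < 0):
        raise ValidationError(f"{name} contains negative entries")
    return arr


def _check_unique(ids: Sequence[str], name: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate {name}: {dupes[:5]}")
    return ids


@dataclasses.dataclass
class ReferenceDataset:
    """One CITE-seq (or scRNA-seq) batch used as training reference.

    ``protein`` may be ``None`` for an RNA-only reference; downstream the
    protein head is then censored everywhere for these cells.
    """

    rna: np.ndarray
    gene_ids: list[str]
    cell_types: np.ndarray
    protein: Optional[np.ndarray] = None
    protein_ids: list[str] = dataclasses.field(default_factory=list)
    batch_id: str = "batch0"

    def __post_init__(self):
        self.rna = _as_count_matrix(self.rna, "rna")
        self.gene_ids = _check_unique(self.gene_ids, "gene ids")
        if self.rna.shape[1] != len(self.gene_ids):
            raise ValidationError(
                f"rna has {self.rna.shape[1]} columns but {len(self.gene_ids)} gene ids"
            )
        self.cell_types = np.asarray(self.cell_types, dtype=object)
        if len(self.cell_types) != self.rna.shape[0]:
            raise ValidationError("cell_types length must equal number of cells")
        if self.protein is not None:
            self.protein = _as_count_matrix(self.protein, "protein")
            if self.protein.shape[0] != self.rna.shape[0]:
                raise ValidationError("protein row count must equal rna row count")
            self.protein_ids = _check_unique(self.protein_ids, "protein ids")
            if self.protein.shape[1] != len(self.protein_ids):
                raise ValidationError("protein column count must match protein ids")
        else:
            if self.protein_ids:
                raise ValidationError("protein_ids given without a protein matrix")

    @property
    def n_cells(self) -> int:
        return self.rna.shape[0]

    @property
    def n_genes(self) -> int:
        return self.rna.shape[1]


@dataclasses.dataclass
class QueryDataset:
    """RNA-only dataset to be annotated / imputed."""

    rna: np.ndarray
    gene_ids: list[str]
    batch_id: str = "query"

    def __post_init__(self):
        self.rna = _as_count_matrix(self.rna, "rna")
        self.gene_ids = _check_unique(self.gene_ids, "gene ids")
        if self.rna.shape[1] != len(self.gene_ids):
            raise ValidationError("rna column count must match gene ids")

    @property
    def n_cells(self) -> int:
        return self.rna.shape[0]


@dataclasses.dataclass
class MergedReference:
    """References stacked on the shared gene catalog and the protein union.

    ``protein_mask[c, p]`` is True exactly when protein ``p`` belongs to the
    panel of cell ``c``'s source dataset.  Catalog ordering is lexicographic,
    so the merge is a deterministic function of the input id sets.
    """

    rna: np.ndarray
    protein: np.ndarray
    protein_mask: np.ndarray
    gene_ids: list[str]
    protein_ids: list[str]
    cell_types: np.ndarray
    batch_ids: np.ndarray
    class_catalog: list[str]

    @property
    def n_cells(self) -> int:
        return self.rna.shape[0]

    @property
    def n_genes(self) -> int:
        return self.rna.shape[1]


def merge_panels(
    datasets: Sequence[ReferenceDataset],
    query: Optional[QueryDataset] = None,
) -> MergedReference:
    """Merge reference datasets (and optionally restrict to query genes).

    Genes: intersection across all references and the query; proteins: union
    of all reference panels.  Both catalogs are sorted lexicographically.
    """
    if len(datasets) == 0:
        raise ValidationError("need at least one reference dataset")
    for d in datasets:
        if d.n_cells == 0 or d.n_genes == 0:
            raise ValidationError("empty reference dataset")

    shared = set(datasets[0].gene_ids)
    for d in datasets[1:]:
        shared &= set(d.gene_ids)
    if query is not None:
        shared &= set(query.gene_ids)
    if not shared:
        raise ValidationError("no shared genes across datasets")
    gene_ids = sorted(shared)

    protein_ids: set[str] = set()
    for d in datasets:
        protein_ids |= set(d.protein_ids)
    protein_ids = sorted(protein_ids)
    p_index = {p: j for j, p in enumerate(protein_ids)}

    rna_blocks, prot_blocks, mask_blocks = [], [], []
    types, batches = [], []
    for d in datasets:
        col = {g: j for j, g in enumerate(d.gene_ids)}
        rna_blocks.append(d.rna[:, [col[g] for g in gene_ids]])
        prot = np.zeros((d.n_cells, len(protein_ids)), dtype=float)
        mask = np.zeros((d.n_cells, len(protein_ids)), dtype=bool)
        if d.protein is not None:
            for j, p in enumerate(d.protein_ids):
                prot[:, p_index[p]] = d.protein[:, j]
                mask[:, p_index[p]] = True
        prot_blocks.append(prot)
        mask_blocks.append(mask)
        types.append(d.cell_types)
        batches.append(np.full(d.n_cells, d.batch_id, dtype=object))

    cell_types = np.concatenate(types)
    return MergedReference(
        rna=np.vstack(rna_blocks),
        protein=np.vstack(prot_blocks),
        protein_mask=np.vstack(mask_blocks),
        gene_ids=gene_ids,
        protein_ids=protein_ids,
        cell_types=cell_types,
        batch_ids=np.concatenate(batches),
        class_catalog=sorted(set(cell_types.tolist())),
    )


def filter_low_quality(
    merged: MergedReference,
    min_genes_per_cell: int = 200,
    min_cells_per_gene: int = 30,
    enabled: bool = True,
) -> MergedReference:
    """Remove low-complexity cells, then rarely detected genes.

    Cells expressing fewer than ``min_genes_per_cell`` genes are dropped
    first; genes detected in fewer than ``min_cells_per_gene`` of the
    surviving cells are dropped second.  Disabled mode is the identity.
    """
    if min_genes_per_cell < 0 or min_cells_per_gene < 0:
        raise ValidationError("thresholds must be nonnegative")
    if not enabled:
        return merged

    expressed = merged.rna > 0
    keep_cells = expressed.sum(axis=1) >= min_genes_per_cell
    if not keep_cells.any():
        raise ValidationError("empty after filtering")
    rna = merged.rna[keep_cells]
    keep_genes = (rna > 0).sum(axis=0) >= min_cells_per_gene
    return MergedReference(
        rna=rna[:, keep_genes],
        protein=merged.protein[keep_cells],
        protein_mask=merged.protein_mask[keep_cells],
        gene_ids=[g for g, k in zip(merged.gene_ids, keep_genes) if k],
        protein_ids=list(merged.protein_ids),
        cell_types=merged.cell_types[keep_cells],
        batch_ids=merged.batch_ids[keep_cells],
        class_catalog=list(merged.class_catalog),
    )


# ---------------------------------------------------------------------------
# Readers / writers.  Three interchange formats: AnnData (.h5ad), Matrix
# Market triplets with gene/barcode sidecars, and dense CSV (header = genes).
# ---------------------------------------------------------------------------

def write_dataset(ds: ReferenceDataset | QueryDataset, path: str | Path, format: str = "csv") -> None:
    path = Path(path)
    is_ref = isinstance(ds, ReferenceDataset)
    if format == "csv":
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(ds.rna, columns=ds.gene_ids).to_csv(path / "rna.csv", index=False)
        if is_ref:
            if ds.protein is not None:
                pd.DataFrame(ds.protein, columns=ds.protein_ids).to_csv(
                    path / "protein.csv", index=False
                )
            pd.DataFrame({"cell_type": ds.cell_types}).to_csv(path / "labels.csv", index=False)
        (path / "batch.txt").write_text(str(ds.batch_id) + "\n")
    elif format == "mtx":
        from scipy import io as spio
        from scipy import sparse

        path.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(str(path / "rna.mtx"), sparse.coo_matrix(ds.rna))
        (path / "genes.tsv").write_text("\n".join(ds.gene_ids) + "\n")
        (path / "barcodes.tsv").write_text(
            "\n".join(f"cell{i}" for i in range(ds.rna.shape[0])) + "\n"
        )
        if is_ref:
            if ds.protein is not None:
                spio.mmwrite(str(path / "protein.mtx"), sparse.coo_matrix(ds.protein))
                (path / "proteins.tsv").write_text("\n".join(ds.protein_ids) + "\n")
            pd.DataFrame({"cell_type": ds.cell_types}).to_csv(path / "labels.csv", index=False)
        (path / "batch.txt").write_text(str(ds.batch_id) + "\n")
    elif format == "h5ad":
        import anndata as ad

        adata = ad.AnnData(X=np.asarray(ds.rna, dtype=np.float64))
        adata.var_names = ds.gene_ids
        adata.obs["batch"] = str(ds.batch_id)
        if is_ref:
            adata.obs["cell_type"] = pd.Categorical(ds.cell_types)
            if ds.protein is not None:
                adata.obsm["protein"] = np.asarray(ds.protein, dtype=np.float64)
                adata.uns["protein_ids"] = list(ds.protein_ids)
        adata.write_h5ad(path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_dataset(path: str | Path, format: str = "csv", kind: str = "reference"):
    """Load a dataset written by :func:`write_dataset`.

    ``kind`` selects the container: ``"reference"`` (labels required,
    proteins optional) or ``"query"`` (RNA only).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    if format == "csv":
        rna_df = pd.read_csv(path / "rna.csv", float_precision="round_trip")
        rna = rna_df.to_numpy()
        gene_ids = list(rna_df.columns)
        batch = (path / "batch.txt").read_text().strip() if (path / "batch.txt").exists() else "batch0"
        if kind == "query":
            return QueryDataset(rna=rna, gene_ids=gene_ids, batch_id=batch)
        labels = pd.read_csv(path / "labels.csv")["cell_type"].to_numpy()
        protein = protein_ids = None
        if (path / "protein.csv").exists():
            pdf = pd.read_csv(path / "protein.csv", float_precision="round_trip")
            protein, protein_ids = pdf.to_numpy(), list(pdf.columns)
        return ReferenceDataset(
            rna=rna, gene_ids=gene_ids, cell_types=labels,
            protein=protein, protein_ids=protein_ids or [], batch_id=batch,
        )
    if format == "mtx":
        from scipy import io as spio

        rna = np.asarray(spio.mmread(str(path / "rna.mtx")).todense())
        gene_ids = (path / "genes.tsv").read_text().splitlines()
        barcodes = (path / "barcodes.tsv").read_text().splitlines()
        if rna.shape[1] != len(gene_ids):
            raise ValidationError(
                f"rna.mtx has {rna.shape[1]} columns but {len(gene_ids)} gene ids"
            )
        if rna.shape[0] != len(barcodes):
            raise ValidationError("barcode count does not match matrix rows")
        batch = (path / "batch.txt").read_text().strip() if (path / "batch.txt").exists() else "batch0"
        if kind == "query":
            return QueryDataset(rna=rna, gene_ids=gene_ids, batch_id=batch)
        labels = pd.read_csv(path / "labels.csv")["cell_type"].to_numpy()
        protein = protein_ids = None
        if (path / "protein.mtx").exists():
            protein = np.asarray(spio.mmread(str(path / "protein.mtx")).todense())
            protein_ids = (path / "proteins.tsv").read_text().splitlines()
        return ReferenceDataset(
            rna=rna, gene_ids=gene_ids, cell_types=labels,
            protein=protein, protein_ids=protein_ids or [], batch_id=batch,
        )
    if format == "h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        rna = np.asarray(adata.X)
        gene_ids = list(adata.var_names)
        batch = str(adata.obs["batch"].iloc[0]) if "batch" in adata.obs else "batch0"
        if kind == "query":
            return QueryDataset(rna=rna, gene_ids=gene_ids, batch_id=batch)
        labels = adata.obs["cell_type"].to_numpy()
        protein = protein_ids = None
        if "protein" in adata.obsm:
            protein = np.asarray(adata.obsm["protein"])
            protein_ids = list(adata.uns["protein_ids"])
        return ReferenceDataset(
            rna=rna, gene_ids=gene_ids, cell_types=labels,
            protein=protein, protein_ids=protein_ids or [], batch_id=batch,
        )
    raise ValueError(f"unknown format {format!r}")
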