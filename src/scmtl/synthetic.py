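"""Synthetic multi-batch CITE-seq generator and noise-injection procedures.

RNA counts are negative-binomial with cell-type- and batch-dependent means;
surface proteins are a linear readout of the cell's type signature plus
Gaussian noise.  Both corruption operators are exact-count (hypergeometric):
"a proportion p" zeroes exactly round(p * nnz) entries / relabels exactly
round(p * n_c) cells per class.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from .data_model import ReferenceDataset


@dataclasses.dataclass
class SimConfig:
    cells_per_type: Sequence[int] = (200, 200, 200)
    n_genes: int = 100
    n_proteins: int = 10
    n_batches: int = 1
    nb_dispersion: float = 2.0
    batch_effect_scale: float = 0.0
    dropout_rate: float = 0.0
    protein_noise_sd: float = 0.5
    signature_overlap: float = 0.0
    markers_per_type: int = 10
    marker_fold: float = 6.0
    seed: int = 0

    @property
    def n_types(self) -> int:
        return len(self.cells_per_type)

    def validate(self) -> None:
        if any(c < 1 for c in self.cells_per_type):
            raise ValueError("cells_per_type entries must be >= 1")
        if min(self.n_genes, self.n_proteins, self.n_batches) < 1:
            raise ValueError("dimensions must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if not (0.0 <= self.signature_overlap < 1.0):
            raise ValueError("signature_overlap must be in [0, 1)")
        if self.n_types * self.markers_per_type > self.n_genes:
            raise ValueError(
                f"cannot place {self.n_types} disjoint marker sets of "
                f"{self.markers_per_type} genes in {self.n_genes} genes"
            )


def type_signatures(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-type expected gene expression (n_types x n_genes).

    Each type up-regulates a disjoint marker block; ``signature_overlap``
    mixes every signature toward the shared mean, shrinking between-type
    separation continuously to zero.
    """
    base = rng.gamma(shape=2.0, scale=1.0, size=config.n_genes) + 0.2
    sig = np.tile(base, (config.n_types, 1))
    for t in range(config.n_types):
        lo = t * config.markers_per_type
        sig[t, lo : lo + config.markers_per_type] *= config.marker_fold
    mean_sig = sig.mean(axis=0)
    return (1 - config.signature_overlap) * sig + config.signature_overlap * mean_sig


def simulate_citeseq(config: SimConfig):
    """Generate per-batch reference datasets plus ground-truth latents.

    Returns ``(datasets, truth)`` where ``truth`` holds the type signatures,
    the protein loading map, expected RNA means and per-batch labels.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    sig = type_signatures(config, rng)
    # proteins = linear map of the one-hot type signal -> per-type protein means
    protein_loading = rng.uniform(1.0, 8.0, size=(config.n_types, config.n_proteins))
    batch_factors = np.exp(
        config.batch_effect_scale * rng.normal(size=(config.n_batches, config.n_genes))
    )

    # round-robin allocation of each type's cells across batches
    per_batch_types: list[list[int]] = [[] for _ in range(config.n_batches)]
    for t, n in enumerate(config.cells_per_type):
        for c in range(n):
            per_batch_types[c % config.n_batches].append(t)

    gene_ids = [f"gene{i:04d}" for i in range(config.n_genes)]
    protein_ids = [f"prot{i:03d}" for i in range(config.n_proteins)]
    datasets = []
    truth_labels = []
    for b in range(config.n_batches):
        types = np.array(per_batch_types[b], dtype=int)
        order = rng.permutation(len(types))
        types = types[order]
        mean = sig[types] * batch_factors[b]  # (cells, genes)

        lam = rng.gamma(shape=config.nb_dispersion, scale=mean / config.nb_dispersion)
        rna = rng.poisson(lam).astype(float)
        if config.dropout_rate > 0:
            rna[rng.random(rna.shape) < config.dropout_rate] = 0.0
        # guard: an all-zero cell breaks normalization downstream
        dead = rna.sum(axis=1) == 0
        if dead.any():
            rna[dead, 0] = 1.0

        prot = protein_loading[types] + config.protein_noise_sd * rng.normal(
            size=(len(types), config.n_proteins)
        )
        prot = np.clip(prot, 0.0, None)

        labels = np.array([f"type{t}" for t in types], dtype=object)
        truth_labels.append(types)
        datasets.append(
            ReferenceDataset(
                rna=rna,
                gene_ids=list(gene_ids),
                cell_types=labels,
                protein=prot,
                protein_ids=list(protein_ids),
                batch_id=f"batch{b}",
            )
        )

    truth = {
        "signatures": sig,
        "protein_loading": protein_loading,
        "batch_factors": batch_factors,
        "types_per_batch": truth_labels,
        "gene_ids": gene_ids,
        "protein_ids": protein_ids,
    }
    return datasets, truth


def inject_dropout(rna: np.ndarray, proportion: float, seed: int = 0) -> np.ndarray:
    """Zero exactly round(proportion * nnz) nonzero entries, chosen uniformly."""
    if not (0.0 <= proportion <= 1.0):
        raise ValueError("proportion must be in [0, 1]")
    rna = np.asarray(rna, dtype=float).copy()
    nz_rows, nz_cols = np.nonzero(rna)
    n_kill = int(round(proportion * len(nz_rows)))
    if n_kill:
        rng = np.random.default_rng(seed)
        pick = rng.choice(len(nz_rows), size=n_kill, replace=False)
        rna[nz_rows[pick], nz_cols[pick]] = 0.0
    return rna


def inject_label_noise(labels, proportion: float, seed: int = 0):
    """Relabel exactly round(proportion * n_c) cells of each class.

    Each selected cell receives a label drawn from the *other* classes with
    probability proportional to their class sizes; no flipped cell keeps its
    original label.  Returns ``(new_labels, flips)`` with flips a list of
    ``(cell_index, old, new)``.
    """
    if not (0.0 <= proportion <= 1.0):
        raise ValueError("proportion must be in [0, 1]")
    labels = np.asarray(labels, dtype=object).copy()
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to inject label noise")
    counts = {c: int(np.sum(labels == c)) for c in classes}
    rng = np.random.default_rng(seed)
    flips = []
    out = labels.copy()
    for c in classes:
        members = np.where(labels == c)[0]
        k = int(round(proportion * len(members)))
        if k == 0:
            continue
        chosen = rng.choice(members, size=k, replace=False)
        others = [o for o in classes if o != c]
        w = np.array([counts[o] for o in others], dtype=float)
        w /= w.sum()
        new = rng.choice(np.array(others, dtype=object), size=k, p=w)
        for i, nl in zip(chosen, new):
            flips.append((int(i), c, nl))
            out[i] = nl
    return out, flips
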