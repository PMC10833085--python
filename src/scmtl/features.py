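"""Hybrid feature extraction for single-cell RNA counts.

Two branches computed from the log-normalized matrix and concatenated:

* branch A — highly-variable-gene (HVG) selection followed by per-gene
  z-scoring;
* branch B — empirical-Bayes batch correction (ComBat), then truncated SVD
  and maximum-likelihood factor analysis, each block z-scored.

The fitted :class:`FeatureTransform` stores every per-gene / per-batch
parameter, so applying it row-wise to any subset of the fitting cells
reproduces the jointly fitted features exactly.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional

import numpy as np
from sklearn.decomposition import FactorAnalysis
from sklearn.exceptions import ConvergenceWarning


class FeatureError(ValueError):
    pass


class FAConvergenceError(RuntimeError):
    def __init__(self, n_iter: int):
        self.n_iter = n_iter
        super().__init__(f"factor analysis did not converge after {n_iter} iterations")


@dataclasses.dataclass
class FeatureConfig:
    n_hvg: int = 550
    k_tsvd: int = 300
    k_fa: int = 180
    normalize_total: float = 1e4
    combat: bool = True
    transductive: bool = True
    # pipeline-level FA stopping rule; looser than fit_fa's standalone
    # default because log-count data converges slowly near the optimum
    fa_max_iter: int = 1000
    fa_tol: float = 1e-2
    seed: int = 0


def normalize_log(rna: np.ndarray, target_total: float = 1e4) -> np.ndarray:
    """Scale each cell to ``target_total`` counts, then apply log1p."""
    rna = np.asarray(rna, dtype=float)
    if np.any(rna < 0):
        raise FeatureError("counts must be nonnegative")
    totals = rna.sum(axis=1)
    zero = np.where(totals == 0)[0]
    if zero.size:
        raise FeatureError(f"cell {zero[0]} has zero total counts")
    return np.log1p(rna * (target_total / totals[:, None]))


def select_hvgs(logdata: np.ndarray, n_hvg: int = 550, n_bins: int = 20) -> np.ndarray:
    """Rank genes by mean-binned normalized dispersion; return top indices.

    Dispersion (variance/mean) is computed on the de-logged normalized
    counts, z-scored within equal-frequency mean bins.  Zero-variance genes
    are never selected while a varying gene remains.  Ties break toward the
    lower gene index; the returned indices are sorted ascending.
    """
    logdata = np.asarray(logdata, dtype=float)
    n_genes = logdata.shape[1]
    if n_hvg > n_genes:
        raise FeatureError(f"n_hvg={n_hvg} exceeds gene count {n_genes}")

    x = np.expm1(logdata)
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(n_genes)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)

    # equal-frequency bins over the mean
    n_bins = min(n_bins, n_genes)
    order = np.argsort(mean, kind="stable")
    bin_of = np.empty(n_genes, dtype=int)
    bin_of[order] = np.minimum((np.arange(n_genes) * n_bins) // n_genes, n_bins - 1)

    norm_disp = np.zeros(n_genes)
    for b in range(n_bins):
        sel = bin_of == b
        if not sel.any():
            continue
        d = disp[sel]
        sd = d.std(ddof=1) if sel.sum() > 1 else 0.0
        norm_disp[sel] = (d - d.mean()) / sd if sd > 0 else 0.0
    constant = logdata.max(axis=0) == logdata.min(axis=0)
    norm_disp[constant] = -np.inf

    ranked = np.lexsort((np.arange(n_genes), -norm_disp))
    return np.sort(ranked[:n_hvg])


# ---------------------------------------------------------------------------
# ComBat — parametric empirical-Bayes location/scale batch adjustment.
# ---------------------------------------------------------------------------

def _combat_it_sol(s_data, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4, max_iter=500):
    """Iterative EB solution for per-batch location/scale (one batch)."""
    n = s_data.shape[0]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = (n * t2 * g_hat + d_old * g_bar) / (n * t2 + d_old)
        sum2 = ((s_data - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.abs(g_new - g_old).max() / np.maximum(np.abs(g_old), 1e-12).max(),
            np.abs(d_new - d_old).max() / np.maximum(np.abs(d_old), 1e-12).max(),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def fit_combat(logdata: np.ndarray, batch_ids) -> dict:
    """Fit parametric ComBat; returns per-batch affine maps per gene.

    The returned dict maps ``batch -> (scale, offset)`` such that
    ``corrected = x * scale + offset`` elementwise for cells of that batch.
    A final per-gene recentering keeps the pooled mean exactly unchanged.
    Single-batch data gets an identity map; a one-cell batch is an error.
    """
    x = np.asarray(logdata, dtype=float)
    batch_ids = np.asarray(batch_ids)
    batches = sorted(set(batch_ids.tolist()))
    n, g = x.shape
    if len(batches) == 1:
        return {batches[0]: (np.ones(g), np.zeros(g))}

    idx = {b: np.where(batch_ids == b)[0] for b in batches}
    for b, ii in idx.items():
        if len(ii) < 2:
            raise FeatureError(f"batch {b!r} has fewer than 2 cells; scale undefined")

    n_b = np.array([len(idx[b]) for b in batches], dtype=float)
    batch_means = np.vstack([x[idx[b]].mean(axis=0) for b in batches])
    stand_mean = (n_b[:, None] * batch_means).sum(axis=0) / n

    resid = x.copy()
    for bi, b in enumerate(batches):
        resid[idx[b]] -= batch_means[bi]
    var_pooled = (resid ** 2).sum(axis=0) / n
    sv = np.sqrt(var_pooled)
    ok = sv > 1e-12  # constant genes pass through untouched
    sv_safe = np.where(ok, sv, 1.0)

    s_data = (x - stand_mean) / sv_safe
    gamma_star = np.zeros((len(batches), g))
    delta_star = np.ones((len(batches), g))
    for bi, b in enumerate(batches):
        sd = s_data[idx[b]]
        g_hat = sd.mean(axis=0)
        d_hat = sd.var(axis=0, ddof=1)
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        m, v = d_hat.mean(), d_hat.var(ddof=1)
        if v <= 0:
            a_prior, b_prior = 2.0, 1.0
        else:
            a_prior = (2 * v + m ** 2) / v
            b_prior = (m * v + m ** 3) / v
        gs, ds = _combat_it_sol(sd, g_hat, d_hat, g_bar, t2, a_prior, b_prior)
        gamma_star[bi] = gs
        delta_star[bi] = np.maximum(ds, 1e-12)

    # x -> ((x - sm)/sv - gamma)/sqrt(delta) * sv + sm, folded to scale/offset
    params = {}
    for bi, b in enumerate(batches):
        scale = np.where(ok, 1.0 / np.sqrt(delta_star[bi]), 1.0)
        offset = np.where(
            ok,
            stand_mean * (1.0 - scale) - gamma_star[bi] * sv_safe / np.sqrt(delta_star[bi]),
            0.0,
        )
        params[b] = (scale, offset)

    # exact pooled-mean preservation (location effects redistributed only)
    adj_mean = np.zeros(g)
    for bi, b in enumerate(batches):
        scale, offset = params[b]
        adj_mean += n_b[bi] * (batch_means[bi] * scale + offset)
    shift = stand_mean - adj_mean / n
    params = {b: (s, o + shift) for b, (s, o) in params.items()}
    return params


def apply_combat(logdata: np.ndarray, batch_ids, params: dict) -> np.ndarray:
    """Apply fitted per-batch maps row-wise; unseen batches pass through."""
    x = np.asarray(logdata, dtype=float)
    out = x.copy()
    batch_ids = np.asarray(batch_ids)
    for b in set(batch_ids.tolist()):
        if b not in params:
            continue
        scale, offset = params[b]
        ii = batch_ids == b
        out[ii] = x[ii] * scale + offset
    return out


def combat_correct(logdata: np.ndarray, batch_ids) -> np.ndarray:
    return apply_combat(logdata, batch_ids, fit_combat(logdata, batch_ids))


# ---------------------------------------------------------------------------
# TSVD and factor analysis
# ---------------------------------------------------------------------------

def fit_tsvd(corrected: np.ndarray, k_tsvd: int = 300):
    """Rank-k truncated SVD of the uncentered matrix.

    Returns ``(components, scores)`` with components of shape
    (genes, k) and scores ``X @ components``.  Component signs are fixed so
    the largest-magnitude loading entry is positive.
    """
    x = np.asarray(corrected, dtype=float)
    n, g = x.shape
    if k_tsvd > min(n, g):
        raise FeatureError(f"k_tsvd={k_tsvd} exceeds min(cells, genes)={min(n, g)}")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int((s > s[0] * max(n, g) * np.finfo(float).eps).sum()) if s.size else 0
    if k_tsvd > rank:
        raise FeatureError(f"k_tsvd={k_tsvd} exceeds numerical rank {rank}")
    comps = vt[:k_tsvd].T.copy()
    flip = np.sign(comps[np.abs(comps).argmax(axis=0), np.arange(k_tsvd)])
    flip[flip == 0] = 1.0
    comps *= flip
    return comps, x @ comps


@dataclasses.dataclass
class FAParams:
    """ML factor-analysis solution: loadings, diagonal noise, gene means."""

    loadings: np.ndarray      # (genes, k)
    noise_variance: np.ndarray  # (genes,)
    mean: np.ndarray          # (genes,)

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Posterior factor means E[z | x]."""
        lam = self.loadings
        psi_inv = 1.0 / self.noise_variance
        cov_z = np.linalg.inv(np.eye(lam.shape[1]) + (lam.T * psi_inv) @ lam)
        return (x - self.mean) @ (psi_inv[:, None] * lam) @ cov_z


def fit_fa(corrected: np.ndarray, k_fa: int = 180, max_iter: int = 1000, tol: float = 1e-4):
    """Maximum-likelihood factor analysis with diagonal uniquenesses.

    Backed by scikit-learn's SVD-based EM solver (deterministic with the
    LAPACK path).  Returns ``(FAParams, scores)``.
    """
    x = np.asarray(corrected, dtype=float)
    if k_fa >= x.shape[1]:
        raise FeatureError(f"k_fa={k_fa} must be < gene count {x.shape[1]}")
    fa = FactorAnalysis(n_components=k_fa, svd_method="lapack", max_iter=max_iter, tol=tol)
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            fa.fit(x)
        except ConvergenceWarning as exc:
            raise FAConvergenceError(max_iter) from exc
    params = FAParams(
        loadings=fa.components_.T.copy(),
        noise_variance=fa.noise_variance_.copy(),
        mean=fa.mean_.copy(),
    )
    return params, params.transform(x)


# ---------------------------------------------------------------------------
# Assembled transform
# ---------------------------------------------------------------------------

def _colstats(x: np.ndarray):
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    return mean, np.where(sd > 0, sd, 1.0)


@dataclasses.dataclass
class FeatureTransform:
    """All fitted parameters of the two-branch feature pipeline."""

    config: FeatureConfig
    n_genes: int
    hvg_indices: np.ndarray
    hvg_mean: np.ndarray
    hvg_sd: np.ndarray
    combat_params: Optional[dict]
    tsvd_components: Optional[np.ndarray]
    tsvd_mean: Optional[np.ndarray]
    tsvd_sd: Optional[np.ndarray]
    fa_params: Optional[FAParams]
    fa_mean: Optional[np.ndarray]
    fa_sd: Optional[np.ndarray]
    fitted_on: str = ""

    @property
    def output_dim(self) -> int:
        return len(self.hvg_indices) + self.config.k_tsvd + self.config.k_fa

    @property
    def block_boundaries(self) -> dict:
        h = len(self.hvg_indices)
        return {
            "hvg": (0, h),
            "tsvd": (h, h + self.config.k_tsvd),
            "fa": (h + self.config.k_tsvd, self.output_dim),
        }

    def apply(self, logdata: np.ndarray, batch_ids) -> "FeatureMatrix":
        x = np.asarray(logdata, dtype=float)
        if x.shape[1] != self.n_genes:
            raise FeatureError(
                f"gene count {x.shape[1]} does not match fitted {self.n_genes}"
            )
        blocks = []
        if len(self.hvg_indices):
            blocks.append((x[:, self.hvg_indices] - self.hvg_mean) / self.hvg_sd)
        if self.config.k_tsvd or self.config.k_fa:
            corrected = (
                apply_combat(x, batch_ids, self.combat_params)
                if self.combat_params is not None
                else x
            )
            if self.config.k_tsvd:
                t = corrected @ self.tsvd_components
                blocks.append((t - self.tsvd_mean) / self.tsvd_sd)
            if self.config.k_fa:
                f = self.fa_params.transform(corrected)
                blocks.append((f - self.fa_mean) / self.fa_sd)
        values = np.hstack(blocks) if blocks else np.zeros((x.shape[0], 0))
        if not np.all(np.isfinite(values)):
            raise FeatureError("non-finite feature values")
        return FeatureMatrix(
            values=values,
            block_boundaries=self.block_boundaries,
            cell_index=np.arange(x.shape[0]),
        )


    def save(self, path) -> None:
        import json
        from pathlib import Path

        arrays = {
            "hvg_indices": self.hvg_indices,
            "hvg_mean": self.hvg_mean,
            "hvg_sd": self.hvg_sd,
        }
        meta = {
            "config": dataclasses.asdict(self.config),
            "n_genes": self.n_genes,
            "fitted_on": self.fitted_on,
            "combat_batches": None,
        }
        if self.combat_params is not None:
            batches = sorted(self.combat_params, key=str)
            meta["combat_batches"] = [str(b) for b in batches]
            arrays["combat_scale"] = np.vstack([self.combat_params[b][0] for b in batches])
            arrays["combat_offset"] = np.vstack([self.combat_params[b][1] for b in batches])
        if self.tsvd_components is not None:
            arrays["tsvd_components"] = self.tsvd_components
            arrays["tsvd_mean"] = self.tsvd_mean
            arrays["tsvd_sd"] = self.tsvd_sd
        if self.fa_params is not None:
            arrays["fa_loadings"] = self.fa_params.loadings
            arrays["fa_noise"] = self.fa_params.noise_variance
            arrays["fa_center"] = self.fa_params.mean
            arrays["fa_mean"] = self.fa_mean
            arrays["fa_sd"] = self.fa_sd
        arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(Path(path), **arrays)

    @classmethod
    def load(cls, path) -> "FeatureTransform":
        import json
        from pathlib import Path

        data = np.load(Path(path))
        meta = json.loads(bytes(data["meta_json"]).decode())
        combat_params = None
        if meta["combat_batches"] is not None:
            combat_params = {
                b: (data["combat_scale"][i], data["combat_offset"][i])
                for i, b in enumerate(meta["combat_batches"])
            }
        fa_params = None
        if "fa_loadings" in data:
            fa_params = FAParams(
                loadings=data["fa_loadings"],
                noise_variance=data["fa_noise"],
                mean=data["fa_center"],
            )
        return cls(
            config=FeatureConfig(**meta["config"]),
            n_genes=meta["n_genes"],
            hvg_indices=data["hvg_indices"],
            hvg_mean=data["hvg_mean"],
            hvg_sd=data["hvg_sd"],
            combat_params=combat_params,
            tsvd_components=data.get("tsvd_components"),
            tsvd_mean=data.get("tsvd_mean"),
            tsvd_sd=data.get("tsvd_sd"),
            fa_params=fa_params,
            fa_mean=data.get("fa_mean"),
            fa_sd=data.get("fa_sd"),
            fitted_on=meta["fitted_on"],
        )


@dataclasses.dataclass
class FeatureMatrix:
    values: np.ndarray
    block_boundaries: dict
    cell_index: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


def fit_feature_transform(
    logdata: np.ndarray,
    batch_ids,
    config: FeatureConfig = FeatureConfig(),
    fitted_on: str = "",
) -> FeatureTransform:
    """Fit both branches on ``logdata`` (the reference, or reference+query
    in transductive mode — the caller decides which cells to pass)."""
    x = np.asarray(logdata, dtype=float)

    hvg_idx = select_hvgs(x, config.n_hvg) if config.n_hvg else np.array([], dtype=int)
    hvg_mean, hvg_sd = _colstats(x[:, hvg_idx]) if len(hvg_idx) else (np.zeros(0), np.ones(0))

    combat_params = tsvd_comps = tsvd_mean = tsvd_sd = None
    fa_params = fa_mean = fa_sd = None
    if config.k_tsvd or config.k_fa:
        combat_params = fit_combat(x, batch_ids) if config.combat else None
        corrected = apply_combat(x, batch_ids, combat_params) if config.combat else x
        if config.k_tsvd:
            tsvd_comps, tsvd_scores = fit_tsvd(corrected, config.k_tsvd)
            tsvd_mean, tsvd_sd = _colstats(tsvd_scores)
        if config.k_fa:
            fa_params, fa_scores = fit_fa(
                corrected, config.k_fa, max_iter=config.fa_max_iter, tol=config.fa_tol
            )
            fa_mean, fa_sd = _colstats(fa_scores)

    return FeatureTransform(
        config=config,
        n_genes=x.shape[1],
        hvg_indices=hvg_idx,
        hvg_mean=hvg_mean,
        hvg_sd=hvg_sd,
        combat_params=combat_params,
        tsvd_components=tsvd_comps,
        tsvd_mean=tsvd_mean,
        tsvd_sd=tsvd_sd,
        fa_params=fa_params,
        fa_mean=fa_mean,
        fa_sd=fa_sd,
        fitted_on=fitted_on,
    )


def assemble_features(logdata: np.ndarray, transform: FeatureTransform, batch_ids=None) -> FeatureMatrix:
    if batch_ids is None:
        batch_ids = np.full(np.asarray(logdata).shape[0], "__none__", dtype=object)
    return transform.apply(logdata, batch_ids)
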