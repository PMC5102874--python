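"""Phenotype distance matrices, classical MDS, and the map/heatmap plots.

Two distances between phenotypes are provided:

* pleiotropy-based: s_ij = log10 of the pairwise pleiotropy-test p-value,
  d_ij = s_ij - 2 min_{k<l} s_kl.  Smaller test p-values (stronger
  pleiotropy) give shorter distances, and subtracting twice the minimum
  keeps every distance nonnegative (all s <= 0 since p <= 1).
* shared-count-based: n_ij = log10(shared risk-SNP count + 1),
  d'_ij = 2 max_{k<l} n_kl - n_ij.  More shared risk SNPs give shorter
  distances.  The +1 offset keeps the transform finite at zero counts.

Distances are embedded in the plane by classical (Torgerson) MDS — double
centering of squared distances and eigendecomposition, the algorithm behind
R's cmdscale with default settings.  A normalized stress is reported as a
diagnostic of how faithful the 2-D picture is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import PvalueMatrix
from .exceptions import ValidationError
from .fdr import local_fdr, select_by_global_fdr
from .model import GPAModel, fit_two_group
from .pleiotropy import PairwisePvalues

__all__ = ["DistanceMatrix", "MDSEmbedding", "pleiotropy_distance",
           "shared_count_distance", "classical_mds", "count_shared_risk",
           "plot_embedding", "plot_heatmap"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative phenotype-by-phenotype distances, zero diagonal."""

    phenotype_labels: tuple[str, ...]
    distances: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        object.__setattr__(self, "distances", d)
        object.__setattr__(self, "phenotype_labels", tuple(self.phenotype_labels))
        k = len(self.phenotype_labels)
        if d.shape != (k, k):
            raise ValidationError(f"distance matrix must be {k} x {k}, got {d.shape}")
        if not np.allclose(d, d.T, atol=1e-10):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(d)) > 1e-10):
            raise ValidationError("distance matrix must have a zero diagonal")
        if np.any(d < -1e-10):
            raise ValidationError("distances must be nonnegative")

    @property
    def n_phenotypes(self) -> int:
        return len(self.phenotype_labels)

    def to_frame(self) -> pd.DataFrame:
        labels = list(self.phenotype_labels)
        return pd.DataFrame(self.distances, index=labels, columns=labels)

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="phenotype")


@dataclass(frozen=True)
class MDSEmbedding:
    """2-D (or ``dims``-D) coordinates from classical MDS.

    ``eigenvalues`` holds the full spectrum of the doubly-centered matrix,
    sorted descending; ``stress_like`` is the normalized residual
    sum_{i<j} (d_ij - dhat_ij)^2 / sum_{i<j} d_ij^2; ``deficient`` flags
    configurations with fewer positive eigenvalues than requested axes
    (the missing coordinates are zero-padded).
    """

    phenotype_labels: tuple[str, ...]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    stress_like: float
    deficient: bool
    negative_eigenmass: float

    def to_frame(self) -> pd.DataFrame:
        dims = self.coordinates.shape[1]
        return pd.DataFrame(
            self.coordinates, index=list(self.phenotype_labels),
            columns=[f"dim{d + 1}" for d in range(dims)],
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="phenotype")

    def pairwise_distances(self) -> np.ndarray:
        diff = self.coordinates[:, None, :] - self.coordinates[None, :, :]
        return np.sqrt((diff ** 2).sum(axis=-1))


def pleiotropy_distance(pairwise: PairwisePvalues) -> DistanceMatrix:
    """d_ij = log10(p_ij) - 2 min_{k<l} log10(p_kl), zero on the diagonal."""
    p = np.asarray(pairwise.pvalues, dtype=float)
    k = pairwise.n_phenotypes
    iu = np.triu_indices(k, 1)
    off = p[iu]
    if np.any(~np.isfinite(off)) or np.any(off <= 0.0):
        raise ValidationError(
            "all off-diagonal p-values must lie in (0, 1]; floor them upstream"
        )
    if np.any(off > 1.0):
        raise ValidationError("p-values above 1 are invalid")
    s = np.log10(off)
    d_off = s - 2.0 * s.min()
    d = np.zeros((k, k))
    d[iu] = d_off
    d = d + d.T
    return DistanceMatrix(phenotype_labels=pairwise.phenotype_labels, distances=d)


def shared_count_distance(counts, phenotype_labels) -> DistanceMatrix:
    """d'_ij = 2 max_{k<l} n_kl - n_ij with n_ij = log10(count_ij + 1)."""
    c = np.asarray(counts, dtype=float)
    k = len(tuple(phenotype_labels))
    if c.shape != (k, k):
        raise ValidationError(f"counts must be {k} x {k}, got {c.shape}")
    if np.any(c < 0):
        raise ValidationError("shared counts must be nonnegative")
    if not np.allclose(c, c.T):
        raise ValidationError("shared-count matrix must be symmetric")
    iu = np.triu_indices(k, 1)
    n = np.log10(c[iu] + 1.0)
    d_off = 2.0 * n.max() - n
    d = np.zeros((k, k))
    d[iu] = d_off
    d = d + d.T
    return DistanceMatrix(phenotype_labels=tuple(phenotype_labels), distances=d)


def classical_mds(dist: DistanceMatrix, dims: int = 2) -> MDSEmbedding:
    """Classical (Torgerson) multidimensional scaling.

    B = -1/2 J (D o D) J with J the centering matrix; coordinates are the
    top ``dims`` eigenvectors scaled by the square roots of their (positive)
    eigenvalues.  Negative eigenvalues — a non-Euclidean distance matrix —
    are excluded from the coordinates and summarized in
    ``negative_eigenmass``.  Eigenvector signs are fixed so the
    largest-magnitude entry of each axis is positive, making the output
    reproducible (MDS is otherwise sign-ambiguous).
    """
    d = dist.distances
    k = d.shape[0]
    j = np.eye(k) - np.ones((k, k)) / k
    b = -0.5 * j @ (d ** 2) @ j
    b = (b + b.T) / 2.0
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    coords = np.zeros((k, dims))
    deficient = False
    for m in range(dims):
        if m < k and w[m] > 1e-12:
            axis = v[:, m] * np.sqrt(w[m])
            sign = np.sign(axis[np.argmax(np.abs(axis))])
            coords[:, m] = axis * (sign if sign != 0 else 1.0)
        else:
            deficient = True
    if deficient:
        logger.warning("fewer than %d positive eigenvalues; "
                       "missing axes zero-padded", dims)
    iu = np.triu_indices(k, 1)
    diff = coords[:, None, :] - coords[None, :, :]
    dhat = np.sqrt((diff ** 2).sum(axis=-1))[iu]
    denom = float((d[iu] ** 2).sum())
    stress = float(((d[iu] - dhat) ** 2).sum() / denom) if denom > 0 else 0.0
    return MDSEmbedding(
        phenotype_labels=dist.phenotype_labels,
        coordinates=coords,
        eigenvalues=w,
        stress_like=stress,
        deficient=deficient,
        negative_eigenmass=float(np.abs(w[w < 0]).sum()),
    )


def count_shared_risk(matrix: PvalueMatrix, tau: float = 0.1,
                      method: str = "joint", **fit_kws) -> np.ndarray:
    """K x K counts of risk SNPs shared between phenotype pairs.

    For each pair the four-state mixture is fitted and SNPs are selected by
    direct-posterior control of the global FDR at ``tau`` on the
    both-phenotype local FDR (``method="joint"``), or as the intersection
    of the two single-phenotype selections (``method="marginal"``).  The
    diagonal holds per-phenotype risk-SNP counts from the marginal
    two-group fit at the same ``tau``.
    """
    if method not in ("joint", "marginal"):
        raise ValueError(f"method must be 'joint' or 'marginal', got {method!r}")
    k = matrix.n_phenotypes
    counts = np.zeros((k, k), dtype=int)
    tg_kws = {kk: vv for kk, vv in fit_kws.items()
              if kk in ("tol", "atol", "max_iter")}
    for idx in range(k):
        marg = fit_two_group(matrix.values[:, idx], **tg_kws)
        sel = select_by_global_fdr(marg.local_fdr(), tau=tau)
        counts[idx, idx] = sel.n_selected
    for i, jdx in combinations(range(k), 2):
        res = GPAModel(matrix.pair(i, jdx)).fit(**fit_kws)
        if method == "joint":
            sel = select_by_global_fdr(local_fdr(res.posteriors, "both"), tau=tau)
            n = sel.n_selected
        else:
            s1 = select_by_global_fdr(local_fdr(res.posteriors, "pheno1"), tau=tau)
            s2 = select_by_global_fdr(local_fdr(res.posteriors, "pheno2"), tau=tau)
            n = int((s1.selected & s2.selected).sum())
        counts[i, jdx] = counts[jdx, i] = n
    return counts


def plot_embedding(emb: MDSEmbedding, path: str | Path) -> Path:
    """Scatter the 2-D map with phenotype labels; format from the suffix."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if len(emb.phenotype_labels) == 0 or any(
            not str(lab) for lab in emb.phenotype_labels):
        raise ValidationError("every phenotype needs a non-empty label")
    fig, ax = plt.subplots(figsize=(6, 6))
    x, y = emb.coordinates[:, 0], emb.coordinates[:, 1]
    ax.scatter(x, y, s=40, color="tab:blue", zorder=3)
    for xi, yi, lab in zip(x, y, emb.phenotype_labels):
        ax.annotate(str(lab), (xi, yi), textcoords="offset points",
                    xytext=(5, 5), fontsize=9)
    ax.set_xlabel("MDS dimension 1")
    ax.set_ylabel("MDS dimension 2")
    ax.set_title(f"Phenotype map (stress = {emb.stress_like:.3f})")
    ax.axhline(0, color="0.85", lw=0.8, zorder=1)
    ax.axvline(0, color="0.85", lw=0.8, zorder=1)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path


def plot_heatmap(counts, phenotype_labels, path: str | Path) -> Path:
    """Heatmap of shared risk-SNP counts on a log10(count + 1) color scale."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [str(lab) for lab in phenotype_labels]
    if len(labels) == 0 or any(not lab for lab in labels):
        raise ValidationError("every phenotype needs a non-empty label")
    c = np.asarray(counts, dtype=float)
    fig, ax = plt.subplots(figsize=(6.5, 5.5))
    im = ax.imshow(np.log10(c + 1.0), cmap="viridis")
    ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=8)
    ax.set_yticks(range(len(labels)), labels, fontsize=8)
    fig.colorbar(im, ax=ax, label="log10(shared risk SNPs + 1)")
    ax.set_title("Shared risk SNPs between phenotypes")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path
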