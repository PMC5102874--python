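"""Local FDR from mixture posteriors and global FDR control.

The local FDR of a SNP for a target hypothesis is its posterior probability
of being *null* for that target given the observed p-value pair:

* ``pheno1`` — null for phenotype 1: post00 + post01
* ``pheno2`` — null for phenotype 2: post00 + post10
* ``both``  — null for at least one phenotype: 1 - post11

Global FDR is controlled by the direct posterior approach: sort the local
FDR values ascending, and raise the threshold kappa while the running mean
of the values at or below it — the estimated FDR of the implied selection —
stays within the bound tau.  All SNPs tied at the final threshold are
selected together; if including a tie group would push the estimate over
tau, the threshold steps back to the previous distinct value.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = ["TARGETS", "LocalFdrVector", "FdrSelection",
           "local_fdr", "select_by_global_fdr"]

TARGETS = ("pheno1", "pheno2", "both")


@dataclass(frozen=True)
class LocalFdrVector:
    """Per-SNP local FDR values for one target hypothesis."""

    values: np.ndarray
    target: str
    snp_ids: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class FdrSelection:
    """Outcome of direct-posterior selection at global FDR bound ``tau``.

    ``selected`` is a boolean mask (SNPs with local FDR <= threshold_kappa);
    ``realized_fdr`` is the mean local FDR of the selected set, 0 (with
    ``empty=True``) when nothing is selected.
    """

    tau: float
    threshold_kappa: float
    selected: np.ndarray
    realized_fdr: float
    snp_ids: np.ndarray | None = None

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    @property
    def empty(self) -> bool:
        return self.n_selected == 0

    @property
    def selected_snp_ids(self) -> np.ndarray | None:
        if self.snp_ids is None:
            return None
        return self.snp_ids[self.selected]

    def to_frame(self, local_fdr_values: np.ndarray | None = None) -> pd.DataFrame:
        data: dict = {}
        if self.snp_ids is not None:
            data["snp"] = self.snp_ids
        if local_fdr_values is not None:
            data["local_fdr"] = np.asarray(local_fdr_values, dtype=float)
        data["selected"] = self.selected.astype(int)
        return pd.DataFrame(data)

    def save(self, path: str | Path,
             local_fdr_values: np.ndarray | None = None) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"# tau={self.tau:g} kappa={self.threshold_kappa:g} "
                     f"realized_fdr={self.realized_fdr:g} "
                     f"n_selected={self.n_selected}\n")
            self.to_frame(local_fdr_values).to_csv(fh, sep="\t", index=False)


def local_fdr(posteriors, target: str = "both",
              snp_ids=None, as_vector: bool = False):
    """Local FDR per SNP from an M x 4 posterior matrix (states 00,10,01,11)."""
    post = np.asarray(posteriors, dtype=float)
    if post.ndim != 2 or post.shape[1] != 4:
        raise ValidationError(f"posteriors must be M x 4, got {post.shape}")
    if target == "pheno1":
        vals = post[:, 0] + post[:, 2]
    elif target == "pheno2":
        vals = post[:, 0] + post[:, 1]
    elif target == "both":
        vals = 1.0 - post[:, 3]
    else:
        raise ValueError(f"target must be one of {TARGETS}, got {target!r}")
    vals = np.clip(vals, 0.0, 1.0)
    if as_vector:
        return LocalFdrVector(values=vals, target=target, snp_ids=snp_ids)
    return vals


def select_by_global_fdr(local_fdr_values, tau: float,
                         snp_ids=None) -> FdrSelection:
    """Direct-posterior selection: largest observed threshold kappa whose
    selection has estimated FDR (mean selected local FDR) <= tau."""
    if isinstance(local_fdr_values, LocalFdrVector):
        if snp_ids is None:
            snp_ids = local_fdr_values.snp_ids
        local_fdr_values = local_fdr_values.values
    f = np.asarray(local_fdr_values, dtype=float)
    if f.ndim != 1 or len(f) == 0:
        raise ValidationError("local FDR vector must be 1-d and non-empty")
    if not 0.0 < tau <= 1.0:
        raise ValueError(f"tau must lie in (0, 1], got {tau}")
    fs = np.sort(f, kind="stable")
    running_mean = np.cumsum(fs) / np.arange(1, len(fs) + 1)
    # candidate thresholds are tie-group ends: indicator 1{f_t <= kappa}
    # cannot split tied values; the 1e-12 slack keeps exact-boundary cases
    # (running mean mathematically equal to tau) from flipping on summation
    # rounding
    group_end = np.r_[fs[1:] != fs[:-1], True]
    ok = np.nonzero(group_end & (running_mean <= tau + 1e-12))[0]
    ids = None if snp_ids is None else np.asarray(snp_ids, dtype=object)
    if ok.size == 0:
        return FdrSelection(tau=tau, threshold_kappa=0.0,
                            selected=np.zeros(f.shape, dtype=bool),
                            realized_fdr=0.0, snp_ids=ids)
    kappa = float(fs[ok[-1]])
    mask = f <= kappa
    return FdrSelection(tau=tau, threshold_kappa=kappa, selected=mask,
                        realized_fdr=float(f[mask].mean()), snp_ids=ids)
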