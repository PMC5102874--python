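"""Likelihood-ratio test of pleiotropy and all-pairs orchestration.

Two phenotypes have independent genetic bases when the both-associated
proportion equals the product of the marginal risk proportions,
``pi11 = pi1* x pi*1``.  The test compares the unconstrained four-state
mixture fit against the independence-constrained fit; the statistic
``-2 log lambda = 2 (llf_alt - llf_null)`` is referred to the upper tail
of a chi-squared distribution with one degree of freedom.

For K phenotypes, :func:`pairwise_tests` runs the test on every pair over
the shared SNP intersection and assembles a symmetric K x K p-value matrix
(the raw material of the MDS distance).  p-values are floored at 1e-300 so
log10 transforms stay finite.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import PvalueMatrix
from .exceptions import ValidationError
from .model import GPAModel, GPAResults

__all__ = ["PVALUE_FLOOR", "PleiotropyTestResult", "PairwisePvalues",
           "test_pleiotropy", "pairwise_tests"]

logger = logging.getLogger(__name__)

PVALUE_FLOOR = 1e-300


@dataclass(frozen=True)
class PleiotropyTestResult:
    """LRT of the independence null for one phenotype pair."""

    fit_alt: GPAResults
    fit_null: GPAResults
    statistic: float
    pvalue: float

    @property
    def converged(self) -> bool:
        return self.fit_alt.converged and self.fit_null.converged

    def summary(self) -> str:
        lab1, lab2 = self.fit_alt.model.phenotype_labels
        return (
            f"Pleiotropy LRT: {lab1} vs {lab2}\n"
            f"  -2 log lambda = {self.statistic:.4f}  "
            f"(chi2 df=1 p = {self.pvalue:.3g})\n"
            f"  llf alt  = {self.fit_alt.llf:.4f}  "
            f"llf null = {self.fit_null.llf:.4f}\n"
            f"  pi11 = {self.fit_alt.params.pi11:.4f}  "
            f"pi1*xpi*1 = "
            f"{self.fit_alt.params.marg1 * self.fit_alt.params.marg2:.4f}\n"
            f"  converged: {self.converged}"
        )


def test_pleiotropy(pvalues, phenotype_labels=None, **fit_kws) -> PleiotropyTestResult:
    """Test pleiotropy between two phenotypes from their paired p-values.

    Accepts anything :class:`~gpamds.model.GPAModel` accepts.  Keyword
    arguments are forwarded to both fits.  A non-converged fit flags the
    result but still yields a p-value.
    """
    model = GPAModel(pvalues, phenotype_labels=phenotype_labels)
    fit_alt = model.fit(**fit_kws)
    fit_null = model.fit(constrained=True,
                         **{k: v for k, v in fit_kws.items()
                            if k in ("tol", "atol", "max_iter")})
    if fit_alt.llf < fit_null.llf:
        # convergence slack left the nested ordering violated: continue the
        # unconstrained EM from the null solution (monotone, so the refit
        # cannot fall below the null likelihood)
        refit_kws = dict(fit_kws)
        refit_kws["init_params"] = fit_null.params
        refit_kws.pop("n_starts", None)
        refit = model.fit(**refit_kws)
        if refit.llf > fit_alt.llf:
            fit_alt = refit
    stat = 2.0 * (fit_alt.llf - fit_null.llf)
    if stat < -1e-6:
        warnings.warn(
            f"LRT statistic {stat:.3g} < 0 beyond numerical tolerance; "
            "unconstrained EM may be at an inferior local optimum",
            stacklevel=2,
        )
    stat = max(stat, 0.0)
    pvalue = max(float(stats.chi2.sf(stat, df=1)), PVALUE_FLOOR)
    return PleiotropyTestResult(fit_alt=fit_alt, fit_null=fit_null,
                                statistic=stat, pvalue=pvalue)


@dataclass(frozen=True)
class PairwisePvalues:
    """Symmetric K x K pleiotropy-test p-values (diagonal undefined/NaN)."""

    phenotype_labels: tuple[str, ...]
    pvalues: np.ndarray
    statistics: np.ndarray
    results: dict[tuple[int, int], PleiotropyTestResult]

    @property
    def n_phenotypes(self) -> int:
        return len(self.phenotype_labels)

    def to_frame(self) -> pd.DataFrame:
        labels = list(self.phenotype_labels)
        return pd.DataFrame(self.pvalues, index=labels, columns=labels)

    def pairs_frame(self) -> pd.DataFrame:
        rows = [
            {"pheno_i": self.phenotype_labels[i],
             "pheno_j": self.phenotype_labels[j],
             "statistic": r.statistic, "pvalue": r.pvalue,
             "converged": r.converged}
            for (i, j), r in sorted(self.results.items())
        ]
        return pd.DataFrame(rows)

    def save(self, pairs_path: str | Path, matrix_path: str | Path | None = None):
        self.pairs_frame().to_csv(pairs_path, sep="\t", index=False)
        if matrix_path is not None:
            self.to_frame().to_csv(matrix_path, sep="\t",
                                   index_label="phenotype")


def pairwise_tests(matrix: PvalueMatrix, **fit_kws) -> PairwisePvalues:
    """Run the pleiotropy LRT for every pair of phenotypes in ``matrix``.

    Each pair is tested on the (global) SNP intersection the matrix already
    encodes.  A failed or non-converged pair is logged and does not abort
    the remaining pairs.
    """
    k = matrix.n_phenotypes
    if k < 2:
        raise ValidationError("need at least 2 phenotypes for pairwise tests")
    pmat = np.full((k, k), np.nan)
    smat = np.full((k, k), np.nan)
    results: dict[tuple[int, int], PleiotropyTestResult] = {}
    for i, j in combinations(range(k), 2):
        res = test_pleiotropy(matrix.pair(i, j), **fit_kws)
        if not res.converged:
            logger.warning("pair (%s, %s): EM not converged",
                           matrix.phenotype_labels[i], matrix.phenotype_labels[j])
        logger.info("pair (%s, %s): stat=%.3f p=%.3g iters=(%d, %d)",
                    matrix.phenotype_labels[i], matrix.phenotype_labels[j],
                    res.statistic, res.pvalue,
                    res.fit_alt.n_iter, res.fit_null.n_iter)
        pmat[i, j] = pmat[j, i] = res.pvalue
        smat[i, j] = smat[j, i] = res.statistic
        results[(i, j)] = res
    return PairwisePvalues(phenotype_labels=matrix.phenotype_labels,
                           pvalues=pmat, statistics=smat, results=results)
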