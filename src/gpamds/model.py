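"""Four-state Beta/Uniform mixture model for a pair of GWAS p-value vectors.

The model
---------
Each SNP t carries a latent association state over two phenotypes:

* ``00`` — null for both: P_t1, P_t2 ~ Uniform(0, 1)
* ``10`` — associated with phenotype 1 only: P_t1 ~ Beta(alpha1, 1)
* ``01`` — associated with phenotype 2 only: P_t2 ~ Beta(alpha2, 1)
* ``11`` — associated with both: P_t1 ~ Beta(alpha1, 1), P_t2 ~ Beta(alpha2, 1)

with mixing proportions (pi00, pi10, pi01, pi11) and, conditional on the
state, independent coordinates.  The Beta(alpha, 1) density is
``f(p) = alpha * p**(alpha - 1)``; the constraint ``0 < alpha < 1`` makes it
monotone decreasing, i.e. small p-values are over-represented in the
non-null groups.

The model is fitted by EM.  Both the E-step (state responsibilities) and
the M-step are available in closed form: mixing proportions update to
responsibility means, and each Beta shape updates to the weighted
Beta(alpha, 1) maximum-likelihood estimate

    alpha_hat = - sum_t w_t / sum_t w_t * log P_t,

where w_t is the responsibility of the states in which the phenotype is
associated.  The independence-constrained fit (the null of the pleiotropy
test, ``pi11 = pi1* x pi*1``) exploits the fact that under the constraint
the joint mixture density factorizes into two marginal Uniform+Beta
two-group models, so fitting each margin separately by EM *is* the
constrained maximum-likelihood fit.

Usage follows the statsmodels convention::

    model = GPAModel(pvalues)          # M x 2 array / DataFrame / PvalueMatrix
    res = model.fit()                  # GPAResults
    res0 = model.fit(constrained=True) # independence-constrained fit
    print(res.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .data_io import PvalueMatrix
from .exceptions import ConvergenceWarning, DegenerateDataError, ValidationError

__all__ = [
    "P_EPS",
    "ALPHA_EPS",
    "STATE_LABELS",
    "beta_density",
    "GPAParams",
    "GPAModel",
    "GPAResults",
    "TwoGroupFit",
    "fit_two_group",
]

#: p-values are clipped into [P_EPS, 1 - P_EPS] before any log/density call;
#: the Beta(alpha, 1) density with alpha < 1 diverges at 0.
P_EPS = 1e-12
#: Beta shapes are kept strictly inside (0, 1) at every M-step.
ALPHA_EPS = 1e-6
STATE_LABELS = ("00", "10", "01", "11")


def beta_density(p, alpha: float):
    """Beta(alpha, 1) density ``alpha * p**(alpha - 1)``, vectorized over p.

    Raises ``ValueError`` for a shape outside (0, 1); p is clipped away
    from 0 so the value is always finite.
    """
    alpha = float(alpha)
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"Beta shape must lie strictly in (0, 1); got {alpha}")
    p = np.clip(np.asarray(p, dtype=float), P_EPS, 1.0)
    return alpha * p ** (alpha - 1.0)


def _beta_log_density(logp: np.ndarray, alpha: float) -> np.ndarray:
    return np.log(alpha) + (alpha - 1.0) * logp


@dataclass(frozen=True)
class GPAParams:
    """Parameters of the four-state mixture.

    ``pi00 + pi10 + pi01 + pi11 = 1`` and ``0 < alpha_k < 1``.  The derived
    marginals ``marg1 = pi10 + pi11`` (pi1*) and ``marg2 = pi01 + pi11``
    (pi*1) are the per-phenotype risk proportions; ``shared_fraction1`` is
    the fraction of phenotype-1 risk SNPs also associated with phenotype 2.
    """

    pi00: float
    pi10: float
    pi01: float
    pi11: float
    alpha1: float
    alpha2: float

    def __post_init__(self) -> None:
        pis = self.pis
        if np.any(pis < -1e-12) or np.any(pis > 1 + 1e-12):
            raise ValueError(f"mixture proportions outside [0, 1]: {pis}")
        if abs(pis.sum() - 1.0) > 1e-8:
            raise ValueError(f"mixture proportions sum to {pis.sum()!r}, not 1")
        for a in (self.alpha1, self.alpha2):
            if not 0.0 < a < 1.0:
                raise ValueError(f"Beta shape must lie in (0, 1); got {a}")

    @property
    def pis(self) -> np.ndarray:
        return np.array([self.pi00, self.pi10, self.pi01, self.pi11], dtype=float)

    @property
    def marg1(self) -> float:
        """pi1* — proportion of SNPs associated with phenotype 1."""
        return self.pi10 + self.pi11

    @property
    def marg2(self) -> float:
        """pi*1 — proportion of SNPs associated with phenotype 2."""
        return self.pi01 + self.pi11

    @property
    def shared_fraction1(self) -> float:
        """pi11 / pi1* — share of phenotype-1 risk SNPs that are pleiotropic."""
        return self.pi11 / self.marg1 if self.marg1 > 0 else np.nan

    @property
    def independence_gap(self) -> float:
        """pi11 - pi1* x pi*1; zero exactly under the independence null."""
        return self.pi11 - self.marg1 * self.marg2

    def swapped(self) -> "GPAParams":
        """Parameters with the two phenotypes exchanged."""
        return GPAParams(self.pi00, self.pi01, self.pi10, self.pi11,
                         self.alpha2, self.alpha1)

    def as_dict(self) -> dict[str, float]:
        return {
            "pi00": self.pi00, "pi10": self.pi10,
            "pi01": self.pi01, "pi11": self.pi11,
            "alpha1": self.alpha1, "alpha2": self.alpha2,
        }

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "GPAParams":
        return cls(**{k: float(d[k]) for k in
                      ("pi00", "pi10", "pi01", "pi11", "alpha1", "alpha2")})


#: Default EM starting point: mild signal prior, symmetric Beta shapes.
DEFAULT_INIT = GPAParams(0.70, 0.10, 0.10, 0.10, 0.5, 0.5)


def _converged(ll: float, old: float, tol: float, atol: float) -> bool:
    delta = abs(ll - old)
    return delta < atol or delta <= tol * abs(old)


# ---------------------------------------------------------------------------
# marginal two-group model (one phenotype): Uniform null + Beta(alpha,1)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoGroupFit:
    """EM fit of the marginal Uniform + Beta(alpha, 1) two-group model."""

    q: float                 # non-null proportion
    alpha: float             # Beta shape of the non-null group
    posterior: np.ndarray    # per-SNP posterior probability of being non-null
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool

    @property
    def llf(self) -> float:
        return float(self.loglik_trace[-1])

    def local_fdr(self) -> np.ndarray:
        """Posterior null probability per SNP (1 - non-null posterior)."""
        return 1.0 - self.posterior


def fit_two_group(pvalues, q0: float = 0.2, alpha0: float = 0.5,
                  tol: float = 1e-6, atol: float = 1e-8,
                  max_iter: int = 2000) -> TwoGroupFit:
    """Fit the marginal two-group model to one p-value vector by EM.

    Closed-form updates: ``q`` becomes the mean non-null responsibility and
    ``alpha`` the responsibility-weighted Beta(alpha, 1) MLE.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValidationError("two-group model expects a 1-d p-value vector")
    logp = np.log(np.clip(p, P_EPS, 1.0 - P_EPS))
    q, alpha = float(q0), float(alpha0)
    q = min(max(q, 1e-10), 1 - 1e-10)
    trace: list[float] = []
    old = np.inf
    converged = False
    z = np.full(p.shape, q)
    for _ in range(max_iter):
        lnum = np.log(q) + _beta_log_density(logp, alpha)
        lden = np.logaddexp(np.log1p(-q), lnum)
        ll = float(lden.sum())
        trace.append(ll)
        if np.isfinite(old) and _converged(ll, old, tol, atol):
            converged = True
            break
        old = ll
        z = np.exp(lnum - lden)
        zsum = float(z.sum())
        denom = float(z @ logp)
        if denom == 0.0:
            raise DegenerateDataError(
                "sum of responsibility-weighted log p-values is zero; "
                "Beta shape update undefined"
            )
        q = min(max(zsum / len(p), 1e-10), 1 - 1e-10)
        alpha = float(np.clip(-zsum / denom, ALPHA_EPS, 1.0 - ALPHA_EPS))
    else:
        # loop exhausted: refresh posterior/loglik at the final parameters
        lnum = np.log(q) + _beta_log_density(logp, alpha)
        lden = np.logaddexp(np.log1p(-q), lnum)
        z = np.exp(lnum - lden)
        trace.append(float(lden.sum()))
    return TwoGroupFit(q=q, alpha=alpha, posterior=z,
                       loglik_trace=np.asarray(trace),
                       n_iter=len(trace) - 1, converged=converged)


# ---------------------------------------------------------------------------
# joint four-state model
# ---------------------------------------------------------------------------

class GPAModel:
    """Four-state Beta/Uniform mixture for a pair of phenotypes.

    Parameters
    ----------
    pvalues
        M x 2 array-like of p-values in [0, 1]: an ndarray, a DataFrame
        (column names become phenotype labels) or a two-column
        :class:`~gpamds.data_io.PvalueMatrix`.
    snp_ids, phenotype_labels
        Optional identifiers carried through to results and output tables.
    """

    def __init__(self, pvalues, snp_ids=None,
                 phenotype_labels: Sequence[str] | None = None) -> None:
        if isinstance(pvalues, PvalueMatrix):
            if pvalues.n_phenotypes != 2:
                raise ValidationError(
                    "GPAModel needs exactly 2 phenotypes; "
                    f"got {pvalues.n_phenotypes} (use .pair(i, j))"
                )
            snp_ids = pvalues.snp_ids if snp_ids is None else snp_ids
            phenotype_labels = phenotype_labels or pvalues.phenotype_labels
            pvalues = pvalues.values
        elif isinstance(pvalues, pd.DataFrame):
            phenotype_labels = phenotype_labels or [str(c) for c in pvalues.columns]
            snp_ids = pvalues.index.to_numpy() if snp_ids is None else snp_ids
            pvalues = pvalues.to_numpy(dtype=float)
        arr = np.asarray(pvalues, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValidationError(f"expected an M x 2 p-value array, got {arr.shape}")
        if not np.all(np.isfinite(arr)) or arr.min() < 0 or arr.max() > 1:
            raise ValidationError("p-values must be finite and in [0, 1]")
        self.pvalues = arr
        self.snp_ids = None if snp_ids is None else np.asarray(snp_ids, dtype=object)
        self.phenotype_labels = tuple(phenotype_labels) if phenotype_labels \
            else ("pheno1", "pheno2")
        self._logp = np.log(np.clip(arr, P_EPS, 1.0 - P_EPS))

    @classmethod
    def from_matrix(cls, matrix: PvalueMatrix,
                    cols: tuple[int | str, int | str] = (0, 1)) -> "GPAModel":
        """Build the model from two columns of a wider p-value matrix."""
        return cls(matrix.pair(*cols))

    @property
    def nobs(self) -> int:
        return self.pvalues.shape[0]

    # -- EM building blocks -------------------------------------------------

    def _log_joint(self, params: GPAParams) -> np.ndarray:
        """M x 4 array of log(pi_l) + log f_l(P_t1, P_t2)."""
        lp1, lp2 = self._logp[:, 0], self._logp[:, 1]
        lf1 = _beta_log_density(lp1, params.alpha1)
        lf2 = _beta_log_density(lp2, params.alpha2)
        with np.errstate(divide="ignore"):
            lpi = np.log(params.pis)
        out = np.empty((self.nobs, 4))
        out[:, 0] = lpi[0]
        out[:, 1] = lpi[1] + lf1
        out[:, 2] = lpi[2] + lf2
        out[:, 3] = lpi[3] + lf1 + lf2
        return out

    def _estep(self, params: GPAParams) -> tuple[np.ndarray, float]:
        lj = self._log_joint(params)
        norm = logsumexp(lj, axis=1)
        return np.exp(lj - norm[:, None]), float(norm.sum())

    def e_step(self, params: GPAParams) -> np.ndarray:
        """Posterior state responsibilities (M x 4, rows sum to 1)."""
        return self._estep(params)[0]

    def m_step(self, posteriors: np.ndarray) -> GPAParams:
        """Closed-form maximizer of the expected complete-data log-likelihood."""
        post = np.asarray(posteriors, dtype=float)
        if post.shape != (self.nobs, 4):
            raise ValidationError(f"posteriors must be {self.nobs} x 4")
        pis = post.mean(axis=0)
        alphas = []
        for j, w in ((0, post[:, 1] + post[:, 3]), (1, post[:, 2] + post[:, 3])):
            denom = float(w @ self._logp[:, j])
            if denom == 0.0:
                raise DegenerateDataError(
                    f"Beta shape update for phenotype {j + 1} undefined "
                    "(weighted log p-values sum to zero)"
                )
            alphas.append(float(np.clip(-w.sum() / denom, ALPHA_EPS, 1.0 - ALPHA_EPS)))
        return GPAParams(*pis, *alphas)

    def loglike(self, params: GPAParams) -> float:
        """Observed-data log-likelihood sum_t log sum_l pi_l f_l(P_t1, P_t2)."""
        return self._estep(params)[1]

    # -- fitting -------------------------------------------------------------

    def fit(self, constrained: bool = False,
            init_params: GPAParams | None = None,
            tol: float = 1e-6, atol: float = 1e-8, max_iter: int = 2000,
            n_starts: int = 1, seed: int | None = None) -> "GPAResults":
        """Fit by EM and return a :class:`GPAResults`.

        Parameters
        ----------
        constrained
            If True, impose the independence null ``pi11 = pi1* x pi*1``
            by fitting the two factorized marginal two-group models.
        init_params
            Starting parameters (default: pi = (0.7, 0.1, 0.1, 0.1),
            alpha1 = alpha2 = 0.5).
        tol, atol
            Convergence when the log-likelihood change is below ``atol``
            absolutely or ``tol`` relatively.
        n_starts, seed
            Optional multi-start: additional runs from random starting
            points (Dirichlet proportions, uniform shapes); the best
            log-likelihood wins.  Non-convergence warns, never raises.
        """
        if self.nobs < 10:
            raise ValidationError(f"need at least 10 SNPs to fit; got {self.nobs}")
        if constrained:
            return self._fit_constrained(tol, atol, max_iter)
        rng = np.random.default_rng(seed)
        best: tuple | None = None
        for s in range(max(1, int(n_starts))):
            if s == 0:
                init = init_params if init_params is not None else DEFAULT_INIT
            else:
                pis = rng.dirichlet(np.ones(4))
                init = GPAParams(*pis, rng.uniform(0.1, 0.9), rng.uniform(0.1, 0.9))
            run = self._run_em(init, tol, atol, max_iter)
            if best is None or run[2][-1] > best[2][-1]:
                best = run
        assert best is not None
        params, post, trace, converged = best
        if not converged:
            warnings.warn(
                f"EM did not converge in {max_iter} iterations "
                f"(last log-likelihood change {trace[-1] - trace[-2]:.3g})",
                ConvergenceWarning, stacklevel=2,
            )
        return GPAResults(self, params, post, np.asarray(trace),
                          converged=converged, constrained=False)

    def _run_em(self, init: GPAParams, tol: float, atol: float,
                max_iter: int) -> tuple[GPAParams, np.ndarray, list[float], bool]:
        params = init
        trace: list[float] = []
        old = np.inf
        for _ in range(max_iter):
            post, ll = self._estep(params)
            trace.append(ll)
            if np.isfinite(old) and _converged(ll, old, tol, atol):
                return params, post, trace, True
            old = ll
            params = self.m_step(post)
        post, ll = self._estep(params)
        trace.append(ll)
        return params, post, trace, False

    def _fit_constrained(self, tol: float, atol: float,
                         max_iter: int) -> "GPAResults":
        margs = [
            fit_two_group(self.pvalues[:, j], q0=DEFAULT_INIT.marg1,
                          alpha0=DEFAULT_INIT.alpha1, tol=tol, atol=atol,
                          max_iter=max_iter)
            for j in (0, 1)
        ]
        q1, q2 = margs[0].q, margs[1].q
        params = GPAParams(
            pi00=(1 - q1) * (1 - q2), pi10=q1 * (1 - q2),
            pi01=(1 - q1) * q2, pi11=q1 * q2,
            alpha1=margs[0].alpha, alpha2=margs[1].alpha,
        )
        post, ll = self._estep(params)
        # joint log-likelihood at each (padded) iteration is the sum of the
        # marginal traces, since the constrained density factorizes
        t1, t2 = margs[0].loglik_trace, margs[1].loglik_trace
        n = max(len(t1), len(t2))
        pad = lambda t: np.concatenate([t, np.full(n - len(t), t[-1])])
        trace = pad(t1) + pad(t2)
        assert abs(trace[-1] - ll) < 1e-6 * max(1.0, abs(ll))
        trace[-1] = ll
        converged = margs[0].converged and margs[1].converged
        if not converged:
            warnings.warn(
                f"constrained EM did not converge in {max_iter} iterations",
                ConvergenceWarning, stacklevel=3,
            )
        return GPAResults(self, params, post, trace,
                          converged=converged, constrained=True,
                          marginal_fits=tuple(margs))


class GPAResults:
    """EM fit of the four-state mixture: estimates, posteriors, diagnostics.

    Attributes
    ----------
    params : GPAParams
    posteriors : ndarray, M x 4 in state order ("00", "10", "01", "11")
    llf : float — final observed-data log-likelihood
    loglik_trace : ndarray — per-iteration log-likelihood (non-decreasing)
    converged, constrained : bool
    """

    def __init__(self, model: GPAModel, params: GPAParams,
                 posteriors: np.ndarray, loglik_trace: np.ndarray,
                 converged: bool, constrained: bool,
                 marginal_fits: tuple[TwoGroupFit, TwoGroupFit] | None = None):
        self.model = model
        self.params = params
        self.posteriors = posteriors
        self.loglik_trace = np.asarray(loglik_trace, dtype=float)
        self.converged = bool(converged)
        self.constrained = bool(constrained)
        self.marginal_fits = marginal_fits

    @property
    def llf(self) -> float:
        return float(self.loglik_trace[-1])

    @property
    def n_iter(self) -> int:
        return len(self.loglik_trace)

    @property
    def df_model(self) -> int:
        """Free parameters: 3 proportions + 2 shapes, minus 1 under the null."""
        return 4 if self.constrained else 5

    # -- FDR conveniences (delegate to gpamds.fdr) ---------------------------

    def local_fdr(self, target: str = "both") -> np.ndarray:
        from .fdr import local_fdr
        return local_fdr(self.posteriors, target=target)

    def select_snps(self, tau: float = 0.1, target: str = "both"):
        """Direct-posterior global-FDR selection at bound ``tau``."""
        from .fdr import select_by_global_fdr
        return select_by_global_fdr(self.local_fdr(target), tau=tau,
                                    snp_ids=self.model.snp_ids)

    # -- reporting -----------------------------------------------------------

    def posteriors_frame(self) -> pd.DataFrame:
        idx = None if self.model.snp_ids is None else pd.Index(
            self.model.snp_ids, name="snp")
        return pd.DataFrame(self.posteriors, index=idx,
                            columns=[f"post{s}" for s in STATE_LABELS])

    def save_params(self, path: str | Path) -> None:
        """Flat key-value text serialization of the fit."""
        lines = [f"{k}\t{v:.10g}" for k, v in self.params.as_dict().items()]
        lines += [
            f"loglik\t{self.llf:.10g}",
            f"n_iter\t{self.n_iter}",
            f"converged\t{int(self.converged)}",
            f"constrained\t{int(self.constrained)}",
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    def save_posteriors(self, path: str | Path) -> None:
        self.posteriors_frame().to_csv(path, sep="\t",
                                       index=self.model.snp_ids is not None)

    def summary(self) -> str:
        p = self.params
        lab1, lab2 = self.model.phenotype_labels
        kind = "constrained (independence null)" if self.constrained \
            else "unconstrained"
        w = 66
        lines = [
            "Four-state Beta/Uniform mixture (GPA) — EM fit".center(w),
            "=" * w,
            f"No. SNPs:        {self.model.nobs:>10d}    model: {kind}",
            f"Log-likelihood:  {self.llf:>14.4f}    iterations: {self.n_iter}"
            f"    converged: {self.converged}",
            "-" * w,
            f"{'state':<10}{'proportion':>12}",
            f"{'pi00':<10}{p.pi00:>12.4f}",
            f"{'pi10':<10}{p.pi10:>12.4f}",
            f"{'pi01':<10}{p.pi01:>12.4f}",
            f"{'pi11':<10}{p.pi11:>12.4f}",
            "-" * w,
            f"alpha1 ({lab1}): {p.alpha1:.4f}    alpha2 ({lab2}): {p.alpha2:.4f}",
            f"pi1* = {p.marg1:.4f}    pi*1 = {p.marg2:.4f}    "
            f"pi11 - pi1*xpi*1 = {p.independence_gap:+.4f}",
            f"shared fraction pi11/pi1* = {p.shared_fraction1:.4f}",
            "=" * w,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<GPAResults llf={self.llf:.2f} n_iter={self.n_iter} "
                f"converged={self.converged} constrained={self.constrained}>")
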