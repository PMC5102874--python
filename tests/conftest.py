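"""Shared fixtures: simulated studies and fitted models reused across tests.

The heavyweight Monte-Carlo batteries (replicated benchmark fits, null
LRT calibration, replicated MDS pipelines) are session-scoped so each is
computed once and shared between property and acceptance tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pytest

from gpamds import (GPAModel, GPAParams, GPAResults, PairwisePvalues,
                    classical_mds, five_phenotype_design,
                    independent_pair_design, pairwise_tests, pleiotropy_distance,
                    simulate_study, test_pleiotropy)
from gpamds.simulate import SimulatedStudy

BENCHMARK_SEED = 11


@pytest.fixture(scope="session")
def benchmark_study() -> SimulatedStudy:
    """One five-phenotype benchmark study (10,000 SNPs, 75% sharing)."""
    return simulate_study(five_phenotype_design(seed=BENCHMARK_SEED))


@pytest.fixture(scope="session")
def small_study() -> SimulatedStudy:
    """Scaled-down benchmark (2,000 SNPs) for cheap structural tests."""
    return simulate_study(five_phenotype_design(n_snps=2000, seed=BENCHMARK_SEED))


@pytest.fixture(scope="session")
def pair12_fits(benchmark_study) -> tuple[GPAResults, GPAResults]:
    """(unconstrained, constrained) fits to benchmark phenotypes 1 and 2."""
    model = GPAModel.from_matrix(benchmark_study.matrix, cols=(0, 1))
    return model.fit(), model.fit(constrained=True)


@dataclass
class ReplicateFit:
    seed: int
    params: GPAParams
    null_params: GPAParams
    llf_alt: float
    llf_null: float
    trace_alt: np.ndarray
    trace_null: np.ndarray
    fdp: float
    n_selected: int


@pytest.fixture(scope="session")
def replicate_fits() -> list[ReplicateFit]:
    """20 replicates of the benchmark study, phenotypes 1-2: unconstrained
    and constrained fits plus the false discovery proportion of the
    direct-posterior both-phenotype selection at tau = 0.1."""
    out = []
    for seed in range(20):
        study = simulate_study(five_phenotype_design(seed=seed))
        model = GPAModel.from_matrix(study.matrix, cols=(0, 1))
        res = model.fit()
        res0 = model.fit(constrained=True)
        sel = res.select_snps(tau=0.1, target="both")
        truly_both = (study.truth[:, 0] == 1) & (study.truth[:, 1] == 1)
        false = int((sel.selected & ~truly_both).sum())
        fdp = false / sel.n_selected if sel.n_selected else 0.0
        out.append(ReplicateFit(
            seed=seed, params=res.params, null_params=res0.params,
            llf_alt=res.llf, llf_null=res0.llf,
            trace_alt=res.loglik_trace, trace_null=res0.loglik_trace,
            fdp=fdp, n_selected=sel.n_selected,
        ))
    return out


@pytest.fixture(scope="session")
def null_lrt_battery() -> tuple[np.ndarray, np.ndarray]:
    """500 pleiotropy LRTs on independently generated phenotype pairs
    (2,000 SNPs each): (statistics, p-values) under the independence null."""
    stats, pvals = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(500):
            study = simulate_study(independent_pair_design(seed=10_000 + i))
            res = test_pleiotropy(study.matrix)
            stats.append(res.statistic)
            pvals.append(res.pvalue)
    return np.asarray(stats), np.asarray(pvals)


@dataclass
class MdsReplicate:
    seed: int
    pairwise: PairwisePvalues
    embedded_dist: np.ndarray  # 5 x 5 Euclidean distances of the 2-D map


@pytest.fixture(scope="session")
def mds_replicates() -> list[MdsReplicate]:
    """20 end-to-end runs of the five-phenotype pipeline:
    simulate -> all-pairs LRT -> distance -> classical MDS."""
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(20):
            study = simulate_study(five_phenotype_design(seed=200 + i))
            pw = pairwise_tests(study.matrix)
            emb = classical_mds(pleiotropy_distance(pw))
            out.append(MdsReplicate(seed=200 + i, pairwise=pw,
                                    embedded_dist=emb.pairwise_distances()))
    return out
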