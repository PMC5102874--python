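"""Synthetic multi-phenotype GWAS p-value studies with known pleiotropy.

A study is described by a :class:`SimulationDesign`: the number of SNPs,
per-phenotype risk fractions and Beta shapes, and a list of pairwise
sharing fractions.  Risk sets are laid out as deterministic contiguous
index blocks — shared blocks first, then private risk blocks, then nulls —
so realized risk counts and pairwise overlaps match the design *exactly*,
not merely in expectation; the mixture model is exchangeable over SNP
index, so the layout does not affect any statistic.  Randomness enters
only through the p-value draws: Uniform(0, 1) for null entries and
Beta(shape, 1) for risk entries.

An alternative ``layout="random"`` places each phenotype's risk set
independently and uniformly at random (no sharing list allowed).  That is
the configuration in which the genetic bases of the phenotypes are truly
independent — pairwise overlap is hypergeometric around risk^2 x M — and
is the appropriate null for calibrating the pleiotropy test, where the
block layout's structurally disjoint sets would instead encode negative
dependence.

:func:`five_phenotype_design` builds the benchmark five-study design:
10,000 SNPs, 20% risk SNPs per phenotype, 75% of risk shared within the
pairs (1,2) and (3,4), nothing shared across groups, and phenotype 5
fully isolated as a negative control; risk p-values follow Beta(0.4, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .data_io import PvalueMatrix, PvalueTable, write_pvalue_table
from .exceptions import DesignError

__all__ = ["PhenotypeSpec", "SharingSpec", "SimulationDesign",
           "SimulatedStudy", "five_phenotype_design", "independent_pair_design",
           "build_risk_sets", "simulate_pvalues", "simulate_study"]


@dataclass(frozen=True)
class PhenotypeSpec:
    label: str
    risk_fraction: float = 0.2
    beta_shape: float = 0.4

    def __post_init__(self) -> None:
        if not 0.0 <= self.risk_fraction <= 1.0:
            raise DesignError(f"risk_fraction must be in [0, 1]; "
                              f"got {self.risk_fraction} for {self.label!r}")
        if not 0.0 < self.beta_shape < 1.0:
            raise DesignError(f"beta_shape must be in (0, 1); "
                              f"got {self.beta_shape} for {self.label!r}")


@dataclass(frozen=True)
class SharingSpec:
    """Fraction of the smaller risk set shared between two phenotypes."""

    pair: tuple[str, str]
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise DesignError(f"sharing fraction must be in [0, 1]; "
                              f"got {self.fraction} for pair {self.pair}")
        if self.pair[0] == self.pair[1]:
            raise DesignError(f"sharing pair must name two distinct "
                              f"phenotypes; got {self.pair}")


@dataclass(frozen=True)
class SimulationDesign:
    n_snps: int
    phenotypes: tuple[PhenotypeSpec, ...]
    sharing: tuple[SharingSpec, ...] = ()
    seed: int | None = None
    layout: str = "blocks"

    def __post_init__(self) -> None:
        object.__setattr__(self, "phenotypes", tuple(self.phenotypes))
        object.__setattr__(self, "sharing", tuple(self.sharing))
        if self.n_snps < 1:
            raise DesignError("n_snps must be positive")
        labels = [p.label for p in self.phenotypes]
        if len(set(labels)) != len(labels):
            raise DesignError("phenotype labels must be unique")
        if self.layout not in ("blocks", "random"):
            raise DesignError(f"layout must be 'blocks' or 'random'; "
                              f"got {self.layout!r}")
        if self.layout == "random" and self.sharing:
            raise DesignError("random layout places risk sets independently; "
                              "a sharing list cannot be honored")
        for sh in self.sharing:
            for lab in sh.pair:
                if lab not in labels:
                    raise DesignError(f"sharing refers to unknown phenotype "
                                      f"{lab!r}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(p.label for p in self.phenotypes)

    def risk_count(self, label: str) -> int:
        spec = self.phenotypes[self.labels.index(label)]
        return int(round(spec.risk_fraction * self.n_snps))

    # -- config round-trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_snps": self.n_snps,
            "seed": self.seed,
            "layout": self.layout,
            "phenotypes": [
                {"label": p.label, "risk_fraction": p.risk_fraction,
                 "beta_shape": p.beta_shape} for p in self.phenotypes
            ],
            "sharing": [
                {"pair": list(s.pair), "fraction": s.fraction}
                for s in self.sharing
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationDesign":
        return cls(
            n_snps=int(d["n_snps"]),
            phenotypes=tuple(PhenotypeSpec(**p) for p in d["phenotypes"]),
            sharing=tuple(
                SharingSpec(pair=tuple(s["pair"]), fraction=float(s["fraction"]))
                for s in d.get("sharing", []) or []
            ),
            seed=d.get("seed"),
            layout=d.get("layout", "blocks"),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationDesign":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def five_phenotype_design(n_snps: int = 10_000, risk_fraction: float = 0.2,
                          shared_fraction: float = 0.75,
                          beta_shape: float = 0.4,
                          seed: int | None = None) -> SimulationDesign:
    """The benchmark five-phenotype design (defaults are the study conditions).

    Pairs (1,2) and (3,4) each share ``shared_fraction`` of their risk SNPs
    in disjoint index ranges; phenotype 5 shares nothing with anyone.
    """
    phenos = tuple(
        PhenotypeSpec(label=f"pheno{i}", risk_fraction=risk_fraction,
                      beta_shape=beta_shape)
        for i in range(1, 6)
    )
    sharing = (
        SharingSpec(pair=("pheno1", "pheno2"), fraction=shared_fraction),
        SharingSpec(pair=("pheno3", "pheno4"), fraction=shared_fraction),
    )
    return SimulationDesign(n_snps=n_snps, phenotypes=phenos,
                            sharing=sharing, seed=seed)


def independent_pair_design(n_snps: int = 2_000, risk_fraction: float = 0.2,
                            beta_shape: float = 0.4,
                            seed: int | None = None) -> SimulationDesign:
    """Two phenotypes with independently placed risk sets (the LRT null)."""
    phenos = (
        PhenotypeSpec("pheno1", risk_fraction, beta_shape),
        PhenotypeSpec("pheno2", risk_fraction, beta_shape),
    )
    return SimulationDesign(n_snps=n_snps, phenotypes=phenos, sharing=(),
                            seed=seed, layout="random")


@dataclass(frozen=True)
class SimulatedStudy:
    """Simulated p-value matrix plus the ground-truth risk indicators."""

    matrix: PvalueMatrix
    truth: np.ndarray = field(repr=False)  # M x K in {0, 1}
    design: SimulationDesign

    def truth_overlap(self, i: int, j: int) -> int:
        return int((self.truth[:, i] & self.truth[:, j]).sum())

    def write(self, outdir: str | Path) -> list[Path]:
        """One p-value TSV per phenotype + truth table + design config."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for j, lab in enumerate(self.matrix.phenotype_labels):
            table = PvalueTable(phenotype_label=lab,
                                snp_ids=self.matrix.snp_ids,
                                pvalues=self.matrix.values[:, j])
            p = outdir / f"{lab}.tsv"
            write_pvalue_table(table, p)
            paths.append(p)
        truth_frame = self.matrix.to_frame().copy()
        truth_frame.loc[:, :] = self.truth
        tp = outdir / "truth.tsv"
        truth_frame.astype(int).to_csv(tp, sep="\t")
        paths.append(tp)
        dp = outdir / "design.yaml"
        self.design.to_yaml(dp)
        paths.append(dp)
        return paths


def build_risk_sets(design: SimulationDesign,
                    seed: int | None = None) -> np.ndarray:
    """M x K binary truth matrix realizing the design's risk structure.

    Block layout: each sharing pair gets a contiguous block of
    ``round(fraction x min(risk_i, risk_j))`` SNPs marked risk for both,
    then each phenotype gets a contiguous private block topping up its risk
    budget; blocks never overlap, so every pairwise overlap equals its
    designed count exactly (zero for unlisted pairs).  Random layout:
    every phenotype's risk set is a uniform draw without replacement,
    independent across phenotypes (``seed`` falls back to ``design.seed``).
    """
    m, labels = design.n_snps, design.labels
    k = len(labels)
    truth = np.zeros((m, k), dtype=np.int8)
    budget = {lab: design.risk_count(lab) for lab in labels}
    if design.layout == "random":
        rng = np.random.default_rng(design.seed if seed is None else seed)
        for j, lab in enumerate(labels):
            idx = rng.choice(m, size=budget[lab], replace=False)
            truth[idx, j] = 1
        return truth
    cursor = 0
    remaining = dict(budget)
    for sh in design.sharing:
        a, b = sh.pair
        n_shared = int(round(sh.fraction * min(budget[a], budget[b])))
        if n_shared > remaining[a] or n_shared > remaining[b]:
            raise DesignError(
                f"sharing for pair {sh.pair} needs {n_shared} SNPs but "
                f"budgets left are {remaining[a]} and {remaining[b]}"
            )
        ja, jb = labels.index(a), labels.index(b)
        truth[cursor:cursor + n_shared, ja] = 1
        truth[cursor:cursor + n_shared, jb] = 1
        cursor += n_shared
        remaining[a] -= n_shared
        remaining[b] -= n_shared
    for j, lab in enumerate(labels):
        n_priv = remaining[lab]
        if cursor + n_priv > m:
            raise DesignError(
                f"design unsatisfiable: allocating private risk SNPs for "
                f"{lab!r} exceeds {m} SNPs"
            )
        truth[cursor:cursor + n_priv, j] = 1
        cursor += n_priv
    return truth


def simulate_pvalues(truth: np.ndarray, design: SimulationDesign,
                     seed: int | None = None) -> SimulatedStudy:
    """Draw p-values given the truth: Uniform nulls, Beta(shape, 1) risk."""
    truth = np.asarray(truth)
    m, k = truth.shape
    if m != design.n_snps or k != len(design.phenotypes):
        raise DesignError(f"truth shape {truth.shape} does not match design")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    values = rng.uniform(size=(m, k))
    for j, spec in enumerate(design.phenotypes):
        risk = truth[:, j] == 1
        values[risk, j] = rng.beta(spec.beta_shape, 1.0, size=int(risk.sum()))
    snp_ids = np.array([f"snp{i + 1:06d}" for i in range(m)], dtype=object)
    matrix = PvalueMatrix(snp_ids=snp_ids, phenotype_labels=design.labels,
                          values=values)
    return SimulatedStudy(matrix=matrix, truth=truth, design=design)


def simulate_study(design: SimulationDesign,
                   seed: int | None = None) -> SimulatedStudy:
    """Build risk sets and draw p-values in one call.

    ``seed`` overrides ``design.seed``.  The (random-layout) risk placement
    and the p-value draws use independent child streams of the seed so the
    two sources of randomness never alias; with the default block layout
    the truth is deterministic and only the p-values are random.
    """
    base = design.seed if seed is None else seed
    child_truth, child_pvals = np.random.SeedSequence(base).spawn(2)
    truth = build_risk_sets(design, seed=child_truth)
    return simulate_pvalues(truth, design, seed=child_pvals)
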