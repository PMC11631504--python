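"""Synthetic genotype/phenotype simulator for the p >> n marker regime.

Genotypes: each line carries two haplotypes; along a haplotype, allele
indicators follow a first-order Markov chain over adjacent markers with a
target correlation ``ld_rho`` (a crude stand-in for linkage
disequilibrium).  Allele frequencies are drawn uniformly from
``maf_range``; dosages are the haplotype sums in {0, 1, 2}.

Phenotypes: an additive polygenic trait y = mu + g + e with g = X beta.
A random subset of ``n_qtl`` markers gets Gaussian effects, then the
genetic values are centered and rescaled to SAMPLE mean 0 / variance 1
(the effects are rescaled with them), and the error variance is set to
sigma_e^2 = (1 - h2) / h2 so the realized genetic-variance share equals
the target heritability exactly on the generated sample.  Centering keeps
the phenotype mean at ``mu`` (default 10), well away from zero, the way
real measured traits sit on a positive scale — which is what makes
mean-normalized error metrics meaningful.  At h2 = 0 the effects are set
to zero and sigma_e^2 = 1.

These choices emulate the typical genomic-selection panel — a few hundred
lines, thousands of biallelic markers, moderately heritable quantitative
traits — without population structure, dominance, or missingness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimTruth",
    "Scenario",
    "simulate_genotypes",
    "simulate_phenotype",
    "make_benchmark_suite",
    "DEFAULT_SCENARIOS",
]

_DEFAULT_MU = 10.0


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of one simulated trait, for recovery tests."""

    qtl_indices: np.ndarray
    effects: np.ndarray
    h2_target: float
    sigma_e2: float
    mu: float
    seed: int
    realized_h2: float  # Var(g) / (Var(g) + sigma_e2) on the generated sample

    def to_json(self) -> str:
        return json.dumps(
            {
                "qtl_indices": self.qtl_indices.tolist(),
                "effects": self.effects.tolist(),
                "h2_target": self.h2_target,
                "sigma_e2": self.sigma_e2,
                "mu": self.mu,
                "seed": self.seed,
                "realized_h2": self.realized_h2,
            },
            sort_keys=True,
        )


def simulate_genotypes(
    n: int,
    p: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_rho: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Simulate an n x p dosage matrix coded {0, 1, 2}.

    ``ld_rho`` is the target correlation between adjacent markers on a
    haplotype; the achievable correlation is clipped when adjacent allele
    frequencies differ strongly.
    """
    if n < 1 or p < 1:
        raise ValueError("n and p must be positive")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    if not 0.0 <= ld_rho < 1.0:
        raise ValueError("ld_rho must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    freqs = rng.uniform(lo, hi, size=p)
    H = np.empty((2 * n, p), dtype=np.int8)
    H[:, 0] = rng.random(2 * n) < freqs[0]
    for j in range(1, p):
        f_prev, f = freqs[j - 1], freqs[j]
        slope = ld_rho * np.sqrt(f * (1 - f) / (f_prev * (1 - f_prev)))
        cond = np.clip(f + slope * (H[:, j - 1] - f_prev), 0.0, 1.0)
        H[:, j] = rng.random(2 * n) < cond
    return (H[:n] + H[n:]).astype(float)


def simulate_phenotype(
    X,
    n_qtl: int,
    h2_target: float,
    effect_dist: str = "gaussian",
    seed: int = 0,
    mu: float = _DEFAULT_MU,
) -> tuple[np.ndarray, SimTruth]:
    """Additive polygenic trait with sample-calibrated heritability."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 1 <= n_qtl <= p:
        raise ValueError("n_qtl must lie in [1, p]")
    if not 0.0 <= h2_target < 1.0:
        raise ValueError("h2_target must lie in [0, 1); h2 = 1 is degenerate")
    if effect_dist != "gaussian":
        raise ValueError(f"unknown effect distribution {effect_dist!r}")

    rng = np.random.default_rng(seed)
    qtl = np.sort(rng.choice(p, size=n_qtl, replace=False))
    if h2_target == 0.0:
        effects = np.zeros(n_qtl)
        g = np.zeros(n)
        sigma_e2 = 1.0
        realized = 0.0
    else:
        effects = rng.standard_normal(n_qtl)
        g = X[:, qtl] @ effects
        sd_g = float(np.std(g))
        if sd_g == 0.0:
            raise ValueError("all sampled QTL are monomorphic; cannot reach h2 > 0")
        effects /= sd_g
        g = (g - g.mean()) / sd_g  # sample mean 0, variance 1
        sigma_e2 = (1.0 - h2_target) / h2_target
        realized = 1.0 / (1.0 + sigma_e2)
    y = mu + g + rng.normal(0.0, np.sqrt(sigma_e2), size=n)
    truth = SimTruth(
        qtl_indices=qtl,
        effects=effects,
        h2_target=h2_target,
        sigma_e2=sigma_e2,
        mu=mu,
        seed=seed,
        realized_h2=realized,
    )
    return y, truth


@dataclass(frozen=True)
class Scenario:
    """One named simulation regime of the benchmark suite."""

    name: str
    n: int
    p: int
    h2: float
    n_qtl: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.3
    seed: int = 0


DEFAULT_SCENARIOS: tuple[Scenario, ...] = (
    Scenario(name="small_h2_0.3", n=100, p=500, h2=0.3, n_qtl=50, seed=11),
    Scenario(name="medium_h2_0.5", n=300, p=2000, h2=0.5, n_qtl=200, seed=12),
    Scenario(name="null", n=100, p=500, h2=0.0, n_qtl=50, seed=13),
)


def make_benchmark_suite(
    scenarios: tuple[Scenario, ...] | None = None,
    seed_offset: int = 0,
) -> dict[str, tuple[np.ndarray, np.ndarray, SimTruth]]:
    """Generate the named scenarios as (X, y, truth) triples.

    ``seed_offset`` shifts every scenario seed deterministically, for
    replicate suites.
    """
    scenarios = DEFAULT_SCENARIOS if scenarios is None else scenarios
    suite = {}
    for sc in scenarios:
        s = sc.seed + seed_offset
        X = simulate_genotypes(sc.n, sc.p, maf_range=sc.maf_range,
                               ld_rho=sc.ld_rho, seed=s)
        y, truth = simulate_phenotype(X, n_qtl=sc.n_qtl, h2_target=sc.h2,
                                      seed=s + 1)
        suite[sc.name] = (X, y, truth)
    return suite
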