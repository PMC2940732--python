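"""Synthetic tRNA gene-copy panels with controlled neighbor correlation.

Generates per-genome anticodon copy-number tables that look like bacterial
tRNA complements -- many absent anticodons, many 1-2 copy species, a few
high-copy species -- while controlling the correlation between an
anticodon's copy number and those of its Hamming-distance-1 neighbors.

The mechanism is a Gaussian copula: a latent zero-mean unit-variance field
over the permitted anticodons is drawn from a covariance with ``rho_target``
between distance-1 pairs (projected to the nearest feasible correlation
matrix when the request is not positive semidefinite), then mapped through
the quantile function of the target count marginal: a point mass at zero
with weight ``sparsity`` and a shifted negative binomial for positive
counts. Because the copula transform and the subsequent neighbor summation
both attenuate correlation, the *attained* latent neighbor correlation is
reported via :func:`attained_neighbor_correlation` rather than assumed
equal to the request.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import genetic_code as gc
from .pool_io import TRNAPool

__all__ = ["SynthConfig", "default_permitted", "synth_panel", "synth_aa_weights"]

log = logging.getLogger(__name__)


def default_permitted() -> tuple[str, ...]:
    """Default permitted anticodons: complements of the 61 sense codons,
    minus anticodons with A at the wobble position (position 34), a coarse
    mimic of their near-absence from bacterial genomes."""
    return tuple(ac for ac in gc.SENSE_ANTICODONS if not ac.startswith("A"))


@dataclass(frozen=True)
class SynthConfig:
    n_genomes: int = 50
    rho_target: float = 0.0
    sparsity: float = 0.35          # fraction of permitted anticodons absent
    mean_positive: float = 2.2      # mean copy number of present species
    dispersion: float = 1.2         # negative-binomial shape (smaller = heavier tail)
    permitted_anticodons: tuple[str, ...] = field(default_factory=default_permitted)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        if not -1.0 <= self.rho_target <= 1.0:
            raise ValueError("rho_target must lie in [-1, 1]")
        if not 0.0 <= self.sparsity < 1.0:
            raise ValueError("sparsity must lie in [0, 1)")
        if self.mean_positive <= 1.0:
            raise ValueError("mean_positive must exceed 1 (positive counts start at 1)")
        if len(self.permitted_anticodons) < 2:
            raise ValueError("need at least 2 permitted anticodons")


def _adjacency(anticodons: tuple[str, ...]) -> np.ndarray:
    k = len(anticodons)
    adj = np.zeros((k, k))
    index = {ac: i for i, ac in enumerate(anticodons)}
    for i, ac in enumerate(anticodons):
        for n in gc.anticodon_neighbors(ac):
            j = index.get(n)
            if j is not None:
                adj[i, j] = 1.0
    return adj


def _neighbor_correlation_matrix(cfg: SynthConfig) -> np.ndarray:
    """rho_target between distance-1 pairs, projected to a valid
    correlation matrix by eigenvalue clipping if needed."""
    adj = _adjacency(cfg.permitted_anticodons)
    sigma = np.eye(len(adj)) + cfg.rho_target * adj
    eigval, eigvec = np.linalg.eigh(sigma)
    if eigval.min() < 1e-10:
        clipped = np.clip(eigval, 1e-8, None)
        sigma = (eigvec * clipped) @ eigvec.T
        dinv = 1.0 / np.sqrt(np.diag(sigma))
        sigma = sigma * np.outer(dinv, dinv)
        attained = float(np.mean(sigma[adj > 0])) if adj.any() else 0.0
        log.info(
            "rho_target=%.3g not positive semidefinite on the anticodon graph; "
            "projected, mean attained latent neighbor correlation %.3g",
            cfg.rho_target,
            attained,
        )
    return sigma


def _count_quantile(u: np.ndarray, cfg: SynthConfig) -> np.ndarray:
    """Inverse CDF of the count marginal: sparsity mass at 0, then a
    shifted negative binomial 1 + NB(r, p) with mean ``mean_positive``."""
    r = cfg.dispersion
    mu = cfg.mean_positive - 1.0
    p = r / (r + mu)
    counts = np.zeros(len(u), dtype=int)
    pos = u >= cfg.sparsity
    if pos.any():
        u_pos = (u[pos] - cfg.sparsity) / (1.0 - cfg.sparsity)
        # guard the open-interval requirement of ppf
        u_pos = np.clip(u_pos, 1e-12, 1.0 - 1e-12)
        counts[pos] = 1 + stats.nbinom.ppf(u_pos, r, p).astype(int)
    return counts


def attained_neighbor_correlation(sigma: np.ndarray, adj: np.ndarray) -> float:
    return float(np.mean(sigma[adj > 0])) if adj.any() else 0.0


def synth_panel(cfg: SynthConfig) -> list[TRNAPool]:
    """Generate ``n_genomes`` pools; deterministic given ``cfg.seed``.

    Genomes drawing an all-zero complement (possible at high sparsity) are
    redrawn from the genome's own stream so every pool validates.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(cfg.seed)))
    sigma = _neighbor_correlation_matrix(cfg)
    chol = np.linalg.cholesky(sigma + 1e-10 * np.eye(len(sigma)))
    pools = []
    for g in range(cfg.n_genomes):
        for _attempt in range(100):
            z = chol @ rng.standard_normal(len(sigma))
            u = stats.norm.cdf(z)
            counts = _count_quantile(u, cfg)
            if counts.sum() > 0:
                break
        else:
            raise RuntimeError("failed to draw a non-empty genome; sparsity too extreme")
        pool = TRNAPool(f"synth{g:03d}")
        for ac, n in zip(cfg.permitted_anticodons, counts):
            pool.add(ac, int(n))
        pools.append(pool)
    return pools


def synth_aa_weights(
    kind: str = "uniform", seed: int = 0, alpha: float = 1.0
) -> dict[str, float]:
    """Amino-acid usage weight table over the 21 sense identities.

    kind: 'uniform', 'degeneracy' (proportional to codon count) or
    'dirichlet' (seeded random draw with concentration ``alpha``).
    """
    aas = list(gc.AMINO_ACIDS)
    if kind == "uniform":
        w = np.full(len(aas), 1.0 / len(aas))
    elif kind == "degeneracy":
        d = np.array([gc.degeneracy(a) for a in aas], dtype=float)
        w = d / d.sum()
    elif kind == "dirichlet":
        rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed)))
        w = rng.dirichlet(np.full(len(aas), alpha))
    else:
        raise ValueError(f"unknown weight kind {kind!r}")
    return dict(zip(aas, map(float, w)))
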