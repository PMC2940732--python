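"""Constrained randomization null for the focal/neighbor correlation.

Gene copies are redistributed over a permitted-anticodon set standing in
for the stereochemical constraints on which anticodons can exist, either
uniformly or with amino-acid usage bias (an amino acid is drawn by weight,
then an anticodon uniformly within it). Per-genome totals are conserved
exactly, and the observed rho_t distribution is compared to the null with a
two-sample Kolmogorov-Smirnov test per degeneracy class.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import genetic_code as gc
from .correlation import DEFAULT_CLASSES, correlate_by_class, focal_neighbor_table
from .pool_io import TRNAPool

__all__ = ["NullConfig", "randomize_pool", "build_null", "null_vs_observed"]


@dataclass(frozen=True)
class NullConfig:
    permitted_anticodons: tuple[str, ...] | None = None  # default: observed in panel
    aa_weights: Mapping[str, float] | None = None  # None -> unbiased variant
    n_reps: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be positive")
        if self.permitted_anticodons is not None:
            if len(self.permitted_anticodons) == 0:
                raise ValueError("permitted anticodon set must be non-empty")
            for ac in self.permitted_anticodons:
                if gc.is_stop_complement(ac):
                    raise ValueError(f"permitted set contains stop-complement {ac}")
        if self.aa_weights is not None:
            w = np.array(list(self.aa_weights.values()), dtype=float)
            if (w < 0).any() or w.sum() <= 0:
                raise ValueError("aa_weights must be non-negative and not all zero")


def observed_anticodons(pools: Iterable[TRNAPool]) -> tuple[str, ...]:
    """Union of anticodons with positive copy number anywhere in the panel."""
    seen: set[str] = set()
    for pool in pools:
        seen.update(sp.anticodon for sp in pool.present())
    return tuple(sorted(seen))


def panel_aa_weights(pools: Iterable[TRNAPool]) -> dict[str, float]:
    """Panel-wide share of gene copies per amino acid (biased-null default)."""
    totals: dict[str, float] = {}
    for pool in pools:
        for sp in pool.present():
            totals[sp.amino_acid] = totals.get(sp.amino_acid, 0.0) + sp.gcn
    grand = sum(totals.values())
    return {aa: v / grand for aa, v in totals.items()}


def _permitted(cfg: NullConfig, pools: Sequence[TRNAPool]) -> tuple[str, ...]:
    if cfg.permitted_anticodons is not None:
        return cfg.permitted_anticodons
    return observed_anticodons(pools)


def randomize_pool(
    pool: TRNAPool,
    permitted: Sequence[str],
    rng: np.random.Generator,
    aa_weights: Mapping[str, float] | None = None,
) -> TRNAPool:
    """Reassign each of the pool's gene copies independently over the
    permitted anticodons, preserving the total exactly.

    Unbiased: uniform over permitted anticodons. Biased: amino acid drawn
    proportional to ``aa_weights``, then uniform over that amino acid's
    permitted anticodons.
    """
    total = int(round(pool.total_gcn))
    permitted = list(permitted)
    if aa_weights is None:
        probs = np.full(len(permitted), 1.0 / len(permitted))
    else:
        by_aa: dict[str, list[int]] = {}
        for i, ac in enumerate(permitted):
            by_aa.setdefault(gc.amino_acid_of_anticodon(ac), []).append(i)
        probs = np.zeros(len(permitted))
        for aa, w in aa_weights.items():
            if w <= 0:
                continue
            if aa not in by_aa:
                raise ValueError(
                    f"amino acid {aa} has positive weight but no permitted anticodon"
                )
            idx = by_aa[aa]
            probs[idx] = w / len(idx)
        probs = probs / probs.sum()
    counts = rng.multinomial(total, probs)
    out = TRNAPool(pool.genome_id)
    for ac, n in zip(permitted, counts):
        if n > 0:
            out.add(ac, int(n))
    return out


def _replicate_rng(seed: int, genome_id: str, rep: int) -> np.random.Generator:
    # deterministic per-(seed, genome, replicate) stream; crc32 is stable
    # across processes (unlike built-in str hashing)
    key = zlib.crc32(genome_id.encode())
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(int(key), int(rep)))
    )


def build_null(
    pools: Sequence[TRNAPool],
    cfg: NullConfig,
    method: str = "pearson",
    classes: Sequence[int] = DEFAULT_CLASSES,
) -> pd.DataFrame:
    """Null rho_t samples: per replicate, every genome's copies are
    redistributed and the per-class correlations recomputed."""
    permitted = _permitted(cfg, pools)
    frames = []
    for rep in range(cfg.n_reps):
        rnd = [
            randomize_pool(p, permitted, _replicate_rng(cfg.seed, p.genome_id, rep), cfg.aa_weights)
            for p in pools
        ]
        res = correlate_by_class(focal_neighbor_table(rnd), method=method, classes=classes)
        res.insert(0, "replicate", rep)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


def null_vs_observed(
    pools: Sequence[TRNAPool],
    cfg: NullConfig,
    method: str = "pearson",
    classes: Sequence[int] = DEFAULT_CLASSES,
) -> pd.DataFrame:
    """Two-sample KS comparison of observed vs null rho_t per class."""
    observed = correlate_by_class(
        focal_neighbor_table(list(pools)), method=method, classes=classes
    )
    null = build_null(pools, cfg, method=method, classes=classes)
    rows = []
    for d in list(classes) + ["all"]:
        obs = observed.loc[
            (observed["class"] == d) & observed["defined"], "rho_t"
        ].to_numpy(dtype=float)
        nul = null.loc[(null["class"] == d) & null["defined"], "rho_t"].to_numpy(dtype=float)
        if len(obs) < 2 or len(nul) < 2:
            raise ValueError(f"class {d}: need at least 2 defined rho_t samples per side")
        ks = stats.ks_2samp(obs, nul)
        rows.append(
            {
                "class": d,
                "n_observed": len(obs),
                "n_null": len(nul),
                "ks_stat": float(ks.statistic),
                "ks_p": float(ks.pvalue),
            }
        )
    return pd.DataFrame(rows)
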