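"""Focal/neighbor tRNA abundance correlations across a genome panel.

For every tRNA species present in a genome, t_F is its own gene copy number
and t_N the summed copy number of its one-step non-synonymous anticodon
neighbors (Hamming distance 1, different amino acid, stop-complements
excluded). Under the classical picture of independent tRNA pools the
across-species correlation rho_t between t_F and t_N should center on zero;
a consistently positive rho_t couples a codon's cognate supply to its
missense-error pressure.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import genetic_code as gc
from .pool_io import TRNAPool

__all__ = ["focal_neighbor_table", "correlate_by_class", "panel_tests"]

#: Degeneracy classes shown in the headline analysis; "all" pools every species.
DEFAULT_CLASSES = (2, 4, 6)


def focal_neighbor_table(
    pools: TRNAPool | Iterable[TRNAPool],
    include_absent: bool = False,
) -> pd.DataFrame:
    """(t_F, t_N) records, one per present tRNA species per genome.

    ``include_absent`` additionally emits records with t_F = 0 for permitted
    anticodons missing from the genome.
    """
    if isinstance(pools, TRNAPool):
        pools = [pools]
    rows = []
    for pool in pools:
        species = pool.species.values() if include_absent else pool.present()
        for sp in species:
            neighbors = gc.anticodon_neighbors(sp.anticodon, nonsynonymous_only=True)
            t_n = sum(pool.gcn(n) for n in neighbors)
            rows.append(
                {
                    "genome_id": pool.genome_id,
                    "anticodon": sp.anticodon,
                    "amino_acid": sp.amino_acid,
                    "degeneracy": gc.degeneracy(sp.amino_acid),
                    "t_F": sp.gcn,
                    "t_N": t_n,
                }
            )
    return pd.DataFrame(
        rows, columns=["genome_id", "anticodon", "amino_acid", "degeneracy", "t_F", "t_N"]
    )


def _corr_and_slope(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, float]:
    if method == "pearson":
        rho = stats.pearsonr(x, y).statistic
    else:
        rho = stats.spearmanr(x, y).statistic
    slope = np.polyfit(x, y, 1)[0]
    return float(rho), float(slope)


def correlate_by_class(
    records: pd.DataFrame,
    method: str = "pearson",
    classes: Sequence[int] = DEFAULT_CLASSES,
    include_all: bool = True,
) -> pd.DataFrame:
    """Per-genome, per-degeneracy-class correlation rho_t and regression
    slope of t_N on t_F.

    Groups with fewer than 3 records or a constant variable are flagged
    ``defined = False`` with NaN statistics.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    groups: list[tuple[str, object, pd.DataFrame]] = []
    for gid, sub in records.groupby("genome_id", sort=True):
        for d in classes:
            groups.append((gid, d, sub[sub["degeneracy"] == d]))
        if include_all:
            groups.append((gid, "all", sub))
    rows = []
    for gid, d, sub in groups:
        x = sub["t_F"].to_numpy(dtype=float)
        y = sub["t_N"].to_numpy(dtype=float)
        ok = len(sub) >= 3 and np.ptp(x) > 0 and np.ptp(y) > 0
        if ok:
            rho, slope = _corr_and_slope(x, y, method)
        else:
            rho = slope = float("nan")
        rows.append(
            {
                "genome_id": gid,
                "class": d,
                "rho_t": rho,
                "slope": slope,
                "n": len(sub),
                "defined": bool(ok),
            }
        )
    return pd.DataFrame(rows)


def panel_tests(results: pd.DataFrame) -> pd.DataFrame:
    """Panel-level location tests of rho_t per degeneracy class.

    Per class: a two-sided Wilcoxon signed-rank test of the per-genome rho_t
    values against 0, and a two-sided binomial sign test of the count of
    positive rho_t against 1/2. Undefined groups are dropped (count logged
    in the output).
    """
    rows = []
    for d, sub in results.groupby("class", sort=False):
        vals = sub.loc[sub["defined"], "rho_t"].to_numpy(dtype=float)
        n_undef = int((~sub["defined"]).sum())
        if len(vals) == 0:
            raise ValueError(f"class {d}: no defined rho_t values to test")
        nonzero = vals[vals != 0]
        if len(nonzero) > 0:
            w = stats.wilcoxon(nonzero, alternative="two-sided")
            w_stat, w_p = float(w.statistic), float(w.pvalue)
        else:
            w_stat, w_p = float("nan"), 1.0
        n_pos = int((vals > 0).sum())
        n_eff = int((vals != 0).sum())  # zeros carry no sign information
        b_p = float(stats.binomtest(n_pos, n_eff, 0.5).pvalue) if n_eff else 1.0
        rows.append(
            {
                "class": d,
                "n_genomes": len(vals),
                "n_undefined": n_undef,
                "mean_rho": float(np.mean(vals)),
                "median_rho": float(np.median(vals)),
                "n_positive": n_pos,
                "wilcoxon_stat": w_stat,
                "wilcoxon_p": w_p,
                "sign_test_p": b_p,
            }
        )
    return pd.DataFrame(rows)
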