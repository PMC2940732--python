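"""Per-amino-acid sign of the elongation-rate / error-rate relationship.

The classical expectation is that within each amino acid the codon with the
fastest cognate elongation (highest R_c) also has the lowest error rates.
This module scores, per genome and amino acid, the sign of the relationship
between R_c and a chosen error rate across the amino acid's synonymous
codons, counts amino acids violating the classical expectation, and
aggregates signs across a genome panel.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from . import genetic_code as gc

__all__ = [
    "relation_sign",
    "relation_signs",
    "count_violations",
    "panel_fractions",
]

POSITIVE = "positive"
NEGATIVE = "negative"
FLAT = "flat"
UNDEFINED = "undefined"


def relation_sign(
    r_c: Iterable[float], eps: Iterable[float], method: str = "pearson"
) -> str:
    """Sign of the relationship between R_c and an error rate across one
    amino acid's synonymous codons.

    Two codons: sign of the product of differences. Three or more: sign of
    the correlation coefficient across the synonyms. Exact ties -> flat.
    """
    x = np.asarray(list(r_c), dtype=float)
    y = np.asarray(list(eps), dtype=float)
    if len(x) < 2:
        return UNDEFINED
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return FLAT
    if len(x) == 2:
        prod = (x[1] - x[0]) * (y[1] - y[0])
        return POSITIVE if prod > 0 else NEGATIVE if prod < 0 else FLAT
    if method == "pearson":
        rho = stats.pearsonr(x, y).statistic
    elif method == "spearman":
        rho = stats.spearmanr(x, y).statistic
    else:
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    return POSITIVE if rho > 0 else NEGATIVE if rho < 0 else FLAT


def relation_signs(
    profiles: pd.DataFrame, target: str = "eps_M", method: str = "pearson"
) -> pd.DataFrame:
    """Sign table over all amino acids with >= 2 synonymous codons, per genome.

    ``profiles`` is the per-codon table from
    :func:`trnaerr.error_model.codon_error_profiles` (single- or multi-genome).
    """
    if target not in ("eps_M", "eps_N"):
        raise ValueError("target must be 'eps_M' or 'eps_N'")
    rows = []
    for (gid, aa), sub in profiles.groupby(["genome_id", "amino_acid"], sort=True):
        d = gc.degeneracy(aa)
        if d < 2:
            continue
        sign = relation_sign(sub["R_c"], sub[target], method=method)
        rows.append(
            {
                "genome_id": gid,
                "amino_acid": aa,
                "degeneracy": d,
                "target": target,
                "sign": sign,
            }
        )
    return pd.DataFrame(rows)


def count_violations(
    profiles: pd.DataFrame, target: str = "eps_M", criterion: str = "argmin"
) -> int:
    """Number of the 21 amino acids violating the classical expectation that
    the highest-R_c codon has the lowest error rate.

    criterion 'argmin': violation iff the highest-R_c codon does not attain
    the minimum error rate among its synonyms (weakest reading).
    criterion 'any': violation iff the highest-R_c codon's error rate
    exceeds at least one synonym's (equivalent for D = 2).
    Single-codon amino acids cannot violate and count as conforming.
    """
    if criterion not in ("argmin", "any"):
        raise ValueError("criterion must be 'argmin' or 'any'")
    if profiles["genome_id"].nunique() != 1:
        raise ValueError("count_violations expects a single genome's profile")
    n = 0
    for aa, sub in profiles.groupby("amino_acid", sort=True):
        if gc.degeneracy(aa) < 2:
            continue
        r_c = sub["R_c"].to_numpy(dtype=float)
        eps = sub[target].to_numpy(dtype=float)
        top = int(np.argmax(r_c))
        if criterion == "argmin":
            violated = eps[top] > eps.min()
        else:
            violated = bool((eps[top] > np.delete(eps, top)).any())
        n += int(violated)
    return n


def panel_fractions(signs: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate a multi-genome sign table.

    Returns (per-amino-acid fractions, per-class binomial tests): the
    fraction of genomes in which each amino acid shows a negative sign, and
    per degeneracy class a two-sided binomial test of pooled positive vs
    negative signs against 1/2 (flat/undefined signs excluded).
    """
    if len(signs) == 0:
        raise ValueError("empty sign table")
    frac_rows = []
    for (aa, d), sub in signs.groupby(["amino_acid", "degeneracy"], sort=True):
        defined = sub[sub["sign"].isin([POSITIVE, NEGATIVE])]
        frac_rows.append(
            {
                "amino_acid": aa,
                "degeneracy": d,
                "n_genomes": sub["genome_id"].nunique(),
                "n_defined": len(defined),
                "fraction_negative": (
                    float((defined["sign"] == NEGATIVE).mean()) if len(defined) else float("nan")
                ),
            }
        )
    test_rows = []
    for d, sub in signs.groupby("degeneracy", sort=True):
        n_pos = int((sub["sign"] == POSITIVE).sum())
        n_neg = int((sub["sign"] == NEGATIVE).sum())
        n_eff = n_pos + n_neg
        p = float(stats.binomtest(n_pos, n_eff, 0.5).pvalue) if n_eff else float("nan")
        test_rows.append(
            {
                "degeneracy": d,
                "n_positive": n_pos,
                "n_negative": n_neg,
                "binomial_p": p,
            }
        )
    return pd.DataFrame(frac_rows), pd.DataFrame(test_rows)
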