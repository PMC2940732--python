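"""Per-codon elongation rates and missense/nonsense error rates.

A ribosome paused at codon i is resolved by the first of three competing
exponential clocks: elongation by a cognate or pseudo-cognate tRNA (rate
R_c), elongation by a near-cognate tRNA, i.e. a missense error (rate R_n),
or premature termination by drop-off / frameshift / release-factor
recognition (codon-independent background rate d). With tRNA arrival rates
proportional to gene copy number, the class rates are

    R_c(i) = a * ( sum_{j in C} w_ij P_c GCN_j  +  sum_{j in P} P_p GCN_j )
    R_n(i) = a * sum_{j in N} P_n GCN_j

and the per-elongation-event error probabilities are the branching
fractions of the competing exponentials:

    eps_M(i) = R_n / (R_c + R_n + d)
    eps_N(i) = d   / (R_c + R_n + d)

The scaling constant a (codons/s per gene copy) is calibrated so that the
harmonic mean of R_c across the 61 sense codons matches a target bulk
elongation rate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import genetic_code as gc
from .kinetics import ElongationProbabilities
from .pairing import WobbleRules, enumerate_classes
from .pool_io import TRNAPool

__all__ = [
    "ModelParams",
    "elongation_rates",
    "calibrate_a",
    "error_rates",
    "derive_dropoff",
    "codon_error_profiles",
    "missense_order_condition",
    "sensitivity_sweep",
]

#: Package defaults: per-entry acceptance probabilities on the Gromadski &
#: Rodnina ensemble-kinetics scale, a 10 codons/s bulk elongation target, and
#: a background drop-off rate reproducing a 4e-4 per-codon nonsense frequency
#: at that rate (see docs/methods.md).
DEFAULT_P_C = 0.99
DEFAULT_P_N = 0.0045
DEFAULT_TARGET_RATE = 10.0
DEFAULT_DROPOFF = 4.0016e-3


@dataclass(frozen=True)
class ModelParams:
    probs: ElongationProbabilities = ElongationProbabilities(
        DEFAULT_P_C, DEFAULT_P_N, DEFAULT_P_N
    )
    rules: WobbleRules = WobbleRules()
    scaling_a: float = 1.0
    dropoff_d: float = DEFAULT_DROPOFF
    target_mean_rate: float = DEFAULT_TARGET_RATE
    harmonic_mean_on: str = "R_c"  # or "R_c+R_n"

    def __post_init__(self) -> None:
        if self.scaling_a <= 0:
            raise ValueError("scaling_a must be positive")
        if self.dropoff_d < 0:
            raise ValueError("dropoff_d must be non-negative")
        if self.harmonic_mean_on not in ("R_c", "R_c+R_n"):
            raise ValueError("harmonic_mean_on must be 'R_c' or 'R_c+R_n'")


def elongation_rates(pool: TRNAPool, params: ModelParams) -> dict[str, tuple[float, float]]:
    """Cognate and near-cognate elongation rates (R_c, R_n) per sense codon."""
    p = params.probs
    out: dict[str, tuple[float, float]] = {}
    for cdn in gc.SENSE_CODONS:
        part = enumerate_classes(pool, cdn, params.rules)
        r_c = sum(w * p.P_c * n for _, n, w in part.cognate)
        r_c += sum(p.P_p * n for _, n in part.pseudo)
        r_n = sum(p.P_n * n for _, n in part.near)
        out[cdn] = (params.scaling_a * r_c, params.scaling_a * r_n)
    return out


def _harmonic_mean(values: np.ndarray) -> float:
    return len(values) / np.sum(1.0 / values)


def calibrate_a(pool: TRNAPool, params: ModelParams) -> float:
    """Scaling constant a making the harmonic mean of per-codon elongation
    rates equal ``params.target_mean_rate``.

    Raises if any codon has a zero rate at a = 1 (a harmonic mean over a
    zero is zero and no finite a can fix it); the offending codons are named.
    """
    base = replace(params, scaling_a=1.0)
    rates = elongation_rates(pool, base)
    if params.harmonic_mean_on == "R_c":
        vals = {c: rc for c, (rc, _) in rates.items()}
    else:
        vals = {c: rc + rn for c, (rc, rn) in rates.items()}
    zero = sorted(c for c, v in vals.items() if v <= 0)
    if zero:
        raise ValueError(
            f"{pool.genome_id}: cannot calibrate, zero elongation rate at codons: "
            + ", ".join(zero)
        )
    hm = _harmonic_mean(np.array(list(vals.values())))
    return params.target_mean_rate / hm


def error_rates(r_c: float, r_n: float, d: float) -> tuple[float, float]:
    """Missense and nonsense error probabilities per elongation event."""
    if r_c < 0 or r_n < 0 or d < 0:
        raise ValueError("rates must be non-negative")
    total = r_c + r_n + d
    if total == 0:
        raise ValueError("R_c, R_n and d are all zero: event probabilities undefined")
    return r_n / total, d / total


def derive_dropoff(per_codon_nonsense_prob: float, reference_total_rate: float) -> float:
    """Back-compute the drop-off rate d from a measured per-codon nonsense
    frequency q at an assumed total elongation rate R: solves d/(R+d) = q."""
    q = per_codon_nonsense_prob
    if not 0.0 < q < 1.0:
        raise ValueError("per-codon nonsense probability must lie in (0, 1)")
    if reference_total_rate <= 0:
        raise ValueError("reference rate must be positive")
    return q * reference_total_rate / (1.0 - q)


def codon_error_profiles(
    pool: TRNAPool, params: ModelParams, calibrate: bool = True
) -> pd.DataFrame:
    """Full 61-row profile: codon, amino_acid, degeneracy, R_c, R_n, eps_M, eps_N.

    With ``calibrate`` the scaling constant is fit per genome so the harmonic
    mean of elongation rates hits the configured target.
    """
    if calibrate:
        a = calibrate_a(pool, params)
        params = replace(params, scaling_a=a)
    rates = elongation_rates(pool, params)
    rows = []
    for cdn in gc.SENSE_CODONS:
        r_c, r_n = rates[cdn]
        eps_m, eps_n = error_rates(r_c, r_n, params.dropoff_d)
        aa = gc.translate(cdn)
        rows.append(
            {
                "genome_id": pool.genome_id,
                "codon": cdn,
                "amino_acid": aa,
                "degeneracy": gc.degeneracy(aa),
                "R_c": r_c,
                "R_n": r_n,
                "eps_M": eps_m,
                "eps_N": eps_n,
            }
        )
    return pd.DataFrame(rows)


def missense_order_condition(
    profile_low: tuple[float, float], profile_high: tuple[float, float], d: float
) -> bool:
    """True iff the higher-R_c member of a synonymous pair has the *higher*
    missense error rate.

    Closed form: with profiles (R_c1, R_n1) and (R_c2, R_n2), eps_M2 > eps_M1
    reduces to R_n2 (R_c1 + d) > R_n1 (R_c2 + d) -- the R_n1*R_n2 cross terms
    cancel when both branching fractions are put over a common denominator.
    """
    r_c1, r_n1 = profile_low
    r_c2, r_n2 = profile_high
    return r_n2 * (r_c1 + d) > r_n1 * (r_c2 + d)


def sensitivity_sweep(
    pool: TRNAPool,
    params: ModelParams,
    d_factors: tuple[float, ...] = (0.1, 1.0, 10.0),
    wobble_tables: tuple[tuple[float, float], ...] = ((0.64, 0.60),),
    target: str = "eps_M",
) -> pd.DataFrame:
    """Sign stability of the per-amino-acid R_c/error-rate relationship over
    a grid of drop-off rates and wobble penalty tables.

    Each grid point rescales d by a factor and substitutes a
    (noncanonical_pupy, pupu_pypy) penalty pair; the output reports, per
    grid point, the fraction of amino acids whose relation sign matches the
    baseline parameterization.
    """
    from .comparative import relation_signs  # local import: avoids a cycle

    if not d_factors or not wobble_tables:
        raise ValueError("sensitivity grid must be non-empty")
    baseline = relation_signs(codon_error_profiles(pool, params), target=target)
    base_map = dict(zip(baseline["amino_acid"], baseline["sign"]))
    rows = []
    for df_, (pen_gu, pen_pp) in itertools.product(d_factors, wobble_tables):
        rules = replace(params.rules, noncanonical_pupy=pen_gu, pupu_pypy=pen_pp)
        pt = replace(params, dropoff_d=params.dropoff_d * df_, rules=rules)
        signs = relation_signs(codon_error_profiles(pool, pt), target=target)
        match = [
            base_map[aa] == s for aa, s in zip(signs["amino_acid"], signs["sign"])
        ]
        rows.append(
            {
                "d_factor": df_,
                "noncanonical_pupy": pen_gu,
                "pupu_pypy": pen_pp,
                "n_amino_acids": len(match),
                "fraction_sign_stable": float(np.mean(match)) if match else float("nan"),
            }
        )
    return pd.DataFrame(rows)
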