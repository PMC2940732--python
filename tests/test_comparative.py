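import numpy as np
import pandas as pd
import pytest

from trnaerr import (
    ModelParams,
    SynthConfig,
    codon_error_profiles,
    count_violations,
    error_rates,
    panel_fractions,
    relation_sign,
    relation_signs,
    synth_panel,
)
from trnaerr import genetic_code as gc


def test_two_codon_sign_rules():
    assert relation_sign([1, 2], [0.1, 0.2]) == "positive"
    assert relation_sign([1, 2], [0.2, 0.1]) == "negative"
    assert relation_sign([1, 2], [0.1, 0.1]) == "flat"
    assert relation_sign([1, 1], [0.1, 0.2]) == "flat"
    assert relation_sign([1], [0.1]) == "undefined"


def test_multi_codon_sign_uses_correlation():
    assert relation_sign([1, 2, 3, 4], [0.1, 0.2, 0.15, 0.4]) == "positive"
    assert relation_sign([1, 2, 3, 4], [0.4, 0.2, 0.25, 0.1], method="spearman") == "negative"
    with pytest.raises(ValueError):
        relation_sign([1, 2, 3], [1, 2, 3], method="kendall")


def test_nonsense_sign_tracks_total_rate_oracle(rng):
    """With shared d, the eps_N ordering of two synonyms is exactly the
    reverse of their total-rate ordering."""
    for _ in range(500):
        rc = rng.uniform(0.1, 30, 2)
        rn = rng.uniform(0.0, 3, 2)
        d = rng.uniform(1e-4, 1.0)
        eps_n = [error_rates(c, n, d)[1] for c, n in zip(rc, rn)]
        total_diff = (rc[1] + rn[1]) - (rc[0] + rn[0])
        if total_diff != 0:
            assert np.sign(eps_n[1] - eps_n[0]) == -np.sign(total_diff)


def _profile_frame(rows, genome="g1"):
    return pd.DataFrame(
        [
            {
                "genome_id": genome,
                "codon": c,
                "amino_acid": aa,
                "degeneracy": gc.degeneracy(aa),
                "R_c": rc,
                "R_n": rn,
                "eps_M": error_rates(rc, rn, 0.01)[0],
                "eps_N": error_rates(rc, rn, 0.01)[1],
            }
            for c, aa, rc, rn in rows
        ]
    )


def test_constant_near_cognate_rate_means_no_violations():
    """When R_n is identical across each amino acid's synonyms, eps_M is
    strictly decreasing in R_c and the classical expectation always holds."""
    rows = []
    for aa in gc.AMINO_ACIDS:
        for i, c in enumerate(gc.codons_of(aa)):
            rows.append((c, aa, 5.0 + i, 0.5))
    prof = _profile_frame(rows)
    assert count_violations(prof) == 0


def test_violation_counting_matches_argmax_argmin_scan(rng):
    """Random profiles vs an independent exhaustive scan oracle."""
    for trial in range(20):
        rows = []
        for aa in gc.AMINO_ACIDS:
            for c in gc.codons_of(aa):
                rows.append((c, aa, float(rng.uniform(1, 30)), float(rng.uniform(0, 2))))
        prof = _profile_frame(rows)
        expected = 0
        for aa in gc.AMINO_ACIDS:
            sub = prof[prof.amino_acid == aa]
            if len(sub) < 2:
                continue
            best = sub.loc[sub.R_c.idxmax()]
            if best.eps_M > sub.eps_M.min():
                expected += 1
        assert count_violations(prof) == expected


def test_violation_criteria_agree_for_two_fold_amino_acids(rng):
    rows = []
    for aa in ("Lys", "Asn", "His"):
        for c in gc.codons_of(aa):
            rows.append((c, aa, float(rng.uniform(1, 30)), float(rng.uniform(0, 2))))
    prof = _profile_frame(rows)
    assert count_violations(prof, criterion="argmin") == count_violations(prof, criterion="any")


def test_count_violations_rejects_multi_genome_input():
    prof = pd.concat([_profile_frame([("AAA", "Lys", 1, 0.1), ("AAG", "Lys", 2, 0.2)], g) for g in ("a", "b")])
    with pytest.raises(ValueError):
        count_violations(prof)


def test_relation_signs_cover_twenty_multi_codon_identities(ecoli_pool, params):
    prof = codon_error_profiles(ecoli_pool, params)
    signs = relation_signs(prof)
    # 21 identities minus Met and Trp (single codon)
    assert len(signs) == 19
    assert set(signs.sign) <= {"positive", "negative", "flat"}


def test_panel_fractions_all_negative_panel():
    rows = []
    for g in ("g1", "g2", "g3"):
        rows.append({"genome_id": g, "amino_acid": "Lys", "degeneracy": 2,
                     "target": "eps_M", "sign": "negative"})
    fracs, tests = panel_fractions(pd.DataFrame(rows))
    assert fracs.fraction_negative.tolist() == [1.0]
    assert tests.iloc[0].n_negative == 3


def test_single_genome_fractions_are_zero_or_one(ecoli_pool, params):
    prof = codon_error_profiles(ecoli_pool, params)
    fracs, _ = panel_fractions(relation_signs(prof))
    defined = fracs.dropna(subset=["fraction_negative"])
    assert set(defined.fraction_negative) <= {0.0, 1.0}


def test_panel_fractions_match_per_genome_recount(params):
    pools = synth_panel(SynthConfig(n_genomes=10, rho_target=0.3, seed=3))
    prof = pd.concat(
        [codon_error_profiles(p, params, calibrate=False) for p in pools], ignore_index=True
    )
    signs = relation_signs(prof)
    fracs, _ = panel_fractions(signs)
    for row in fracs.itertuples():
        sub = signs[(signs.amino_acid == row.amino_acid) & signs.sign.isin(["positive", "negative"])]
        if len(sub):
            assert row.fraction_negative == pytest.approx((sub.sign == "negative").mean())


def test_empty_sign_table_raises():
    with pytest.raises(ValueError):
        panel_fractions(pd.DataFrame())
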