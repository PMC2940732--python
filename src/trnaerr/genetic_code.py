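"""Standard bacterial genetic code with codon/anticodon algebra.

Codons and anticodons are plain 3-letter RNA strings written 5'->3'
(``codon()`` / ``anticodon()`` normalize DNA input). Amino-acid identities
follow the standard code except that serine, whose six codons fall into two
disjoint degenerate families that cannot interconvert by single point
changes, is split into two identities: ``Ser4`` (UCN box) and ``Ser2``
(AGU/AGC). This yields 21 sense amino-acid identities whose degeneracies sum
to 61.

A tRNA's amino-acid identity is taken to be ``translate(revcomp(anticodon))``
unless an explicit per-anticodon override is supplied (hook for modified-base
exceptions such as bacterial tRNA-Ile2, whose lysidine-modified CAU anticodon
reads AUA as isoleucine).
"""

from __future__ import annotations

from typing import Mapping

from Bio.Data import CodonTable

__all__ = [
    "RNA_BASES",
    "STOP",
    "SENSE_CODONS",
    "SENSE_ANTICODONS",
    "AMINO_ACIDS",
    "codon",
    "anticodon",
    "revcomp",
    "translate",
    "amino_acid_of_anticodon",
    "degeneracy",
    "codons_of",
    "anticodon_neighbors",
    "is_stop_complement",
]

RNA_BASES = "ACGU"
STOP = "*"

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}

_TABLE = CodonTable.unambiguous_rna_by_id[1]  # standard code, RNA alphabet


def _build_code() -> dict[str, str]:
    code: dict[str, str] = {}
    for cdn, aa1 in _TABLE.forward_table.items():
        aa = _AA3[aa1]
        if aa == "Ser":
            aa = "Ser4" if cdn.startswith("UC") else "Ser2"
        code[cdn] = aa
    for cdn in _TABLE.stop_codons:
        code[cdn] = STOP
    return code


_CODE: dict[str, str] = _build_code()

SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c, aa in _CODE.items() if aa != STOP)
)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

#: The 21 sense identities (serine split), in alphabetical order.
AMINO_ACIDS: tuple[str, ...] = tuple(sorted({aa for aa in _CODE.values() if aa != STOP}))

_DEGENERACY: dict[str, int] = {
    aa: sum(1 for v in _CODE.values() if v == aa) for aa in AMINO_ACIDS
}


def _normalize(seq: str, kind: str) -> str:
    if not isinstance(seq, str):
        raise TypeError(f"{kind} must be a string, got {type(seq).__name__}")
    s = seq.strip().upper().replace("T", "U")
    if len(s) != 3 or any(b not in RNA_BASES for b in s):
        raise ValueError(f"malformed {kind} {seq!r}: need 3 letters over A/C/G/U (or T)")
    return s


def codon(seq: str) -> str:
    """Validate and normalize a codon (DNA accepted, returned as RNA)."""
    return _normalize(seq, "codon")


def anticodon(seq: str) -> str:
    """Validate and normalize an anticodon (DNA accepted, returned as RNA)."""
    return _normalize(seq, "anticodon")


def revcomp(seq: str) -> str:
    """Watson-Crick reverse complement; maps anticodons to the codon they
    pair with perfectly, and vice versa."""
    s = _normalize(seq, "sequence")
    return "".join(_COMPLEMENT[b] for b in reversed(s))


def translate(cdn: str) -> str:
    """Amino-acid identity of a codon ('Ala' ... 'Ser2'/'Ser4'; '*' for stop)."""
    return _CODE[codon(cdn)]


def amino_acid_of_anticodon(
    ac: str, overrides: Mapping[str, str] | None = None
) -> str:
    """Amino acid charged on a tRNA with this anticodon.

    Default rule: translate the reverse complement. ``overrides`` maps
    anticodons to identities for known modified-base exceptions.
    """
    ac = anticodon(ac)
    if overrides and ac in overrides:
        return overrides[ac]
    return translate(revcomp(ac))


def degeneracy(aa: str) -> int:
    """Number of synonymous codons of a sense identity (D in {1,2,3,4,6})."""
    if aa == STOP:
        raise ValueError("degeneracy is undefined for the stop sentinel")
    try:
        return _DEGENERACY[aa]
    except KeyError:
        raise ValueError(f"unknown amino-acid identity {aa!r}") from None


def codons_of(aa: str) -> tuple[str, ...]:
    """Synonymous codons of a sense identity, sorted."""
    if aa not in _DEGENERACY:
        raise ValueError(f"unknown amino-acid identity {aa!r}")
    return tuple(sorted(c for c, v in _CODE.items() if v == aa))

SENSE_ANTICODONS: tuple[str, ...] = tuple(sorted(revcomp(c) for c in SENSE_CODONS))


def is_stop_complement(ac: str) -> bool:
    """True if this anticodon perfectly pairs a stop codon (e.g. UUA -> UAA)."""
    return revcomp(ac) in STOP_CODONS


def anticodon_neighbors(
    ac: str,
    nonsynonymous_only: bool = False,
    overrides: Mapping[str, str] | None = None,
) -> set[str]:
    """All anticodons at Hamming distance 1 from ``ac``.

    With ``nonsynonymous_only`` keep only neighbors charging a *different*
    amino acid than the focal anticodon; neighbors whose reverse complement
    is a stop codon encode no amino acid and are always dropped from the
    non-synonymous set.
    """
    ac = anticodon(ac)
    out: set[str] = set()
    for i in range(3):
        for b in RNA_BASES:
            if b == ac[i]:
                continue
            out.add(ac[:i] + b + ac[i + 1:])
    if not nonsynonymous_only:
        return out
    focal_aa = amino_acid_of_anticodon(ac, overrides)
    keep = set()
    for n in out:
        if is_stop_complement(n):
            continue
        if amino_acid_of_anticodon(n, overrides) != focal_aa:
            keep.add(n)
    return keep


def sense_codons_of_class(d: int) -> tuple[str, ...]:
    """Sense codons whose amino acid has degeneracy ``d``."""
    return tuple(c for c in SENSE_CODONS if _DEGENERACY[_CODE[c]] == d)
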