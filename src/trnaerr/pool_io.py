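"""Reading, validating and writing per-genome tRNA gene-copy tables.

The ingestion contract is a TSV with header columns ``genome_id``,
``anticodon``, ``gcn`` and optional ``#`` comment lines. Anticodons may be
written in DNA or RNA; copy numbers may be real-valued so that empirical
abundance estimates flow through the same pipeline as gene copy numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from . import genetic_code as gc

__all__ = ["TRNASpecies", "TRNAPool", "load_pools", "write_pools"]

_COLUMNS = ["genome_id", "anticodon", "gcn"]


@dataclass(frozen=True)
class TRNASpecies:
    anticodon: str
    gcn: float
    amino_acid: str

    def __post_init__(self) -> None:
        if self.gcn < 0:
            raise ValueError(f"negative gene copy number for {self.anticodon}: {self.gcn}")


@dataclass
class TRNAPool:
    """One genome's tRNA complement, keyed by anticodon.

    Species with ``gcn == 0`` are legal absent-species records; anticodons
    complementary to stop codons are rejected (those tRNAs would be
    suppressors, outside the sense-codon model).
    """

    genome_id: str
    species: dict[str, TRNASpecies] = field(default_factory=dict)

    @classmethod
    def from_counts(
        cls,
        genome_id: str,
        counts: Mapping[str, float],
        overrides: Mapping[str, str] | None = None,
    ) -> "TRNAPool":
        pool = cls(genome_id)
        for ac, n in counts.items():
            pool.add(ac, n, overrides)
        return pool

    def add(self, ac: str, n: float, overrides: Mapping[str, str] | None = None) -> None:
        ac = gc.anticodon(ac)
        if gc.is_stop_complement(ac):
            raise ValueError(
                f"{self.genome_id}: anticodon {ac} pairs a stop codon and cannot be pooled"
            )
        aa = gc.amino_acid_of_anticodon(ac, overrides)
        if ac in self.species:
            n = self.species[ac].gcn + n
        self.species[ac] = TRNASpecies(ac, float(n), aa)

    @property
    def total_gcn(self) -> float:
        return sum(sp.gcn for sp in self.species.values())

    def present(self) -> list[TRNASpecies]:
        """Species with positive copy number."""
        return [sp for sp in self.species.values() if sp.gcn > 0]

    def gcn(self, ac: str) -> float:
        sp = self.species.get(gc.anticodon(ac))
        return sp.gcn if sp is not None else 0.0


def load_pools(
    path: str | Path,
    lenient: bool = False,
    overrides: Mapping[str, str] | None = None,
) -> list[TRNAPool]:
    """Load one pool per genome_id from a TSV table.

    Duplicate (genome, anticodon) rows are summed with a warning. Anticodons
    complementary to stop codons raise, or are skipped under ``lenient``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"genome_id": str, "anticodon": str})
    if list(df.columns) != _COLUMNS:
        raise ValueError(
            f"{path}: expected columns {_COLUMNS}, found {list(df.columns)}"
        )
    if (df["gcn"] < 0).any():
        bad = df.loc[df["gcn"] < 0]
        raise ValueError(f"{path}: negative gcn rows:\n{bad}")
    pools: dict[str, TRNAPool] = {}
    n_dup = 0
    for row in df.itertuples(index=False):
        pool = pools.setdefault(row.genome_id, TRNAPool(row.genome_id))
        ac = gc.anticodon(row.anticodon)
        if ac in pool.species:
            n_dup += 1
        try:
            pool.add(ac, row.gcn, overrides)
        except ValueError:
            if lenient:
                warnings.warn(
                    f"skipping stop-complement anticodon {ac} in {row.genome_id}",
                    stacklevel=2,
                )
                continue
            raise
    if n_dup:
        warnings.warn(f"{path}: {n_dup} duplicate (genome, anticodon) rows summed", stacklevel=2)
    out = list(pools.values())
    for pool in out:
        if pool.total_gcn <= 0:
            raise ValueError(f"{pool.genome_id}: total gene copy number must be positive")
    return out


def write_pools(
    pools: Iterable[TRNAPool],
    path: str | Path,
    header_comments: Iterable[str] = (),
) -> None:
    """Write pools back to the TSV dialect accepted by :func:`load_pools`."""
    path = Path(path)
    rows = []
    for pool in pools:
        for ac in sorted(pool.species):
            sp = pool.species[ac]
            g = sp.gcn
            rows.append((pool.genome_id, ac, int(g) if float(g).is_integer() else g))
    with path.open("w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        fh.write("\t".join(_COLUMNS) + "\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")
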