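"""Intra-ribosomal tRNA selection kinetics.

A ternary complex entering the A-site walks through a short chain of
reversible steps (codon recognition, GTPase activation, accommodation /
proofreading). Every step has a forward rate, an optional backward rate
(from the first step, backward means dissociation and loss of the tRNA) and
an optional direct rejection rate. The per-entry elongation probability is
the probability that the walk is absorbed at peptidyl transfer rather than
lost, which for this birth-death topology has the standard first-passage
recursion

    alpha_i = f_i / (f_i + r_i + b_i * (1 - alpha_{i-1})),   P = prod_i alpha_i

with alpha_{-1} = 0 (a tRNA pushed back off the first step is gone).

Cognate and near-cognate ternary complexes traverse the same topology with
very different rate constants, which is what turns a modest free-energy
difference into a ~200-fold acceptance ratio; wobble-read cognates are
penalized downstream by a multiplier on P_c rather than by perturbing the
constants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "KineticStep",
    "KineticScheme",
    "ElongationProbabilities",
    "elongation_success_probability",
    "default_probabilities",
]


@dataclass(frozen=True)
class KineticStep:
    """One step of the selection pathway.

    forward: rate toward the next step (1/s)
    backward: rate back toward the previous state (1/s); from the first
        step this is dissociation from the ribosome
    reject: direct rejection/loss rate from this state (1/s)
    """

    forward: float
    backward: float = 0.0
    reject: float = 0.0

    def __post_init__(self) -> None:
        for name in ("forward", "backward", "reject"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} rate must be non-negative, got {v}")


@dataclass(frozen=True)
class KineticScheme:
    steps: tuple[KineticStep, ...]

    def __post_init__(self) -> None:
        if len(self.steps) == 0:
            raise ValueError("a kinetic scheme needs at least one step")

    @classmethod
    def from_rates(cls, rates: Sequence[dict]) -> "KineticScheme":
        return cls(tuple(KineticStep(**r) for r in rates))


def elongation_success_probability(scheme: KineticScheme) -> float:
    """Probability that a tRNA entering the A-site is elongated rather than
    lost, i.e. the absorption probability at the terminal success state."""
    p = 1.0
    alpha_prev = 0.0
    for step in scheme.steps:
        exit_rate = step.reject + step.backward * (1.0 - alpha_prev)
        total = step.forward + exit_rate
        if total == 0.0 or step.forward == 0.0:
            warnings.warn(
                "kinetic step with zero forward flux: success probability is 0",
                RuntimeWarning,
                stacklevel=2,
            )
            return 0.0
        alpha = step.forward / total
        p *= alpha
        alpha_prev = alpha
    return p


@dataclass(frozen=True)
class ElongationProbabilities:
    """Per-entry acceptance probabilities of the three competing tRNA classes.

    Pseudo-cognates deliver the correct amino acid but through a
    non-standard read, and are accepted at the near-cognate probability
    (P_p = P_n) unless explicitly overridden.
    """

    P_c: float
    P_n: float
    P_p: float

    def __post_init__(self) -> None:
        for name in ("P_c", "P_n", "P_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def default_probabilities(config: dict) -> ElongationProbabilities:
    """Resolve per-entry probabilities from a config mapping.

    Accepted keys: explicit ``P_c``/``P_n`` (optionally ``P_p``), or
    ``cognate_scheme``/``near_cognate_scheme`` as lists of step dicts.
    Explicit values take precedence over scheme computation.
    """
    if "P_c" in config and "P_n" in config:
        pc = float(config["P_c"])
        pn = float(config["P_n"])
    elif "cognate_scheme" in config and "near_cognate_scheme" in config:
        pc = elongation_success_probability(KineticScheme.from_rates(config["cognate_scheme"]))
        pn = elongation_success_probability(
            KineticScheme.from_rates(config["near_cognate_scheme"])
        )
    else:
        raise ValueError(
            "config must supply explicit P_c/P_n or cognate_scheme/near_cognate_scheme"
        )
    pp = float(config["P_p"]) if "P_p" in config else pn
    return ElongationProbabilities(P_c=pc, P_n=pn, P_p=pp)
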