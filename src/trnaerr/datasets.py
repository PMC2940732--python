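"""Bundled reference data: the E. coli K-12 tRNA pool and default parameters.

The K-12 table is a reconstruction compiled from the standard K-12 tRNA
gene complement (see the TSV header), not a database export.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .error_model import ModelParams
from .kinetics import default_probabilities
from .pairing import WobbleRules
from .pool_io import TRNAPool, load_pools

__all__ = ["ecoli_k12_pool", "default_params", "load_params_yaml"]


def _data_path(name: str):
    return resources.files("trnaerr.data").joinpath(name)


def ecoli_k12_pool() -> TRNAPool:
    """The bundled E. coli K-12 tRNA gene-copy pool (85 genes, 39 anticodons)."""
    with resources.as_file(_data_path("ecoli_k12_trna_gcn.tsv")) as p:
        return load_pools(p)[0]


def params_from_config(cfg: dict) -> ModelParams:
    """Build ModelParams from a nested config mapping (see default_params.yaml)."""
    probs = default_probabilities(cfg.get("probabilities", {}))
    rules = WobbleRules(**cfg.get("wobble", {}))
    model = cfg.get("model", {})
    return ModelParams(
        probs=probs,
        rules=rules,
        dropoff_d=float(model.get("dropoff_d", ModelParams().dropoff_d)),
        target_mean_rate=float(model.get("target_mean_rate", ModelParams().target_mean_rate)),
        harmonic_mean_on=model.get("harmonic_mean_on", "R_c"),
    )


def load_params_yaml(path) -> ModelParams:
    with open(path) as fh:
        return params_from_config(yaml.safe_load(fh))


def default_params() -> ModelParams:
    """Package default model parameterization (data/default_params.yaml)."""
    with resources.as_file(_data_path("default_params.yaml")) as p:
        return load_params_yaml(p)
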