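"""Genotype fixture registry.

Loads ``data/paper_params.yaml``, which maps genotype names (WT, W2A, R14E,
V81D/V174D, EC5) to the ground-truth parameters their synthetic fixtures
are generated with, and builds ready-to-use generator parameter sets.
"""
from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml

from .errors import InvalidParameterError
from .synthetic_data import DisassemblyParams, SceneParams, SpheroidParams


@lru_cache(maxsize=1)
def fixture_registry() -> dict:
    ref = resources.files("junctionkit.data").joinpath("paper_params.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def _lookup(section: str, genotype: str) -> dict:
    reg = fixture_registry()
    try:
        return reg[section][genotype]
    except KeyError:
        raise InvalidParameterError(
            f"no {section} fixture for genotype {genotype!r}; "
            f"have {sorted(reg.get(section, {}))}"
        ) from None


def bleach_scene_params(genotype: str, noise_sd: float = 0.02, seed: int = 0) -> SceneParams:
    """Scene parameters whose ground-truth ratio is the genotype's fixture value."""
    fx = _lookup("bleach_fret", genotype)
    return SceneParams(fret_ratio_true=fx["fret_ratio"], noise_sd=noise_sd, seed=seed)


def ratiometric_drop(genotype: str) -> float:
    return float(_lookup("ratiometric", genotype)["drop_fraction"])


def assembly_rate(genotype: str) -> float:
    return float(_lookup("assembly", genotype)["rate"])


def presence_fraction(genotype: str) -> float:
    return float(_lookup("assembly", genotype)["presence_fraction"])


def disassembly_params(genotype: str, noise_sd: float = 0.02, seed: int = 0) -> DisassemblyParams:
    fx = _lookup("disassembly", genotype)
    return DisassemblyParams(
        tau_true=fx["tau"],
        lag_true=fx["lag"],
        plateau_fraction=fx["plateau_fraction"],
        noise_sd=noise_sd,
        seed=seed,
    )


def spheroid_params(genotype: str, noise_sd: float = 0.02, seed: int = 0, **overrides) -> SpheroidParams:
    fx = _lookup("spheroid", genotype)
    kwargs = dict(
        roundness_start=fx["start"],
        roundness_plateau=fx["plateau"],
        tau_fast=fx["tau_fast"],
        tau_slow=fx["tau_slow"],
        fast_fraction=fx["fast_fraction"],
        baseline_h=fx["baseline_h"],
        noise_sd=noise_sd,
        seed=seed,
    )
    kwargs.update(overrides)
    return SpheroidParams(**kwargs)


def ca_dose_reference() -> dict[float, float]:
    """Wild-type 20 h roundness plateau per external Ca2+ concentration."""
    return {float(k): float(v) for k, v in fixture_registry()["ca_dose_wt"].items()}
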