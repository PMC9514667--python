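"""Experiment configuration: YAML/JSON schema, validation, preset resolution.

One canonical internal form (`ExperimentConfig`) is produced from either
dialect.  Validation is strict: unknown keys are rejected with itemized
errors, radical presets are resolved by name, and rates given in both
aggregate and component form must agree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .constants import GMF_UT, HMF_UT
from .model import RateSet, ReducedPairModel
from .presets import preset_radical
from .spin import HyperfineTensor, Mobility, Nucleus, Radical

__all__ = ["ExperimentConfig", "load_config", "radical_to_dict", "radical_from_dict"]

EXPERIMENTS = ("sweep", "map", "mfe", "validate")


class ConfigError(ValueError):
    """Schema violation; carries an itemized list of problems."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n" + "\n".join(f"- {p}" for p in problems))


def _check_keys(block: dict, allowed: set[str], where: str, problems: list[str]):
    for key in block:
        if key not in allowed:
            problems.append(f"unknown key {key!r} in {where}")


def radical_from_dict(spec: Any, problems: list[str], where: str) -> Radical | None:
    """Build a Radical from a preset name or an inline definition."""
    if isinstance(spec, str):
        try:
            return preset_radical(spec)
        except KeyError as exc:
            problems.append(f"{where}: {exc.args[0]}")
            return None
    if not isinstance(spec, dict):
        problems.append(f"{where}: expected preset name or mapping")
        return None
    allowed = {"preset", "label", "g_factor", "mobility", "nuclei"}
    _check_keys(spec, allowed, where, problems)
    if "preset" in spec:
        try:
            return preset_radical(spec["preset"], spec.get("mobility"))
        except KeyError as exc:
            problems.append(f"{where}: {exc.args[0]}")
            return None
    nuclei = []
    for i, nd in enumerate(spec.get("nuclei", [])):
        nwhere = f"{where}.nuclei[{i}]"
        _check_keys(nd, {"label", "multiplicity", "tensor", "a_iso"}, nwhere, problems)
        if ("tensor" in nd) == ("a_iso" in nd):
            problems.append(f"{nwhere}: give exactly one of 'tensor' or 'a_iso'")
            continue
        if "a_iso" in nd:
            tensor = HyperfineTensor.isotropic(float(nd["a_iso"]))
        else:
            mat = np.asarray(nd["tensor"], dtype=float)
            if mat.shape != (3, 3):
                problems.append(f"{nwhere}: tensor must be 3x3")
                continue
            tensor = HyperfineTensor(mat)
        try:
            nuclei.append(Nucleus(nd.get("label", f"n{i}"), int(nd["multiplicity"]), tensor))
        except (KeyError, ValueError) as exc:
            problems.append(f"{nwhere}: {exc}")
    try:
        return Radical(
            spec.get("label", "radical"),
            tuple(nuclei),
            float(spec.get("g_factor", 2.0023)),
            Mobility(spec.get("mobility", "free")),
        )
    except ValueError as exc:
        problems.append(f"{where}: {exc}")
        return None


def radical_to_dict(radical: Radical) -> dict:
    return {
        "label": radical.label,
        "g_factor": radical.g_factor,
        "mobility": radical.mobility.value,
        "nuclei": [
            {
                "label": n.label,
                "multiplicity": n.multiplicity,
                "tensor": np.asarray(n.tensor.matrix).tolist(),
            }
            for n in radical.nuclei
        ],
    }


def _rates_from_dict(block: dict, problems: list[str]) -> RateSet | None:
    allowed = {"k_X", "k_Sigma", "k_F", "k_E", "k_Ep", "k_Xp", "phi"}
    _check_keys(block, allowed, "model.rates", problems)
    if "k_X" not in block:
        problems.append("model.rates: k_X is required")
        return None
    try:
        return RateSet(
            k_X=float(block["k_X"]),
            k_sigma=float(block["k_Sigma"]) if "k_Sigma" in block else None,
            k_F=float(block.get("k_F", 0.0)),
            k_E=float(block.get("k_E", 0.0)),
            k_Ep=float(block.get("k_Ep", 0.0)),
            k_Xp=float(block.get("k_Xp", 0.0)),
            phi=float(block.get("phi", 0.0)),
        )
    except ValueError as exc:
        problems.append(f"model.rates: {exc}")
        return None


@dataclass(frozen=True)
class ExperimentConfig:
    """Validated experiment description with presets resolved."""

    experiment: str
    model: ReducedPairModel
    fields_ut: tuple[float, ...] = ()
    field_ut: float = HMF_UT
    field_ref_ut: float = GMF_UT
    k_x_grid: tuple[float, ...] = ()
    k_sigma_grid: tuple[float, ...] = ()
    n_orientations: int = 72
    output_format: str = "csv"
    log_level: str = "info"
    raw: dict = field(default_factory=dict, compare=False)


def parse_config(data: dict) -> ExperimentConfig:
    """Validate a parsed YAML/JSON mapping into an ExperimentConfig."""
    problems: list[str] = []
    if not isinstance(data, dict):
        raise ConfigError(["top level must be a mapping"])
    allowed = {
        "experiment",
        "model",
        "fields_uT",
        "field_uT",
        "field_ref_uT",
        "k_X_grid",
        "k_Sigma_grid",
        "orientations",
        "format",
        "log_level",
    }
    _check_keys(data, allowed, "top level", problems)
    experiment = data.get("experiment")
    if experiment not in EXPERIMENTS:
        problems.append(f"experiment must be one of {EXPERIMENTS}, got {experiment!r}")
    mblock = data.get("model")
    model = None
    if not isinstance(mblock, dict):
        problems.append("a 'model' mapping is required")
    else:
        _check_keys(
            mblock, {"radical1", "radical3", "rates", "phi", "relaxation"}, "model", problems
        )
        r1 = radical_from_dict(mblock.get("radical1", "flavin_3N"), problems, "model.radical1")
        r3 = radical_from_dict(mblock.get("radical3", "ascorbyl_H4"), problems, "model.radical3")
        rates = _rates_from_dict(mblock.get("rates", {}), problems)
        g1 = g3 = 0.0
        relax = mblock.get("relaxation", {})
        if relax:
            _check_keys(relax, {"gamma1", "gamma3"}, "model.relaxation", problems)
            g1 = float(relax.get("gamma1", 0.0))
            g3 = float(relax.get("gamma3", 0.0))
        if r1 and r3 and rates and not problems:
            model = ReducedPairModel(r1, r3, rates, g1, g3)
    fmt = data.get("format", "csv")
    if fmt not in ("csv", "json", "hdf5"):
        problems.append(f"format must be csv|json|hdf5, got {fmt!r}")
    n_orient = int(data.get("orientations", 72))
    if n_orient < 1:
        problems.append("orientations must be >= 1")
    if problems:
        raise ConfigError(problems)
    return ExperimentConfig(
        experiment=str(experiment),
        model=model,
        fields_ut=tuple(float(b) for b in data.get("fields_uT", ())),
        field_ut=float(data.get("field_uT", HMF_UT)),
        field_ref_ut=float(data.get("field_ref_uT", GMF_UT)),
        k_x_grid=tuple(float(k) for k in data.get("k_X_grid", ())),
        k_sigma_grid=tuple(float(k) for k in data.get("k_Sigma_grid", ())),
        n_orientations=n_orient,
        output_format=str(fmt),
        log_level=str(data.get("log_level", "info")),
        raw=dict(data),
    )


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate a YAML or JSON experiment configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return parse_config(data)


def save_config(config: ExperimentConfig, path: str | Path) -> None:
    """Write the canonical form back out (YAML or JSON by suffix)."""
    path = Path(path)
    data = dict(config.raw)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
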