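"""Configuration files, HDF5 checkpoints and spike-record export."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .connectivity import Architecture, Projection, ProjectionSpec, KernelSpec
from .network import Network
from .params import ModelParameters, PlasticityParameters, preset as make_preset
from .protocols import TrainingConfig, EvaluationConfig, StimulusPattern

__all__ = [
    "RunConfig", "ConfigurationError", "load_config", "save_config",
    "save_checkpoint", "load_checkpoint", "CheckpointError",
    "save_patterns", "load_patterns", "spikes_to_frame", "write_spikes_csv",
]

CHECKPOINT_SCHEMA = 1


class ConfigurationError(ValueError):
    """A config file referenced an unknown key or violated an invariant."""


class CheckpointError(IOError):
    """A checkpoint container is missing, corrupt or incompatible."""


@dataclass
class RunConfig:
    """Everything a reproducible run needs: preset, protocol, seed, output."""

    preset: str = "nest"
    params: ModelParameters = None
    training: TrainingConfig = field(default_factory=TrainingConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    links: list | None = None          # None -> default link table
    seed: int = 0
    outdir: str = "."
    verbosity: int = 1

    def __post_init__(self):
        if self.params is None:
            self.params = make_preset(self.preset)


def _apply_overrides(obj, overrides: dict, context: str):
    names = {f.name for f in dataclasses.fields(obj)}
    for key, value in overrides.items():
        if key not in names:
            raise ConfigurationError(f"unknown key {context}.{key}")
        if key == "plasticity":
            _apply_overrides(obj.plasticity, value, context + ".plasticity")
        else:
            expected = type(getattr(obj, key))
            if expected is tuple and isinstance(value, list):
                value = tuple(value)
            if getattr(obj, key) is not None and not isinstance(value, expected) \
                    and not (expected is float and isinstance(value, int)):
                raise ConfigurationError(
                    f"type mismatch for {context}.{key}: expected "
                    f"{expected.__name__}, got {type(value).__name__}")
            setattr(obj, key, float(value) if expected is float else value)
    return obj


def load_config(path) -> RunConfig:
    """Read a YAML run configuration.

    The ``preset`` key selects the parameter column ('felix' or 'nest');
    any other key overrides the preset default.  Unknown keys and type
    mismatches raise :class:`ConfigurationError` naming the offending key.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {"preset", "params", "training", "evaluation", "links", "seed",
             "outdir", "verbosity"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown key {sorted(unknown)[0]}")
    cfg = RunConfig(preset=raw.get("preset", "nest"))
    _apply_overrides(cfg.params, raw.get("params", {}), "params")
    _apply_overrides(cfg.training, raw.get("training", {}), "training")
    _apply_overrides(cfg.evaluation, raw.get("evaluation", {}), "evaluation")
    if "links" in raw and raw["links"] is not None:
        cfg.links = [tuple(l) for l in raw["links"]]
    cfg.seed = int(raw.get("seed", 0))
    cfg.outdir = str(raw.get("outdir", "."))
    cfg.verbosity = int(raw.get("verbosity", 1))
    try:
        cfg.params.validate()
    except ValueError as exc:
        raise ConfigurationError(str(exc)) from exc
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    doc = {
        "preset": cfg.preset,
        "params": cfg.params.to_dict(),
        "training": dataclasses.asdict(cfg.training),
        "evaluation": dataclasses.asdict(cfg.evaluation),
        "links": [list(l) for l in cfg.links] if cfg.links is not None else None,
        "seed": cfg.seed,
        "outdir": cfg.outdir,
        "verbosity": cfg.verbosity,
    }
    doc["training"]["stsi_areas"] = list(doc["training"]["stsi_areas"])
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(net: Network, path, preset_name: str | None = None) -> None:
    """Write the full network - wiring, weights, state, noise stream - to HDF5.

    A restored network continues bit-identically: the RNG state is stored
    alongside the state arrays, so simulating after a reload matches an
    uninterrupted run.
    """
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = CHECKPOINT_SCHEMA
        f.attrs["params"] = yaml.safe_dump(net.params.to_dict())
        if preset_name:
            f.attrs["preset"] = preset_name
        f.attrs["areas"] = json.dumps(list(net.arch.areas))
        f.attrs["links"] = json.dumps([list(l) for l in net.arch.links])
        f.attrs["rng_state"] = json.dumps(net.rng.bit_generator.state)
        st = f.create_group("state")
        for name in ("V_e", "om_a", "om_r", "phi", "V_i", "G"):
            st.create_dataset(name, data=getattr(net, name))
        for i, proj in enumerate(net.projections):
            g = f.create_group(f"projections/{i:04d}")
            spec = dataclasses.asdict(proj.spec)
            kern = spec.pop("kernel")
            g.attrs["spec"] = yaml.safe_dump(spec)
            g.attrs["kernel"] = yaml.safe_dump(kern) if kern else ""
            g.create_dataset("pre", data=proj.pre)
            g.create_dataset("post", data=proj.post)
            g.create_dataset("weight", data=proj.weight)


def load_checkpoint(path, expected_params: ModelParameters | None = None) -> Network:
    """Restore a network saved by :func:`save_checkpoint`.

    If ``expected_params`` is given and disagrees with the stored
    parameters, loading fails: state evolved under one parameter set is
    not portable to another.
    """
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise CheckpointError(f"cannot open checkpoint {path}: {exc}") from exc
    with f:
        version = f.attrs.get("schema_version")
        if version != CHECKPOINT_SCHEMA:
            raise CheckpointError(f"unsupported checkpoint schema {version!r}")
        params = ModelParameters.from_dict(yaml.safe_load(f.attrs["params"]))
        if expected_params is not None and expected_params.to_dict() != params.to_dict():
            raise CheckpointError(
                "checkpoint was written with a different parameter preset")
        links = tuple(tuple(l) for l in json.loads(f.attrs["links"]))
        arch = Architecture(links=links)
        projections = []
        for key in sorted(f["projections"]):
            g = f[f"projections/{key}"]
            spec_d = yaml.safe_load(g.attrs["spec"])
            kern_raw = g.attrs["kernel"]
            kernel = KernelSpec(**yaml.safe_load(kern_raw)) if kern_raw else None
            projections.append(Projection(
                spec=ProjectionSpec(**spec_d, kernel=kernel),
                pre=g["pre"][...], post=g["post"][...],
                weight=g["weight"][...]))
        net = Network(params, arch, projections)
        for name in ("V_e", "om_a", "om_r", "phi", "V_i", "G"):
            getattr(net, name)[...] = f["state"][name][...]
        net.rng.bit_generator.state = json.loads(f.attrs["rng_state"])
    return net


def save_patterns(path_or_h5, patterns) -> None:
    """Store stimulus patterns (in the checkpoint file or a separate one)."""
    own = not isinstance(path_or_h5, h5py.File)
    f = h5py.File(path_or_h5, "a") if own else path_or_h5
    try:
        if "patterns" in f:
            del f["patterns"]
        for p in patterns:
            g = f.create_group(f"patterns/{p.word_id:03d}")
            g.attrs["word_id"] = p.word_id
            g.attrs["category"] = p.category
            for area, cells in p.cells.items():
                g.create_dataset(area, data=np.asarray(cells))
    finally:
        if own:
            f.close()


def load_patterns(path_or_h5) -> list[StimulusPattern]:
    own = not isinstance(path_or_h5, h5py.File)
    f = h5py.File(path_or_h5, "r") if own else path_or_h5
    try:
        patterns = []
        for key in sorted(f["patterns"]):
            g = f[f"patterns/{key}"]
            cells = {area: g[area][...] for area in g}
            patterns.append(StimulusPattern(int(g.attrs["word_id"]),
                                            str(g.attrs["category"]), cells))
        return patterns
    finally:
        if own:
            f.close()


# ---------------------------------------------------------------------------
# spike records
# ---------------------------------------------------------------------------

def spikes_to_frame(raster: np.ndarray, areas, cells_per_area: int) -> pd.DataFrame:
    """Columnar spike record: one row per spike (time_step, area, neuron)."""
    t, e = np.nonzero(np.asarray(raster))
    return pd.DataFrame({
        "time_step": t,
        "area": [areas[i // cells_per_area] for i in e],
        "neuron_index": e % cells_per_area,
    })


def write_spikes_csv(raster: np.ndarray, path, areas, cells_per_area: int) -> None:
    spikes_to_frame(raster, areas, cells_per_area).to_csv(path, index=False)
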