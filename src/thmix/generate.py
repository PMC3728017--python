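"""Synthetic flow-cytometry-like single-cell data over an IL-12 x IL-4 matrix.

Per-cell channel intensities follow the statistical structure the analysis
stage assumes:

* TF channels (tbet, gata3) are unimodal lognormals whose medians factorize
  as F1(IL-12) x F2(IL-4) + background (rank-1 in log space after background
  subtraction).
* Cytokine channels (ifng, il4, optionally il13/il5) are bimodal: "off" cells
  sit at the autofluorescence background, "on" cells at a condition-
  independent on-level; the on/off state is a TF-biased independent coin per
  cytokine (see :mod:`thmix.two_stage`).
* A shared per-cell lognormal extrinsic factor (cell size) multiplies every
  channel; per-channel intrinsic lognormal noise is independent.

Isotype controls put every channel at background; the T-bet knockout control
puts only tbet at background.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .errors import DatasetParseError
from .two_stage import BiasFunction, CYTOKINE_TF, DEFAULT_BIASES, draw_cytokine_states

__all__ = [
    "Condition",
    "ResponseCurve",
    "SaturatingRise",
    "SaturatingFall",
    "SeparableResponse",
    "GeneratorConfig",
    "FlowSample",
    "InputMatrixDataset",
    "separable_median",
    "generate_sample",
    "generate_matrix_dataset",
    "dataset_roundtrip",
    "default_config",
    "default_grid",
    "TH1", "TH2", "MIXED",
]


@dataclass(frozen=True)
class Condition:
    """One culture condition: external IL-12 and IL-4 in ng/ml."""

    il12: float
    il4: float
    label: str = ""

    def __post_init__(self):
        if self.il12 < 0 or self.il4 < 0:
            raise ValueError("concentrations must be >= 0")


TH1 = Condition(540.0, 0.0, "Th1")
TH2 = Condition(0.0, 540.0, "Th2")
MIXED = Condition(100.0, 4.0, "mixed")


class ResponseCurve:
    """Monotone 1-D dose-response curve (callable on ng/ml)."""

    def __call__(self, conc):  # pragma: no cover - interface
        raise NotImplementedError


@dataclass(frozen=True)
class SaturatingRise(ResponseCurve):
    """baseline + amplitude * c / (c + K); monotone increasing."""

    amplitude: float
    K: float
    baseline: float = 0.0

    def __call__(self, conc):
        c = np.asarray(conc, dtype=float)
        return self.baseline + self.amplitude * c / (c + self.K)


@dataclass(frozen=True)
class SaturatingFall(ResponseCurve):
    """1 / (1 + depth * c / (c + K)); monotone decreasing from 1."""

    depth: float
    K: float

    def __call__(self, conc):
        c = np.asarray(conc, dtype=float)
        return 1.0 / (1.0 + self.depth * c / (c + self.K))


@dataclass(frozen=True)
class SeparableResponse:
    """Separable input function: median = F1(IL-12) * F2(IL-4) + background."""

    f1: Callable
    f2: Callable


# Default separable responses (arbitrary fluorescence units).  The constants
# are calibrated jointly with the backgrounds so that (relative to the 100
# a.u. TF background) the T-bet fold change under Th1 input (540, 0) is 2.5,
# the GATA3 fold change under Th2 input (0, 540) is 20, and the two fold
# changes are equal (~2.19) at the mixed condition (100, 4) -- which pins the
# normalized GATA3/T-bet ratio statistic at ~0.4, ~20 and ~1 respectively.
_DEFAULT_RESPONSES: Mapping[str, SeparableResponse] = {
    # increasing in IL-12, weakly decreasing in IL-4
    "tbet": SeparableResponse(SaturatingRise(158.33, 30.0),
                              SaturatingFall(0.3, 40.0)),
    # increasing in IL-4, weakly increasing in IL-12
    "gata3": SeparableResponse(SaturatingRise(0.2, 100.0, baseline=1.0),
                               SaturatingRise(2169.1, 76.498)),
}
# For gata3 the (f1, f2) roles are (IL-12 modifier, IL-4 drive); medians are
# computed as f1(il12) * f2(il4) regardless, so both channels share one code
# path and the log-median matrix stays exactly rank-1.


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic generator."""

    sigma_intrinsic: float = 0.2
    sigma_extrinsic: float = 0.35
    backgrounds: Mapping[str, float] = field(default_factory=lambda: {
        "tbet": 100.0, "gata3": 100.0, "ifng": 80.0, "il4": 80.0,
        "il13": 80.0, "il5": 80.0})
    on_medians: Mapping[str, float] = field(default_factory=lambda: {
        "ifng": 2400.0, "il4": 2400.0, "il13": 2400.0, "il5": 2400.0})
    responses: Mapping[str, SeparableResponse] = field(
        default_factory=lambda: dict(_DEFAULT_RESPONSES))
    biases: Mapping[str, BiasFunction] = field(
        default_factory=lambda: dict(DEFAULT_BIASES))
    include_il13: bool = True
    include_il5: bool = False
    persistence_rho: float = 0.2

    def __post_init__(self):
        if self.sigma_intrinsic < 0 or self.sigma_extrinsic < 0:
            raise ValueError("sigmas must be >= 0")
        for cyt, on in self.on_medians.items():
            if on <= self.backgrounds.get(cyt, 0.0):
                raise ValueError(f"on-level median for {cyt} must exceed background")

    @property
    def sigma_total(self) -> float:
        return math.hypot(self.sigma_intrinsic, self.sigma_extrinsic)

    @property
    def cytokines(self) -> tuple:
        out = ["ifng", "il4"]
        if self.include_il13:
            out.append("il13")
        if self.include_il5:
            out.append("il5")
        return tuple(out)

    @property
    def tf_channels(self) -> tuple:
        return ("tbet", "gata3")

    @property
    def channels(self) -> tuple:
        return self.tf_channels + self.cytokines


def default_config() -> GeneratorConfig:
    return GeneratorConfig()


def default_grid() -> np.ndarray:
    """8-point per-axis input grid: zero plus log-spaced up to 540 ng/ml."""
    return np.concatenate([[0.0], np.geomspace(1.0, 540.0, 7)])


def separable_median(condition: Condition, response: SeparableResponse,
                     channel: str, config: GeneratorConfig | None = None) -> float:
    """Median channel intensity F1(il12) * F2(il4) + background."""
    config = config or default_config()
    if channel not in config.backgrounds:
        raise ValueError(f"unknown channel {channel!r}")
    return (float(response.f1(condition.il12)) * float(response.f2(condition.il4))
            + config.backgrounds[channel])


@dataclass
class FlowSample:
    """Per-cell channel intensities for one culture condition."""

    cells: pd.DataFrame
    condition: Condition
    sample_kind: str  # experiment | isotype | knockout
    seed: int
    extrinsic: np.ndarray | None = None  # latent per-cell size factor
    states: pd.DataFrame | None = None   # latent true cytokine coin states

    def __post_init__(self):
        if self.sample_kind not in ("experiment", "isotype", "knockout"):
            raise ValueError(f"bad sample_kind {self.sample_kind!r}")

    def __len__(self):
        return len(self.cells)

    @property
    def key(self) -> str:
        return sample_key(self.condition, self.sample_kind)


def sample_key(condition: Condition, kind: str) -> str:
    if kind != "experiment":
        return kind
    return f"il12_{condition.il12:g}_il4_{condition.il4:g}"


def _tf_median(channel: str, condition: Condition, config: GeneratorConfig) -> float:
    return separable_median(condition, config.responses[channel], channel, config)


def generate_sample(condition: Condition, config: GeneratorConfig,
                    n_cells: int, seed: int,
                    sample_kind: str = "experiment") -> FlowSample:
    """Generate one synthetic sample of ``n_cells`` cells.

    Intensities are median * extrinsic * intrinsic lognormal noise, with the
    additive background folded into the median (so sample medians match the
    configured medians and all intensities stay > 0).  Cytokine on/off states
    come from :func:`thmix.two_stage.draw_cytokine_states` applied to the
    realized per-cell TF levels.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    rng = np.random.default_rng(seed)
    n = int(n_cells)
    E = np.exp(config.sigma_extrinsic * rng.standard_normal(n))

    def noisy(median):
        return median * E * np.exp(config.sigma_intrinsic * rng.standard_normal(n))

    data = {}
    for ch in config.tf_channels:
        if sample_kind == "isotype" or (sample_kind == "knockout" and ch == "tbet"):
            med = config.backgrounds[ch]
        else:
            med = _tf_median(ch, condition, config)
        data[ch] = noisy(med)

    if sample_kind == "isotype":
        states = pd.DataFrame({f"{c}_on": np.zeros(n, dtype=np.int8)
                               for c in config.cytokines})
    else:
        tf_table = pd.DataFrame({c: data[c] for c in config.tf_channels})
        biases = {c: config.biases[c] for c in config.cytokines}
        states = draw_cytokine_states(tf_table, biases,
                                      seed=int(rng.integers(2 ** 31)))
    for cyt in config.cytokines:
        on = states[f"{cyt}_on"].to_numpy().astype(bool)
        med = np.where(on, config.on_medians[cyt], config.backgrounds[cyt])
        data[cyt] = noisy(med)

    cells = pd.DataFrame(data)
    cells.insert(0, "cell_id", np.arange(n))
    return FlowSample(cells=cells, condition=condition, sample_kind=sample_kind,
                      seed=int(seed), extrinsic=E, states=states)


@dataclass
class InputMatrixDataset:
    """FlowSamples over an IL-12 x IL-4 grid plus isotype/knockout controls."""

    samples: dict  # key -> FlowSample (experiment samples)
    isotype: FlowSample
    knockout: FlowSample
    il12_grid: np.ndarray
    il4_grid: np.ndarray
    master_seed: int
    config: GeneratorConfig

    def __iter__(self):
        return iter(self.samples.values())

    def __len__(self):
        return len(self.samples)

    def all_samples(self):
        return list(self.samples.values()) + [self.isotype, self.knockout]

    def sample_at(self, il12: float, il4: float) -> FlowSample:
        return self.samples[sample_key(Condition(il12, il4), "experiment")]


def generate_matrix_dataset(config: GeneratorConfig, il12_grid, il4_grid,
                            n_cells: int, seed: int) -> InputMatrixDataset:
    """One experiment sample per grid point plus isotype and knockout controls.

    Per-sample seeds are spawned deterministically from the master seed, so
    identical master seeds give bit-identical datasets.
    """
    il12_grid = np.asarray(il12_grid, dtype=float)
    il4_grid = np.asarray(il4_grid, dtype=float)
    if il12_grid.size == 0 or il4_grid.size == 0:
        raise ValueError("grids must be nonempty")
    ss = np.random.SeedSequence(seed)
    n_samples = il12_grid.size * il4_grid.size + 2
    child_seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(n_samples)]
    samples = {}
    k = 0
    for c12 in il12_grid:
        for c4 in il4_grid:
            cond = Condition(float(c12), float(c4))
            s = generate_sample(cond, config, n_cells, child_seeds[k])
            samples[s.key] = s
            k += 1
    isotype = generate_sample(Condition(0.0, 0.0, "isotype"), config, n_cells,
                              child_seeds[k], sample_kind="isotype")
    knockout = generate_sample(TH1, config, n_cells, child_seeds[k + 1],
                               sample_kind="knockout")
    return InputMatrixDataset(samples, isotype, knockout, il12_grid, il4_grid,
                              int(seed), config)


# ---------------------------------------------------------------------------
# serialization: one TSV per sample with a '#'-prefixed metadata header block,
# plus a JSON manifest listing all files and the master seed.

_REQUIRED_META = ("il12_ng_ml", "il4_ng_ml", "sample_kind", "seed")


def write_sample(sample: FlowSample, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# il12_ng_ml\t{sample.condition.il12:.17g}\n")
        fh.write(f"# il4_ng_ml\t{sample.condition.il4:.17g}\n")
        fh.write(f"# label\t{sample.condition.label}\n")
        fh.write(f"# sample_kind\t{sample.sample_kind}\n")
        fh.write(f"# seed\t{sample.seed}\n")
        sample.cells.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_sample(path) -> FlowSample:
    path = Path(path)
    meta = {}
    n_meta = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_meta += 1
            parts = line[1:].strip().split("\t")
            if len(parts) == 2:
                meta[parts[0]] = parts[1]
            elif len(parts) == 1:
                meta[parts[0]] = ""
    for key in _REQUIRED_META:
        if key not in meta:
            raise DatasetParseError(f"missing metadata key {key!r}", path=path,
                                    line=n_meta + 1)
    cells = pd.read_csv(path, sep="\t", skiprows=n_meta)
    for col in ("cell_id", "tbet", "gata3", "ifng", "il4"):
        if col not in cells.columns:
            raise DatasetParseError(f"missing required column", path=path,
                                    line=n_meta + 1, column=col)
    cond = Condition(float(meta["il12_ng_ml"]), float(meta["il4_ng_ml"]),
                     meta.get("label", ""))
    return FlowSample(cells=cells, condition=cond,
                      sample_kind=meta["sample_kind"], seed=int(meta["seed"]))


def config_hash(config: GeneratorConfig) -> str:
    blob = json.dumps(_config_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _config_dict(config: GeneratorConfig) -> dict:
    def enc(v):
        if isinstance(v, (SaturatingRise, SaturatingFall, BiasFunction)):
            return {"type": type(v).__name__, **vars(v)}
        if isinstance(v, SeparableResponse):
            return {"f1": enc(v.f1), "f2": enc(v.f2)}
        if isinstance(v, Mapping):
            return {k: enc(x) for k, x in v.items()}
        return v
    return {k: enc(v) for k, v in vars(config).items()}


def write_dataset(dataset: InputMatrixDataset, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    files = {}
    for s in dataset.all_samples():
        fname = f"{s.key}.tsv"
        write_sample(s, path / fname)
        files[s.key] = fname
    manifest = {
        "master_seed": dataset.master_seed,
        "il12_grid": [float(v) for v in dataset.il12_grid],
        "il4_grid": [float(v) for v in dataset.il4_grid],
        "config_hash": config_hash(dataset.config),
        "config": _config_dict(dataset.config),
        "files": files,
    }
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
        fh.write("\n")


def read_dataset(path) -> InputMatrixDataset:
    path = Path(path)
    mpath = path / "manifest.json"
    if not mpath.exists():
        raise DatasetParseError("manifest.json not found", path=path)
    with open(mpath) as fh:
        manifest = json.load(fh)
    samples = {}
    isotype = knockout = None
    for key, fname in manifest["files"].items():
        s = read_sample(path / fname)
        if s.sample_kind == "isotype":
            isotype = s
        elif s.sample_kind == "knockout":
            knockout = s
        else:
            samples[key] = s
    if isotype is None or knockout is None:
        raise DatasetParseError("control samples missing from manifest", path=path)
    return InputMatrixDataset(
        samples, isotype, knockout,
        np.asarray(manifest["il12_grid"], dtype=float),
        np.asarray(manifest["il4_grid"], dtype=float),
        int(manifest["master_seed"]),
        default_config(),  # full config round-trip is informational only
    )


def dataset_roundtrip(dataset: InputMatrixDataset, path) -> InputMatrixDataset:
    """Write the dataset to ``path`` and read it back."""
    write_dataset(dataset, path)
    return read_dataset(path)
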