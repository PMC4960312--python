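"""Flat key-value run configuration.

A single plain-text file fully determines a pipeline run. Lines are
``key=value``; sections use dotted prefixes; ``#`` starts a comment.
``seed`` is mandatory. Example::

    seed=42
    mode=amplitude_only
    n_nmjs=10
    genotype.control.n_rrp=300
    genotype.dlrrk_oe.n_rrp=530
    protocol.vm.ca_levels=0.5,1.0,1.5,2.0,2.5,3.0
    protocol.vm.n_stim=20
    analysis.k_noise=2.0

Unlisted genotype fields fall back to :class:`~nmjquant.simulate.GroundTruth`
defaults, so a genotype block only needs the parameters that differ.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

from .errors import FormatError, ValidationError
from .simulate import GroundTruth

__all__ = ["AnalysisParams", "ProtocolParams", "RunConfig", "load_config", "dump_config", "default_config"]


@dataclass(frozen=True)
class AnalysisParams:
    """Analysis constants applied downstream of simulation/detection."""

    k_noise: float = 2.0  # failure criterion: noise mean + k * noise sd
    mini_pct: float = 5.0  # failure criterion: mini-distribution percentile
    threshold_k: float = 4.5  # mini detection threshold in sample-noise s.d.
    alpha_var: float = 0.05  # variance-test level for branch selection
    vm_weights: str = "invvar"  # parabola weighting: invvar | none | n_events
    noise_method: str = "range"  # window statistic: range | sd
    qc_ca_mm: float = 0.5  # calcium level used for the direct QC ratio

    def __post_init__(self) -> None:
        if self.k_noise < 0 or self.threshold_k <= 0:
            raise ValidationError("k_noise must be >= 0 and threshold_k > 0")
        if not 0 < self.alpha_var < 1:
            raise ValidationError("alpha_var must be in (0, 1)")
        if not 0 < self.mini_pct < 50:
            raise ValidationError("mini_pct must be in (0, 50)")
        if self.vm_weights not in ("invvar", "none", "n_events"):
            raise ValidationError("vm_weights must be 'invvar', 'none' or 'n_events'")
        if self.noise_method not in ("range", "sd"):
            raise ValidationError("noise_method must be 'range' or 'sd'")


@dataclass(frozen=True)
class ProtocolParams:
    """Protocol geometry shared by all genotypes in a run."""

    vm_ca_levels: tuple = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
    vm_n_stim: int = 100
    failure_ca_mm: float = 0.25
    failure_n_stim: int = 300
    train_ca_mm: float = 3.0
    train_n_stim: int = 30
    spontaneous_duration_s: float = 60.0

    def __post_init__(self) -> None:
        if len(self.vm_ca_levels) < 2:
            raise ValidationError("need >= 2 calcium levels for variance-mean analysis")


@dataclass
class RunConfig:
    seed: int = 0
    mode: str = "amplitude_only"
    n_nmjs: int = 10
    genotypes: dict = field(default_factory=dict)  # label -> GroundTruth
    protocol: ProtocolParams = field(default_factory=ProtocolParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    sample_rate_hz: float = 10000.0

    def __post_init__(self) -> None:
        if self.mode not in ("amplitude_only", "full_trace"):
            raise ValidationError("mode must be amplitude_only or full_trace")
        if self.n_nmjs < 1:
            raise ValidationError("n_nmjs must be >= 1")

    def config_hash(self) -> str:
        return hashlib.sha256(dump_config(self).encode()).hexdigest()[:16]


_GT_FIELDS = {f.name: f.type for f in dataclasses.fields(GroundTruth)}


def _parse_value(key: str, value: str):
    if "," in value:
        return tuple(float(v) for v in value.split(",") if v.strip())
    for caster in (int, float):
        try:
            return caster(value)
        except ValueError:
            continue
    return value


def load_config(path) -> RunConfig:
    """Parse a key-value config file into a validated :class:`RunConfig`."""
    text = Path(path).read_text(encoding="utf-8")
    flat: dict[str, object] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"{path}: line {lineno} is not key=value: {raw!r}")
        key, _, value = line.partition("=")
        flat[key.strip()] = _parse_value(key.strip(), value.strip())
    return config_from_flat(flat, source=str(path))


def config_from_flat(flat: dict, source: str = "<dict>") -> RunConfig:
    if "seed" not in flat:
        raise ValidationError(f"{source}: 'seed' is a mandatory config entry")
    geno_fields: dict[str, dict] = {}
    proto_kwargs: dict[str, object] = {}
    ana_kwargs: dict[str, object] = {}
    top: dict[str, object] = {}
    proto_map = {
        "vm.ca_levels": "vm_ca_levels",
        "vm.n_stim": "vm_n_stim",
        "failure.ca_mm": "failure_ca_mm",
        "failure.n_stim": "failure_n_stim",
        "train.ca_mm": "train_ca_mm",
        "train.n_stim": "train_n_stim",
        "spontaneous.duration_s": "spontaneous_duration_s",
    }
    for key, value in flat.items():
        if key.startswith("genotype."):
            _, label, fname = key.split(".", 2)
            if fname not in _GT_FIELDS:
                raise ValidationError(f"{source}: unknown ground-truth field {fname!r} in {key!r}")
            geno_fields.setdefault(label, {})[fname] = value
        elif key.startswith("protocol."):
            sub = key.split(".", 1)[1]
            if sub not in proto_map:
                raise ValidationError(f"{source}: unknown protocol key {key!r}")
            proto_kwargs[proto_map[sub]] = value
        elif key.startswith("analysis."):
            sub = key.split(".", 1)[1]
            if sub not in {f.name for f in dataclasses.fields(AnalysisParams)}:
                raise ValidationError(f"{source}: unknown analysis key {key!r}")
            ana_kwargs[sub] = value
        elif key in ("seed", "mode", "n_nmjs", "sample_rate_hz"):
            top[key] = value
        else:
            raise ValidationError(f"{source}: unknown config key {key!r}")
    if not geno_fields:
        raise ValidationError(f"{source}: at least one genotype block is required")
    if isinstance(proto_kwargs.get("vm_ca_levels"), (int, float)):
        proto_kwargs["vm_ca_levels"] = (float(proto_kwargs["vm_ca_levels"]),)
    genotypes = {}
    for label, kwargs in geno_fields.items():
        if "n_rrp" in kwargs:
            kwargs["n_rrp"] = int(kwargs["n_rrp"])
        genotypes[label] = GroundTruth(**kwargs)
    return RunConfig(
        seed=int(top["seed"]),
        mode=str(top.get("mode", "amplitude_only")),
        n_nmjs=int(top.get("n_nmjs", 10)),
        genotypes=genotypes,
        protocol=ProtocolParams(**proto_kwargs),
        analysis=AnalysisParams(**ana_kwargs),
        sample_rate_hz=float(top.get("sample_rate_hz", 10000.0)),
    )


def dump_config(config: RunConfig) -> str:
    """Serialize a config to canonical key-value text (hash-stable)."""
    lines = [
        f"seed={config.seed}",
        f"mode={config.mode}",
        f"n_nmjs={config.n_nmjs}",
        f"sample_rate_hz={config.sample_rate_hz:g}",
    ]
    for label in sorted(config.genotypes):
        gt = config.genotypes[label]
        for f in dataclasses.fields(GroundTruth):
            lines.append(f"genotype.{label}.{f.name}={getattr(gt, f.name):g}")
    p = config.protocol
    lines += [
        "protocol.vm.ca_levels=" + ",".join(f"{c:g}" for c in p.vm_ca_levels),
        f"protocol.vm.n_stim={p.vm_n_stim}",
        f"protocol.failure.ca_mm={p.failure_ca_mm:g}",
        f"protocol.failure.n_stim={p.failure_n_stim}",
        f"protocol.train.ca_mm={p.train_ca_mm:g}",
        f"protocol.train.n_stim={p.train_n_stim}",
        f"protocol.spontaneous.duration_s={p.spontaneous_duration_s:g}",
    ]
    a = config.analysis
    for f in dataclasses.fields(AnalysisParams):
        v = getattr(a, f.name)
        lines.append(f"analysis.{f.name}={v:g}" if isinstance(v, float) else f"analysis.{f.name}={v}")
    return "\n".join(lines) + "\n"


def default_config(seed: int = 42, n_nmjs: int = 10) -> RunConfig:
    """Two-genotype default: a control cohort and an RRP-enlarged cohort
    (~1.7-fold, the retrograde-enhancement effect size)."""
    return RunConfig(
        seed=seed,
        n_nmjs=n_nmjs,
        genotypes={
            "control": GroundTruth(n_rrp=300),
            "dlrrk_oe": GroundTruth(n_rrp=530),
        },
    )
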