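"""Campaign configuration: YAML parsing, validation, defaults.

Defaults mirror the reference octapeptide campaign: chain length 8, poly-Ala
start, temperature ladder kBT = 0.2/0.4/0.6 kcal/mol, 100 optimization steps,
9 independent runs; rescoring at kBT = 0.6 over the last 10 configurations of
10 runs of 100 steps.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .backends import (
    DockingConfig,
    SITE_BINDING,
    SITE_CONTROL,
    SyntheticLandscape,
    generate_landscape,
    read_landscape,
)
from .sequence import CANONICAL_AA
from .thermo import RT_ROOM


class ConfigError(ValueError):
    """Configuration validation failure; the message names the offending field."""


@dataclass
class RescoreConfig:
    kBT: float = 0.6
    n_runs: int = 10
    n_steps: int = 100
    retain_last: int = 10


@dataclass
class CampaignConfig:
    length: int = 8
    start_sequence: str = "AAAAAAAA"
    alphabet: str = CANONICAL_AA
    ladder: list[float] = field(default_factory=lambda: [0.2, 0.4, 0.6])
    n_steps: int = 100
    n_runs: int = 9
    seed: int = 0
    rt: float = RT_ROOM
    rescore: RescoreConfig = field(default_factory=RescoreConfig)
    backend: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        """Stable short hash of the full configuration, for output headers."""
        canon = repr(
            (
                self.length,
                self.start_sequence,
                self.alphabet,
                tuple(self.ladder),
                self.n_steps,
                self.n_runs,
                self.seed,
                self.rt,
                (
                    self.rescore.kBT,
                    self.rescore.n_runs,
                    self.rescore.n_steps,
                    self.rescore.retain_last,
                ),
                tuple(sorted((k, repr(v)) for k, v in self.backend.items())),
            )
        )
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _require(data: dict, key: str, kind, where: str):
    if key not in data:
        raise ConfigError(f"missing required field {where}{key!r}")
    value = data[key]
    if kind is float and isinstance(value, int):
        value = float(value)
    if not isinstance(value, kind):
        raise ConfigError(
            f"field {where}{key!r} must be {getattr(kind, '__name__', kind)}, "
            f"got {type(value).__name__}"
        )
    return value


def load_config(path: str | Path) -> CampaignConfig:
    """Load and validate a YAML campaign configuration.

    Every field is optional except those listed in the file; unknown fields
    raise, so typos fail loudly rather than silently using a default.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    known = {
        "length",
        "start_sequence",
        "alphabet",
        "ladder",
        "n_steps",
        "n_runs",
        "seed",
        "rt",
        "rescore",
        "backend",
    }
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config fields: {sorted(unknown)}")

    cfg = CampaignConfig()
    if "length" in raw:
        cfg.length = _require(raw, "length", int, "")
    if "alphabet" in raw:
        cfg.alphabet = str(_require(raw, "alphabet", str, ""))
    if "start_sequence" in raw:
        cfg.start_sequence = str(_require(raw, "start_sequence", str, "")).upper()
    elif "length" in raw:
        cfg.start_sequence = "A" * cfg.length
    if "ladder" in raw:
        ladder = _require(raw, "ladder", list, "")
        if not ladder:
            raise ConfigError("field 'ladder' must be a non-empty list of kBT values")
        try:
            cfg.ladder = [float(t) for t in ladder]
        except (TypeError, ValueError):
            raise ConfigError("field 'ladder' entries must be numbers") from None
    for key in ("n_steps", "n_runs", "seed"):
        if key in raw:
            setattr(cfg, key, _require(raw, key, int, ""))
    if "rt" in raw:
        cfg.rt = float(_require(raw, "rt", float, ""))
    if "rescore" in raw:
        block = _require(raw, "rescore", dict, "")
        unknown = set(block) - {"kBT", "n_runs", "n_steps", "retain_last"}
        if unknown:
            raise ConfigError(f"unknown rescore fields: {sorted(unknown)}")
        rc = RescoreConfig()
        if "kBT" in block:
            rc.kBT = float(_require(block, "kBT", float, "rescore."))
        for key in ("n_runs", "n_steps", "retain_last"):
            if key in block:
                setattr(rc, key, _require(block, key, int, "rescore."))
        cfg.rescore = rc
    if "backend" in raw:
        cfg.backend = _require(raw, "backend", dict, "")

    _validate(cfg)
    return cfg


def _validate(cfg: CampaignConfig) -> None:
    if cfg.length < 1:
        raise ConfigError("field 'length' must be >= 1")
    if len(cfg.start_sequence) != cfg.length:
        raise ConfigError(
            f"field 'start_sequence' has length {len(cfg.start_sequence)}, "
            f"expected 'length' = {cfg.length}"
        )
    if any(t <= 0 for t in cfg.ladder):
        raise ConfigError("field 'ladder' temperatures must all be > 0")
    if len(set(cfg.ladder)) != len(cfg.ladder):
        raise ConfigError("field 'ladder' temperatures must be distinct")
    if cfg.n_steps < 0:
        raise ConfigError("field 'n_steps' must be >= 0")
    if cfg.n_runs < 1:
        raise ConfigError("field 'n_runs' must be >= 1")
    if cfg.rescore.retain_last < 1 or cfg.rescore.retain_last > cfg.rescore.n_steps:
        raise ConfigError("field 'rescore.retain_last' must be in [1, rescore.n_steps]")


def build_backend(cfg: CampaignConfig) -> SyntheticLandscape:
    """Materialize the scoring backend named by the config's ``backend`` block.

    ``type: synthetic`` (default) draws a landscape from the generator
    (parameters under ``landscape:``, seeded from the campaign seed unless a
    ``seed`` is given) or loads one from ``table: <path>``.  ``type: external``
    names a docking-adapter stub; only its metadata is validated here — running
    an external engine is the adapter's job, not the core's.
    """
    block = dict(cfg.backend)
    kind = block.pop("type", "synthetic")
    if kind == "synthetic":
        if "table" in block:
            return read_landscape(block["table"])
        params = dict(block.pop("landscape", {}))
        params.setdefault("length", cfg.length)
        params.setdefault("alphabet", cfg.alphabet)
        params.setdefault("seed", cfg.seed)
        return generate_landscape(**params)
    if kind == "external":
        raise ConfigError(
            "external docking adapters carry metadata only in this build; "
            "use backend type 'synthetic'"
        )
    raise ConfigError(f"unknown backend type {kind!r}")


def site_configs(cfg: CampaignConfig) -> tuple[DockingConfig, DockingConfig]:
    """Binding-site and control-site :class:`DockingConfig` pair from the config.

    Box geometry defaults mirror a 25×25×25 Å search box centred on the target
    site; adapters receive these verbatim, the synthetic backend ignores them.
    """

    def one(site: str) -> DockingConfig:
        block = dict(cfg.backend.get(site, {}))
        return DockingConfig(
            site_label=site,
            box_center=tuple(block.get("box_center", (0.0, 0.0, 0.0))),
            box_size=tuple(block.get("box_size", (25.0, 25.0, 25.0))),
            exhaustiveness=int(block.get("exhaustiveness", 10)),
            energy_range=float(block.get("energy_range", 4.0)),
            receptor_path=block.get("receptor"),
        )

    return one(SITE_BINDING), one(SITE_CONTROL)
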