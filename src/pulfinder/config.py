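"""Run configuration shared by every pipeline stage.

The whole pipeline is driven by a single plain-text ``key = value`` file
(list values ';'-separated, ``#`` comments).  Every key has a shipped
default (``data/default.cfg``); unknown keys are rejected so typos fail
loudly rather than silently falling back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path


class ConfigError(ValueError):
    """Raised for unknown keys, bad values, or inconsistent role maps."""


# keys whose values are ';'-separated lists
_LIST_KEYS = {
    "role.susc.require",
    "role.susd.any",
    "role.sulfatase.any",
    "role.htcs.require",
    "role.ecf_sigma.require",
    "role.anti_sigma.any",
}
_INT_KEYS = {"gap.max_gap_genes", "gap.max_gap_bp", "gap.pair_max_gap_genes"}
_FLOAT_KEYS = {"growth.baseline_delta", "growth.plateau_eps", "sec.extrapolation_margin"}
_STR_KEYS = {"gap.pair_orientation"}


@dataclass(frozen=True)
class RoleConfig:
    """Domain-accession signatures that assign a semantic role to a gene."""

    susc_require: frozenset[str]
    susd_any: frozenset[str]
    sulfatase_any: frozenset[str]
    htcs_require: frozenset[str]
    ecf_sigma_require: frozenset[str]
    anti_sigma_any: frozenset[str]


@dataclass(frozen=True)
class GapConfig:
    """Locus-extension rule: how far a PUL reaches beyond its SusC/D pair."""

    max_gap_genes: int = 2
    max_gap_bp: int = 5000
    pair_max_gap_genes: int = 0
    pair_orientation: str = "transcription"  # or "plus_coordinate"

    def __post_init__(self) -> None:
        if self.pair_orientation not in ("transcription", "plus_coordinate"):
            raise ConfigError(
                f"gap.pair_orientation must be 'transcription' or "
                f"'plus_coordinate', got {self.pair_orientation!r}"
            )
        if self.max_gap_genes < 0 or self.max_gap_bp < 0 or self.pair_max_gap_genes < 0:
            raise ConfigError("gap rule values must be non-negative")


@dataclass(frozen=True)
class RunConfig:
    """Union of all module configuration, parsed and typed."""

    roles: RoleConfig
    gaps: GapConfig
    # substrate name -> (core families, accessory families)
    substrates: dict[str, tuple[frozenset[str], frozenset[str]]]
    growth_baseline_delta: float = 0.05
    growth_plateau_eps: float = 0.02
    sec_extrapolation_margin: float = 0.1
    raw: dict[str, object] = field(default_factory=dict, repr=False, compare=False)


def parse_config_text(text: str) -> dict[str, object]:
    """Parse the key=value dialect into a flat dict (typed values)."""
    values: dict[str, object] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {line!r}")
        key, _, raw = line.partition("=")
        key = key.strip()
        raw = raw.strip()
        if key in _LIST_KEYS:
            values[key] = [tok.strip() for tok in raw.split(";") if tok.strip()]
        elif key in _INT_KEYS:
            try:
                values[key] = int(raw)
            except ValueError as exc:
                raise ConfigError(f"line {lineno}: {key} needs an integer") from exc
        elif key in _FLOAT_KEYS:
            try:
                values[key] = float(raw)
            except ValueError as exc:
                raise ConfigError(f"line {lineno}: {key} needs a number") from exc
        elif key in _STR_KEYS:
            values[key] = raw
        elif key.startswith("substrate.") and key.count(".") == 2:
            _, name, part = key.split(".")
            if part not in ("core", "accessory"):
                raise ConfigError(f"line {lineno}: unknown substrate key {key!r}")
            values[key] = [tok.strip() for tok in raw.split(";") if tok.strip()]
        else:
            raise ConfigError(f"line {lineno}: unknown configuration key {key!r}")
    return values


def _default_text() -> str:
    return resources.files("pulfinder.data").joinpath("default.cfg").read_text()


def _build(values: dict[str, object]) -> RunConfig:
    roles = RoleConfig(
        susc_require=frozenset(values["role.susc.require"]),
        susd_any=frozenset(values["role.susd.any"]),
        sulfatase_any=frozenset(values["role.sulfatase.any"]),
        htcs_require=frozenset(values["role.htcs.require"]),
        ecf_sigma_require=frozenset(values["role.ecf_sigma.require"]),
        anti_sigma_any=frozenset(values["role.anti_sigma.any"]),
    )
    if not roles.susc_require or not roles.susd_any:
        raise ConfigError("SusC/SusD signatures must be non-empty")
    gaps = GapConfig(
        max_gap_genes=values["gap.max_gap_genes"],
        max_gap_bp=values["gap.max_gap_bp"],
        pair_max_gap_genes=values["gap.pair_max_gap_genes"],
        pair_orientation=values["gap.pair_orientation"],
    )
    names = {k.split(".")[1] for k in values if k.startswith("substrate.")}
    substrates: dict[str, tuple[frozenset[str], frozenset[str]]] = {}
    for name in sorted(names):
        core = frozenset(values.get(f"substrate.{name}.core", []))
        accessory = frozenset(values.get(f"substrate.{name}.accessory", []))
        if not core:
            raise ConfigError(f"substrate {name!r} has an empty core family set")
        if core & accessory:
            raise ConfigError(f"substrate {name!r}: core and accessory overlap")
        substrates[name] = (core, accessory)
    return RunConfig(
        roles=roles,
        gaps=gaps,
        substrates=substrates,
        growth_baseline_delta=values["growth.baseline_delta"],
        growth_plateau_eps=values["growth.plateau_eps"],
        sec_extrapolation_margin=values["sec.extrapolation_margin"],
        raw=dict(values),
    )


def default_config() -> RunConfig:
    """The shipped defaults."""
    return _build(parse_config_text(_default_text()))


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a config file layered over the shipped defaults.

    Keys present in *path* override the default; absent keys keep their
    shipped value, so a user file only needs the keys it changes.
    """
    values = parse_config_text(_default_text())
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(p)
        values.update(parse_config_text(p.read_text()))
    return _build(values)
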