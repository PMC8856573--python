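"""YAML run configuration: sequence parameters and tissue relaxometry.

Schema (all keys optional; omitted values fall back to the defaults)::

    sequence:
      mprage:    {alpha_deg, te_ms, ti_ms, tr_ms}
      spin_echo: {te_ms, tr_ms}
    tissues:
      wm:  {t1_ms, t2_ms, t2star_ms, rho}
      gm:  {t1_ms, t2_ms, t2star_ms, rho}
      csf: {t1_ms, t2_ms, t2star_ms, rho}

Unknown keys are rejected rather than ignored, so a typo cannot
silently leave a parameter at its default. Relaxometry overrides exist
because tissue T1/T2 shift with age and pathology; the defaults are 3T
healthy-adult values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .exceptions import ConfigError
from .signal_models import (
    MPRAGEParams,
    PropertyRegistry,
    SpinEchoParams,
    TissueProperties,
    default_mprage,
    default_registry,
    default_spin_echo,
)

__all__ = ["RunConfig", "default_config", "load_config"]

_TISSUE_KEYS = {"t1_ms", "t2_ms", "t2star_ms", "rho"}
_MPRAGE_KEYS = {"alpha_deg", "te_ms", "ti_ms", "tr_ms"}
_SE_KEYS = {"te_ms", "tr_ms"}


@dataclass(frozen=True)
class RunConfig:
    mprage: MPRAGEParams
    spin_echo: SpinEchoParams
    registry: PropertyRegistry


def default_config() -> RunConfig:
    return RunConfig(
        mprage=default_mprage(),
        spin_echo=default_spin_echo(),
        registry=default_registry(),
    )


def _check_keys(section: str, mapping: dict, allowed: set) -> None:
    if not isinstance(mapping, dict):
        raise ConfigError(f"section '{section}' must be a mapping")
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section '{section}' "
            f"(allowed: {sorted(allowed)})"
        )


def _tissue(section: str, mapping: dict, base: TissueProperties) -> TissueProperties:
    _check_keys(section, mapping, _TISSUE_KEYS)
    return TissueProperties(
        t1=float(mapping.get("t1_ms", base.t1)),
        t2=float(mapping.get("t2_ms", base.t2)),
        t2star=float(mapping.get("t2star_ms", base.t2star)),
        rho=float(mapping.get("rho", base.rho)),
    )


def load_config(path) -> RunConfig:
    """Parse a YAML config file into a validated :class:`RunConfig`."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except FileNotFoundError:
        raise ConfigError(f"config file not found: {path}") from None
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path} as YAML: {exc}") from exc
    if raw is None:
        return default_config()
    _check_keys("<root>", raw, {"sequence", "tissues"})

    cfg = default_config()
    mprage, spin_echo, registry = cfg.mprage, cfg.spin_echo, cfg.registry

    try:
        return _parse_body(raw, mprage, spin_echo, registry)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid parameter values in {path}: {exc}") from exc


def _parse_body(raw, mprage, spin_echo, registry) -> RunConfig:
    seq = raw.get("sequence", {})
    _check_keys("sequence", seq, {"mprage", "spin_echo"})
    if "mprage" in seq:
        _check_keys("sequence.mprage", seq["mprage"], _MPRAGE_KEYS)
        mp = seq["mprage"]
        mprage = MPRAGEParams(
            alpha_deg=float(mp.get("alpha_deg", mprage.alpha_deg)),
            te_ms=float(mp.get("te_ms", mprage.te_ms)),
            ti_ms=float(mp.get("ti_ms", mprage.ti_ms)),
            tr_ms=float(mp.get("tr_ms", mprage.tr_ms)),
        )
    if "spin_echo" in seq:
        _check_keys("sequence.spin_echo", seq["spin_echo"], _SE_KEYS)
        se = seq["spin_echo"]
        spin_echo = SpinEchoParams(
            te_ms=float(se.get("te_ms", spin_echo.te_ms)),
            tr_ms=float(se.get("tr_ms", spin_echo.tr_ms)),
        )

    tissues = raw.get("tissues", {})
    _check_keys("tissues", tissues, {"wm", "gm", "csf"})
    registry = PropertyRegistry(
        wm=_tissue("tissues.wm", tissues.get("wm", {}), registry.wm),
        gm=_tissue("tissues.gm", tissues.get("gm", {}), registry.gm),
        csf=_tissue("tissues.csf", tissues.get("csf", {}), registry.csf),
    )
    return RunConfig(mprage=mprage, spin_echo=spin_echo, registry=registry)
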