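"""Built-in sequence presets and config-file loading.

The built-ins mirror the protocol table of the three whole-brain 0.6 mm
isotropic vessel-wall protocols (plus the DANTE and AntiDrive comparators):

======================  ========  =======  ==========  =====  ====  ===
preset                  TR (ms)   TE (ms)  TEprep/TI   ESP    ETL   prep
======================  ========  =======  ==========  =====  ====  ===
t2ir-space              2500      92       200 / 950   4.4    77    T2IR
flair-space             6250      345      - / 2100    4.4    195   IR
t2w-space               2500      123      - / -       4.4    77    none
dante-space             2500      123      - / -       4.4    77    DANTE
t2w-antidrive           2500      123      - / -       4.4    77    none + restore
======================  ========  =======  ==========  =====  ====  ===

User files (YAML, or JSON — a YAML subset) overlay the built-ins field by
field: a block may change one timing value and inherit the rest.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .prep import DanteConfig, T2IRConfig
from .sequence import SequenceSpec, SequenceTiming

__all__ = ["BUILTIN_PRESETS", "load_presets", "spec_from_dict", "get_preset"]

BUILTIN_PRESETS: dict[str, dict] = {
    "t2ir-space": dict(
        tr_ms=2500.0, te_ms=92.0, esp_ms=4.4, etl=77,
        te_prep_ms=200.0, ti_ms=950.0, prep="t2ir", flip_mode="t2var",
    ),
    "flair-space": dict(
        tr_ms=6250.0, te_ms=345.0, esp_ms=4.4, etl=195,
        ti_ms=2100.0, prep="ir", flip_mode="t2var",
    ),
    "t2w-space": dict(
        tr_ms=2500.0, te_ms=123.0, esp_ms=4.4, etl=77,
        prep="none", flip_mode="t2var",
    ),
    "dante-space": dict(
        tr_ms=2500.0, te_ms=123.0, esp_ms=4.4, etl=77,
        prep="dante", flip_mode="t2var",
    ),
    "t2w-antidrive": dict(
        tr_ms=2500.0, te_ms=123.0, esp_ms=4.4, etl=77,
        prep="none", antidrive=True, flip_mode="t2var",
    ),
}

_TIMING_KEYS = ("tr_ms", "te_ms", "esp_ms", "etl", "ti_ms", "te_prep_ms")
_SPEC_KEYS = ("prep", "antidrive", "flip_mode", "constant_flip_deg", "n_reps")
_T2IR_KEYS = ("n_refocus", "phase_scheme", "composite_tipdown")
_DANTE_KEYS = ("flip_deg", "n_pulses", "interpulse_ms", "gradient_mT_m")


def spec_from_dict(name: str, cfg: dict) -> SequenceSpec:
    """Build a :class:`SequenceSpec` from a flat key-value block."""
    unknown = set(cfg) - set(_TIMING_KEYS) - set(_SPEC_KEYS) - set(_T2IR_KEYS) - set(_DANTE_KEYS) - {"flip_angles"}
    if unknown:
        raise ValueError(f"preset {name!r}: unknown keys {sorted(unknown)}")
    timing = SequenceTiming(**{k: cfg[k] for k in _TIMING_KEYS if k in cfg})
    kwargs: dict = {k: cfg[k] for k in _SPEC_KEYS if k in cfg}
    prep = kwargs.get("prep", "none")
    if prep == "t2ir":
        t2ir_kwargs = {k: cfg[k] for k in _T2IR_KEYS if k in cfg}
        kwargs["t2ir"] = T2IRConfig(te_prep_ms=timing.te_prep_ms or 200.0, **t2ir_kwargs)
    if prep == "dante":
        dante_kwargs = {k: cfg[k] for k in _DANTE_KEYS if k in cfg}
        kwargs["dante"] = DanteConfig(**dante_kwargs)
    if cfg.get("flip_angles") is not None:
        kwargs["flip_angles"] = tuple(float(a) for a in cfg["flip_angles"])
    return SequenceSpec(name=name, timing=timing, **kwargs)


def load_presets(path: str | Path | None = None) -> dict[str, SequenceSpec]:
    """Load the preset registry, optionally overlaying a user config file.

    The file maps preset names to key-value blocks; keys present in a block
    override the built-in values for that preset, everything else is
    inherited.  New preset names are accepted as long as the block is
    complete enough to build a timing.
    """
    merged = {name: dict(block) for name, block in BUILTIN_PRESETS.items()}
    if path is not None:
        text = Path(path).read_text()
        try:
            overlay = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ValueError(f"could not parse preset file {path}: {exc}") from exc
        if overlay is None:
            overlay = {}
        if not isinstance(overlay, dict):
            raise ValueError(f"preset file {path} must map preset names to blocks")
        for name, block in overlay.items():
            if not isinstance(block, dict):
                raise ValueError(f"preset {name!r} in {path}: expected a mapping")
            merged.setdefault(name, {}).update(block)
    return {name: spec_from_dict(name, block) for name, block in merged.items()}


def get_preset(name: str, registry: dict[str, SequenceSpec] | None = None) -> SequenceSpec:
    reg = registry if registry is not None else load_presets()
    if name not in reg:
        raise KeyError(
            f"unknown preset {name!r}; known presets: {', '.join(sorted(reg))}"
        )
    return reg[name]
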