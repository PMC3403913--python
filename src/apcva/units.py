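"""Concentration unit parsing for the CLI and config files.

Internal computation is always molar; user-facing inputs may carry
nM/µM-style suffixes ("2nM", "1.4uM", "20e-9").
"""

from __future__ import annotations

import re

__all__ = ["parse_concentration", "format_concentration"]

_SCALE = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,  # micro sign
    "μM": 1e-6,  # greek mu
    "nM": 1e-9,
    "pM": 1e-12,
    "fM": 1e-15,
}

_PATTERN = re.compile(
    r"^\s*([+-]?\d*\.?\d+(?:[eE][+-]?\d+)?)\s*([a-zA-Zµμ]*)\s*$"
)


def parse_concentration(text: str | float) -> float:
    """Parse a concentration with optional unit suffix into molar."""
    if isinstance(text, (int, float)):
        return float(text)
    m = _PATTERN.match(text)
    if not m:
        raise ValueError(f"cannot parse concentration {text!r}")
    value, unit = float(m.group(1)), m.group(2)
    if not unit:
        return value
    if unit not in _SCALE:
        raise ValueError(f"unknown concentration unit {unit!r} in {text!r}")
    return value * _SCALE[unit]


def format_concentration(molar: float) -> str:
    """Render a molar value with a convenient suffix (e.g. 2e-9 → '2 nM')."""
    if molar == 0:
        return "0 M"
    for unit, scale in (("M", 1.0), ("mM", 1e-3), ("uM", 1e-6), ("nM", 1e-9),
                        ("pM", 1e-12), ("fM", 1e-15)):
        if abs(molar) >= scale or scale == 1e-15:
            return f"{molar / scale:g} {unit}"
    return f"{molar:g} M"
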