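"""Bundled example datasets (long-format CSV, shipped with the package)."""

from __future__ import annotations

from importlib import resources

from .io import LongTable, read_long_table

__all__ = ["dataset_path", "load_testosterone", "load_blood_counts"]

_CONTROL = {
    "testosterone.csv": "Non-smokers",
    "blood_counts.csv": "Control",
}


def dataset_path(name: str) -> str:
    """Filesystem path of a bundled dataset (``testosterone.csv`` or ``blood_counts.csv``)."""
    if name not in _CONTROL:
        raise ValueError(f"unknown dataset {name!r}; available: {sorted(_CONTROL)}")
    return str(resources.files("varctrl.data").joinpath(name))


def load_testosterone() -> LongTable:
    """Testosterone levels (ug/dl) of four smoking-habit groups of ten men;
    the non-smokers are the control."""
    return read_long_table(dataset_path("testosterone.csv"), _CONTROL["testosterone.csv"])


def load_blood_counts() -> LongTable:
    """Blood counts of three animal groups of unequal size (6, 4, 5); the
    untreated group is the control."""
    return read_long_table(dataset_path("blood_counts.csv"), _CONTROL["blood_counts.csv"])
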