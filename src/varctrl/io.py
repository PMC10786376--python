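"""Long-format data ingestion, validation, and reporting."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .mim import GroupSummary, StudySummary, TestResult

__all__ = [
    "LongTable",
    "Report",
    "read_long_table",
    "summarize",
    "group_table",
    "normality_screen",
]


@dataclass(frozen=True)
class LongTable:
    """Validated long-format data: one (group, value) row per observation."""

    data: pd.DataFrame  # columns: "group" (str), "value" (float)
    control_label: str

    @property
    def labels(self) -> list[str]:
        """Group labels in first-appearance order, control first."""
        seen = list(dict.fromkeys(self.data["group"]))
        seen.remove(self.control_label)
        return [self.control_label] + seen

    def values(self, label: str) -> np.ndarray:
        return self.data.loc[self.data["group"] == label, "value"].to_numpy()


def read_long_table(
    path: str,
    control_label: str,
    *,
    group_col: str = "group",
    value_col: str = "value",
    sep: str | None = None,
) -> LongTable:
    """Read a delimited long-format file and validate it.

    ``sep=None`` sniffs the delimiter (comma or tab).  Validation errors name
    the offending group or row: the control label must be present, every
    group needs at least two rows, and all values must parse as numbers.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    for col in (group_col, value_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r} (found {list(df.columns)})")
    out = pd.DataFrame({
        "group": df[group_col].astype(str).str.strip(),
        "value": pd.to_numeric(df[value_col], errors="coerce"),
    })
    bad = out.index[out["value"].isna()]
    if len(bad):
        # header is line 1, so data row i lives on line i + 2
        lines = ", ".join(str(i + 2) for i in bad[:5])
        raise ValueError(f"{path}: non-numeric value(s) in column {value_col!r} at line(s) {lines}")
    counts = out["group"].value_counts()
    if control_label not in counts.index:
        raise ValueError(
            f"{path}: control group {control_label!r} not found "
            f"(groups present: {sorted(counts.index)})"
        )
    small = counts[counts < 2]
    if len(small):
        raise ValueError(
            f"{path}: every group needs at least 2 observations; "
            f"offending group(s): {dict(small)}"
        )
    if len(counts) < 2:
        raise ValueError(f"{path}: need at least one non-control group")
    return LongTable(data=out, control_label=control_label)


def summarize(table: LongTable) -> StudySummary:
    """Per-group sufficient statistics (n and sample variance, divisor n-1)."""
    groups = [
        GroupSummary(label=lab, n=len(v), s2=float(np.var(v, ddof=1)))
        for lab in table.labels
        for v in [table.values(lab)]
    ]
    return StudySummary(control=groups[0], treatments=tuple(groups[1:]))


def group_table(table: LongTable) -> pd.DataFrame:
    """Summary frame with label, n, mean, and variance per group."""
    rows = []
    for lab in table.labels:
        v = table.values(lab)
        rows.append({
            "group": lab,
            "role": "control" if lab == table.control_label else "treatment",
            "n": len(v),
            "mean": float(np.mean(v)),
            "variance": float(np.var(v, ddof=1)),
        })
    return pd.DataFrame(rows)


def normality_screen(table: LongTable) -> dict[str, float | None]:
    """Advisory Shapiro-Wilk p-value per group (None when n < 3).

    A small p-value flags non-normality but never blocks the test; with the
    small samples typical here the screen has little power either way.
    """
    out: dict[str, float | None] = {}
    for lab in table.labels:
        v = table.values(lab)
        out[lab] = float(stats.shapiro(v).pvalue) if len(v) >= 3 else None
    return out


@dataclass
class Report:
    """Everything the CLI prints: summaries, screens, results, provenance."""

    groups: pd.DataFrame
    normality: Mapping[str, float | None]
    results: list[TestResult]
    upper_bound: float | None = None
    upper_bound_alpha: float | None = None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "groups": self.groups.to_dict(orient="records"),
            "normality": dict(self.normality),
            "results": [
                {
                    "method": r.method,
                    "statistic": r.statistic,
                    "plausibility": r.plausibility,
                    "alpha": r.alpha,
                    "reject": r.reject,
                }
                for r in self.results
            ],
            "upper_bound": self.upper_bound,
            "upper_bound_alpha": self.upper_bound_alpha,
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def format_text(self, warn_threshold: float = 0.05) -> str:
        lines = ["Group summaries:"]
        frame = self.groups.copy()
        frame["mean"] = frame["mean"].map(lambda v: f"{v:.4f}")
        frame["variance"] = frame["variance"].map(lambda v: f"{v:.4f}")
        lines.append(frame.to_string(index=False))
        lines.append("")
        lines.append("Normality screen (Shapiro-Wilk, advisory):")
        for lab, p in self.normality.items():
            if p is None:
                lines.append(f"  {lab}: skipped (fewer than 3 observations)")
            else:
                note = "  ** below threshold, interpret with care" if p < warn_threshold else ""
                lines.append(f"  {lab}: p = {p:.4f}{note}")
        lines.append("")
        for r in self.results:
            label = "plausibility" if r.method == "MIM" else "p-value"
            decision = "reject H0" if r.reject else "fail to reject H0"
            lines.append(
                f"{r.method}: statistic T = {r.statistic:.4f}, "
                f"{label} = {r.plausibility:.4f} -> {decision} at alpha = {r.alpha:g}"
            )
        if self.upper_bound is not None:
            lines.append(
                f"Upper {100 * (1 - (self.upper_bound_alpha or 0)):.0f}% confidence bound "
                f"for min variance ratio: {self.upper_bound:.4f}"
            )
        if self.provenance:
            lines.append("")
            lines.append("Provenance: " + json.dumps(self.provenance, sort_keys=True))
        return "\n".join(lines)
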