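"""Reporter-assay and immunoblot quantification formulas.

Three small normalizations used when validating SH2-ligand models against
cell-based readouts:

* relative response ratio (RRR) — scales a luciferase signal between its
  negative (0%) and positive (100%) controls:
  ``((sample - neg) * 100) / (pos - neg)``;
* renilla normalization — firefly luciferase activity divided by the renilla
  transfection control, per well;
* phospho-blot ratio — (phospho-protein / total protein) band intensities,
  normalized to a loading control (e.g. GAPDH): ``(phospho/total)/loading``.

The blot normalization divides by the raw loading intensity, not by loading
relative to a reference lane.  Replicate statistics use the sample (n-1)
standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ReporterMeasurement:
    sample: float
    negative_control: float
    positive_control: float

    def __post_init__(self) -> None:
        if self.positive_control == self.negative_control:
            raise ValueError(
                "positive and negative controls are equal; the relative "
                "response ratio is undefined")


@dataclass(frozen=True)
class BlotMeasurement:
    phospho: float
    total: float
    loading: float  # loading control, e.g. GAPDH

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError("total-protein band intensity must be positive")
        if self.loading <= 0:
            raise ValueError("loading-control band intensity must be positive")


def relative_response_ratio(m: ReporterMeasurement) -> float:
    """Percent activity between the controls: sample=pos -> 100, sample=neg -> 0."""
    return ((m.sample - m.negative_control) * 100.0
            / (m.positive_control - m.negative_control))


def normalized_phospho_ratio(m: BlotMeasurement) -> float:
    """(phospho / total) normalized to the loading-control signal."""
    return (m.phospho / m.total) / m.loading


def reporter_normalize(firefly: float, renilla: float) -> float:
    """Firefly luciferase activity per unit renilla transfection control."""
    if renilla <= 0:
        raise ValueError("renilla control must be positive")
    return firefly / renilla


def replicate_stats(ratios) -> tuple[float, float]:
    """Mean and sample SD (ddof=1) of per-well normalized ratios."""
    arr = np.asarray(list(ratios), dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two replicates for mean/SD")
    return float(arr.mean()), float(arr.std(ddof=1))


# ---------------------------------------------------------------------------
# CSV interfaces (one row per well / lane; computed column appended)

_MODE_COLUMNS = {
    "reporter_rrr": ["sample", "negative_control", "positive_control"],
    "blot_ratio": ["phospho", "total", "loading"],
    "reporter_norm": ["firefly", "renilla"],
}


def quantify_dataframe(df: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Append the computed column for ``mode``; row order preserved."""
    if mode not in _MODE_COLUMNS:
        raise ValueError(f"unknown quantification mode {mode!r}")
    missing = [c for c in _MODE_COLUMNS[mode] if c not in df.columns]
    if missing:
        raise KeyError(f"missing column(s) {missing} for mode {mode!r}")
    out = df.copy()
    if mode == "reporter_rrr":
        out["relative_response_pct"] = [
            relative_response_ratio(ReporterMeasurement(
                r.sample, r.negative_control, r.positive_control))
            for r in df.itertuples(index=False)]
    elif mode == "blot_ratio":
        out["normalized_phospho_ratio"] = [
            normalized_phospho_ratio(BlotMeasurement(r.phospho, r.total, r.loading))
            for r in df.itertuples(index=False)]
    else:
        out["normalized_activity"] = [
            reporter_normalize(r.firefly, r.renilla)
            for r in df.itertuples(index=False)]
    return out
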