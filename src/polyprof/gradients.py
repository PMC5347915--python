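"""Sucrose-gradient absorbance quantification and spike-normalized qPCR.

A fractionated gradient's 254 nm absorbance trace is baseline-corrected
against a blank gradient; the total area under the corrected curve is a
proxy for ribosome abundance, and the fraction of area beyond the
monosome/polysome boundary (two or more ribosomes) is the polysome
loading.  rRNA-type ratios come from qPCR Cq values normalized to the
geometric mean of exogenous spike-in standards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import argrelmin

__all__ = [
    "GradientTrace",
    "read_trace",
    "preprocess_trace",
    "polysome_loading",
    "detect_boundary",
    "spike_normalized_abundance",
]


@dataclass
class GradientTrace:
    """Absorbance vs gradient depth (positions strictly increasing)."""

    positions: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.positions.size < 2 or self.positions.size != self.absorbance.size:
            raise ValueError("trace needs >= 2 (position, absorbance) points")
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def total_area(self) -> float:
        return float(np.trapezoid(self.absorbance, self.positions))


def read_trace(path) -> GradientTrace:
    """Read a two-column TSV (position, absorbance)."""
    df = pd.read_csv(path, sep="\t")
    pos_col, abs_col = df.columns[:2]
    return GradientTrace(df[pos_col].to_numpy(), df[abs_col].to_numpy())


def preprocess_trace(
    trace: GradientTrace,
    blank: GradientTrace,
    normalize: bool = False,
    clip_negative: bool = True,
) -> tuple[GradientTrace, float]:
    """Subtract the blank-gradient baseline and report the total area.

    The blank is linearly interpolated onto the trace's position grid
    (its range must cover the trace).  Negative corrected values are
    clipped at zero with a warning.  With ``normalize=True`` the
    corrected trace is rescaled to unit area (ribosome-abundance
    comparisons then use the returned pre-normalization area).
    """
    if blank.positions[0] > trace.positions[0] or blank.positions[-1] < trace.positions[-1]:
        raise ValueError("blank gradient does not cover the trace's position range")
    baseline = np.interp(trace.positions, blank.positions, blank.absorbance)
    corrected = trace.absorbance - baseline
    if (corrected < 0).any():
        if clip_negative:
            warnings.warn("negative corrected absorbance clipped at 0")
            corrected = np.clip(corrected, 0.0, None)
    out = GradientTrace(trace.positions.copy(), corrected)
    area = out.total_area
    if normalize:
        if area <= 0:
            raise ValueError("cannot normalize a zero-area trace")
        out = GradientTrace(out.positions, out.absorbance / area)
    return out, area


def polysome_loading(corrected: GradientTrace, boundary: float) -> float:
    """Fraction of the corrected trace's area at two or more ribosomes.

    ``boundary`` is the gradient position separating the <= 1-ribosome
    region from the polysome region; the trace value there is obtained by
    linear interpolation.
    """
    pos, ab = corrected.positions, corrected.absorbance
    if not (pos[0] <= boundary <= pos[-1]):
        raise ValueError("boundary outside the trace's position range")
    total = corrected.total_area
    if total <= 0:
        raise ValueError("zero total area: polysome loading undefined")
    b_val = np.interp(boundary, pos, ab)
    mask = pos > boundary
    seg_pos = np.concatenate([[boundary], pos[mask]])
    seg_ab = np.concatenate([[b_val], ab[mask]])
    if seg_pos.size < 2:
        return 0.0
    return float(np.trapezoid(seg_ab, seg_pos) / total)


def detect_boundary(corrected: GradientTrace) -> float:
    """Monosome/polysome boundary: first local minimum after the 80S peak.

    The 80S (monosome) peak is taken as the global maximum of the
    corrected trace; an eyeball-free stand-in for the boundary usually
    placed by inspection.
    """
    ab = corrected.absorbance
    peak = int(np.argmax(ab))
    minima = argrelmin(ab)[0]
    after = minima[minima > peak]
    if after.size == 0:
        raise ValueError("no local minimum after the main peak")
    return float(corrected.positions[after[0]])


def spike_normalized_abundance(
    cq: pd.DataFrame,
    spike_ids,
    default_efficiency: float = 2.0,
) -> tuple[pd.Series, pd.Series]:
    """Spike-normalized relative quantities and rRNA-type fractions.

    ``cq`` needs columns ``target`` and ``cq``; an ``efficiency`` column
    (per-target amplification efficiency E in (1, 2]) is optional and
    defaults to 2.0 with a warning.  Quantity Q = E**(-Cq) is divided by
    the geometric mean of the spike quantities; the non-spike targets
    (the rRNA types) are additionally rescaled to sum to 1.

    Returns ``(normalized_quantities, rrna_fractions)`` indexed by target.
    """
    spike_ids = list(spike_ids)
    df = cq.set_index("target") if "target" in cq.columns else cq
    missing = set(spike_ids) - set(df.index)
    if missing:
        raise ValueError(f"missing spike-in records: {sorted(missing)}")
    if "efficiency" in df.columns and df["efficiency"].notna().all():
        eff = df["efficiency"].astype(float)
    else:
        warnings.warn("no primer efficiencies given; assuming E = 2.0")
        eff = pd.Series(default_efficiency, index=df.index, dtype=float)
    if ((eff <= 1) | (eff > 2)).any():
        raise ValueError("amplification efficiencies must lie in (1, 2]")
    q = eff ** (-df["cq"].astype(float))
    gm = float(np.exp(np.log(q.loc[spike_ids]).mean()))
    q_norm = q / gm
    rrna = q_norm.drop(index=spike_ids)
    fractions = rrna / rrna.sum()
    return q_norm, fractions
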