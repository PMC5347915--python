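"""Loading, validation, noise filtering and replicate QC of expression matrices.

The experimental design is a time course of paired RNA fractions: at each
time point (hours after the start of imbibition) both total mRNA and
polysome-associated mRNA are profiled in replicate, on a log2 intensity
scale after normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "NoiseFilterResult",
    "noise_filter",
    "QCReport",
    "replicate_qc",
]

FRACTIONS = ("total", "polysomal")


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 intensity matrix with design metadata.

    ``values`` is indexed by gene id with one column per sample id;
    ``samples`` is indexed by sample id with columns ``time_point``
    (hours), ``fraction`` ("total"/"polysomal") and ``replicate``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.values.index.duplicated().any():
            raise ValueError("gene ids must be unique")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        bad = set(self.samples["fraction"]) - set(FRACTIONS)
        if bad:
            raise ValueError(f"unknown fractions: {sorted(bad)}")
        if (self.samples["replicate"] < 1).any():
            raise ValueError("replicate indices must be positive")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def time_points(self) -> list:
        return sorted(self.samples["time_point"].unique())

    def condition_samples(self, time_point, fraction: str) -> list[str]:
        """Sample ids of one (time point, fraction) condition, by replicate."""
        sel = self.samples[
            (self.samples["time_point"] == time_point)
            & (self.samples["fraction"] == fraction)
        ]
        return list(sel.sort_values("replicate").index)

    def condition_values(self, time_point, fraction: str) -> pd.DataFrame:
        return self.values[self.condition_samples(time_point, fraction)]

    def subset(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.samples)


def read_expression(matrix_path, meta_path) -> ExpressionMatrix:
    """Read a TSV matrix (first column gene id) and a sample metadata TSV.

    The metadata file needs columns ``sample_id``, ``time_point``,
    ``fraction`` and ``replicate``.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t")
    required = {"sample_id", "time_point", "fraction", "replicate"}
    if not required <= set(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    meta = meta.set_index("sample_id")
    return ExpressionMatrix(values, meta)


@dataclass
class NoiseFilterResult:
    kept: pd.Index
    removed: pd.Index
    threshold: float
    rule: str


def noise_filter(
    m: ExpressionMatrix,
    threshold: float = 4.0,
    rule: str = "all_replicates",
) -> NoiseFilterResult:
    """Remove genes whose intensities never rise above background noise.

    Default rule ("all_replicates"): a gene is kept iff there is at least
    one (time point, fraction) condition in which *every* replicate value
    strictly exceeds ``threshold``.  The looser alternative
    ("any_sample") keeps any gene with a single sample above threshold.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if rule == "any_sample":
        keep = (m.values > threshold).any(axis=1)
    elif rule == "all_replicates":
        keep = pd.Series(False, index=m.genes)
        for tp in m.time_points:
            for fraction in FRACTIONS:
                cols = m.condition_samples(tp, fraction)
                if cols:
                    keep |= (m.values[cols] > threshold).all(axis=1)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return NoiseFilterResult(
        kept=m.genes[keep],
        removed=m.genes[~keep],
        threshold=threshold,
        rule=rule,
    )


@dataclass
class QCReport:
    """Within-condition replicate correlations with low-correlation flags."""

    correlations: pd.DataFrame  # time_point, fraction, sample_a, sample_b, r, flagged
    min_r: float
    intensity_summary: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def flagged_pairs(self) -> pd.DataFrame:
        return self.correlations[self.correlations["flagged"]]


def replicate_qc(m: ExpressionMatrix, min_r: float = 0.95) -> QCReport:
    """Pearson correlation of every within-condition replicate pair.

    Pairs below ``min_r`` are flagged; a constant replicate column yields
    an undefined (NaN) correlation which is flagged rather than raised.
    """
    rows = []
    for tp in m.time_points:
        for fraction in FRACTIONS:
            cols = m.condition_samples(tp, fraction)
            if len(cols) < 2:
                raise ValueError(
                    f"condition ({tp}, {fraction}) has fewer than 2 replicates"
                )
            for i in range(len(cols)):
                for j in range(i + 1, len(cols)):
                    a = m.values[cols[i]].to_numpy()
                    b = m.values[cols[j]].to_numpy()
                    if a.std() == 0 or b.std() == 0:
                        r = np.nan
                    else:
                        r = float(np.corrcoef(a, b)[0, 1])
                    rows.append(
                        {
                            "time_point": tp,
                            "fraction": fraction,
                            "sample_a": cols[i],
                            "sample_b": cols[j],
                            "r": r,
                            "flagged": (not np.isfinite(r)) or r < min_r,
                        }
                    )
    summary = m.values.describe().T
    return QCReport(
        correlations=pd.DataFrame(rows), min_r=min_r, intensity_summary=summary
    )
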