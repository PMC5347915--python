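"""Polysome occupancy, translational shift detection and regulatory modes.

Polysome occupancy (PO) of a gene is the log2 ratio of its polysome-bound
mRNA level to its total mRNA level, a proxy for translational efficiency.
Comparing PO between consecutive time points identifies translational
shifts; comparing the total (T), polysomal (P) and PO contrasts for the
same interval attributes each shift to transcription, translation, or
combinations thereof.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .expression import ExpressionMatrix

__all__ = [
    "OccupancyMatrix",
    "compute_polysome_occupancy",
    "ContrastResult",
    "differential_call",
    "ShiftResult",
    "detect_shifts",
    "classify_regulatory_mode",
    "gene_set_ora",
    "pca_variance",
]

MODES = ("T+", "T-", "P+", "P-", "T+/P+", "T-/P-", "additive", "opposite")


@dataclass
class OccupancyMatrix:
    """Per-gene log2 polysome occupancy, one column per (time, replicate)."""

    values: pd.DataFrame  # columns: MultiIndex (time_point, replicate)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def time_points(self) -> list:
        return sorted({t for t, _ in self.values.columns})

    def at_time(self, time_point) -> pd.DataFrame:
        return self.values.loc[:, self.values.columns.get_level_values(0) == time_point]


def compute_polysome_occupancy(m: ExpressionMatrix) -> OccupancyMatrix:
    """PO = polysomal - total (log2 scale), per gene and replicate pair.

    Fractions are paired by replicate index within each time point;
    replicates lacking a partner in the other fraction are dropped with a
    warning.
    """
    cols = {}
    for tp in m.time_points:
        total = m.samples[
            (m.samples["time_point"] == tp) & (m.samples["fraction"] == "total")
        ]
        poly = m.samples[
            (m.samples["time_point"] == tp) & (m.samples["fraction"] == "polysomal")
        ]
        t_by_rep = dict(zip(total["replicate"], total.index))
        p_by_rep = dict(zip(poly["replicate"], poly.index))
        shared = sorted(set(t_by_rep) & set(p_by_rep))
        orphan = (set(t_by_rep) | set(p_by_rep)) - set(shared)
        if orphan:
            warnings.warn(
                f"time {tp}: replicates {sorted(orphan)} lack a fraction partner; dropped"
            )
        for rep in shared:
            cols[(tp, rep)] = m.values[p_by_rep[rep]] - m.values[t_by_rep[rep]]
    if not cols:
        raise ValueError("no matched total/polysomal replicate pairs")
    values = pd.DataFrame(cols)
    values.columns = pd.MultiIndex.from_tuples(
        cols.keys(), names=["time_point", "replicate"]
    )
    return OccupancyMatrix(values)


@dataclass
class ContrastResult:
    """Per-gene calls for one named contrast.

    ``table`` columns: log2fc, p, padj, call (up/down/ns).  A gene is
    called up iff log2fc > fc_threshold AND padj < alpha (strict
    inequalities, per the calling rule); down is symmetric.
    """

    label: str
    table: pd.DataFrame
    fc_threshold: float
    alpha: float

    @property
    def up(self) -> pd.Index:
        return self.table.index[self.table["call"] == "up"]

    @property
    def down(self) -> pd.Index:
        return self.table.index[self.table["call"] == "down"]

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["call"] != "ns"]


def _two_group_contrast(
    a: pd.DataFrame,
    b: pd.DataFrame,
    label: str,
    fc_threshold: float,
    alpha: float,
    d0: float | None = None,
) -> ContrastResult:
    """Moderated-t contrast of group b minus group a (genes x replicates)."""
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 replicates")
    av, bv = a.to_numpy(float), b.to_numpy(float)
    coef = bv.mean(axis=1) - av.mean(axis=1)
    pooled = ((na - 1) * av.var(axis=1, ddof=1) + (nb - 1) * bv.var(axis=1, ddof=1)) / (
        na + nb - 2
    )
    fit = stats.moderated_t_fit(
        coef,
        pooled,
        df_residual=na + nb - 2,
        stdev_unscaled=np.sqrt(1.0 / na + 1.0 / nb),
        d0=d0,
    )
    padj = stats.bh_adjust(fit.p)
    call = np.where(
        (coef > fc_threshold) & (padj < alpha),
        "up",
        np.where((coef < -fc_threshold) & (padj < alpha), "down", "ns"),
    )
    table = pd.DataFrame(
        {"log2fc": coef, "p": fit.p, "padj": padj, "call": call}, index=a.index
    )
    return ContrastResult(label=label, table=table, fc_threshold=fc_threshold, alpha=alpha)


def differential_call(
    data: ExpressionMatrix | OccupancyMatrix,
    group_a,
    group_b,
    fc_threshold: float = 1.0,
    alpha: float = 0.05,
    label: str | None = None,
    d0: float | None = None,
) -> ContrastResult:
    """Differential call between two conditions (b vs a).

    For an :class:`ExpressionMatrix` the groups are ``(time_point,
    fraction)`` pairs; for an :class:`OccupancyMatrix` they are time
    points (all replicates of the PO value).  Moderated t per gene, BH
    adjustment across genes, strict thresholds on |log2FC| and adjusted p.
    """
    if isinstance(data, ExpressionMatrix):
        tp_a, frac_a = group_a
        tp_b, frac_b = group_b
        a = data.condition_values(tp_a, frac_a)
        b = data.condition_values(tp_b, frac_b)
        default = f"{frac_b} {tp_a}->{tp_b}"
    elif isinstance(data, OccupancyMatrix):
        a = data.at_time(group_a)
        b = data.at_time(group_b)
        default = f"PO {group_a}->{group_b}"
    else:
        raise TypeError("data must be an ExpressionMatrix or OccupancyMatrix")
    if a.shape[1] == 0 or b.shape[1] == 0:
        raise ValueError("group has no samples")
    return _two_group_contrast(a, b, label or default, fc_threshold, alpha, d0=d0)


@dataclass
class ShiftResult:
    contrasts: list[ContrastResult]
    summary: pd.DataFrame  # index interval label, columns up/down counts


def detect_shifts(
    po: OccupancyMatrix,
    time_points=None,
    fc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> ShiftResult:
    """Consecutive-time-point PO contrasts with per-interval shift counts."""
    tps = list(time_points) if time_points is not None else po.time_points
    if len(tps) < 2:
        raise ValueError("need at least 2 time points")
    if len(set(tps)) != len(tps) or tps != sorted(tps):
        raise ValueError("time points must be strictly increasing and unique")
    contrasts, rows = [], []
    for t1, t2 in zip(tps[:-1], tps[1:]):
        c = differential_call(po, t1, t2, fc_threshold, alpha)
        contrasts.append(c)
        rows.append({"interval": c.label, "up": len(c.up), "down": len(c.down)})
    return ShiftResult(contrasts=contrasts, summary=pd.DataFrame(rows).set_index("interval"))


def classify_regulatory_mode(
    dT: ContrastResult, dP: ContrastResult, dPO: ContrastResult
) -> pd.DataFrame:
    """Attribute each significant PO change to a regulatory mode.

    For a gene whose polysome occupancy changed significantly over an
    interval, the total-mRNA (dT) and polysomal-mRNA (dP) contrasts over
    the same interval determine the mode:

    - ``P+``/``P-``: polysomal level changed (same direction as PO) while
      total did not - translation alone.
    - ``T+``/``T-``: total level changed, opposite in sign to the PO
      change, while polysomal did not - transcription alone moves the
      ratio.
    - ``T+/P+``/``T-/P-``: both levels changed in the same direction.
    - ``additive``: neither level changed significantly on its own; the
      two sub-threshold effects jointly shift the ratio.
    - ``opposite``: both changed but in opposing directions, or the
      pattern contradicts the PO direction.
    """
    genes = dPO.significant
    po_sign = np.sign(dPO.table.loc[genes, "log2fc"])
    t_call = dT.table["call"].reindex(genes, fill_value="ns")
    p_call = dP.table["call"].reindex(genes, fill_value="ns")
    t_sign = np.sign(dT.table["log2fc"].reindex(genes, fill_value=0.0))
    p_sign = np.sign(dP.table["log2fc"].reindex(genes, fill_value=0.0))

    modes = []
    for g in genes:
        po_s = po_sign[g]
        t_sig = t_call[g] != "ns"
        p_sig = p_call[g] != "ns"
        if not t_sig and not p_sig:
            mode = "additive"
        elif p_sig and not t_sig:
            mode = ("P+" if po_s > 0 else "P-") if p_sign[g] == po_s else "opposite"
        elif t_sig and not p_sig:
            mode = ("T-" if po_s > 0 else "T+") if t_sign[g] == -po_s else "opposite"
        else:  # both significant
            if t_sign[g] == p_sign[g] == po_s:
                mode = "T+/P+" if po_s > 0 else "T-/P-"
            else:
                mode = "opposite"
        modes.append(mode)
    out = pd.DataFrame(
        {
            "po_direction": np.where(po_sign > 0, "up", "down"),
            "mode": modes,
        },
        index=genes,
    )
    out["label"] = dPO.label + " " + out["po_direction"] + " " + out["mode"]
    return out


def gene_set_ora(
    query,
    annotation: dict,
    background,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of annotation terms in a query gene set.

    One-tailed Fisher enrichment per term against the background, with a
    Hochberg step-up adjustment across terms.
    """
    query = set(query)
    background = set(background)
    if not query or not background:
        raise ValueError("query and background must be non-empty")
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    rows = []
    for term, members in annotation.items():
        members = set(members) & background
        overlap = len(members & query)
        table = [
            [overlap, len(query) - overlap],
            [len(members) - overlap, len(background) - len(query) - len(members) + overlap],
        ]
        p = stats.fisher_exact_one_tailed(table, "enrichment")
        rows.append(
            {"term": term, "overlap": overlap, "term_size": len(members), "p": p}
        )
    out = pd.DataFrame(rows).set_index("term")
    if len(out):
        out["padj"] = stats.hochberg_adjust(out["p"].to_numpy())
        out["significant"] = out["padj"] < alpha
        out = out.sort_values("p")
    return out


def pca_variance(po: OccupancyMatrix) -> np.ndarray:
    """Fraction of variance explained per principal component of PO.

    Samples are the observations; each gene is centered across samples
    before the singular-value decomposition.
    """
    x = po.values.to_numpy(float)
    if x.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    x = x - x.mean(axis=1, keepdims=True)
    total = (x**2).sum()
    if total == 0:
        raise ValueError("constant matrix: PCA undefined")
    s = np.linalg.svd(x, compute_uv=False)
    frac = s**2 / (s**2).sum()
    return frac
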