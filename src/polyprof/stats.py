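"""Statistical primitives shared by the analysis stages.

Multiple-testing step-up adjustments, exact 2x2 tests, rank tests, and the
empirical-Bayes moderated t-statistic used for differential expression and
polysome-occupancy calling.

The moderated t follows the hierarchical model of Smyth (2004): per-gene
sample variances s2_g with d_g residual degrees of freedom are assumed to be
scaled-F distributed around a prior variance s0^2 with d0 prior degrees of
freedom.  (d0, s0^2) are estimated by the method of moments on the log
variances, and each gene's variance is shrunk toward the prior before
computing the t statistic, which gains d0 extra degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_adjust",
    "hochberg_adjust",
    "fisher_exact_one_tailed",
    "chisq_2x2",
    "mann_whitney_u",
    "ModeratedFit",
    "moderated_t_fit",
    "trigamma_inverse",
]


def _check_pvalues(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if not np.all(np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    Returns adjusted values in the original input order, capped at 1.
    """
    p = _check_pvalues(p)
    return multipletests(p, method="fdr_bh")[1]


def hochberg_adjust(p) -> np.ndarray:
    """Hochberg step-up adjustment (FWER control under independence/PRDS)."""
    p = _check_pvalues(p)
    return multipletests(p, method="simes-hochberg")[1]


def fisher_exact_one_tailed(table, direction: str = "enrichment") -> float:
    """One-tailed Fisher exact test on a 2x2 table.

    ``direction="enrichment"`` asks whether cell (0, 0) is larger than
    expected under fixed margins (hypergeometric upper tail);
    ``"depletion"`` asks the lower tail.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("table counts must be non-negative")
    if t.sum() == 0:
        raise ValueError("table total must be positive")
    alt = {"enrichment": "greater", "depletion": "less"}.get(direction)
    if alt is None:
        raise ValueError(f"unknown direction {direction!r}")
    return float(sps.fisher_exact(t, alternative=alt)[1])


def chisq_2x2(
    observed_in_set: int,
    set_size: int,
    class_total: int,
    background_total: int,
    continuity: bool = False,
) -> tuple[float, float, float]:
    """Chi-square over-representation test of a class within a gene set.

    Compares the observed number of set members in the class with the
    expectation ``set_size * class_total / background_total`` via a 1-df
    goodness-of-fit statistic over the two cells (in-class / not-in-class
    within the set).  No Yates continuity correction by default.

    Returns ``(expected, statistic, p)``.
    """
    if set_size > background_total or class_total > background_total:
        raise ValueError("set and class must be subsets of the background")
    if observed_in_set > set_size:
        raise ValueError("observed count exceeds set size")
    expected = set_size * class_total / background_total
    expected_out = set_size - expected
    if expected <= 0 or expected_out <= 0:
        raise ValueError(
            "zero expected count; use fisher_exact_one_tailed for sparse tables"
        )
    cc = 0.5 if continuity else 0.0
    dev = max(abs(observed_in_set - expected) - cc, 0.0)
    stat = dev**2 / expected + dev**2 / expected_out
    p = float(sps.chi2.sf(stat, df=1))
    return expected, stat, p


def mann_whitney_u(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U rank-sum test.

    Exact null distribution when min(n, m) <= 8 and there are no ties;
    normal approximation with midrank tie correction otherwise.  The
    returned U counts pairs where an ``x`` value exceeds a ``y`` value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve psi'(y) = x for y > 0 by Newton iteration.

    Starting value 0.5 + 1/x; converges monotonically for the method-of-
    moments fit (x > 0).
    """
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


@dataclass
class ModeratedFit:
    """Result of an empirical-Bayes moderated t fit.

    All per-gene fields are aligned 1-d arrays; ``d0`` may be ``inf``
    (fully pooled variance) and ``0`` (no pooling; ordinary t).
    """

    coef: np.ndarray  # log2-scale effect estimate per gene
    s2: np.ndarray  # residual variance per gene
    df_residual: np.ndarray  # residual degrees of freedom per gene
    stdev_unscaled: np.ndarray  # unscaled standard error u_g
    d0: float  # prior degrees of freedom
    s0_2: float  # prior variance
    s2_post: np.ndarray  # posterior (shrunk) variance
    t: np.ndarray  # moderated t statistic
    p: np.ndarray  # two-sided p-value
    df_total: np.ndarray  # d0 + d_g


def _fit_f_dist(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior on sample variances."""
    ok = s2 > 0
    if not ok.any():
        raise ValueError("all residual variances are zero; degenerate data")
    z = np.log(s2[ok])
    d = df[ok]
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    n = e.size
    e_mean = e.mean()
    e_var = ((e - e_mean) ** 2).sum() / (n - 1) if n > 1 else 0.0
    # subtract the sampling variance of each log-variance
    resid_var = e_var - np.mean(special.polygamma(1, d / 2.0))
    if resid_var > 0:
        d0 = 2.0 * trigamma_inverse(resid_var)
        s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    elif e.max() == e.min():
        # degenerate input: all sample variances identical, so they are not
        # noisy draws; pool exactly at the common variance
        d0 = np.inf
        s0_2 = float(np.exp(z.mean()))
    else:
        # genuine sample whose spread is no larger than sampling alone
        # predicts: fully pooled prior at the debiased location
        d0 = np.inf
        s0_2 = float(np.exp(e_mean))
    return d0, s0_2


def moderated_t_fit(
    coef,
    s2,
    df_residual,
    stdev_unscaled,
    d0: float | None = None,
    s0_2: float | None = None,
) -> ModeratedFit:
    """Empirical-Bayes moderated t statistics from per-gene summaries.

    Parameters
    ----------
    coef
        Per-gene effect estimate on the log2 scale (e.g. a group mean
        difference).
    s2
        Per-gene residual variance.
    df_residual
        Residual degrees of freedom (scalar or per gene).
    stdev_unscaled
        Unscaled standard error of the coefficient (e.g.
        ``sqrt(1/na + 1/nb)`` for a two-group difference).
    d0, s0_2
        Optional prior overrides.  ``d0=0`` reproduces the ordinary t
        exactly; ``d0=inf`` pools all variances at ``s0_2`` (z test).
        When omitted, both are estimated from the data.
    """
    coef = np.asarray(coef, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    df_residual = np.broadcast_to(
        np.asarray(df_residual, dtype=float), coef.shape
    ).copy()
    stdev_unscaled = np.broadcast_to(
        np.asarray(stdev_unscaled, dtype=float), coef.shape
    ).copy()
    if coef.size < 10 and d0 is None:
        raise ValueError("need >= 10 genes to estimate the variance prior")
    if (df_residual < 1).any():
        raise ValueError("residual degrees of freedom must be >= 1")

    if d0 is None:
        d0, s0_2_hat = _fit_f_dist(s2, df_residual)
        if s0_2 is None:
            s0_2 = s0_2_hat
    elif s0_2 is None:
        if np.isinf(d0):
            s0_2 = float(np.exp(np.mean(np.log(s2[s2 > 0]))))
        elif d0 == 0:
            s0_2 = float("nan")  # unused: posterior equals sample variance
        else:
            _, s0_2 = _fit_f_dist(s2, df_residual)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.full_like(df_residual, np.inf)
    elif d0 == 0:
        s2_post = s2.copy()
        df_total = df_residual.copy()
    else:
        s2_post = (d0 * s0_2 + df_residual * s2) / (d0 + df_residual)
        df_total = d0 + df_residual

    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / (stdev_unscaled * np.sqrt(s2_post))
    finite_df = np.isfinite(df_total)
    p = np.empty_like(t)
    p[finite_df] = 2.0 * sps.t.sf(np.abs(t[finite_df]), df_total[finite_df])
    p[~finite_df] = 2.0 * sps.norm.sf(np.abs(t[~finite_df]))
    p = np.clip(p, 0.0, 1.0)
    return ModeratedFit(
        coef=coef,
        s2=s2,
        df_residual=df_residual,
        stdev_unscaled=stdev_unscaled,
        d0=float(d0),
        s0_2=float(s0_2),
        s2_post=s2_post,
        t=t,
        p=p,
        df_total=df_total,
    )
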