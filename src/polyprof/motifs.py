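"""PWM motif scanning with exact p-values, enrichment and positional density.

Motifs are position weight matrices (MEME minimal text format).  Scanning
scores each window by its log-odds against a 0-order background; the
p-value of a score is the exact probability that a background-generated
w-mer scores at least as high, computed by dynamic programming over
integer-discretized scores (granularity 1/1000 bit), as FIMO does.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from . import stats

__all__ = [
    "MotifModel",
    "MotifHit",
    "read_meme_motifs",
    "write_meme_motifs",
    "scan_pwm",
    "scan_sequences",
    "motif_enrichment_test",
    "positional_density",
]

ALPHABET = "ACGT"
SCORE_GRANULARITY = 1000  # integer score units per bit


@dataclass
class MotifModel:
    """A nucleotide position weight matrix with background frequencies."""

    name: str
    matrix: np.ndarray  # 4 x w probabilities, rows A, C, G, T
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 1e-4

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4 or self.width < 1:
            raise ValueError("matrix must be 4 x w with w >= 1")
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError(f"motif {self.name}: columns must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def log_odds(self) -> np.ndarray:
        """Pseudocounted log2 odds matrix (bits), 4 x w."""
        p = self.matrix + self.pseudocount
        p /= p.sum(axis=0, keepdims=True)
        return np.log2(p / self.background[:, None])

    def int_scores(self) -> np.ndarray:
        """Log-odds discretized to integer units of 1/1000 bit."""
        return np.rint(self.log_odds() * SCORE_GRANULARITY).astype(np.int64)

    def score_pvalues(self) -> tuple[np.ndarray, np.ndarray, int]:
        """Exact null distribution of the integer window score.

        Returns ``(tail_p, prob, offset)``: for integer score s,
        ``tail_p[s - offset]`` is P(background w-mer scores >= s).
        """
        s = self.int_scores()
        lo = int(s.min(axis=0).sum())
        hi = int(s.max(axis=0).sum())
        # position-by-position convolution of the score distribution
        cur = np.array([1.0])
        cur_lo = 0
        for j in range(self.width):
            col = s[:, j]
            cmin, cmax = int(col.min()), int(col.max())
            nxt = np.zeros(cur.size + (cmax - cmin))
            for a in range(4):
                sh = int(col[a]) - cmin
                nxt[sh : sh + cur.size] += self.background[a] * cur
            cur = nxt
            cur_lo += cmin
        assert cur_lo == lo and cur.size == hi - lo + 1
        tail = np.cumsum(cur[::-1])[::-1]
        return tail, cur, lo


@dataclass
class MotifHit:
    motif: str
    sequence_id: str
    start: int  # 0-based offset
    stop: int  # exclusive
    score: float  # log2 odds, bits
    p: float


def _parse_minimal_fallback(path) -> list[MotifModel]:
    """Minimal MEME parser used when the file lacks a background section."""
    models = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability matrix"
            ):
                i += 1
            if i >= len(lines):
                raise ValueError(f"motif {name}: missing probability matrix")
            header = lines[i].strip()
            width = int(header.split("w=")[1].split()[0])
            rows = []
            for k in range(width):
                i += 1
                try:
                    rows.append([float(x) for x in lines[i].split()])
                except (IndexError, ValueError) as exc:
                    raise ValueError(
                        f"motif {name}: malformed matrix at line {i + 1}"
                    ) from exc
            models.append(MotifModel(name, np.array(rows).T))
        i += 1
    return models


def read_meme_motifs(path) -> list[MotifModel]:
    """Read motifs from a MEME minimal text file.

    When the file has no background-frequency section a uniform
    background is assumed (with a warning).
    """
    try:
        with open(path) as fh:
            record = bio_motifs.parse(fh, "minimal")
    except Exception:
        warnings.warn(f"{path}: no background section; assuming uniform background")
        return _parse_minimal_fallback(path)
    background = np.array([record.background[b] for b in ALPHABET])
    models = []
    for m in record:
        matrix = np.array([list(m.pwm[b]) for b in ALPHABET])
        models.append(MotifModel(m.name, matrix, background))
    return models


def write_meme_motifs(models: list[MotifModel], path) -> None:
    """Write motifs in MEME minimal text format."""
    if not models:
        raise ValueError("no motifs to write")
    bg = models[0].background
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: +\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.6f}" for b, f in zip(ALPHABET, bg)) + "\n\n")
        for m in models:
            fh.write(f"MOTIF {m.name}\n")
            fh.write(
                # large nsites keeps probability -> count -> probability
                # round-tripping below 1e-6
                f"letter-probability matrix: alength= 4 w= {m.width} nsites= 1000000 E= 0\n"
            )
            for j in range(m.width):
                fh.write(" ".join(f"{x:.6f}" for x in m.matrix[:, j]) + "\n")
            fh.write("\n")


_LETTER_INDEX = {b: i for i, b in enumerate(ALPHABET)}


def scan_pwm(seq: str, motif: MotifModel, alpha: float = 0.001, seq_id: str = "") -> list[MotifHit]:
    """Scan the sense strand of a sequence, keeping hits with p <= alpha.

    Windows containing a non-ACGT character are skipped.  The reported
    p-value is the exact per-window tail probability under the motif's
    0-order background.
    """
    seq = seq.upper()
    w = motif.width
    if len(seq) < w:
        return []
    tail, _, lo = motif.score_pvalues()
    s_int = motif.int_scores()
    lod = motif.log_odds()
    idx = np.array([_LETTER_INDEX.get(c, -1) for c in seq])
    hits = []
    for off in range(len(seq) - w + 1):
        window = idx[off : off + w]
        if (window < 0).any():
            continue
        score_i = int(s_int[window, np.arange(w)].sum())
        p = float(tail[score_i - lo])
        if p <= alpha:
            hits.append(
                MotifHit(
                    motif=motif.name,
                    sequence_id=seq_id,
                    start=off,
                    stop=off + w,
                    score=float(lod[window, np.arange(w)].sum()),
                    p=p,
                )
            )
    return hits


def scan_sequences(
    sequences: dict[str, str], motif: MotifModel, alpha: float = 0.001
) -> list[MotifHit]:
    """Scan a collection of sequences with one motif."""
    hits: list[MotifHit] = []
    for sid, seq in sequences.items():
        hits.extend(scan_pwm(seq, motif, alpha=alpha, seq_id=sid))
    return hits


def hits_to_frame(hits: list[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "motif": h.motif,
                "sequence": h.sequence_id,
                "start_0based": h.start,
                "stop": h.stop,
                "score": h.score,
                "p": h.p,
            }
            for h in hits
        ]
    )


def motif_enrichment_test(
    hits: list[MotifHit],
    query,
    background,
    unit: str = "gene",
    n_windows: dict[str, int] | None = None,
) -> tuple[np.ndarray, float]:
    """One-tailed Fisher enrichment of motif hits in a query gene set.

    Default counting unit is the gene: a gene counts once if it has at
    least one significant hit.  ``unit="hit"`` counts every hit against
    the number of scannable windows per gene (``n_windows``, i.e.
    L - w + 1), pooling offsets.

    Returns the 2x2 counts table ``[[query_with, query_without],
    [rest_with, rest_without]]`` and the enrichment p-value.
    """
    query, background = set(query), set(background)
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    rest = background - query
    if unit == "gene":
        hit_genes = {h.sequence_id for h in hits} & background
        a = len(query & hit_genes)
        c = len(rest & hit_genes)
        table = np.array([[a, len(query) - a], [c, len(rest) - c]])
    elif unit == "hit":
        if n_windows is None:
            raise ValueError("unit='hit' requires n_windows per gene")
        nq = sum(1 for h in hits if h.sequence_id in query)
        nr = sum(1 for h in hits if h.sequence_id in rest)
        wq = sum(n_windows.get(g, 0) for g in query)
        wr = sum(n_windows.get(g, 0) for g in rest)
        table = np.array([[nq, wq - nq], [nr, wr - nr]])
    else:
        raise ValueError(f"unknown counting unit {unit!r}")
    p = stats.fisher_exact_one_tailed(table, "enrichment")
    return table, p


def positional_density(
    hits: list[MotifHit],
    lengths: dict[str, int],
    nbins: int = 100,
) -> np.ndarray:
    """Relative motif density along scaled sequence positions.

    Each hit is placed at its midpoint relative position
    ``(start + w/2)/L`` and accumulated into ``nbins`` bins; the density
    is normalized to sum to 1 (all-zero with a warning when there are no
    hits).
    """
    counts = np.zeros(nbins)
    n_used = 0
    for h in hits:
        L = lengths.get(h.sequence_id)
        if not L:
            continue
        rel = (h.start + (h.stop - h.start) / 2.0) / L
        counts[min(int(rel * nbins), nbins - 1)] += 1
        n_used += 1
    if n_used == 0:
        warnings.warn("no hits with known sequence length; density is all zero")
        return counts
    return counts / counts.sum()
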