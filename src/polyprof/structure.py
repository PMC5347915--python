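"""Metagene profiles of per-nucleotide RNA structure scores.

Structure scores (higher = more double-stranded) are mapped onto the
5'UTR/CDS/3'UTR partition of each transcript and rescaled to a fixed
number of bins per region, so that region profiles of transcripts of
different lengths can be averaged into a meta-profile per gene set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .seqfeatures import REGIONS, TranscriptModel

__all__ = [
    "StructureTrack",
    "read_structure_tracks",
    "bin_scores",
    "MetaProfile",
    "binned_meta_profile",
    "region_mean_comparison",
]


@dataclass
class StructureTrack:
    """Per-nucleotide structure scores in 0-based transcript coordinates."""

    transcript_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)

    def region_scores(self, transcript: TranscriptModel, region: str) -> np.ndarray:
        if len(self.scores) != transcript.length:
            raise ValueError(
                f"{self.transcript_id}: track length {len(self.scores)} != "
                f"transcript length {transcript.length}"
            )
        start, stop = transcript.region_bounds(region)
        return self.scores[start:stop]


def read_structure_tracks(path) -> dict[str, StructureTrack]:
    """Read a long-format TSV: transcript_id, position_0based, score."""
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "position_0based", "score"}
    if not required <= set(df.columns):
        raise ValueError(f"structure TSV must have columns {sorted(required)}")
    tracks = {}
    for tid, grp in df.groupby("transcript_id", sort=False):
        grp = grp.sort_values("position_0based")
        pos = grp["position_0based"].to_numpy()
        if not np.array_equal(pos, np.arange(len(pos))):
            raise ValueError(f"{tid}: positions must cover 0..L-1 without gaps")
        tracks[tid] = StructureTrack(str(tid), grp["score"].to_numpy(float))
    return tracks


def bin_scores(scores: np.ndarray, nbins: int = 100) -> np.ndarray:
    """Rescale a score vector to ``nbins`` by proportional overlap.

    Nucleotide i occupies the relative interval [i/L, (i+1)/L); its score
    is distributed over the bins it overlaps in proportion to the
    overlap.  Every bin receives total weight L/nbins, so the plain mean
    of the bin values equals the region mean exactly, and a region of
    length ``nbins`` maps to itself.
    """
    scores = np.asarray(scores, dtype=float)
    L = scores.size
    if L == 0:
        raise ValueError("empty score vector")
    # piecewise-linear cumulative sum lets fractional spans be read off exactly
    csum = np.concatenate([[0.0], np.cumsum(scores)])

    def integral(x: np.ndarray) -> np.ndarray:
        i = np.minimum(np.floor(x).astype(int), L - 1)
        return csum[i] + (x - i) * scores[i]

    edges = np.linspace(0.0, L, nbins + 1)
    sums = integral(edges[1:]) - integral(edges[:-1])
    return sums / (L / nbins)


@dataclass
class MetaProfile:
    region: str
    nbins: int
    mean: np.ndarray  # per-bin mean across transcripts
    se: np.ndarray  # per-bin standard error across transcripts
    n_transcripts: int
    n_skipped: int  # transcripts without the region or without scores


def binned_meta_profile(
    tracks: dict[str, StructureTrack],
    transcripts: dict[str, TranscriptModel],
    gene_set,
    region: str,
    nbins: int = 100,
) -> MetaProfile:
    """Average region structure profiles of a gene set into ``nbins`` bins.

    Averaging is two-stage: each transcript is first rescaled to the bin
    grid, then bins are averaged across transcripts, so the standard
    error reflects between-transcript variation.  Transcripts with an
    empty region or no structure track are skipped (and counted).
    """
    if region not in (*REGIONS, "full"):
        raise ValueError(f"unknown region {region!r}")
    per_transcript = []
    skipped = 0
    for gid in gene_set:
        t = transcripts.get(gid)
        track = tracks.get(gid)
        if t is None or track is None:
            skipped += 1
            continue
        seg = track.region_scores(t, region)
        if seg.size == 0:
            skipped += 1
            continue
        per_transcript.append(bin_scores(seg, nbins))
    if not per_transcript:
        raise ValueError(f"no transcript in the set has a non-empty {region}")
    mat = np.vstack(per_transcript)
    n = mat.shape[0]
    se = mat.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(nbins)
    return MetaProfile(
        region=region,
        nbins=nbins,
        mean=mat.mean(axis=0),
        se=se,
        n_transcripts=n,
        n_skipped=skipped,
    )


def region_mean_comparison(
    tracks: dict[str, StructureTrack],
    transcripts: dict[str, TranscriptModel],
    set_a,
    background,
    region: str,
    equal_var: bool = True,
) -> dict:
    """Two-sample t-test of per-transcript region mean structure scores.

    The unit of analysis is the transcript (its region mean); Student's
    t with pooled variance by default, Welch via ``equal_var=False``.
    """

    def region_means(genes) -> np.ndarray:
        vals = []
        for gid in genes:
            t, track = transcripts.get(gid), tracks.get(gid)
            if t is None or track is None:
                continue
            seg = track.region_scores(t, region)
            if seg.size:
                vals.append(seg.mean())
        return np.asarray(vals)

    a = region_means(set_a)
    b = region_means(background)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 transcripts with the region")
    t_stat, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return {
        "mean_set": float(a.mean()),
        "mean_background": float(b.mean()),
        "se_set": float(a.std(ddof=1) / np.sqrt(a.size)),
        "se_background": float(b.std(ddof=1) / np.sqrt(b.size)),
        "n_set": int(a.size),
        "n_background": int(b.size),
        "t": float(t_stat),
        "p": float(p),
    }
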