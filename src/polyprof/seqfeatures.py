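"""Per-transcript sequence features and set-vs-background comparisons.

Region lengths and GC content, GC at synonymous third codon positions
(GC3), codon-usage bias via the effective number of codons (Nc), and
upstream open reading frame (uORF) detection in 5'UTRs.  Feature
distributions of translationally regulated gene sets are compared with the
array background by rank tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

from . import stats

__all__ = [
    "TranscriptModel",
    "read_transcripts",
    "region_metrics",
    "CdsValidity",
    "validate_cds",
    "gc3",
    "effective_number_of_codons",
    "find_uorfs",
    "uorf_overrepresentation",
    "feature_table",
    "compare_feature_distributions",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
MIN_CODONS_FOR_BIAS = 100
REGIONS = ("utr5", "cds", "utr3")


def _codon_families(split_sixfold: bool = False) -> dict[str, tuple[str, ...]]:
    """Synonymous codon families of the standard genetic code.

    By default the three 6-fold amino acids (Leu, Ser, Arg) are kept as
    single 6-codon families; ``split_sixfold`` separates each into its
    2-codon and 4-codon subfamilies (labelled e.g. ``L2``/``L4``).
    """
    fwd = CodonTable.unambiguous_dna_by_id[1].forward_table
    fams: dict[str, list[str]] = {}
    for codon, aa in fwd.items():
        fams.setdefault(aa, []).append(codon)
    if split_sixfold:
        out: dict[str, list[str]] = {}
        for aa, codons in fams.items():
            if len(codons) == 6:
                prefixes: dict[str, list[str]] = {}
                for c in codons:
                    prefixes.setdefault(c[:2], []).append(c)
                # the 4-fold box shares one first-two-base prefix
                for prefix, group in prefixes.items():
                    key = f"{aa}{len(group)}" if len(group) == 4 else f"{aa}2"
                    out.setdefault(key, []).extend(group)
            else:
                out[aa] = codons
        fams = out
    return {aa: tuple(sorted(c)) for aa, c in fams.items()}


@dataclass
class TranscriptModel:
    """A transcript split into 5'UTR, CDS and 3'UTR (5'->3', sense strand)."""

    id: str
    utr5: str = ""
    cds: str = ""
    utr3: str = ""

    def __post_init__(self) -> None:
        self.utr5 = self.utr5.upper()
        self.cds = self.cds.upper()
        self.utr3 = self.utr3.upper()

    @property
    def sequence(self) -> str:
        return self.utr5 + self.cds + self.utr3

    @property
    def length(self) -> int:
        return len(self.sequence)

    def region(self, name: str) -> str:
        if name == "full":
            return self.sequence
        if name not in REGIONS:
            raise KeyError(name)
        return getattr(self, name)

    def region_bounds(self, name: str) -> tuple[int, int]:
        """Half-open [start, stop) transcript coordinates of a region."""
        u5, c = len(self.utr5), len(self.cds)
        return {
            "utr5": (0, u5),
            "cds": (u5, u5 + c),
            "utr3": (u5 + c, self.length),
            "full": (0, self.length),
        }[name]

    def has_utr(self, name: str) -> bool:
        """A UTR counts as present only when longer than 1 nucleotide."""
        return len(self.region(name)) > 1


def _read_region_tsv(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    required = {"id", "utr5_len", "cds_len", "utr3_len"}
    if not required <= set(ann.columns):
        raise ValueError(f"region TSV must have columns {sorted(required)}")
    return ann.set_index("id")


def _read_region_gff3(path) -> pd.DataFrame:
    """Collect per-transcript region lengths from transcript-space GFF3.

    Expects ``five_prime_UTR``/``CDS``/``three_prime_UTR`` features with
    1-based inclusive coordinates on the transcript (column 1 = transcript
    id).
    """
    spans: dict[str, dict[str, int]] = {}
    type_map = {"five_prime_UTR": "utr5_len", "CDS": "cds_len", "three_prime_UTR": "utr3_len"}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            seqid, _, ftype, start, end = parts[:5]
            if ftype not in type_map:
                continue
            rec = spans.setdefault(
                seqid, {"utr5_len": 0, "cds_len": 0, "utr3_len": 0}
            )
            rec[type_map[ftype]] += int(end) - int(start) + 1
    out = pd.DataFrame.from_dict(spans, orient="index")
    out.index.name = "id"
    return out


def read_transcripts(fasta_path, annot_path) -> dict[str, TranscriptModel]:
    """Build transcript models from a FASTA and a region annotation.

    The annotation is either a TSV (``id, utr5_len, cds_len, utr3_len``)
    or a GFF3 with UTR/CDS features in transcript coordinates; lengths
    must sum to each sequence length.
    """
    annot_path = str(annot_path)
    if annot_path.endswith((".gff", ".gff3")):
        ann = _read_region_gff3(annot_path)
    else:
        ann = _read_region_tsv(annot_path)
    models = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in ann.index:
            warnings.warn(f"{rec.id}: no region annotation; skipped")
            continue
        seq = str(rec.seq).upper()
        u5, c, u3 = (int(ann.loc[rec.id, k]) for k in ("utr5_len", "cds_len", "utr3_len"))
        if u5 + c + u3 != len(seq):
            raise ValueError(
                f"{rec.id}: region lengths {u5}+{c}+{u3} != sequence length {len(seq)}"
            )
        models[rec.id] = TranscriptModel(rec.id, seq[:u5], seq[u5 : u5 + c], seq[u5 + c :])
    return models


def _gc(seq: str, strict_acgt: bool = False) -> tuple[float | None, int]:
    """GC fraction over A/C/G/T positions; ambiguity codes are dropped."""
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt < len(seq):
        if strict_acgt:
            raise ValueError("non-ACGT character in sequence")
    if acgt == 0:
        return None, 0
    return (seq.count("G") + seq.count("C")) / acgt, acgt


def region_metrics(t: TranscriptModel, strict_acgt: bool = False) -> dict[str, dict]:
    """Length and GC per region and for the full transcript.

    Empty regions report length 0 and GC ``None``.
    """
    out = {}
    for name in (*REGIONS, "full"):
        seq = t.region(name)
        gc, _ = _gc(seq, strict_acgt) if seq else (None, 0)
        out[name] = {"length": len(seq), "gc": gc}
    return out


@dataclass
class CdsValidity:
    has_start: bool
    has_premature_stop: bool
    frame_ok: bool
    codon_count: int
    reason: str | None = None

    @property
    def valid(self) -> bool:
        return self.frame_ok and self.has_start and not self.has_premature_stop

    @property
    def eligible_for_codon_bias(self) -> bool:
        return self.valid and self.codon_count >= MIN_CODONS_FOR_BIAS


def validate_cds(cds: str) -> CdsValidity:
    """Check start codon, reading frame and premature in-frame stops.

    Codon-bias eligibility additionally requires >= 100 codons.
    """
    cds = cds.upper()
    if len(cds) < 3 or len(cds) % 3 != 0:
        return CdsValidity(False, False, False, len(cds) // 3, "length not a multiple of 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    has_start = codons[0] == "ATG"
    premature = any(c in STOP_CODONS for c in codons[:-1])
    reason = None
    if not has_start:
        reason = "missing start codon"
    elif premature:
        reason = "premature stop codon"
    return CdsValidity(has_start, premature, True, len(codons), reason)


def _coding_codons(cds: str) -> list[str]:
    """Codons of a validated CDS, excluding a terminal stop codon."""
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    return codons


def gc3(cds: str, include_start: bool = True) -> float:
    """Fraction of G/C at third codon positions.

    The terminal stop codon is excluded; the start codon is included by
    default (its third base, G, is invariant).
    """
    v = validate_cds(cds)
    if not v.frame_ok:
        raise ValueError(v.reason)
    codons = _coding_codons(cds.upper())
    if not include_start:
        codons = codons[1:]
    if not codons:
        raise ValueError("no codons left for GC3")
    thirds = [c[2] for c in codons]
    return sum(b in "GC" for b in thirds) / len(thirds)


def effective_number_of_codons(
    cds: str,
    method: str = "sun2013",
    split_sixfold: bool = False,
) -> float | None:
    """Effective number of codons (Nc) of a CDS.

    Nc ranges from 20 (a single codon per amino acid, extreme bias) to 61
    (all sense codons used evenly).  The default estimator adds a
    pseudocount of one per codon within each synonymous family: with
    within-family counts ``n_i`` (total n, family size m),
    ``F = sum_i ((n_i + 1)/(n + m))**2`` and ``Nc = sum_families 1/F``.
    Met and Trp contribute exactly 1 each and stop codons are excluded,
    so uniform usage gives Nc = 61 exactly.

    ``method="wright1990"`` gives the classic homozygosity estimator
    ``F = (n * sum p_i**2 - 1)/(n - 1)`` with degeneracy-class averaging,
    for comparison.

    Returns ``None`` (with the reason warned) for CDSs not eligible for
    codon-bias analysis (invalid, or shorter than 100 codons).
    """
    v = validate_cds(cds)
    if not v.eligible_for_codon_bias:
        warnings.warn(f"CDS not eligible for codon bias: {v.reason or 'fewer than 100 codons'}")
        return None
    fams = _codon_families(split_sixfold)
    counts: dict[str, int] = {}
    for codon in _coding_codons(cds.upper()):
        counts[codon] = counts.get(codon, 0) + 1

    if method == "sun2013":
        nc = 0.0
        for codons in fams.values():
            m = len(codons)
            n_i = np.array([counts.get(c, 0) for c in codons], dtype=float)
            n = n_i.sum()
            f = (((n_i + 1.0) / (n + m)) ** 2).sum()
            nc += 1.0 / f
        return float(nc)

    if method == "wright1990":
        by_deg: dict[int, list[float]] = {}
        n_single = 0
        for codons in fams.values():
            m = len(codons)
            if m == 1:
                n_single += 1
                continue
            n_i = np.array([counts.get(c, 0) for c in codons], dtype=float)
            n = n_i.sum()
            if n < 2:
                continue
            p = n_i / n
            f = (n * (p**2).sum() - 1.0) / (n - 1.0)
            if f > 0:
                by_deg.setdefault(m, []).append(f)
        class_sizes = {}
        for codons in fams.values():
            m = len(codons)
            if m > 1:
                class_sizes[m] = class_sizes.get(m, 0) + 1
        nc = float(n_single)
        for m, k in class_sizes.items():
            fs = by_deg.get(m)
            if not fs:  # class unobserved: assume no bias information
                nc += k
                continue
            nc += k / float(np.mean(fs))
        return float(min(nc, 61.0))

    raise ValueError(f"unknown method {method!r}")


def find_uorfs(
    t: TranscriptModel,
    min_codons: int = 2,
    allow_cds_overlap: bool = True,
) -> list[tuple[int, int]]:
    """Upstream ORFs: ATGs in the 5'UTR with an in-frame stop downstream.

    Returns half-open (start, stop_end) transcript coordinates, stop
    codon included.  ``min_codons`` counts the stop codon.  When
    ``allow_cds_overlap`` is false the whole uORF must lie within the
    5'UTR.  Within one reading frame, an ATG nested inside an already
    counted uORF does not start a new one (first ATG wins).
    """
    u5 = len(t.utr5)
    if u5 == 0:
        return []
    seq = t.sequence
    uorfs: list[tuple[int, int]] = []
    claimed_until = {0: -1, 1: -1, 2: -1}  # per frame, end of the last counted uORF
    for start in range(u5 - 2):
        if seq[start : start + 3] != "ATG":
            continue
        frame = start % 3
        if start <= claimed_until[frame]:
            continue
        for pos in range(start, len(seq) - 2, 3):
            if seq[pos : pos + 3] in STOP_CODONS:
                end = pos + 3
                n_codons = (end - start) // 3
                if n_codons >= min_codons and (allow_cds_overlap or end <= u5):
                    uorfs.append((start, end))
                    claimed_until[frame] = end - 1
                break
    return uorfs


def uorf_overrepresentation(
    query, uorf_genes, background
) -> tuple[int, float, float, float]:
    """Chi-square test of uORF-gene over-representation in a query set.

    Returns ``(observed, expected, statistic, p)``; the uORF class is
    intersected with the background before testing.
    """
    query, background = set(query), set(background)
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    uorf_in_bg = set(uorf_genes) & background
    observed = len(query & uorf_in_bg)
    expected, stat, p = stats.chisq_2x2(
        observed, len(query), len(uorf_in_bg), len(background)
    )
    return observed, expected, stat, p


def feature_table(
    transcripts: dict[str, TranscriptModel],
    external: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-transcript feature table (lengths, GC, GC3, Nc, uORF count).

    ``external`` (e.g. decay rates, intron counts) is joined on the
    transcript id.  Features that are undefined for a transcript (empty
    region, ineligible CDS) are left as NaN.
    """
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tid, t in transcripts.items():
            metrics = region_metrics(t)
            row: dict = {"id": tid}
            for region in (*REGIONS, "full"):
                row[f"{region}_length"] = metrics[region]["length"]
                row[f"{region}_gc"] = metrics[region]["gc"]
            v = validate_cds(t.cds) if t.cds else None
            if v is not None and v.frame_ok:
                row["gc3"] = gc3(t.cds)
                row["nc"] = effective_number_of_codons(t.cds)
            else:
                row["gc3"] = None
                row["nc"] = None
            row["uorf_count"] = len(find_uorfs(t)) if t.utr5 else 0
            rows.append(row)
    out = pd.DataFrame(rows).set_index("id").astype(float)
    if external is not None:
        out = out.join(external, how="left")
    return out


def compare_feature_distributions(
    gene_sets: dict[str, set],
    background,
    features: pd.DataFrame,
) -> pd.DataFrame:
    """Rank-test every (set, feature) pair against the background.

    The comparison uses the two-sample Mann-Whitney rank-sum test (the
    set-vs-background design is unpaired) with medians reported as the
    descriptive statistic; NaN feature values are excluded and ``n``
    reflects the non-null set size.
    """
    background = [g for g in background if g in features.index]
    rows = []
    for set_name, genes in gene_sets.items():
        genes = [g for g in genes if g in features.index]
        for feat in features.columns:
            sv = features.loc[genes, feat].dropna()
            bv = features.loc[background, feat].dropna()
            row = {
                "set": set_name,
                "feature": feat,
                "n": int(sv.size),
                "set_median": float(sv.median()) if sv.size else np.nan,
                "background_median": float(bv.median()) if bv.size else np.nan,
            }
            if sv.size and bv.size:
                _, p = stats.mann_whitney_u(sv.to_numpy(), bv.to_numpy(), "two-sided")
                row["p"] = p
                row["direction"] = (
                    "higher" if row["set_median"] > row["background_median"] else "lower"
                )
            else:
                row["p"] = np.nan
                row["direction"] = None
            rows.append(row)
    return pd.DataFrame(rows)
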