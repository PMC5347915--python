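"""Synthetic data generators with ground truth for every pipeline stage.

The default settings emulate a germination-style polysome-profiling
study: five time points (0, 6, 26, 48 and 72 hours after the start of
imbibition) x {total, polysomal} fractions x 3 replicates on a log2
intensity scale, with planted transcriptional effects (both fractions)
and translational effects (polysomal fraction only) confined to the two
transition intervals 0->6 and 26->48.  Companion generators emit
transcriptomes with controllable length/GC/codon-bias/uORF content and
planted motifs, per-nucleotide structure tracks with dips at the CDS
start and stop, gradient absorbance traces built from Gaussian peaks on
a linear baseline, and spike-in qPCR Cq tables.

Every generator is deterministic given the configuration seed, and each
returns a ground-truth object consistent with the emitted data, so the
analysis modules can be scored against known answers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio.Data import CodonTable

from .expression import ExpressionMatrix
from .gradients import GradientTrace
from .motifs import MotifModel, write_meme_motifs
from .seqfeatures import STOP_CODONS, TranscriptModel
from .structure import StructureTrack

__all__ = [
    "PlantedSet",
    "ExpressionConfig",
    "TranscriptomeConfig",
    "StructureConfig",
    "GradientConfig",
    "QpcrConfig",
    "SimulationConfig",
    "simulate_expression",
    "simulate_transcriptome",
    "simulate_structure_tracks",
    "simulate_gradient_trace",
    "simulate_cq_table",
    "simulate_all",
]


@dataclass
class PlantedSet:
    """A disjoint gene set carrying one planted effect.

    ``kind="transcriptional"`` adds the effect to both fractions from the
    end of the interval onward (total mRNA change, PO unchanged);
    ``kind="translational"`` adds it to the polysomal fraction only
    (PO change of the same magnitude).
    """

    name: str
    size: int
    kind: str  # transcriptional | translational
    interval: tuple[float, float]
    effect: float  # log2 units


def _default_planted() -> list[PlantedSet]:
    # translational set sizes echo the scale of germination studies:
    # ~1200 down / ~450 up at hydration, ~700 down / ~200 up at germination
    return [
        PlantedSet("hts_down", 1200, "translational", (0, 6), -1.5),
        PlantedSet("hts_up", 450, "translational", (0, 6), +1.5),
        PlantedSet("gts_down", 700, "translational", (26, 48), -1.5),
        PlantedSet("gts_up", 200, "translational", (26, 48), +1.5),
        PlantedSet("txn_up_hydration", 1000, "transcriptional", (0, 6), +2.0),
        PlantedSet("txn_down_hydration", 1000, "transcriptional", (0, 6), -2.0),
        PlantedSet("txn_up_germination", 800, "transcriptional", (26, 48), +2.0),
        PlantedSet("txn_down_germination", 800, "transcriptional", (26, 48), -2.0),
    ]


@dataclass
class ExpressionConfig:
    n_genes: int = 20000
    time_points: tuple = (0, 6, 26, 48, 72)
    n_replicates: int = 3
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.25
    planted: list[PlantedSet] = field(default_factory=_default_planted)
    # optional inverse-gamma per-gene variance heterogeneity (prior df);
    # None keeps the noise homoscedastic
    variance_prior_df: float | None = None


@dataclass
class TranscriptomeConfig:
    n_transcripts: int = 300
    utr5_mean: int = 130
    utr3_mean: int = 230
    cds_codons_mean: int = 400
    cds_codons_min: int = 40
    utr_gc: float = 0.36
    utr_absent_prob: float = 0.05
    codon_bias: float = 0.3  # 0 = uniform synonymous usage, 1 = single codon
    uorf_probability: float = 0.2
    uorf_codons: tuple[int, int] = (3, 8)  # body length range, incl. stop
    motif_consensus: str | None = "GAAGAAGAAG"
    motif_region: str = "utr5"
    motif_set_size: int = 30
    motif_rel_position: float = 0.8  # relative position within the region


@dataclass
class StructureConfig:
    region_means: tuple[float, float, float] = (0.30, 0.55, 0.35)  # 5'UTR, CDS, 3'UTR
    dip_depth: float = 0.4
    dip_width: float = 12.0  # Gaussian sd of the start/stop dips, nt
    noise_sd: float = 0.10
    # name -> (region, additive offset) applied to a designated gene set
    planted_offsets: dict = field(default_factory=dict)
    planted_sets: dict = field(default_factory=dict)  # name -> list of transcript ids


@dataclass
class GradientConfig:
    # (center, sd, height) per Gaussian peak; the first three are the
    # 40S/60S/80S region, the rest the polysome series
    peaks: tuple = (
        (1.0, 0.18, 0.15),
        (1.5, 0.18, 0.20),
        (2.2, 0.22, 1.00),
        (3.2, 0.25, 0.50),
        (4.0, 0.25, 0.35),
        (4.8, 0.25, 0.25),
        (5.6, 0.25, 0.15),
        (6.4, 0.25, 0.08),
    )
    n_monosome_peaks: int = 3  # leading peaks counted as <= 1 ribosome
    baseline_intercept: float = 0.10
    baseline_slope: float = 0.02
    boundary: float = 2.8
    x_range: tuple[float, float] = (0.0, 10.0)
    n_points: int = 1001
    noise_sd: float = 0.002


@dataclass
class QpcrConfig:
    rrna_cq: dict = field(
        default_factory=lambda: {"cytosolic": 10.0, "plastidic": 11.0, "mitochondrial": 12.0}
    )
    spike_cq: dict = field(
        default_factory=lambda: {"lys": 20.0, "phe": 19.0, "thr": 18.0, "dap": 16.5}
    )
    efficiency: float = 2.0
    cq_noise_sd: float = 0.0


@dataclass
class SimulationConfig:
    seed: int
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    transcriptome: TranscriptomeConfig = field(default_factory=TranscriptomeConfig)
    structure: StructureConfig = field(default_factory=StructureConfig)
    gradient: GradientConfig = field(default_factory=GradientConfig)
    qpcr: QpcrConfig = field(default_factory=QpcrConfig)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        kwargs = {"seed": int(raw["seed"])}
        for key, klass in (
            ("expression", ExpressionConfig),
            ("transcriptome", TranscriptomeConfig),
            ("structure", StructureConfig),
            ("gradient", GradientConfig),
            ("qpcr", QpcrConfig),
        ):
            if key in raw:
                section = dict(raw[key])
                if key == "expression" and "planted" in section:
                    section["planted"] = [
                        PlantedSet(
                            name=p["name"],
                            size=int(p["size"]),
                            kind=p["kind"],
                            interval=tuple(p["interval"]),
                            effect=float(p["effect"]),
                        )
                        for p in section["planted"]
                    ]
                kwargs[key] = klass(**section)
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# expression


def simulate_expression(cfg: SimulationConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate the paired total/polysomal time-course matrix.

    value(gene, time, fraction, replicate) = baseline_g
      + transcriptional effect (both fractions, from the interval's end)
      + translational effect (polysomal only)
      + Normal(0, noise_sd).

    Returns the matrix and a per-gene truth table (set, kind, interval,
    effect; NaN rows for unplanted genes).
    """
    ec = cfg.expression
    rng = np.random.default_rng(cfg.seed)
    n_planted = sum(p.size for p in ec.planted)
    if n_planted > ec.n_genes:
        raise ValueError("planted sets exceed the number of genes")
    genes = [f"g{i:05d}" for i in range(ec.n_genes)]
    order = rng.permutation(ec.n_genes)

    truth = pd.DataFrame(
        {
            "set": pd.Series([None] * ec.n_genes, dtype=object),
            "kind": pd.Series([None] * ec.n_genes, dtype=object),
            "interval_start": np.nan,
            "interval_end": np.nan,
            "effect": np.nan,
        },
        index=pd.Index(genes, name="gene"),
    )
    pos = 0
    for p in ec.planted:
        idx = order[pos : pos + p.size]
        pos += p.size
        gsel = [genes[i] for i in idx]
        truth.loc[gsel, "set"] = p.name
        truth.loc[gsel, "kind"] = p.kind
        truth.loc[gsel, "interval_start"] = p.interval[0]
        truth.loc[gsel, "interval_end"] = p.interval[1]
        truth.loc[gsel, "effect"] = p.effect

    baseline = rng.normal(ec.baseline_mean, ec.baseline_sd, size=ec.n_genes)
    if ec.variance_prior_df is not None:
        d0 = ec.variance_prior_df
        gene_var = ec.noise_sd**2 * d0 / rng.chisquare(d0, size=ec.n_genes)
    else:
        gene_var = np.full(ec.n_genes, ec.noise_sd**2)
    gene_sd = np.sqrt(gene_var)

    txn = np.zeros((ec.n_genes, len(ec.time_points)))
    trl = np.zeros_like(txn)
    for p in ec.planted:
        mask = (truth["set"] == p.name).to_numpy()
        step = np.array([t >= p.interval[1] for t in ec.time_points], dtype=float)
        target = txn if p.kind == "transcriptional" else trl
        target[mask] += p.effect * step

    columns, data, meta = [], [], []
    for ti, tp in enumerate(ec.time_points):
        for fraction in ("total", "polysomal"):
            for rep in range(1, ec.n_replicates + 1):
                sid = f"t{tp}_{fraction}_r{rep}"
                mean = baseline + txn[:, ti]
                if fraction == "polysomal":
                    mean = mean + trl[:, ti]
                data.append(mean + rng.normal(0, 1, size=ec.n_genes) * gene_sd)
                columns.append(sid)
                meta.append(
                    {"sample_id": sid, "time_point": tp, "fraction": fraction, "replicate": rep}
                )
    values = pd.DataFrame(np.column_stack(data), index=genes, columns=columns)
    samples = pd.DataFrame(meta).set_index("sample_id")
    return ExpressionMatrix(values, samples), truth


# ---------------------------------------------------------------------------
# transcriptome

_SENSE_CODONS = sorted(CodonTable.unambiguous_dna_by_id[1].forward_table)
_FAMILIES: dict[str, list[str]] = {}
for _c in _SENSE_CODONS:
    _FAMILIES.setdefault(CodonTable.unambiguous_dna_by_id[1].forward_table[_c], []).append(_c)
# preferred codon per family: the most G/C-rich third position, so that
# increasing bias strength also raises GC3 (as optimal codons tend to)
_PREFERRED = {
    aa: max(codons, key=lambda c: (c[2] in "GC", c))
    for aa, codons in _FAMILIES.items()
}


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])


def _scrub_atg(seq: list[str], allowed_starts: set[int], protected: list[tuple[int, int]]) -> None:
    """Mutate every ATG whose start is not whitelisted.

    The mutated position is chosen outside protected spans (planted
    motifs, uORF bodies) so insertions survive; the offending base is
    replaced by C.
    """

    def is_protected(i: int) -> bool:
        return any(a <= i < b for a, b in protected)

    changed = True
    while changed:
        changed = False
        s = "".join(seq)
        start = s.find("ATG")
        while start != -1:
            if start not in allowed_starts:
                for off in (2, 1, 0):  # prefer mutating the G
                    if not is_protected(start + off):
                        seq[start + off] = "C"
                        changed = True
                        break
                else:  # fully protected occurrence: leave it (cannot happen
                    pass  # with ATG-free protected content)
            start = s.find("ATG", start + 1)
            if changed:
                break


def _sample_cds(rng: np.random.Generator, n_codons: int, bias: float) -> str:
    """CDS whose within-family codon usage tracks the bias dial exactly.

    Codons are drawn by quota balancing: within each synonymous family
    the next codon is the one furthest below its target share, so at
    bias 0 the counts are as equal as possible (Nc near its 61 maximum
    for realistic lengths) and at bias 1 only the preferred codon is
    used (Nc near 20).  Amino acids themselves are drawn uniformly.
    """
    aas = list(_FAMILIES)
    chosen = rng.choice(len(aas), size=n_codons - 1)
    counts: dict[str, int] = {}
    fam_totals: dict[str, int] = {}
    codons = ["ATG"]
    for k in chosen:
        aa = aas[k]
        fam = _FAMILIES[aa]
        m = len(fam)
        w = np.full(m, (1.0 - bias) / m)
        w[fam.index(_PREFERRED[aa])] += bias
        n = fam_totals.get(aa, 0)
        deficit = (n + 1) * w - np.array([counts.get(c, 0) for c in fam])
        deficit += rng.uniform(0, 1e-9, size=m)  # random tie-break
        pick = fam[int(np.argmax(deficit))]
        counts[pick] = counts.get(pick, 0) + 1
        fam_totals[aa] = n + 1
        codons.append(pick)
    codons.append(rng.choice(sorted(STOP_CODONS)))
    return "".join(codons)


@dataclass
class TranscriptomeTruth:
    uorf_counts: dict[str, int]
    uorf_positions: dict[str, list[tuple[int, int]]]  # transcript coords
    motif_genes: set[str]
    motif_positions: dict[str, int]  # transcript coords of the planted instance


def simulate_transcriptome(
    cfg: SimulationConfig,
) -> tuple[dict[str, TranscriptModel], TranscriptomeTruth]:
    """Generate transcripts with known uORF content and planted motifs.

    5'UTRs are kept free of ATG triplets except at inserted uORF starts,
    so the true uORF count equals exactly what a scanner finds; CDSs
    start with ATG, end with a stop, and contain no internal stops.  The
    codon-bias parameter interpolates between uniform synonymous usage
    (Nc near 61) and single-codon usage (Nc near 20).
    """
    tc = cfg.transcriptome
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    models: dict[str, TranscriptModel] = {}
    truth = TranscriptomeTruth({}, {}, set(), {})
    motif = tc.motif_consensus
    motif_ids = set()
    if motif:
        ids = rng.choice(tc.n_transcripts, size=min(tc.motif_set_size, tc.n_transcripts), replace=False)
        motif_ids = {f"tr{i:04d}" for i in ids}
    for i in range(tc.n_transcripts):
        tid = f"tr{i:04d}"
        u5_len = 0 if rng.random() < tc.utr_absent_prob else max(
            20, int(rng.gamma(2.0, tc.utr5_mean / 2.0))
        )
        u3_len = 0 if rng.random() < tc.utr_absent_prob else max(
            20, int(rng.gamma(2.0, tc.utr3_mean / 2.0))
        )
        n_codons = max(tc.cds_codons_min, int(rng.gamma(3.0, tc.cds_codons_mean / 3.0)))
        utr5 = list(_random_seq(rng, u5_len, tc.utr_gc))
        utr3 = _random_seq(rng, u3_len, tc.utr_gc)
        cds = _sample_cds(rng, n_codons, tc.codon_bias)

        protected: list[tuple[int, int]] = []
        allowed: set[int] = set()
        uorfs: list[tuple[int, int]] = []
        if u5_len >= 40 and rng.random() < tc.uorf_probability:
            body = int(rng.integers(tc.uorf_codons[0], tc.uorf_codons[1] + 1))
            length = 3 * body
            start = int(rng.integers(0, u5_len - length + 1))
            # A-free body codons avoid incidental ATGs inside the uORF
            body_codons = ["".join(rng.choice(list("CGT"), size=3)) for _ in range(body - 2)]
            body_codons = [c if c not in STOP_CODONS else "CCG" for c in body_codons]
            insert = "ATG" + "".join(body_codons) + "TAA"
            utr5[start : start + length] = list(insert)
            allowed.add(start)
            protected.append((start, start + length))
            uorfs.append((start, start + length))
        if tid in motif_ids and tc.motif_region == "utr5" and u5_len >= len(motif) + 2:
            free = [
                p
                for p in range(u5_len - len(motif) + 1)
                if not any(a < p + len(motif) and p < b for a, b in protected)
            ]
            if free:
                p = min(free, key=lambda x: abs(x - tc.motif_rel_position * u5_len))
                utr5[p : p + len(motif)] = list(motif)
                protected.append((p, p + len(motif)))
                truth.motif_genes.add(tid)
                truth.motif_positions[tid] = p
        _scrub_atg(utr5, allowed, protected)
        models[tid] = TranscriptModel(tid, "".join(utr5), cds, utr3)
        truth.uorf_counts[tid] = len(uorfs)
        truth.uorf_positions[tid] = uorfs
    return models, truth


# ---------------------------------------------------------------------------
# structure tracks


def simulate_structure_tracks(
    transcripts: dict[str, TranscriptModel],
    cfg: SimulationConfig,
) -> tuple[dict[str, StructureTrack], pd.DataFrame]:
    """Per-nucleotide structure scores with start/stop dips.

    score = region mean + planted set offset - Gaussian dips centered on
    the CDS start and stop + Normal(0, noise).  Returns the tracks and a
    truth table of each transcript's planted offset per region.
    """
    sc = cfg.structure
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    region_mean = dict(zip(("utr5", "cds", "utr3"), sc.region_means))
    offsets_by_gene: dict[str, dict[str, float]] = {}
    for set_name, (region, offset) in sc.planted_offsets.items():
        for gid in sc.planted_sets.get(set_name, []):
            offsets_by_gene.setdefault(gid, {})[region] = offset

    tracks = {}
    rows = []
    for tid, t in transcripts.items():
        base = np.empty(t.length)
        for region in ("utr5", "cds", "utr3"):
            a, b = t.region_bounds(region)
            base[a:b] = region_mean[region] + offsets_by_gene.get(tid, {}).get(region, 0.0)
        pos = np.arange(t.length, dtype=float)
        cds_start, cds_stop = t.region_bounds("cds")
        dip = sc.dip_depth * (
            np.exp(-((pos - cds_start) ** 2) / (2 * sc.dip_width**2))
            + np.exp(-((pos - (cds_stop - 1)) ** 2) / (2 * sc.dip_width**2))
        )
        scores = base - dip + rng.normal(0, sc.noise_sd, size=t.length)
        tracks[tid] = StructureTrack(tid, scores)
        rows.append(
            {
                "transcript_id": tid,
                **{f"{r}_offset": offsets_by_gene.get(tid, {}).get(r, 0.0) for r in ("utr5", "cds", "utr3")},
            }
        )
    return tracks, pd.DataFrame(rows).set_index("transcript_id")


# ---------------------------------------------------------------------------
# gradient traces and qPCR


def simulate_gradient_trace(
    cfg: SimulationConfig,
) -> tuple[GradientTrace, GradientTrace, float]:
    """Gaussian-peak absorbance trace, its blank, and the true loading.

    The blank carries only the linear baseline; the true polysome loading
    is the analytic mass of the polysome peaks divided by the total peak
    mass (each Gaussian's mass is height * sd * sqrt(2*pi)).
    """
    gc = cfg.gradient
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    x = np.linspace(*gc.x_range, gc.n_points)
    baseline = gc.baseline_intercept + gc.baseline_slope * x
    signal = np.zeros_like(x)
    masses = []
    for center, sd, height in gc.peaks:
        signal += height * np.exp(-((x - center) ** 2) / (2 * sd**2))
        masses.append(height * sd * np.sqrt(2 * np.pi))
    masses = np.asarray(masses)
    true_loading = float(masses[gc.n_monosome_peaks :].sum() / masses.sum())
    noisy = signal + baseline + rng.normal(0, gc.noise_sd, size=x.size)
    return GradientTrace(x, noisy), GradientTrace(x, baseline), true_loading


def simulate_cq_table(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.Series]:
    """qPCR Cq table (rRNA targets + spike-ins) with true rRNA fractions."""
    qc = cfg.qpcr
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 4]))
    rows = []
    for target, cq in {**qc.rrna_cq, **qc.spike_cq}.items():
        rows.append(
            {
                "target": target,
                "cq": cq + rng.normal(0, qc.cq_noise_sd),
                "efficiency": qc.efficiency,
                "is_spike": target in qc.spike_cq,
            }
        )
    table = pd.DataFrame(rows)
    q = pd.Series(
        {t: qc.efficiency ** (-cq) for t, cq in qc.rrna_cq.items()}, dtype=float
    )
    return table, q / q.sum()


# ---------------------------------------------------------------------------
# orchestration


def simulate_all(cfg: SimulationConfig, outdir) -> dict[str, Path]:
    """Generate every input the pipeline consumes and write it to disk.

    Emits the expression matrix + sample metadata, transcript FASTA +
    region TSV, structure-score TSV, a MEME file with the planted motif,
    gradient trace/blank TSVs, a qPCR Cq table, and the matching truth
    tables.  Returns the paths keyed by artifact name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    matrix, truth = simulate_expression(cfg)
    paths["matrix"] = outdir / "matrix.tsv"
    matrix.values.rename_axis("gene").to_csv(paths["matrix"], sep="\t")
    paths["samples"] = outdir / "samples.tsv"
    matrix.samples.rename_axis("sample_id").to_csv(paths["samples"], sep="\t")
    paths["expression_truth"] = outdir / "expression_truth.tsv"
    truth.to_csv(paths["expression_truth"], sep="\t")

    transcripts, tr_truth = simulate_transcriptome(cfg)
    paths["fasta"] = outdir / "transcripts.fasta"
    with open(paths["fasta"], "w") as fh:
        for t in transcripts.values():
            fh.write(f">{t.id}\n{t.sequence}\n")
    paths["regions"] = outdir / "regions.tsv"
    pd.DataFrame(
        [
            {"id": t.id, "utr5_len": len(t.utr5), "cds_len": len(t.cds), "utr3_len": len(t.utr3)}
            for t in transcripts.values()
        ]
    ).to_csv(paths["regions"], sep="\t", index=False)
    paths["transcriptome_truth"] = outdir / "transcriptome_truth.json"
    with open(paths["transcriptome_truth"], "w") as fh:
        json.dump(
            {
                "uorf_counts": tr_truth.uorf_counts,
                "motif_genes": sorted(tr_truth.motif_genes),
                "motif_positions": tr_truth.motif_positions,
            },
            fh,
            indent=1,
        )

    tracks, st_truth = simulate_structure_tracks(transcripts, cfg)
    paths["structure"] = outdir / "structure.tsv"
    with open(paths["structure"], "w") as fh:
        fh.write("transcript_id\tposition_0based\tscore\n")
        for tid, track in tracks.items():
            for pos, score in enumerate(track.scores):
                fh.write(f"{tid}\t{pos}\t{score:.5f}\n")
    paths["structure_truth"] = outdir / "structure_truth.tsv"
    st_truth.to_csv(paths["structure_truth"], sep="\t")

    if cfg.transcriptome.motif_consensus:
        consensus = cfg.transcriptome.motif_consensus
        matrix4 = np.full((4, len(consensus)), 0.01)
        for j, c in enumerate(consensus):
            matrix4["ACGT".index(c), j] = 0.97
        paths["motifs"] = outdir / "motifs.meme"
        write_meme_motifs([MotifModel("planted", matrix4)], paths["motifs"])

    trace, blank, loading = simulate_gradient_trace(cfg)
    for key, tr in (("trace", trace), ("blank", blank)):
        paths[key] = outdir / f"{key}.tsv"
        pd.DataFrame({"position": tr.positions, "absorbance": tr.absorbance}).to_csv(
            paths[key], sep="\t", index=False
        )
    paths["gradient_truth"] = outdir / "gradient_truth.json"
    with open(paths["gradient_truth"], "w") as fh:
        json.dump({"true_loading": loading, "boundary": cfg.gradient.boundary}, fh)

    cq, fractions = simulate_cq_table(cfg)
    paths["cq"] = outdir / "cq.tsv"
    cq.to_csv(paths["cq"], sep="\t", index=False)
    paths["qpcr_truth"] = outdir / "qpcr_truth.json"
    with open(paths["qpcr_truth"], "w") as fh:
        json.dump(fractions.to_dict(), fh)
    return paths
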