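"""Sequence features: region metrics, CDS validity, GC3, Nc, uORFs."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyprof import seqfeatures as sf


# ---------------------------------------------------------------------------
# region metrics


def test_region_metrics_extremes():
    t = sf.TranscriptModel("t", utr5="", cds="GCGC", utr3="")
    m = sf.region_metrics(t)
    assert m["cds"] == {"length": 4, "gc": 1.0}
    assert m["utr5"] == {"length": 0, "gc": None}
    assert sf.region_metrics(sf.TranscriptModel("t", cds="ATAT"))["cds"]["gc"] == 0.0


def test_region_metrics_full_transcript():
    t = sf.TranscriptModel("t", utr5="AGGC", cds="ATGTAA")
    m = sf.region_metrics(t)
    assert m["full"]["length"] == 10
    assert m["full"]["gc"] == pytest.approx(0.4)


def test_full_gc_is_length_weighted_mean_of_regions(rng):
    bases = np.array(list("ACGT"))
    t = sf.TranscriptModel(
        "t",
        utr5="".join(rng.choice(bases, 37)),
        cds="".join(rng.choice(bases, 120)),
        utr3="".join(rng.choice(bases, 53)),
    )
    m = sf.region_metrics(t)
    weighted = sum(
        m[r]["gc"] * m[r]["length"] for r in ("utr5", "cds", "utr3")
    ) / m["full"]["length"]
    assert m["full"]["gc"] == pytest.approx(weighted)


def test_ambiguity_codes_excluded_from_gc():
    m = sf.region_metrics(sf.TranscriptModel("t", cds="GCNN"))
    assert m["cds"]["gc"] == 1.0  # N dropped from numerator and denominator
    with pytest.raises(ValueError):
        sf.region_metrics(sf.TranscriptModel("t", cds="GCNN"), strict_acgt=True)


def test_utr_presence_needs_more_than_one_nt():
    assert not sf.TranscriptModel("t", utr5="A", cds="ATGTAA").has_utr("utr5")
    assert sf.TranscriptModel("t", utr5="AG", cds="ATGTAA").has_utr("utr5")


# ---------------------------------------------------------------------------
# CDS validity and GC3


@pytest.mark.parametrize(
    "cds,start,premature,count",
    [
        ("ATGAAATAA", True, False, 3),
        ("ATGTAAAAA", True, True, 3),
        ("CTGAAATAA", False, False, 3),
    ],
)
def test_validate_cds_flags(cds, start, premature, count):
    v = sf.validate_cds(cds)
    assert v.frame_ok
    assert v.has_start == start
    assert v.has_premature_stop == premature
    assert v.codon_count == count
    assert not v.eligible_for_codon_bias  # all far below 100 codons


def test_validate_cds_frame_violation():
    v = sf.validate_cds("ATGAAATA")
    assert not v.frame_ok and not v.valid
    assert "multiple of 3" in v.reason


def test_gc3_excludes_terminal_stop():
    # codons ATG GCG AAA TTC + stop: thirds G, G, A, C
    assert sf.gc3("ATGGCGAAATTCTAA") == pytest.approx(3 / 4)
    assert sf.gc3("ATGGCGAAATTCTAA", include_start=False) == pytest.approx(2 / 3)


def test_gc3_extremes():
    assert sf.gc3("GCGGCCGGC") == 1.0
    assert sf.gc3("ATTAAAATATAA") == 0.0


# ---------------------------------------------------------------------------
# effective number of codons


def uniform_usage_cds(repeats=3):
    """CDS using every sense codon equally often (start/stop corrected)."""
    families = sf._codon_families()
    body = "".join(c for fam in families.values() for c in fam if c != "ATG")
    return "ATG" + body * repeats + "TAA"


def single_codon_cds(n_codons=3000):
    families = sf._codon_families()
    picks = [fam[0] for fam in families.values() if fam[0] != "ATG"]
    seq = "ATG" + "".join(picks[i % len(picks)] for i in range(n_codons - 2)) + "TAA"
    return seq


def test_nc_uniform_usage_is_exactly_61():
    assert sf.effective_number_of_codons(uniform_usage_cds()) == pytest.approx(
        61.0, abs=1e-12
    )


def test_nc_single_codon_usage_approaches_20():
    nc = sf.effective_number_of_codons(single_codon_cds())
    assert 20.0 <= nc <= 21.0


def test_nc_range_and_monotone_concentration():
    # concentrating usage within families can only lower Nc
    families = sf._codon_families()
    rng = np.random.default_rng(5)
    prev = None
    for bias in (0.0, 0.5, 0.9):
        codons = []
        for _ in range(600):
            fam = families[list(families)[rng.integers(len(families))]]
            m = len(fam)
            w = np.full(m, (1 - bias) / m)
            w[0] += bias
            codons.append(fam[rng.choice(m, p=w)])
        cds = "ATG" + "".join(c for c in codons if c != "ATG") + "TAA"
        nc = sf.effective_number_of_codons(cds)
        assert 20.0 <= nc <= 61.0
        if prev is not None:
            assert nc < prev
        prev = nc


def test_nc_invariant_to_synonymous_relabelling():
    # swapping which synonymous codon carries the counts leaves Nc unchanged
    cds_a = "ATG" + "GCT" * 60 + "AAA" * 60 + "TAA"
    cds_b = "ATG" + "GCC" * 60 + "AAG" * 60 + "TAA"
    assert sf.effective_number_of_codons(cds_a) == pytest.approx(
        sf.effective_number_of_codons(cds_b)
    )


def test_nc_hand_computed_value():
    # 121 coding codons: Ala GCT x40/GCC x20, Lys AAA x30/AAG x30, Met start
    cds = "ATG" + "GCT" * 40 + "GCC" * 20 + "AAA" * 30 + "AAG" * 30 + "TAA"
    families = sf._codon_families()
    expected = 0.0
    counts = {"GCT": 40, "GCC": 20, "AAA": 30, "AAG": 30, "ATG": 1}
    for fam in families.values():
        m = len(fam)
        n_i = np.array([counts.get(c, 0) for c in fam], dtype=float)
        n = n_i.sum()
        expected += 1.0 / ((((n_i + 1) / (n + m)) ** 2).sum())
    assert sf.effective_number_of_codons(cds) == pytest.approx(expected)


def test_nc_ineligible_returns_none():
    with pytest.warns(UserWarning):
        assert sf.effective_number_of_codons("ATGAAATAA") is None


def test_nc_wright_estimator_agrees_at_extremes():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        uniform = sf.effective_number_of_codons(uniform_usage_cds(), method="wright1990")
        single = sf.effective_number_of_codons(single_codon_cds(), method="wright1990")
    assert uniform == pytest.approx(61.0, abs=2.0)
    assert single == pytest.approx(20.0, abs=1.0)


def test_nc_sixfold_split_conventions():
    # uniform usage hits the 61 identity under both conventions (2+4 = 6)
    assert sf.effective_number_of_codons(
        uniform_usage_cds(), split_sixfold=True
    ) == pytest.approx(61.0, abs=1e-12)
    # usage concentrated in one Leu codon: merged treats all 6 as one
    # family, split sees an untouched 2-codon subfamily -> different Nc
    biased = "ATG" + "CTG" * 90 + "TTA" * 12 + "TAA"
    merged = sf.effective_number_of_codons(biased)
    split = sf.effective_number_of_codons(biased, split_sixfold=True)
    assert merged != pytest.approx(split)


# ---------------------------------------------------------------------------
# uORFs


def test_find_uorfs_no_atg():
    t = sf.TranscriptModel("t", utr5="CCCCCCCCCC", cds="ATGAAATAA")
    assert sf.find_uorfs(t) == []


def test_find_uorfs_hand_walked_frame():
    # ATG at offset 2 -> ATG GCT TAA within the 5'UTR
    t = sf.TranscriptModel("t", utr5="ACATGGCTTAAGG", cds="ATGAAATAA")
    uorfs = sf.find_uorfs(t)
    assert uorfs == [(2, 11)]


def test_find_uorfs_overlap_flag():
    # ATG near the UTR end: stop only reachable inside the CDS
    # (uORF frame: ATG at 2, then ATG at 5, TAA at 8)
    t = sf.TranscriptModel("t", utr5="CCATG", cds="ATGTAACCCTAA")
    with_overlap = sf.find_uorfs(t, allow_cds_overlap=True)
    without = sf.find_uorfs(t, allow_cds_overlap=False)
    assert len(with_overlap) == 1
    assert without == []


def test_find_uorfs_invariant_to_utr3_when_overlap_disallowed():
    for utr3 in ("", "TAATAATAA", "ATGTAAATGTAA"):
        t = sf.TranscriptModel("t", utr5="ACATGGCTTAAGG", cds="ATGAAATAA", utr3=utr3)
        assert len(sf.find_uorfs(t, allow_cds_overlap=False)) == 1


def test_find_uorfs_nested_atg_counts_once():
    # second ATG sits inside the first uORF in the same frame
    t = sf.TranscriptModel("t", utr5="ATGATGGCTTAACC", cds="ATGAAATAA")
    uorfs = sf.find_uorfs(t)
    assert len(uorfs) == 1 and uorfs[0][0] == 0


def test_find_uorfs_min_codons():
    t = sf.TranscriptModel("t", utr5="CCATGTAACC", cds="ATGAAATAA")  # 2 codons
    assert len(sf.find_uorfs(t, min_codons=2)) == 1
    assert sf.find_uorfs(t, min_codons=3) == []


# ---------------------------------------------------------------------------
# over-representation and distribution comparison


def test_uorf_overrepresentation_delegates_to_chisq():
    background = {f"g{i}" for i in range(100)}
    query = {f"g{i}" for i in range(10)}
    uorf_genes = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(50, 65)}
    observed, expected, stat, p = sf.uorf_overrepresentation(query, uorf_genes, background)
    assert observed == 5
    assert expected == pytest.approx(2.0)
    assert stat == pytest.approx(5.625)


def test_uorf_overrepresentation_null_calibration(rng):
    background = [f"g{i}" for i in range(500)]
    uorf_genes = set(rng.choice(background, size=100, replace=False))
    ps = []
    for _ in range(200):
        query = set(rng.choice(background, size=50, replace=False))
        *_, p = sf.uorf_overrepresentation(query, uorf_genes, background)
        ps.append(p)
    assert 0.01 <= np.mean(np.array(ps) < 0.05) <= 0.12


def test_compare_feature_distributions_identity_and_separation(rng):
    n = 10000
    table = pd.DataFrame(
        {
            "cds_length": rng.lognormal(7, 0.5, size=n),
            "gc3": rng.uniform(0.2, 0.8, size=n),
        },
        index=[f"g{i}" for i in range(n)],
    )
    background = set(table.index)
    top_decile = set(table.nlargest(n // 10, "cds_length").index)
    out = sf.compare_feature_distributions(
        {"self": background, "long": top_decile}, background, table
    )
    self_rows = out[out["set"] == "self"]
    assert (self_rows["p"] > 0.9).all()  # a set equal to background is null
    long_len = out[(out["set"] == "long") & (out["feature"] == "cds_length")]
    assert long_len["p"].iloc[0] < 1e-10
    assert long_len["direction"].iloc[0] == "higher"


def test_compare_feature_distributions_null_bookkeeping():
    table = pd.DataFrame(
        {"f": [1.0, 2.0, np.nan, 4.0]}, index=["a", "b", "c", "d"]
    )
    out = sf.compare_feature_distributions({"s": {"a", "b", "c"}}, set(table.index), table)
    assert out["n"].iloc[0] == 2  # NaN excluded from ranks and from n


# ---------------------------------------------------------------------------
# I/O


def test_read_transcripts_tsv_and_gff(tmp_path):
    fasta = tmp_path / "t.fasta"
    fasta.write_text(">tr1\nAGGCATGTAACC\n")
    tsv = tmp_path / "regions.tsv"
    tsv.write_text("id\tutr5_len\tcds_len\tutr3_len\ntr1\t4\t6\t2\n")
    gff = tmp_path / "regions.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "tr1\t.\tfive_prime_UTR\t1\t4\t.\t+\t.\tID=u\n"
        "tr1\t.\tCDS\t5\t10\t.\t+\t.\tID=c\n"
        "tr1\t.\tthree_prime_UTR\t11\t12\t.\t+\t.\tID=u3\n"
    )
    for annot in (tsv, gff):
        models = sf.read_transcripts(fasta, annot)
        assert models["tr1"].utr5 == "AGGC"
        assert models["tr1"].cds == "ATGTAA"
        assert models["tr1"].utr3 == "CC"


def test_read_transcripts_length_mismatch(tmp_path):
    fasta = tmp_path / "t.fasta"
    fasta.write_text(">tr1\nAGGCATGTAACC\n")
    tsv = tmp_path / "regions.tsv"
    tsv.write_text("id\tutr5_len\tcds_len\tutr3_len\ntr1\t4\t6\t9\n")
    with pytest.raises(ValueError, match="length"):
        sf.read_transcripts(fasta, tsv)
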