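"""Polysome occupancy, shift detection, regulatory modes, ORA and PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from polyprof import expression, occupancy

from conftest import toy_matrix


def po_from_toy(values_by_gene, **kw):
    return occupancy.compute_polysome_occupancy(toy_matrix(values_by_gene, **kw))


def test_po_zero_when_fractions_equal():
    po = po_from_toy({"g1": (6.0, 6.2, 5.8)})
    assert np.allclose(po.values.to_numpy(), 0.0)


def test_po_is_log_ratio_per_replicate_pair():
    cols = {
        "t0_total_r1": [6.0],
        "t0_total_r2": [6.2],
        "t0_polysomal_r1": [7.0],
        "t0_polysomal_r2": [6.8],
    }
    meta = pd.DataFrame(
        [
            {"sample_id": s, "time_point": 0, "fraction": s.split("_")[1], "replicate": int(s[-1])}
            for s in cols
        ]
    ).set_index("sample_id")
    m = expression.ExpressionMatrix(pd.DataFrame(cols, index=["g1"]), meta)
    po = occupancy.compute_polysome_occupancy(m)
    assert np.allclose(po.values.loc["g1"].to_numpy(), [1.0, 0.6])


def test_po_unpaired_replicate_dropped_with_warning():
    cols = {
        "t0_total_r1": [6.0],
        "t0_total_r2": [6.2],
        "t0_polysomal_r1": [7.0],
    }
    meta = pd.DataFrame(
        [
            {"sample_id": s, "time_point": 0, "fraction": s.split("_")[1], "replicate": int(s[-1])}
            for s in cols
        ]
    ).set_index("sample_id")
    m = expression.ExpressionMatrix(pd.DataFrame(cols, index=["g1"]), meta)
    with pytest.warns(UserWarning, match="partner"):
        po = occupancy.compute_polysome_occupancy(m)
    assert po.values.shape[1] == 1


def test_po_invariant_to_joint_fraction_shift(sim_expression):
    m, _ = sim_expression
    shifted = expression.ExpressionMatrix(m.values + 3.0, m.samples)
    po_a = occupancy.compute_polysome_occupancy(m)
    po_b = occupancy.compute_polysome_occupancy(shifted)
    assert np.allclose(po_a.values.to_numpy(), po_b.values.to_numpy())


def test_differential_call_null_gene_is_ns(rng):
    n = 200
    a = pd.DataFrame(rng.normal(6, 0.2, size=(n, 3)))
    po = occupancy.OccupancyMatrix(
        pd.DataFrame(
            np.hstack([a.to_numpy(), a.to_numpy() + rng.normal(0, 0.2, size=(n, 3))]),
            columns=pd.MultiIndex.from_product([[0, 6], [1, 2, 3]]),
        )
    )
    c = occupancy.differential_call(po, 0, 6)
    assert (c.table["call"] == "ns").mean() > 0.95


def test_differential_call_boundary_fold_change_is_ns():
    # log2 FC exactly at the threshold stays non-significant (strict rule)
    rng = np.random.default_rng(3)
    n = 500
    base = rng.normal(0, 0.05, size=(n, 3))
    vals = np.hstack([base, base + rng.normal(0, 0.05, size=(n, 3))])
    vals[0, 3:] = vals[0, :3] + 1.0  # exact +1.0 shift, zero noise for gene 0
    po = occupancy.OccupancyMatrix(
        pd.DataFrame(vals, columns=pd.MultiIndex.from_product([[0, 6], [1, 2, 3]]))
    )
    c = occupancy.differential_call(po, 0, 6)
    g0 = c.table.iloc[0]
    assert g0["log2fc"] == pytest.approx(1.0)
    assert g0["call"] == "ns"


def test_differential_call_recovers_planted_effects():
    rng = np.random.default_rng(11)
    n, n_planted = 1000, 50
    a = rng.normal(7, 0.25, size=(n, 3))
    b = rng.normal(7, 0.25, size=(n, 3))
    b[:n_planted] += 2.0
    po = occupancy.OccupancyMatrix(
        pd.DataFrame(
            np.hstack([a, b]), columns=pd.MultiIndex.from_product([[0, 6], [1, 2, 3]])
        )
    )
    c = occupancy.differential_call(po, 0, 6)
    assert (c.table.iloc[:n_planted]["call"] == "up").sum() >= 45


def test_detect_shifts_null_and_planted(small_cfg, sim_expression):
    m, truth = sim_expression
    kept = expression.noise_filter(m).kept
    po = occupancy.compute_polysome_occupancy(m.subset(kept))
    res = occupancy.detect_shifts(po)
    counts = res.summary
    planted_first = truth[
        (truth["kind"] == "translational") & (truth["interval_end"] == 6)
    ]
    # shifts concentrate at the planted intervals; null intervals near zero
    assert counts.loc["PO 0->6"].sum() > 0.5 * len(planted_first)
    assert counts.loc["PO 6->26"].sum() <= 0.05 * len(planted_first)
    assert counts.loc["PO 48->72"].sum() <= 0.05 * len(planted_first)
    # sign consistency: planted PO increases are counted as "up"
    up_genes = set(res.contrasts[0].up)
    hts_up = set(truth.index[truth["set"] == "hts_up"]) & set(kept)
    assert len(up_genes & hts_up) > 0.5 * len(hts_up)
    assert len(up_genes & set(truth.index[truth["set"] == "hts_down"])) == 0


def test_detect_shifts_rejects_unordered_time_points(sim_expression):
    m, _ = sim_expression
    po = occupancy.compute_polysome_occupancy(m)
    with pytest.raises(ValueError):
        occupancy.detect_shifts(po, time_points=[6, 0, 26, 48, 72])
    with pytest.raises(ValueError):
        occupancy.detect_shifts(po, time_points=[0, 0, 6])


def _mode_fixture(po_fc, po_call, t_fc, t_call, p_fc, p_call):
    def contrast(fc, call, label):
        table = pd.DataFrame(
            {"log2fc": [fc], "p": [0.001], "padj": [0.001 if call != "ns" else 0.9],
             "call": [call]},
            index=["g1"],
        )
        return occupancy.ContrastResult(label, table, 1.0, 0.05)

    return occupancy.classify_regulatory_mode(
        contrast(t_fc, t_call, "T"), contrast(p_fc, p_call, "P"), contrast(po_fc, po_call, "PO")
    )


@pytest.mark.parametrize(
    "po,t,p,mode",
    [
        ((1.5, "up"), (0.1, "ns"), (1.6, "up"), "P+"),  # translation alone
        ((1.5, "up"), (-1.6, "down"), (0.1, "ns"), "T-"),  # transcription alone
        ((1.5, "up"), (0.4, "ns"), (0.6, "ns"), "additive"),
        ((-1.5, "down"), (0.1, "ns"), (-1.6, "down"), "P-"),
        ((1.5, "up"), (1.2, "up"), (2.7, "up"), "T+/P+"),
        ((-1.5, "down"), (-1.2, "down"), (-2.7, "down"), "T-/P-"),
        ((1.5, "up"), (1.2, "up"), (-1.2, "down"), "opposite"),
    ],
)
def test_classify_regulatory_mode_semantics(po, t, p, mode):
    out = _mode_fixture(po[0], po[1], t[0], t[1], p[0], p[1])
    assert out.loc["g1", "mode"] == mode


def test_classify_partitions_significant_genes(sim_expression):
    m, truth = sim_expression
    po = occupancy.compute_polysome_occupancy(m)
    dPO = occupancy.differential_call(po, 0, 6)
    dT = occupancy.differential_call(m, (0, "total"), (6, "total"))
    dP = occupancy.differential_call(m, (0, "polysomal"), (6, "polysomal"))
    modes = occupancy.classify_regulatory_mode(dT, dP, dPO)
    assert set(modes.index) == set(dPO.significant)
    assert modes["mode"].isin(occupancy.MODES).all()


def test_gene_set_ora_point_mass_and_tail():
    background = {f"g{i}" for i in range(20)}
    query = {f"g{i}" for i in range(5)}
    exact = occupancy.gene_set_ora(query, {"term": set(query)}, background)
    assert exact.loc["term", "p"] == pytest.approx(1 / comb(20, 5, exact=True))
    partial = occupancy.gene_set_ora(
        query, {"term": {"g0", "g1", "g2", "g10", "g11"}}, background
    )
    assert partial.loc["term", "p"] == pytest.approx(1126 / 15504)


def test_gene_set_ora_null_calibration(rng):
    background = [f"g{i}" for i in range(200)]
    annotation = {
        f"t{j}": set(rng.choice(background, size=40, replace=False)) for j in range(20)
    }
    n_sig = 0
    n_terms = 0
    for _ in range(50):
        query = set(rng.choice(background, size=30, replace=False))
        res = occupancy.gene_set_ora(query, annotation, background)
        n_sig += (res["p"] < 0.05).sum()
        n_terms += len(res)
    assert n_sig / n_terms <= 0.08  # ~alpha, Fisher is conservative


def test_gene_set_ora_rejects_bad_inputs():
    with pytest.raises(ValueError):
        occupancy.gene_set_ora(set(), {"t": {"a"}}, {"a"})
    with pytest.raises(ValueError):
        occupancy.gene_set_ora({"x"}, {"t": {"a"}}, {"a"})


def test_pca_variance_rank_one_and_conservation(rng):
    u = rng.normal(size=(100, 1))
    v = rng.normal(size=(1, 6))
    po = occupancy.OccupancyMatrix(
        pd.DataFrame(u @ v, columns=pd.MultiIndex.from_product([[0, 6], [1, 2, 3]]))
    )
    frac = occupancy.pca_variance(po)
    assert frac[0] == pytest.approx(1.0)
    noisy = occupancy.OccupancyMatrix(
        pd.DataFrame(
            rng.normal(size=(5000, 6)), columns=pd.MultiIndex.from_product([[0, 6], [1, 2, 3]])
        )
    )
    frac = occupancy.pca_variance(noisy)
    assert frac.sum() == pytest.approx(1.0, abs=1e-9)
    # isotropic noise with many more genes than samples: no dominant axis
    assert frac.max() < 2.0 / 5


def test_pca_variance_constant_matrix_error():
    po = occupancy.OccupancyMatrix(
        pd.DataFrame(
            np.ones((10, 4)), columns=pd.MultiIndex.from_product([[0, 6], [1, 2]])
        )
    )
    with pytest.raises(ValueError):
        occupancy.pca_variance(po)
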