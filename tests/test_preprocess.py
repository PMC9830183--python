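"""Readers, orthogroup policy, size factors, VST, and center-scaling."""


import numpy as np
import pandas as pd
import pytest

import socortex as sc
from socortex import preprocess as pre


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def test_counts_tsv_round_trip(tmp_path, rng):
    counts = pd.DataFrame(
        rng.integers(0, 500, (10, 4)),
        index=[f"g{i}" for i in range(10)],
        columns=[f"s{i}" for i in range(4)])
    path = tmp_path / "c.tsv"
    pre.write_counts(counts, path)
    back = sc.read_counts(path)
    pd.testing.assert_frame_equal(back, counts, check_names=False)


def test_duplicate_gene_id_rejected(tmp_path):
    p = _write(tmp_path, "c.tsv", "gene\ts1\ts2\ng1\t1\t2\ng1\t3\t4\n")
    with pytest.raises(ValueError, match="duplicated gene ids"):
        sc.read_counts(p)


@pytest.mark.parametrize("text,msg", [
    ("sample_id\tspecies\tclade\na\tx\ty\n", "missing metadata columns"),
    ("sample_id\tspecies\tclade\tphenotype\na\tx\ty\tqueen\n",
     "unknown phenotype"),
    ("sample_id\tspecies\tclade\tphenotype\na\tx\ty\treproductive\n"
     "a\tx\ty\tnon_reproductive\n", "duplicated sample"),
])
def test_metadata_validation(tmp_path, text, msg):
    p = _write(tmp_path, "m.tsv", text)
    with pytest.raises(ValueError, match=msg):
        sc.read_metadata(p)


ORTHO_TSV = (
    "Orthogroup\tspA\tspB\tspC\tspD\tspE\tspF\n"
    # present in 5/6 species, <= 3 copies: retained
    "OG1\ta1, a2\tb1\tc1\td1\te1\t\n"
    # 4 copies in spA: dropped (copy_number)
    "OG2\ta1, a2, a3, a4\tb1\tc1\td1\te1\tf1\n"
    # absent in two species: dropped (absence)
    "OG3\ta1\tb1\tc1\td1\t\t\n"
    # single copy everywhere: retained
    "OG4\ta9\tb9\tc9\td9\te9\tf9\n"
)


def test_orthogroup_policy_filtering(tmp_path):
    p = _write(tmp_path, "Orthogroups.tsv", ORTHO_TSV)
    kept, dropped = sc.read_orthogroups(p)
    assert list(kept) == ["OG1", "OG4"]  # input order preserved
    assert dropped == [("OG2", "copy_number"), ("OG3", "absence")]
    assert kept["OG1"]["spA"] == ["a1", "a2"]
    assert "spF" not in kept["OG1"]
    assert len(kept) + len(dropped) == 4


def test_orthogroup_policy_bounds(tmp_path):
    with pytest.raises(ValueError):
        sc.OrthologyFilterPolicy(max_copies_per_species=0)
    with pytest.raises(ValueError):
        sc.OrthologyFilterPolicy(max_absent_species=-1)
    # a zero-absence policy additionally drops OG1 (absent in spF)
    p = _write(tmp_path, "Orthogroups.tsv", ORTHO_TSV)
    kept, dropped = sc.read_orthogroups(
        p, sc.OrthologyFilterPolicy(max_absent_species=0))
    assert list(kept) == ["OG4"]
    assert ("OG1", "absence") in dropped


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def _toy_assembly_inputs():
    counts_a = pd.DataFrame(
        {"a_s1": [10, 7], "a_s2": [30, 9]}, index=["gA1", "gA2"])
    counts_b = pd.DataFrame({"b_s1": [5, 100]}, index=["gB1", "gB2"])
    meta = pd.DataFrame({
        "sample_id": ["a_s1", "a_s2", "b_s1"],
        "species": ["A", "A", "B"],
        "clade": ["x", "x", "y"],
        "phenotype": ["reproductive", "non_reproductive", "reproductive"],
    }).set_index("sample_id", drop=False)
    ortho = {"OG1": {"A": ["gA1", "gA2"], "B": ["gB1"]},
             "OG2": {"A": ["gA2"], "B": ["gB2"]}}
    return {"A": counts_a, "B": counts_b}, ortho, meta


@pytest.mark.parametrize("reduction,og1_a", [("sum", [17, 39]), ("max", [10, 30])])
def test_multi_copy_reduction(reduction, og1_a):
    per_species, ortho, meta = _toy_assembly_inputs()
    ds = sc.assemble_ortho_matrix(per_species, ortho, meta, reduction=reduction)
    assert ds.counts.loc["OG1", ["a_s1", "a_s2"]].tolist() == og1_a
    # single-copy rows equal the original gene rows
    assert ds.counts.loc["OG2", "b_s1"] == 100


def test_sample_missing_from_metadata_rejected():
    per_species, ortho, meta = _toy_assembly_inputs()
    with pytest.raises(ValueError, match="absent from metadata"):
        sc.assemble_ortho_matrix(
            per_species, ortho, meta.drop(index=["b_s1"]), reduction="sum")


# ---------------------------------------------------------------------------
# Size factors
# ---------------------------------------------------------------------------

def test_size_factors_scaling_case(rng):
    a = rng.integers(10, 200, 50).astype(float)
    counts = pd.DataFrame({"A": a, "B": 2 * a})
    f = sc.size_factors(counts)
    assert f["B"] / f["A"] == pytest.approx(2.0)


def test_size_factors_identical_samples(rng):
    a = rng.integers(10, 200, 30).astype(float)
    counts = pd.DataFrame({"A": a, "B": a, "C": a})
    f = sc.size_factors(counts)
    assert np.allclose(f, f.iloc[0])


def test_size_factors_hand_example():
    counts = pd.DataFrame({"s1": [10, 20, 40], "s2": [20, 10, 160]},
                          index=["g1", "g2", "g3"])
    # brute-force median of ratios against the per-gene geometric means
    geo = np.exp(np.log(counts.to_numpy()).mean(axis=1))
    want = np.median(counts.to_numpy() / geo[:, None], axis=0)
    f = sc.size_factors(counts)
    assert np.allclose(f.to_numpy(), want)


def test_size_factors_fallback_on_no_common_gene(caplog):
    counts = pd.DataFrame({"s1": [10, 0], "s2": [0, 30]}, index=["g1", "g2"])
    with caplog.at_level("WARNING", logger="socortex"):
        f = sc.size_factors(counts)
    assert "totals" in caplog.text
    assert np.allclose(f.to_numpy(), np.array([10, 30]) / np.sqrt(300))


# ---------------------------------------------------------------------------
# VST
# ---------------------------------------------------------------------------

def test_vst_closed_form_monotone(rng):
    q = np.sort(rng.uniform(0, 2000, 200))
    g = sc.vst_closed_form(q, a0=0.05, a1=1.0)
    assert np.all(np.diff(g) >= 0)


def test_vst_closed_form_log_slope_one_for_large_counts():
    """In the small-a0 limit the transform is affine in log2(q) at large q."""
    q = np.array([1e6, 1e7, 1e8])  # large relative to 1/a0
    g = sc.vst_closed_form(q, a0=1e-4, a1=0.0)
    slopes = np.diff(g) / np.diff(np.log2(q))
    assert np.allclose(slopes, 1.0, atol=1e-2)


def test_vst_flattens_poisson_variance(rng):
    """Simulation oracle: near-Poisson counts get near-constant variance."""
    means = np.repeat([20, 80, 300, 1200, 5000], 40)
    counts = pd.DataFrame(
        rng.poisson(means[:, None], (200, 60)),
        index=[f"g{i}" for i in range(200)],
        columns=[f"s{i}" for i in range(60)])
    meta = pd.DataFrame({
        "sample_id": counts.columns, "species": "A", "clade": "x",
        "phenotype": "reproductive"}).set_index("sample_id", drop=False)
    ds = sc.OrthoExpressionDataset(counts=counts, samples=meta)
    nm = sc.variance_stabilize(ds, species_aware=False)
    v = nm.values.to_numpy().var(axis=1, ddof=1)
    bin_vars = [v[means == m].mean() for m in [20, 80, 300, 1200, 5000]]
    assert max(bin_vars) / min(bin_vars) < 3


def test_vst_reduces_heteroscedasticity(small_sim, small_vst):
    _, ds, _ = small_sim
    raw = ds.counts.to_numpy(dtype=float)
    lm = np.log(raw.mean(axis=1) + 1)
    slope_before = np.polyfit(lm, np.log(raw.var(axis=1, ddof=1) + 1e-9), 1)[0]
    v = small_vst.values.to_numpy()
    slope_after = np.polyfit(lm, np.log(v.var(axis=1, ddof=1) + 1e-9), 1)[0]
    assert small_vst.transform == "vst"
    assert slope_before > 0.8
    assert slope_after <= 0.3


def test_vst_monotone_within_sample(small_sim, small_vst):
    _, ds, _ = small_sim
    col = ds.counts.columns[0]
    order = np.argsort(ds.counts[col].to_numpy())
    transformed = small_vst.values[col].to_numpy()[order]
    assert np.all(np.diff(transformed) >= -1e-12)


def test_degenerate_trend_falls_back_to_log(monkeypatch, small_sim, caplog):
    _, ds, _ = small_sim
    monkeypatch.setattr(pre, "_fit_dispersion_trend", lambda a, m: (-0.5, 0.0))
    with caplog.at_level("WARNING", logger="socortex"):
        nm = sc.variance_stabilize(ds)
    assert nm.transform == "log_size_factor"
    assert "log2(q+1)" in caplog.text


def test_trend_fit_negative_intercept_reachable():
    # steeply decreasing dispersion trend: intercept goes negative
    mu = np.array([0.1, 0.2, 10.0, 20.0, 40.0])
    alpha = np.array([50.0, 20.0, 1e-6, 1e-6, 1e-6])
    a0, a1 = pre._fit_dispersion_trend(alpha, mu)
    assert a0 <= 0


# ---------------------------------------------------------------------------
# Center-scaling
# ---------------------------------------------------------------------------

def test_center_scale_global(rng):
    vals = pd.DataFrame(rng.normal(3, 2, (4, 6)),
                        index=list("abcd"), columns=[f"s{i}" for i in range(6)])
    nm = sc.NormalizedMatrix(values=vals, transform="vst", species_aware=False)
    out = sc.center_scale(nm, scope="global")
    arr = out.values.to_numpy()
    assert np.abs(arr.mean(axis=1)).max() < 1e-12
    assert np.allclose(arr.std(axis=1, ddof=1), 1.0)


def test_center_scale_constant_row_flagged():
    vals = pd.DataFrame([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]],
                        index=["flat", "ok"], columns=["a", "b", "c"])
    nm = sc.NormalizedMatrix(values=vals, transform="vst", species_aware=False)
    out = sc.center_scale(nm, scope="global")
    assert out.zero_variance_rows == ["flat"]
    assert np.allclose(out.values.loc["flat"], 0.0)


def test_center_scale_per_species(small_sim, small_scaled):
    _, ds, _ = small_sim
    for sp, cols in ds.per_species_view.items():
        block = small_scaled.values[cols].to_numpy()
        assert np.abs(block.mean(axis=1)).max() < 1e-10


def test_center_scale_unknown_scope(small_vst):
    with pytest.raises(ValueError, match="scope"):
        sc.center_scale(small_vst, scope="per_clade")
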