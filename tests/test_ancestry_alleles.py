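import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from basalkit import ancestry_alleles as aa
from basalkit import synthetic_data as sd
from basalkit.io_formats import PopulationPanel

from conftest import make_matrix


def test_seed_detection_thresholds():
    """AF 0.25 in one TIA and 0.05 in refs -> seed; AF 0.15 everywhere -> not."""
    n = 200  # haplotypes per pop, deterministic construction
    def col(freq):
        c = np.zeros(n, dtype=np.int8)
        c[: int(freq * n)] = 1
        return c

    pops = {"PNG": [0.25, 0.15], "EUR": [0.05, 0.15], "EAS": [0.05, 0.15]}
    cols = {p: np.column_stack([col(f) for f in fs]) for p, fs in pops.items()}
    haps = np.vstack([cols["PNG"], cols["EUR"], cols["EAS"]])
    m = make_matrix(haps, positions=[1_000, 2_000_000], sample_prefix="x")
    ids = [f"{p}_{i}" for p in pops for i in range(n // 2)]
    m.sample_ids = ids
    panel = PopulationPanel(
        {s: s.split("_")[0] for s in ids},
        {"PNG": "representative_TIA", "EUR": "nonindigenous_EUR", "EAS": "nonindigenous_EAS"},
    )
    res = aa.identify_basn_alleles(m, panel, ["PNG"], ["EUR", "EAS"])
    assert res.site_ids == ["s0"]
    assert res.table["stage"].tolist() == ["seed"]


def test_detection_recovers_truth_private_sites():
    cfg = sd.DemographyConfig(seed=21)
    af, matrix, panel, truth = sd.simulate_structured_frequencies(cfg)
    res = aa.identify_basn_alleles(
        matrix, panel, ("ADM", "MLS", "PHI", "PNG"), ("EUR", "EAS")
    )
    detected = set(res.site_ids)
    truth_ids = set(truth["site_id"])
    recall = len(detected & truth_ids) / len(truth_ids)
    seeds = set(res.table.loc[res.table["stage"] == "seed", "site_id"])
    false_frac = len(seeds - truth_ids) / max(len(detected), 1)
    assert recall >= 0.9
    assert false_frac <= 0.05


def test_detection_invariant_to_sample_order():
    cfg = sd.DemographyConfig(seed=4, n_sites=300, n_basn_private_sites=100)
    _, matrix, panel, _ = sd.simulate_structured_frequencies(cfg)
    res1 = aa.identify_basn_alleles(matrix, panel, ("ADM", "MLS", "PHI", "PNG"), ("EUR", "EAS"))
    perm = np.random.default_rng(0).permutation(matrix.n_samples)
    m2 = make_matrix(
        np.vstack([matrix.haplotypes[2 * i : 2 * i + 2] for i in perm]),
        positions=matrix.positions,
    )
    m2.sample_ids = [matrix.sample_ids[i] for i in perm]
    res2 = aa.identify_basn_alleles(m2, panel, ("ADM", "MLS", "PHI", "PNG"), ("EUR", "EAS"))
    assert res1.site_ids == res2.site_ids


def test_ld_r2_matches_haplotype_count_formula(rng):
    """r^2 from the 2x2 haplotype-count formula on 20 haplotypes."""
    haps = (rng.random((20, 2)) < 0.5).astype(np.int8)
    m = make_matrix(haps)
    x, y = haps[:, 0], haps[:, 1]
    p_ab = np.mean(x * y)
    p_a, p_b = x.mean(), y.mean()
    D = p_ab - p_a * p_b
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    expected = D**2 / denom if denom > 0 else 0.0
    assert aa.ld_r2(m, "s0", "s1") == pytest.approx(expected, abs=1e-12)


def test_ld_r2_perfect_and_independent(rng):
    co = np.tile([[0], [1]], (10, 1))
    m = make_matrix(np.hstack([co, co]))
    assert aa.ld_r2(m, "s0", "s1") == pytest.approx(1.0)
    x = (rng.random((4000, 1)) < 0.5).astype(np.int8)
    y = (rng.random((4000, 1)) < 0.5).astype(np.int8)
    m2 = make_matrix(np.hstack([x, y]))
    assert aa.ld_r2(m2, "s0", "s1") < 0.01


def _alleles(positions, chrom="1"):
    t = pd.DataFrame(
        {
            "site_id": [f"a{i}" for i in range(len(positions))],
            "chrom": chrom,
            "pos": positions,
            "allele": "G",
            "stage": "seed",
        }
    )
    return aa.assign_blocks(aa.BasnAlleleSet(t))


def test_block_assignment_chaining():
    assert _alleles([1, 600_001]).n_blocks == 2
    chained = _alleles([1, 400_001, 950_001])
    assert chained.table["block_id"].tolist() == [1, 1, 2]
    # a gap of exactly 500 kb still chains (block boundary requires > 500 kb)
    assert _alleles([1, 500_001]).n_blocks == 1


@given(st.lists(st.integers(1, 10_000_000), min_size=1, max_size=40, unique=True))
@settings(deadline=None, derandomize=True)
def test_block_count_matches_interval_merge(positions):
    positions = sorted(positions)
    res = _alleles(positions)
    # brute-force: merge intervals [p, p+500kb]
    n_blocks = 1
    for prev, cur in zip(positions, positions[1:]):
        if cur - prev > 500_000:
            n_blocks += 1
    assert res.n_blocks == n_blocks


def test_gs_worked_examples(block_alleles):
    row = pd.Series({f"b{i}": 1 for i in range(100)})
    assert aa.gs_unweighted(row, block_alleles) == 1.0
    row[:] = 0
    assert aa.gs_unweighted(row, block_alleles) == 0.0
    # 3 derived of 8 genotyped
    row[:] = -1
    for i in range(8):
        row[f"b{i}"] = 1 if i < 3 else 0
    assert aa.gs_unweighted(row, block_alleles) == pytest.approx(0.375)


def test_gs_weighted_two_block_case():
    t = pd.DataFrame(
        {
            "site_id": ["x", "y", "z"],
            "chrom": "1",
            "pos": [1, 100, 700_000],
            "allele": "G",
            "stage": "seed",
        }
    )
    alleles = aa.assign_blocks(aa.BasnAlleleSet(t))
    row = pd.Series({"x": 1, "y": 0, "z": 1})
    assert aa.gs_weighted(row, alleles) == pytest.approx(0.75)
    assert aa.gs_unweighted(row, alleles) == pytest.approx(2 / 3)


@given(st.integers(0, 2**31 - 1))
@settings(deadline=None, derandomize=True, max_examples=200)
def test_gs_weighted_equals_unweighted_on_singleton_blocks(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(3, 30)
    t = pd.DataFrame(
        {
            "site_id": [f"q{i}" for i in range(n)],
            "chrom": "1",
            "pos": np.arange(n) * 600_000 + 1,
            "allele": "G",
            "stage": "seed",
        }
    )
    alleles = aa.assign_blocks(aa.BasnAlleleSet(t))
    calls = rng.choice([-1, 0, 1], size=n)
    if (calls == -1).all():
        calls[0] = 1
    row = pd.Series(dict(zip(t["site_id"], calls)))
    assert aa.gs_weighted(row, alleles) == pytest.approx(aa.gs_unweighted(row, alleles))


def test_gs_weighted_matches_two_level_mean_oracle(rng):
    for _ in range(20):
        n = int(rng.integers(5, 40))
        pos = np.sort(rng.choice(np.arange(1, 20_000_000, 1000), n, replace=False))
        t = pd.DataFrame(
            {"site_id": [f"q{i}" for i in range(n)], "chrom": "1", "pos": pos,
             "allele": "G", "stage": "seed"}
        )
        alleles = aa.assign_blocks(aa.BasnAlleleSet(t))
        calls = rng.choice([-1, 0, 1], size=n, p=[0.3, 0.35, 0.35])
        if (calls == -1).all():
            calls[0] = 0
        row = pd.Series(dict(zip(t["site_id"], calls)))
        # brute force two-level mean
        blocks = alleles.table["block_id"].to_numpy()
        means = []
        for b in set(blocks):
            vals = [c for c, bb in zip(calls, blocks) if bb == b and c != -1]
            if vals:
                means.append(np.mean(vals))
        assert aa.gs_weighted(row, alleles) == pytest.approx(np.mean(means))


def test_gs_undefined_without_genotyped_sites(block_alleles):
    row = pd.Series({f"b{i}": -1 for i in range(100)})
    with pytest.raises(ValueError, match="undefined"):
        aa.gs_unweighted(row, block_alleles)


def test_regression_exact_linear_case():
    """A cohort whose GS is exactly 0.001 * date recovers beta_time to 1e-10."""
    rng = np.random.default_rng(3)
    n_sites, n_samples = 200, 60
    t = pd.DataFrame(
        {"site_id": [f"q{i}" for i in range(n_sites)], "chrom": "1",
         "pos": np.arange(n_sites) * 600_000 + 1, "allele": "G", "stage": "seed"}
    )
    alleles = aa.assign_blocks(aa.BasnAlleleSet(t))
    dates = rng.integers(0, 201, size=n_samples) * 5  # GS = date/5 / 200 = 0.001*date
    calls = np.zeros((n_samples, n_sites), dtype=np.int8)
    for i, d in enumerate(dates):
        calls[i, : d // 5] = 1
    cohort = pd.DataFrame(
        {"sample_id": [f"a{i}" for i in range(n_samples)], "date": dates.astype(float),
         "lat": rng.normal(size=n_samples), "lon": rng.normal(size=n_samples)}
    )
    for j in range(1, 11):
        cohort[f"PC{j}"] = rng.normal(size=n_samples)
    cohort = pd.concat([cohort, pd.DataFrame(calls, columns=t["site_id"])], axis=1)
    fit = aa.gs_time_regression(cohort, alleles)
    assert fit.beta_time == pytest.approx(0.001, abs=1e-10)


def test_regression_first_quartile_exclusion_and_fit(block_alleles):
    cfg = sd.AncientCohortConfig(seed=17)
    cohort = sd.simulate_ancient_cohort(cfg, block_alleles.site_ids)
    fit = aa.gs_time_regression(cohort, block_alleles)
    counts = (cohort[block_alleles.site_ids].to_numpy() != -1).sum(axis=1)
    q1 = np.quantile(counts, 0.25)
    assert len(fit.excluded) == int((counts < q1).sum())
    assert fit.n_used == cfg.n_samples - len(fit.excluded)
    assert np.isfinite(fit.bse_robust["date"])


def test_regression_null_calibration(block_alleles):
    cover = 0
    for seed in range(50):
        cfg = sd.AncientCohortConfig(slope_east=0.0, seed=seed)
        cohort = sd.simulate_ancient_cohort(cfg, block_alleles.site_ids)
        fit = aa.gs_time_regression(cohort, block_alleles)
        lo, hi = fit.conf_int.loc["date"]
        cover += lo <= 0 <= hi
    assert cover >= 45  # >= 90% of 50 null replicates


def test_regression_positive_slope_power(block_alleles):
    signs = 0
    for seed in range(50):
        cfg = sd.AncientCohortConfig(seed=1000 + seed)
        cohort = sd.simulate_ancient_cohort(cfg, block_alleles.site_ids)
        east = cohort[cohort["region"] == "East"].reset_index(drop=True)
        fit = aa.gs_time_regression(east, block_alleles)
        signs += fit.beta_time > 0
    assert signs >= 48  # >= 95% of 50 replicates


def test_regression_rank_deficiency_error(block_alleles):
    cfg = sd.AncientCohortConfig(n_samples=60, seed=1)
    cohort = sd.simulate_ancient_cohort(cfg, block_alleles.site_ids)
    cohort["lon"] = cohort["lat"]  # perfectly collinear
    with pytest.raises(ValueError, match="collinear"):
        aa.gs_time_regression(cohort, block_alleles)
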