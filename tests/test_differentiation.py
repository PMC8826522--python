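import io

import numpy as np
import pandas as pd
import pytest

from basalkit import differentiation as diff
from basalkit.synthetic_data import DemographyConfig, simulate_structured_frequencies

from conftest import make_matrix, make_panel


def wc_oracle(counts, sizes):
    """Textbook Weir–Cockerham (1984) components, haploid samples, per site.

    Independent scalar-loop implementation used only as a cross-check.
    """
    counts = np.asarray(counts, float)
    sizes = np.asarray(sizes, float)
    r = len(sizes)
    nbar = sizes.mean()
    nc = (sizes.sum() - (sizes**2).sum() / sizes.sum()) / (r - 1)
    out = []
    for row in counts:
        p = row / sizes
        pbar = row.sum() / sizes.sum()
        if pbar in (0.0, 1.0):
            out.append((0.0, 0.0))
            continue
        s2 = sum(sizes[k] * (p[k] - pbar) ** 2 for k in range(r)) / ((r - 1) * nbar)
        hbar = 0.0  # haploid: no heterozygotes
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        out.append((a, b + hbar / 2))
    return np.array(out)


def _random_dataset(rng, n_pops=3, n_per=20, n_sites=200):
    haps = (rng.random((2 * n_pops * n_per, n_sites)) < rng.uniform(0.1, 0.9, n_sites)).astype(np.int8)
    m = make_matrix(haps, sample_prefix="")
    pops = [f"P{k}" for k in range(n_pops)]
    s2p = {}
    for k, pop in enumerate(pops):
        for i in range(n_per):
            s2p[m.sample_ids[k * n_per + i]] = pop
    from basalkit.io_formats import PopulationPanel

    panel = PopulationPanel(s2p, {p: "representative_TIA" for p in pops})
    return m, panel, pops


def test_per_snp_components_match_textbook_oracle(rng):
    m, panel, pops = _random_dataset(rng)
    comp = diff.fst_per_snp(m, panel, pops)
    counts = np.column_stack(
        [m.haplotypes[m.sample_haplotype_rows(panel.samples_of(p))].sum(axis=0) for p in pops]
    )
    oracle = wc_oracle(counts, [40, 40, 40])
    np.testing.assert_allclose(comp.a, oracle[:, 0], atol=1e-12)
    np.testing.assert_allclose(comp.bc, oracle[:, 1], atol=1e-12)


def test_no_differentiation_gives_small_nonpositive_fst():
    # both populations carry 10 derived / 20 haplotypes
    a, bc = diff.fst_from_counts(np.array([[10.0, 10.0]]), [20, 20])
    fst = a[0] / (a[0] + bc[0])
    assert fst <= 0 and abs(fst) < 0.06


def test_fixed_difference_gives_fst_near_one():
    a, bc = diff.fst_from_counts(np.array([[50.0, 0.0]]), [50, 50])
    assert a[0] / (a[0] + bc[0]) >= 0.99


def test_weighted_fst_single_site_and_duplication_invariance(rng):
    m, panel, pops = _random_dataset(rng, n_pops=2, n_sites=50)
    comp = diff.fst_per_snp(m, panel, pops)
    one = diff.FstComponents(
        comp.site_ids[:1], comp.chrom[:1], comp.pos[:1], comp.a[:1], comp.bc[:1]
    )
    assert diff.fst_weighted(one) == pytest.approx(comp.per_site[0])
    doubled = diff.FstComponents(
        comp.site_ids * 2,
        np.concatenate([comp.chrom] * 2),
        np.concatenate([comp.pos] * 2),
        np.concatenate([comp.a] * 2),
        np.concatenate([comp.bc] * 2),
    )
    assert diff.fst_weighted(doubled) == pytest.approx(diff.fst_weighted(comp))


def test_four_population_fst_nonnegative_and_label_invariant():
    cfg = DemographyConfig(
        populations=("W", "X", "Y", "Z"),
        categories=("representative_TIA",) * 4,
        sample_sizes=(15, 15, 15, 15),
        n_sites=300,
        fst=0.02,
        basn_admixture=0.0,
        n_basn_private_sites=0,
        seed=8,
    )
    _, m, panel, _ = simulate_structured_frequencies(cfg)
    pops = ["W", "X", "Y", "Z"]
    comp = diff.fst_per_snp(m, panel, pops)
    w = diff.fst_weighted(comp)
    assert w >= 0
    comp_perm = diff.fst_per_snp(m, panel, pops[::-1])
    assert diff.fst_weighted(comp_perm) == pytest.approx(w, abs=1e-12)


def test_windows_localize_high_fst_region():
    rng = np.random.default_rng(0)
    n_sites = 400
    pos = np.sort(rng.choice(np.arange(1, 200_001), n_sites, replace=False))
    freq_a = rng.uniform(0.3, 0.7, n_sites)
    freq_b = freq_a.copy()
    hot = (pos >= 90_000) & (pos < 110_000)
    freq_b[hot] = np.clip(freq_a[hot] + 0.6, 0, 1)  # strongly differentiated region
    haps_a = (rng.random((60, n_sites)) < freq_a).astype(np.int8)
    haps_b = (rng.random((60, n_sites)) < freq_b).astype(np.int8)
    m = make_matrix(np.vstack([haps_a, haps_b]), positions=pos, sample_prefix="")
    from basalkit.io_formats import PopulationPanel

    s2p = {m.sample_ids[i]: ("A" if i < 30 else "B") for i in range(60)}
    panel = PopulationPanel(s2p, {"A": "representative_TIA", "B": "representative_TIA"})
    comp = diff.fst_per_snp(m, panel, ["A", "B"])
    win = diff.fst_windows(comp, window_bp=10_000, step_bp=1_000)
    top = win.loc[win["fst"].idxmax()]
    assert top["start"] < 110_000 and top["end"] > 90_000
    # shifting all positions by +1 kb shifts window starts by exactly 1 kb
    comp2 = diff.FstComponents(comp.site_ids, comp.chrom, comp.pos + 1000, comp.a, comp.bc)
    win2 = diff.fst_windows(comp2, window_bp=10_000, step_bp=1_000)
    merged = win.merge(win2, left_on="start", right_on=win2["start"] - 1000, suffixes=("", "_s"))
    np.testing.assert_allclose(merged["fst"], merged["fst_s"])


def test_all_sites_in_one_window_equals_genome_value(rng):
    m, panel, pops = _random_dataset(rng, n_pops=2, n_sites=8)
    comp = diff.fst_per_snp(m, panel, pops)
    win = diff.fst_windows(comp, window_bp=1_000_000, step_bp=1_000_000)
    assert len(win) == 1
    assert win["fst"].iloc[0] == pytest.approx(diff.fst_weighted(comp))


def test_gene_outliers_flags_constructed_outlier():
    windows = pd.DataFrame(
        {
            "chrom": "1",
            "start": np.arange(30) * 1000,
            "end": np.arange(30) * 1000 + 10_000,
            "n_snps": 5,
            "fst": [0.01] * 29 + [0.4],
        }
    )
    genes = pd.DataFrame(
        {
            "chrom": "1",
            "start": np.arange(30) * 1000 + 1,
            "end": np.arange(30) * 1000 + 500,
            "gene": [f"g{i}" for i in range(30)],
        }
    )
    table = diff.gene_fst_outliers(windows, genes)
    assert table.loc[table["gene"] == "g29", "outlier"].item()
    flagged = table[table["outlier"]]["gene"].tolist()
    assert "g0" not in flagged
    # equal values -> no outliers; negative window fst truncated before sqrt
    windows["fst"] = 0.05
    assert not diff.gene_fst_outliers(windows, genes)["outlier"].any()
    windows.loc[0, "fst"] = -0.01
    assert (diff.gene_fst_outliers(windows, genes)["sqrt_fst"] >= 0).all()


def three_point_lengths(d):
    """Branch lengths of the unique 3-taxon unrooted tree."""
    return (
        (d[0, 1] + d[0, 2] - d[1, 2]) / 2,
        (d[0, 1] + d[1, 2] - d[0, 2]) / 2,
        (d[0, 2] + d[1, 2] - d[0, 1]) / 2,
    )


def _patristic(newick):
    import skbio

    tree = skbio.TreeNode.read(io.StringIO(newick))
    dm = tree.tip_tip_distances()
    return pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)


def test_nj_three_taxa_solves_three_point_equations():
    d = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
    labels = ["A", "B", "C"]
    newick = diff.nj_tree(pd.DataFrame(d, index=labels, columns=labels))
    pat = _patristic(newick)
    la, lb, lc = three_point_lengths(d)
    assert pat.loc["A", "B"] == pytest.approx(la + lb, abs=1e-10)
    assert pat.loc["A", "C"] == pytest.approx(la + lc, abs=1e-10)
    assert pat.loc["B", "C"] == pytest.approx(lb + lc, abs=1e-10)


def test_nj_recovers_additive_five_taxon_metric_with_outgroup_root():
    # classic additive matrix: ((A,B),C) vs (D,E)
    d = np.array(
        [
            [0, 5, 9, 9, 8],
            [5, 0, 10, 10, 9],
            [9, 10, 0, 8, 7],
            [9, 10, 8, 0, 3],
            [8, 9, 7, 3, 0],
        ],
        dtype=float,
    )
    labels = ["A", "B", "C", "D", "E"]
    dm = pd.DataFrame(d, index=labels, columns=labels)
    newick = diff.nj_tree(dm, outgroup="E")
    pat = _patristic(newick)
    for i in labels:
        for j in labels:
            if i != j:
                assert pat.loc[i, j] == pytest.approx(dm.loc[i, j], abs=1e-9)
    assert newick.startswith("(") and "E" in newick


def test_nj_unknown_outgroup_raises():
    d = pd.DataFrame(np.array([[0.0, 1, 1], [1, 0, 1], [1, 1, 0]]),
                     index=list("ABC"), columns=list("ABC"))
    with pytest.raises(KeyError):
        diff.nj_tree(d, outgroup="Z")


def test_lsbl_components_sum_to_pairwise_distance(rng):
    """Cross-module consistency: LSBL_A + LSBL_B = d_AB for every pair."""
    from basalkit.selection_scan import lsbl

    d_ab = rng.uniform(0, 0.5, 50)
    d_ao = rng.uniform(0, 0.5, 50)
    d_bo = rng.uniform(0, 0.5, 50)
    np.testing.assert_allclose(
        lsbl(d_ab, d_ao, d_bo) + lsbl(d_ab, d_bo, d_ao), d_ab, atol=1e-12
    )
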