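"""Region-calling chain against hand traces and brute-force combination."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methdmr.datamodel import ParameterError, ProbeManifest, SampleSheet
from methdmr.dmr import (
    ACFEstimate,
    call_dmrs,
    estimate_acf,
    find_candidate_regions,
    hypermethylated_fraction,
    probit_z,
    region_significance,
    sidak_correct,
    slk_correct,
    stouffer_liptak,
)

from conftest import make_matrix


def _manifest_at(positions, chrom="chr1"):
    rows = []
    for i, pos in enumerate(positions):
        rows.append({"probe_id": f"cg{i:03d}", "chrom": chrom, "pos": pos,
                     "genes": [], "gene_region": [], "island_relation": "OpenSea",
                     "snp_overlap": False, "sex_chrom": False})
    return ProbeManifest(pd.DataFrame(rows).set_index("probe_id"))


def _zero_acf(dist=1000, bin_width=50):
    n = dist // bin_width
    return ACFEstimate(bin_edges=np.arange(0, dist + bin_width, bin_width),
                       correlations=np.zeros(n), n_pairs=np.zeros(n, dtype=int))


def brute_force_stouffer(pvals):
    """Independent plain-Stouffer oracle."""
    z = stats.norm.isf(np.clip(pvals, 1e-15, 1 - 1e-15))
    return stats.norm.sf(z.sum() / np.sqrt(len(z)))


class TestProbitZ:
    @pytest.mark.parametrize("p, expected", [
        (0.5, 0.0), (0.05, 1.6449), (0.95, -1.6449),
    ])
    def test_known_quantiles(self, p, expected):
        assert probit_z(p) == pytest.approx(expected, abs=1e-4)

    def test_antisymmetry(self):
        for p in (0.01, 0.2, 0.4):
            assert probit_z(p) == pytest.approx(-probit_z(1 - p), abs=1e-12)


class TestStoufferLiptak:
    def test_independent_pair(self):
        assert stouffer_liptak([0.05, 0.05], np.eye(2)) \
            == pytest.approx(0.0100, abs=2e-4)

    def test_perfectly_correlated_pair_adds_nothing(self):
        assert stouffer_liptak([0.05, 0.05], np.ones((2, 2))) \
            == pytest.approx(0.05, abs=1e-12)

    def test_single_p_identity(self):
        assert stouffer_liptak([0.5]) == pytest.approx(0.5, abs=1e-12)

    def test_reduces_to_plain_stouffer_with_zero_offdiag(self, rng):
        for m in (2, 5, 10):
            p = rng.uniform(0.001, 0.999, m)
            assert stouffer_liptak(p, np.eye(m)) \
                == pytest.approx(brute_force_stouffer(p), abs=1e-12)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ParameterError):
            stouffer_liptak([0.1, 0.2], np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestSidak:
    def test_single_possible_region_identity(self):
        assert sidak_correct(0.01, 500, 500) == pytest.approx(0.01, abs=1e-12)

    def test_ratio_100(self):
        assert sidak_correct(0.001, 10, 1000) == pytest.approx(0.09521, abs=1e-5)

    def test_zero_p(self):
        assert sidak_correct(0.0, 10, 1000) == 0.0

    def test_monotone_in_ratio_and_p(self):
        assert sidak_correct(0.001, 10, 2000) > sidak_correct(0.001, 10, 1000)
        assert sidak_correct(0.002, 10, 1000) > sidak_correct(0.001, 10, 1000)

    def test_zero_length_rejected(self):
        with pytest.raises(ParameterError):
            sidak_correct(0.01, 0, 1000)


class TestEstimateACF:
    def test_identical_pair_values_give_correlation_one(self, rng):
        # 15 isolated pairs 30 bp apart with identical p inside each pair
        positions, pvals = [], []
        for k in range(15):
            base = 10_000 * (k + 1)
            p = rng.uniform(0.05, 0.95)
            positions += [base, base + 30]
            pvals += [p, p]
        manifest = _manifest_at(positions)
        acf = estimate_acf(np.array(pvals), manifest, min_pairs=10)
        assert acf.correlations[0] == pytest.approx(1.0, abs=1e-12)

    def test_independent_p_gives_near_zero(self, rng):
        positions, pvals = [], []
        for k in range(10_000):
            base = 10_000 * (k + 1)
            positions += [base, base + 30]
            pvals += list(rng.uniform(size=2))
        manifest = _manifest_at(positions)
        acf = estimate_acf(np.array(pvals), manifest, min_pairs=10)
        assert acf.correlations[0] <= 0.05  # clipped at 0 from below

    def test_sparse_bin_inherits_previous(self, rng):
        # dense pairs at ~30 bp (bin 0), only 3 pairs at ~80 bp (bin 1)
        positions, pvals = [], []
        for k in range(20):
            base = 10_000 * (k + 1)
            p = rng.uniform(0.05, 0.95)
            positions += [base, base + 30]
            pvals += [p, p]
        for k in range(3):
            base = 10_000 * (k + 100)
            positions += [base, base + 80]
            pvals += list(rng.uniform(size=2))
        order = np.argsort(positions)
        manifest = _manifest_at(list(np.array(positions)[order]))
        acf = estimate_acf(np.array(pvals)[order], manifest, min_pairs=10)
        assert acf.n_pairs[1] == 3
        assert acf.correlations[1] == acf.correlations[0]

    def test_lookup_boundaries(self):
        acf = _zero_acf()
        acf.correlations[:] = 0.5
        np.testing.assert_allclose(acf.lookup(np.array([0, 25, 1000, 1001])),
                                   [1.0, 0.5, 0.5, 0.0])


class TestSLKCorrect:
    def test_isolated_probe_keeps_p(self):
        manifest = _manifest_at([100, 50_000])
        p = np.array([0.02, 0.6])
        out = slk_correct(p, manifest, _zero_acf())
        np.testing.assert_allclose(out, p, atol=1e-12)

    def test_two_neighbours_zero_acf(self):
        manifest = _manifest_at([100, 200])
        out = slk_correct(np.array([0.05, 0.05]), manifest, _zero_acf())
        np.testing.assert_allclose(out, 0.0100, atol=2e-4)

    def test_flat_neighbour_worsens_slk_p(self):
        manifest2 = _manifest_at([100, 200])
        manifest3 = _manifest_at([100, 200, 300])
        pair = slk_correct(np.array([0.01, 0.01]), manifest2, _zero_acf())
        triple = slk_correct(np.array([0.01, 0.01, 1.0]), manifest3, _zero_acf())
        assert triple[0] > pair[0]

    def test_matches_brute_force_plain_stouffer(self, rng):
        positions = [100, 160, 240, 330, 5000, 5100]
        manifest = _manifest_at(positions)
        p = rng.uniform(0.001, 0.999, 6)
        out = slk_correct(p, manifest, _zero_acf())
        pos = np.array(positions)
        for i in range(6):
            window = np.abs(pos - pos[i]) <= 1000
            assert out[i] == pytest.approx(brute_force_stouffer(p[window]),
                                           abs=1e-12)


class TestPeakFinding:
    def test_hand_traced_scan(self):
        manifest = _manifest_at([100, 200, 1500, 1600])
        slk = np.array([0.01, 0.04, 0.20, 0.01])
        regions = find_candidate_regions(slk, manifest, seed_p=0.05,
                                         dist=1000, min_probes=2)
        assert len(regions) == 1
        assert regions[0]["start"] == 100 and regions[0]["end"] == 200
        assert regions[0]["indices"] == [0, 1]

    def test_no_regions_when_all_above_seed(self):
        manifest = _manifest_at([100, 150, 200])
        assert find_candidate_regions(np.array([0.06, 0.5, 0.9]), manifest) == []

    def test_full_chain_of_ten(self):
        manifest = _manifest_at(list(range(100, 600, 50)))
        regions = find_candidate_regions(np.full(10, 0.01), manifest)
        assert len(regions) == 1
        assert len(regions[0]["indices"]) == 10

    def test_chromosome_boundary_breaks_region(self):
        rows = []
        for i, (chrom, pos) in enumerate([("chr1", 100), ("chr1", 150),
                                          ("chr2", 100), ("chr2", 150)]):
            rows.append({"probe_id": f"cg{i:03d}", "chrom": chrom, "pos": pos,
                         "genes": [], "gene_region": [],
                         "island_relation": "OpenSea",
                         "snp_overlap": False, "sex_chrom": False})
        manifest = ProbeManifest(pd.DataFrame(rows).set_index("probe_id"))
        regions = find_candidate_regions(np.full(4, 0.01), manifest)
        assert len(regions) == 2


class TestRegionSignificance:
    def test_single_probe_region_identity(self):
        manifest = _manifest_at([100, 200])
        p = np.array([0.03, 0.5])
        assert region_significance([0], p, manifest, _zero_acf()) \
            == pytest.approx(0.03, abs=1e-12)

    def test_two_probe_independent(self):
        manifest = _manifest_at([100, 200])
        p = np.array([0.05, 0.05])
        assert region_significance([0, 1], p, manifest, _zero_acf()) \
            == pytest.approx(0.0100, abs=2e-4)

    def test_weak_probe_increases_region_p(self):
        manifest = _manifest_at([100, 200, 300])
        p = np.array([0.01, 0.01, 0.9])
        small = region_significance([0, 1], p, manifest, _zero_acf())
        large = region_significance([0, 1, 2], p, manifest, _zero_acf())
        assert large > small


@pytest.fixture(scope="module")
def effect_cohort():
    from methdmr import synthetic
    from methdmr.ewas import build_design, fit_sitewise
    manifest = synthetic.generate_manifest(600, n_chroms=2, seed=50,
                                           snp_fraction=0.0)
    sheet = synthetic.generate_cohort(10, 10, seed=51)
    baselines = synthetic.generate_baselines(manifest, seed=52)
    truth = synthetic.generate_truth(
        manifest, n_dmrs=4, seed=53, baselines=baselines,
        delta_beta_range=(0.10, 0.14), min_dmr_probes=5, hyper_fraction=1.0)
    matrix, _ = synthetic.simulate_betas(manifest, sheet, truth,
                                         baselines=baselines, seed=54)
    design = build_design(sheet, terms=("intercept", "group", "age", "sex"))
    results = fit_sitewise(matrix, design)
    return manifest, sheet, matrix, truth, results


class TestCallDmrs:
    def test_injected_hyper_regions_called_hyper(self, effect_cohort):
        manifest, sheet, matrix, truth, results = effect_cohort
        dmrs, _ = call_dmrs(results["p"].to_numpy(), matrix, manifest, sheet,
                            sidak_alpha=0.05)
        assert dmrs, "no regions called on a strong-effect cohort"
        for d in dmrs:
            assert d.direction == "hyper"
            assert d.mean_diff > 0

    def test_probes_lie_within_region_bounds(self, effect_cohort):
        manifest, sheet, matrix, truth, results = effect_cohort
        dmrs, audit = call_dmrs(results["p"].to_numpy(), matrix, manifest, sheet)
        table = audit["manifest_sorted"].table
        for d in dmrs:
            pos = table.loc[d.probe_ids, "pos"]
            assert d.start <= pos.min() and pos.max() <= d.end
            assert d.p_sidak >= d.p_region - 1e-15
            assert d.n_probes >= 2

    def test_sample_order_invariance(self, effect_cohort):
        manifest, sheet, matrix, truth, results = effect_cohort
        dmrs_a, _ = call_dmrs(results["p"].to_numpy(), matrix, manifest, sheet)
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(sheet.sample_ids))
        from methdmr.datamodel import BetaMatrix
        matrix_p = BetaMatrix(matrix.values[perm])
        sheet_p = sheet.restrict(perm)
        dmrs_b, _ = call_dmrs(results["p"].to_numpy(), matrix_p, manifest, sheet_p)
        assert [(d.chrom, d.start, d.end) for d in dmrs_a] \
            == [(d.chrom, d.start, d.end) for d in dmrs_b]
        np.testing.assert_allclose([d.p_sidak for d in dmrs_a],
                                   [d.p_sidak for d in dmrs_b], atol=1e-12)


class TestHyperFraction:
    def test_counting(self):
        from methdmr.dmr import DMR

        def mk(direction):
            return DMR(chrom="chr1", start=1, end=2, probe_ids=["a", "b"],
                       p_region=0.01, p_sidak=0.02, direction=direction)

        dmrs = [mk("hyper")] * 78 + [mk("hypo")] * 22
        assert hypermethylated_fraction(dmrs) == pytest.approx(0.78)
        assert hypermethylated_fraction([mk("hyper")]) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            hypermethylated_fraction([])
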