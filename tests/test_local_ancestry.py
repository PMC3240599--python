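import itertools

import numpy as np
import pytest

import admixkit as ak
from admixkit import simulate as sim
from admixkit.datamodel import DataModelError

from conftest import flat_markers


def brute_force_forward(alleles, freqs, q, tau, cm):
    """Path-enumeration likelihood and marginal posteriors for K=2, small M."""
    M = alleles.shape[0] if alleles.ndim == 1 else alleles.shape[1]
    x = alleles if alleles.ndim == 1 else alleles[0]
    fc = np.clip(freqs, 1e-3, 1 - 1e-3)
    d = np.diff(cm) / 100.0
    p_sw = 1 - np.exp(-tau * d)

    def emis(k, m):
        return fc[k, m] if x[m] == 1 else 1 - fc[k, m]

    total = 0.0
    post0 = np.zeros(M)
    for path in itertools.product(range(2), repeat=M):
        pr = q[path[0]] * emis(path[0], 0)
        for m in range(1, M):
            p = p_sw[m - 1]
            pr *= ((1 - p) * (path[m] == path[m - 1]) + p * q[path[m]]) * emis(path[m], m)
        total += pr
        for m in range(M):
            if path[m] == 0:
                post0[m] += pr
    return np.log(total), post0 / total


class TestDecode:
    def test_fully_informative_markers_recover_truth(self):
        M = 60
        markers = flat_markers(M)
        freqs = np.vstack([np.ones(M), np.zeros(M)])
        params = ak.HmmParams(K=2, ref_freqs=freqs, q=np.array([0.5, 0.5]), tau=12.0)
        truth = np.concatenate([np.zeros(M // 2, int), np.ones(M // 2, int)])
        alleles = np.where(truth == 0, 1, 0).astype(np.uint8)[None, :]
        panel = ak.HaplotypePanel(alleles=np.vstack([alleles, alleles]),
                                  markers=markers, sample_ids=["s0"])
        track = ak.decode_ancestry(panel, params)
        assert np.array_equal(track.labels[0], truth)

    def test_single_population_is_certain(self):
        M = 30
        markers = flat_markers(M)
        params = ak.HmmParams(K=1, ref_freqs=np.full((1, M), 0.4),
                              q=np.array([1.0]), tau=12.0)
        rng = np.random.default_rng(0)
        panel = ak.HaplotypePanel(alleles=(rng.random((2, M)) < 0.4).astype(np.uint8),
                                  markers=markers, sample_ids=["s0"])
        track = ak.decode_ancestry(panel, params)
        assert (track.labels == 0).all()
        np.testing.assert_allclose(track.posteriors, 1.0)

    def test_posteriors_sum_to_one(self, cohort6k):
        params = ak.estimate_hmm_params(
            {"a": cohort6k["sources"]["mats"][0].astype(float),
             "b": cohort6k["sources"]["mats"][1].astype(float)},
            q=np.array([0.5, 0.5]), tau=12.0)
        sub = ak.HaplotypePanel(alleles=cohort6k["panel"].alleles[:8],
                                markers=cohort6k["panel"].markers,
                                sample_ids=cohort6k["panel"].sample_ids[:4])
        track = ak.decode_ancestry(sub, params)
        np.testing.assert_allclose(track.posteriors.sum(axis=2), 1.0, atol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_loglik_and_posteriors_match_path_enumeration(self, seed):
        """Forward-backward agrees with brute-force path summation at M = 10."""
        rng = np.random.default_rng(seed)
        M = 10
        cm = np.sort(rng.uniform(0, 5, M))
        markers = flat_markers(M)
        markers["pos_cm"] = cm
        freqs = rng.uniform(0.1, 0.9, (2, M))
        q = np.array([0.3, 0.7])
        params = ak.HmmParams(K=2, ref_freqs=freqs, q=q, tau=8.0)
        alleles = (rng.random((2, M)) < 0.5).astype(np.uint8)
        panel = ak.HaplotypePanel(alleles=alleles, markers=markers, sample_ids=["s0"])
        track = ak.decode_ancestry(panel, params)
        for h in range(2):
            ll, post0 = brute_force_forward(alleles[h], freqs, q, 8.0, cm)
            assert track.loglik[h] == pytest.approx(ll, abs=1e-8)
            np.testing.assert_allclose(track.posteriors[h, :, 0], post0, atol=1e-10)

    def test_decode_is_deterministic(self, cohort6k):
        params = ak.estimate_hmm_params(
            {"a": cohort6k["sources"]["mats"][0].astype(float),
             "b": cohort6k["sources"]["mats"][1].astype(float)},
            q=np.array([0.5, 0.5]), tau=12.0)
        sub = ak.HaplotypePanel(alleles=cohort6k["panel"].alleles[:4],
                                markers=cohort6k["panel"].markers,
                                sample_ids=cohort6k["panel"].sample_ids[:2])
        t1 = ak.decode_ancestry(sub, params)
        t2 = ak.decode_ancestry(sub, params)
        assert np.array_equal(t1.labels, t2.labels)
        np.testing.assert_array_equal(t1.posteriors, t2.posteriors)

    def test_misaligned_frequencies_raise(self, cohort6k):
        params = ak.HmmParams(K=2, ref_freqs=np.full((2, 10), 0.5),
                              q=np.array([0.5, 0.5]), tau=12.0)
        with pytest.raises(DataModelError, match="match"):
            ak.decode_ancestry(cohort6k["panel"], params)


class TestDecodeAccuracy:
    @pytest.fixture(scope="class")
    def dense_sim(self):
        rng = np.random.default_rng(21)
        M = 20000
        markers = sim.simulate_markers(M, sim.DEFAULT_CHROM_LENGTHS_CM, rng)
        p_anc = rng.uniform(0.1, 0.9, M)
        freqs = sim.draw_population_freqs(p_anc, 0.15, 2, rng)
        mats = sim.simulate_source_haplotypes(freqs, 200, 0.3, markers, rng)
        cfg = sim.SimulationConfig(K=2, fst=0.15, M=M, T=12, n_individuals=8,
                                   z_dist=0.5, seed=13)
        panel, truth, z, info = sim.simulate_admixed_cohort(
            cfg, {"a": mats[0], "b": mats[1]}, markers,
            rng=np.random.default_rng(13))
        return panel, truth, mats

    def test_label_error_rate_low_at_dense_markers(self, dense_sim):
        """Per-marker error stays below 10% at FST 0.15, T = 12, 20k markers.

        The error is dominated by boundary fuzz: ~200 effective switch points
        per haploid genome, each localized to within a handful of markers by
        ~0.15 nats of frequency information per marker.
        """
        panel, truth, mats = dense_sim
        params = ak.estimate_hmm_params(
            {"a": mats[0].astype(float), "b": mats[1].astype(float)},
            q=np.array([0.5, 0.5]), tau=12.0)
        track = ak.decode_ancestry(panel, params)
        err = np.mean(track.labels != truth.labels)
        assert err < 0.10

    def test_order1_emissions_do_not_degrade_accuracy(self, dense_sim):
        panel, truth, mats = dense_sim
        refs = {"a": mats[0].astype(float), "b": mats[1].astype(float)}
        e = {}
        for order in (0, 1):
            params = ak.estimate_hmm_params(refs, q=np.array([0.5, 0.5]),
                                            tau=12.0, markov_order=order)
            track = ak.decode_ancestry(panel, params)
            e[order] = np.mean(track.labels != truth.labels)
        assert e[1] <= e[0] + 0.01

    def test_error_rate_monotone_in_differentiation(self):
        """Mean label error decreases as source FST grows (0.02, 0.05, 0.15)."""
        errors = {}
        rng = np.random.default_rng(31)
        M = 6000
        markers = sim.simulate_markers(M, sim.DEFAULT_CHROM_LENGTHS_CM, rng)
        p_anc = rng.uniform(0.1, 0.9, M)
        for fst in (0.02, 0.05, 0.15):
            errs = []
            for seed in range(10):
                r = np.random.default_rng(1000 * seed + int(fst * 100))
                freqs = sim.draw_population_freqs(p_anc, fst, 2, r)
                mats = sim.simulate_source_haplotypes(freqs, 120, 0.3, markers, r)
                cfg = sim.SimulationConfig(K=2, fst=fst, M=M, T=12,
                                           n_individuals=2, z_dist=0.5, seed=seed)
                panel, truth, z, info = sim.simulate_admixed_cohort(
                    cfg, {"a": mats[0], "b": mats[1]}, markers, rng=r)
                params = ak.estimate_hmm_params(
                    {"a": mats[0].astype(float), "b": mats[1].astype(float)},
                    q=np.array([0.5, 0.5]), tau=12.0)
                track = ak.decode_ancestry(panel, params)
                errs.append(np.mean(track.labels != truth.labels))
            errors[fst] = np.mean(errs)
        assert errors[0.02] > errors[0.05] > errors[0.15]


class TestReferenceRefinement:
    def test_clean_references_converge_immediately(self, sources6k):
        mats = sources6k["mats"]
        alleles = np.vstack([mats[0][:40], mats[1][:40]])
        panel = ak.HaplotypePanel(alleles=alleles, markers=sources6k["markers"],
                                  sample_ids=[f"s{i}" for i in range(40)])
        refs = {"a": list(range(20)), "b": list(range(20, 40))}
        params, masks = ak.refine_reference_panel(panel, refs, tau=12.0)
        direct_a = np.clip(mats[0][:40].mean(axis=0), 1e-3, 1 - 1e-3)
        kept_frac = masks["a"].mean()
        assert kept_frac > 0.97
        assert np.mean(np.abs(params.ref_freqs[0] - direct_a)) < 0.01
        assert np.corrcoef(params.ref_freqs[0], direct_a)[0, 1] > 0.99

    def test_contaminated_references_improve_after_refinement(self, sources6k):
        """References carrying ~20% foreign segments yield frequencies closer
        (L2) to the donor panel's empirical frequencies after refinement."""
        mats, markers = sources6k["mats"], sources6k["markers"]
        cfg = sim.SimulationConfig(K=2, fst=0.15, M=sources6k["M"], T=12,
                                   n_individuals=30, z_dist=0.2, seed=3)
        contaminated, truth, z, info = sim.simulate_admixed_cohort(
            cfg, {"a": mats[0], "b": mats[1]}, markers,
            rng=np.random.default_rng(3))
        pure = sim.simulate_source_panel(mats[0], markers, "pa")
        panel = ak.HaplotypePanel(
            alleles=np.vstack([pure.alleles, contaminated.alleles]),
            markers=markers,
            sample_ids=pure.sample_ids + contaminated.sample_ids)
        refs = {"a": list(range(pure.n_samples)),
                "b": [pure.n_samples + i for i in range(30)]}
        params, masks = ak.refine_reference_panel(panel, refs, tau=12.0)
        target = mats[1].mean(axis=0)
        err_naive = np.linalg.norm(contaminated.alleles.mean(axis=0) - target)
        err_refined = np.linalg.norm(params.ref_freqs[1] - target)
        assert err_refined < err_naive

    def test_empty_reference_set_raises(self, sources6k):
        panel = sim.simulate_source_panel(sources6k["mats"][0],
                                          sources6k["markers"], "s")
        with pytest.raises(DataModelError, match="empty"):
            ak.refine_reference_panel(panel, {"a": [], "b": [0, 1]})


class TestGlobalAncestry:
    def test_uniform_posterior_gives_uniform_ancestry(self):
        K, H, M = 3, 4, 10
        post = np.full((H, M, K), 1 / K)
        labels = np.zeros((H, M), dtype=np.int16)
        track = ak.AncestryTrack(labels=labels, K=K, ancestry_names=list("abc"),
                                 posteriors=post)
        ga = ak.global_ancestry_from_local(track)
        np.testing.assert_allclose(ga, 1 / K)

    def test_pure_individual_gives_unit_vector(self):
        H, M = 2, 10
        post = np.zeros((H, M, 2))
        post[:, :, 1] = 1.0
        labels = np.ones((H, M), dtype=np.int16)
        track = ak.AncestryTrack(labels=labels, K=2, ancestry_names=["a", "b"],
                                 posteriors=post)
        np.testing.assert_allclose(ak.global_ancestry_from_local(track),
                                   [[0.0, 1.0]])

    def test_correlates_with_true_admixture_proportion(self, cohort6k):
        """Averaging decoded local ancestry recovers z with r > 0.99."""
        params = ak.estimate_hmm_params(
            {"a": cohort6k["sources"]["mats"][0].astype(float),
             "b": cohort6k["sources"]["mats"][1].astype(float)},
            q=np.array([0.5, 0.5]), tau=12.0)
        track = ak.decode_ancestry(cohort6k["panel"], params)
        ga = ak.global_ancestry_from_local(track)
        assert np.corrcoef(ga[:, 0], cohort6k["z"])[0, 1] > 0.99


class TestAncestryDeviation:
    def test_neutral_cohort_rarely_flags(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 2, (300, 800)).astype(np.int16)
        res = ak.ancestry_deviation_scan(
            ak.AncestryTrack(labels=labels, K=2, ancestry_names=["a", "b"]))
        assert len(res.flagged) / 800 < 0.001
        np.testing.assert_allclose(res.marker_means.mean(axis=0),
                                   res.genome_mean, atol=1e-12)

    def test_planted_shift_is_flagged(self):
        rng = np.random.default_rng(8)
        labels = rng.integers(0, 2, (300, 800)).astype(np.int16)
        labels[:260, 400:410] = 1   # raise ancestry-1 dosage locally by ~0.35
        res = ak.ancestry_deviation_scan(
            ak.AncestryTrack(labels=labels, K=2, ancestry_names=["a", "b"]))
        assert np.intersect1d(res.flagged, np.arange(400, 410)).size > 0

    def test_degenerate_identical_tracks_flag_nothing(self):
        labels = np.zeros((10, 50), dtype=np.int16)
        res = ak.ancestry_deviation_scan(
            ak.AncestryTrack(labels=labels, K=2, ancestry_names=["a", "b"]))
        assert len(res.flagged) == 0
        assert np.isnan(res.z_scores).all()
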