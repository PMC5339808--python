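"""Random-effects model selection, exceedance probabilities, group averages."""

import math

import numpy as np
import pandas as pd
import pytest

from actibout import distmodels as dm
from actibout.fitting import FitResult, SubjectFitSet, fit_all
from actibout.groupsel import (bms_dirichlet, compare_groups_logbf,
                               dirichlet_exceedance, evidence_from_bic,
                               evidence_matrix, group_average_params,
                               logbf_verbal_scale)
from actibout.synthetic import sample_durations

FAMS = ("exponential", "power_law", "weibull")


def make_fitset(sid, bics, family_params=None):
    fits = {}
    for fam, b in bics.items():
        params = (family_params or {}).get(fam, _default_params(fam))
        spec = dm.ModelSpec(fam, params, 1.0)
        fits[fam] = FitResult(spec=spec, loglik=-b / 2, n_tail=100,
                              k=dm.n_params(fam), bic=b, ks=0.1)
    return SubjectFitSet(subject_id=sid, state="pooled", event_type="active",
                         fits=fits, x_min=1.0,
                         best_family_by_bic=min(bics, key=bics.get))


def _default_params(fam):
    return {"exponential": {"lam": 1.0}, "power_law": {"alpha": 2.0},
            "weibull": {"beta": 1.0, "lam": 1.0},
            "trunc_power_law": {"alpha": 1.5, "lam": 0.01}}[fam]


class TestEvidence:
    def test_equal_bic_equal_evidence(self):
        ev = evidence_from_bic(make_fitset("a", {"exponential": 10.0,
                                                 "power_law": 10.0}))
        assert ev["exponential"] == ev["power_law"]

    def test_linear_map(self):
        d = 2 * math.log(100)
        ev = evidence_from_bic(make_fitset("a", {"exponential": 0.0,
                                                 "power_law": d}))
        assert ev["exponential"] - ev["power_law"] == pytest.approx(math.log(100))

    def test_renormalized_evidences_sum_to_one(self):
        ev = evidence_from_bic(make_fitset("a", {"exponential": 3.0,
                                                 "power_law": 9.0,
                                                 "weibull": 5.0}))
        vals = np.array(list(ev.values()))
        w = np.exp(vals - vals.max())
        assert w.sum() > 0 and np.isclose((w / w.sum()).sum(), 1.0)

    def test_single_converged_fit_rejected(self):
        fs = make_fitset("a", {"exponential": 1.0, "power_law": 2.0})
        fs.fits["power_law"].converged = False
        with pytest.raises(ValueError):
            evidence_from_bic(fs)


class TestExceedance:
    def test_beta_closed_form(self):
        # Dirichlet(2, 1): P(p1 > 1/2) = 1 - (1/2)^2 = 0.75 exactly
        phi = dirichlet_exceedance(np.array([2.0, 1.0]))
        assert phi[0] == pytest.approx(0.75, abs=1e-12)
        assert phi.sum() == pytest.approx(1.0)

    def test_symmetric_alpha_gives_uniform_phi(self):
        phi = dirichlet_exceedance(np.ones(5) * 3.0, mc_samples=1_000_000,
                                   seed=1)
        assert np.allclose(phi, 0.2, atol=3.0 / math.sqrt(1_000_000) * 10)

    def test_monte_carlo_matches_beta_for_k2(self):
        a = np.array([4.2, 2.9])
        exact = dirichlet_exceedance(a)
        rng_phi = np.zeros(2)
        draws = np.random.default_rng(0).dirichlet(a, size=500_000)
        rng_phi[0] = np.mean(draws[:, 0] > 0.5)
        assert rng_phi[0] == pytest.approx(exact[0], abs=3 / math.sqrt(500_000))


class TestBms:
    def _ev(self, rows, fams=FAMS):
        return pd.DataFrame(rows, columns=list(fams))

    def test_equal_evidence_symmetry(self):
        ev = self._ev(np.zeros((6, 3)))
        res = bms_dirichlet(ev, seed=0)
        assert np.allclose(res.exceedance, 1 / 3, atol=0.01)
        assert res.expected_frequencies.sum() == pytest.approx(1.0, abs=1e-10)

    def test_overwhelming_family_wins(self):
        ev = self._ev([[0.0, -50.0, -50.0]] * 10)
        res = bms_dirichlet(ev, seed=0)
        assert res.winner() == "exponential"
        assert res.exceedance[0] > 0.99

    def test_phi_monotone_in_cohort_size(self):
        phis = []
        for n in (5, 15, 30):
            ev = self._ev([[0.0, -3.0, -3.0]] * n)
            res = bms_dirichlet(ev, seed=0)
            phis.append(res.exceedance[0])
        assert phis[0] < phis[1] < phis[2]

    def test_invariance_to_per_subject_constant(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(8, 3))
        shifted = base + rng.normal(size=(8, 1)) * 100
        r1 = bms_dirichlet(self._ev(base), seed=5)
        r2 = bms_dirichlet(self._ev(shifted), seed=5)
        assert np.allclose(r1.dirichlet_alpha, r2.dirichlet_alpha, atol=1e-6)

    def test_missing_family_handled_by_row_renormalization(self):
        ev = self._ev([[0.0, -10.0, np.nan]] * 4)
        res = bms_dirichlet(ev, seed=0)
        assert res.winner() == "exponential"

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError):
            bms_dirichlet(self._ev([[0.0, 1.0, 2.0]]), seed=0)


class TestGroupAverages:
    def test_single_subject_identity(self):
        fs = make_fitset("a", {"exponential": 0.0, "power_law": 500.0})
        out = group_average_params([fs], "exponential")
        assert out["params"] == {"lam": 1.0}

    def test_equal_weight_mean(self):
        fs1 = make_fitset("a", {"power_law": 0.0, "exponential": 500.0},
                          {"power_law": {"alpha": 1.5}})
        fs2 = make_fitset("b", {"power_law": 0.0, "exponential": 500.0},
                          {"power_law": {"alpha": 2.5}})
        out = group_average_params([fs1, fs2], "power_law")
        assert out["params"]["alpha"] == pytest.approx(2.0)

    def test_never_plausible_family_is_na(self):
        # power_law evidence ratio exp(-250) << 0.05 for every subject
        fs = [make_fitset(s, {"exponential": 0.0, "power_law": 500.0})
              for s in "ab"]
        assert group_average_params(fs, "power_law") is None

    def test_weights_sum_to_one_within_subject(self):
        fs = make_fitset("a", {"exponential": 0.0, "power_law": 1.0,
                               "weibull": 2.0})
        ev = evidence_matrix([fs])
        row = ev.loc["a"].dropna()
        w = np.exp(row - row.max())
        assert (w / w.sum()).sum() == pytest.approx(1.0)


class TestLogBF:
    def test_duplicated_group_cannot_support_separation(self):
        x = sample_durations(dm.ModelSpec("exponential", {"lam": 0.3}), 1500,
                             seed=4)
        assert compare_groups_logbf(x, x.copy(), "exponential") < 0

    def test_same_distribution_usually_pools(self):
        spec = dm.ModelSpec("exponential", {"lam": 0.3}, 1.0)
        neg = 0
        for seed in range(10):
            a = sample_durations(spec, 1000, seed=2 * seed)
            b = sample_durations(spec, 1000, seed=2 * seed + 1)
            neg += compare_groups_logbf(a, b, "exponential") < 0
        assert neg >= 9

    def test_verbal_scale(self):
        assert logbf_verbal_scale(13.2) == "strong"
        assert logbf_verbal_scale(-0.2) == "inconclusive"


def test_end_to_end_tpl_cohort_recovery():
    """30 TPL subjects drive the TPL exceedance probability to ~1."""
    rng = np.random.default_rng(42)
    fitsets = []
    for i in range(12):
        x = sample_durations(
            dm.ModelSpec("trunc_power_law", {"alpha": 1.64, "lam": 2e-4}),
            4000, seed=int(rng.integers(2**31)))
        fitsets.append(fit_all(x, x_min=1.0, seed=i, n_starts=3,
                               subject_id=f"s{i}"))
    ev = evidence_matrix(fitsets)
    res = bms_dirichlet(ev, seed=0)
    assert res.winner() == "trunc_power_law"
    assert res.as_series()["trunc_power_law"] > 0.95
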