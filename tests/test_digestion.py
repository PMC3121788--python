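"""Digestion model: analytic oracle, Monte Carlo, amplicon detection."""

import math

import numpy as np
import pytest
from scipy import stats

from conftest import bare_loop
from nmloops.digestion import (
    analytic_amplicon_survival,
    analytic_attached_fraction,
    simulate_amplicon_detection,
    simulate_digestion,
)
from nmloops.errors import InvalidParameterError
from nmloops.types import AccessibilityProfile, Amplicon, NucleoidModel, SimulationConfig


def uniform_closed_form(theta: float) -> float:
    """Expected attached fraction for uniform hazard with total cut rate theta."""
    return (2.0 / theta) * (1.0 - math.exp(-theta)) - math.exp(-theta)


def enumerated_uniform_attached(theta: float, nmax: int = 80) -> float:
    """Independent enumeration oracle over discretized cut configurations.

    Condition on the cut count N ~ Poisson(theta); given N >= 1 cuts at
    iid uniform positions, the attached (anchor-containing) mass is
    min + (1 - max), with expectation 2 / (N + 1).
    """
    pmf = stats.poisson.pmf(np.arange(nmax + 1), theta)
    masses = np.concatenate([[1.0], 2.0 / (np.arange(1, nmax + 1) + 1.0)])
    return float(np.sum(pmf * masses))


class TestAnalyticOracle:
    def test_time_zero_fully_attached(self, default_profile):
        loop = bare_loop(20_000, 200, 200)
        assert analytic_attached_fraction(loop, default_profile, 0.0) == 1.0

    def test_zero_hazard_fully_attached(self):
        loop = bare_loop(20_000)
        prof = AccessibilityProfile(k0=0.0, alpha=2.0)
        assert analytic_attached_fraction(loop, prof, 60.0) == 1.0

    @pytest.mark.parametrize("theta", [0.3, 1.0, 3.0, 10.0])
    def test_uniform_hazard_matches_closed_form(self, theta):
        """alpha -> 0 limit, no footprints: exact closed form."""
        L = 10_000.0
        loop = bare_loop(L)
        prof = AccessibilityProfile(k0=theta / L, alpha=0.0)
        got = analytic_attached_fraction(loop, prof, 1.0)
        assert got == pytest.approx(uniform_closed_form(theta), abs=1e-9)
        # and the enumeration oracle agrees with the closed form
        assert enumerated_uniform_attached(theta) == pytest.approx(
            uniform_closed_form(theta), abs=1e-9
        )

    def test_negative_time_rejected(self, default_profile):
        with pytest.raises(InvalidParameterError):
            analytic_attached_fraction(bare_loop(1000), default_profile, -1.0)


class TestMonteCarlo:
    def test_no_digestion_without_enzyme(self):
        model = NucleoidModel(
            loops=[bare_loop(30_000, 300, 300)],
            profile=AccessibilityProfile(k0=0.0, alpha=2.0),
            seed=3,
        )
        res = simulate_digestion(model, SimulationConfig(n_nucleoids=50, seed=1))
        assert all(p.pct_attached == 100.0 for p in res.timecourse.points)

    def test_initial_condition(self, single_loop_model):
        res = simulate_digestion(single_loop_model, SimulationConfig(n_nucleoids=50, seed=1))
        assert res.timecourse.points[0].pct_attached == 100.0

    def test_empty_model_errors(self, default_profile):
        model = NucleoidModel(loops=[], profile=default_profile, seed=0)
        with pytest.raises(InvalidParameterError):
            simulate_digestion(model, SimulationConfig(n_nucleoids=5, seed=0))

    def test_uniform_hazard_matches_enumeration(self):
        """Single loop, uniform hazard (alpha->0), no footprints: Monte-Carlo
        attached fraction at total cut rate 1 agrees with the brute-force
        enumeration over cut configurations within 3 SE."""
        L = 10_000.0
        loop = bare_loop(L)
        prof = AccessibilityProfile(k0=1.0 / L / 60.0, alpha=0.0)  # theta=1 at t=60
        model = NucleoidModel(loops=[loop], profile=prof, seed=0)
        cfg = SimulationConfig(n_nucleoids=4000, seed=21)
        res = simulate_digestion(model, cfg)
        last = res.timecourse.points[-1]
        se = last.sd / math.sqrt(last.n)
        expect = 100.0 * enumerated_uniform_attached(1.0)
        assert abs(last.pct_attached - expect) <= 3 * se

    def test_monte_carlo_agrees_with_analytic_on_grid(self):
        """2 x 2 (k0, alpha) grid, all time points, one loop with MARs."""
        loop = bare_loop(30_000, 300, 300)
        cells = ok = 0
        for i, k0 in enumerate((8e-5, 4e-4)):
            for j, alpha in enumerate((0.5, 3.0)):
                prof = AccessibilityProfile(k0=k0, alpha=alpha)
                model = NucleoidModel(loops=[loop], profile=prof, seed=0)
                cfg = SimulationConfig(n_nucleoids=3000, seed=100 + 10 * i + j)
                res = simulate_digestion(model, cfg)
                for p in res.timecourse.points[1:]:
                    ana = 100.0 * analytic_attached_fraction(loop, prof, p.time_min)
                    se = p.sd / math.sqrt(p.n)
                    cells += 1
                    ok += abs(p.pct_attached - ana) <= 3 * se
        assert ok >= cells - 1  # allow one 3-sigma fluctuation in 16 cells

    def test_monotone_and_floored_random_configs(self, rng):
        """Attached %% never increases in time and never drops below the
        embedded floor, across random model/sampling configurations."""
        for _ in range(20):
            loops = []
            for i in range(rng.integers(1, 4)):
                total = float(rng.integers(5_000, 50_000))
                emb = rng.uniform(0, 0.1)
                loops.append(
                    bare_loop(total, emb * total / 2, emb * total / 2, loop_id=f"l{i}")
                )
            prof = AccessibilityProfile(
                k0=float(rng.uniform(0, 5e-4)), alpha=float(rng.uniform(0, 4))
            )
            model = NucleoidModel(loops=loops, profile=prof, seed=0)
            cfg = SimulationConfig(n_nucleoids=int(rng.integers(5, 20)), seed=int(rng.integers(1 << 30)))
            res = simulate_digestion(model, cfg)
            vals = res.timecourse.values
            assert all(b <= a + 1e-9 for a, b in zip(vals, vals[1:]))
            assert all(v >= 100.0 * model.embedded_fraction - 1e-9 for v in vals)

    def test_deterministic_given_seed(self, single_loop_model):
        cfg = SimulationConfig(n_nucleoids=200, seed=77)
        r1 = simulate_digestion(single_loop_model, cfg)
        r2 = simulate_digestion(single_loop_model, cfg)
        assert r1.timecourse.values == r2.timecourse.values
        assert np.array_equal(r1.per_nucleoid_pct, r2.per_nucleoid_pct)


class TestAmpliconDetection:
    def make_model(self, k0=2e-4, alpha=2.0):
        loop = bare_loop(42_000, 420, 420, loop_id="host")
        return NucleoidModel(
            loops=[loop], profile=AccessibilityProfile(k0=k0, alpha=alpha), seed=0
        )

    def test_amplicon_inside_footprint_always_detected(self):
        model = self.make_model(k0=8e-4)
        amp = Amplicon("embedded", "host", start_bp=50, length_bp=250)
        matrix = simulate_amplicon_detection(
            model, [amp], SimulationConfig(n_nucleoids=300, seed=4)
        )
        assert matrix.entries["detected"].all()

    def test_zero_hazard_all_positive(self):
        model = self.make_model(k0=0.0)
        amp = Amplicon("apex", "host", start_bp=20_000, length_bp=250)
        matrix = simulate_amplicon_detection(
            model, [amp], SimulationConfig(n_nucleoids=100, seed=4)
        )
        assert matrix.entries["detected"].all()

    def test_apex_amplicon_negative_after_threshold_crossing(self):
        """Analytic survival far below threshold at 15 min implies negative
        calls at 15, 30 and 60 min."""
        model = self.make_model(k0=8e-4)
        loop = model.loops[0]
        amp = Amplicon("apex", "host", start_bp=loop.total_bp / 2 - 125, length_bp=250)
        cfg = SimulationConfig(n_nucleoids=2000, detection_threshold=1e-2, seed=9)
        surv15 = analytic_amplicon_survival(loop, model.profile, amp, 15.0)
        assert surv15 < cfg.detection_threshold / 10
        matrix = simulate_amplicon_detection(model, [amp], cfg)
        late = matrix.entries[matrix.entries["timepoint_min"] >= 15.0]
        assert not late["detected"].any()

    def test_dangling_loop_id_errors(self):
        model = self.make_model()
        amp = Amplicon("ghost", "nonexistent", start_bp=0, length_bp=100)
        with pytest.raises(InvalidParameterError):
            simulate_amplicon_detection(model, [amp], SimulationConfig(n_nucleoids=5, seed=0))

    def test_gradient_ordering_analytic_and_empirical(self):
        """On one loop, the amplicon closer to the NM survives at least as
        well as a more distal one at every time point."""
        model = self.make_model()
        loop = model.loops[0]
        near = Amplicon("near", "host", start_bp=2_000, length_bp=250)
        far = Amplicon("far", "host", start_bp=15_000, length_bp=250)
        for t in (5.0, 15.0, 30.0, 60.0):
            assert analytic_amplicon_survival(loop, model.profile, near, t) >= (
                analytic_amplicon_survival(loop, model.profile, far, t)
            )
        cfg = SimulationConfig(n_nucleoids=3000, seed=6)
        entries = simulate_amplicon_detection(model, [near, far], cfg).entries
        frac = entries.groupby(["amplicon", "timepoint_min"])["survival_fraction"].mean()
        for t in (5.0, 15.0, 30.0, 60.0):
            assert frac[("near", t)] >= frac[("far", t)] - 0.02

    def test_deterministic_given_seed(self):
        model = self.make_model()
        amp = Amplicon("a", "host", start_bp=5_000, length_bp=250)
        cfg = SimulationConfig(n_nucleoids=500, seed=13)
        m1 = simulate_amplicon_detection(model, [amp], cfg)
        m2 = simulate_amplicon_detection(model, [amp], cfg)
        assert m1.entries.equals(m2.entries)
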