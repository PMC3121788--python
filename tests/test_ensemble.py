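"""Ensemble construction, aging operators, halo emission, fixture round trip."""

import numpy as np
import pytest
from scipy import stats

from conftest import bare_loop
from nmloops.ensemble import (
    build_nucleoid_ensemble,
    evolve_nhos,
    export_fixture,
    import_fixture,
    loop_size_distribution,
    simulate_halo_radii,
)
from nmloops.errors import InvalidParameterError
from nmloops.halo import loop_size_from_halo
from nmloops.types import AccessibilityProfile, Amplicon, NucleoidModel


@pytest.fixture
def profile():
    return AccessibilityProfile(k0=2e-4, alpha=2.0)


class TestBuild:
    def test_embedded_fraction_hits_target(self, profile):
        model = build_nucleoid_ensemble(1000, 42.0, 0.1, 0.02, profile, seed=1)
        assert 0.018 <= model.embedded_fraction <= 0.022
        sizes = np.array([lp.total_bp for lp in model.loops])
        assert sizes.mean() == pytest.approx(42_000, rel=0.02)
        assert sizes.std() / sizes.mean() == pytest.approx(0.1, rel=0.15)

    def test_zero_embedded_target(self, profile):
        model = build_nucleoid_ensemble(50, 42.0, 0.1, 0.0, profile, seed=1)
        assert model.embedded_fraction == 0.0
        assert all(lp.embedded_bp == 0 for lp in model.loops)

    def test_footprints_split_equally(self, profile):
        model = build_nucleoid_ensemble(10, 42.0, 0.1, 0.02, profile, seed=2)
        for lp in model.loops:
            assert lp.left_footprint_bp == lp.right_footprint_bp

    def test_same_seed_identical_tables(self, profile):
        m1 = build_nucleoid_ensemble(100, 42.0, 0.1, 0.02, profile, seed=9)
        m2 = build_nucleoid_ensemble(100, 42.0, 0.1, 0.02, profile, seed=9)
        assert m1.to_frame().equals(m2.to_frame())

    def test_invalid_embedded_target(self, profile):
        with pytest.raises(InvalidParameterError):
            build_nucleoid_ensemble(10, 42.0, 0.1, 1.0, profile, seed=0)


class TestEvolveModeB:
    def test_zero_extension_is_identity(self, profile):
        model = build_nucleoid_ensemble(20, 42.0, 0.1, 0.02, profile, seed=3)
        evolved = evolve_nhos(model, "B_extension", extension=0.0, seed=1)
        assert evolved.to_frame().equals(model.to_frame())

    def test_twenty_percent_absorption_conserves_mass_exactly(self, profile):
        """Deterministic 10% per-anchor growth absorbs exactly 20% of free
        DNA: embedded_new = embedded_old + 0.20 (1 - embedded_old)."""
        model = build_nucleoid_ensemble(200, 42.0, 0.1, 0.02, profile, seed=4)
        e0 = model.embedded_fraction
        evolved = evolve_nhos(model, "B_extension", extension=0.1, seed=1)
        assert evolved.total_bp == model.total_bp  # mass conserved exactly
        assert evolved.embedded_fraction == pytest.approx(e0 + 0.2 * (1 - e0), abs=1e-9)
        assert evolved.n_loops <= model.n_loops

    def test_mean_size_preserved_and_embedding_strictly_increases(self, profile):
        model = build_nucleoid_ensemble(500, 42.0, 0.1, 0.02, profile, seed=5)
        mean0 = np.mean([lp.total_bp for lp in model.loops])
        evolved = evolve_nhos(model, "B_extension", seed=2)
        mean1 = np.mean([lp.total_bp for lp in evolved.loops])
        assert abs(mean1 - mean0) / mean0 <= 0.10
        assert evolved.embedded_fraction > model.embedded_fraction

    def test_overgrowth_clipped_and_loop_absorbed(self, profile):
        loop = bare_loop(10_000, 100, 100, loop_id="tiny")
        model = NucleoidModel(loops=[loop], profile=profile, seed=0)
        evolved = evolve_nhos(
            model, "B_extension", extension={"kind": "fixed_bp", "bp": 20_000}, seed=1
        )
        assert evolved.n_loops == 0
        assert evolved.absorbed_bp == 10_000
        assert evolved.total_bp == model.total_bp
        assert "tiny" in evolved.absorbed_loop_ids

    def test_random_extensions_conserve_mass_and_shrink_loop_count(self, profile):
        model = build_nucleoid_ensemble(300, 42.0, 0.3, 0.02, profile, seed=6)
        evolved = evolve_nhos(
            model, "B_extension",
            extension={"kind": "exponential", "mean_fraction": 0.4}, seed=7,
        )
        assert evolved.total_bp == pytest.approx(model.total_bp, abs=1e-6)
        assert evolved.n_loops <= model.n_loops
        assert all(lp.free_bp >= 0 for lp in evolved.loops)


class TestEvolveModeA:
    def test_full_substitution_redraws_size_distribution(self, profile):
        model = build_nucleoid_ensemble(1000, 42.0, 0.1, 0.02, profile, seed=8)
        evolved = evolve_nhos(
            model, "A_substitution", p_sub=1.0, loop_size_dist=(30.0, 0.3), seed=3
        )
        sizes = np.array([lp.total_bp for lp in evolved.loops])
        dist = loop_size_distribution(30.0, 0.3)
        d_stat = stats.kstest(sizes, dist.cdf).statistic
        assert d_stat < 1.949 / np.sqrt(len(sizes))  # KS alpha=0.001 critical value

    def test_no_substitution_is_identity(self, profile):
        model = build_nucleoid_ensemble(50, 42.0, 0.1, 0.02, profile, seed=8)
        evolved = evolve_nhos(
            model, "A_substitution", p_sub=0.0, loop_size_dist=(30.0, 0.3), seed=3
        )
        assert evolved.to_frame().equals(model.to_frame())

    def test_amplicons_stay_inside_their_loops(self, profile):
        model = build_nucleoid_ensemble(50, 42.0, 0.1, 0.02, profile, seed=8)
        amps = [
            Amplicon(f"a{i}", lp.loop_id, start_bp=lp.total_bp / 3, length_bp=250)
            for i, lp in enumerate(model.loops[:10])
        ]
        evolved, new_amps = evolve_nhos(
            model, "A_substitution", p_sub=1.0, loop_size_dist=(30.0, 0.3),
            seed=3, amplicons=amps,
        )
        for amp in new_amps:
            loop = evolved.loop_by_id(amp.loop_id)
            assert 0 <= amp.start_bp and amp.end_bp <= loop.total_bp


class TestHaloEmission:
    def test_noise_free_radius_is_exact(self, profile):
        model = build_nucleoid_ensemble(100, 42.0, 0.0, 0.0, profile, seed=2)
        ms = simulate_halo_radii(model, 10, 0.0, seed=3)
        radii = ms.records["halo_radius_um"]
        assert np.allclose(radii, 7.14, atol=0.005)  # 42000 x 0.34 / 1000 / 2

    def test_round_trip_recovers_loop_size(self, profile):
        model = build_nucleoid_ensemble(100, 42.0, 0.0, 0.0, profile, seed=2)
        noise_cv, n = 0.05, 400
        ms = simulate_halo_radii(model, n, noise_cv, seed=5)
        est = loop_size_from_halo(ms.records["halo_radius_um"].to_numpy()).mean()
        assert abs(est - 42.0) / 42.0 <= 2 * noise_cv / np.sqrt(n)

    def test_noise_zero_roundtrip_is_exact_inverse(self, profile):
        model = build_nucleoid_ensemble(50, 36.0, 0.0, 0.0, profile, seed=2)
        ms = simulate_halo_radii(model, 5, 0.0, seed=1)
        kbp = loop_size_from_halo(ms.records["halo_radius_um"].to_numpy())
        assert np.allclose(kbp, 36.0, atol=1e-9)

    def test_configured_nm_wider_than_nucleus(self, profile):
        from nmloops.halo import nm_resilience

        model = build_nucleoid_ensemble(20, 42.0, 0.1, 0.02, profile, seed=2)
        ms = simulate_halo_radii(model, 200, 0.05, seed=8)
        assert nm_resilience(ms)["resilient"]

    def test_invalid_inputs(self, profile):
        model = build_nucleoid_ensemble(5, 42.0, 0.1, 0.02, profile, seed=2)
        with pytest.raises(InvalidParameterError):
            simulate_halo_radii(model, 0, 0.1)
        with pytest.raises(InvalidParameterError):
            simulate_halo_radii(model, 10, -0.1)


class TestFixtureRoundTrip:
    def test_export_import_equality(self, tmp_path, profile):
        model = build_nucleoid_ensemble(5, 3.0, 0.2, 0.02, profile, seed=6)
        amps = [
            Amplicon("a1", model.loops[0].loop_id, 500.0, 250.0, "1q1", True),
            Amplicon("a2", model.loops[2].loop_id, 900.0, 150.0, "2p3", False),
        ]
        paths = export_fixture(model, amps, tmp_path / "fix")
        model2, amps2 = import_fixture(tmp_path / "fix")
        assert model2.to_frame().equals(model.to_frame())
        assert model2.profile == model.profile
        assert amps2 == amps
        assert paths["fasta"].exists() and paths["bed"].exists()

    def test_bed_intervals_within_loop_bounds(self, tmp_path, profile):
        model = build_nucleoid_ensemble(4, 2.0, 0.1, 0.05, profile, seed=7)
        amps = [Amplicon("a1", model.loops[1].loop_id, 200.0, 100.0)]
        paths = export_fixture(model, amps, tmp_path / "fix")
        totals = {lp.loop_id: lp.total_bp for lp in model.loops}
        n_amp_lines = 0
        for line in paths["bed"].read_text().splitlines():
            chrom, start, end, name = line.split("\t")[:4]
            assert 0 <= int(start) < int(end) <= round(totals[chrom])
            n_amp_lines += not name.endswith(("_MAR_left", "_MAR_right"))
        assert n_amp_lines == len(amps)

    def test_fasta_lengths_match_loops(self, tmp_path, profile):
        from Bio import SeqIO

        model = build_nucleoid_ensemble(3, 1.5, 0.1, 0.0, profile, seed=8)
        paths = export_fixture(model, [], tmp_path / "fix")
        records = {r.id: len(r.seq) for r in SeqIO.parse(str(paths["fasta"]), "fasta")}
        assert records == {lp.loop_id: round(lp.total_bp) for lp in model.loops}
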