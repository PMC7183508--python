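"""The synthetic-experiment generator and its planted ground truth."""
import filecmp

import numpy as np
import pytest

from dacmet.chem import PROTON_MASS, S34_OFFSET, default_reaction_table
from dacmet.synth import (FixtureSpec, generate_fixture, subnetwork_a_fixture,
                          write_fixture)


class TestDeterminism:
    def test_same_seed_byte_identical_files(self, tmp_path):
        for sub in ("one", "two"):
            write_fixture(generate_fixture(FixtureSpec(seed=1)), tmp_path / sub)
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "one", tmp_path / "two",
            [p.name for p in (tmp_path / "one").iterdir()], shallow=False)
        assert not mismatch and not errors

    def test_different_seeds_differ(self):
        a = generate_fixture(FixtureSpec(seed=1))
        b = generate_fixture(FixtureSpec(seed=2))
        mz_a = [p.mz for p in a.feature_table.peaks.values()]
        mz_b = [p.mz for p in b.feature_table.peaks.values()]
        assert mz_a != mz_b


class TestSpecValidation:
    def test_conjugate_without_source_rejected(self):
        with pytest.raises(ValueError, match="source"):
            FixtureSpec(n_source_compounds=0, conjugates_per_source=2)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            FixtureSpec(n_source_compounds=-1)


class TestPlantedStructure:
    def test_planted_edges_satisfy_exact_deltas(self):
        fx = generate_fixture(FixtureSpec(seed=3, mass_noise_ppm=0.0))
        deltas = {r.name: r.delta_mass for r in default_reaction_table()}
        for src, dst, reaction in fx.ground_truth.edges:
            m_src = fx.ground_truth.metabolite(src).neutral_mass
            m_dst = fx.ground_truth.metabolite(dst).neutral_mass
            assert m_dst - m_src == pytest.approx(deltas[reaction], abs=1e-6)

    def test_planted_shifts_inside_windows(self):
        fx = generate_fixture(FixtureSpec(seed=4))
        windows = {r.name: r.rt_window for r in default_reaction_table()}
        for src, dst, reaction in fx.ground_truth.edges:
            shift = (fx.ground_truth.metabolite(dst).rt
                     - fx.ground_truth.metabolite(src).rt)
            lo, hi = windows[reaction]
            assert lo <= shift <= hi

    def test_sulfates_carry_34s_and_nl80(self):
        fx = generate_fixture(FixtureSpec(seed=5))
        sulfates = [m for m in fx.ground_truth.metabolites
                    if m.formula and m.formula["S"] > 0]
        assert sulfates
        so3 = 79.956816
        for m in sulfates:
            pid = m.peak_ids[0]
            assert any(abs(off - S34_OFFSET) < 0.01
                       for off, _ in fx.isotopes[pid])
            spec = fx.msms[pid]
            assert any(abs(spec.precursor_mz - frag - so3) < 0.05
                       for frag, _ in spec.fragments)

    def test_decoys_violate_filtration_rules(self):
        fx = generate_fixture(FixtureSpec(seed=6))
        detected = fx.feature_table.detected()
        design = fx.design
        mock = design.samples_of_class("mock")
        pre = design.samples_of_class("pre")
        for m in fx.ground_truth.metabolites:
            if m.is_maoto_derived:
                for pid in m.peak_ids:
                    assert not detected.loc[pid, mock].any()
                    assert not detected.loc[pid, pre].any()
            elif "background" in m.name:
                assert detected.loc[m.peak_ids[0], pre].any()
            elif "mock_contaminant" in m.name:
                assert detected.loc[m.peak_ids[0], mock].any()

    def test_consensus_mz_close_to_true_mass(self):
        fx = generate_fixture(FixtureSpec(seed=8))
        for m in fx.ground_truth.metabolites:
            if not m.is_maoto_derived:
                continue
            peak = fx.feature_table.peaks[m.peak_ids[0]]
            err_ppm = abs(peak.neutral_mass - m.neutral_mass) / m.neutral_mass * 1e6
            assert err_ppm < 4.0  # 2 ppm/scan shrinks with detection count


class TestSubnetworkAPreset:
    def test_masses_from_formulas(self, subnet_fixture):
        truth = {m.name: m for m in subnet_fixture.ground_truth.metabolites}
        assert truth["liquiritin"].neutral_mass == pytest.approx(418.12638, abs=2e-5)
        assert truth["liquiritigenin"].neutral_mass == pytest.approx(
            256.07356, abs=2e-5)
        assert truth["liquiritigenin sulfate"].neutral_mass == pytest.approx(
            336.03038, abs=2e-5)
        assert truth["liquiritigenin glucuronide"].neutral_mass == pytest.approx(
            432.10565, abs=2e-5)
        assert truth["liquiritigenin glucuronide sulfate"
                     ].neutral_mass == pytest.approx(512.06247, abs=2e-5)

    def test_shift_geometry_self_consistent(self, subnet_fixture):
        """The planted shifts (LG: -1.3/-1.7; ILG: -2.8/-3.2) imply a single
        constant ILG - LG retention offset of 1.5 min."""
        truth = {m.name: m for m in subnet_fixture.ground_truth.metabolites}
        lg, ilg = truth["liquiritigenin"], truth["isoliquiritigenin"]
        sulf = truth["liquiritigenin sulfate"]
        gluc = truth["liquiritigenin glucuronide"]
        assert sulf.rt - lg.rt == pytest.approx(-1.3)
        assert gluc.rt - lg.rt == pytest.approx(-1.7)
        assert sulf.rt - ilg.rt == pytest.approx(-2.8)
        assert gluc.rt - ilg.rt == pytest.approx(-3.2)
        assert ilg.rt - lg.rt == pytest.approx(2.8 - 1.3)
        assert ilg.rt - lg.rt == pytest.approx(3.2 - 1.7)

    def test_duplicate_ion_pair_planted(self, subnet_fixture):
        truth = {m.name: m for m in subnet_fixture.ground_truth.metabolites}
        assert truth["liquiritigenin glucuronide"].peak_ids == ["P8722", "N6061"]
        table = subnet_fixture.feature_table
        assert table.peaks["P8722"].ion_mode == "positive"
        assert table.peaks["N6061"].ion_mode == "negative"
        assert abs(table.peaks["P8722"].rt - table.peaks["N6061"].rt) <= 0.2


class TestPipelineRecovery:
    """Zero-noise, zero-decoy runs recover the planted truth exactly."""

    def _pair_sets(self, fx, result):
        name_by_pid = {pid: m.name for m in fx.ground_truth.metabolites
                       for pid in m.peak_ids}

        def names(node):
            return frozenset(name_by_pid[p] for p in node.member_peaks)

        found = set()
        for e in result.network.edges:
            if e.within_window:
                found.add(frozenset(
                    names(result.network.nodes[e.source])
                    | names(result.network.nodes[e.target])))
        planted = {frozenset((s, d)) for s, d, _ in fx.ground_truth.edges}
        return planted, found

    def test_noise_free_recovery_is_exact(self):
        from dacmet.pipeline import run_all

        fx = generate_fixture(FixtureSpec(
            seed=11, mass_noise_ppm=0.0, intensity_noise_sd=0.0,
            n_decoy_peaks=0))
        result = run_all(fx.feature_table, fx.design)
        planted, found = self._pair_sets(fx, result)
        assert planted == found            # recall = precision = 1
        assert set(result.kept) == fx.ground_truth.maoto_peak_ids

    def test_filtration_recall_with_decoys(self):
        from dacmet.pipeline import run_all

        fx = generate_fixture(FixtureSpec(seed=12))
        result = run_all(fx.feature_table, fx.design)
        kept = set(result.kept)
        assert fx.ground_truth.maoto_peak_ids <= kept
        decoy_ids = {pid for m in fx.ground_truth.metabolites
                     if not m.is_maoto_derived for pid in m.peak_ids}
        assert not (decoy_ids & kept)
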