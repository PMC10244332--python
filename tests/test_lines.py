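"""Cell-line building: profiles, pruning, fitting, lesions, persistence."""

import numpy as np
import pytest

from bh3sim.lines import (
    DensitometryProfile,
    LesionSpec,
    ProfileError,
    apply_lesion,
    coip_fractions_of_state,
    fit_cell_line,
    load_line,
    normalized_abundances,
    profile_of_state,
    protein_totals,
    prune_network,
    save_line,
)
from bh3sim.network import NetworkValidationError
from bh3sim.synthetic import generate_ground_truth, synth_densitometry

ALL = ("BAX", "BAK", "BCL2", "BCLXL", "MCL1", "BCL2A1", "BID", "BIM", "PUMA", "NOXA")


def full_profile(**abund):
    base = {p: 0.5 for p in ALL}
    base["BCL2"] = 1.0
    base.update(abund)
    return DensitometryProfile(abundances=base)


class TestProfileValidation:
    def test_unknown_protein_rejected(self):
        with pytest.raises(ProfileError, match="unknown protein"):
            DensitometryProfile(abundances={"BAD": 1.0})

    def test_top_anti_apoptotic_must_be_one(self):
        with pytest.raises(ProfileError, match="must be 1.0"):
            DensitometryProfile(abundances={"BCL2": 0.7, "BAX": 0.5})

    def test_partner_fraction_sum_above_one_is_infeasible(self):
        with pytest.raises(ProfileError, match="infeasible"):
            DensitometryProfile(
                abundances={"BCL2": 1.0, "MCL1": 0.5, "BIM": 0.4, "BAX": 0.3},
                coip_fractions={("BCL2", "BIM"): 0.7, ("MCL1", "BIM"): 0.5},
            )

    def test_csv_round_trip(self, tmp_path):
        prof = full_profile()
        prof.coip_fractions = {("BCL2", "BIM"): 0.4, ("MCL1", "NOXA"): 0.2}
        prof.to_csvs(tmp_path / "p.csv", tmp_path / "c.csv")
        back = DensitometryProfile.from_csvs(tmp_path / "p.csv", tmp_path / "c.csv")
        assert back.abundances == pytest.approx(prof.abundances)
        assert back.coip_fractions == pytest.approx(prof.coip_fractions)


class TestPruning:
    def test_undetected_protein_fully_removed(self, canonical):
        pruned = prune_network(canonical, full_profile(BCL2A1=0.0))
        assert "BCL2A1" not in pruned.monomers()
        for s in pruned.species:
            assert "BCL2A1" not in s.constituents
            assert s.name != "BCL2A1_m"
        touched = {n for r in pruned.reactions for n in (*r.reactants, *r.products)}
        assert not any("BCL2A1" in n for n in touched)
        assert pruned.n_species < canonical.n_species
        assert pruned.n_reactions < canonical.n_reactions

    def test_all_detected_is_identity(self, canonical):
        pruned = prune_network(canonical, full_profile())
        assert pruned.n_species == canonical.n_species
        assert pruned.n_reactions == canonical.n_reactions

    def test_removing_all_effectors_rejected(self, canonical):
        profile = full_profile(BAX=0.0, BAK=0.0)
        with pytest.raises(NetworkValidationError, match="MOMP"):
            prune_network(canonical, profile)


@pytest.fixture(scope="module")
def recovered():
    """One seeded noiseless ground truth refit from its own profile."""
    gt = generate_ground_truth("BCLxL_dependent", 77)
    profile = synth_densitometry(gt)
    line = fit_cell_line(gt.line.model, profile, seed=1)
    return gt, profile, line


class TestFitting:
    def test_noiseless_profile_recovered(self, recovered):
        gt, profile, line = recovered
        sim = normalized_abundances(line.model, line.fitted_state.state)
        errs = [
            abs(sim[p] / profile.abundances[p] - 1.0)
            for p in profile.abundances
            if profile.abundances[p] > 0
        ]
        assert np.median(errs) < 0.05
        fracs = coip_fractions_of_state(line.model, line.fitted_state.state)
        ferrs = [abs(fracs.get(k, 0.0) - v) for k, v in profile.coip_fractions.items()]
        assert np.median(ferrs) < 0.05

    def test_fit_objective_reported_and_converged(self, recovered):
        _, _, line = recovered
        assert line.fit_objective is not None and line.fit_objective >= 0
        assert line.converged

    def test_refit_against_own_profile_is_stable(self, recovered):
        """Fit idempotence: a fitted line refit to its own summary barely moves."""
        _, _, line = recovered
        profile2 = profile_of_state(line.model, line.fitted_state.state)
        line2 = fit_cell_line(line.model, profile2, seed=1)
        a1 = normalized_abundances(line.model, line.fitted_state.state)
        a2 = normalized_abundances(line2.model, line2.fitted_state.state)
        for p, v in a1.items():
            assert a2[p] == pytest.approx(v, rel=0.05, abs=5e-3)

    def test_profile_without_effectors_rejected(self, canonical):
        profile = DensitometryProfile(
            abundances={"BCL2": 1.0, "MCL1": 0.4, "BIM": 0.2}
        )
        with pytest.raises(ProfileError, match="effector"):
            fit_cell_line(canonical, profile)


class TestLesions:
    def test_identity_lesion_leaves_state_unchanged(self, bclxl_fixture):
        line = bclxl_fixture.line
        same = apply_lesion(line, LesionSpec("identity", {"s_BAX": 1.0}))
        np.testing.assert_allclose(
            same.fitted_state.state, line.fitted_state.state, rtol=1e-6, atol=1e-10
        )

    def test_myc_translocation_raises_bax_and_bim(self, bclxl_fixture):
        line = bclxl_fixture.line
        before = protein_totals(line.model, line.fitted_state.state)
        after_line = apply_lesion(line, "MYC_translocation")
        after = protein_totals(after_line.model, after_line.fitted_state.state)
        assert after["BAX"] > before["BAX"]
        assert after["BIM"] > before["BIM"]
        # original untouched
        assert line.overrides == bclxl_fixture.line.overrides

    def test_p300_truncation_lowers_mcl1(self, bclxl_fixture):
        line = bclxl_fixture.line
        before = protein_totals(line.model, line.fitted_state.state)
        after_line = apply_lesion(line, "p300_truncation")
        after = protein_totals(after_line.model, after_line.fitted_state.state)
        assert after["MCL1"] < before["MCL1"]

    def test_unknown_lesion_parameter_rejected(self, bclxl_fixture):
        with pytest.raises(KeyError):
            apply_lesion(bclxl_fixture.line, LesionSpec("bad", {"s_NOPE": 2.0}))

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            LesionSpec("bad", {"s_BAX": 0.0})


class TestPersistence:
    def test_save_load_round_trip(self, bclxl_fixture, tmp_path):
        line = bclxl_fixture.line
        save_line(line, tmp_path / "line.yaml")
        back = load_line(tmp_path / "line.yaml")
        assert back.overrides == pytest.approx(line.overrides)
        np.testing.assert_allclose(
            back.fitted_state.state, line.fitted_state.state, rtol=1e-5, atol=1e-8
        )


class TestYamlConfig:
    def test_profile_from_yaml_config(self, tmp_path):
        text = """
name: demo
densitometry:
  BCL2: 1.0
  MCL1: 0.4
  BAX: 0.6
  BIM: 0.2
coip:
  BCL2:
    BIM: 0.5
    BAX: 0.2
"""
        path = tmp_path / "line.yaml"
        path.write_text(text)
        profile = DensitometryProfile.from_yaml(path)
        assert profile.abundances["MCL1"] == 0.4
        assert profile.coip_fractions[("BCL2", "BIM")] == 0.5
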