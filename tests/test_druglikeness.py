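import itertools

import pytest

from phytomarker.druglikeness import (AdmissionConfig, DescriptorRecord,
                                      GAEllipse, admission_decision,
                                      admit_marker, classify_ga,
                                      evaluate_rules)
from phytomarker.errors import ConfigError

# SMILES of study compounds, used with the toolkit adapter where installed
SMILES = {
    "caffeic_acid": "O=C(O)/C=C/c1ccc(O)c(O)c1",
    "luteolin": "O=c1cc(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12",
    "apigenin": "O=c1cc(-c2ccc(O)cc2)oc2cc(O)cc(O)c12",
    "kaempferol": "O=c1c(O)c(-c2ccc(O)cc2)oc2cc(O)cc(O)c12",
    "cichoric_acid":
        "O=C(O)C(OC(=O)/C=C/c1ccc(O)c(O)c1)C(OC(=O)/C=C/c1ccc(O)c(O)c1)C(=O)O",
}


def aspirin_like():
    return DescriptorRecord(
        compound_id="aspirin", mw=180.16, logp_wlogp=1.31, tpsa=63.6,
        hbd=1, hba=4, rotatable_bonds=3, molar_refractivity=44.9,
        heavy_atoms=13, rings=1, carbons=9, heteroatoms=4)


class TestRules:
    def test_small_acid_passes_lipinski_cleanly(self):
        v = evaluate_rules(aspirin_like())
        assert v["lipinski"].passed and not v["lipinski"].violations
        assert v["veber"].passed and v["egan"].passed

    def test_heavy_polar_molecule_fails_lipinski(self):
        d = DescriptorRecord("big", mw=700, logp_wlogp=2.0, hbd=7, hba=13)
        v = evaluate_rules(d)
        assert v["lipinski"].passed is False
        assert len(v["lipinski"].violations) >= 2  # > 1 violation tolerated

    def test_veber_violation_names_descriptor(self):
        d = DescriptorRecord("flex", rotatable_bonds=11, tpsa=100)
        v = evaluate_rules(d)
        assert v["veber"].passed is False
        assert any("rotatable_bonds" in msg for msg in v["veber"].violations)

    def test_missing_descriptors_make_rule_not_evaluable(self):
        d = DescriptorRecord("partial", mw=300.0, hbd=2, hba=5, logp_wlogp=1.0)
        v = evaluate_rules(d)
        assert v["lipinski"].passed is not None
        assert v["veber"].passed is None and "tpsa" in v["veber"].missing

    def test_rules_passed_counts_only_evaluable_rules(self):
        d = DescriptorRecord("partial", mw=300.0, hbd=2, hba=5,
                             logp_wlogp=1.0, tpsa=80.0, rotatable_bonds=4)
        with pytest.warns(UserWarning, match="not evaluable"):
            report = admit_marker(d, 1.0, 1.0)
        passes = [v.passed for v in report.verdicts.values() if v.passed is not None]
        assert report.rules_passed == sum(passes)
        assert report.rules_evaluable == len(passes)


class TestGAClassification:
    def test_center_is_high(self):
        e = GAEllipse()
        assert classify_ga(e.center_tpsa, e.center_wlogp) == "high"

    def test_far_outside_is_low(self):
        e = GAEllipse()
        assert classify_ga(e.center_tpsa + 10 * e.width, e.center_wlogp) == "low"

    def test_boundary_counts_as_inside(self):
        e = GAEllipse(center_tpsa=50, center_wlogp=2, width=100, height=4,
                      angle_deg=0.0)
        assert classify_ga(100.0, 2.0, e) == "high"   # exactly on the boundary
        assert classify_ga(100.0 + 1e-9, 2.0, e) == "low"

    def test_invariant_under_full_rotation(self):
        e = GAEllipse()
        e2 = GAEllipse(angle_deg=e.angle_deg + 360.0)
        for tpsa, wlogp in [(10, 0), (71, 2.3), (130, 4), (200, 1)]:
            assert classify_ga(tpsa, wlogp, e) == classify_ga(tpsa, wlogp, e2)

    def test_degenerate_axes_rejected(self):
        with pytest.raises(ConfigError):
            GAEllipse(width=0.0)


class TestAdmission:
    def test_rule_is_exactly_the_disjunction(self):
        """(GA high and >= 3 rules) OR content ratio > 20, over all
        2^5 rule patterns x GA class x {ratio 1, 25}."""
        for pattern in itertools.product([True, False], repeat=5):
            n_passed = sum(pattern)
            for ga in ("high", "low"):
                for ratio in (1.0, 25.0):
                    adm, override = admission_decision(ga, n_passed, ratio)
                    expected = (ga == "high" and n_passed >= 3) or ratio > 20
                    assert adm == expected
                    assert adm == ((ga == "high" and n_passed > 2)
                                   or override or (ga == "high" and n_passed >= 3))

    def test_high_content_override_admits_poorly_absorbed_compound(self):
        # the high-abundance phenolic acid: GA low, content ratio ~25
        d = DescriptorRecord("7", mw=474.37, logp_wlogp=1.42, tpsa=208.12,
                             hbd=6, hba=12, rotatable_bonds=9,
                             molar_refractivity=112.0, heavy_atoms=34,
                             rings=2, carbons=22, heteroatoms=12)
        report = admit_marker(d, 25.0, 1.0)
        assert report.ga_class == "low"
        assert report.admissible and report.override_applied

    def test_no_override_when_already_admissible(self):
        report = admit_marker(aspirin_like(), 25.0, 1.0)
        assert report.admissible and not report.override_applied

    def test_failing_both_routes_is_rejected(self):
        d = DescriptorRecord("bad", mw=700, logp_wlogp=7.0, tpsa=250,
                             hbd=9, hba=15, rotatable_bonds=20,
                             molar_refractivity=200, heavy_atoms=80,
                             rings=8, carbons=40, heteroatoms=20)
        report = admit_marker(d, 1.0, 1.0)
        assert not report.admissible

    def test_admission_is_monotone(self):
        cfg = AdmissionConfig()
        for n in range(5):
            for ga in ("low", "high"):
                for ratio in (1.0, 30.0):
                    adm, _ = admission_decision(ga, n, ratio, cfg)
                    if adm:
                        assert admission_decision(ga, n + 1, ratio, cfg)[0]
                        assert admission_decision("high", n, ratio, cfg)[0] or ga == "high"
                        assert admission_decision(ga, n, ratio * 2, cfg)[0]

    def test_negative_content_rejected(self):
        with pytest.raises(ConfigError):
            admit_marker(aspirin_like(), -1.0, 1.0)


class TestToolkitAdapter:
    rdkit = pytest.importorskip("rdkit")

    def test_study_marker_descriptors_behave_as_expected(self):
        from phytomarker.descriptors import descriptors_from_smiles
        records = {name: descriptors_from_smiles(smi, name)[0]
                   for name, smi in SMILES.items()}
        # small phenolic acid and the flavones absorb well...
        for name in ("caffeic_acid", "luteolin", "apigenin", "kaempferol"):
            d = records[name]
            assert classify_ga(d.tpsa, d.logp_wlogp) == "high"
            report = admit_marker(d, 1.0, 1.0)
            assert report.rules_passed >= 3 and report.admissible
        # ...the bulky double-caffeoyl tartrate does not
        cich = records["cichoric_acid"]
        assert classify_ga(cich.tpsa, cich.logp_wlogp) == "low"
        assert not admit_marker(cich, 1.0, 1.0).admissible
        assert admit_marker(cich, 25.0, 1.0).override_applied

    def test_adapter_matches_hand_record_for_aspirin(self):
        from phytomarker.descriptors import descriptors_from_smiles
        d, notes = descriptors_from_smiles("CC(=O)Oc1ccccc1C(=O)O", "aspirin")
        ref = aspirin_like()
        assert d.mw == pytest.approx(ref.mw, abs=0.1)
        assert d.tpsa == pytest.approx(ref.tpsa, abs=0.2)
        assert d.hbd == ref.hbd and d.rings == ref.rings
        assert "wildman-crippen" in notes["logp_wlogp"]
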