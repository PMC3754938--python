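"""PAI matching, confidence tiers, marker grouping and strain profiling."""

import pytest

from loxotype import chem
from loxotype.chem import Derivatization, adduct_mz
from loxotype.config import PipelineConfig
from loxotype.constants import UV_KETO_NM, UV_OXO_ACID_NM
from loxotype.errors import ValidationError
from loxotype.fragmentation import pathway_products
from loxotype.identify import Confidence, MSFeature, match_feature, profile_strain
from loxotype.phylo import Chemotype
from loxotype.simulate import SimulationConfig, StrainSpec, simulate_strain

ME = Derivatization.METHYL_ESTER


class TestMatchFeature:
    def test_theoretical_epoxy_alcohol_identified_with_lox_call(
            self, lib, pcfg, theoretical_feature):
        f = theoretical_feature(pathway_products(8).primary_epoxy_alcohol)
        r = match_feature(f, lib, pcfg)
        assert r.confidence is Confidence.IDENTIFIED
        assert r.matched_entry.name == "10,8-HEpETE"
        assert r.lox_call == 8
        assert {"precursor", "fragments"} <= r.matched_indicators

    def test_keto_uv_353_without_fragments_is_unknown_marker(self, lib, pcfg):
        mz, _ = adduct_mz(chem.keto_epa(), ME, "M+Na")
        f = MSFeature("m1", rt_min=21.2, precursor_mz=mz, peak_area=500.0,
                      uv_lambda_max_nm=UV_KETO_NM, assumed_adduct="M+Na")
        r = match_feature(f, lib, pcfg)
        assert r.confidence is Confidence.UNKNOWN_MARKER
        assert r.mk_group == "Mk353#2"  # nearest isomer RT on the reference scale

    def test_marker_unresolved_without_rt_reference(self, lib):
        cfg = PipelineConfig(rt_reference=False)
        mz, _ = adduct_mz(chem.keto_epa(), ME, "M+Na")
        f = MSFeature("m1", rt_min=21.2, precursor_mz=mz, peak_area=500.0,
                      uv_lambda_max_nm=UV_KETO_NM, assumed_adduct="M+Na")
        r = match_feature(f, lib, cfg)
        assert r.confidence is Confidence.UNKNOWN_MARKER
        assert r.mk_group == "353-unresolved"

    def test_oxo_acid_called_putative_by_precursor_and_uv(self, lib, pcfg):
        mz, _ = adduct_mz(chem.oxo15(), ME, "M+Na")
        f = MSFeature("o1", rt_min=16.8, precursor_mz=mz, peak_area=100.0,
                      uv_lambda_max_nm=UV_OXO_ACID_NM, assumed_adduct="M+Na")
        r = match_feature(f, lib, pcfg)
        assert r.confidence is Confidence.PUTATIVE
        assert r.matched_entry.name == "15-OXO"
        assert "uv" in r.matched_indicators

    def test_unmatched_precursor_is_unassigned(self, lib, pcfg):
        f = MSFeature("x1", rt_min=10.0, precursor_mz=199.9876, peak_area=1.0)
        assert match_feature(f, lib, pcfg).confidence is Confidence.UNASSIGNED

    def test_empty_library_rejected(self, pcfg):
        f = MSFeature("x1", rt_min=10.0, precursor_mz=355.2, peak_area=1.0)
        with pytest.raises(ValidationError):
            match_feature(f, [], pcfg)

    @pytest.mark.parametrize("kwargs,field", [
        (dict(rt_min=-1.0, precursor_mz=355.2, peak_area=1.0), "rt_min"),
        (dict(rt_min=1.0, precursor_mz=0.0, peak_area=1.0), "precursor_mz"),
        (dict(rt_min=1.0, precursor_mz=355.2, peak_area=-5.0), "peak_area"),
        (dict(rt_min=1.0, precursor_mz=355.2, peak_area=1.0,
              fragments=((100.0, -1.0),)), "fragments"),
    ])
    def test_malformed_feature_names_the_field(self, kwargs, field):
        with pytest.raises(ValidationError, match=field):
            MSFeature("bad", **kwargs)

    def test_determinism(self, lib, pcfg, theoretical_feature):
        f = theoretical_feature(pathway_products(12).primary_epoxy_alcohol)
        r1, r2 = match_feature(f, lib, pcfg), match_feature(f, lib, pcfg)
        assert (r1.matched_entry.name, r1.lox_call, r1.matched_indicators) \
            == (r2.matched_entry.name, r2.lox_call, r2.matched_indicators)

    def test_widening_tolerance_never_loses_indicators(self, lib, theoretical_feature):
        """Indicator count is monotone in the matching tolerances."""
        sp = pathway_products(15).primary_epoxy_alcohol
        f = theoretical_feature(sp)
        # perturb the feature so some indicators sit near the tolerance edge
        f = MSFeature(f.feature_id, rt_min=f.rt_min, peak_area=f.peak_area,
                      precursor_mz=f.precursor_mz + 0.015,
                      assumed_adduct=f.assumed_adduct,
                      fragments=tuple((mz + 0.04, i) for mz, i in f.fragments))
        narrow = PipelineConfig(precursor_tol_da=0.02, fragment_tol_da=0.05)
        wide = PipelineConfig(precursor_tol_da=0.04, fragment_tol_da=0.10)
        rn, rw = match_feature(f, lib, narrow), match_feature(f, lib, wide)
        assert len(rw.matched_indicators) >= len(rn.matched_indicators)
        assert rw.n_matched_fragments >= rn.n_matched_fragments


class TestProfileStrain:
    def _profile(self, lox=frozenset(), markers=frozenset(), oxo=False,
                 strain_id="S1", species="sp"):
        ct = Chemotype(lox_positions=frozenset(lox),
                       marker_groups=frozenset(markers), oxo_present=oxo)
        spec = StrainSpec(strain_id, species, ct)
        cfg = SimulationConfig.noiseless((spec,), seed=3)
        feats = simulate_strain(cfg, spec)
        return profile_strain(feats, cfg=PipelineConfig(rt_reference=True),
                              strain_id=strain_id, species_label=species)

    def test_dual_lox_chemotype_recovered(self):
        prof = self._profile(lox={15, 12})
        assert prof.lox_positions == {15, 12}
        assert {"15-HEPE", "13,14-HEpETE", "12-HEPE", "10,11-HEpETE"} \
            <= set(prof.compound_areas)
        assert prof.is_area and prof.is_area > 0

    def test_5_lox_chemotype(self):
        prof = self._profile(lox={5})
        assert prof.lox_positions == {5}
        assert {"5-HEPE", "7,5-HEpETE"} == set(prof.compound_areas)

    def test_empty_feature_list_gives_empty_profile(self, lib, pcfg):
        prof = profile_strain([], lib, pcfg, strain_id="E")
        assert prof.identifications == []
        assert prof.compound_areas == {}
        assert prof.missing_internal_standard

    @pytest.mark.parametrize("lox", [{5}, {8}, {12}, {14}, {15}])
    def test_no_cross_talk_at_zero_noise(self, lox):
        """A noiseless strain never yields a LOX call outside its chemotype."""
        prof = self._profile(lox=lox)
        assert prof.lox_positions == set(lox)

    def test_marker_isomer_pair_aggregates_to_one_row(self):
        prof = self._profile(markers={"Mk353#2"})
        assert set(prof.compound_areas) == {"Mk353#2"}
        assert prof.marker_groups == {"Mk353#2"}
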