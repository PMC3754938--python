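import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lib():
    from loxotype.library import default_library

    return default_library()


@pytest.fixture()
def pcfg():
    from loxotype.config import PipelineConfig

    return PipelineConfig(rt_reference=True)


@pytest.fixture()
def theoretical_feature():
    """Factory: exact precursor + full theoretical ion set for one compound."""
    from loxotype import chem, fragmentation
    from loxotype.chem import Derivatization, OxylipinClass
    from loxotype.identify import MSFeature

    def build(species, feature_id="f1", uv=None, rt=20.0, area=1000.0,
              adduct="M+Na", with_fragments=True):
        deriv = Derivatization.METHYL_ESTER
        mz, _ = chem.adduct_mz(species, deriv, adduct)
        frags = ()
        if with_fragments:
            if species.cls is OxylipinClass.HEPETE:
                ions = fragmentation.diagnostic_ions(species, deriv, adduct)
            elif species.cls is OxylipinClass.HEPE:
                ions = fragmentation.alpha_cleavage_ions(species, deriv, adduct)
            else:
                ions = ()
            frags = tuple((ion.mz, 10.0) for ion in ions)
        return MSFeature(feature_id=feature_id, rt_min=rt, precursor_mz=mz,
                         peak_area=area, uv_lambda_max_nm=uv,
                         assumed_adduct=adduct, fragments=frags)

    return build
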