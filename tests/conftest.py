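import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from barleyauth import fusion_chemometrics as fc
from barleyauth import pipeline as pl
from barleyauth import synthetic_data as sd


@pytest.fixture(scope="session")
def gen():
    """Default study-condition generator configuration, seed fixed."""
    return sd.GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def isotopes(gen):
    return sd.gen_isotopes(gen)


def _fused_table(gen, isotopes, cultivar):
    binned = {}
    for year in (2017, 2018):
        ids = gen.sample_ids(cultivar, year)
        for sid, reps in zip(ids, sd.gen_nir_spectra(gen, cultivar, year)):
            binned[sid] = pl.prepare_sample(reps)
    recs = [r for r in isotopes if r.cultivar == cultivar]
    return fc.fuse(binned, recs, cultivar=cultivar)


@pytest.fixture(scope="session")
def quench_table(gen, isotopes):
    return _fused_table(gen, isotopes, "Quench")


@pytest.fixture(scope="session")
def steffi_table(gen, isotopes):
    return _fused_table(gen, isotopes, "Steffi")
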