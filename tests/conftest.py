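import hypothesis
import pytest

import meioscreen as ms

hypothesis.settings.register_profile(
    "det", derandomize=True, max_examples=60, deadline=None
)
hypothesis.settings.load_profile("det")


# The published derived block of the nondisjunction assay, used as a frozen
# regression fixture: genotype -> (adjusted total, %X ND, %4 ND, %nullo-X,
# %diplo-X, %nullo-4, %diplo-4) exactly as printed (main ND rows at one
# decimal, component rows gaining a second decimal below 1%).
PRINTED_DERIVED_BLOCK = {
    "y w":          (820, "0.7", "0.7", "0.24", "0.49", "0.49", "0.24"),
    "mei-39^1":     (398, "42.2", "33.4", "20.1", "22.1", "22.6", "10.8"),
    "mei-39^166":   (575, "47.7", "37.0", "27.1", "20.5", "26.1", "11.0"),
    "mei-39^129":   (557, "38.4", "32.0", "19.0", "19.4", "20.1", "11.8"),
    "mei-826":      (550, "41.1", "31.8", "17.5", "23.6", "17.3", "14.5"),
    "mei-217^1330": (663, "32.3", "23.2", "12.7", "19.6", "13.6", "9.7"),
    "mei-218^125":  (192, "41.7", "24.5", "26.0", "15.6", "10.4", "14.1"),
    "mei-218^621":  (215, "27.9", "21.4", "11.2", "16.7", "9.3", "12.1"),
    "mei-218^1940": (398, "37.7", "31.7", "18.6", "19.1", "23.4", "8.3"),
    "mei-218^136":  (393, "43.8", "28.2", "18.8", "24.9", "15.5", "12.7"),
}


@pytest.fixture(scope="session")
def count_tables():
    return {t.genotype: t for t in ms.load_table1_counts()}


@pytest.fixture(scope="session")
def allele_table():
    return ms.load_allele_table()


@pytest.fixture(scope="session")
def complementation_tests():
    return ms.load_complementation_tests()
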