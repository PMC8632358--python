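import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from radsexscreen import Sex, SexLabels


@pytest.fixture
def table2_genotypes():
    """The validation-population marker genotypes: 100 individuals at one
    G/A locus (females: 56 het, 9 hom-alt; males: 33 hom-ref, 2 het)."""
    geno = {}
    labels = {}
    for i in range(65):
        ind = f"F{i + 1}"
        labels[ind] = Sex.FEMALE
        geno[ind] = "A/G" if i < 56 else "A/A"
    for i in range(35):
        ind = f"M{i + 1}"
        labels[ind] = Sex.MALE
        geno[ind] = "G/G" if i < 33 else "A/G"
    return geno, SexLabels(labels)


def make_labels(n_female: int, n_male: int) -> SexLabels:
    sexes = {f"F{i + 1}": Sex.FEMALE for i in range(n_female)}
    sexes.update({f"M{i + 1}": Sex.MALE for i in range(n_male)})
    return SexLabels(sexes)
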