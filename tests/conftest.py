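import numpy as np
import pytest

from mscdate import GammaPrior, load_species_tree
from mscdate.mcmc import PriorSet

THETAS4 = {k: 0.01 for k in ("A", "B", "C", "D", "AB", "CD", "ABC", "ABCD")}


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def symmetric4():
    """Fig. 4a-style symmetric tree: root 0.01, AB 0.007, CD 0.004 (mu = 1e-9)."""
    return load_species_tree(
        "((A,B)AB,(C,D)CD)ABCD;",
        {k: 0.01 for k in ("A", "B", "C", "D", "AB", "CD", "ABCD")},
        {"ABCD": 0.01, "AB": 0.007, "CD": 0.004},
    )


@pytest.fixture
def asymmetric4():
    return load_species_tree(
        "(((A,B)AB,C)ABC,D)ABCD;",
        {k: 0.005 for k in ("A", "B", "C", "D", "AB", "ABC", "ABCD")},
        {"ABCD": 0.01, "ABC": 0.007, "AB": 0.004},
    )


@pytest.fixture
def validation_priors():
    """Priors used by the validation experiments (root age, rate, theta)."""
    return PriorSet(
        tau_root=GammaPrior(10.0, 100.0),
        mu=GammaPrior(10.0, 1e8),
        theta=GammaPrior(8.0, 2000.0),
    )


def random_gene_tree(st, n_per_species, rng, max_age_frac=0.0):
    """Simulate a valid random gene tree (optionally with random tip dates)."""
    from mscdate.simulate import sample_genealogy

    tips = []
    ts = []
    labels = []
    for p in st.tips:
        bound = st.parent_tau(p)
        for i in range(n_per_species):
            tips.append(p)
            age = rng.uniform(0.0, max_age_frac * bound) if max_age_frac else 0.0
            ts.append(age)
            labels.append(f"{st.labels[p]}{i + 1}")
    return sample_genealogy(st, np.asarray(tips), np.asarray(ts), rng, labels)
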