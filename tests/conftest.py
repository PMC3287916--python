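import pytest

from ibdfilter import SimConfig, simulate_study
from ibdfilter.pedigree import FEMALE, MALE, Individual, Pedigree


@pytest.fixture(scope="session")
def small_study():
    """One modest simulated study shared by read-only tests."""
    cfg = SimConfig.scaled(seed=7, n_genes=150, n_snps=750, n_replicates=6)
    return simulate_study(cfg)


def _ind(iid, father, mother, sex, fam="F1"):
    return Individual(iid, father, mother, sex, fam)


@pytest.fixture
def cousin_pedigree():
    """Founding couple, two married children, one child each: first cousins
    A1 and B1; A1's child A2 extends the chain one more generation."""
    return Pedigree(
        [
            _ind("F", None, None, MALE),
            _ind("M", None, None, FEMALE),
            _ind("A", "F", "M", MALE),
            _ind("B", "F", "M", FEMALE),
            _ind("SA", None, None, FEMALE),
            _ind("SB", None, None, MALE),
            _ind("A1", "A", "SA", FEMALE),
            _ind("B1", "SB", "B", MALE),
            _ind("SA1", None, None, MALE),
            _ind("A2", "SA1", "A1", MALE),
        ]
    )


@pytest.fixture
def chain_pedigree():
    """Straight descent chain G0 .. G4 (four transmissions)."""
    inds = [_ind("G0", None, None, MALE), _ind("W0", None, None, FEMALE)]
    for g in range(1, 5):
        inds.append(_ind(f"G{g}", f"G{g-1}", f"W{g-1}", MALE))
        if g < 4:
            inds.append(_ind(f"W{g}", None, None, FEMALE))
    return Pedigree(inds)
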