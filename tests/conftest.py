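import numpy as np
import pandas as pd
import pytest

from phylofa.fatty_acids import CompositionTable, parse_fa_label
from phylofa.phylogeny import tree_from_string, vcv


def make_composition(rows: dict[str, dict[str, float]],
                     closure_tol: float = 0.5) -> CompositionTable:
    """Composition from {species: {fa_label: mol%}} filling absent acids with 0."""
    labels = sorted({l for row in rows.values() for l in row})
    species = list(rows)
    props = np.array([[rows[sp].get(l, 0.0) for l in labels] for sp in species])
    return CompositionTable(species, [parse_fa_label(l) for l in labels], props,
                            closure_tol=closure_tol)


@pytest.fixture
def worked_tree():
    """((A:1,B:1):1,C:2); — depths 2, A-B share path length 1."""
    return tree_from_string("((A:1,B:1):1,C:2);")


@pytest.fixture
def random_composition():
    """60 species x 12 acids, Dirichlet rows closing exactly to 100."""
    rng = np.random.default_rng(42)
    labels = ["C14:0", "C16:0", "C16:1n7", "C18:0", "C18:1n9", "C18:2n6",
              "C18:3n3", "C20:4n6", "C20:5n3", "C22:5n6", "C22:6n3", "C22:0"]
    props = 100.0 * rng.dirichlet(np.full(len(labels), 2.0), size=60)
    species = [f"sp{i:02d}" for i in range(60)]
    return CompositionTable(species, [parse_fa_label(l) for l in labels], props)
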