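import numpy as np
import pytest

from hmmvar import DomainHit, ModelSource, ProfileHMM


def make_model(
    emissions, model_id="M1", source=ModelSource.PFAM_A, compo=None, map_annotation=None
):
    return ProfileHMM(
        model_id=model_id,
        source=source,
        match_emissions=np.asarray(emissions, dtype=float),
        compo=compo,
        map_annotation=map_annotation,
    )


def point_mass_rows(residue_indices):
    rows = np.zeros((len(residue_indices), 20))
    for i, j in enumerate(residue_indices):
        rows[i, j] = 1.0
    return rows


@pytest.fixture
def uniform_model():
    """Four match states, every residue at probability 0.05."""
    return make_model(np.full((4, 20), 0.05), model_id="UNIF")


@pytest.fixture
def point_model():
    """Three match states with all mass on A, C, D respectively."""
    return make_model(point_mass_rows([0, 1, 2]), model_id="POINT")


@pytest.fixture
def identity_hit_for():
    def _make(protein_id, model, e_value=1e-6):
        from hmmvar import identity_hit

        return identity_hit(protein_id, model, e_value=e_value)

    return _make


def random_stochastic_vectors(rng, n):
    """Random emission distributions of varied peakedness, some with zeros."""
    alphas = rng.choice([0.05, 0.3, 1.0, 5.0], size=n)
    vecs = np.vstack([rng.dirichlet(np.full(20, a)) for a in alphas])
    # plant exact zeros in a fraction of rows, as "*" cells occur in real models
    for i in range(0, n, 7):
        row = vecs[i]
        row[rng.integers(0, 20)] = 0.0
        vecs[i] = row / row.sum()
    return vecs
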