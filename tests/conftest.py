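import numpy as np
import pytest

from torsionflux import (
    EnsembleSpec,
    SignalSpec,
    synth_ensemble,
    synth_features,
    write_multimodel_pdb,
)


@pytest.fixture(scope="session")
def helix_ensemble():
    """Planted-noise ensemble: 40 residues, 50 models, sigma 18 degrees."""
    return synth_ensemble(
        EnsembleSpec(L=40, M=50, sigma_phi=18.0, sigma_psi=18.0, seed=42)
    )


@pytest.fixture(scope="session")
def planted_signal():
    """20 chains x 25 residues, 5 informative of 50 columns, noise 0.1."""
    spec = SignalSpec(
        n_chains=20,
        length=25,
        n_columns=50,
        terms=[(0, c, 0.35) for c in range(5)],
        noise_sd=0.1,
        seed=7,
    )
    return synth_features(spec), spec


@pytest.fixture()
def toy_pdb(tmp_path):
    """Two-model, three-residue backbone written in PDB dialect."""
    e = synth_ensemble(
        EnsembleSpec(L=3, M=2, sigma_phi=5.0, sigma_psi=5.0, seed=1, chain_id="toy_A")
    )
    e.sequence = "AAA"
    path = tmp_path / "toy.pdb"
    write_multimodel_pdb(e, path)
    return path, e
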