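import copy

import pytest

from glycodelta.glycan_annotation import classify_saccharides, detect_sites
from glycodelta.pair_builder import ChainRecord, PairClass, StructurePair
from glycodelta.synthetic_data import (
    GaussianNoise,
    SiteSpec,
    SyntheticSpec,
    attach_mock_glycan,
    delete_glycans,
    generate_toy_protein,
    perturb,
)


@pytest.fixture
def toy_glycoprotein():
    """60-residue helix with a 2-sugar glycan on Asn-20 (sequon satisfied)."""
    spec = SyntheticSpec(n_residues=60, geometry="helix",
                         sites=[SiteSpec(residue=20, n_sugars=2)], seed=42)
    model = generate_toy_protein(spec)
    attach_mock_glycan(model, 20, 2)
    classify_saccharides(model)
    return model


def make_pair(gp_model, noise_sigma=0.0, seed=0, perturbation=None):
    """GP/P StructurePair from a glycosylated model and a perturbed copy."""
    gp_model = copy.deepcopy(gp_model)
    classify_saccharides(gp_model)
    sites = detect_sites(gp_model)
    if perturbation is not None:
        p_model = perturb(gp_model, perturbation, seed=seed)
    elif noise_sigma > 0:
        p_model = perturb(gp_model, GaussianNoise(noise_sigma), seed=seed)
    else:
        p_model = copy.deepcopy(gp_model)
    delete_glycans(p_model)
    chain_a = gp_model.chains[0]
    chain_b = p_model.chains[0]
    rec_a = ChainRecord(entry_id="GPX", chain_id=chain_a.chain_id,
                        sequence=chain_a.sequence, glycosylated=True,
                        sites=sites, chain=chain_a)
    rec_b = ChainRecord(entry_id="PX", chain_id=chain_b.chain_id,
                        sequence=chain_b.sequence, glycosylated=False,
                        chain=chain_b)
    return StructurePair(rec_a, rec_b, PairClass.GP_P), sites


@pytest.fixture
def gp_p_pair(toy_glycoprotein):
    """Noise-perturbed GP/P pair plus its glycosylation sites."""
    return make_pair(toy_glycoprotein, noise_sigma=0.3, seed=7)


def random_rigid_transform(rng):
    """A uniformly random proper rotation and a translation."""
    from scipy.spatial.transform import Rotation
    rot = Rotation.random(rng=rng).as_matrix()
    trans = rng.uniform(-20, 20, 3)
    return rot, trans


def apply_rigid_to_model(model, rot, trans):
    out = copy.deepcopy(model)
    for _, _, atom in out.atoms():
        atom.xyz = rot @ atom.xyz + trans
    return out
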