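import pytest
from rdkit import Chem

from bbbfp import dockparse as dp
from bbbfp import fixtures as fx


@pytest.fixture
def complex_on_disk(tmp_path):
    """Factory: build a toy complex, write it, parse it back.

    Returns (receptor, ligand_mol, truth, paths) for a given ComplexSpec.
    """

    def build(spec: fx.ComplexSpec):
        pdb_text, sdf_text, truth = fx.make_toy_complex(spec)
        rp = tmp_path / f"receptor_{spec.seed}_{len(spec.interaction_types)}.pdb"
        sp = tmp_path / f"pose_{spec.seed}_{len(spec.interaction_types)}.sdf"
        rp.write_text(pdb_text)
        sp.write_text(sdf_text)
        receptor = dp.read_receptor(rp)
        mol = next(
            m for m in Chem.SDMolSupplier(str(sp), removeHs=False) if m is not None
        )
        return receptor, mol, truth, (rp, sp)

    return build


@pytest.fixture(scope="session")
def library200():
    """Planted-signal labeled library: n=200, noise 0, fixed seed."""
    records, truth = fx.make_labeled_library(fx.LibrarySpec(n=200, noise_rate=0.0, seed=42))
    return records, truth
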