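"""Ca distance between two residues in a real PDB entry.

Usage:

    python examples/real_structure_distance.py 1ook.pdb B 60 166

Measures the Ca-Ca distance between two residues of one chain — e.g.
between a glycosylated Asn and the residue showing the largest RMSF
change upon deglycosylation, to quantify how far the dynamic effect of
a glycan propagates.  For entry 1OOK chain B, residues Asn-60 and
Pro-166 are 33.7 A apart.

Needs a locally downloaded PDB file (this repository ships no
third-party data).
"""

import sys

import numpy as np

from glycodelta import parse_structure


def ca_distance(pdb_path: str, chain_id: str, res_a: int, res_b: int) -> float:
    model = parse_structure(pdb_path)
    chain = model.chain(chain_id)
    if chain is None:
        raise SystemExit(f"chain {chain_id!r} not found in {pdb_path}")
    atoms = []
    for number in (res_a, res_b):
        res = chain.residue(number)
        if res is None or res.atom("CA") is None:
            raise SystemExit(f"residue {number} missing (or lacks Ca)")
        atoms.append(res.atom("CA").xyz)
    return float(np.linalg.norm(atoms[0] - atoms[1]))


if __name__ == "__main__":
    if len(sys.argv) != 5:
        raise SystemExit(__doc__)
    path, chain_id, a, b = sys.argv[1:]
    d = ca_distance(path, chain_id, int(a), int(b))
    print(f"Ca distance {chain_id}:{a} <-> {chain_id}:{b} = {d:.1f} A")
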