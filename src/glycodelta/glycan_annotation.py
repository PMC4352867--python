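"""Saccharide classification and glycosylation-site detection.

N-linked glycans are attached to the side-chain nitrogen (ND2) of an
asparagine within the consensus sequon Asn-X-Ser/Thr (X != Pro); O-linked
glycans attach to the side-chain oxygen of serine (OG) or threonine (OG1).
Detection here is purely geometric/topological: a residue is a saccharide
when its three-letter code is in a configurable vocabulary of carbohydrate
component codes, and an attachment is a covalent-range contact (or an
explicit CONECT hint) between the attachment atom and a sugar carbon.

Glycan size is counted per saccharide residue by walking the inter-sugar
bond graph from the root sugar (connected-component search).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

import numpy as np

from .structure_io import (
    Atom,
    ChainModel,
    Residue,
    ResidueKind,
    StructureModel,
)

__all__ = [
    "SACCHARIDE_VOCAB",
    "LinkClass",
    "GlycosylationSite",
    "HBond",
    "classify_saccharides",
    "detect_sites",
    "validate_sequon",
    "detect_protein_glycan_hbonds",
    "glycan_tree_residues",
]

#: Default vocabulary of PDB chemical-component codes treated as sugars.
#: Covers the common N-/O-glycan monosaccharides (GlcNAc, mannose,
#: galactose, glucose, fucose, sialic acid, xylose, GalNAc and anomers).
SACCHARIDE_VOCAB = frozenset({
    "NAG", "NDG", "BMA", "MAN", "GAL", "GLA", "GLC", "BGC",
    "FUC", "FUL", "SIA", "NAN", "SLB", "XYS", "XYP", "A2G", "NGA",
    "RIB", "ARA", "RAM", "GCU", "IDS", "BDP",
})

#: Distance treated as a covalent bond between an attachment heteroatom
#: (N/O) and a sugar carbon: covers C-N/C-O bond lengths (~1.43-1.45 A)
#: with crystallographic tolerance while excluding nonbonded contacts.
COVALENT_CUTOFF = 1.9

#: Heavy-atom distance cutoff for a protein-glycan hydrogen bond.
HBOND_CUTOFF = 3.5


class LinkClass(str, Enum):
    N_LINKED = "N_linked"
    O_LINKED = "O_linked"


_ATTACHMENT_ATOMS = {
    ("ASN", "ND2"): LinkClass.N_LINKED,
    ("SER", "OG"): LinkClass.O_LINKED,
    ("THR", "OG1"): LinkClass.O_LINKED,
}


@dataclass
class GlycosylationSite:
    """A covalent protein-glycan attachment point."""

    chain_id: str
    residue_number: int
    icode: str = ""
    attachment_atom: str = "ND2"
    link_class: LinkClass = LinkClass.N_LINKED
    glycan_residue_count: int = 1
    root_saccharide: tuple[str, int, str] = ("", 0, "")  # (chain, number, icode)
    sequon_ok: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.glycan_residue_count < 1:
            raise ValueError("glycan_residue_count must be >= 1")
        n_linked = self.attachment_atom == "ND2"
        if n_linked != (self.link_class is LinkClass.N_LINKED):
            raise ValueError("link class inconsistent with attachment atom")


@dataclass
class HBond:
    donor: tuple[str, int, str, str]     # chain, resnum, icode, atom name
    acceptor: tuple[str, int, str, str]
    distance: float


def classify_saccharides(model: StructureModel,
                         vocab: Optional[Iterable[str]] = None) -> StructureModel:
    """Mark residues whose code is in the saccharide vocabulary.

    Recognition is name-based only: a sugar-shaped residue under an
    unknown code is deliberately not detected.  Returns the same model
    with residue kinds updated.
    """
    vocab = frozenset(vocab) if vocab is not None else SACCHARIDE_VOCAB
    for chain in model.chains:
        for res in chain.residues:
            if res.name in vocab:
                res.kind = ResidueKind.SACCHARIDE
    return model


def _saccharide_residues(model: StructureModel) -> list[tuple[ChainModel, Residue]]:
    return [(c, r) for c in model.chains for r in c.residues
            if r.kind is ResidueKind.SACCHARIDE]


def _conect_pairs_between(model: StructureModel, res_a: Residue, res_b: Residue) -> bool:
    serials_a = {a.serial for a in res_a.atoms}
    serials_b = {a.serial for a in res_b.atoms}
    for pair in model.conect:
        p = tuple(pair)
        if len(p) == 2 and ((p[0] in serials_a and p[1] in serials_b)
                            or (p[1] in serials_a and p[0] in serials_b)):
            return True
    return False


def _min_dist(atoms_a: list[Atom], atoms_b: list[Atom]) -> float:
    if not atoms_a or not atoms_b:
        return np.inf
    xa = np.array([a.xyz for a in atoms_a])
    xb = np.array([b.xyz for b in atoms_b])
    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=-1)
    return float(d.min())


def _sugar_bond_graph(model: StructureModel, cutoff: float) -> dict[int, set[int]]:
    """Adjacency over saccharide residues: O-C contact <= cutoff or CONECT."""
    sugars = _saccharide_residues(model)
    adj: dict[int, set[int]] = {i: set() for i in range(len(sugars))}
    for i in range(len(sugars)):
        for j in range(i + 1, len(sugars)):
            _, ri = sugars[i]
            _, rj = sugars[j]
            o_i = [a for a in ri.atoms if a.element == "O"]
            c_i = [a for a in ri.atoms if a.element == "C"]
            o_j = [a for a in rj.atoms if a.element == "O"]
            c_j = [a for a in rj.atoms if a.element == "C"]
            bonded = (min(_min_dist(o_i, c_j), _min_dist(c_i, o_j)) <= cutoff
                      or _conect_pairs_between(model, ri, rj))
            if bonded:
                adj[i].add(j)
                adj[j].add(i)
    return adj


def glycan_tree_residues(model: StructureModel, site: "GlycosylationSite",
                         cutoff: float = COVALENT_CUTOFF) -> list[tuple[ChainModel, Residue]]:
    """All saccharide residues reachable from the site's root sugar."""
    sugars = _saccharide_residues(model)
    index = {(c.chain_id, r.number, r.icode): i for i, (c, r) in enumerate(sugars)}
    root = index.get(site.root_saccharide)
    if root is None:
        return []
    adj = _sugar_bond_graph(model, cutoff)
    seen = {root}
    stack = [root]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return [sugars[i] for i in sorted(seen)]


def detect_sites(model: StructureModel,
                 bond_cutoff: float = COVALENT_CUTOFF) -> list[GlycosylationSite]:
    """Find covalent glycosylation sites in a classified model.

    A site is reported when an Asn ND2 / Ser OG / Thr OG1 atom lies within
    ``bond_cutoff`` of a saccharide carbon (anomeric C1 preferred) or a
    CONECT record links the two residues.  Each site's
    ``glycan_residue_count`` is the size of the sugar connected component
    rooted at the attached saccharide.  Sites violating the N-sequon are
    reported with ``sequon_ok=False``, not dropped.
    """
    sugars = _saccharide_residues(model)
    if not sugars:
        return []
    sites: list[GlycosylationSite] = []
    for chain in model.chains:
        for res in chain.residues:
            if res.kind is not ResidueKind.AMINO_ACID:
                continue
            for (resname, atom_name), link_class in _ATTACHMENT_ATOMS.items():
                if res.name != resname:
                    continue
                att = res.atom(atom_name)
                if att is None:
                    continue
                root = None
                best_d = np.inf
                for sc, sres in sugars:
                    c1 = sres.atom("C1")
                    candidates = [c1] if c1 is not None else [
                        a for a in sres.atoms if a.element == "C"]
                    d = _min_dist([att], [a for a in candidates if a is not None])
                    linked = d <= bond_cutoff or _conect_pairs_between(model, res, sres)
                    if linked and d < best_d:
                        best_d = d
                        root = (sc, sres)
                if root is None:
                    continue
                site = GlycosylationSite(
                    chain_id=chain.chain_id,
                    residue_number=res.number,
                    icode=res.icode,
                    attachment_atom=atom_name,
                    link_class=link_class,
                    glycan_residue_count=1,
                    root_saccharide=(root[0].chain_id, root[1].number, root[1].icode),
                )
                site.glycan_residue_count = len(
                    glycan_tree_residues(model, site, cutoff=bond_cutoff))
                if link_class is LinkClass.N_LINKED:
                    site.sequon_ok = validate_sequon(chain, site)
                sites.append(site)
    return sites


def validate_sequon(chain: ChainModel, site: GlycosylationSite) -> bool:
    """Check the N-glycosylation consensus sequon Asn-X-Ser/Thr, X != Pro.

    Positions are taken along the chain's amino-acid residues; a site too
    close to the C-terminus to have an i+2 residue fails the check rather
    than raising.
    """
    if site.link_class is not LinkClass.N_LINKED:
        raise ValueError("sequon validation applies to N-linked sites")
    aa = chain.amino_acid_residues()
    idx = next((i for i, r in enumerate(aa)
                if r.number == site.residue_number and r.icode == site.icode), None)
    if idx is None:
        raise ValueError(
            f"site residue {site.residue_number}{site.icode} not in chain {chain.chain_id}")
    seq = "".join(r.one_letter for r in aa)
    if seq[idx] != "N":
        return False
    if idx + 2 >= len(seq):
        return False
    return seq[idx + 1] != "P" and seq[idx + 2] in ("S", "T")


def detect_protein_glycan_hbonds(model: StructureModel, site: GlycosylationSite,
                                 cutoff: float = HBOND_CUTOFF) -> list[HBond]:
    """Protein-glycan hydrogen bonds by a heavy-atom distance criterion.

    Donor/acceptor candidates are N and O atoms; a bond is reported when
    one atom belongs to the protein, the other to the site's glycan tree,
    and their distance is <= ``cutoff`` (no angular term).  The covalent
    attachment itself (N/O to sugar carbon) never qualifies since carbon
    is not polar.
    """
    tree = glycan_tree_residues(model, site)
    glycan_polar = [(c, r, a) for c, r in tree for a in r.atoms
                    if a.element in ("N", "O")]
    protein_polar = [(c, r, a) for c in model.chains for r in c.residues
                     if r.kind is ResidueKind.AMINO_ACID
                     for a in r.atoms if a.element in ("N", "O")]
    bonds = []
    for pc, pr, pa in protein_polar:
        for gc, gr, ga in glycan_polar:
            d = float(np.linalg.norm(pa.xyz - ga.xyz))
            if d <= cutoff:
                bonds.append(HBond(
                    donor=(pc.chain_id, pr.number, pr.icode, pa.name),
                    acceptor=(gc.chain_id, gr.number, gr.icode, ga.name),
                    distance=d,
                ))
    return bonds
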