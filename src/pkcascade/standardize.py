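"""SMILES standardization and pH-7.4 protonation.

The standardization chain is: sanitize → normalize → largest fragment →
canonical tautomer → protonation-state assignment at pH 7.4 → canonical
SMILES. The whole chain is idempotent: standardizing its own output returns
the same string.

Protonation uses a small rule table of SMARTS patterns for the ionizable
groups that dominate drug-like chemistry, each with a reference pKa. A group
is (de)protonated when pH 7.4 is more than ~1 unit past its pKa, i.e. when
the charged microstate is >90% populated; borderline groups (imidazole,
anilines, amides, phenols) stay neutral. Rules are mutually exclusive after
application, which is what makes the chain idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from rdkit import Chem, RDLogger
from rdkit.Chem.Descriptors import ExactMolWt
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed or standardized."""

    def __init__(self, smiles: str, reason: str = "unparsable SMILES"):
        self.smiles = smiles
        super().__init__(f"{reason}: {smiles!r}")


@dataclass(frozen=True)
class _ProtonationRule:
    name: str
    smarts: str
    charge: int           # formal charge to assign to the matched atom
    pka: float            # reference pKa, documentation only
    max_sites: int = 99   # how many matches to transform per molecule


# Atom 0 of each SMARTS is the atom transformed. Patterns are written so a
# transformed site no longer matches (carboxylate has no O-H; ammonium is
# not trivalent N), guaranteeing idempotence.
_RULES = [
    # acids deprotonated at pH 7.4 (pKa well below 6.4)
    _ProtonationRule("carboxylic acid", "[OX2H1][CX3]=[OX1]", -1, 4.2),
    _ProtonationRule("sulfonic acid", "[OX2H1][SX4](=[OX1])=[OX1]", -1, -1.5),
    _ProtonationRule("sulfinic acid", "[OX2H1][SX3]=[OX1]", -1, 2.0),
    # phosphates/phosphonates: first proton only (pKa1 ~2, pKa2 ~7 is borderline)
    _ProtonationRule("phosphorus acid", "[OX2H1][PX4](=[OX1])", -1, 2.1, max_sites=1),
    _ProtonationRule("tetrazole", "[nX3H1;$(n1nnnc1),$(n1nncn1)]", -1, 4.9),
    # bases protonated at pH 7.4 (pKa well above 8.4): aliphatic amines not
    # adjacent to carbonyl/sulfonyl/aromatic systems, and amidine/guanidine C=N
    _ProtonationRule(
        "aliphatic amine",
        "[NX3;H2,H1,H0;+0;!$(N=*);!$(N-[#6]=[O,N,S]);!$(N-[a]);!$(N-[SX4]);"
        "!$(N-[NX3]);!$(N-[OX2]);$(N-[CX4])]",
        +1,
        10.0,
    ),
    _ProtonationRule("amidine/guanidine", "[NX2;H1,H0;+0]=[CX3]([NX3;+0])[NX3,CX4,#1;+0]", +1, 12.0),
]

_COMPILED = [(r, Chem.MolFromSmarts(r.smarts)) for r in _RULES]


def protonate_ph74(mol: Chem.Mol) -> Chem.Mol:
    """Assign formal charges matching the dominant microstate at pH 7.4."""
    rw = Chem.RWMol(mol)
    for rule, patt in _COMPILED:
        matches = rw.GetMol().GetSubstructMatches(patt)
        hit_atoms = []
        for match in matches:
            if len(hit_atoms) >= rule.max_sites:
                break
            idx = match[0]
            if idx in hit_atoms:
                continue
            atom = rw.GetAtomWithIdx(idx)
            if atom.GetFormalCharge() != 0:
                continue
            if rule.charge == -1:
                if atom.GetTotalNumHs() < 1:
                    continue
                atom.SetFormalCharge(-1)
                atom.SetNumExplicitHs(max(atom.GetTotalNumHs() - 1, 0))
                atom.SetNoImplicit(True)
            else:
                atom.SetFormalCharge(+1)
                atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
                atom.SetNoImplicit(True)
            hit_atoms.append(idx)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


_normalizer = rdMolStandardize.Normalizer()
_fragment_chooser = rdMolStandardize.LargestFragmentChooser()
_tautomer_enumerator = rdMolStandardize.TautomerEnumerator()


def standardize_mol(raw_smiles: str) -> Chem.Mol:
    """Run the full standardization chain, returning an RDKit Mol."""
    if not raw_smiles or not raw_smiles.strip():
        raise SmilesParseError(raw_smiles, "empty SMILES")
    mol = Chem.MolFromSmiles(raw_smiles)
    if mol is None:
        raise SmilesParseError(raw_smiles)
    try:
        mol = rdMolStandardize.Cleanup(mol)
        mol = _normalizer.normalize(mol)
        mol = _fragment_chooser.choose(mol)
        # neutralize before tautomer canonicalization so the canonical
        # tautomer is chosen on the neutral parent
        mol = rdMolStandardize.Uncharger().uncharge(mol)
        mol = _tautomer_enumerator.Canonicalize(mol)
        mol = protonate_ph74(mol)
    except SmilesParseError:
        raise
    except Exception as exc:  # pragma: no cover - RDKit failure modes vary
        raise SmilesParseError(raw_smiles, f"standardization failed ({exc})") from exc
    if mol is None or mol.GetNumAtoms() == 0:
        raise SmilesParseError(raw_smiles, "standardization produced an empty molecule")
    return mol


def standardize_smiles(raw_smiles: str, pH: float = 7.4) -> str:
    """Canonical standardized SMILES of the largest fragment at pH 7.4.

    Idempotent: ``standardize_smiles(standardize_smiles(s)) ==
    standardize_smiles(s)``. Raises :class:`SmilesParseError` on unparsable
    input.
    """
    if pH != 7.4:
        raise NotImplementedError("only the pH 7.4 rule table is implemented")
    return Chem.MolToSmiles(standardize_mol(raw_smiles))


def exact_mol_weight(std_smiles: str) -> float:
    mol = Chem.MolFromSmiles(std_smiles)
    if mol is None:
        raise SmilesParseError(std_smiles)
    return float(ExactMolWt(mol))
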