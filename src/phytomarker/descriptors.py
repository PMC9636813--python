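"""Optional adapter filling descriptor records from SMILES via RDKit.

Kept separate from the rule engine so the latter stays testable with
hand-written records and usable without a cheminformatics toolkit.
RDKit provides the Wildman-Crippen logP (WLOGP); the Moriguchi and XLOGP3
estimators are not available, so those fields stay unset and the rule
engine's documented fallback (WLOGP) applies. ``estimator_notes`` records
which estimator filled each logP field.
"""

from __future__ import annotations

from .druglikeness import DescriptorRecord
from .errors import ConfigError


def descriptors_from_smiles(smiles: str, compound_id: str
                            ) -> tuple[DescriptorRecord, dict[str, str]]:
    """Compute the rule-input descriptors for one molecule."""
    try:
        from rdkit import Chem
        from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors
    except ImportError as exc:  # pragma: no cover - rdkit is an extra
        raise ImportError(
            "descriptor computation needs the 'chem' extra (rdkit)") from exc
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ConfigError(f"unparseable SMILES for {compound_id!r}: {smiles!r}")
    record = DescriptorRecord(
        compound_id=compound_id,
        mw=float(Descriptors.MolWt(mol)),
        logp_wlogp=float(Crippen.MolLogP(mol)),
        tpsa=float(rdMolDescriptors.CalcTPSA(mol)),
        hbd=int(Lipinski.NumHDonors(mol)),
        hba=int(Lipinski.NumHAcceptors(mol)),
        rotatable_bonds=int(Lipinski.NumRotatableBonds(mol)),
        molar_refractivity=float(Crippen.MolMR(mol)),
        heavy_atoms=int(mol.GetNumHeavyAtoms()),
        rings=int(rdMolDescriptors.CalcNumRings(mol)),
        carbons=sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "C"),
        heteroatoms=sum(1 for a in mol.GetAtoms()
                        if a.GetSymbol() not in ("C", "H")),
    )
    notes = {"logp_wlogp": "wildman-crippen (rdkit Crippen.MolLogP)",
             "logp_mlogp": "unavailable; rules fall back to wlogp",
             "logp_xlogp": "unavailable; rules fall back to wlogp"}
    return record, notes
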