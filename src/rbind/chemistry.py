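"""Residue chemistry dictionaries used by hydrogen-bond detection.

Donor/acceptor assignments follow the standard hydrogen-bonding chemistry of
the 20 amino acids and 4 ribonucleotides.  On the RNA side the sugar hydroxyls
O2' and O3' are treated as potential donors, and the phosphate/sugar oxygens
OP1, OP2, O2', O3', O4' and O5' as potential acceptors, in addition to the
usual nucleobase sites.  Each acceptor carries one covalently bonded heavy
atom (its "antecedent"), required for the H-A-AA angle criterion.
"""

from __future__ import annotations

# 3-letter -> 1-letter amino acid codes (standard 20 only; anything else is
# typed as a non-polymer / modified residue and excluded downstream).
AA3_TO_1: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

# RNA residue names as deposited (current and legacy spellings).
RNA_NAMES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "RA": "A", "RC": "C", "RG": "G", "RU": "U",
    "ADE": "A", "CYT": "C", "GUA": "G", "URA": "U",
}

NUCLEOTIDES: str = "ACGU"

# Legacy PDB atom-name spellings -> current ones (primes and phosphate oxygens).
ATOM_ALIASES: dict[str, str] = {
    "O1P": "OP1", "O2P": "OP2", "O3P": "OP3",
}


def canonical_atom_name(name: str) -> str:
    """Map legacy RNA atom spellings (O2*, O1P, ...) onto current names."""
    name = name.strip().replace("*", "'")
    return ATOM_ALIASES.get(name, name)


# ---------------------------------------------------------------------------
# Protein donors/acceptors.  Maps 1-letter code -> {atom: antecedent}.
# The backbone amide N (donor) and carbonyl O (acceptor) are common to every
# residue; proline's backbone N carries no hydrogen and is excluded.

PROTEIN_BACKBONE_DONOR = {"N": "CA"}
PROTEIN_BACKBONE_ACCEPTOR = {"O": "C"}

PROTEIN_SIDECHAIN_DONORS: dict[str, dict[str, str]] = {
    "R": {"NE": "CZ", "NH1": "CZ", "NH2": "CZ"},
    "N": {"ND2": "CG"},
    "Q": {"NE2": "CD"},
    "H": {"ND1": "CG", "NE2": "CD2"},
    "K": {"NZ": "CE"},
    "S": {"OG": "CB"},
    "T": {"OG1": "CB"},
    "W": {"NE1": "CD1"},
    "Y": {"OH": "CZ"},
    "C": {"SG": "CB"},
}

PROTEIN_SIDECHAIN_ACCEPTORS: dict[str, dict[str, str]] = {
    "D": {"OD1": "CG", "OD2": "CG"},
    "E": {"OE1": "CD", "OE2": "CD"},
    "N": {"OD1": "CG"},
    "Q": {"OE1": "CD"},
    "H": {"ND1": "CG", "NE2": "CD2"},
    "S": {"OG": "CB"},
    "T": {"OG1": "CB"},
    "Y": {"OH": "CZ"},
}

# ---------------------------------------------------------------------------
# RNA donors/acceptors.  Sugar and phosphate sites are shared by all four
# nucleotides; base sites depend on the nucleotide.

RNA_SUGAR_DONORS = {"O2'": "C2'", "O3'": "C3'"}
RNA_BACKBONE_ACCEPTORS = {
    "OP1": "P", "OP2": "P",
    "O2'": "C2'", "O3'": "C3'", "O4'": "C4'", "O5'": "C5'",
}

RNA_BASE_DONORS: dict[str, dict[str, str]] = {
    "A": {"N6": "C6"},
    "G": {"N1": "C6", "N2": "C2"},
    "C": {"N4": "C4"},
    "U": {"N3": "C2"},
}

RNA_BASE_ACCEPTORS: dict[str, dict[str, str]] = {
    "A": {"N1": "C6", "N3": "C2", "N7": "C5"},
    "G": {"O6": "C6", "N3": "C2", "N7": "C5"},
    "C": {"O2": "C2", "N3": "C2"},
    "U": {"O2": "C2", "O4": "C4"},
}


def protein_donor_map(one_letter: str) -> dict[str, str]:
    """Donor atoms {name: antecedent} for one amino acid type."""
    sites = {} if one_letter == "P" else dict(PROTEIN_BACKBONE_DONOR)
    sites.update(PROTEIN_SIDECHAIN_DONORS.get(one_letter, {}))
    return sites


def protein_acceptor_map(one_letter: str) -> dict[str, str]:
    sites = dict(PROTEIN_BACKBONE_ACCEPTOR)
    sites.update(PROTEIN_SIDECHAIN_ACCEPTORS.get(one_letter, {}))
    return sites


def rna_donor_map(nucleotide: str) -> dict[str, str]:
    sites = dict(RNA_SUGAR_DONORS)
    sites.update(RNA_BASE_DONORS.get(nucleotide, {}))
    return sites


def rna_acceptor_map(nucleotide: str) -> dict[str, str]:
    sites = dict(RNA_BACKBONE_ACCEPTORS)
    sites.update(RNA_BASE_ACCEPTORS.get(nucleotide, {}))
    return sites
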