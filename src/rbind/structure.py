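"""Parsing of protein-RNA complex structures and hydrogen-bond detection.

A residue of the protein chain is annotated as RNA-binding when it makes at
least one hydrogen bond with the partner RNA chain under four geometric
criteria, all strict: donor-acceptor distance < 3.9 A, hydrogen-acceptor
distance < 2.5 A, donor-hydrogen-acceptor angle > 90 deg, and
hydrogen-acceptor-acceptor-antecedent angle > 90 deg.

X-ray structures usually lack hydrogen positions.  Two placement modes are
supported: ``explicit`` uses deposited hydrogens (error when absent), and
``toward_acceptor`` places H at 1.0 A from the donor toward the candidate
acceptor, which makes the D-H-A angle 180 deg and therefore vacuous.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import chemistry

__all__ = [
    "Atom", "Residue", "Structure", "HBondCriteria", "HBond",
    "InteractionPair", "PDBParseError", "parse_pdb", "donor_acceptor_sites",
    "place_hydrogen", "detect_hbonds", "label_binding",
    "write_hbonds_tsv", "write_labels_tsv", "write_pairs_json", "read_pairs_json",
]

H_COVALENT_MAX = 1.3  # A; a deposited H within this distance of a donor heavy
                      # atom is taken as covalently bonded to it


class PDBParseError(ValueError):
    pass


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if not np.all(np.isfinite(self.coords)) or self.coords.shape != (3,):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")


@dataclass
class Residue:
    chain_id: str
    number: int
    icode: str
    name: str          # 3-letter amino acid or 1-letter nucleotide code
    polymer: str       # "protein" | "rna" | "other"
    atoms: list[Atom] = field(default_factory=list)

    @property
    def code(self) -> str:
        """One-letter code: amino acid, nucleotide, or sentinel X/N."""
        if self.polymer == "protein":
            return chemistry.AA3_TO_1.get(self.name, "X")
        if self.polymer == "rna":
            return chemistry.RNA_NAMES.get(self.name, "N")
        return "X"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Structure:
    id: str
    chains: list[tuple[str, list[Residue]]]

    def chain(self, chain_id: str) -> list[Residue]:
        for cid, residues in self.chains:
            if cid == chain_id:
                return residues
        raise KeyError(f"chain {chain_id!r} not found in structure {self.id!r}")

    @property
    def chain_ids(self) -> list[str]:
        return [cid for cid, _ in self.chains]


@dataclass(frozen=True)
class HBondCriteria:
    """Thresholds of the four geometric criteria, applied as strict inequalities."""
    d_da_max: float = 3.9     # A
    d_ha_max: float = 2.5     # A
    ang_dha_min: float = 90.0  # degrees, at H
    ang_haaa_min: float = 90.0  # degrees, at A

    def __post_init__(self) -> None:
        if self.d_da_max <= 0 or self.d_ha_max <= 0:
            raise ValueError("distance thresholds must be positive")
        for ang in (self.ang_dha_min, self.ang_haaa_min):
            if not 0 < ang < 180:
                raise ValueError("angle thresholds must lie in (0, 180)")


@dataclass
class HBond:
    donor: Atom
    donor_residue: Residue
    hydrogen: np.ndarray
    acceptor: Atom
    acceptor_residue: Residue
    antecedent: Atom
    d_da: float
    d_ha: float
    ang_dha: float
    ang_haaa: float
    d_proj: float


@dataclass
class InteractionPair:
    """One protein sequence paired with one RNA sequence plus binding labels.

    ``labels[i]`` is +1 when protein residue i (0-based here, 1-based in the
    ``contacts`` records) hydrogen-bonds the RNA, else -1.  Each contact is
    ``(residue_index_1based, nucleotide, d_proj)``.
    """
    pair_id: str
    protein_seq: str
    rna_seq: str
    labels: list[int]
    contacts: list[tuple[int, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.protein_seq):
            raise ValueError("labels and protein sequence lengths differ")
        for i, b, d in self.contacts:
            if not 1 <= i <= len(self.protein_seq):
                raise ValueError(f"contact residue index {i} out of range")
            if b not in chemistry.NUCLEOTIDES:
                raise ValueError(f"contact nucleotide {b!r} not in ACGU")
            if d <= 0:
                raise ValueError("contact d_proj must be positive")
        bound = {i for i, _, _ in self.contacts}
        for i, lab in enumerate(self.labels, start=1):
            if (lab == 1) != (i in bound):
                raise ValueError(f"label/contact mismatch at residue {i}")


# ---------------------------------------------------------------------------
# PDB parsing

def _polymer_type(resname: str) -> str:
    if resname in chemistry.AA3_TO_1:
        return "protein"
    if resname in chemistry.RNA_NAMES:
        return "rna"
    return "other"


def parse_pdb(pdb_text: str, structure_id: str = "structure") -> Structure:
    """Parse fixed-column PDB text (ATOM/HETATM records, model 1 only).

    Alternate locations keep the highest-occupancy conformer; on ties altloc
    'A' wins, then first occurrence.  Legacy RNA atom names (O2*, O1P) are
    canonicalised.
    """
    if not pdb_text.strip():
        raise PDBParseError("empty PDB input")

    # (chain, resseq, icode) -> resname, {atom name -> list of Atom}
    order: list[tuple[str, int, str]] = []
    resnames: dict[tuple[str, int, str], str] = {}
    atoms: dict[tuple[str, int, str], dict[str, list[Atom]]] = {}

    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "ENDMDL":
            break  # only model 1
        if rec not in ("ATOM", "HETATM"):
            continue
        try:
            name = chemistry.canonical_atom_name(line[12:16])
            altloc = line[16].strip()
            resname = line[17:20].strip()
            chain_id = line[21].strip() or " "
            resseq = int(line[22:26])
            icode = line[26].strip()
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            occ_field = line[54:60].strip()
            occupancy = float(occ_field) if occ_field else 1.0
            element = line[76:78].strip() if len(line) >= 78 else ""
        except (ValueError, IndexError) as exc:
            raise PDBParseError(f"malformed PDB record at line {lineno}: {exc}") from exc
        if not element:
            # fall back on the atom-name convention: first alphabetic character
            stripped = name.lstrip("0123456789")
            element = stripped[:1].upper()
        key = (chain_id, resseq, icode)
        if key not in atoms:
            order.append(key)
            resnames[key] = resname
            atoms[key] = {}
        atoms[key].setdefault(name, []).append(
            Atom(name=name, element=element, coords=(x, y, z),
                 altloc=altloc, occupancy=occupancy))

    if not order:
        raise PDBParseError("no ATOM/HETATM records found")

    def pick_altloc(candidates: list[Atom]) -> Atom:
        if len(candidates) == 1:
            return candidates[0]
        best_occ = max(a.occupancy for a in candidates)
        tied = [a for a in candidates if a.occupancy == best_occ]
        for a in tied:
            if a.altloc == "A":
                return a
        return tied[0]

    chains: dict[str, list[Residue]] = {}
    chain_order: list[str] = []
    for key in order:
        chain_id, resseq, icode = key
        resname = resnames[key]
        residue = Residue(
            chain_id=chain_id, number=resseq, icode=icode, name=resname,
            polymer=_polymer_type(resname),
            atoms=[pick_altloc(group) for group in atoms[key].values()])
        if chain_id not in chains:
            chains[chain_id] = []
            chain_order.append(chain_id)
        chains[chain_id].append(residue)

    for cid in chain_order:
        chains[cid].sort(key=lambda r: (r.number, r.icode))
    return Structure(id=structure_id, chains=[(cid, chains[cid]) for cid in chain_order])


# ---------------------------------------------------------------------------
# Donor / acceptor site enumeration

def donor_acceptor_sites(residue: Residue) -> tuple[list[tuple[Atom, Atom | None]],
                                                    list[tuple[Atom, Atom | None]]]:
    """Enumerate hydrogen-bond donor and acceptor sites of one residue.

    Returns ``(donors, acceptors)``, each a list of ``(atom, antecedent)``.
    Acceptors with a missing antecedent atom are dropped (the H-A-AA angle
    could not be measured); donors keep a ``None`` antecedent.
    """
    if residue.polymer == "protein":
        donor_map = chemistry.protein_donor_map(residue.code)
        acceptor_map = chemistry.protein_acceptor_map(residue.code)
        if residue.code == "X":
            warnings.warn(f"unknown protein residue {residue.name!r}: no donor/acceptor sites")
            return [], []
    elif residue.polymer == "rna":
        donor_map = chemistry.rna_donor_map(residue.code)
        acceptor_map = chemistry.rna_acceptor_map(residue.code)
        if residue.code == "N":
            warnings.warn(f"unknown RNA residue {residue.name!r}: no donor/acceptor sites")
            return [], []
    else:
        raise ValueError(f"residue {residue.name!r} is not a protein or RNA residue")

    donors = []
    for name, ante in donor_map.items():
        atom = residue.atom(name)
        if atom is not None:
            donors.append((atom, residue.atom(ante)))
    acceptors = []
    for name, ante in acceptor_map.items():
        atom = residue.atom(name)
        ante_atom = residue.atom(ante)
        if atom is not None and ante_atom is not None:
            acceptors.append((atom, ante_atom))
    return donors, acceptors


# ---------------------------------------------------------------------------
# Geometry helpers

def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    """Angle at ``vertex`` between rays to ``a`` and ``b``, in degrees."""
    u = a - vertex
    v = b - vertex
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("degenerate angle: coincident points")
    c = float(np.dot(u, v) / (nu * nv))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def place_hydrogen(donor: Atom, antecedent: Atom | None, acceptor: Atom,
                   mode: str = "toward_acceptor",
                   residue: Residue | None = None) -> np.ndarray:
    """Hydrogen position for a donor-acceptor candidate.

    ``explicit`` returns the deposited hydrogen bonded to the donor (closest
    to the acceptor if several); ``toward_acceptor`` constructs it at 1.0 A
    from the donor along the donor->acceptor direction.
    """
    if mode == "explicit":
        if residue is None:
            raise ValueError("explicit mode requires the donor's residue")
        hydrogens = _bonded_hydrogens(donor, residue)
        if not hydrogens:
            raise ValueError(
                f"no deposited hydrogen bonded to donor {donor.name}; "
                "use mode='toward_acceptor'")
        return min(hydrogens, key=lambda h: np.linalg.norm(h - acceptor.coords))
    if mode == "toward_acceptor":
        v = acceptor.coords - donor.coords
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError("donor and acceptor coincide")
        return donor.coords + v / norm
    raise ValueError(f"unknown hydrogen placement mode {mode!r}")


def _bonded_hydrogens(donor: Atom, residue: Residue) -> list[np.ndarray]:
    return [a.coords for a in residue.atoms
            if a.element == "H"
            and np.linalg.norm(a.coords - donor.coords) <= H_COVALENT_MAX]


def _evaluate_candidate(donor: Atom, donor_res: Residue, acceptor: Atom,
                        antecedent: Atom, acceptor_res: Residue,
                        criteria: HBondCriteria, mode: str) -> HBond | None:
    d_da = float(np.linalg.norm(donor.coords - acceptor.coords))
    if not d_da < criteria.d_da_max:
        return None
    if mode == "explicit":
        hydrogens = _bonded_hydrogens(donor, donor_res)
        if not hydrogens:
            return None
    else:
        hydrogens = [place_hydrogen(donor, None, acceptor, mode="toward_acceptor")]

    best: HBond | None = None
    for h in hydrogens:
        d_ha = float(np.linalg.norm(h - acceptor.coords))
        if not d_ha < criteria.d_ha_max:
            continue
        try:
            ang_dha = _angle_deg(donor.coords, h, acceptor.coords)
            ang_haaa = _angle_deg(h, acceptor.coords, antecedent.coords)
        except ValueError:
            continue
        if not (ang_dha > criteria.ang_dha_min and ang_haaa > criteria.ang_haaa_min):
            continue
        # projection of the H-A separation onto the D-A axis, via the D-A-H
        # angle at the acceptor; collinear D-H-A gives d_proj == d_ha
        try:
            ang_dah = _angle_deg(donor.coords, acceptor.coords, h)
        except ValueError:
            continue
        d_proj = d_ha * math.cos(math.radians(ang_dah))
        if best is None or d_ha < best.d_ha:
            best = HBond(donor=donor, donor_residue=donor_res, hydrogen=np.asarray(h),
                         acceptor=acceptor, acceptor_residue=acceptor_res,
                         antecedent=antecedent, d_da=d_da, d_ha=d_ha,
                         ang_dha=ang_dha, ang_haaa=ang_haaa, d_proj=d_proj)
    return best


def detect_hbonds(structure: Structure, protein_chain: str, rna_chain: str,
                  criteria: HBondCriteria | None = None,
                  mode: str = "toward_acceptor") -> list[HBond]:
    """Detect protein-RNA hydrogen bonds in both donor directions.

    Every donor-acceptor pairing (protein donor -> RNA acceptor and RNA donor
    -> protein acceptor) that satisfies all four strict criteria yields one
    bond.  Candidate pairs are pruned with a k-d tree on the D-A distance.
    """
    criteria = criteria or HBondCriteria()
    if mode not in ("explicit", "toward_acceptor"):
        raise ValueError(f"unknown hydrogen placement mode {mode!r}")
    prot_residues = [r for r in structure.chain(protein_chain) if r.polymer == "protein"]
    rna_residues = [r for r in structure.chain(rna_chain) if r.polymer == "rna"]

    def sites(residues: list[Residue]):
        donors, acceptors = [], []
        for res in residues:
            d, a = donor_acceptor_sites(res)
            donors.extend((atom, ante, res) for atom, ante in d)
            acceptors.extend((atom, ante, res) for atom, ante in a)
        return donors, acceptors

    prot_donors, prot_acceptors = sites(prot_residues)
    rna_donors, rna_acceptors = sites(rna_residues)

    bonds: list[HBond] = []
    for donors, acceptors in ((prot_donors, rna_acceptors),
                              (rna_donors, prot_acceptors)):
        if not donors or not acceptors:
            continue
        acc_tree = cKDTree(np.array([a.coords for a, _, _ in acceptors]))
        don_coords = np.array([d.coords for d, _, _ in donors])
        for di, ai_list in enumerate(
                acc_tree.query_ball_point(don_coords, criteria.d_da_max)):
            donor, _, donor_res = donors[di]
            for ai in sorted(ai_list):
                acceptor, antecedent, acceptor_res = acceptors[ai]
                bond = _evaluate_candidate(donor, donor_res, acceptor, antecedent,
                                           acceptor_res, criteria, mode)
                if bond is not None:
                    bonds.append(bond)
    return bonds


def label_binding(structure: Structure, protein_chain: str, rna_chain: str,
                  criteria: HBondCriteria | None = None,
                  mode: str = "toward_acceptor") -> InteractionPair:
    """Annotate each protein residue as RNA-binding (+1) or not (-1).

    A residue is binding when it participates in at least one detected
    hydrogen bond with the RNA chain, in either donor direction.  Modified
    (non-standard) residues are excluded from the sequence and the labels.
    """
    prot_residues = [r for r in structure.chain(protein_chain) if r.polymer == "protein"]
    rna_residues = [r for r in structure.chain(rna_chain) if r.polymer == "rna"]
    protein_seq = "".join(r.code for r in prot_residues)
    rna_seq = "".join(r.code for r in rna_residues)

    index_of = {id(r): i + 1 for i, r in enumerate(prot_residues)}
    bonds = detect_hbonds(structure, protein_chain, rna_chain, criteria, mode)

    contacts: list[tuple[int, str, float]] = []
    for bond in bonds:
        if bond.donor_residue.polymer == "protein":
            prot_res, rna_res = bond.donor_residue, bond.acceptor_residue
        else:
            prot_res, rna_res = bond.acceptor_residue, bond.donor_residue
        contacts.append((index_of[id(prot_res)], rna_res.code, bond.d_proj))

    bound = {i for i, _, _ in contacts}
    labels = [1 if i in bound else -1 for i in range(1, len(protein_seq) + 1)]
    return InteractionPair(
        pair_id=f"{structure.id}_{protein_chain}_{rna_chain}",
        protein_seq=protein_seq, rna_seq=rna_seq,
        labels=labels, contacts=contacts)


# ---------------------------------------------------------------------------
# Serialization

def write_pairs_json(pairs: list[InteractionPair], path) -> None:
    import json
    with open(path, "w") as fh:
        json.dump([{"pair_id": p.pair_id, "protein_seq": p.protein_seq,
                    "rna_seq": p.rna_seq, "labels": p.labels,
                    "contacts": [[i, b, round(d, 6)] for i, b, d in p.contacts]}
                   for p in pairs], fh)


def read_pairs_json(path) -> list[InteractionPair]:
    import json
    with open(path) as fh:
        raw = json.load(fh)
    return [InteractionPair(pair_id=r["pair_id"], protein_seq=r["protein_seq"],
                            rna_seq=r["rna_seq"], labels=list(r["labels"]),
                            contacts=[(int(i), b, float(d)) for i, b, d in r["contacts"]])
            for r in raw]


def write_hbonds_tsv(bonds: list[HBond], path) -> None:
    with open(path, "w") as fh:
        fh.write("donor_chain\tdonor_res\tdonor_atom\tacceptor_chain\tacceptor_res\t"
                 "acceptor_atom\td_DA\td_HA\tang_DHA\tang_HAAA\td_proj\n")
        for b in bonds:
            fh.write(f"{b.donor_residue.chain_id}\t{b.donor_residue.number}\t{b.donor.name}\t"
                     f"{b.acceptor_residue.chain_id}\t{b.acceptor_residue.number}\t"
                     f"{b.acceptor.name}\t{b.d_da:.3f}\t{b.d_ha:.3f}\t"
                     f"{b.ang_dha:.2f}\t{b.ang_haaa:.2f}\t{b.d_proj:.3f}\n")


def write_labels_tsv(pair: InteractionPair, path) -> None:
    with open(path, "w") as fh:
        fh.write("index\tresidue\tlabel\n")
        for i, (aa, lab) in enumerate(zip(pair.protein_seq, pair.labels), start=1):
            fh.write(f"{i}\t{aa}\t{lab:+d}\n")
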