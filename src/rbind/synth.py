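"""Synthetic protein-RNA complexes and interaction pairs with planted truth.

``synth_complex`` writes a fixed-column PDB text containing a backbone-only
protein chain and a minimal RNA chain (phosphate groups only), with each
requested hydrogen-bond geometry realized by direct trigonometric placement
of the donor, an explicit hydrogen, the acceptor (OP1) and its antecedent
(P).  Because the construction is analytic, the accept/reject outcome of
every planted bond under the four geometric criteria is known exactly and
the generator returns the expected binding-label vector alongside the text.

Residues are spaced 30 A apart so no unplanned donor-acceptor pairing can
fall under the distance thresholds.  A nucleotide hosts at most one planted
bond.  A residue may host up to two bonds, placed along orthogonal
directions so the hydrogen planted for one bond cannot satisfy the distance
criterion toward the other bond's acceptor; bonds made invalid through an
angle criterion get a residue to themselves, because an extra hydrogen on
the shared donor could otherwise rescue the geometry.

``synth_pairs`` generates sequence-level interaction pairs with contacts
drawn at a base rate optionally multiplied per enriched triplet, for
exercising the propensity statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chemistry import AMINO_ACIDS, NUCLEOTIDES
from .structure import HBondCriteria, InteractionPair

__all__ = ["PlantedBond", "ComplexSpec", "PairSpec", "synth_complex", "synth_pairs"]

# alphabet for synthetic protein chains; proline is left out because its
# backbone nitrogen carries no hydrogen and could not host a planted bond
_SYNTH_AAS = AMINO_ACIDS.replace("P", "")

_AA1_TO_3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

_SPACING = 30.0    # A between consecutive residues of either chain
_RNA_OFFSET = 200.0  # default x offset of unbound nucleotides
_R_DH = 1.0        # donor-hydrogen covalent length
_R_AAA = 1.4       # acceptor-antecedent covalent length


@dataclass(frozen=True)
class PlantedBond:
    residue_index: int      # 1-based protein residue
    nucleotide_index: int   # 1-based RNA nucleotide
    d_da: float             # requested donor-acceptor distance, A
    ang_dha: float = 180.0  # requested D-H-A angle at H, degrees
    ang_haaa: float = 130.0  # requested H-A-AA angle at A, degrees

    def geometry(self) -> tuple[float, float, float]:
        """(d_da, d_ha, ang_dha) realized by the analytic construction."""
        th = math.radians(self.ang_dha)
        d_ha = _R_DH * math.cos(th) + math.sqrt(
            self.d_da ** 2 - (_R_DH * math.sin(th)) ** 2)
        return self.d_da, d_ha, self.ang_dha

    def is_valid(self, criteria: HBondCriteria | None = None) -> bool:
        criteria = criteria or HBondCriteria()
        _, d_ha, _ = self.geometry()
        return (self.d_da < criteria.d_da_max and d_ha < criteria.d_ha_max
                and self.ang_dha > criteria.ang_dha_min
                and self.ang_haaa > criteria.ang_haaa_min)

    def angle_invalid(self, criteria: HBondCriteria | None = None) -> bool:
        criteria = criteria or HBondCriteria()
        return (self.ang_dha <= criteria.ang_dha_min
                or self.ang_haaa <= criteria.ang_haaa_min)


@dataclass(frozen=True)
class ComplexSpec:
    seed: int
    n_protein_residues: int
    n_rna_nucleotides: int
    planted_bonds: tuple[PlantedBond, ...] = ()
    decoy_contacts: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted_bonds", tuple(self.planted_bonds))
        if self.n_protein_residues < 1 or self.n_rna_nucleotides < 1:
            raise ValueError("chains must have at least one residue")
        per_res: dict[int, list[PlantedBond]] = {}
        used_nt: set[int] = set()
        for b in self.planted_bonds:
            if not 1 <= b.residue_index <= self.n_protein_residues:
                raise ValueError(f"planted residue index {b.residue_index} out of range")
            if not 1 <= b.nucleotide_index <= self.n_rna_nucleotides:
                raise ValueError(f"planted nucleotide index {b.nucleotide_index} out of range")
            if not 2.4 < b.d_da < 5.0:
                raise ValueError(f"requested d_DA={b.d_da} outside the achievable (2.4, 5.0)")
            if not 0 < b.ang_dha <= 180 or not 0 < b.ang_haaa <= 180:
                raise ValueError("planted angles must lie in (0, 180]")
            if b.nucleotide_index in used_nt:
                raise ValueError(f"nucleotide {b.nucleotide_index} hosts more than one bond")
            used_nt.add(b.nucleotide_index)
            per_res.setdefault(b.residue_index, []).append(b)
        for i, bonds in per_res.items():
            if len(bonds) > 2:
                raise ValueError(f"residue {i} hosts more than two planted bonds")
            if len(bonds) > 1 and any(b.angle_invalid() for b in bonds):
                raise ValueError(
                    f"residue {i}: an angle-invalid bond must be the residue's only bond")
        if self.decoy_contacts < 0:
            raise ValueError("decoy_contacts must be non-negative")


@dataclass(frozen=True)
class PairSpec:
    seed: int
    n_pairs: int = 200
    protein_len: tuple[int, int] = (30, 80)
    rna_len: tuple[int, int] = (15, 40)
    enriched_triplets: dict[str, float] = field(default_factory=dict)
    base_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.n_pairs < 0 or self.base_rate < 0:
            raise ValueError("n_pairs and base_rate must be non-negative")
        for t, mult in self.enriched_triplets.items():
            if len(t) != 3 or any(a not in AMINO_ACIDS for a in t):
                raise ValueError(f"invalid enriched triplet {t!r}")
            if mult < 0:
                raise ValueError("enrichment multipliers must be non-negative")


def _rotate_in_plane(eu: float, ev: float, psi_deg: float) -> tuple[float, float]:
    psi = math.radians(psi_deg)
    return (eu * math.cos(psi) - ev * math.sin(psi),
            eu * math.sin(psi) + ev * math.cos(psi))


def _bond_atoms(donor: np.ndarray, bond: PlantedBond,
                u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Place (hydrogen, acceptor, antecedent) realizing the requested geometry.

    The donor sits at ``donor``; the acceptor is placed at d_DA along ``u``;
    the hydrogen in the (u, v) plane so the D-H-A angle is exact; the
    antecedent by rotating the A->H direction by the H-A-AA angle in-plane.
    """
    d, d_ha, _ = bond.geometry()
    acceptor = donor + d * u
    cos_alpha = (_R_DH ** 2 + d ** 2 - d_ha ** 2) / (2 * _R_DH * d)
    cos_alpha = max(-1.0, min(1.0, cos_alpha))
    sin_alpha = math.sqrt(1.0 - cos_alpha ** 2)
    hydrogen = donor + _R_DH * (cos_alpha * u + sin_alpha * v)
    e = hydrogen - acceptor
    e /= np.linalg.norm(e)
    eu, ev = float(np.dot(e, u)), float(np.dot(e, v))
    au, av = _rotate_in_plane(eu, ev, bond.ang_haaa)
    antecedent = acceptor + _R_AAA * (au * u + av * v)
    return hydrogen, acceptor, antecedent


def synth_complex(spec: ComplexSpec) -> tuple[str, list[int]]:
    """Emit PDB text plus the expected per-residue binding labels.

    Protein chain A carries backbone N/CA atoms (plus explicit hydrogens on
    donors of planted or decoy bonds); RNA chain B carries P/OP1 phosphate
    atoms.  Byte-identical output for identical specs.
    """
    rng = np.random.default_rng(spec.seed)
    protein_seq = "".join(rng.choice(list(_SYNTH_AAS), size=spec.n_protein_residues))
    rna_seq = "".join(rng.choice(list(NUCLEOTIDES), size=spec.n_rna_nucleotides))

    bonds_by_res: dict[int, list[PlantedBond]] = {}
    for b in spec.planted_bonds:
        bonds_by_res.setdefault(b.residue_index, []).append(b)
    used_nt = {b.nucleotide_index for b in spec.planted_bonds}

    # decoy contacts: distance-invalid geometries on otherwise unused pairs
    free_res = [i for i in range(1, spec.n_protein_residues + 1) if i not in bonds_by_res]
    free_nt = [j for j in range(1, spec.n_rna_nucleotides + 1) if j not in used_nt]
    if spec.decoy_contacts > min(len(free_res), len(free_nt)):
        raise ValueError("not enough unused residues/nucleotides for the requested decoys")
    for k in range(spec.decoy_contacts):
        d_da = float(rng.uniform(4.0, 4.8))
        decoy = PlantedBond(free_res[k], free_nt[k], d_da=d_da)
        bonds_by_res.setdefault(decoy.residue_index, []).append(decoy)
        used_nt.add(decoy.nucleotide_index)

    axes = [(np.array([1.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0])),
            (np.array([0.0, 0.0, 1.0]), np.array([0.0, 1.0, 0.0]))]

    lines: list[str] = []
    serial = 1

    def put(name: str, resname: str, chain: str, resseq: int,
            xyz: np.ndarray, element: str) -> None:
        nonlocal serial
        lines.append(
            f"ATOM  {serial:5d}  {name:<3s} {resname:>3s} {chain}{resseq:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {element:>2s}")
        serial += 1

    nt_atoms: dict[int, list[tuple[str, np.ndarray]]] = {}
    for i in range(1, spec.n_protein_residues + 1):
        base = np.array([0.0, _SPACING * i, 0.0])
        resname = _AA1_TO_3[protein_seq[i - 1]]
        put("N", resname, "A", i, base, "N")
        put("CA", resname, "A", i, base + np.array([-1.45, 0.0, 0.0]), "C")
        for k, bond in enumerate(bonds_by_res.get(i, [])):
            u, v = axes[k]
            hydrogen, acceptor, antecedent = _bond_atoms(base, bond, u, v)
            put("H" if k == 0 else "H2", resname, "A", i, hydrogen, "H")
            nt_atoms[bond.nucleotide_index] = [("P", antecedent), ("OP1", acceptor)]

    for j in range(1, spec.n_rna_nucleotides + 1):
        resname = rna_seq[j - 1]
        atoms = nt_atoms.get(j)
        if atoms is None:
            base = np.array([_RNA_OFFSET, _SPACING * j, 0.0])
            atoms = [("P", base), ("OP1", base + np.array([1.5, 0.0, 0.0]))]
        for name, xyz in atoms:
            put(name, resname, "B", j, xyz, name[0])
    lines.append("END")

    valid_res = {b.residue_index
                 for bonds in bonds_by_res.values() for b in bonds if b.is_valid()}
    labels = [1 if i in valid_res else -1
              for i in range(1, spec.n_protein_residues + 1)]
    return "\n".join(lines) + "\n", labels


def synth_pairs(spec: PairSpec) -> list[InteractionPair]:
    """Generate interaction pairs with triplet-dependent contact rates.

    Enriched triplets are implanted once per protein sequence, then each
    internal residue makes a contact with probability
    min(1, base_rate * multiplier(triplet)); the contacted nucleotide is a
    uniformly random RNA position and the projected H-A distance is drawn
    uniformly from (1.5, 3.0) A.
    """
    rng = np.random.default_rng(spec.seed)
    pairs: list[InteractionPair] = []
    for idx in range(spec.n_pairs):
        n = int(rng.integers(spec.protein_len[0], spec.protein_len[1] + 1))
        seq = list(rng.choice(list(AMINO_ACIDS), size=n))
        for t in sorted(spec.enriched_triplets):
            p = int(rng.integers(2, n))  # 1-based centre in 2 .. n-1
            seq[p - 2:p + 1] = list(t)
        seq = "".join(seq)
        m = int(rng.integers(spec.rna_len[0], spec.rna_len[1] + 1))
        rna = "".join(rng.choice(list(NUCLEOTIDES), size=m))

        contacts: list[tuple[int, str, float]] = []
        for i in range(2, n):
            t = seq[i - 2:i + 1]
            rate = spec.base_rate * spec.enriched_triplets.get(t, 1.0)
            if rng.random() < min(rate, 1.0):
                j = int(rng.integers(1, m + 1))
                contacts.append((i, rna[j - 1], float(rng.uniform(1.5, 3.0))))
        bound = {i for i, _, _ in contacts}
        labels = [1 if i in bound else -1 for i in range(1, n + 1)]
        pairs.append(InteractionPair(pair_id=f"synth{idx}", protein_seq=seq,
                                     rna_seq=rna, labels=labels, contacts=contacts))
    return pairs
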