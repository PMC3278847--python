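"""Fixed-layout feature-vector encoding of protein-RNA pairs.

Each protein residue is encoded against its RNA partner as a vector of
9w + 17 elements for an odd sliding window of w >= 3 residues:

* 21 global elements: normalized sequence length L plus the 20 amino-acid
  composition frequencies C, encoded once per pair;
* 4 partner elements R_A, R_C, R_G, R_U: per-nucleotide positional mass of
  the RNA sequence, encoded once per pair;
* w - 2 internal window slots with 9 local elements each: normalized
  position N, hydropathy H, accessible surface area A, molecular mass M,
  side-chain pKa P, and the four triplet interaction propensities
  IP_A..IP_U of the triplet centred on the slot;
* 2 terminal window slots (the outermost window positions) with the 5
  N, H, A, M, P elements only, since no complete centred triplet fits.

Window positions outside the sequence are padded with the sentinel X whose
local elements are all zero, so a length-n protein always yields n vectors.
Every element is normalized into [0, 1].  The vector label is +1 when the
window's middle residue is RNA-binding and -1 otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chemistry import AMINO_ACIDS, NUCLEOTIDES
from .propensity import TripletPropensityTable, lookup
from .structure import InteractionPair

__all__ = [
    "AminoAcidScales", "FeatureSchema", "FeatureVector", "DEFAULT_SCALES",
    "normalized_position", "global_features", "rna_partner_features",
    "vector_length", "encode_residue", "encode_pair",
    "write_vectors_tsv", "read_vectors_tsv",
]

# Kyte-Doolittle hydropathy index.
HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Theoretical maximum accessible surface area per residue type (A^2),
# Tien et al. 2013 values.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

# Monoisotopic residue masses (Da).
RESIDUE_MASS = {
    "A": 71.03711, "R": 156.10111, "N": 114.04293, "D": 115.02694,
    "C": 103.00919, "Q": 128.05858, "E": 129.04259, "G": 57.02146,
    "H": 137.05891, "I": 113.08406, "L": 113.08406, "K": 128.09496,
    "M": 131.04049, "F": 147.06841, "P": 97.05276, "S": 87.03203,
    "T": 101.04768, "W": 186.07931, "Y": 163.06333, "V": 99.06841,
}

# Side-chain pKa; residues without an ionizable side chain are absent.
SIDE_CHAIN_PKA = {
    "D": 3.65, "E": 4.25, "H": 6.0, "C": 8.3,
    "Y": 10.07, "K": 10.53, "R": 12.48,
}


def _minmax(table: dict[str, float]) -> dict[str, float]:
    lo, hi = min(table.values()), max(table.values())
    return {k: (v - lo) / (hi - lo) for k, v in table.items()}


@dataclass(frozen=True)
class AminoAcidScales:
    """Per-residue physicochemical scales with min-max normalized companions.

    Hydropathy, max ASA and residue mass are min-max normalized over the
    20-residue alphabet; side-chain pKa is divided by 14 with non-ionizable
    residues mapped to 0.
    """
    hydropathy: dict[str, float] = field(default_factory=lambda: dict(HYDROPATHY))
    max_asa: dict[str, float] = field(default_factory=lambda: dict(MAX_ASA))
    mass: dict[str, float] = field(default_factory=lambda: dict(RESIDUE_MASS))
    side_chain_pka: dict[str, float] = field(default_factory=lambda: dict(SIDE_CHAIN_PKA))

    def __post_init__(self) -> None:
        for table in (self.hydropathy, self.max_asa, self.mass):
            if set(table) != set(AMINO_ACIDS):
                raise ValueError("scale must cover exactly the 20 standard amino acids")
        object.__setattr__(self, "hydropathy_norm", _minmax(self.hydropathy))
        object.__setattr__(self, "max_asa_norm", _minmax(self.max_asa))
        object.__setattr__(self, "mass_norm", _minmax(self.mass))
        object.__setattr__(self, "pka_norm",
                           {a: self.side_chain_pka.get(a, 0.0) / 14.0
                            for a in AMINO_ACIDS})

    def local(self, aa: str) -> tuple[float, float, float, float]:
        """(H, A, M, P) normalized values; all zero for the sentinel X."""
        if aa not in self.hydropathy:
            return (0.0, 0.0, 0.0, 0.0)
        return (self.hydropathy_norm[aa], self.max_asa_norm[aa],
                self.mass_norm[aa], self.pka_norm[aa])


DEFAULT_SCALES = AminoAcidScales()


def vector_length(w: int) -> int:
    """Feature-vector length 9w + 17 for an odd window of w >= 3 residues."""
    if w < 3 or w % 2 == 0:
        raise ValueError(f"window size must be an odd integer >= 3, got {w}")
    return 9 * w + 17


@dataclass(frozen=True)
class FeatureSchema:
    window: int = 15
    length_cap: int = 1000

    def __post_init__(self) -> None:
        vector_length(self.window)  # validates
        if self.length_cap < 1:
            raise ValueError("length_cap must be positive")

    @property
    def n_features(self) -> int:
        return vector_length(self.window)

    @property
    def layout(self) -> list[str]:
        names = ["L"] + [f"C_{a}" for a in AMINO_ACIDS] + \
                [f"R_{b}" for b in NUCLEOTIDES]
        half = (self.window - 1) // 2
        for k in range(-half, half + 1):
            slot = f"slot{k:+d}"
            names += [f"{slot}_{x}" for x in "NHAMP"]
            if abs(k) != half:  # internal slot carries the 4 triplet IPs
                names += [f"{slot}_IP_{b}" for b in NUCLEOTIDES]
        return names

    def to_dict(self) -> dict:
        return {"window": self.window, "length_cap": self.length_cap,
                "n_features": self.n_features, "layout": self.layout}


@dataclass
class FeatureVector:
    values: np.ndarray
    label: int
    pair_id: str = ""
    residue_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.label not in (1, -1):
            raise ValueError("label must be +1 or -1")


def normalized_position(i: int, n: int) -> float:
    """Normalized 1-based position i/n in (0, 1]."""
    if not 1 <= i <= n:
        raise ValueError(f"position {i} out of range for length {n}")
    return i / n


def global_features(protein_seq: str, length_cap: int = 1000) -> np.ndarray:
    """21 global elements: capped length fraction + 20 composition frequencies."""
    if not protein_seq:
        raise ValueError("empty protein sequence")
    n = len(protein_seq)
    out = np.zeros(21)
    out[0] = min(n / length_cap, 1.0)
    for aa in protein_seq:
        if aa in AMINO_ACIDS:
            out[1 + AMINO_ACIDS.index(aa)] += 1.0
    out[1:] /= n
    return out


def rna_partner_features(rna_seq: str) -> np.ndarray:
    """Per-nucleotide positional mass of the partner RNA, summing to 1.

    raw_b = sum of j/n over 1-based positions j holding nucleotide b, then
    normalized by the total so each element lies in [0, 1].
    """
    if not rna_seq:
        raise ValueError("empty RNA sequence")
    n = len(rna_seq)
    raw = np.zeros(4)
    for j, b in enumerate(rna_seq, start=1):
        if b in NUCLEOTIDES:
            raw[NUCLEOTIDES.index(b)] += j / n
    total = raw.sum()
    return raw / total if total > 0 else raw


def encode_residue(pair: InteractionPair, i: int, schema: FeatureSchema,
                   ip_table: TripletPropensityTable,
                   scales: AminoAcidScales = DEFAULT_SCALES) -> FeatureVector:
    """Encode residue i (1-based) of a pair as one feature vector."""
    n = len(pair.protein_seq)
    if not 1 <= i <= n:
        raise ValueError(f"residue index {i} out of range for length {n}")
    w = schema.window
    half = (w - 1) // 2
    ip_max = ip_table.ip_max

    values = np.empty(schema.n_features)
    values[:21] = global_features(pair.protein_seq, schema.length_cap)
    values[21:25] = rna_partner_features(pair.rna_seq)

    pos = 25
    for k in range(-half, half + 1):
        j = i + k
        in_range = 1 <= j <= n
        aa = pair.protein_seq[j - 1] if in_range else "X"
        if in_range and aa in AMINO_ACIDS:
            values[pos] = normalized_position(j, n)
            values[pos + 1:pos + 5] = scales.local(aa)
        else:
            values[pos:pos + 5] = 0.0
        pos += 5
        if abs(k) != half:
            if in_range and 2 <= j <= n - 1:
                triplet = pair.protein_seq[j - 2:j + 1]
            else:
                triplet = "XXX"
            for b in NUCLEOTIDES:
                ip = lookup(ip_table, triplet, b) if "X" not in triplet else 0.0
                values[pos] = min(ip / ip_max, 1.0) if ip_max > 0 else 0.0
                pos += 1
    assert pos == schema.n_features
    return FeatureVector(values=values, label=pair.labels[i - 1],
                         pair_id=pair.pair_id, residue_index=i)


def encode_pair(pair: InteractionPair, schema: FeatureSchema,
                ip_table: TripletPropensityTable,
                scales: AminoAcidScales = DEFAULT_SCALES) -> list[FeatureVector]:
    """Encode every residue of a pair: a length-n protein yields n vectors."""
    if not pair.protein_seq:
        raise ValueError("empty protein sequence")
    return [encode_residue(pair, i, schema, ip_table, scales)
            for i in range(1, len(pair.protein_seq) + 1)]


# ---------------------------------------------------------------------------
# TSV interchange: one vector per row, label in the final column.

def write_vectors_tsv(vectors: list[FeatureVector], path,
                      schema: FeatureSchema | None = None) -> None:
    with open(path, "w") as fh:
        if schema is not None:
            fh.write("\t".join(schema.layout) + "\tlabel\n")
        for v in vectors:
            fh.write("\t".join(f"{x:.6f}" for x in v.values) + f"\t{v.label:+d}\n")


def read_vectors_tsv(path) -> list[FeatureVector]:
    vectors = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            try:
                label = int(parts[-1])
            except ValueError:
                continue  # header
            vectors.append(FeatureVector(
                values=np.array([float(x) for x in parts[:-1]]), label=label))
    return vectors
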