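"""Interaction propensity of amino-acid triplets with nucleotides.

For each of the 20^3 = 8,000 overlapping amino-acid triplets t and each of
the 4 nucleotides b, the interaction propensity is a distance-weighted
observed-over-expected statistic computed from hydrogen-bond contact records:

    IP_tb = [ S_tb / N_PR ] / [ (N_t / N_P) * (N_b / N_R) ]

where S_tb is the sum over hydrogen bonds between triplet t and nucleotide b
of the inverse projected H-A distance (the H-A distance times the cosine of
the D-A-H angle), N_PR is the number of triplet instances that bind any
nucleotide, N_t / N_P count occurrences of triplet t and of all triplets in
the protein sequences, and N_b / N_R count nucleotide b and all nucleotides
in the RNA sequences.  Close donor-acceptor pairs therefore contribute more
than distant ones, and a triplet-nucleotide pair with no observed bonds has
IP exactly 0.  The full table always holds 32,000 keys.

A contact is attributed to the triplet centred on the bonded residue;
terminal residues (no complete centred triplet) are skipped and counted.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

from .chemistry import AMINO_ACIDS, NUCLEOTIDES
from .structure import HBond, InteractionPair, _angle_deg

__all__ = [
    "TripletPropensityTable", "projected_distance", "triplets_of",
    "build_table", "lookup", "write_table", "read_table",
]

ALL_TRIPLETS = ["".join(t) for t in itertools.product(AMINO_ACIDS, repeat=3)]


@dataclass
class TripletPropensityTable:
    ip: dict[tuple[str, str], float]      # zero-filled over all 32,000 keys
    n_pr: int                              # triplet instances binding >= 1 nucleotide
    n_t: dict[str, int]                    # occurrences per triplet
    n_p: int                               # total triplet instances
    n_b: dict[str, int]                    # occurrences per nucleotide
    n_r: int                               # total nucleotides
    skipped_terminal_contacts: int = 0
    ip_max: float = field(init=False)

    def __post_init__(self) -> None:
        self.ip_max = max(self.ip.values(), default=0.0)


def projected_distance(hbond: HBond) -> float:
    """Projected H-A distance on the D-A axis: d_HA * cos(angle D-A-H at A).

    Raises when the hydrogen projects behind the acceptor relative to the
    donor (D-A-H angle >= 90 deg); such bonds are excluded from propensity
    accumulation.
    """
    ang_dah = _angle_deg(hbond.donor.coords, hbond.acceptor.coords, hbond.hydrogen)
    if ang_dah >= 90.0:
        raise ValueError(f"D-A-H angle {ang_dah:.1f} >= 90 deg: projection not positive")
    return hbond.d_ha * math.cos(math.radians(ang_dah))


def triplets_of(seq: str) -> list[tuple[int, str]]:
    """Overlapping triplets of a sequence as (1-based centre index, triplet).

    A length-n sequence yields max(0, n-2) triplets, centred on positions
    2 .. n-1.
    """
    return [(i, seq[i - 2:i + 1]) for i in range(2, len(seq))]


def _center_triplet(seq: str, i: int) -> str | None:
    """Triplet centred at 1-based position i, or None at the termini."""
    if i < 2 or i > len(seq) - 1:
        return None
    return seq[i - 2:i + 1]


def build_table(pairs: list[InteractionPair]) -> TripletPropensityTable:
    """Accumulate the propensity table from interaction pairs.

    Every pair contributes to the marginal counts; only pairs with contacts
    contribute to the weighted sums.  Contacts on terminal residues or on
    triplets containing the sentinel X are skipped (counted in
    ``skipped_terminal_contacts``).
    """
    if not pairs:
        raise ValueError("cannot build a propensity table from no pairs")

    n_t: dict[str, int] = {}
    n_b: dict[str, int] = {}
    n_p = 0
    n_r = 0
    sums: dict[tuple[str, str], float] = {}
    bound_instances: set[tuple[str, int]] = set()
    skipped = 0

    for pair in pairs:
        for _, t in triplets_of(pair.protein_seq):
            if "X" in t:
                continue
            n_t[t] = n_t.get(t, 0) + 1
            n_p += 1
        for b in pair.rna_seq:
            if b in NUCLEOTIDES:
                n_b[b] = n_b.get(b, 0) + 1
                n_r += 1
        for i, b, d_proj in pair.contacts:
            if d_proj <= 0:
                raise ValueError(f"non-positive d_proj {d_proj} in pair {pair.pair_id}")
            t = _center_triplet(pair.protein_seq, i)
            if t is None or "X" in t or b not in NUCLEOTIDES:
                skipped += 1
                continue
            sums[(t, b)] = sums.get((t, b), 0.0) + 1.0 / d_proj
            bound_instances.add((pair.pair_id, i))

    n_pr = len(bound_instances)
    if n_pr == 0:
        raise ValueError("no qualifying contacts: propensity table would be all-zero")

    ip = {(t, b): 0.0 for t in ALL_TRIPLETS for b in NUCLEOTIDES}
    for (t, b), s in sums.items():
        expected = (n_t[t] / n_p) * (n_b.get(b, 0) / n_r)
        ip[(t, b)] = (s / n_pr) / expected
    return TripletPropensityTable(ip=ip, n_pr=n_pr, n_t=n_t, n_p=n_p,
                                  n_b=n_b, n_r=n_r,
                                  skipped_terminal_contacts=skipped)


def lookup(table: TripletPropensityTable, triplet: str, nucleotide: str) -> float:
    """IP of (triplet, nucleotide); 0 for unobserved or X-containing triplets."""
    if nucleotide not in NUCLEOTIDES:
        raise ValueError(f"nucleotide {nucleotide!r} not in ACGU")
    if "X" in triplet:
        return 0.0
    if len(triplet) != 3 or any(a not in AMINO_ACIDS for a in triplet):
        raise ValueError(f"invalid amino-acid triplet {triplet!r}")
    return table.ip[(triplet, nucleotide)]


# ---------------------------------------------------------------------------
# Serialization: TSV of nonzero entries + JSON sidecar with the count
# statistics; round-trip exact at 6 decimals.

def write_table(table: TripletPropensityTable, tsv_path, sidecar_path=None) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("triplet\tnucleotide\tip\n")
        for (t, b), v in sorted(table.ip.items()):
            if v != 0.0:
                fh.write(f"{t}\t{b}\t{v:.6f}\n")
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump({"n_pr": table.n_pr, "n_p": table.n_p, "n_r": table.n_r,
                       "n_t": table.n_t, "n_b": table.n_b,
                       "ip_max": round(table.ip_max, 6),
                       "skipped_terminal_contacts": table.skipped_terminal_contacts},
                      fh, indent=1)


def read_table(tsv_path, sidecar_path=None) -> TripletPropensityTable:
    ip = {(t, b): 0.0 for t in ALL_TRIPLETS for b in NUCLEOTIDES}
    with open(tsv_path) as fh:
        header = fh.readline()
        if not header.startswith("triplet"):
            raise ValueError("not a propensity table TSV")
        for line in fh:
            t, b, v = line.rstrip("\n").split("\t")
            ip[(t, b)] = float(v)
    meta = {"n_pr": 0, "n_p": 0, "n_r": 0, "n_t": {}, "n_b": {},
            "skipped_terminal_contacts": 0}
    if sidecar_path is not None:
        with open(sidecar_path) as fh:
            loaded = json.load(fh)
        meta.update({k: loaded[k] for k in meta if k in loaded})
    return TripletPropensityTable(ip=ip, n_pr=meta["n_pr"], n_t=meta["n_t"],
                                  n_p=meta["n_p"], n_b=meta["n_b"], n_r=meta["n_r"],
                                  skipped_terminal_contacts=meta["skipped_terminal_contacts"])
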