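"""Shared fixtures: synthetic complexes, toy datasets, independent oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

from rbind.structure import Structure, donor_acceptor_sites
from rbind.synth import ComplexSpec, PairSpec, PlantedBond, synth_pairs
from rbind.encoding import FeatureVector


def random_complex_spec(seed: int) -> ComplexSpec:
    """A random mixture of valid and invalid planted hydrogen-bond geometries."""
    rng = np.random.default_rng(seed)
    n_res = int(rng.integers(8, 20))
    n_nt = int(rng.integers(6, 16))
    n_bonds = int(rng.integers(0, min(n_res, n_nt, 6) + 1))
    residues = rng.choice(np.arange(1, n_res + 1), size=n_bonds, replace=False)
    nucleotides = rng.choice(np.arange(1, n_nt + 1), size=n_bonds, replace=False)
    bonds = []
    for r, nt in zip(residues, nucleotides):
        kind = rng.integers(0, 4)
        if kind == 0:      # all four criteria satisfied
            bonds.append(PlantedBond(int(r), int(nt),
                                     d_da=float(rng.uniform(2.6, 3.3)),
                                     ang_dha=float(rng.uniform(150, 180)),
                                     ang_haaa=float(rng.uniform(110, 170))))
        elif kind == 1:    # donor-acceptor distance too large
            bonds.append(PlantedBond(int(r), int(nt),
                                     d_da=float(rng.uniform(4.0, 4.9))))
        elif kind == 2:    # D-H-A angle below the threshold
            bonds.append(PlantedBond(int(r), int(nt),
                                     d_da=float(rng.uniform(2.6, 3.3)),
                                     ang_dha=float(rng.uniform(40, 89)),
                                     ang_haaa=float(rng.uniform(110, 170))))
        else:              # H-A-AA angle below the threshold
            bonds.append(PlantedBond(int(r), int(nt),
                                     d_da=float(rng.uniform(2.6, 3.3)),
                                     ang_dha=float(rng.uniform(150, 180)),
                                     ang_haaa=float(rng.uniform(20, 89))))
    decoys = int(rng.integers(0, 3))
    decoys = min(decoys, n_res - n_bonds, n_nt - n_bonds)
    return ComplexSpec(seed=seed, n_protein_residues=n_res, n_rna_nucleotides=n_nt,
                       planted_bonds=tuple(bonds), decoy_contacts=max(decoys, 0))


def brute_force_hbond_keys(structure: Structure, protein_chain: str,
                           rna_chain: str, criteria) -> set[tuple]:
    """All-pairs hydrogen-bond scan, written independently of the detector.

    Uses explicit deposited hydrogens and plain trigonometry; returns keys
    (donor resnum, donor atom, acceptor resnum, acceptor atom).
    """
    def ang(a, vertex, b):
        u = np.asarray(a) - vertex
        v = np.asarray(b) - vertex
        c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
        return math.degrees(math.acos(max(-1.0, min(1.0, c))))

    prot = [r for r in structure.chain(protein_chain) if r.polymer == "protein"]
    rna = [r for r in structure.chain(rna_chain) if r.polymer == "rna"]

    def sites(residues):
        donors, acceptors = [], []
        for res in residues:
            d, a = donor_acceptor_sites(res)
            hydrogens = [x for x in res.atoms if x.element == "H"]
            for atom, _ in d:
                hs = [h.coords for h in hydrogens
                      if np.linalg.norm(h.coords - atom.coords) <= 1.3]
                donors.append((res, atom, hs))
            for atom, ante in a:
                acceptors.append((res, atom, ante))
        return donors, acceptors

    pd, pa = sites(prot)
    rd, ra = sites(rna)
    found = set()
    for donors, acceptors in ((pd, ra), (rd, pa)):
        for dres, datom, hs in donors:
            for ares, aatom, ante in acceptors:
                d_da = float(np.linalg.norm(datom.coords - aatom.coords))
                if not d_da < criteria.d_da_max:
                    continue
                for h in hs:
                    d_ha = float(np.linalg.norm(h - aatom.coords))
                    if not d_ha < criteria.d_ha_max:
                        continue
                    if not ang(datom.coords, h, aatom.coords) > criteria.ang_dha_min:
                        continue
                    if not ang(h, aatom.coords, ante.coords) > criteria.ang_haaa_min:
                        continue
                    found.add((dres.number, datom.name, ares.number, aatom.name))
                    break
    return found


@pytest.fixture(scope="session")
def toy_pairs():
    """Small synthetic pair set with contacts, for propensity/encoding tests."""
    return synth_pairs(PairSpec(seed=11, n_pairs=12, protein_len=(10, 25),
                                rna_len=(8, 15), base_rate=0.15))


@pytest.fixture(scope="session")
def separable_vectors():
    """Two well-separated 2-feature clusters of 50 points per class."""
    rng = np.random.default_rng(42)
    pos = rng.normal(loc=10.0, scale=1.0, size=(50, 2))
    neg = rng.normal(loc=0.0, scale=1.0, size=(50, 2))
    vectors = [FeatureVector(values=row, label=1) for row in pos]
    vectors += [FeatureVector(values=row, label=-1) for row in neg]
    return vectors


@pytest.fixture(scope="session")
def imbalanced_vectors():
    """1:9 positive:negative fixture with partial overlap between classes."""
    rng = np.random.default_rng(7)
    pos = rng.normal(loc=2.0, scale=1.0, size=(30, 4))
    neg = rng.normal(loc=0.0, scale=1.0, size=(270, 4))
    vectors = [FeatureVector(values=row, label=1) for row in pos]
    vectors += [FeatureVector(values=row, label=-1) for row in neg]
    return vectors
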