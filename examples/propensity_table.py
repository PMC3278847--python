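"""Build a triplet-nucleotide interaction propensity table and inspect it.

Generates synthetic interaction pairs in which the triplet CRR hydrogen-bonds
RNA at ten times the background rate, accumulates the distance-weighted
observed-over-expected propensity statistic over all 8,000 x 4 keys, and
prints the CRR row against the table-wide background.
"""

from rbind import build_table, lookup
from rbind.synth import PairSpec, synth_pairs

pairs = synth_pairs(PairSpec(seed=1, n_pairs=200,
                             enriched_triplets={"CRR": 10.0}, base_rate=0.05))
table = build_table([p for p in pairs if p.contacts])

nonzero = [v for v in table.ip.values() if v > 0]
print(f"table: {len(table.ip)} keys, {len(nonzero)} nonzero "
      f"({100 * len(nonzero) / len(table.ip):.1f}%), max IP {table.ip_max:.3f}")
print(f"counts: N_PR={table.n_pr} bound triplet instances, "
      f"N_P={table.n_p} triplets, N_R={table.n_r} nucleotides")
print("IP of the enriched triplet CRR with each nucleotide:")
for b in "ACGU":
    print(f"  IP(CRR, {b}) = {lookup(table, 'CRR', b):.3f}")
print("every CRR value is nonzero because the triplet was implanted with a")
print("10x contact rate; an unobserved triplet-nucleotide pair has IP = 0")
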