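"""Simulate co-assembly of 200 RNAs under two move sets.

Each RNA carries 30 packaging signals of uniform affinity (-9 kcal/mol).
Under {2,3,4,5} a fraction of RNAs is packaged into complete capsids; under
{2,5,6,7} no capsid can ever form because none of its moves creates a
protein-protein contact, so nucleation is impossible (yield exactly 0).
"""
from pscapsid import KineticParams, MoveSet, RNAVariant, build_lattice, run_assembly

lattice = build_lattice()
params = KineticParams()
rna = RNAVariant.uniform(-9.0)

for moves in ["2345", "2567"]:
    res = run_assembly(rna, params, MoveSet.parse(moves), seed=17, n_rna=200,
                       lattice=lattice)
    print(f"move set {{{','.join(moves)}}}: {res.n_cap}/{res.n_rna} capsids "
          f"({res.yield_pct:.1f}%), stopped: {res.stop_reason}")
    print(f"  events: {res.event_counts}")
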