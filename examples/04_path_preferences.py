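"""Which RNA paths do assembled capsids actually use?

With an optimised profile under {2,3,4,5}, almost every completed capsid
follows one of two path types that differ only in the few moves around the
nucleation five-fold (the clockwise and anticlockwise starts) -- out of 64
geometrically possible paths.
"""
from pscapsid import (KineticParams, MoveSet, RNAVariant, build_lattice,
                      classify_paths, count_paths, run_assembly)

lattice = build_lattice()
ms = MoveSet.parse("2345")
census = count_paths(lattice, ms, enumerate_paths=True)
optimal = RNAVariant.uniform(-5.0).with_dg(range(28, 30), -11.0)
res = run_assembly(optimal, KineticParams(), ms, seed=31, n_rna=300,
                   lattice=lattice)
cls = classify_paths(res.paths, census=census, top=2)
print(f"{res.n_cap} capsids; {len(cls.table)} distinct path types "
      f"(census has {census.n_path})")
print(f"top-2 path types cover {100 * cls.top_fraction(2):.1f}% of capsids; "
      f"they share their first {cls.top_shared_prefix_len} moves")
print(cls.table.head(3).to_string(index=False))
print(f"all observed paths are members of the census: {cls.all_in_census}")
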