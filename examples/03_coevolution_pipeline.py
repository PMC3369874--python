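"""The core pipeline on planted coevolving groups: NMI/Z-scoring, split-half
consensus resampling to a 0-100% reproducibility matrix, and maximal-clique
extraction of the fully reproducible coupling network."""

import itertools

from coevnet import (
    build_graph,
    degree_profile,
    fully_reproducible,
    joint_identity_histogram,
    maximal_cliques,
    reproducibility_protocol,
    top_cliques,
)
from coevnet.simulate import CoupledGroup, MsaSpec, generate_msa

# Plant a 3-clique, a 5-clique and a 6-clique of deterministically covarying
# columns among independent background columns.
groups = (
    CoupledGroup((2, 30, 60), ("DRK", "EKD")),
    CoupledGroup((10, 25, 45, 70, 90), ("DRKLM", "EKDVF")),
    CoupledGroup((5, 20, 40, 65, 80, 95), ("DRKLMN", "EKDVFH")),
)
aln = generate_msa(MsaSpec(n_seqs=200, n_cols=100, coupled_groups=groups,
                           gap_rate=0.02, seed=0))
print(f"alignment: {aln.n_seqs} sequences x {aln.n_cols} columns")

r = reproducibility_protocol(aln, iterations=100, subset_size=150, seed=0)
print(f"resampling: {r.iterations} iterations, top-{r.k} per split, "
      f"mean consensus ratio {sum(r.consensus_ratios)/len(r.consensus_ratios):.2f}")

full = fully_reproducible(r)
deg = degree_profile(full)
print(f"100%-reproducible couplings: {len(full)} over {len(deg)} positions")

cliques = maximal_cliques(build_graph(full))
selected, union = top_cliques(cliques, n_top=3)
print(f"maximal cliques (size >= 2): {len(cliques)}; "
      f"top-3 sizes {[len(c) for c in selected]}; union of {len(union)} positions")
for g in groups:
    print("  planted", sorted(p + 1 for p in g.members),
          "recovered" if frozenset(p + 1 for p in g.members) in set(cliques)
          else "MISSED")

# Joint residue identities behind one recovered coupling (1-based positions):
i, j = sorted(full)[0]
hist = joint_identity_histogram(aln, i, j)
print(f"joint identities at ({i}, {j}):",
      {f"{a}{b}": round(f, 2) for (a, b), f in sorted(hist.items())})
# Each cell is the frequency of one residue-type combination among the
# mutually ungapped rows (cells under 5% dropped, renormalized) — two cells
# near 0.5 is the signature of a planted two-state covariation.
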