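# chemseq

Alignment-free characterization of protein sequences through the chemistry
of their side chains. The 20 standard amino acids are collapsed onto eight
chemical groups — Acidic {D,E}, Basic {R,H,K}, Aromatic {Y,F,W}, Aliphatic
{I,L,V,A,G}, Cyclic {P}, Sulfur-containing {M,C}, Hydroxyl-containing {S,T}
and Acidic-amide {Q,N}, numbered 1..8 — and every analysis runs over this
reduced alphabet:

- **Group composition.** For sequence *S_i* of length *L_i*, the count
  *S_i(T_k)* of residues in group *G_k* and its score per hundred
  *S_i(G_k) = S_i(T_k)/L_i × 100*.
- **Chemical dissimilarity.** Between two sequences,
  *D_ij = Σ_k |S_i(G_k) − S_j(G_k)|* — the L1 distance between 8-dimensional
  percent vectors, bounded by 200 and metric on those vectors.
- **Phylogenetic tree.** Single-linkage (nearest distance) agglomeration of
  the pairwise dissimilarity matrix, serialized as Newick plus a merge table.
- **Order-pair digraph.** Nodes are the group codes present in a sequence;
  each consecutive pair (T(i), T(i+1)) of the reduced sequence is a directed
  edge. Edge sets are compared across homolog groups to find edges present
  in every member of one set and absent from the other.
- **Cycles and subdomains.** Simple directed cycles of bounded length
  (default 3–6) are enumerated per digraph; a cycle's subdomain is the
  minimal residue window containing an occurrence of each of its edges.
- **Chemical patterns.** Search for a pattern over group codes (e.g.
  `624621`) with a mismatch budget, and alignment-free discovery of group
  k-mers conserved within or specific to sequence sets.

The package was built around the five homologous triheme periplasmic
c7-type cytochromes of *Geobacter sulfurreducens* (PpcA–E), where
group-level contrasts separate PpcA (the only deoxycholate binder) and the
structurally divergent PpcD from the rest; the reference count and pattern
tables for those five sequences ship with the package. It is intended for
sequence analysts who want reduced-alphabet, alignment-free comparisons of
small homolog families.

## Worked example

```python
import chemseq as cs

# percent composition and dissimilarity from the packaged count tables
vectors = [cs.composition_from_counts(v) for v in cs.cytochrome_count_vectors()]
by_id = {v.id: v for v in vectors}
print([round(p, 4) for p in by_id["PpcA"].percents])
# [10.989, 27.4725, 4.3956, 36.2637, 4.3956, 10.989, 3.2967, 2.1978]

print(round(cs.dissimilarity(by_id["PpcA"], by_id["PpcB"]), 4))
# 17.5824      (acidic term alone: |10.9890 - 8.7912| = 2.1978)

D = cs.dissimilarity_matrix(vectors)
tree = cs.single_linkage(D)
print([round(h, 4) for h in tree.heights])
# [11.8535, 12.0391, 16.5313, 17.5824]
print(cs.to_newick(tree))
# ((PpcB:6.01954,PpcE:6.01954):2.77167,(PpcA:8.26565,(PpcC:5.92677,PpcD:5.92677):2.33887):0.525561);
```

PpcC and PpcD merge first (11.85% apart), then PpcB with PpcE (12.04%);
PpcA joins the (PpcC, PpcD) cluster at 16.53% and the root closes at
17.58%. The digraph/pattern layer works the same way:

```python
r = cs.encode_sequence(cs.AminoAcidSequence("block", "CKGCHE"))
print(str(r))                 # 624621
g = cs.build_digraph(r)
print(sorted(cs.edge_set(g))) # [(2, 1), (2, 4), (4, 6), (6, 2)]
```

All residue coordinates in every output are 1-based inclusive.

## Command line

`chemseq` exposes `encode`, `compose`, `dissim`, `tree`, `graph`, `cycles`,
`patterns`, `compare`, `synth` and the all-in-one `characterize`:

```
chemseq characterize sequences.fasta --outdir out/
chemseq compare sequences.fasta --group-a PpcA --group-b PpcB,PpcC,PpcD,PpcE --kmer 4 --outdir out/
chemseq synth --length 91 --counts 10,25,4,33,4,10,3,2 --seed 7
```

`characterize` writes the composition and dissimilarity TSVs, Newick tree,
merge table, per-sequence adjacency/DOT files, a cycle report and a JSON
summary.

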