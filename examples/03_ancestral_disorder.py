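"""Map N-terminal disorder length onto an ancestral reconstruction.

Simulates a peptide family descending from a root with a designed
eight-residue disordered prefix, reconstructs every ancestral sequence
by marginal ASR under the WAG model, and annotates each node of the
tree with its predicted N-terminal disorder length.
"""

from gammatail import (
    SubstitutionModel,
    annotate_disorder_lengths,
    estimate_frequencies,
    make_disordered_family,
    marginal_asr,
    read_newick,
    write_newick,
)
from gammatail.asr import node_label

tree = read_newick(
    "(((A:.03,B:.03):.03,(C:.03,D:.03):.03):.02,"
    "((E:.03,F:.03):.03,(G:.03,H:.03):.03):.02);"
)
leaves, record = make_disordered_family(tree, prefix_len=8, core_len=40,
                                        model=SubstitutionModel.wag(), seed=11)

pi = estimate_frequencies(leaves, pseudocount=0.5)
model = SubstitutionModel.wag(pi=pi)
rec = marginal_asr(tree, leaves, model)
lengths = annotate_disorder_lengths(tree, rec, leaves)

print(f"designed root prefix length: {record.truth['prefix_len']}")
print(f"tree log-likelihood: {rec.log_likelihood:.2f}\n")
for nd in tree.preorder_node_iter():
    label = node_label(nd)
    kind = "leaf" if nd.is_leaf() else "ancestor"
    print(f"  {label:4s} ({kind:8s})  N-terminal disorder length = {lengths[label]}")

annotated = write_newick(tree, {k: {"disorder_len": v} for k, v in lengths.items()})
print("\nannotated tree:\n" + annotated.strip())
print(
    "\nThe root's recovered disorder length should sit within a couple of "
    "residues of the designed 8-residue prefix at this divergence."
)
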