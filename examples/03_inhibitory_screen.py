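"""Find dicodons whose usage is lower than single-codon frequencies predict.

Compares each dicodon's directly estimated contribution with the product of
its codons' contributions (the expected value if pair usage were reducible
to codon usage).  Pairs with observed/expected far below 1 are specifically
avoided; in the simulation these are the planted inhibitory dicodons, and
in real genomes such pairs include experimentally confirmed translation
inhibitors.
"""

import numpy as np

import dicodex as dx

records, profile, truth = dx.simulate_genes(dx.SimulationParams(seed=1))
seqs = dx.qc_filter(records)
weights = dx.weights_from_expression(profile)
gene_ids = {s.gene_id for s in seqs}
planted = set(truth.inhibitory_dicodons)

# Observed vs expected on adaptiveness tables from the S_80 reference set.
ref = dx.select_reference_set(profile, gene_ids, 80)
ref_seqs = [s for s in seqs if s.gene_id in ref.gene_ids]
a_dicodon = dx.relative_adaptiveness(dx.count_tokens(ref_seqs, 2))
a_codon = dx.relative_adaptiveness(dx.count_tokens(ref_seqs, 1))
ratio = dx.expected_vs_observed(a_dicodon, a_codon).sort_values("ratio")

print("Most depleted dicodons (observed / expected-from-codon-product):")
print("token    observed  expected  ratio   planted?")
for _, row in ratio.head(12).iterrows():
    mark = "YES" if row["token"] in planted else ""
    print(f"{row['token']}  {row['observed']:.2e}  {row['expected']:.2e}"
          f"  {row['ratio']:5.3f}   {mark}")

decile = int(np.ceil(0.1 * len(ratio)))
in_decile = sum(tok in planted for tok in ratio["token"].head(decile))
print(f"\nplanted inhibitory pairs in the bottom ratio decile: {in_decile}/17")

# Low-contribution screen on the expression-weighted S_90 table, where the
# avoidance by highly expressed genes drives planted pairs toward zero.
ref90 = dx.select_reference_set(profile, gene_ids, 90)
ref_seqs90 = [s for s in seqs if s.gene_id in ref90.gene_ids]
f_dicodon = dx.relative_adaptiveness(
    dx.weighted_count_tokens(ref_seqs90, weights, 2)
)
screen = dx.low_contribution_screen(f_dicodon, threshold=1e-6,
                                    known_inhibitors=planted)
print(f"screen at f_d < 1e-6: {len(screen.flagged)} dicodons flagged, "
      f"{len(screen.known_overlap)}/17 planted pairs among them")
print("A flagged dicodon is (nearly) unused by highly expressed genes —")
print("a candidate for mediating translational inhibition.")
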