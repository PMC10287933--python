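"""Compare the four index schemes across reference-set percentiles.

The four schemes are codon vs dicodon contributions, each with or without
expression weighting (weighted counts b_t = sum_i o_t(s_i) w(s_i), with
w = exp(E) for log-normalized expression).  Correlations with expression
level are also compared with a paired t-test across simulation replicates,
and the squared-contribution variant is shown for the full gene set S_0.
"""

import dicodex as dx


def scheme_table(seqs, profile, weights, p, arity, weighted, power=1):
    ref = dx.select_reference_set(profile, {s.gene_id for s in seqs}, p)
    ref_seqs = [s for s in seqs if s.gene_id in ref.gene_ids]
    counts = (dx.weighted_count_tokens(ref_seqs, weights, arity) if weighted
              else dx.count_tokens(ref_seqs, arity))
    table = dx.relative_adaptiveness(counts)
    return dx.power_transform(table, power) if power != 1 else table


def pearson(seqs, profile, weights, p, arity, weighted, power=1):
    table = scheme_table(seqs, profile, weights, p, arity, weighted, power)
    idx = dx.index_profile(seqs, table)
    return dx.correlate(idx, profile).r


schemes = [("codon      ", 1, False), ("codon  (w) ", 1, True),
           ("dicodon    ", 2, False), ("dicodon (w)", 2, True)]

r_codon, r_dicodon = [], []
for seed in (1, 2, 3):
    records, profile, _ = dx.simulate_genes(dx.SimulationParams(seed=seed))
    seqs = dx.qc_filter(records)
    weights = dx.weights_from_expression(profile)
    if seed == 1:
        print("Pearson r with expression level (seed 1):")
        print("scheme        " + "".join(f"  S_{p:<4}" for p in (97, 90, 80)))
        for label, arity, weighted in schemes:
            rs = [pearson(seqs, profile, weights, p, arity, weighted)
                  for p in (97, 90, 80)]
            print(f"{label}   " + "".join(f"{r:7.3f}" for r in rs))
        r_sq = pearson(seqs, profile, weights, 0, 2, True, power=2)
        r_plain = pearson(seqs, profile, weights, 0, 2, True)
        print(f"\nsquared weighted dicodon contributions on S_0: r = {r_sq:.3f}"
              f" (plain: {r_plain:.3f})")
    r_codon.append(pearson(seqs, profile, weights, 97, 1, True))
    r_dicodon.append(pearson(seqs, profile, weights, 97, 2, True))

diff, t, p_value = dx.paired_scheme_test(r_codon, r_dicodon)
print(f"\npaired t-test, dicodon vs codon (weighted, S_97, {len(r_codon)} replicates):")
print(f"  mean r gain = {diff:+.3f}, t = {t:.2f}, p = {p_value:.3g}")
print("Dicodon-based and expression-weighted schemes correlate better with")
print("expression because pair-level avoidance (planted inhibitory dicodons)")
print("carries information single-codon frequencies cannot express.")
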