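"""Independent brute-force oracles used by the tests.

Deliberately naive re-implementations (plain loops, no shared code paths
with the package) of token counting and per-class normalization.
"""

from collections import Counter

STOPS = {"TAA", "TAG", "TGA"}


def naive_codon_tokens(codons):
    return [c for c in list(codons)[1:] if c not in STOPS]


def naive_dicodon_tokens(codons):
    codons = list(codons)
    out = []
    for i in range(len(codons) - 1):
        if i == 0:
            continue  # first dicodon discarded
        a, b = codons[i], codons[i + 1]
        if a in STOPS or b in STOPS:
            continue
        out.append(a + b)
    return out


def naive_counts(seqs, arity, weights=None):
    """Per-sequence recount; weights=None gives plain counts."""
    total = Counter()
    for seq in seqs:
        tokens = (
            naive_codon_tokens(seq.codons)
            if arity == 1
            else naive_dicodon_tokens(seq.codons)
        )
        w = 1.0 if weights is None else weights[seq.gene_id]
        for tok in tokens:
            total[tok] += w
    return dict(total)


def naive_class_normalize(counts_by_token, classes):
    """max/divide per synonymy class, no pseudo-counts or flooring."""
    out = {}
    for members in classes.values():
        cmax = max(counts_by_token.get(t, 0.0) for t in members)
        for t in members:
            out[t] = counts_by_token.get(t, 0.0) / cmax if cmax > 0 else 0.0
    return out


def random_toy_set(rng, n_seqs=None, code=None):
    """A random list of CodingSequence objects (<= 10, lengths 3..30)."""
    import dicodex as dx

    code = code or dx.STANDARD_CODE
    sense = list(code.sense_codons)
    n_seqs = n_seqs or int(rng.integers(1, 11))
    seqs = []
    for i in range(n_seqs):
        L = int(rng.integers(3, 31))
        codons = tuple(sense[j] for j in rng.integers(0, len(sense), size=L))
        seqs.append(dx.CodingSequence(f"t{i}", codons, L))
    return seqs
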