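"""Independent brute-force oracles used by the equivalence checks."""

from bisect import bisect_left, bisect_right


def cluster_doomed(positions, window=35, min_snvs=3):
    """All-windows scan: an SNV is removed iff some window of `window`
    consecutive bases contains at least `min_snvs` SNVs including it."""
    pos = sorted(set(positions))
    doomed = set()
    for p in pos:
        for start in range(p - window + 1, p + 1):
            lo = bisect_left(pos, start)
            hi = bisect_right(pos, start + window - 1)
            if hi - lo >= min_snvs:
                doomed.update(pos[lo:hi])
    return doomed


def compare_counts(profile_calls, reference_variants):
    """Position-by-position dict scan returning (overlap, match)."""
    ref_by_pos = {}
    for v in reference_variants:
        ref_by_pos.setdefault(v.position, set()).add(v.mut_allele)
    overlap = match = 0
    for pos, call in profile_calls.items():
        if pos not in ref_by_pos:
            continue
        overlap += 1
        if ref_by_pos[pos] & set(call.called_alleles):
            match += 1
    return overlap, match
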