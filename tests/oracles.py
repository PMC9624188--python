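"""Independent closed-form oracles used to check Monte-Carlo machinery.

These are written directly from sampling theory, not from the package's code
paths, and use exact integer arithmetic where possible.
"""

from math import comb

from gramprod.paradigms import Paradigm, normalize_marker
from gramprod.token_io import TokenSample


def expected_distinct_count(category_counts, n, k) -> float:
    """Expected number of distinct categories captured by a uniform
    without-replacement subsample of size k from a multiset of n items, where
    ``category_counts`` are the per-category multiplicities.

    Multivariate hypergeometric: each category with count c is missed with
    probability C(n-c, k) / C(n, k), so
    E[distinct] = sum_c (1 - C(n-c, k) / C(n, k)).
    """
    total = comb(n, k)
    out = 0.0
    for c in category_counts:
        missed = comb(n - c, k) if n - c >= k else 0
        out += 1.0 - missed / total
    return out


def distinct_count_variance(category_counts, n, k) -> float:
    """Exact variance of the distinct-category count under the same
    without-replacement model, via inclusion indicators I_m:

    Var = sum_m p_m(1-p_m) + 2 sum_{m<m'} [P(both) - p_m p_m'],
    P(miss m) = C(n-c_m, k)/C(n, k),
    P(miss both) = C(n-c_m-c_m', k)/C(n, k).
    """
    total = comb(n, k)

    def p_miss(c):
        return comb(n - c, k) / total if n - c >= k else 0.0

    cs = list(category_counts)
    ps = [1.0 - p_miss(c) for c in cs]
    var = sum(p * (1.0 - p) for p in ps)
    for i in range(len(cs)):
        for j in range(i + 1, len(cs)):
            p_both = 1.0 - p_miss(cs[i]) - p_miss(cs[j]) + p_miss(cs[i] + cs[j])
            var += 2.0 * (p_both - ps[i] * ps[j])
    return max(var, 0.0)


def expected_creativity_by_lemma(
    sample: TokenSample, paradigm: Paradigm, k: int
) -> dict[str, float]:
    """Expected per-lemma distinct-slot count at subsample size k.

    Counts (lemma, slot) multiplicities in the full sample and applies the
    hypergeometric inclusion formula per lemma.  This is the rarefaction
    expectation the averaged profile estimates under absent_policy='zero'.
    """
    counts: dict[str, dict[str, int]] = {}
    for t in sample:
        slot = normalize_marker(paradigm, t.marker)
        by_slot = counts.setdefault(t.lemma, {})
        by_slot[slot] = by_slot.get(slot, 0) + 1
    n = sample.n_tokens
    return {
        lemma: expected_distinct_count(list(by_slot.values()), n, k)
        for lemma, by_slot in counts.items()
    }
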