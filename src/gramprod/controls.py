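"""The two comparison hazards and their controls.

Comparing raw creativity across two speakers confounds grammar with two
nuisances: the *lexical hazard* (LH) — a larger vocabulary offers more lemmas
to combine — and the *sample hazard* (SH) — a larger sample catches more
combinations by exposure alone.  LH is controlled by restricting both samples
to their shared lemma set; SH by drawing many size-matched random subsamples
(without replacement) of the larger sample and averaging, a rarefaction-style
correction.  LH is applied before SH: lemmas absent from one side are removed
first, then subsamples are drawn from the filtered larger sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MatchSizeError, NoSharedLexemesError
from .token_io import TokenSample

__all__ = [
    "ControlConfig",
    "shared_lexicon_filter",
    "resolve_match_size",
    "draw_subsamples",
]

#: match-size policies: use sample 1's size before LH filtering (the default,
#: matching how published token counts line up), after filtering, or an
#: explicit integer.
_POLICIES = ("prefilter_sample1", "postfilter_sample1")


@dataclass
class ControlConfig:
    """Settings for the SH control and downstream randomness.

    ``n_subsamples`` random size-matched draws are averaged (default 1,000).
    ``match_size_policy`` picks the common size: sample 1's unfiltered token
    count (``prefilter_sample1``, default), its post-LH count
    (``postfilter_sample1``), or an explicit positive integer.
    ``absent_policy`` says what a draw without any token of a lemma
    contributes to that lemma's average: 0 (``zero``, the rarefaction
    expectation) or nothing (``skip``).  ``seed`` feeds the single random
    stream used for subsampling and bootstrapping.
    """

    n_subsamples: int = 1000
    match_size_policy: str | int = "prefilter_sample1"
    absent_policy: str = "zero"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subsamples < 1:
            raise ValueError("n_subsamples must be >= 1")
        if isinstance(self.match_size_policy, bool) or (
            isinstance(self.match_size_policy, int) and self.match_size_policy < 1
        ):
            raise ValueError("explicit match size must be a positive integer")
        if isinstance(self.match_size_policy, str) and self.match_size_policy not in _POLICIES:
            raise ValueError(
                f"match_size_policy must be one of {_POLICIES} or a positive integer, "
                f"got {self.match_size_policy!r}"
            )
        if self.absent_policy not in ("zero", "skip"):
            raise ValueError("absent_policy must be 'zero' or 'skip'")


def shared_lexicon_filter(
    s1: TokenSample, s2: TokenSample
) -> tuple[TokenSample, TokenSample]:
    """Restrict both samples to lemmas attested in each (the LH control).

    Tokens whose lemma is missing from the other sample are dropped; token
    order is preserved and the operation is idempotent.  Raises
    :class:`NoSharedLexemesError` when the vocabularies are disjoint.
    """
    shared = s1.lemma_set & s2.lemma_set
    if not shared:
        raise NoSharedLexemesError(
            f"no shared lexemes between {s1.label!r} ({s1.n_lemmas} lemmas) "
            f"and {s2.label!r} ({s2.n_lemmas} lemmas)"
        )
    f1 = TokenSample(tuple(t for t in s1 if t.lemma in shared), label=s1.label)
    f2 = TokenSample(tuple(t for t in s2 if t.lemma in shared), label=s2.label)
    return f1, f2


def resolve_match_size(
    s1_original: TokenSample,
    s1_filtered: TokenSample,
    cfg: ControlConfig,
    upper_bound: int | None = None,
) -> int:
    """Resolve the common subsample size k from the configured policy.

    ``upper_bound``, when given, is the filtered larger sample's token count;
    a k that cannot be drawn from it raises :class:`MatchSizeError`.
    """
    policy = cfg.match_size_policy
    if policy == "prefilter_sample1":
        k = s1_original.n_tokens
    elif policy == "postfilter_sample1":
        k = s1_filtered.n_tokens
    else:
        k = int(policy)
    if k < 1:
        raise MatchSizeError(f"resolved match size {k} is not positive")
    if upper_bound is not None and k > upper_bound:
        raise MatchSizeError(
            f"cannot subsample {k} tokens from a filtered sample of {upper_bound}"
        )
    return k


def draw_index_sets(
    n: int, k: int, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n_draws`` sorted index sets of size k from range(n), without
    replacement within each draw.  Shared by :func:`draw_subsamples` and the
    averaged-creativity computation so both consume the random stream
    identically."""
    if not 1 <= k <= n:
        raise MatchSizeError(f"cannot subsample {k} tokens from {n}")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    out = np.empty((n_draws, k), dtype=np.int64)
    for i in range(n_draws):
        out[i] = np.sort(rng.choice(n, size=k, replace=False))
    return out


def draw_subsamples(
    sample: TokenSample,
    k: int,
    n_draws: int,
    seed: int | np.random.Generator,
) -> list[TokenSample]:
    """Materialize ``n_draws`` uniform size-k subsamples (without replacement).

    Each subsample keeps the original token order.  Fully reproducible: a
    fixed integer seed yields an identical sequence of draws.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = draw_index_sets(sample.n_tokens, k, n_draws, rng)
    toks = sample.tokens
    return [
        TokenSample(tuple(toks[j] for j in row), label=f"{sample.label}[sub{i}]")
        for i, row in enumerate(idx)
    ]
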