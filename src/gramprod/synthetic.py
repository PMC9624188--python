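"""Synthetic corpus generator with the statistical structure the estimator assumes.

Spontaneous-speech token lists have two salient properties: lemma frequencies
follow a Zipf-like power law (a handful of verbs carry most of the tokens),
and each lemma spreads its uses over the agreement paradigm to a degree that
varies from fully trite (one form only) to fully productive (all K slots).
The generator models exactly those two facts and nothing else:

* lemma probabilities are proportional to ``rank^(-zipf_exponent)``;
* each lemma receives a private slot-usage distribution drawn once from a
  Dirichlet with parameters ``concentration x slot_base_probs`` — a small
  concentration locks lemmas onto single slots (triteness ~ 100%), a large
  one approaches the base distribution for every lemma (creativity ~ K);
* tokens are drawn i.i.d. (lemma first, then slot given lemma), with
  transcript indices assigned in consecutive blocks so chronological
  splitting can be exercised.

Markers are emitted as slot labels, so generated samples are already
normalized under their paradigm.  Paired designs share a configurable
fraction of the lemma inventory (the shared lemmas occupy the top Zipf ranks
of both samples); the true productivity difference between the members of a
pair is governed entirely by their two concentrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .paradigms import Paradigm, load_paradigm
from .token_io import Token, TokenSample

__all__ = ["SyntheticConfig", "generate_sample", "generate_pair", "skewed_slot_probs"]


def skewed_slot_probs(paradigm: Paradigm, dominant_share: float = 0.5) -> np.ndarray:
    """A skewed base distribution giving ``dominant_share`` of probability to
    the third-singular slot (the workhorse of colloquial speech) and the rest
    uniformly to the others.  Preset for realism in power studies."""
    k = paradigm.max_creativity
    probs = np.full(k, (1.0 - dominant_share) / (k - 1))
    slots = list(paradigm.slots)
    dom = slots.index("3SG") if "3SG" in slots else 0
    probs[dom] = dominant_share
    return probs


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic sample.

    ``concentration`` is the per-lemma usage-spread knob: the Dirichlet
    concentration multiplying ``slot_base_probs``.  Values well below 1 give
    trite single-form lemmas; values well above 1 give full-paradigm use.
    ``slot_base_probs`` defaults to uniform over the paradigm's slots.
    """

    n_lemmas: int
    n_tokens: int
    paradigm: Paradigm | str = "es-pres-ind"
    zipf_exponent: float = 1.0
    slot_base_probs: np.ndarray | None = None
    concentration: float = 1.0
    seed: int = 0
    n_transcripts: int = 10
    label: str = "synthetic"

    def __post_init__(self) -> None:
        if isinstance(self.paradigm, str):
            self.paradigm = load_paradigm(self.paradigm)
        if self.n_lemmas < 1 or self.n_tokens < 1:
            raise ValueError("n_lemmas and n_tokens must be positive")
        if self.zipf_exponent < 0:
            raise ValueError("zipf_exponent must be >= 0")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        if self.n_transcripts < 1:
            raise ValueError("n_transcripts must be >= 1")
        k = self.paradigm.max_creativity
        if self.slot_base_probs is None:
            self.slot_base_probs = np.full(k, 1.0 / k)
        else:
            self.slot_base_probs = np.asarray(self.slot_base_probs, dtype=float)
            if self.slot_base_probs.shape != (k,):
                raise ValueError(f"slot_base_probs must have length {k}")
            if np.any(self.slot_base_probs < 0):
                raise ValueError("slot_base_probs must be non-negative")
            if abs(self.slot_base_probs.sum() - 1.0) > 1e-9:
                raise ValueError("slot_base_probs must sum to 1 (within 1e-9)")


def _zipf_probs(n_lemmas: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, n_lemmas + 1, dtype=float)
    w = ranks ** (-exponent)
    return w / w.sum()


def _draw_tokens(
    cfg: SyntheticConfig, lemma_names: list[str], rng: np.random.Generator
) -> TokenSample:
    paradigm = cfg.paradigm
    assert isinstance(paradigm, Paradigm)
    k = paradigm.max_creativity
    lemma_probs = _zipf_probs(cfg.n_lemmas, cfg.zipf_exponent)
    # one slot-usage distribution per lemma, drawn once
    alpha = cfg.concentration * np.asarray(cfg.slot_base_probs)
    slot_dists = rng.dirichlet(np.maximum(alpha, 1e-12), size=cfg.n_lemmas)
    lemma_ids = rng.choice(cfg.n_lemmas, size=cfg.n_tokens, p=lemma_probs)
    u = rng.random(cfg.n_tokens)
    cum = np.cumsum(slot_dists, axis=1)
    cum[:, -1] = 1.0
    slot_ids = (u[:, None] > cum[lemma_ids]).sum(axis=1)
    slot_ids = np.minimum(slot_ids, k - 1)
    # transcript indices in consecutive equal blocks
    block = math.ceil(cfg.n_tokens / cfg.n_transcripts)
    tokens = tuple(
        Token(lemma_names[li], paradigm.slots[si], transcript_index=j // block)
        for j, (li, si) in enumerate(zip(lemma_ids, slot_ids))
    )
    return TokenSample(tokens, label=cfg.label)


def generate_sample(
    cfg: SyntheticConfig, lemma_names: list[str] | None = None
) -> TokenSample:
    """Generate one token sample from a :class:`SyntheticConfig`.

    Reproducible: the same config (including seed) always yields the same
    sample.  ``lemma_names`` overrides the default ``v0001``-style inventory,
    in Zipf-rank order.
    """
    if lemma_names is None:
        lemma_names = [f"v{i:04d}" for i in range(cfg.n_lemmas)]
    elif len(lemma_names) != cfg.n_lemmas:
        raise ValueError("lemma_names must have length n_lemmas")
    rng = np.random.default_rng(cfg.seed)
    return _draw_tokens(cfg, lemma_names, rng)


def generate_pair(
    cfg1: SyntheticConfig,
    cfg2: SyntheticConfig,
    shared_lexicon_fraction: float = 1.0,
) -> tuple[TokenSample, TokenSample]:
    """Generate a two-sample design with a controlled lexical overlap.

    Exactly ``ceil(fraction x min(n_lemmas))`` lemmas are shared between the
    two inventories (they occupy the top Zipf ranks of both samples, as
    frequent verbs are the ones both speakers use); the rest are
    sample-private, exercising the lexical-hazard filter.  The true
    productivity gap is set by ``cfg2.concentration - cfg1.concentration``.
    With fraction 0 the samples are lexically disjoint.
    """
    if not 0.0 <= shared_lexicon_fraction <= 1.0:
        raise ValueError("shared_lexicon_fraction must be in [0, 1]")
    n_shared = math.ceil(shared_lexicon_fraction * min(cfg1.n_lemmas, cfg2.n_lemmas))
    shared = [f"v{i:04d}" for i in range(n_shared)]
    names1 = shared + [f"a{i:04d}" for i in range(cfg1.n_lemmas - n_shared)]
    names2 = shared + [f"b{i:04d}" for i in range(cfg2.n_lemmas - n_shared)]
    return generate_sample(cfg1, names1), generate_sample(cfg2, names2)
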