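"""Creativity (CRE) and triteness (TRI) statistics.

Per-lemma *creativity* is the number of distinct paradigm slots a lemma is
attested with — an integer in ``[1, K]`` for a single sample.  Sample-level
CRE is the mean of these values across lemma types ("inflections per verb");
*triteness* is the percentage of lemma types stuck in exactly one slot.  Under
the sample-hazard control, creativity is instead the mean over many
size-matched subsamples of the per-draw distinct-slot count, giving a
real-valued rarefied profile; TRI is still taken from the full filtered
sample, since random subsampling does not change which lemmas are one-form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .controls import ControlConfig, draw_index_sets
from .errors import EmptySampleError
from .paradigms import Paradigm, normalize_marker
from .token_io import TokenSample

__all__ = [
    "PerLemmaProfile",
    "ProductivityResult",
    "per_lemma_creativity",
    "averaged_profile",
    "summarize",
]


@dataclass(frozen=True)
class PerLemmaProfile:
    """Creativity per lemma: integer counts for one sample, real means when
    averaged across subsample draws."""

    values: Mapping[str, float]
    n_draws: int = 1
    absent_policy: str = "zero"

    def __post_init__(self) -> None:
        if not self.values:
            raise EmptySampleError("empty per-lemma profile")

    @property
    def lemmas(self) -> tuple[str, ...]:
        return tuple(sorted(self.values))

    def as_array(self) -> np.ndarray:
        return np.asarray([self.values[v] for v in self.lemmas], dtype=float)


@dataclass(frozen=True)
class ProductivityResult:
    """One report row: control condition, CRE mean/sd, counts, TRI percent."""

    control: str
    label: str
    cre_mean: float
    cre_sd: float
    n_tokens: int
    n_lemmas: int
    tri_pct: float


def per_lemma_creativity(
    sample: TokenSample, paradigm: Paradigm, strict: bool = False
) -> PerLemmaProfile:
    """Count the distinct agreement slots attested with each lemma.

    Markers are slot-normalized first, so allomorphs of one slot count once;
    multiplicities are irrelevant.  Every lemma of the sample appears in the
    result with a value in ``[1, K]``.
    """
    if sample.n_tokens == 0:
        raise EmptySampleError("cannot profile an empty sample")
    slots: dict[str, set[str]] = {}
    for t in sample:
        slots.setdefault(t.lemma, set()).add(normalize_marker(paradigm, t.marker, strict=strict))
    return PerLemmaProfile({v: float(len(s)) for v, s in slots.items()})


def _encode(sample: TokenSample, paradigm: Paradigm, strict: bool) -> tuple[
    list[str], np.ndarray, np.ndarray, int
]:
    """Integer-encode tokens as (lemma id, slot id) for vectorized counting."""
    lemmas = sorted(sample.lemma_set)
    lemma_id = {v: i for i, v in enumerate(lemmas)}
    slot_id: dict[str, int] = {}
    li = np.empty(sample.n_tokens, dtype=np.int64)
    si = np.empty(sample.n_tokens, dtype=np.int64)
    for j, t in enumerate(sample):
        li[j] = lemma_id[t.lemma]
        s = normalize_marker(paradigm, t.marker, strict=strict)
        si[j] = slot_id.setdefault(s, len(slot_id))
    return lemmas, li, si, max(len(slot_id), 1)


def averaged_profile(
    sample2_filtered: TokenSample,
    k: int,
    cfg: ControlConfig,
    paradigm: Paradigm,
    rng: np.random.Generator | None = None,
    strict: bool = False,
) -> PerLemmaProfile:
    """Rarefied creativity: per-lemma distinct-slot counts averaged over
    ``cfg.n_subsamples`` random size-k subsamples (the SH control).

    A draw containing no token of a lemma contributes 0 under
    ``absent_policy="zero"`` (making the average a Monte-Carlo estimate of the
    expected creativity at sample size k) or is left out of that lemma's
    average under ``"skip"``.  With ``k`` equal to the full sample size every
    draw is the whole sample and the integer profile is recovered exactly.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lemmas, li, si, n_slot_codes = _encode(sample2_filtered, paradigm, strict)
    n = sample2_filtered.n_tokens
    pair = li * n_slot_codes + si
    n_lemmas = len(lemmas)
    sums = np.zeros(n_lemmas)
    present = np.zeros(n_lemmas, dtype=np.int64)
    idx = draw_index_sets(n, k, cfg.n_subsamples, rng)
    for row in idx:
        counts = np.bincount(np.unique(pair[row]) // n_slot_codes, minlength=n_lemmas)
        sums += counts
        present += counts > 0
    if cfg.absent_policy == "zero":
        values = sums / cfg.n_subsamples
    else:
        # skip: average over draws where the lemma appeared; a lemma missed by
        # every draw (possible only for very rare lemmas at tiny k) reports 0
        values = np.where(present > 0, sums / np.maximum(present, 1), 0.0)
    return PerLemmaProfile(
        dict(zip(lemmas, values.tolist())),
        n_draws=cfg.n_subsamples,
        absent_policy=cfg.absent_policy,
    )


def summarize(
    profile: PerLemmaProfile,
    n_tokens: int,
    control: str,
    label: str = "",
    tri_profile: PerLemmaProfile | None = None,
) -> ProductivityResult:
    """Collapse a per-lemma profile into one report row.

    CRE mean and sd are taken across lemma types (sd with the n-1
    denominator; 0 for a single lemma).  TRI is the percentage of lemmas
    attested in exactly one slot, computed from ``tri_profile`` when given —
    used for subsample-averaged rows, where one-form status is a property of
    the full filtered sample, not of any random draw.
    """
    vals = profile.as_array()
    cre_mean = float(vals.mean())
    cre_sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    tri_vals = (tri_profile or profile).as_array()
    tri_pct = 100.0 * float(np.sum(tri_vals == 1.0)) / tri_vals.size
    return ProductivityResult(
        control=control,
        label=label,
        cre_mean=cre_mean,
        cre_sd=cre_sd,
        n_tokens=int(n_tokens),
        n_lemmas=len(profile.values),
        tri_pct=tri_pct,
    )
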