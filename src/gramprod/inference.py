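"""Verb-by-verb differences and nonparametric bootstrap confidence intervals.

After the lexical control both samples share one lemma set, so creativity can
be differenced lemma by lemma: ``delta_v = CRE_2(v) - CRE_1(v)`` with sample 2
conventionally the larger/adult/later sample.  Inference on the mean
difference M uses the ordinary nonparametric bootstrap — R resamples of the
delta vector with replacement, statistic = mean — with two interval methods:

* **percentile** — the empirical (α/2, 1−α/2) quantiles of the replicate
  means, type-1 (inverse-ECDF) quantile rule;
* **BCa** — bias-corrected and accelerated: the bias correction
  ``z0 = Φ⁻¹(#{θ* < θ̂}/R)`` and the acceleration ``a`` from the jackknife
  skewness of the mean, ``a = Σ(θ̄−θᵢ)³ / (6[Σ(θ̄−θᵢ)²]^{3/2})``, shift the
  quantile levels to ``α_j = Φ(z0 + (z0+z_j)/(1−a(z0+z_j)))``.

A constant delta vector yields a degenerate interval ``[c, c]`` with a flag
rather than an error; when every replicate falls on one side of the observed
mean the z0 count is clamped to ``[1, R−1]`` and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .controls import ControlConfig, resolve_match_size, shared_lexicon_filter
from .errors import LemmaMismatchError
from .paradigms import Paradigm
from .productivity import (
    PerLemmaProfile,
    ProductivityResult,
    averaged_profile,
    per_lemma_creativity,
    summarize,
)
from .token_io import TokenSample

__all__ = [
    "DifferenceVector",
    "BootstrapCI",
    "difference_vector",
    "bootstrap_mean_ci",
    "bootstrap_mean_cis",
    "compare_samples",
]


@dataclass(frozen=True)
class DifferenceVector:
    """Per-lemma creativity differences (profile 2 minus profile 1)."""

    lemmas: tuple[str, ...]
    deltas: tuple[float, ...]

    @property
    def mean(self) -> float:
        return float(np.mean(self.deltas))

    @property
    def sd(self) -> float:
        d = np.asarray(self.deltas)
        return float(d.std(ddof=1)) if d.size > 1 else 0.0

    def __len__(self) -> int:
        return len(self.deltas)


@dataclass(frozen=True)
class BootstrapCI:
    """A bootstrap interval for the mean difference."""

    method: str
    level: float
    low: float
    high: float
    n_replicates: int
    observed_mean: float
    seed: int | None = None
    degenerate: bool = False
    z0_clamped: bool = False


def difference_vector(
    profile1: PerLemmaProfile, profile2: PerLemmaProfile
) -> DifferenceVector:
    """Align two per-lemma profiles and subtract (profile2 − profile1).

    Both profiles must cover the same lemma set — guaranteed after the
    lexical control — and the result is ordered lexicographically by lemma.
    """
    l1, l2 = set(profile1.values), set(profile2.values)
    if l1 != l2:
        diff = sorted(l1 ^ l2)
        raise LemmaMismatchError(
            f"profiles differ on {len(diff)} lemmas, e.g. {diff[:10]}"
        )
    lemmas = tuple(sorted(l1))
    deltas = tuple(
        float(profile2.values[v]) - float(profile1.values[v]) for v in lemmas
    )
    return DifferenceVector(lemmas=lemmas, deltas=deltas)


def _type1_quantile(sorted_reps: np.ndarray, q: float) -> float:
    """Nearest-order-statistic (inverse ECDF) quantile of sorted replicates."""
    r = sorted_reps.size
    # round before ceil so float round-trips (e.g. cdf(ppf(q))) cannot shift
    # the index across an exact integer boundary
    i = int(np.ceil(round(q * r, 8))) - 1
    return float(sorted_reps[min(max(i, 0), r - 1)])


def _jackknife_acceleration(deltas: np.ndarray) -> float:
    n = deltas.size
    theta_i = (deltas.sum() - deltas) / (n - 1)
    d = theta_i.mean() - theta_i
    denom = 6.0 * (np.sum(d**2) ** 1.5)
    if denom == 0.0:
        return 0.0
    return float(np.sum(d**3) / denom)


def _bca_levels(z0: float, a: float, level: float) -> tuple[float, float]:
    alpha = 1.0 - level
    out = []
    for z in (norm.ppf(alpha / 2.0), norm.ppf(1.0 - alpha / 2.0)):
        t = z0 + z
        out.append(float(norm.cdf(z0 + t / (1.0 - a * t))))
    return out[0], out[1]


def _interval_from_reps(
    reps_sorted: np.ndarray,
    deltas: np.ndarray,
    observed: float,
    method: str,
    level: float,
    z0_override: float | None = None,
    accel_override: float | None = None,
) -> tuple[float, float, bool]:
    r = reps_sorted.size
    alpha = 1.0 - level
    if method == "percentile":
        return (
            _type1_quantile(reps_sorted, alpha / 2.0),
            _type1_quantile(reps_sorted, 1.0 - alpha / 2.0),
            False,
        )
    if method != "bca":
        raise ValueError(f"unknown CI method {method!r}")
    clamped = False
    if z0_override is not None:
        z0 = z0_override
    else:
        below = int(np.count_nonzero(reps_sorted < observed))
        if below < 1 or below > r - 1:
            below = min(max(below, 1), r - 1)
            clamped = True
        z0 = float(norm.ppf(below / r))
    a = _jackknife_acceleration(deltas) if accel_override is None else accel_override
    a1, a2 = _bca_levels(z0, a, level)
    lo = _type1_quantile(reps_sorted, a1)
    hi = _type1_quantile(reps_sorted, a2)
    if lo > hi:  # can only happen via extreme overrides; keep the contract
        lo, hi = hi, lo
    return lo, hi, clamped


def _replicate_means(
    deltas: np.ndarray, n_replicates: int, rng: np.random.Generator
) -> np.ndarray:
    n = deltas.size
    # chunked so R x n never exceeds a few million cells
    chunk = max(1, int(4_000_000 / n))
    means = np.empty(n_replicates)
    for start in range(0, n_replicates, chunk):
        stop = min(start + chunk, n_replicates)
        idx = rng.integers(0, n, size=(stop - start, n))
        means[start:stop] = deltas[idx].mean(axis=1)
    return means


def bootstrap_mean_ci(
    dv: DifferenceVector | np.ndarray,
    method: str = "bca",
    level: float = 0.95,
    n_replicates: int = 10_000,
    seed: int | np.random.Generator = 0,
    z0_override: float | None = None,
    accel_override: float | None = None,
) -> BootstrapCI:
    """Bootstrap CI for the mean of a difference vector.

    ``method`` is ``"percentile"`` or ``"bca"``.  ``z0_override`` and
    ``accel_override`` inject fixed bias-correction/acceleration values for
    diagnostics (both zero reduces BCa to the percentile method exactly).
    Reproducible for a fixed integer seed.
    """
    deltas = np.asarray(dv.deltas if isinstance(dv, DifferenceVector) else dv, dtype=float)
    if deltas.size < 2:
        raise ValueError("need at least two per-lemma differences")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if n_replicates < 100:
        raise ValueError("n_replicates must be >= 100")
    observed = float(deltas.mean())
    seed_val = seed if isinstance(seed, int) else None
    if np.ptp(deltas) == 0.0:
        return BootstrapCI(
            method=method,
            level=level,
            low=observed,
            high=observed,
            n_replicates=n_replicates,
            observed_mean=observed,
            seed=seed_val,
            degenerate=True,
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reps = np.sort(_replicate_means(deltas, n_replicates, rng))
    lo, hi, clamped = _interval_from_reps(
        reps, deltas, observed, method, level, z0_override, accel_override
    )
    return BootstrapCI(
        method=method,
        level=level,
        low=lo,
        high=hi,
        n_replicates=n_replicates,
        observed_mean=observed,
        seed=seed_val,
        z0_clamped=clamped,
    )


def bootstrap_mean_cis(
    dv: DifferenceVector | np.ndarray,
    level: float = 0.95,
    n_replicates: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> tuple[BootstrapCI, BootstrapCI]:
    """BCa and percentile intervals computed from one shared replicate set."""
    deltas = np.asarray(dv.deltas if isinstance(dv, DifferenceVector) else dv, dtype=float)
    if deltas.size < 2:
        raise ValueError("need at least two per-lemma differences")
    observed = float(deltas.mean())
    seed_val = seed if isinstance(seed, int) else None
    if np.ptp(deltas) == 0.0:
        deg = [
            BootstrapCI(m, level, observed, observed, n_replicates, observed,
                        seed=seed_val, degenerate=True)
            for m in ("bca", "percentile")
        ]
        return deg[0], deg[1]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reps = np.sort(_replicate_means(deltas, n_replicates, rng))
    out = []
    for m in ("bca", "percentile"):
        lo, hi, clamped = _interval_from_reps(reps, deltas, observed, m, level)
        out.append(
            BootstrapCI(m, level, lo, hi, n_replicates, observed,
                        seed=seed_val, z0_clamped=clamped)
        )
    return out[0], out[1]


def compare_samples(
    s1: TokenSample,
    s2: TokenSample,
    paradigm: Paradigm,
    cfg: ControlConfig | None = None,
    level: float = 0.95,
    n_bootstrap: int = 10_000,
    strict: bool = False,
) -> tuple[list[ProductivityResult], DifferenceVector, tuple[BootstrapCI, BootstrapCI]]:
    """Run the full two-sample pipeline.

    Sample 1 is the reference (typically the child or the earlier occasion):
    it sets the match size.  Sample 2 (parent / later occasion) is filtered,
    subsampled and averaged.  Returns the five descriptive rows in report
    order — no control for each sample, lexical control for each sample, and
    the lexically+size-controlled row for sample 2 — plus the per-lemma
    difference vector (averaged sample 2 minus lexically-filtered sample 1)
    and its (BCa, percentile) bootstrap intervals.  One seeded random stream
    drives subsampling then bootstrapping, so runs are bit-reproducible.
    """
    cfg = cfg or ControlConfig()
    rng = np.random.default_rng(cfg.seed)
    p1_full = per_lemma_creativity(s1, paradigm, strict=strict)
    p2_full = per_lemma_creativity(s2, paradigm, strict=strict)
    rows = [
        summarize(p1_full, s1.n_tokens, "None", s1.label),
        summarize(p2_full, s2.n_tokens, "None", s2.label),
    ]
    f1, f2 = shared_lexicon_filter(s1, s2)
    p1_lh = per_lemma_creativity(f1, paradigm, strict=strict)
    p2_lh = per_lemma_creativity(f2, paradigm, strict=strict)
    rows += [
        summarize(p1_lh, f1.n_tokens, "LH", f1.label),
        summarize(p2_lh, f2.n_tokens, "LH", f2.label),
    ]
    k = resolve_match_size(s1, f1, cfg, upper_bound=f2.n_tokens)
    p2_avg = averaged_profile(f2, k, cfg, paradigm, rng=rng, strict=strict)
    rows.append(summarize(p2_avg, k, "LH and SH", f2.label, tri_profile=p2_lh))
    dv = difference_vector(p1_lh, p2_avg)
    ci_bca, ci_pct = bootstrap_mean_cis(dv, level=level, n_replicates=n_bootstrap, seed=rng)
    ci_bca = BootstrapCI(**{**ci_bca.__dict__, "seed": cfg.seed})
    ci_pct = BootstrapCI(**{**ci_pct.__dict__, "seed": cfg.seed})
    return rows, dv, (ci_bca, ci_pct)
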