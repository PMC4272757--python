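"""Binomial significance testing of transformations.

A transformation "significantly" affects an endpoint when its matched pairs
move the property in one direction more often than a fair coin would:

* continuous endpoints: ``p = P[Bin(N, 0.5) <= min(n_pos, n_neg)]`` over the
  N non-tied pairs (exact big-integer summation, no normal approximation);
* binary endpoints: ``p = min(P[Bin(N, n_pos/N) <= n~_pos],
  P[Bin(N, n_neg/N) <= n~_neg])`` comparing the active/inactive composition
  before and after the transformation;
* ``significance_level = -log10(p)``.

Multiple testing across the transformations of an endpoint is controlled
with the Holm-Bonferroni step-down procedure.  When model predictions
contribute pairs, their stated uncertainties feed a replica bootstrap that
discards transformations whose significance does not survive prediction
noise.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .index import PairDelta, Transformation

__all__ = [
    "TransformationStats",
    "pvalue_regression",
    "pvalue_classification",
    "significance_level",
    "holm_bonferroni",
    "bootstrap_significance",
    "significant_transformations",
    "null_fwer_simulation",
]

_MIN_P = 5e-324  # smallest positive float; exact tail probabilities are clamped here


def pvalue_regression(n_pos: int, n_neg: int) -> float:
    """Exact sign-test p-value ``P[Bin(N, 0.5) <= min(n_pos, n_neg)]``.

    ``n_pos``/``n_neg`` are the numbers of pairs increasing/decreasing the
    property; ties are excluded before calling.  Computed by exact integer
    summation of the binomial lower tail.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("counts must be nonnegative")
    n = n_pos + n_neg
    if n < 1:
        raise ValueError("p-value undefined for zero pairs")
    m = min(n_pos, n_neg)
    tail = sum(math.comb(n, k) for k in range(m + 1))
    p = tail / (1 << n)
    return max(p, _MIN_P)


def pvalue_classification(n_pos: int, n_neg: int, after_pos: int, after_neg: int) -> float:
    """Binomial p-value for a shift in active/inactive composition.

    ``n_pos``/``n_neg`` count active/inactive molecules before the
    transformation, ``after_pos``/``after_neg`` after it.  The null takes the
    before-composition as the success rate; the p-value is the smaller of the
    two lower-tail probabilities at the observed after-counts.  Degenerate
    rates 0 and 1 use the point-mass distribution.
    """
    if min(n_pos, n_neg, after_pos, after_neg) < 0:
        raise ValueError("counts must be nonnegative")
    n = n_pos + n_neg
    if n < 1:
        raise ValueError("p-value undefined for zero pairs")
    if after_pos + after_neg != n:
        raise ValueError("before/after totals must match")

    def lower_tail(k: int, rate: float) -> float:
        if rate <= 0.0:
            return 1.0
        if rate >= 1.0:
            return 1.0 if k >= n else 0.0
        return float(binom.cdf(k, n, rate))

    p = min(lower_tail(after_pos, n_pos / n), lower_tail(after_neg, n_neg / n))
    return max(p, _MIN_P)


def significance_level(p: float) -> float:
    """Log-scale significance: ``-log10(p)`` (0.01 -> 2, 0.001 -> 3)."""
    if not 0 < p <= 1:
        raise ValueError(f"p-value must lie in (0, 1], got {p}")
    return -math.log10(p)


def holm_bonferroni(pvalues: list[float], alpha: float = 0.05) -> list[bool]:
    """Holm step-down rejection flags, returned in input order.

    Sort ascending; reject the k-th smallest while ``p_(k) <= alpha/(m-k+1)``;
    stop at the first failure.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    for p in pvalues:
        if not 0 < p <= 1:
            raise ValueError(f"p-values must lie in (0, 1], got {p}")
    m = len(pvalues)
    flags = [False] * m
    order = sorted(range(m), key=lambda i: pvalues[i])
    for k, i in enumerate(order):
        if pvalues[i] <= alpha / (m - k):
            flags[i] = True
        else:
            break
    return flags


def _oriented(delta: PairDelta, sign: int) -> PairDelta:
    if sign >= 0:
        return delta
    return PairDelta(
        kind=delta.kind,
        value_a=delta.value_b,
        value_b=delta.value_a,
        provenance=delta.provenance,
        uncertainty_a=delta.uncertainty_b,
        uncertainty_b=delta.uncertainty_a,
    )


def _continuous_counts(deltas: list[PairDelta], tie_tol: float) -> tuple[int, int, int]:
    n_pos = sum(1 for d in deltas if d.delta > tie_tol)
    n_neg = sum(1 for d in deltas if d.delta < -tie_tol)
    return n_pos, n_neg, len(deltas) - n_pos - n_neg


def _binary_counts(deltas: list[PairDelta]) -> tuple[int, int, int, int, int, int]:
    n_pos = sum(1 for d in deltas if d.value_a == "active")
    after_pos = sum(1 for d in deltas if d.value_b == "active")
    n = len(deltas)
    deact = sum(1 for d in deltas if d.value_a == "active" and d.value_b == "inactive")
    act = sum(1 for d in deltas if d.value_a == "inactive" and d.value_b == "active")
    return n_pos, n - n_pos, after_pos, n - after_pos, act, deact


def _pvalue_from_deltas(deltas: list[PairDelta], kind: str, tie_tol: float) -> float | None:
    if kind == "continuous":
        n_pos, n_neg, _ = _continuous_counts(deltas, tie_tol)
        if n_pos + n_neg == 0:
            return None
        return pvalue_regression(n_pos, n_neg)
    n_pos, n_neg, after_pos, after_neg, _, _ = _binary_counts(deltas)
    return pvalue_classification(n_pos, n_neg, after_pos, after_neg)


def bootstrap_significance(
    deltas: list[PairDelta],
    n_replicas: int = 1000,
    seed: int = 0,
    tie_tol: float = 1e-9,
) -> float:
    """Median replica p-value under prediction-noise perturbation.

    Each replica perturbs every predicted value independently: continuous
    values get Gaussian noise with standard deviation equal to the stated
    prediction uncertainty; binary labels flip with probability equal to the
    stated misclassification probability.  Experimental values (uncertainty
    0) are never perturbed.  Fully reproducible from the seed.
    """
    if n_replicas < 1:
        raise ValueError("n_replicas must be >= 1")
    if not deltas:
        raise ValueError("no pair observations supplied")
    for d in deltas:
        if d.uncertainty_a is None or d.uncertainty_b is None:
            raise ValueError("predicted values must carry an uncertainty for the bootstrap")
    rng = np.random.default_rng(seed)
    kind = deltas[0].kind
    n = len(deltas)
    if kind == "continuous":
        base = np.array([d.delta for d in deltas])
        sd = np.array([d.uncertainty for d in deltas])
        noise = rng.standard_normal((n_replicas, n)) * sd
        rep = base + noise
        n_pos = (rep > tie_tol).sum(axis=1)
        n_neg = (rep < -tie_tol).sum(axis=1)
        total = n_pos + n_neg
        m = np.minimum(n_pos, n_neg)
        p = np.ones(n_replicas)
        nz = total > 0
        p[nz] = binom.cdf(m[nz], total[nz], 0.5)
    else:
        a = np.array([d.value_a == "active" for d in deltas])
        b = np.array([d.value_b == "active" for d in deltas])
        ua = np.array([d.uncertainty_a for d in deltas])
        ub = np.array([d.uncertainty_b for d in deltas])
        ra = a ^ (rng.random((n_replicas, n)) < ua)
        rb = b ^ (rng.random((n_replicas, n)) < ub)
        n_pos = ra.sum(axis=1)
        after_pos = rb.sum(axis=1)
        rate_pos = n_pos / n
        rate_neg = 1.0 - rate_pos
        with np.errstate(all="ignore"):
            p1 = binom.cdf(after_pos, n, rate_pos)
            p2 = binom.cdf(n - after_pos, n, rate_neg)
        p1 = np.where(rate_pos <= 0, 1.0, np.where(rate_pos >= 1, (after_pos >= n) * 1.0, p1))
        p2 = np.where(rate_neg <= 0, 1.0, np.where(rate_neg >= 1, (after_pos <= 0) * 1.0, p2))
        p = np.minimum(p1, p2)
    p = np.maximum(p, _MIN_P)
    return float(np.median(p))


@dataclass
class TransformationStats:
    """Significance summary of one transformation on one endpoint.

    Counts are in the transformation's canonical left -> right direction:
    for continuous endpoints ``n_pos``/``n_neg``/``n_zero`` split the N
    usable pairs by the sign of their delta; for binary endpoints
    ``n_pos``/``n_neg`` are the active/inactive counts before the
    transformation and ``after_pos``/``after_neg`` after it.
    """

    transformation_id: str
    endpoint: str
    kind: str
    N: int
    n_pos: int
    n_neg: int
    n_zero: int = 0
    after_pos: int | None = None
    after_neg: int | None = None
    n_activated: int | None = None
    n_deactivated: int | None = None
    mean_delta: float | None = None
    p_value: float | None = None
    sig_level: float | None = None
    tested: bool = False
    holm_significant: bool = False
    bootstrap_p: float | None = None
    bootstrap_excluded: bool = False
    n_experimental_pairs: int = 0
    n_predicted_pairs: int = 0
    p_experimental: float | None = None
    experimental_significant: bool = False
    provenance_class: str = "none"

    @property
    def significance_level(self) -> float | None:
        return self.sig_level

    @property
    def deactivation_ratio(self) -> float | None:
        if self.n_deactivated is None or self.n_pos == 0:
            return None
        return self.n_deactivated / self.n_pos


def _usable_deltas(t: Transformation, endpoint: str, include_ood: bool) -> list[PairDelta]:
    """Oriented effective deltas, one per distinct molecule pair."""
    seen: set[tuple[str, str]] = set()
    out = []
    for pair, sign in t.pairs:
        if pair.pair_group in seen:
            continue
        data = pair.deltas.get(endpoint)
        if data is None:
            continue
        delta = data.effective(include_ood)
        if delta is None:
            continue
        seen.add(pair.pair_group)
        out.append(_oriented(delta, sign))
    return out


def _bootstrap_seed(seed: int, transformation_id: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([seed, zlib.crc32(transformation_id.encode())])


def significant_transformations(
    transformations: list[Transformation],
    endpoint: str,
    config=None,
) -> list[TransformationStats]:
    """Test every transformation of one endpoint and mark the significant ones.

    Transformations with fewer than ``config.min_pairs`` usable pairs are
    reported untested.  Holm-Bonferroni runs across all tested
    transformations of the endpoint (once on the combined evidence, once on
    the experimental subsets for provenance classification).  Transformations
    supported by predictions additionally face the replica bootstrap; those
    whose median replica p-value exceeds alpha are excluded.
    """
    from .amplify import classify_provenance
    from .config import AnalysisConfig

    config = config or AnalysisConfig()
    results: list[TransformationStats] = []
    kinds: set[str] = set()
    per_t: list[tuple[TransformationStats, list[PairDelta], list[PairDelta]]] = []

    for t in transformations:
        deltas = _usable_deltas(t, endpoint, config.include_out_of_domain)
        if not deltas:
            continue
        t_kinds = {d.kind for d in deltas}
        if len(t_kinds) > 1:
            raise ValueError(f"endpoint {endpoint!r} mixes kinds across pairs of {t.id}")
        kind = t_kinds.pop()
        kinds.add(kind)
        if len(kinds) > 1:
            raise ValueError(f"endpoint {endpoint!r} kind inconsistent across transformations")
        exp = [d for d in deltas if d.provenance == "experimental"]
        pred = [d for d in deltas if d.provenance == "predicted"]
        stats = TransformationStats(
            transformation_id=t.id,
            endpoint=endpoint,
            kind=kind,
            N=len(deltas),
            n_pos=0,
            n_neg=0,
            n_experimental_pairs=len(exp),
            n_predicted_pairs=len(pred),
        )
        if kind == "continuous":
            stats.n_pos, stats.n_neg, stats.n_zero = _continuous_counts(deltas, config.tie_tol)
            stats.mean_delta = float(np.mean([d.delta for d in deltas]))
        else:
            (
                stats.n_pos,
                stats.n_neg,
                stats.after_pos,
                stats.after_neg,
                stats.n_activated,
                stats.n_deactivated,
            ) = _binary_counts(deltas)
        if stats.N >= config.min_pairs:
            p = _pvalue_from_deltas(deltas, kind, config.tie_tol)
            if p is not None:
                stats.p_value = p
                stats.sig_level = significance_level(p)
                stats.tested = True
        if len(exp) >= config.min_pairs:
            stats.p_experimental = _pvalue_from_deltas(exp, kind, config.tie_tol)
        per_t.append((stats, deltas, exp))
        results.append(stats)

    # Holm-Bonferroni across the endpoint's tested transformations
    tested = [s for s, _, _ in per_t if s.tested]
    flags = holm_bonferroni([s.p_value for s in tested], config.alpha)
    for s, flag in zip(tested, flags):
        s.holm_significant = flag
    exp_tested = [s for s, _, _ in per_t if s.p_experimental is not None]
    exp_flags = holm_bonferroni([s.p_experimental for s in exp_tested], config.alpha)
    for s, flag in zip(exp_tested, exp_flags):
        s.experimental_significant = flag

    # applicability-domain bootstrap for prediction-supported transformations
    for s, deltas, _ in per_t:
        if not s.tested or s.n_predicted_pairs == 0:
            continue
        seed = _bootstrap_seed(config.seed, s.transformation_id)
        s.bootstrap_p = bootstrap_significance(
            deltas, n_replicas=config.n_replicas, seed=seed, tie_tol=config.tie_tol
        )
        if s.holm_significant and s.bootstrap_p > config.alpha:
            s.bootstrap_excluded = True
            s.holm_significant = False

    for s, _, _ in per_t:
        s.provenance_class = classify_provenance(
            p_experimental=s.p_experimental,
            p_combined=s.p_value,
            n_exp_pairs=s.n_experimental_pairs,
            n_pred_pairs=s.n_predicted_pairs,
            alpha=config.alpha,
            experimental_significant=s.experimental_significant,
            combined_significant=s.holm_significant,
        )
    return results


def null_fwer_simulation(
    transformations: list[Transformation],
    n_runs: int = 500,
    seed: int = 0,
    config=None,
) -> float:
    """Family-wise error rate under a structure-independent endpoint.

    Each run draws an independent standard-normal value per molecule,
    recomputes every transformation's sign counts and p-value, and applies
    Holm-Bonferroni; returns the fraction of runs with at least one
    rejection.  Under a calibrated procedure this stays at or below alpha.
    """
    from .config import AnalysisConfig

    config = config or AnalysisConfig()
    per_t: list[list[tuple[str, str, int]]] = []
    mol_ids: set[str] = set()
    for t in transformations:
        seen: set[tuple[str, str]] = set()
        obs = []
        for pair, sign in t.pairs:
            if pair.pair_group in seen:
                continue
            seen.add(pair.pair_group)
            obs.append((pair.mol_a, pair.mol_b, sign))
            mol_ids.update(pair.pair_group)
        if len(obs) >= config.min_pairs:
            per_t.append(obs)
    ids = sorted(mol_ids)
    rng = np.random.default_rng(seed)
    n_hit = 0
    for _ in range(n_runs):
        values = dict(zip(ids, rng.standard_normal(len(ids))))
        pvals = []
        for obs in per_t:
            deltas = [sign * (values[b] - values[a]) for a, b, sign in obs]
            n_pos = sum(1 for d in deltas if d > config.tie_tol)
            n_neg = sum(1 for d in deltas if d < -config.tie_tol)
            if n_pos + n_neg == 0:
                continue
            pvals.append(pvalue_regression(n_pos, n_neg))
        if any(holm_bonferroni(pvals, config.alpha)):
            n_hit += 1
    return n_hit / n_runs
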