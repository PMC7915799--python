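"""Normalized-Euclidean discriminant model and nearest-cluster
classification of the five sinus indicators.

Two diagnostic groups with per-indicator means m⁽⁰⁾, m⁽¹⁾ and standard
deviations σ⁽⁰⁾, σ⁽¹⁾ are separated, per indicator, by the standardized
difference

    δᵢ = |mᵢ⁽⁰⁾ − mᵢ⁽¹⁾| / σᵢ,     σᵢ = max(σᵢ⁽⁰⁾, σᵢ⁽¹⁾)

and jointly by the normalized Euclidean distance δ = √Σ δᵢ².  Under the
Gaussian equal-variance discrimination model the probability of a
decision error is

    per = 1 − Φ(δ/2)

where Φ is the probability integral Φ(x) = erf(x/√2) = 2Φ_N(x) − 1
(the convention of the Russian-language statistics literature;
equivalently per = 2(1 − Φ_N(δ/2)) with the standard normal CDF Φ_N).
per(0) = 1 and per decreases strictly to 0 as the groups separate.
Adding indicators to the model can only grow δ² (a sum of squares), so
δ(j) is non-decreasing and per(j) non-increasing as features accumulate.

A new patient is assigned to the cluster (diagnostic group) whose
centre lies at the shortest normalized Euclidean distance, each cluster
normalizing by its own σ; with diagonal covariance this distance equals
the Mahalanobis distance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import erfc
from scipy.stats import norm as _norm
from scipy import linalg

__all__ = [
    "FEATURES",
    "GroupStats",
    "DiscriminantComparison",
    "ClassificationResult",
    "standardized_diff",
    "normalized_distance",
    "error_probability",
    "incremental_curves",
    "classify_patient",
    "mahalanobis_distance",
    "load_group_stats",
    "tabulated_comparisons",
]

FEATURES = ("x1", "x2", "x3", "x4", "x5")

_FIXTURE = "group_stats.json"


@dataclass(frozen=True)
class GroupStats:
    """Per-group means and SDs of the five indicators."""

    name: str
    mean: Mapping[str, float]
    sd: Mapping[str, float]
    n: int | None = None

    def __post_init__(self) -> None:
        for f in FEATURES:
            if f not in self.mean or f not in self.sd:
                raise ValueError(f"group {self.name!r} missing indicator {f!r}")
            if self.sd[f] < 0:
                raise ValueError(f"group {self.name!r} has negative sd for {f!r}")


@dataclass
class DiscriminantComparison:
    """Feature-wise and cumulative separation of two groups."""

    group0: str
    group1: str
    feature_order: tuple[str, ...]
    per_feature: dict  # feature -> delta_i (may be inf)
    delta_curve: list  # delta(j), cumulative over the feature order
    per_curve: list  # per(j)
    delta: float  # final delta over all (finite) features
    per: float
    sigma_used: dict  # feature -> max-rule sigma
    degenerate: list  # features flagged infinite (sigma 0, means differ)


@dataclass
class ClassificationResult:
    """Nearest-cluster assignment of one indicator vector."""

    ranking: list  # [(group, distance)] ascending, inf-distance clusters last
    winner: str
    tie: bool
    weights: dict  # softmax over negative squared distances (extrapolated aid)


# ---------------------------------------------------------------------------
# core quantities


def standardized_diff(m0: float, m1: float, s0: float, s1: float) -> float:
    """Standardized mean difference |m0 − m1| / max(σ0, σ1).

    Degenerate spread (both σ zero): 0 when the means agree, else
    ``inf`` — an infinitely separating feature that callers exclude
    from finite sums and flag.
    """
    if s0 < 0 or s1 < 0:
        raise ValueError("standard deviations must be non-negative")
    sigma = max(s0, s1)
    diff = abs(m0 - m1)
    if sigma == 0.0:
        return 0.0 if diff == 0.0 else math.inf
    return diff / sigma


def normalized_distance(stats0: GroupStats, stats1: GroupStats,
                        features: Sequence[str] | None = None) -> float:
    """Normalized Euclidean distance δ = √Σ δᵢ² over the given features.

    Features whose max-rule σ is zero while the means differ separate
    the groups perfectly; they are excluded from the finite sum (use
    :func:`incremental_curves` to see which were flagged).
    """
    features = tuple(FEATURES if features is None else features)
    if not features:
        raise ValueError("empty feature set")
    total = 0.0
    n_finite = 0
    for f in features:
        d = standardized_diff(stats0.mean[f], stats1.mean[f], stats0.sd[f], stats1.sd[f])
        if math.isfinite(d):
            total += d * d
            n_finite += 1
    if n_finite == 0:
        raise ValueError("no non-degenerate features in the comparison")
    return math.sqrt(total)


def error_probability(delta: float, convention: str = "probability_integral") -> float:
    """Decision-error probability per = 1 − Φ(δ/2).

    ``convention`` selects the reading of Φ: ``"probability_integral"``
    (default) takes Φ(x) = erf(x/√2), giving per = erfc(δ/(2√2)) with
    per(0) = 1; ``"normal_cdf"`` takes Φ as the standard normal CDF.
    """
    if delta < 0:
        raise ValueError(f"delta must be non-negative, got {delta}")
    if convention == "probability_integral":
        return float(erfc(delta / (2.0 * math.sqrt(2.0))))
    if convention == "normal_cdf":
        return float(1.0 - _norm.cdf(delta / 2.0))
    raise ValueError(f"unknown convention {convention!r}")


def incremental_curves(stats0: GroupStats, stats1: GroupStats,
                       feature_order: Sequence[str] | None = None) -> DiscriminantComparison:
    """δ(j) and per(j) as indicators are added cumulatively to the model.

    The default order is x1…x5 (the presentation order; indicators are
    deliberately not ranked by information content).  δ(j) is
    non-decreasing and per(j) non-increasing by construction.
    """
    order = tuple(feature_order or FEATURES)
    if sorted(order) != sorted(set(order)) or not set(order) <= set(FEATURES):
        raise ValueError(f"feature_order must be distinct features from {FEATURES}, got {order}")
    per_feature: dict[str, float] = {}
    sigma_used: dict[str, float] = {}
    degenerate: list[str] = []
    total = 0.0
    delta_curve: list[float] = []
    per_curve: list[float] = []
    for f in order:
        s = max(stats0.sd[f], stats1.sd[f])
        d = standardized_diff(stats0.mean[f], stats1.mean[f], stats0.sd[f], stats1.sd[f])
        per_feature[f] = d
        sigma_used[f] = s
        if math.isfinite(d):
            total += d * d
        else:
            degenerate.append(f)
        delta_curve.append(math.sqrt(total))
        per_curve.append(error_probability(delta_curve[-1]))
    return DiscriminantComparison(
        group0=stats0.name, group1=stats1.name, feature_order=order,
        per_feature=per_feature, delta_curve=delta_curve, per_curve=per_curve,
        delta=delta_curve[-1], per=per_curve[-1],
        sigma_used=sigma_used, degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# classification


def _cluster_distance(x: Mapping[str, float], stats: GroupStats,
                      features: Sequence[str]) -> float:
    """Normalized Euclidean distance to a cluster centre, the cluster's
    own σ per feature.  σ = 0 features are skipped when the value sits
    exactly on the centre, else they exclude the cluster (inf)."""
    total = 0.0
    for f in features:
        s = stats.sd[f]
        diff = x[f] - stats.mean[f]
        if s == 0.0:
            if diff == 0.0:
                continue
            return math.inf
        total += (diff / s) ** 2
    return math.sqrt(total)


def classify_patient(x: Mapping[str, float], clusters: Sequence[GroupStats],
                     features: Sequence[str] | None = None) -> ClassificationResult:
    """Assign an indicator vector to the nearest cluster centre.

    Ties (equal shortest distances) keep the cluster-list order and are
    flagged.  The auxiliary ``weights`` rank the candidate diagnoses by
    a softmax over negative squared distances — an explicit
    extrapolation turning the ranked distances into compliance
    probabilities.
    """
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    features = tuple(features or FEATURES)
    missing = [f for f in features if f not in x or x[f] is None]
    if missing:
        raise ValueError(f"indicator vector missing features {missing}")
    dists = [(c.name, _cluster_distance(x, c, features)) for c in clusters]
    ranking = sorted(dists, key=lambda t: (t[1], [c.name for c in clusters].index(t[0])))
    winner = ranking[0][0]
    tie = len(ranking) > 1 and math.isclose(ranking[0][1], ranking[1][1],
                                            rel_tol=0.0, abs_tol=1e-12)
    finite = [(g, d) for g, d in dists if math.isfinite(d)]
    if finite:
        sq = np.array([d * d for _, d in finite])
        w = np.exp(-(sq - sq.min()))
        w /= w.sum()
        weights = {g: float(wi) for (g, _), wi in zip(finite, w)}
    else:
        weights = {}
    return ClassificationResult(ranking=ranking, winner=winner, tie=tie, weights=weights)


def mahalanobis_distance(x: Sequence[float], center: Sequence[float],
                         covariance: np.ndarray) -> float:
    """Mahalanobis distance √((x−m)ᵀ Σ⁻¹ (x−m)).

    With diagonal covariance diag(σᵢ²) this reduces exactly to the
    normalized Euclidean distance used for cluster assignment.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(center, dtype=float)
    cov = np.asarray(covariance, dtype=float)
    if cov.shape != (x.size, x.size):
        raise ValueError(f"covariance shape {cov.shape} does not match vector size {x.size}")
    try:
        chol = linalg.cholesky(cov, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError("covariance must be symmetric positive-definite") from exc
    z = linalg.solve_triangular(chol, x - m, lower=True)
    return float(np.sqrt(z @ z))


# ---------------------------------------------------------------------------
# fixture


def load_group_stats(source: str | Path | None = None) -> list[GroupStats]:
    """Load group statistics: the packaged clinical-cohort fixture by
    default, or a user JSON file with the same schema."""
    raw = _load_fixture(source)
    groups = []
    for name, entry in raw["groups"].items():
        groups.append(GroupStats(name=name, mean=dict(entry["mean"]),
                                 sd=dict(entry["sd"]), n=entry.get("n")))
    return groups


def tabulated_comparisons(source: str | Path | None = None) -> list[dict]:
    """The eight published group comparisons with both the printed δ/per
    and the values recomputed here from the group means and SDs.

    The printed distances are not exactly recoverable from the printed
    statistics (see the methods note); both are exposed so neither is
    silently preferred.
    """
    raw = _load_fixture(source)
    by_name = {g.name: g for g in load_group_stats(source)}
    out = []
    for comp in raw["comparisons"]:
        a, b = comp["pair"]
        curves = incremental_curves(by_name[a], by_name[b])
        out.append({
            "pair": (a, b),
            "printed_delta": comp["printed_delta"],
            "printed_per": comp["printed_per"],
            "recomputed_delta": curves.delta,
            "recomputed_per": curves.per,
            "per_from_printed_delta": error_probability(comp["printed_delta"]),
            "curves": curves,
        })
    return out


def _load_fixture(source: str | Path | None) -> dict:
    if source is None:
        text = resources.files("sinudens.data").joinpath(_FIXTURE).read_text()
    else:
        text = Path(source).read_text()
    raw = json.loads(text)
    if "groups" not in raw:
        raise ValueError("group-stats source missing 'groups'")
    return raw


def sample_cohort(clusters: Sequence[GroupStats], n_per_group: int, seed: int,
                  features: Sequence[str] = FEATURES) -> list[tuple[str, dict]]:
    """Draw synthetic patients feature-wise from each group's (m, σ).

    Features are sampled independently (the discrimination model itself
    assumes independent components).  Returns (true group, vector)
    pairs; deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    out = []
    for c in clusters:
        for _ in range(n_per_group):
            vec = {f: float(rng.normal(c.mean[f], c.sd[f])) for f in features}
            out.append((c.name, vec))
    return out
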