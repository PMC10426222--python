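"""Per-session univariate linear separability screening with permutation nulls.

For every feature within a day session, the best single-threshold linear rule
(threshold + direction, fit and evaluated in-sample) measures how well that
feature alone separates anger from non-anger windows.  Chance-level scores are
calibrated with a permutation null (labels shuffled, k = 1000 by default) and
features count as significant only if they survive Benjamini-Hochberg FDR at
q = 0.01 within the session AND strictly beat the majority-vote baseline of
the session's class imbalance.

Sessions are then categorized per participant (strong / moderate / weak
evidence depending on whether both / one / neither session reaches the
40-feature threshold), top features are pooled across sessions by tertiary
operation family, cross-session stability is scored with cosine similarity of
binary family-indicator vectors plus average-linkage clustering, and the
category distributions of the TBI and non-TBI groups are compared with the
Freeman-Halton (r x c) extension of Fisher's exact test.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .tsfeatures import FeatureMatrix, tertiary_family

__all__ = [
    "SeparabilityConfig",
    "SeparabilityReport",
    "linear1d_accuracy",
    "permutation_null",
    "significance",
    "screen_session",
    "screen_cohort",
    "categorize_participant",
    "pool_top_features",
    "stability_matrix",
    "cosine_similarity_binary",
    "group_distribution_test",
]


@dataclass(frozen=True)
class SeparabilityConfig:
    k_perm: int = 1000
    fdr_q: float = 0.01
    top_k: int = 40
    strong_threshold: int = 40
    cosine_group_threshold: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_perm < 100:
            raise ValueError("k_perm must be >= 100")
        if not (0.0 < self.fdr_q < 1.0):
            raise ValueError("fdr_q must lie in (0, 1)")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass
class SeparabilityReport:
    session_id: str
    feature_ids: list[str]
    accuracies: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    majority_baseline: float
    n_anger: int
    n_windows: int

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())

    def top_features(self, top_k: int = 40) -> list[tuple[str, float]]:
        """Up to ``top_k`` significant features, sorted by accuracy (id ties
        broken lexicographically for determinism)."""
        idx = np.nonzero(self.significant)[0]
        ranked = sorted(idx, key=lambda i: (-self.accuracies[i], self.feature_ids[i]))
        return [(self.feature_ids[i], float(self.accuracies[i])) for i in ranked[:top_k]]

    def to_dict(self) -> dict:
        return {
            "type": "separability",
            "session_id": self.session_id,
            "n_windows": self.n_windows,
            "n_anger": self.n_anger,
            "majority_baseline": self.majority_baseline,
            "n_significant": self.n_significant,
            "top_features": [
                {"feature": f, "accuracy": a} for f, a in self.top_features()
            ],
            "features": {
                f: {
                    "accuracy": float(a),
                    "p_value": float(p),
                    "significant": bool(s),
                }
                for f, a, p, s in zip(
                    self.feature_ids, self.accuracies, self.p_values, self.significant
                )
            },
        }


# ---------------------------------------------------------------------------
# single-feature linear rule
# ---------------------------------------------------------------------------

def _boundaries(sorted_values: np.ndarray) -> np.ndarray:
    """Cut positions: 0, n, and every index where the sorted value changes
    (thresholds live at midpoints between distinct adjacent values)."""
    n = len(sorted_values)
    change = np.nonzero(np.diff(sorted_values) != 0)[0] + 1
    return np.r_[0, change, n]


def linear1d_accuracy(values: np.ndarray, labels: np.ndarray) -> float:
    """In-sample accuracy of the best threshold-and-direction rule.

    Equivalent to exhaustively scanning all thresholds at midpoints between
    adjacent sorted distinct values (plus the two extremes) and both
    directions; ties between equally good thresholds resolve to the lower
    one, which does not change the accuracy.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need both classes present in the session")
    if counts.min() < 2:
        raise ValueError("need >= 2 windows per class")
    n = len(values)
    order = np.argsort(values, kind="stable")
    y = labels[order]
    cum1 = np.r_[0, np.cumsum(y)]  # anger count left of each cut
    cuts = _boundaries(values[order])
    n1 = cum1[-1]
    n0 = n - n1
    # rule "anger if value <= threshold": correct = left anger + right non-anger
    correct = cum1[cuts] + (n0 - (cuts - cum1[cuts]))
    best = np.maximum(correct, n - correct).max()  # direction flip
    return float(best) / n


def permutation_null(
    values: np.ndarray,
    labels: np.ndarray,
    k_perm: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Null accuracy sample under label permutation, and the permutation p.

    p = (1 + #{null >= observed}) / (k_perm + 1), so p is never exactly zero.
    """
    observed = linear1d_accuracy(values, labels)
    null = _null_accuracies(values, np.asarray(labels, dtype=int), k_perm,
                            np.random.default_rng(seed))
    p = (1.0 + float(np.sum(null >= observed - 1e-12))) / (k_perm + 1.0)
    return null, p


def _null_accuracies(
    values: np.ndarray,
    labels: np.ndarray,
    k_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    n = len(values)
    order = np.argsort(values, kind="stable")
    cuts = _boundaries(np.asarray(values, dtype=float)[order])
    perms = rng.permuted(np.tile(labels, (k_perm, 1)), axis=1)
    y = perms[:, order]
    cum1 = np.concatenate(
        [np.zeros((k_perm, 1), dtype=int), np.cumsum(y, axis=1)], axis=1
    )
    n1 = cum1[:, -1][:, None]
    n0 = n - n1
    c = cum1[:, cuts]
    correct = c + (n0 - (cuts[None, :] - c))
    best = np.maximum(correct, n - correct).max(axis=1)
    return best / n


def significance(
    p_values: np.ndarray,
    accuracies: np.ndarray,
    majority_baseline: float,
    fdr_q: float = 0.01,
) -> np.ndarray:
    """Benjamini-Hochberg at ``fdr_q`` within the session AND a strict
    improvement over the majority-vote baseline."""
    p_values = np.asarray(p_values, dtype=float)
    if len(p_values) == 0:
        return np.zeros(0, dtype=bool)
    rejected, *_ = multipletests(p_values, alpha=fdr_q, method="fdr_bh")
    return rejected & (np.asarray(accuracies) > majority_baseline)


def screen_session(
    session_id: str,
    values: np.ndarray,
    labels: np.ndarray,
    feature_ids: list[str],
    config: SeparabilityConfig = SeparabilityConfig(),
) -> SeparabilityReport:
    """Screen every feature of one session (``values`` is windows x features)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    n1 = int(labels.sum())
    majority = max(n1, n - n1) / n
    # derive one child seed per feature from the config seed + session id
    sid_key = int.from_bytes(
        hashlib.sha256(session_id.encode()).digest()[:4], "big"
    )
    base = np.random.SeedSequence([config.seed, sid_key]).spawn(values.shape[1])
    accs = np.empty(values.shape[1])
    ps = np.empty(values.shape[1])
    for j in range(values.shape[1]):
        accs[j] = linear1d_accuracy(values[:, j], labels)
        null = _null_accuracies(
            values[:, j], labels, config.k_perm, np.random.default_rng(base[j])
        )
        ps[j] = (1.0 + float(np.sum(null >= accs[j] - 1e-12))) / (config.k_perm + 1.0)
    sig = significance(ps, accs, majority, config.fdr_q)
    return SeparabilityReport(
        session_id=session_id,
        feature_ids=list(feature_ids),
        accuracies=accs,
        p_values=ps,
        significant=sig,
        majority_baseline=majority,
        n_anger=n1,
        n_windows=n,
    )


def screen_cohort(
    matrix: FeatureMatrix,
    config: SeparabilityConfig = SeparabilityConfig(),
) -> list[SeparabilityReport]:
    """Screen every day session of a normalized feature matrix."""
    sess = matrix.session_ids()
    reports = []
    for sid in sess.unique():
        mask = (sess == sid).to_numpy()
        reports.append(
            screen_session(
                sid,
                matrix.values.to_numpy()[mask],
                matrix.metadata["anger"].to_numpy()[mask],
                matrix.feature_ids,
                config,
            )
        )
    return reports


# ---------------------------------------------------------------------------
# categorization, pooling, stability
# ---------------------------------------------------------------------------

def categorize_participant(
    n_significant_a: int, n_significant_b: int, strong_threshold: int = 40
) -> str:
    """strong: both sessions reach the threshold; moderate: exactly one;
    weak: neither."""
    hits = (n_significant_a >= strong_threshold) + (n_significant_b >= strong_threshold)
    return {2: "strong", 1: "moderate", 0: "weak"}[hits]


def _top_families(report: SeparabilityReport, top_k: int) -> set[str]:
    return {tertiary_family(f) for f, _ in report.top_features(top_k)}


def pool_top_features(
    reports: list[SeparabilityReport], top_k: int = 40
) -> dict[str, int]:
    """Tally, per tertiary family, the number of sessions in whose top-K list
    it appears at least once (session-level counting: multiplicity within a
    session does not increase the tally)."""
    if not reports:
        raise ValueError("need at least one report")
    tally: dict[str, int] = {}
    for rep in reports:
        for fam in _top_families(rep, top_k):
            tally[fam] = tally.get(fam, 0) + 1
    return dict(sorted(tally.items(), key=lambda kv: (-kv[1], kv[0])))


def cosine_similarity_binary(set_a: set[str], set_b: set[str]) -> float:
    """Cosine similarity of binary indicator vectors over a shared vocabulary.

    Identical sets score 1, disjoint sets 0; two 40-element sets sharing 20
    entries score 20 / sqrt(40 * 40) = 0.5.
    """
    if not set_a or not set_b:
        return 0.0
    inter = len(set_a & set_b)
    return inter / math.sqrt(len(set_a) * len(set_b))


@dataclass
class StabilityResult:
    session_ids: list[str]
    cosine: np.ndarray  # pairwise cosine similarity
    linkage: np.ndarray  # scipy average-linkage matrix (Euclidean)
    groups: list[set[str]]  # connected components at cosine > threshold
    empty_sessions: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "type": "stability",
            "session_ids": self.session_ids,
            "cosine": self.cosine,
            "groups": [sorted(g) for g in self.groups],
            "empty_sessions": self.empty_sessions,
        }


def stability_matrix(
    reports: list[SeparabilityReport],
    config: SeparabilityConfig = SeparabilityConfig(),
) -> StabilityResult:
    """Cross-session stability of the top separable feature families.

    Each session is a binary indicator vector over the pooled tertiary-family
    vocabulary of its top-K list; cosine similarity compares sessions pairwise
    and average-linkage clustering on Euclidean distances organizes them.
    Sessions whose top list is empty score 0 against all others.
    """
    if len(reports) < 2:
        raise ValueError("need >= 2 reports")
    fam_sets = [_top_families(r, config.top_k) for r in reports]
    ids = [r.session_id for r in reports]
    empties = [sid for sid, s in zip(ids, fam_sets) if not s]
    vocab = sorted(set().union(*fam_sets))
    m = len(reports)
    cos = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            cos[i, j] = cos[j, i] = cosine_similarity_binary(fam_sets[i], fam_sets[j])
    vectors = np.array(
        [[1.0 if f in s else 0.0 for f in vocab] for s in fam_sets]
    ) if vocab else np.zeros((m, 1))
    link = hierarchy.linkage(vectors, method="average", metric="euclidean")
    # group sessions whose pairwise cosine exceeds the threshold (connected
    # components of the thresholded similarity graph)
    thr = config.cosine_group_threshold
    parent = list(range(m))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(m):
        for j in range(i + 1, m):
            if cos[i, j] > thr:
                parent[find(i)] = find(j)
    comp: dict[int, set[str]] = {}
    for i in range(m):
        comp.setdefault(find(i), set()).add(ids[i])
    groups = [g for g in comp.values() if len(g) > 1]
    return StabilityResult(ids, cos, link, groups, empties)


# ---------------------------------------------------------------------------
# Freeman-Halton exact test (2 x c)
# ---------------------------------------------------------------------------

def group_distribution_test(table: np.ndarray) -> float:
    """Exact two-sided p for a 2 x c contingency table (Freeman-Halton).

    Enumerates every table with the observed margins and sums the
    probabilities of tables no more probable than the observed one under the
    multivariate hypergeometric distribution.
    """
    table = np.asarray(table, dtype=int)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("expected a 2 x c table of counts")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if rows.min() == 0 or cols.min() == 0:
        import warnings

        warnings.warn("degenerate margin: p = 1", stacklevel=2)
        return 1.0
    n = int(table.sum())
    r1 = int(rows[0])
    logdenom = _log_comb(n, r1)

    def log_prob(top: tuple[int, ...]) -> float:
        return sum(_log_comb(int(c), int(t)) for c, t in zip(cols, top)) - logdenom

    obs_lp = log_prob(tuple(table[0]))
    total = 0.0
    c = len(cols)

    def rec(idx: int, remaining: int, top: list[int]) -> None:
        nonlocal total
        if idx == c - 1:
            if remaining <= cols[idx]:
                lp = log_prob(tuple(top + [remaining]))
                if lp <= obs_lp + 1e-9:
                    total += math.exp(lp)
            return
        for v in range(min(int(cols[idx]), remaining) + 1):
            rec(idx + 1, remaining - v, top + [v])

    rec(0, r1, [])
    return float(min(total, 1.0))


def _log_comb(n: int, k: int) -> float:
    if k < 0 or k > n:
        return -math.inf
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
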