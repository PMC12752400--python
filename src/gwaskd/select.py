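"""SNP feature scoring and cross-cohort selection.

Three per-SNP association scores are provided:

* ``association_test`` — a Cochran-Armitage trend test on the 2x3
  case/control-by-genotype table (the standard additive GWAS scan; its
  ``-log10 p`` values are Manhattan-plot ready),
* ``f_score`` — the one-way ANOVA F statistic (between-class variance over
  within-class variance of the dosage across the two label groups),
* ``mutual_information`` — the plug-in discrete MI (nats) between the
  3-level genotype and the binary label.

Cross-cohort selection intersects each cohort's top-m list and keeps the k
best by mean per-cohort rank, so only SNPs informative in *every* cohort
survive — the property that makes a feature set transferable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from gwaskd.simulate import CohortDataset

__all__ = [
    "FeatureRanking",
    "CommonFeatureSet",
    "association_test",
    "f_score",
    "mutual_information",
    "select_common_top",
    "overlap_curve",
]


@dataclass
class FeatureRanking:
    """Per-SNP scores from one method on one cohort, with dense ranks.

    ``ranks`` are 1-based dense ranks: 1 = best, meaning the largest score
    (f_score / mutual_information) or the smallest p-value
    (association_p). Ties share a rank.
    """

    method: str
    rsids: list[str]
    scores: np.ndarray
    ranks: np.ndarray
    pvalues: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.ranks = np.asarray(self.ranks, dtype=int)
        if not (len(self.rsids) == self.scores.size == self.ranks.size):
            raise ValueError("rsids/scores/ranks length mismatch")

    def top(self, k: int) -> list[str]:
        """rsIDs of the k best-ranked SNPs (ties broken lexicographically)."""
        order = np.lexsort((np.asarray(self.rsids), self.ranks))
        return [self.rsids[i] for i in order[:k]]


@dataclass
class CommonFeatureSet:
    """SNPs ranked top-m in every cohort, ordered by mean rank."""

    rsids: list[str]
    per_cohort_ranks: dict[str, np.ndarray]
    aggregate_rank: np.ndarray
    m_per_cohort: int
    k: int
    shortfall: bool = False


def _dense_ranks(scores: np.ndarray, descending: bool = True) -> np.ndarray:
    """1-based dense ranks; equal scores share a rank."""
    key = -scores if descending else scores
    order = np.unique(key)
    return np.searchsorted(order, key) + 1


def _require_imputed(dataset: CohortDataset) -> np.ndarray:
    if dataset.missing_mask.any():
        raise ValueError("dataset must be imputed (missing entries present)")
    return dataset.genotypes


def _genotype_classes(geno: np.ndarray) -> np.ndarray:
    """Round real-valued (imputed) dosages to the nearest of {0,1,2}."""
    return np.clip(np.rint(geno), 0, 2).astype(int)


def association_test(dataset: CohortDataset) -> FeatureRanking:
    """Cochran-Armitage trend test per SNP, vectorised over SNPs.

    With weights ``w = (0, 1, 2)`` the statistic is the dosage sum among
    cases, centred at its hypergeometric-null expectation and scaled by the
    finite-population variance:

        T = sum_j w_j r_j,    E[T] = R mu,
        Var[T] = R (N - R) / (N - 1) * sigma_w^2,

    where ``r_j`` counts cases with genotype j, ``R`` is the case total,
    ``mu``/``sigma_w^2`` the population mean/variance of the dosage.
    Two-sided normal p-values; zero-variance SNPs get p = 1.
    """
    geno = _require_imputed(dataset)
    y = dataset.labels
    if len(np.unique(y)) < 2:
        raise ValueError("association_test requires both classes")
    g = _genotype_classes(geno)
    n_total = g.shape[0]
    n_cases = int(y.sum())

    counts = np.stack(
        [(g == level).sum(axis=0) for level in (0, 1, 2)], axis=0
    )  # (3, p) totals
    case_counts = np.stack(
        [((g == level) & (y[:, None] == 1)).sum(axis=0) for level in (0, 1, 2)],
        axis=0,
    )
    w = np.array([0.0, 1.0, 2.0])
    t_obs = w @ case_counts
    mu = (w @ counts) / n_total
    var_w = (w[:, None] ** 2 * counts).sum(axis=0) / n_total - mu**2
    var_t = n_cases * (n_total - n_cases) / (n_total - 1) * var_w

    z = np.zeros(g.shape[1])
    nonzero = var_t > 0
    z[nonzero] = (t_obs[nonzero] - n_cases * mu[nonzero]) / np.sqrt(
        var_t[nonzero]
    )
    pvals = np.ones(g.shape[1])
    pvals[nonzero] = 2 * stats.norm.sf(np.abs(z[nonzero]))
    with np.errstate(divide="ignore"):
        neglog = -np.log10(pvals)
    return FeatureRanking(
        method="association_p",
        rsids=list(dataset.rsids),
        scores=neglog,
        ranks=_dense_ranks(pvals, descending=False),
        pvalues=pvals,
    )


def f_score(dataset: CohortDataset) -> FeatureRanking:
    """One-way ANOVA F statistic per SNP across the two label groups.

    For two groups F equals the squared pooled-variance t statistic.
    Degenerate columns: zero between- and within-group variance scores 0;
    zero within-group variance with real separation would be infinite and
    is replaced by (max finite score + 1) so ranking stays well defined.
    """
    geno = _require_imputed(dataset)
    y = dataset.labels
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("f_score requires both classes with >= 2 samples")
    g0 = geno[y == 0]
    g1 = geno[y == 1]
    n0, n1 = g0.shape[0], g1.shape[0]
    n = n0 + n1
    m0 = g0.mean(axis=0)
    m1 = g1.mean(axis=0)
    grand = geno.mean(axis=0)
    ss_between = n0 * (m0 - grand) ** 2 + n1 * (m1 - grand) ** 2
    ss_within = ((g0 - m0) ** 2).sum(axis=0) + ((g1 - m1) ** 2).sum(axis=0)
    ms_between = ss_between / 1.0  # k - 1 = 1
    ms_within = ss_within / (n - 2)

    scores = np.zeros(geno.shape[1])
    regular = ms_within > 0
    scores[regular] = ms_between[regular] / ms_within[regular]
    degenerate = (~regular) & (ms_between > 0)
    if degenerate.any():
        finite_max = scores[regular].max() if regular.any() else 0.0
        scores[degenerate] = finite_max + 1.0
    return FeatureRanking(
        method="f_score",
        rsids=list(dataset.rsids),
        scores=scores,
        ranks=_dense_ranks(scores),
    )


def mutual_information(dataset: CohortDataset, n_bins: int = 3) -> FeatureRanking:
    """Plug-in discrete MI (nats) between 3-level genotype and label.

    Real-valued imputed dosages are binned to the nearest of {0,1,2};
    ``n_bins`` is fixed at 3 for the ordinal dosage encoding.
    """
    if n_bins != 3:
        raise ValueError("dosages are 3-level; n_bins must be 3")
    geno = _require_imputed(dataset)
    y = dataset.labels
    g = _genotype_classes(geno)
    n = g.shape[0]
    p_y = np.array([(y == 0).mean(), (y == 1).mean()])

    mi = np.zeros(g.shape[1])
    for level in (0, 1, 2):
        ind = g == level  # (n, p)
        p_x = ind.mean(axis=0)
        for cls in (0, 1):
            p_xy = (ind & (y[:, None] == cls)).sum(axis=0) / n
            pos = p_xy > 0
            mi[pos] += p_xy[pos] * np.log(
                p_xy[pos] / (p_x[pos] * p_y[cls])
            )
    mi = np.maximum(mi, 0.0)  # guard tiny negative rounding
    return FeatureRanking(
        method="mutual_information",
        rsids=list(dataset.rsids),
        scores=mi,
        ranks=_dense_ranks(mi),
    )


def select_common_top(
    rankings: dict[str, FeatureRanking], m_per_cohort: int, k: int
) -> CommonFeatureSet:
    """Intersect each cohort's top-m SNPs and keep the k best by mean rank.

    The candidate set is the intersection of every cohort's top-m rsID
    list; candidates are ordered by mean per-cohort rank with ties broken
    lexicographically by rsID. If fewer than k SNPs survive the
    intersection, all of them are returned with ``shortfall`` flagged.
    """
    if not rankings:
        raise ValueError("empty rankings map")
    if k > m_per_cohort:
        raise ValueError("k must be <= m_per_cohort")
    universe = None
    for r in rankings.values():
        s = set(r.rsids)
        universe = s if universe is None else universe & s
        if s != set(next(iter(rankings.values())).rsids):
            raise ValueError("rankings must share a harmonised rsID universe")

    tops = {c: set(r.top(m_per_cohort)) for c, r in rankings.items()}
    candidates = set.intersection(*tops.values())
    rank_of = {
        c: dict(zip(r.rsids, r.ranks)) for c, r in rankings.items()
    }
    cand = sorted(candidates)
    agg = np.array(
        [np.mean([rank_of[c][r] for c in rankings]) for r in cand]
    )
    order = np.lexsort((np.asarray(cand), agg))
    shortfall = len(cand) < k
    if shortfall:
        warnings.warn(
            f"top-{m_per_cohort} intersection has only {len(cand)} SNPs (< k={k})"
        )
    chosen = order[: min(k, len(cand))]
    rsids = [cand[i] for i in chosen]
    return CommonFeatureSet(
        rsids=rsids,
        per_cohort_ranks={
            c: np.array([rank_of[c][r] for r in rsids]) for c in rankings
        },
        aggregate_rank=agg[chosen],
        m_per_cohort=m_per_cohort,
        k=k,
        shortfall=shortfall,
    )


def overlap_curve(
    ranking_a: FeatureRanking,
    ranking_b: FeatureRanking,
    thresholds: list[int],
) -> list[tuple[int, int]]:
    """|top-t(a) ∩ top-t(b)| for each threshold t; monotone in t."""
    if set(ranking_a.rsids) != set(ranking_b.rsids):
        raise ValueError("rankings must share an rsID universe")
    n = len(ranking_a.rsids)
    out = []
    for t in thresholds:
        if t > n:
            warnings.warn(f"threshold {t} exceeds universe size {n}; capped")
            t = n
        out.append((t, len(set(ranking_a.top(t)) & set(ranking_b.top(t)))))
    return out
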