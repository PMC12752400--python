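"""Multi-cohort synthetic genotype simulator with planted causal SNPs.

Generates case/control cohorts that share an rsID universe but differ in
allele frequency (a simple model of population structure between study
cohorts). Disease status follows a logistic liability model over additive
dosage effects plus optional pairwise dosage-product epistasis, so every
downstream stage — feature selection, teacher/student training, transfer
evaluation, attribution — can be tested against known ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "SimulationConfig",
    "CohortDataset",
    "GroundTruth",
    "simulate_cohorts",
    "planted_recovery_report",
    "write_ground_truth",
]

MAF_FLOOR = 0.01
MAF_CEIL = 0.99


@dataclass
class CohortDataset:
    """One cohort's dosage matrix with labels and a missingness mask.

    Attributes
    ----------
    name:
        Cohort identifier.
    genotypes:
        ``(n_samples, n_snps)`` float array of minor-allele dosages.
        Non-missing entries are in ``{0, 1, 2}`` (real-valued entries may
        appear after mean imputation); missing entries hold ``nan``.
    rsids:
        Ordered, unique SNP identifiers, one per genotype column.
    labels:
        ``(n_samples,)`` int array; 1 = case, 0 = control.
    missing_mask:
        Boolean array, same shape as ``genotypes``; True where missing.
    sample_ids:
        Per-row identifiers, used by the evaluation leakage audit.
    """

    name: str
    genotypes: np.ndarray
    rsids: list[str]
    labels: np.ndarray
    missing_mask: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n, p = self.genotypes.shape
        if len(self.rsids) != p:
            raise ValueError(
                f"rsids length {len(self.rsids)} != genotype columns {p}"
            )
        if len(set(self.rsids)) != p:
            raise ValueError("duplicate rsIDs in dataset")
        if self.labels.shape != (n,):
            raise ValueError("labels length != number of samples")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be binary 0/1")
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.genotypes.shape:
            raise ValueError("missing_mask shape mismatch")
        observed = self.genotypes[~self.missing_mask]
        if observed.size and not np.isfinite(observed).all():
            raise ValueError("non-finite observed dosages")
        if not self.sample_ids:
            self.sample_ids = [f"{self.name}_s{i}" for i in range(n)]
        elif len(self.sample_ids) != n:
            raise ValueError("sample_ids length != number of samples")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def copy(self) -> "CohortDataset":
        return CohortDataset(
            name=self.name,
            genotypes=self.genotypes.copy(),
            rsids=list(self.rsids),
            labels=self.labels.copy(),
            missing_mask=self.missing_mask.copy(),
            sample_ids=list(self.sample_ids),
        )


@dataclass
class GroundTruth:
    """Planted simulation truth: causal SNPs, effects, per-cohort MAFs."""

    causal_indices: np.ndarray
    effect_sizes: np.ndarray
    per_cohort_mafs: np.ndarray
    epistatic_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    intercepts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.causal_indices = np.asarray(self.causal_indices, dtype=int)
        self.effect_sizes = np.asarray(self.effect_sizes, dtype=float)
        self.per_cohort_mafs = np.asarray(self.per_cohort_mafs, dtype=float)
        n_snps = self.per_cohort_mafs.shape[1]
        if self.causal_indices.size and (
            self.causal_indices.min() < 0 or self.causal_indices.max() >= n_snps
        ):
            raise ValueError("causal index outside [0, n_snps)")
        if self.effect_sizes.shape != self.causal_indices.shape:
            raise ValueError("effect_sizes not aligned to causal_indices")
        if (
            (self.per_cohort_mafs < MAF_FLOOR - 1e-12)
            | (self.per_cohort_mafs > MAF_CEIL + 1e-12)
        ).any():
            raise ValueError("per-cohort MAF outside [0.01, 0.99]")


@dataclass
class SimulationConfig:
    """Study-design parameters for the multi-cohort generator.

    Defaults mirror a five-cohort Alzheimer's-style case/control design:
    sample sizes and case fractions on the order of real genotyping cohorts
    (a few hundred to ~1500 samples, 57-70% cases), moderately common
    variants (MAF 0.05-0.5), a between-cohort allele-frequency perturbation
    of SD 0.05, and 2% missing genotypes.
    """

    n_cohorts: int = 5
    n_samples_per_cohort: Sequence[int] = (1462, 534, 1386, 240, 1310)
    n_snps: int = 29630
    n_causal: int = 50
    effect_sizes: Sequence[float] | None = None
    epistatic_pairs: Sequence[tuple[int, int, float]] = ()
    base_maf_range: tuple[float, float] = (0.05, 0.5)
    cohort_maf_shift_sd: float = 0.05
    case_fraction_per_cohort: Sequence[float] = (
        0.617, 0.672, 0.595, 0.696, 0.573,
    )
    missing_rate: float = 0.02
    seed: int = 0
    #: optional per-cohort effect heterogeneity: one scalar per cohort, or
    #: one vector of length n_causal per cohort (zeros make a causal SNP
    #: cohort-private to the cohorts where it is non-zero)
    effect_size_multiplier_per_cohort: Sequence[float] | Sequence[Sequence[float]] | None = None
    cohort_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if self.n_cohorts <= 0:
            raise ValueError("n_cohorts must be positive")
        if len(self.n_samples_per_cohort) != self.n_cohorts:
            raise ValueError("n_samples_per_cohort length != n_cohorts")
        if any(n <= 0 for n in self.n_samples_per_cohort):
            raise ValueError("sample counts must be positive")
        if self.n_snps <= 0:
            raise ValueError("n_snps must be positive")
        if not 0 <= self.n_causal <= self.n_snps:
            raise ValueError("require 0 <= n_causal <= n_snps")
        if self.effect_sizes is None:
            # modest log-odds effects, alternating sign
            self.effect_sizes = tuple(
                0.25 * (1 if i % 2 == 0 else -1) for i in range(self.n_causal)
            )
        if len(self.effect_sizes) != self.n_causal:
            raise ValueError("effect_sizes length != n_causal")
        for a, b, _g in self.epistatic_pairs:
            if not (0 <= a < self.n_snps and 0 <= b < self.n_snps):
                raise ValueError("epistatic SNP index out of range")
        lo, hi = self.base_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("base_maf_range must lie in (0, 0.5]")
        if self.cohort_maf_shift_sd < 0:
            raise ValueError("cohort_maf_shift_sd must be non-negative")
        if len(self.case_fraction_per_cohort) != self.n_cohorts:
            raise ValueError("case_fraction_per_cohort length != n_cohorts")
        if any(not 0 < f < 1 for f in self.case_fraction_per_cohort):
            raise ValueError("case fractions must lie in (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.effect_size_multiplier_per_cohort is not None and len(
            self.effect_size_multiplier_per_cohort
        ) != self.n_cohorts:
            raise ValueError("effect multiplier length != n_cohorts")
        if self.cohort_names is None:
            self.cohort_names = tuple(
                f"cohort{c}" for c in range(self.n_cohorts)
            )
        elif len(self.cohort_names) != self.n_cohorts:
            raise ValueError("cohort_names length != n_cohorts")


def _solve_intercept(
    raw_liability: np.ndarray, uniforms: np.ndarray, target_cases: int
) -> float:
    """Bisect the liability intercept so the realised case count hits target.

    A sample is a case when its uniform draw falls below
    ``sigmoid(raw_liability + c)``; the case count is monotone
    non-decreasing in ``c``, so bisection on the sampled liabilities
    converges to an intercept whose realised count is within ±1 of target.
    """
    from scipy.special import expit

    def count(c: float) -> int:
        return int((uniforms < expit(raw_liability + c)).sum())

    lo, hi = -60.0, 60.0
    if count(lo) > target_cases or count(hi) < target_cases:
        raise ValueError(
            "requested case fraction unreachable by intercept shift"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if count(mid) < target_cases:
            lo = mid
        else:
            hi = mid
    c = hi
    if abs(count(c) - target_cases) > 1:
        raise ValueError(
            "requested case fraction unreachable by intercept shift "
            "(tied liabilities)"
        )
    return c


def simulate_cohorts(
    config: SimulationConfig,
) -> tuple[list[CohortDataset], GroundTruth]:
    """Generate per-cohort genotype/label data with planted causal SNPs.

    Per cohort ``c`` and SNP ``j`` the allele frequency is
    ``clip(base_maf[j] + shift[c, j], 0.01, 0.99)`` with
    ``base_maf ~ Uniform(base_maf_range)`` and
    ``shift ~ Normal(0, cohort_maf_shift_sd^2)``; dosages are
    ``Binomial(2, maf)``. The liability is the additive causal score plus
    dosage-product epistasis plus a per-cohort intercept solved by bisection
    so the realised case count matches the requested fraction within one
    sample; labels are Bernoulli(sigmoid(liability)). Missing entries are
    masked uniformly at ``missing_rate``. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_snps = config.n_snps
    width = max(6, len(str(n_snps - 1)))
    rsids = [f"rs{j:0{width}d}" for j in range(n_snps)]

    base_maf = rng.uniform(*config.base_maf_range, size=n_snps)
    causal = rng.choice(n_snps, size=config.n_causal, replace=False)
    causal.sort()
    betas = np.asarray(config.effect_sizes, dtype=float)

    datasets: list[CohortDataset] = []
    mafs = np.empty((config.n_cohorts, n_snps))
    intercepts = np.empty(config.n_cohorts)
    for c in range(config.n_cohorts):
        n = config.n_samples_per_cohort[c]
        shift = rng.normal(0.0, config.cohort_maf_shift_sd, size=n_snps)
        maf = np.clip(base_maf + shift, MAF_FLOOR, MAF_CEIL)
        mafs[c] = maf
        geno = rng.binomial(2, maf, size=(n, n_snps)).astype(float)

        if config.effect_size_multiplier_per_cohort is not None:
            mult = np.asarray(
                config.effect_size_multiplier_per_cohort[c], dtype=float
            )
            if mult.ndim == 1 and mult.size != config.n_causal:
                raise ValueError(
                    "per-SNP effect multiplier must have length n_causal"
                )
        else:
            mult = np.asarray(1.0)
        gamma_mult = float(mult.mean()) if mult.ndim else float(mult)
        liability = geno[:, causal] @ (betas * mult)
        for a, b, gamma in config.epistatic_pairs:
            liability = liability + gamma * gamma_mult * geno[:, a] * geno[:, b]

        uniforms = rng.uniform(size=n)
        target_cases = int(round(config.case_fraction_per_cohort[c] * n))
        target_cases = min(max(target_cases, 1), n - 1)
        from scipy.special import expit

        c0 = _solve_intercept(liability, uniforms, target_cases)
        intercepts[c] = c0
        labels = (uniforms < expit(liability + c0)).astype(int)

        mask = rng.uniform(size=geno.shape) < config.missing_rate
        geno[mask] = np.nan
        datasets.append(
            CohortDataset(
                name=config.cohort_names[c],
                genotypes=geno,
                rsids=list(rsids),
                labels=labels,
                missing_mask=mask,
            )
        )

    truth = GroundTruth(
        causal_indices=causal,
        effect_sizes=betas,
        per_cohort_mafs=mafs,
        epistatic_pairs=[tuple(p) for p in config.epistatic_pairs],
        intercepts=intercepts,
    )
    return datasets, truth


def planted_recovery_report(
    datasets: Sequence[CohortDataset],
    truth: GroundTruth,
    ranking,
    k: int,
) -> float:
    """Fraction of planted causal SNPs recovered in a ranking's top-k.

    ``ranking`` is a :class:`gwaskd.select.FeatureRanking` (anything with
    ``rsids`` and ``ranks``). Causal indices refer to the simulator's rsID
    order, taken from the first dataset.
    """
    if truth.causal_indices.size == 0:
        raise ValueError("empty causal set")
    if k < truth.causal_indices.size:
        raise ValueError("k must be >= number of causal SNPs")
    causal_rsids = {datasets[0].rsids[i] for i in truth.causal_indices}
    order = np.argsort(np.asarray(ranking.ranks))
    top = {ranking.rsids[i] for i in order[:k]}
    return len(top & causal_rsids) / len(causal_rsids)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Serialise planted truth as JSON."""
    payload = {
        "causal_indices": truth.causal_indices.tolist(),
        "effect_sizes": truth.effect_sizes.tolist(),
        "per_cohort_mafs": truth.per_cohort_mafs.tolist(),
        "epistatic_pairs": [list(p) for p in truth.epistatic_pairs],
        "intercepts": (
            truth.intercepts.tolist() if truth.intercepts is not None else None
        ),
    }
    Path(path).write_text(json.dumps(payload))
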