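"""Genotype table I/O, cohort harmonisation, imputation, balancing, splits.

Readers accept two plain-text layouts:

* CSV with header ``sample_id,label,rs...`` and dosage cells in {0,1,2}
  (blank/``NA``/unparseable cells become missing), and
* PLINK ``.raw``-style whitespace tables
  (``FID IID PAT MAT SEX PHENOTYPE rsID_allele ...``) where PHENOTYPE uses
  the PLINK convention 1 = control, 2 = case; ``-9``/``NA`` phenotypes drop
  the row with a warning.

All randomised operations are deterministic given their ``seed``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from gwaskd.simulate import CohortDataset

__all__ = [
    "SplitPair",
    "read_genotypes",
    "write_genotypes",
    "harmonise_cohorts",
    "impute_missing",
    "fit_imputer_means",
    "apply_imputer_means",
    "balance_classes",
    "stratified_split",
    "kfold_indices",
    "concatenate_cohorts",
    "subset_samples",
    "subset_snps",
]


@dataclass
class SplitPair:
    """A stratified train/test partition of one cohort."""

    train: CohortDataset
    test: CohortDataset
    fraction: float


def _validate_dosages(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coerce raw cells to float dosages; unparseable/invalid become nan."""
    num = (
        pd.DataFrame(values)
        .apply(pd.to_numeric, errors="coerce")
        .to_numpy(dtype=float)
    )
    geno = np.where(np.isin(num, (0.0, 1.0, 2.0)), num, np.nan)
    return geno, np.isnan(geno)


def read_genotypes(
    path: str | Path, format: str = "csv", name: str | None = None
) -> CohortDataset:
    """Read one cohort from CSV or PLINK ``.raw``-style text.

    Unparseable dosage cells become missing entries; duplicate rsIDs,
    non-binary labels and empty files raise ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.stat().st_size == 0:
        raise ValueError(f"empty file: {path}")
    cohort_name = name or path.stem

    # pandas mangles duplicate header names; check the raw header first
    with path.open() as fh:
        header_line = fh.readline().strip()
    raw_cols = header_line.split("," if format == "csv" else None)
    snp_cols = raw_cols[2:] if format == "csv" else raw_cols[6:]
    if format == "plink_raw":
        snp_cols = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
    seen: set[str] = set()
    for c in snp_cols:
        if c in seen:
            raise ValueError(f"duplicate rsID: {c}")
        seen.add(c)

    if format == "csv":
        df = pd.read_csv(path, dtype=str)
        if df.shape[0] == 0:
            raise ValueError(f"no data rows in {path}")
        if list(df.columns[:2]) != ["sample_id", "label"]:
            raise ValueError("CSV header must start with sample_id,label")
        rsids = list(df.columns[2:])
        sample_ids = df["sample_id"].astype(str).tolist()
        labels_raw = df["label"]
        try:
            labels = labels_raw.astype(float)
        except ValueError as exc:
            raise ValueError(f"non-binary labels: {exc}") from None
        if not set(np.unique(labels)) <= {0.0, 1.0}:
            raise ValueError("non-binary labels (expected 0/1)")
        labels = labels.astype(int).to_numpy()
        values = df[rsids].to_numpy(dtype=object)
    elif format == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", dtype=str)
        if df.shape[0] == 0:
            raise ValueError(f"no data rows in {path}")
        fixed = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        if list(df.columns[:6]) != fixed:
            raise ValueError("PLINK .raw header must start with " + " ".join(fixed))
        # strip the _allele suffix PLINK appends to each SNP column
        rsids = [c.rsplit("_", 1)[0] if "_" in c else c for c in df.columns[6:]]
        pheno = df["PHENOTYPE"]
        keep = []
        labels_list = []
        for i, v in enumerate(pheno):
            if v in ("-9", "NA", "-9.0", None) or pd.isna(v):
                warnings.warn(
                    f"dropping sample {df['IID'].iloc[i]} with missing phenotype"
                )
                continue
            x = float(v)
            if x not in (1.0, 2.0):
                raise ValueError(
                    f"non-binary PLINK phenotype {v!r} (expected 1/2)"
                )
            keep.append(i)
            labels_list.append(int(x) - 1)  # PLINK: 1=control, 2=case
        if not keep:
            raise ValueError(f"no usable samples in {path}")
        df = df.iloc[keep]
        labels = np.asarray(labels_list)
        sample_ids = df["IID"].astype(str).tolist()
        values = df.iloc[:, 6:].to_numpy(dtype=object)
    else:
        raise ValueError(f"unknown format {format!r}")

    dupes = pd.Index(rsids)[pd.Index(rsids).duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate rsID: {dupes[0]}")

    geno, mask = _validate_dosages(values)
    return CohortDataset(
        name=cohort_name,
        genotypes=geno,
        rsids=rsids,
        labels=labels,
        missing_mask=mask,
        sample_ids=sample_ids,
    )


def write_genotypes(
    dataset: CohortDataset, path: str | Path, format: str = "csv"
) -> None:
    """Write a cohort as CSV (``sample_id,label,rs...``) or PLINK ``.raw``."""
    path = Path(path)
    geno = dataset.genotypes.copy()
    geno[dataset.missing_mask] = np.nan

    def fmt(x: float) -> str:
        if np.isnan(x):
            return "NA"
        return str(int(x)) if float(x).is_integer() else repr(float(x))

    if format == "csv":
        with path.open("w") as fh:
            fh.write("sample_id,label," + ",".join(dataset.rsids) + "\n")
            for i in range(dataset.n_samples):
                row = ",".join(fmt(x) for x in geno[i])
                fh.write(f"{dataset.sample_ids[i]},{dataset.labels[i]},{row}\n")
    elif format == "plink_raw":
        with path.open("w") as fh:
            header = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
            header += [f"{r}_A" for r in dataset.rsids]
            fh.write(" ".join(header) + "\n")
            for i in range(dataset.n_samples):
                sid = dataset.sample_ids[i]
                row = [sid, sid, "0", "0", "0", str(dataset.labels[i] + 1)]
                row += [fmt(x) for x in geno[i]]
                fh.write(" ".join(row) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def harmonise_cohorts(datasets: list[CohortDataset]) -> list[CohortDataset]:
    """Restrict every cohort to the shared rsIDs, in sorted order.

    The returned datasets all carry the lexicographically sorted
    intersection of the input rsID sets; sample rows are untouched.
    Idempotent. Raises on an empty intersection.
    """
    if len(datasets) < 2:
        raise ValueError("harmonise_cohorts needs at least 2 datasets")
    shared = set(datasets[0].rsids)
    for ds in datasets[1:]:
        shared &= set(ds.rsids)
    if not shared:
        raise ValueError("empty rsID intersection across cohorts")
    order = sorted(shared)
    out = []
    for ds in datasets:
        pos = {r: i for i, r in enumerate(ds.rsids)}
        cols = np.asarray([pos[r] for r in order])
        out.append(
            CohortDataset(
                name=ds.name,
                genotypes=ds.genotypes[:, cols],
                rsids=order,
                labels=ds.labels.copy(),
                missing_mask=ds.missing_mask[:, cols],
                sample_ids=list(ds.sample_ids),
            )
        )
    return out


def fit_imputer_means(dataset: CohortDataset) -> np.ndarray:
    """Per-SNP mean of observed dosages (nan where a SNP is fully missing)."""
    geno = dataset.genotypes.copy()
    geno[dataset.missing_mask] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(geno, axis=0)


def apply_imputer_means(
    dataset: CohortDataset, means: np.ndarray
) -> CohortDataset:
    """Fill missing entries with supplied per-SNP means (train-fit means
    applied to held-out data avoid leakage). SNPs whose mean is nan are
    dropped with a warning."""
    out = dataset.copy()
    keep = ~np.isnan(means)
    if not keep.all():
        dropped = [out.rsids[j] for j in np.flatnonzero(~keep)]
        warnings.warn(f"dropping fully-missing SNPs: {dropped}")
        out = subset_snps(out, np.flatnonzero(keep))
        means = means[keep]
    fill = np.broadcast_to(means, out.genotypes.shape)
    out.genotypes[out.missing_mask] = fill[out.missing_mask]
    out.missing_mask = np.zeros_like(out.missing_mask)
    return out


def _knn_impute(dataset: CohortDataset, k: int) -> CohortDataset:
    n = dataset.n_samples
    if k >= n:
        raise ValueError("k_neighbours must be < n_samples")
    geno = dataset.genotypes.copy()
    geno[dataset.missing_mask] = np.nan
    obs = ~np.isnan(geno)
    # pairwise sqrt(mean squared difference) over mutually observed SNPs
    dist = np.full((n, n), np.inf)
    for i in range(n):
        both = obs[i] & obs
        diff = np.where(both, geno[i] - geno, 0.0)
        cnt = both.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.sqrt((diff**2).sum(axis=1) / cnt)
        d[cnt == 0] = np.inf
        dist[i] = d
    np.fill_diagonal(dist, np.inf)

    out = dataset.copy()
    for i, j in zip(*np.where(np.isnan(geno))):
        candidates = np.flatnonzero(obs[:, j])
        if candidates.size == 0:
            continue  # handled as fully-missing below
        order = candidates[np.lexsort((candidates, dist[i, candidates]))]
        chosen = order[:k]
        out.genotypes[i, j] = geno[chosen, j].mean()
        out.missing_mask[i, j] = False
    # drop SNPs nobody observes
    fully_missing = np.flatnonzero(~obs.any(axis=0))
    if fully_missing.size:
        warnings.warn(
            "dropping fully-missing SNPs: "
            f"{[out.rsids[j] for j in fully_missing]}"
        )
        out = subset_snps(out, np.setdiff1d(np.arange(out.n_snps), fully_missing))
    return out


def impute_missing(
    dataset: CohortDataset, method: str = "mean", k_neighbours: int = 5
) -> CohortDataset:
    """Fill missing dosages by per-SNP mean or k-nearest-neighbour mean.

    The mean method preserves each SNP's observed mean exactly (real-valued
    fills permitted). The nearest-neighbour method fills a cell with the
    mean dosage of the ``k_neighbours`` samples closest in Euclidean
    distance over mutually observed SNPs that observe that SNP. SNPs with
    no observed values are dropped with a warning.
    """
    if not dataset.missing_mask.any():
        return dataset.copy()
    if method == "mean":
        return apply_imputer_means(dataset, fit_imputer_means(dataset))
    if method == "nearest_neighbour":
        return _knn_impute(dataset, k_neighbours)
    raise ValueError(f"unknown imputation method {method!r}")


def balance_classes(
    dataset: CohortDataset, seed: int = 0, rho: float = 0.8
) -> CohortDataset:
    """Two-stage class balancing: oversample minority, undersample majority.

    Stage 1 oversamples the minority class with replacement up to
    ``rho * majority_count``; stage 2 undersamples the majority class
    without replacement down to the new minority count, yielding equal
    class counts. Every output row is a copy of some input row.
    """
    rng = np.random.default_rng(seed)
    labels = dataset.labels
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("balance_classes requires both classes present")
    order = np.argsort(counts, kind="stable")  # stable so a tie still yields
    minority = classes[order[0]]               # two distinct classes
    majority = classes[order[-1]]
    min_idx = np.flatnonzero(labels == minority)
    maj_idx = np.flatnonzero(labels == majority)

    target_min = int(round(rho * maj_idx.size))
    if target_min > min_idx.size:
        extra = rng.choice(min_idx, size=target_min - min_idx.size, replace=True)
        min_idx = np.concatenate([min_idx, extra])
    new_min = min_idx.size
    if maj_idx.size > new_min:
        maj_idx = rng.choice(maj_idx, size=new_min, replace=False)
    idx = np.concatenate([min_idx, maj_idx])
    idx.sort(kind="stable")
    return subset_samples(dataset, idx)


def stratified_split(
    dataset: CohortDataset, test_fraction: float = 0.2, seed: int = 0
) -> SplitPair:
    """Stratified train/test split preserving class proportions."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    _, counts = np.unique(dataset.labels, return_counts=True)
    if (counts < 2).any():
        raise ValueError("each class needs >= 2 samples to stratify")
    splitter = StratifiedShuffleSplit(
        n_splits=1, test_size=test_fraction, random_state=seed
    )
    (train_idx, test_idx), = splitter.split(
        np.zeros(dataset.n_samples), dataset.labels
    )
    train_idx.sort()
    test_idx.sort()
    return SplitPair(
        train=subset_samples(dataset, train_idx),
        test=subset_samples(dataset, test_idx),
        fraction=test_fraction,
    )


def kfold_indices(
    dataset: CohortDataset, k: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold (train, validation) index pairs covering all samples."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > dataset.n_samples:
        raise ValueError("k exceeds number of samples")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        (tr, va)
        for tr, va in skf.split(np.zeros(dataset.n_samples), dataset.labels)
    ]


def concatenate_cohorts(
    datasets: list[CohortDataset], name: str | None = None
) -> CohortDataset:
    """Stack harmonised cohorts row-wise (rsID orders must already agree)."""
    first = datasets[0]
    for ds in datasets[1:]:
        if ds.rsids != first.rsids:
            raise ValueError("cohorts must be harmonised before concatenation")
    return CohortDataset(
        name=name or "+".join(ds.name for ds in datasets),
        genotypes=np.vstack([ds.genotypes for ds in datasets]),
        rsids=list(first.rsids),
        labels=np.concatenate([ds.labels for ds in datasets]),
        missing_mask=np.vstack([ds.missing_mask for ds in datasets]),
        sample_ids=[sid for ds in datasets for sid in ds.sample_ids],
    )


def subset_samples(dataset: CohortDataset, idx: np.ndarray) -> CohortDataset:
    idx = np.asarray(idx, dtype=int)
    return CohortDataset(
        name=dataset.name,
        genotypes=dataset.genotypes[idx],
        rsids=list(dataset.rsids),
        labels=dataset.labels[idx],
        missing_mask=dataset.missing_mask[idx],
        sample_ids=[dataset.sample_ids[i] for i in idx],
    )


def subset_snps(dataset: CohortDataset, cols: np.ndarray) -> CohortDataset:
    cols = np.asarray(cols, dtype=int)
    return CohortDataset(
        name=dataset.name,
        genotypes=dataset.genotypes[:, cols],
        rsids=[dataset.rsids[j] for j in cols],
        labels=dataset.labels.copy(),
        missing_mask=dataset.missing_mask[:, cols],
        sample_ids=list(dataset.sample_ids),
    )
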