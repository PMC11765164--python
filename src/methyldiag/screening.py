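"""Two-stage CpG key-site screening.

Stage one restricts to healthy samples and tests every CpG site for tissue
specificity with a contingency chi-square: the site's beta values are
discretized into equal-width bins on [0, 1], counts are cross-tabulated
against the tissue label, and the usual statistic

    chi2 = sum over cells (O - E)^2 / E,   E from row/column margins,

is referred to the chi-square distribution with
(occupied_bins - 1) * (tissues - 1) degrees of freedom.  Sites with upper-tail
p-value below a threshold tau_p (default 0.01) are kept.

Stage two works per tissue: a regularized logistic regression of health status
on the candidate sites' (standardized) beta values is fitted, and sites are
ranked by coefficient magnitude; the top-k (default 400) become that tissue's
disease-specific panel.  Ranking by |beta| rather than signed beta keeps
hypomethylated disease sites (fold change < 1), which signed-descending
ordering would discard; the signed variant is available via ``criterion``.

Per-site summaries report healthy/disease medians, their ratio ("fold
change"/magnification) and group standard errors, mirroring the standard
disease-versus-healthy methylation table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .io import MethylationMatrix, SampleMetadataTable, ValidationError

__all__ = [
    "ChiSquareResult",
    "TissueScreenResult",
    "DiseaseSiteRanking",
    "SiteSummary",
    "bin_beta_values",
    "chi_square_tissue_test",
    "screen_tissue_specific",
    "rank_disease_sites",
    "site_summary",
]

DEFAULT_TAU_P = 0.01
DEFAULT_N_BINS = 10
DEFAULT_TOP_K = 400


@dataclass
class ChiSquareResult:
    """Chi-square tissue-specificity test for one CpG site."""

    site_id: str
    statistic: float
    df: int
    p_value: float


@dataclass
class TissueScreenResult:
    """All per-site chi-square results plus the selected tissue-specific set.

    ``selected_sites`` holds exactly the sites with p_value < tau_p, ordered
    by ascending p-value with lexicographic site_id tie-break.
    """

    results: list[ChiSquareResult]
    tau_p: float
    n_bins: int
    selected_sites: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.selected_sites = self._select()

    def _select(self) -> list[str]:
        hits = [r for r in self.results if r.p_value < self.tau_p]
        hits.sort(key=lambda r: (r.p_value, r.site_id))
        return [r.site_id for r in hits]


@dataclass
class DiseaseSiteRanking:
    """Per-tissue logistic-regression ranking of candidate sites."""

    tissue: str
    site_ids_ranked: list[str]
    coefficients: dict[str, float]
    intercept: float
    top_k: int
    selected_sites: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.selected_sites:
            self.selected_sites = self.site_ids_ranked[
                : min(self.top_k, len(self.site_ids_ranked))
            ]


@dataclass
class SiteSummary:
    """Healthy/disease medians, fold change and standard errors for one site.

    ``magnification`` is the disease-median over healthy-median ratio; it is
    None (reported as undefined) when the healthy median is zero.
    """

    site_id: str
    tissue: str
    h_m: float
    d_m: float
    magnification: float | None
    h_se: float
    d_se: float


def bin_beta_values(values: Sequence[float], n_bins: int) -> np.ndarray:
    """Equal-width bin indices on [0, 1]; the value 1.0 falls in the last bin."""
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    vals = np.asarray(values, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (vals < 0.0) | (vals > 1.0)
    if bad.any():
        raise ValidationError(
            f"beta value {vals[bad][0]!r} outside [0, 1] cannot be binned"
        )
    idx = np.floor(vals * n_bins).astype(float)
    idx = np.minimum(idx, n_bins - 1)
    out = np.where(np.isnan(vals), -1, idx).astype(int)
    return out


def _contingency(
    bins: np.ndarray, tissue_codes: np.ndarray, n_bins: int, n_tissues: int
) -> np.ndarray:
    """Counts table (n_bins x n_tissues); bin -1 (missing) rows are dropped."""
    counts = np.zeros((n_bins, n_tissues), dtype=float)
    valid = bins >= 0
    np.add.at(counts, (bins[valid], tissue_codes[valid]), 1.0)
    return counts


def _chi_square_from_counts(counts: np.ndarray) -> tuple[float, int, float]:
    """Statistic, df and upper-tail p-value from a bins x groups table.

    Rows and columns with zero margin are dropped before computing expected
    counts, so df = (occupied_bins - 1) * (occupied_groups - 1).  A table with
    a single occupied row or column carries no association information:
    statistic 0, df 0, p-value 1.
    """
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    occ = counts[np.ix_(row > 0, col > 0)]
    if occ.shape[0] < 2 or occ.shape[1] < 2:
        return 0.0, 0, 1.0
    total = occ.sum()
    expected = np.outer(occ.sum(axis=1), occ.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (occ - expected) ** 2 / expected, 0.0)
    statistic = float(terms.sum())
    df = (occ.shape[0] - 1) * (occ.shape[1] - 1)
    p_value = float(stats.chi2.sf(statistic, df))
    return statistic, df, p_value


def chi_square_tissue_test(
    site_values: Sequence[float],
    tissue_labels: Sequence[str],
    n_bins: int = DEFAULT_N_BINS,
    site_id: str = "",
) -> ChiSquareResult:
    """Contingency chi-square of one site's binned betas against tissue.

    Missing values are dropped pairwise (the sample contributes nothing).
    Raises if fewer than two distinct tissues remain.
    """
    vals = np.asarray(site_values, dtype=float)
    labels = np.asarray(tissue_labels)
    if vals.shape != labels.shape:
        raise ValidationError("site_values and tissue_labels must be parallel")
    keep = ~np.isnan(vals)
    vals, labels = vals[keep], labels[keep]
    uniq, codes = np.unique(labels, return_inverse=True)
    if uniq.size < 2:
        raise ValidationError(
            f"chi-square tissue test needs >= 2 tissues, got {uniq.size}"
        )
    bins = bin_beta_values(vals, n_bins)
    counts = _contingency(bins, codes, n_bins, uniq.size)
    statistic, df, p_value = _chi_square_from_counts(counts)
    return ChiSquareResult(site_id=site_id, statistic=statistic, df=df, p_value=p_value)


def screen_tissue_specific(
    matrix: MethylationMatrix,
    metadata: SampleMetadataTable,
    tau_p: float = DEFAULT_TAU_P,
    n_bins: int = DEFAULT_N_BINS,
) -> TissueScreenResult:
    """Stage-one screen: chi-square tissue test on healthy samples, all sites.

    Only healthy samples enter the test (disease effects must not masquerade
    as tissue specificity).  A site observed in fewer than two tissues after
    pairwise missing-value removal is assigned statistic 0, df 0, p-value 1.
    """
    if not 0.0 <= tau_p <= 1.0:
        raise ValidationError(f"tau_p must lie in [0, 1], got {tau_p}")
    healthy_ids = metadata.select(status=0)
    if not healthy_ids:
        raise ValidationError("no healthy samples available for the tissue screen")
    tissues = metadata.tissue_for(healthy_ids)
    uniq, codes = np.unique(np.asarray(tissues), return_inverse=True)
    if uniq.size < 2:
        raise ValidationError("tissue screen needs healthy samples from >= 2 tissues")
    sub = matrix.subset_samples(healthy_ids)

    # vectorized binning, then per-tissue counts in one pass per (tissue, bin)
    bins = np.full(sub.betas.shape, -1, dtype=int)
    finite = ~np.isnan(sub.betas)
    bins[finite] = bin_beta_values(sub.betas[finite], n_bins)
    n_sites = sub.n_sites
    counts = np.zeros((n_sites, n_bins, uniq.size), dtype=float)
    for t in range(uniq.size):
        bt = bins[codes == t, :]  # samples of tissue t x sites
        for b in range(n_bins):
            counts[:, b, t] = (bt == b).sum(axis=0)

    row = counts.sum(axis=2)  # (sites, bins)
    col = counts.sum(axis=1)  # (sites, tissues)
    total = row.sum(axis=1)  # (sites,)
    occupied = (row > 0).sum(axis=1)
    groups = (col > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = row[:, :, None] * col[:, None, :] / total[:, None, None]
        terms = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    statistic = terms.sum(axis=(1, 2))
    df = (occupied - 1) * (groups - 1)
    degenerate = (occupied < 2) | (groups < 2)
    statistic = np.where(degenerate, 0.0, statistic)
    df = np.where(degenerate, 0, df)
    p_value = np.ones(n_sites)
    ok = df > 0
    p_value[ok] = stats.chi2.sf(statistic[ok], df[ok])

    results = [
        ChiSquareResult(
            site_id=s,
            statistic=float(statistic[j]),
            df=int(df[j]),
            p_value=float(p_value[j]),
        )
        for j, s in enumerate(sub.site_ids)
    ]
    return TissueScreenResult(results=results, tau_p=tau_p, n_bins=n_bins)


def rank_disease_sites(
    matrix: MethylationMatrix,
    metadata: SampleMetadataTable,
    tissue: str,
    candidate_sites: Sequence[str],
    top_k: int = DEFAULT_TOP_K,
    criterion: str = "absolute",
    C: float = 1.0,
    max_iter: int = 2000,
) -> DiseaseSiteRanking:
    """Stage-two ranking: logistic regression of status on candidate sites.

    Fits an L2-regularized logistic model (inverse regularization ``C``) on
    samples of the given tissue only, after standardizing each site to zero
    mean and unit variance within that tissue.  Sites are ordered by
    descending coefficient magnitude (``criterion="absolute"``, default) or by
    signed descending coefficient (``criterion="signed"``); ties break
    lexicographically by site_id.  Missing betas are mean-imputed within the
    tissue before fitting.
    """
    if criterion not in ("absolute", "signed"):
        raise ValidationError(f"unknown ranking criterion {criterion!r}")
    candidates = list(candidate_sites)
    if not candidates:
        raise ValidationError("candidate_sites must be non-empty")
    if top_k <= 0:
        raise ValidationError("top_k must be positive")
    sample_ids = metadata.select(tissue=tissue)
    if not sample_ids:
        raise ValidationError(f"no samples of tissue {tissue!r}")
    y = metadata.status_for(sample_ids)
    if len(np.unique(y)) < 2:
        raise ValidationError(
            f"tissue {tissue!r} has a single health status; cannot rank"
        )
    sub = matrix.subset_samples(sample_ids).subset_sites(candidates)
    X = sub.betas.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_rows, nan_cols = np.where(np.isnan(X))
    X[nan_rows, nan_cols] = col_mean[nan_cols]
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - X.mean(axis=0)) / sd

    # default penalty is L2; C is the inverse regularization strength
    clf = LogisticRegression(C=C, solver="lbfgs", max_iter=max_iter, tol=1e-8)
    clf.fit(X, y)
    beta = clf.coef_.ravel()
    score = np.abs(beta) if criterion == "absolute" else beta
    order = sorted(range(len(candidates)), key=lambda j: (-score[j], candidates[j]))
    ranked = [candidates[j] for j in order]
    return DiseaseSiteRanking(
        tissue=tissue,
        site_ids_ranked=ranked,
        coefficients={candidates[j]: float(beta[j]) for j in range(len(candidates))},
        intercept=float(clf.intercept_[0]),
        top_k=int(top_k),
    )


def _median_se(values: np.ndarray, method: str, rng: np.random.Generator | None,
               n_boot: int) -> float:
    if method == "mean":
        if values.size < 2:
            return float("nan")
        return float(values.std(ddof=1) / np.sqrt(values.size))
    # bootstrap SE of the median
    if rng is None:
        rng = np.random.default_rng(0)
    meds = np.median(
        rng.choice(values, size=(n_boot, values.size), replace=True), axis=1
    )
    return float(meds.std(ddof=1))


def site_summary(
    matrix: MethylationMatrix,
    metadata: SampleMetadataTable,
    tissue: str,
    site_id: str,
    se_method: str = "mean",
    seed: int = 0,
    n_boot: int = 1000,
) -> SiteSummary:
    """Healthy/disease medians, fold change and SEs for one site in one tissue.

    Medians use the mean-of-middle-two convention for even group sizes.
    ``se_method="mean"`` reports the standard error of the mean (sd/sqrt(n));
    ``se_method="median"`` reports a seeded bootstrap SE of the median.
    """
    if se_method not in ("mean", "median"):
        raise ValidationError(f"unknown se_method {se_method!r}")
    j = matrix.site_index([site_id])[0]
    groups = {}
    for status in (0, 1):
        ids = metadata.select(tissue=tissue, status=status)
        if not ids:
            raise ValidationError(
                f"tissue {tissue!r} lacks {'healthy' if status == 0 else 'disease'} "
                f"samples for site summary"
            )
        vals = matrix.betas[matrix.sample_index(ids), j]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise ValidationError(
                f"site {site_id!r} has no non-missing values in tissue {tissue!r} "
                f"status {status}"
            )
        groups[status] = vals
    rng = np.random.default_rng(seed) if se_method == "median" else None
    h_m = float(np.median(groups[0]))
    d_m = float(np.median(groups[1]))
    return SiteSummary(
        site_id=site_id,
        tissue=tissue,
        h_m=h_m,
        d_m=d_m,
        magnification=(d_m / h_m) if h_m > 0 else None,
        h_se=_median_se(groups[0], se_method, rng, n_boot),
        d_se=_median_se(groups[1], se_method, rng, n_boot),
    )
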