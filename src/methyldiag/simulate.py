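"""Synthetic methylation cohorts with planted tissue- and disease-specific sites.

The generator emulates 450K-style beta values: every cell is drawn from a beta
distribution (bounded in [0, 1], variance shrinking near the bounds)
parameterized by a per-site true mean and a shared concentration.  Planted
tissue-specific sites get a mean offset in one target tissue; planted
disease-specific sites additionally get a status-dependent offset within their
tissue, with the sign of the shift random per site so that both hyper- and
hypomethylation (fold changes above and below 1) occur, as seen in real
disease/healthy median comparisons.

The generative model is the package's own construction — the study it mirrors
works from public array cohorts and states no simulation model.  It emulates
mean shifts and bounded noise only; probe artifacts, batch effects, cell-type
composition and age structure of real data are deliberately absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import MethylationMatrix, SampleMetadataTable, ValidationError

__all__ = [
    "SyntheticCohortConfig",
    "GroundTruth",
    "generate_cohort",
    "null_cohort",
    "interaction_cohort",
]

_MEAN_MARGIN = 0.02  # true means kept inside [margin, 1 - margin]


@dataclass
class SyntheticCohortConfig:
    """Settings for :func:`generate_cohort`.

    Defaults give six tissues of 50 healthy + 50 disease samples over 2,000
    sites, with 200 planted tissue-specific sites (mean offset 0.25) of which
    20 per tissue are additionally disease-shifted (offset 0.2, random sign),
    matching the effect sizes the screening stages are designed to detect.
    """

    tissues: Sequence[str] = (
        "brain", "saliva", "whole blood", "kidney", "lung", "breast",
    )
    n_healthy_per_tissue: int = 50
    n_disease_per_tissue: int = 50
    n_sites: int = 2000
    n_tissue_specific: int = 200
    n_disease_specific_per_tissue: int = 20
    baseline_beta_low: float = 0.1
    baseline_beta_high: float = 0.9
    tissue_shift: float = 0.25
    disease_shift: float = 0.2
    dispersion: float = 30.0
    noise_family: str = "beta"  # or "truncnorm"
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not self.tissues:
            raise ValidationError("tissues must be non-empty")
        if len(set(self.tissues)) != len(self.tissues):
            raise ValidationError("tissue labels must be unique")
        if min(self.n_healthy_per_tissue, self.n_disease_per_tissue) < 0:
            raise ValidationError("sample counts must be non-negative")
        if self.n_healthy_per_tissue + self.n_disease_per_tissue == 0:
            raise ValidationError("at least one sample per tissue required")
        if not (
            0
            <= self.n_disease_specific_per_tissue
            <= self.n_tissue_specific
            <= self.n_sites
        ):
            raise ValidationError(
                "need n_disease_specific_per_tissue <= n_tissue_specific <= n_sites"
            )
        if not (0.0 < self.baseline_beta_low < self.baseline_beta_high < 1.0):
            raise ValidationError("baseline beta range must satisfy 0 < low < high < 1")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be positive")
        if self.noise_family not in ("beta", "truncnorm"):
            raise ValidationError(f"unknown noise family {self.noise_family!r}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must be in [0, 1)")


@dataclass
class GroundTruth:
    """Planted-site manifest for recovery tests.

    ``means`` holds one row per (site, tissue) with the true healthy and
    disease means actually used for sampling.
    """

    tissue_specific_sites: set[str]
    disease_specific_sites: dict[str, set[str]]
    means: pd.DataFrame

    def manifest(self) -> pd.DataFrame:
        """Long-form TSV-ready manifest (site_id, category, tissue, means)."""
        df = self.means.copy()
        cat = []
        for site, tissue in zip(df["site_id"], df["tissue"]):
            if site in self.disease_specific_sites.get(tissue, set()):
                cat.append("disease_specific")
            elif site in self.tissue_specific_sites:
                cat.append("tissue_specific")
            else:
                cat.append("background")
        df["category"] = cat
        return df[["site_id", "category", "tissue", "healthy_mean", "disease_mean"]]


def _site_ids(n: int) -> list[str]:
    return [f"cg{i:08d}" for i in range(n)]


def _shift_mean(base: np.ndarray, shift: float, sign: np.ndarray) -> np.ndarray:
    """Apply a signed offset, flipping the sign where it would leave (0, 1)."""
    shifted = base + sign * shift
    flip = (shifted < _MEAN_MARGIN) | (shifted > 1.0 - _MEAN_MARGIN)
    shifted = np.where(flip, base - sign * shift, shifted)
    return np.clip(shifted, _MEAN_MARGIN, 1.0 - _MEAN_MARGIN)


def _draw(rng: np.random.Generator, means: np.ndarray, cfg_dispersion: float,
          family: str) -> np.ndarray:
    if family == "beta":
        a = means * cfg_dispersion
        b = (1.0 - means) * cfg_dispersion
        return rng.beta(a, b)
    # matched-moment truncated normal, resampled into [0, 1]
    sd = np.sqrt(means * (1.0 - means) / (1.0 + cfg_dispersion))
    vals = rng.normal(means, sd)
    bad = (vals < 0.0) | (vals > 1.0)
    while bad.any():
        vals[bad] = rng.normal(means[bad], sd[bad])
        bad = (vals < 0.0) | (vals > 1.0)
    return vals


def generate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[MethylationMatrix, SampleMetadataTable, GroundTruth]:
    """Generate a cohort with planted tissue- and disease-specific sites.

    Returns the beta matrix (samples x sites), the matching metadata table,
    and the :class:`GroundTruth` manifest of planted sites and true means.
    Identical configs (including seed) give bit-identical cohorts: sub-streams
    for structure, noise and missingness are spawned from the root seed in a
    fixed order.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    structure_rng, noise_rng, missing_rng = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    tissues = list(config.tissues)
    n_t = len(tissues)
    site_ids = _site_ids(config.n_sites)

    base = structure_rng.uniform(
        config.baseline_beta_low, config.baseline_beta_high, config.n_sites
    )
    # healthy means per tissue: background sites share the baseline
    healthy_means = np.tile(base, (n_t, 1))

    ts_idx = structure_rng.choice(
        config.n_sites, size=config.n_tissue_specific, replace=False
    )
    target_tissue = structure_rng.integers(0, n_t, size=config.n_tissue_specific)
    ts_sign = structure_rng.choice([-1.0, 1.0], size=config.n_tissue_specific)
    healthy_means[target_tissue, ts_idx] = _shift_mean(
        base[ts_idx], config.tissue_shift, ts_sign
    )

    disease_means = healthy_means.copy()
    disease_sets: dict[str, set[str]] = {t: set() for t in tissues}
    for ti, tissue in enumerate(tissues):
        if config.n_disease_specific_per_tissue == 0:
            continue
        pick = structure_rng.choice(
            config.n_tissue_specific,
            size=config.n_disease_specific_per_tissue,
            replace=False,
        )
        d_idx = ts_idx[pick]
        d_sign = structure_rng.choice([-1.0, 1.0], size=d_idx.size)
        disease_means[ti, d_idx] = _shift_mean(
            healthy_means[ti, d_idx], config.disease_shift, d_sign
        )
        disease_sets[tissue] = {site_ids[j] for j in d_idx}

    # assemble per-sample mean rows in a fixed sample order
    sample_ids: list[str] = []
    rows_tissue: list[int] = []
    rows_status: list[int] = []
    for ti, tissue in enumerate(tissues):
        tag = tissue.replace(" ", "")
        for i in range(config.n_healthy_per_tissue):
            sample_ids.append(f"{tag}-h{i:03d}")
            rows_tissue.append(ti)
            rows_status.append(0)
        for i in range(config.n_disease_per_tissue):
            sample_ids.append(f"{tag}-d{i:03d}")
            rows_tissue.append(ti)
            rows_status.append(1)
    rows_tissue_arr = np.array(rows_tissue)
    rows_status_arr = np.array(rows_status)
    mean_rows = np.where(
        rows_status_arr[:, None] == 0,
        healthy_means[rows_tissue_arr, :],
        disease_means[rows_tissue_arr, :],
    )

    betas = _draw(noise_rng, mean_rows, config.dispersion, config.noise_family)
    if config.missing_rate > 0:
        mask = missing_rng.random(betas.shape) < config.missing_rate
        betas = betas.copy()
        betas[mask] = np.nan

    matrix = MethylationMatrix(sample_ids, site_ids, betas)
    meta = SampleMetadataTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "tissue": [tissues[t] for t in rows_tissue],
                "status": rows_status,
                "dataset_id": "synthetic",
            }
        ),
        tissue_vocabulary=tuple(tissues),
    )

    means_long = pd.DataFrame(
        {
            "site_id": np.repeat(site_ids, n_t),
            "tissue": np.tile(tissues, config.n_sites),
            "healthy_mean": healthy_means.T.ravel(),
            "disease_mean": disease_means.T.ravel(),
        }
    )
    truth = GroundTruth(
        tissue_specific_sites={site_ids[j] for j in ts_idx},
        disease_specific_sites=disease_sets,
        means=means_long,
    )
    return matrix, meta, truth


def null_cohort(
    n_samples_per_tissue: int,
    n_sites: int,
    tissues: Sequence[str],
    seed: int,
    dispersion: float = 30.0,
) -> tuple[MethylationMatrix, SampleMetadataTable]:
    """Cohort with zero planted effects, for type-I-error calibration.

    Every site is identically distributed across tissues; all samples are
    labelled healthy so the tissue screen sees the full cohort.
    """
    if n_samples_per_tissue <= 0 or n_sites <= 0:
        raise ValidationError("n_samples_per_tissue and n_sites must be positive")
    cfg = SyntheticCohortConfig(
        tissues=tuple(tissues),
        n_healthy_per_tissue=n_samples_per_tissue,
        n_disease_per_tissue=0,
        n_sites=n_sites,
        n_tissue_specific=0,
        n_disease_specific_per_tissue=0,
        dispersion=dispersion,
        seed=seed,
    )
    matrix, meta, _ = generate_cohort(cfg)
    return matrix, meta


def interaction_cohort(
    n_per_class: int = 100,
    n_sites: int = 20,
    seed: int = 0,
    low: float = 0.3,
    high: float = 0.7,
    dispersion: float = 30.0,
    tissue: str = "whole blood",
) -> tuple[MethylationMatrix, SampleMetadataTable, tuple[str, str]]:
    """Cohort whose disease label is an XOR interaction of two planted sites.

    Two key sites each sit in a low (~``low``) or high (~``high``) methylation
    state per sample; the disease label is 1 exactly when the two states
    disagree, so no single site (and no linear combination of the two) carries
    marginal signal.  Remaining sites are background noise.  Returns the two
    key site ids alongside the cohort.
    """
    if n_sites < 2:
        raise ValidationError("need at least the two interacting sites")
    ss = np.random.SeedSequence(seed)
    structure_rng, noise_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    site_ids = _site_ids(n_sites)
    key_a, key_b = site_ids[0], site_ids[1]

    # equal class sizes: disease states from {(0,1),(1,0)}, healthy from {(0,0),(1,1)}
    z = np.zeros((2 * n_per_class, 2), dtype=int)
    labels = np.array([0] * n_per_class + [1] * n_per_class)
    same = structure_rng.integers(0, 2, size=n_per_class)
    z[:n_per_class, 0] = same
    z[:n_per_class, 1] = same
    diff = structure_rng.integers(0, 2, size=n_per_class)
    z[n_per_class:, 0] = diff
    z[n_per_class:, 1] = 1 - diff

    base = structure_rng.uniform(0.2, 0.8, n_sites)
    means = np.tile(base, (2 * n_per_class, 1))
    level = np.array([low, high])
    means[:, 0] = level[z[:, 0]]
    means[:, 1] = level[z[:, 1]]

    betas = _draw(noise_rng, means, dispersion, "beta")
    order = structure_rng.permutation(2 * n_per_class)
    betas = betas[order]
    labels = labels[order]

    tag = tissue.replace(" ", "")
    sample_ids = [f"{tag}-x{i:03d}" for i in range(2 * n_per_class)]
    matrix = MethylationMatrix(sample_ids, site_ids, betas)
    meta = SampleMetadataTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "tissue": tissue,
                "status": labels,
                "dataset_id": "synthetic-xor",
            }
        ),
        tissue_vocabulary=(tissue,),
    )
    return matrix, meta, (key_a, key_b)
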