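"""Quality control and normalization of metabolite and ASV feature tables.

Metabolite tables go through a fixed preprocessing chain: drop metabolites
with excessive missingness, optionally adjust plasma intensities by sample
volume, rescale each metabolite to a median of one, impute remaining missing
cells with half the metabolite's observed minimum, and natural-log transform.
ASV count tables are prevalence-filtered and transformed with the centered
log-ratio (CLR). Finally, multivariate outlier samples are flagged by their
squared Mahalanobis distance in a low-dimensional PCA score space against a
chi-squared reference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "MetaboliteTable",
    "AsvTable",
    "filter_missing",
    "volume_adjust",
    "median_scale",
    "impute_half_min",
    "log_transform",
    "metabolite_qc_pipeline",
    "filter_asvs",
    "clr_transform",
    "mahalanobis_threshold",
    "detect_outliers",
]


@dataclass
class MetaboliteTable:
    """Sample x metabolite intensity matrix with explicit missing cells.

    ``values`` is a pandas DataFrame (rows = samples, columns = metabolites);
    missing measurements are NaN, which is distinct from an observed zero.
    ``sample_metadata`` is indexed by sample id and may carry ``genotype``,
    ``diet`` and ``volume`` columns. ``block_label`` identifies the omics
    block ("plasma" or "feces").
    """

    values: pd.DataFrame
    block_label: str = "plasma"
    sample_metadata: pd.DataFrame | None = None
    log_transformed: bool = False  # log-scale values may be negative

    def __post_init__(self) -> None:
        if self.log_transformed:
            return
        observed = self.values.to_numpy(dtype=float)
        if np.nanmin(observed, initial=0.0) < 0:
            raise ValueError("metabolite intensities must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.columns)

    def missing_fraction(self) -> pd.Series:
        """Per-metabolite fraction of missing cells."""
        return self.values.isna().mean(axis=0)


@dataclass
class AsvTable:
    """Sample x taxon count matrix (non-negative integers)."""

    counts: pd.DataFrame
    taxonomy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("ASV counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("ASV counts must be integers")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)


def filter_missing(t: MetaboliteTable, max_missing: float = 0.30) -> MetaboliteTable:
    """Remove metabolites whose missing fraction strictly exceeds ``max_missing``.

    A metabolite with missingness exactly at the threshold is retained
    (strictly-greater removal). Column order of survivors is preserved.
    """
    if t.values.empty:
        raise ValueError("cannot filter an empty metabolite table")
    frac = t.missing_fraction()
    keep = frac.index[frac.to_numpy() <= max_missing]
    removed = [m for m in t.metabolite_ids if m not in set(keep)]
    if removed:
        logger.info(
            "filter_missing: removed %d/%d metabolites (> %.0f%% missing)",
            len(removed), t.values.shape[1], 100 * max_missing,
        )
    if len(keep) == 0:
        warnings.warn("all metabolites removed by missingness filter", stacklevel=2)
    return replace(t, values=t.values.loc[:, keep])


def volume_adjust(t: MetaboliteTable) -> MetaboliteTable:
    """Divide each sample's intensities by its recorded collection volume.

    Applies to the plasma block only; feces tables pass through unchanged.
    Requires a ``volume`` column in ``sample_metadata``.
    """
    if t.block_label != "plasma":
        return t
    if t.sample_metadata is None or "volume" not in t.sample_metadata.columns:
        raise ValueError("volume adjustment requires 'volume' sample metadata")
    vols = t.sample_metadata.loc[t.values.index, "volume"].astype(float)
    if (vols <= 0).any():
        raise ValueError("sample volumes must be positive")
    return replace(t, values=t.values.div(vols, axis=0))


def median_scale(t: MetaboliteTable) -> MetaboliteTable:
    """Rescale each metabolite so its median over observed entries equals one.

    Missing cells stay missing; medians are computed over observed values only.
    Idempotent: scaling an already-scaled table is a no-op.
    """
    med = t.values.median(axis=0, skipna=True)
    if med.isna().any():
        bad = list(med.index[med.isna()])
        raise ValueError(f"metabolites with no observed values: {bad[:5]}")
    if (med <= 0).any():
        bad = list(med.index[med <= 0])
        raise ValueError(f"non-positive medians for metabolites: {bad[:5]}")
    return replace(t, values=t.values.div(med, axis=1))


def impute_half_min(t: MetaboliteTable) -> MetaboliteTable:
    """Replace each missing cell with half the metabolite's observed minimum.

    Presumes values are missing-not-at-random at low abundance (left
    censoring), so half the smallest observed value is a conservative stand-in.
    Observed values are never altered.
    """
    mins = t.values.min(axis=0, skipna=True)
    if mins.isna().any():
        bad = list(mins.index[mins.isna()])
        raise ValueError(f"cannot impute metabolites with no observations: {bad[:5]}")
    filled = t.values.fillna(0.5 * mins)
    return replace(t, values=filled)


def log_transform(t: MetaboliteTable) -> MetaboliteTable:
    """Natural-log transform; every cell must be strictly positive."""
    arr = t.values.to_numpy(dtype=float)
    if np.isnan(arr).any():
        i, j = np.argwhere(np.isnan(arr))[0]
        raise ValueError(
            f"missing cell at sample={t.values.index[i]!r}, "
            f"metabolite={t.values.columns[j]!r}; impute before log transform"
        )
    if (arr <= 0).any():
        i, j = np.argwhere(arr <= 0)[0]
        raise ValueError(
            f"non-positive value at sample={t.values.index[i]!r}, "
            f"metabolite={t.values.columns[j]!r}"
        )
    return replace(t, values=np.log(t.values), log_transformed=True)


def metabolite_qc_pipeline(
    t: MetaboliteTable, max_missing: float = 0.30, adjust_volume: bool | None = None
) -> MetaboliteTable:
    """Run the full metabolite chain: filter -> (volume) -> scale -> impute -> log.

    The stage order is fixed; ``adjust_volume`` defaults to True for the
    plasma block when volume metadata is available.
    """
    out = filter_missing(t, max_missing=max_missing)
    if adjust_volume is None:
        adjust_volume = (
            t.block_label == "plasma"
            and t.sample_metadata is not None
            and "volume" in t.sample_metadata.columns
        )
    if adjust_volume:
        out = volume_adjust(out)
    out = median_scale(out)
    out = impute_half_min(out)
    return log_transform(out)


def filter_asvs(
    a: AsvTable,
    prevalence_min: float = 0.10,
    require_zero_median: bool = True,
) -> AsvTable:
    """Drop taxa that are both rare and typically absent.

    A taxon is removed when its prevalence (fraction of samples with a
    non-zero count) is below ``prevalence_min`` AND (when
    ``require_zero_median``) its median count across samples is zero. The
    conjunction keeps taxa that are rare but abundant where present.
    """
    prevalence = (a.counts > 0).mean(axis=0)
    median = a.counts.median(axis=0)
    low_prev = prevalence < prevalence_min
    drop = low_prev & (median == 0) if require_zero_median else low_prev
    keep = a.counts.columns[~drop.to_numpy()]
    if drop.any():
        logger.info("filter_asvs: removed %d/%d taxa", int(drop.sum()), a.counts.shape[1])
    taxonomy = {k: v for k, v in a.taxonomy.items() if k in set(keep)}
    return AsvTable(counts=a.counts.loc[:, keep], taxonomy=taxonomy)


def clr_transform(a: AsvTable, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centered log-ratio transform of counts, one composition per sample.

    Each sample row becomes log(count + pseudocount) minus its own mean, so
    rows sum to zero. The transform is exactly scale-invariant only when the
    pseudocount is scaled with the counts; with a fixed pseudocount the
    invariance is approximate for large counts.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    logged = np.log(a.counts.to_numpy(dtype=float) + pseudocount)
    centered = logged - logged.mean(axis=1, keepdims=True)
    return pd.DataFrame(centered, index=a.counts.index, columns=a.counts.columns)


def mahalanobis_threshold(n_components: int = 2, quantile: float = 0.99) -> float:
    """Chi-squared inverse-CDF cutoff for squared Mahalanobis distances."""
    return float(stats.chi2.ppf(quantile, df=n_components))


def detect_outliers(
    x: pd.DataFrame | np.ndarray,
    n_components: int = 2,
    quantile: float = 0.99,
    iterative: bool = False,
) -> set:
    """Flag multivariate outlier samples in PCA score space.

    Samples are projected onto the first ``n_components`` principal
    components; the squared Mahalanobis distance of each score vector from
    the score centroid is compared against the chi-squared(df=n_components)
    inverse CDF at ``quantile``. Under multivariate normality roughly
    ``1 - quantile`` of samples are flagged.

    With ``iterative=True`` flagged samples are removed and the rule is
    re-applied until no new sample is flagged (off by default).
    """
    values = x.to_numpy(dtype=float) if isinstance(x, pd.DataFrame) else np.asarray(x, float)
    ids = list(x.index) if isinstance(x, pd.DataFrame) else list(range(values.shape[0]))
    if values.shape[0] < n_components + 2:
        raise ValueError("need at least n_components + 2 samples")

    threshold = mahalanobis_threshold(n_components, quantile)
    flagged: set = set()
    active = np.arange(values.shape[0])
    while True:
        scores = PCA(n_components=n_components).fit_transform(values[active])
        centered = scores - scores.mean(axis=0)
        cov = np.cov(centered, rowvar=False)
        if np.linalg.matrix_rank(np.atleast_2d(cov)) < n_components:
            raise np.linalg.LinAlgError(
                "singular score covariance; try fewer principal components"
            )
        d2 = np.einsum("ij,jk,ik->i", centered, np.linalg.inv(np.atleast_2d(cov)), centered)
        new = active[d2 > threshold]
        flagged.update(ids[i] for i in new)
        if not iterative or len(new) == 0:
            break
        active = np.array([i for i in active if i not in set(new)])
        if len(active) < n_components + 2:
            break
    return flagged
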