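"""Count-matrix container, CPM/TPM computation, TMM normalization and
expression-presence filters.

These primitives are shared by every downstream stage: the per-species
differential-expression tests run on TMM-normalized CPM, marker specificity
and threshold calibration run on TPM, and "expressed in a species" is
defined everywhere as passing :func:`filter_expressed`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

CONDITION_CLASSES = ("sexual", "vegetative_control", "atlas")
STAGES = ("S", "P", "GZ", "A")

SAMPLE_META_COLUMNS = ("species", "condition_class", "stage", "condition_label", "replicate")


@dataclass
class ExpressionMatrix:
    """Gene x sample read counts with per-sample metadata.

    ``counts`` is a genes-by-samples DataFrame (fractional counts are
    allowed; expectation-based quantifiers produce non-integers).
    ``sample_meta`` is indexed by sample id with columns ``species``,
    ``condition_class`` (sexual / vegetative_control / atlas), ``stage``
    (S, P, GZ, A or "none"), ``condition_label`` and ``replicate``.
    ``gene_lengths`` (bases) is optional and only required for TPM.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.counts.columns.duplicated().any():
            dups = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [s for s in self.counts.columns if s not in self.sample_meta.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing[:5]}")
        meta = self.sample_meta.loc[self.counts.columns]
        for col in SAMPLE_META_COLUMNS:
            if col not in meta.columns:
                raise ValueError(f"sample_meta missing column {col!r}")
        bad_class = set(meta["condition_class"]) - set(CONDITION_CLASSES)
        if bad_class:
            raise ValueError(f"unknown condition_class values: {sorted(bad_class)}")
        sexual = meta["condition_class"] == "sexual"
        if (meta.loc[sexual, "stage"] == "none").any():
            raise ValueError("sexual samples must carry a stage (S/P/GZ/A)")
        if (meta.loc[~sexual, "stage"] != "none").any():
            raise ValueError("non-sexual samples must have stage 'none'")
        if self.gene_lengths is not None:
            self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
            if self.gene_lengths.isna().any():
                raise ValueError("gene_lengths missing for some genes")
            if (self.gene_lengths <= 0).any():
                raise ValueError("gene_lengths must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def meta(self) -> pd.DataFrame:
        """Metadata aligned to the count columns."""
        return self.sample_meta.loc[self.counts.columns]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        ids = list(sample_ids)
        return ExpressionMatrix(
            self.counts[ids], self.sample_meta.loc[ids], self.gene_lengths
        )

    def samples_where(self, **criteria) -> list[str]:
        """Sample ids whose metadata match all given column=value pairs."""
        mask = pd.Series(True, index=self.counts.columns)
        meta = self.meta
        for col, val in criteria.items():
            mask &= meta[col] == val
        return list(self.counts.columns[mask])


@dataclass
class GeneFamilyTable:
    """Gene -> homologous family map with per-species copy counts.

    ``membership`` has one row per gene: gene_id, family_id, species.
    ``family_info`` is indexed by family_id with at least a boolean
    ``diatom_specific`` column (taxonomic scope of the family).
    ``copy_counts`` is a family x species matrix of gene copy numbers,
    derived from the membership unless supplied.
    """

    membership: pd.DataFrame
    family_info: pd.DataFrame
    copy_counts: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for col in ("gene_id", "family_id", "species"):
            if col not in self.membership.columns:
                raise ValueError(f"membership missing column {col!r}")
        if self.membership["gene_id"].duplicated().any():
            dup = self.membership.loc[self.membership["gene_id"].duplicated(), "gene_id"]
            raise ValueError(f"genes mapped to more than one family: {dup.tolist()[:5]}")
        if "diatom_specific" not in self.family_info.columns:
            raise ValueError("family_info missing column 'diatom_specific'")
        if self.copy_counts is None:
            self.copy_counts = (
                self.membership.groupby(["family_id", "species"])  # type: ignore[assignment]
                .size()
                .unstack(fill_value=0)
            )
        if (self.copy_counts.to_numpy() < 0).any():
            raise ValueError("copy counts must be non-negative")

    def family_of(self) -> pd.Series:
        """Series mapping gene_id -> family_id."""
        return self.membership.set_index("gene_id")["family_id"]

    def genes_in(self, family_id: str, species: str | None = None) -> list[str]:
        rows = self.membership[self.membership["family_id"] == family_id]
        if species is not None:
            rows = rows[rows["species"] == species]
        return rows["gene_id"].tolist()

    @property
    def family_ids(self) -> list[str]:
        return list(self.family_info.index)


@dataclass
class NormalizationResult:
    """Library sizes and TMM scale factors; geometric mean of factors is 1."""

    library_sizes: pd.Series
    tmm_factors: pd.Series

    def __post_init__(self) -> None:
        if (self.tmm_factors <= 0).any():
            raise ValueError("TMM factors must be positive")
        logf = np.log(self.tmm_factors.to_numpy(dtype=float))
        if abs(logf.mean()) > 1e-9:
            raise ValueError("TMM factors must have geometric mean 1")

    @property
    def effective_sizes(self) -> pd.Series:
        return self.library_sizes * self.tmm_factors


def compute_cpm(
    matrix: ExpressionMatrix, norm: NormalizationResult | None = None
) -> pd.DataFrame:
    """Counts per million, optionally on TMM-effective library sizes.

    CPM[g, s] = count[g, s] / effective_size[s] * 1e6. Without a
    normalization result the raw library size (column sum) is used.
    """
    if norm is None:
        sizes = matrix.counts.sum(axis=0)
    else:
        sizes = norm.effective_sizes.reindex(matrix.counts.columns)
    zero = sizes[sizes <= 0]
    if len(zero):
        raise ValueError(f"zero-library sample(s): {list(zero.index)}")
    return matrix.counts.div(sizes, axis=1) * 1e6


def tmm_factors(
    matrix: ExpressionMatrix,
    log_ratio_trim: float = 0.3,
    abs_expr_trim: float = 0.05,
) -> NormalizationResult:
    """Trimmed-mean-of-M-values scale factors.

    The reference sample is the one whose 75th-percentile CPM is closest
    to the mean 75th percentile (ties broken by lowest column index). For
    every sample, M (log2 expression ratio) and A (mean log2 abundance)
    are computed on genes with positive counts in both the sample and the
    reference; both tails are trimmed (30 % on M, 5 % on A) and the factor
    is 2 to the inverse-variance-weighted mean of the remaining M values.
    Factors are rescaled to geometric mean 1.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    samples = list(matrix.counts.columns)
    if len(samples) < 2:
        raise ValueError("TMM normalization requires at least 2 samples")
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = [s for s, l in zip(samples, lib) if l <= 0]
        raise ValueError(f"zero-library sample(s): {bad}")

    cpm = counts / lib * 1e6
    q75 = np.percentile(cpm, 75, axis=0)
    ref = int(np.argmin(np.abs(q75 - q75.mean())))

    factors = np.ones(len(samples))
    for j in range(len(samples)):
        if j == ref:
            factors[j] = 1.0
            continue
        factors[j] = _tmm_pair(
            counts[:, j], counts[:, ref], lib[j], lib[ref],
            log_ratio_trim, abs_expr_trim,
        )
    factors /= np.exp(np.mean(np.log(factors)))
    return NormalizationResult(
        library_sizes=pd.Series(lib, index=samples),
        tmm_factors=pd.Series(factors, index=samples),
    )


def _tmm_pair(obs, ref, n_obs, n_ref, log_ratio_trim, abs_expr_trim) -> float:
    pos = (obs > 0) & (ref > 0)
    if pos.sum() == 0:
        return 1.0
    o, r = obs[pos], ref[pos]
    log_r = np.log2((o / n_obs) / (r / n_ref))
    abs_e = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    # asymptotic variance of M (delta method); weight is its inverse
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    fin = np.isfinite(log_r) & np.isfinite(abs_e) & np.isfinite(v)
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    n = log_r.size
    if n == 0:
        return 1.0
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    lo_l = np.floor(n * log_ratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * abs_expr_trim) + 1
    hi_s = n + 1 - lo_s
    rank_m = rankdata(log_r)
    rank_a = rankdata(abs_e)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if keep.sum() == 0 or np.sum(1.0 / v[keep]) == 0:
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def filter_expressed(
    cpm: pd.DataFrame, min_cpm: float = 1.0, min_samples: int = 3
) -> pd.Index:
    """Genes with CPM strictly greater than ``min_cpm`` in >= ``min_samples`` samples."""
    if min_samples > cpm.shape[1]:
        raise ValueError(
            f"min_samples ({min_samples}) exceeds the number of samples ({cpm.shape[1]})"
        )
    n_over = (cpm > min_cpm).sum(axis=1)
    return cpm.index[n_over >= min_samples]


def compute_tpm(counts, lengths) -> pd.Series | np.ndarray:
    """Transcripts per million from counts and gene lengths (bases).

    rate_g = count_g / (length_g / 1000); TPM_g = rate_g / sum(rate) * 1e6.
    """
    counts_arr = np.asarray(counts, dtype=float)
    lengths_arr = np.asarray(lengths, dtype=float)
    if (lengths_arr <= 0).any():
        raise ValueError("gene lengths must be positive")
    if counts_arr.sum() <= 0:
        raise ValueError("all counts are zero: TPM composition undefined")
    rate = counts_arr / (lengths_arr / 1000.0)
    tpm = rate / rate.sum() * 1e6
    if isinstance(counts, pd.Series):
        return pd.Series(tpm, index=counts.index)
    return tpm


def tpm_table(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-sample TPM for every sample of an expression matrix.

    Requires ``gene_lengths``. Samples with zero total counts are dropped.
    """
    if matrix.gene_lengths is None:
        raise ValueError("TPM requires gene lengths")
    lengths = matrix.gene_lengths.to_numpy(dtype=float)
    rate = matrix.counts.to_numpy(dtype=float) / (lengths[:, None] / 1000.0)
    total = rate.sum(axis=0)
    keep = total > 0
    tpm = rate[:, keep] / total[keep] * 1e6
    return pd.DataFrame(tpm, index=matrix.counts.index,
                        columns=matrix.counts.columns[keep])
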