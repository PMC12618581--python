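"""Genus-level abundance association with sexual signals.

Relative abundances (fraction of total diatom reads per sample) are
compared between samples where a genus shows a sexual co-expression
signal and the remaining samples, with a two-sided Mann-Whitney U test,
Bonferroni correction over genera x amplicon regions, a rank-biserial
effect size (2U/(n1*n2) - 1) and a bootstrap percentile confidence
interval. Metabarcoding (ASV) tables are filtered by the taxonomy and
minimum-relative-abundance rules before aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig

logger = logging.getLogger(__name__)

REMOVED_PHYLA = {"Metazoa"}
REMOVED_CLASSES = {"Embryophyceae", "Streptophyta"}
UNIDENTIFIED = {"", "unidentified", "unknown", "na", "nan"}


def relative_abundance(
    reads: pd.DataFrame, diatom_genera: set[str] | None = None
) -> pd.DataFrame:
    """Per-sample genus fractions relative to total diatom reads.

    ``reads`` is long-format (sample_id, genus, reads). When
    ``diatom_genera`` is given, only those genera enter the denominator
    and the output. Samples with zero diatom reads are dropped with a log
    entry.
    """
    df = reads.copy()
    if diatom_genera is not None:
        df = df[df["genus"].isin(diatom_genera)]
    totals = df.groupby("sample_id")["reads"].sum()
    empty = totals[totals <= 0].index
    if len(empty):
        logger.info("dropping %d sample(s) with zero diatom reads", len(empty))
        df = df[~df["sample_id"].isin(empty)]
        totals = totals.drop(empty)
    df = df.groupby(["sample_id", "genus"], as_index=False)["reads"].sum()
    df["rel_abund"] = df["reads"] / df["sample_id"].map(totals)
    return df


@dataclass
class AssocResult:
    """Mann-Whitney association of abundance with the sexual signal."""

    genus: str
    region: str
    n_signal: int
    n_other: int
    u_statistic: float
    p_two_sided: float
    p_bonferroni: float
    effect_size: float
    ci95: tuple[float, float]


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of group x via the rank-sum identity (ties get half-wins)."""
    ranks = stats.rankdata(np.concatenate([x, y]))
    r1 = ranks[: x.size].sum()
    return float(r1 - x.size * (x.size + 1) / 2.0)


def mannwhitney_assoc(
    signal: np.ndarray,
    other: np.ndarray,
    *,
    genus: str = "",
    region: str = "",
    m_tests: int = 1,
    n_boot: int = 10_000,
    seed: int = 0,
    exact_limit: int = 10_000,
) -> AssocResult:
    """Two-sided Mann-Whitney U comparison of two abundance groups.

    The p-value is exact when n1*n2 <= ``exact_limit`` and the data are
    tie-free, otherwise the tie-corrected normal approximation is used.
    The effect size is the rank-biserial correlation with a bootstrap
    percentile 95 % CI (``n_boot`` resamples, seeded).
    """
    x = np.asarray(signal, dtype=float)
    y = np.asarray(other, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size * y.size <= exact_limit and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u = float(res.statistic)
    p = float(res.pvalue)
    n1n2 = x.size * y.size
    effect = 2.0 * u / n1n2 - 1.0

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        xb = x[rng.integers(0, x.size, x.size)]
        yb = y[rng.integers(0, y.size, y.size)]
        boots[b] = 2.0 * _u_statistic(xb, yb) / n1n2 - 1.0
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))

    return AssocResult(
        genus=genus, region=region, n_signal=int(x.size), n_other=int(y.size),
        u_statistic=u, p_two_sided=p,
        p_bonferroni=float(min(1.0, p * m_tests)),
        effect_size=float(effect), ci95=ci,
    )


def associate_genera(
    abundance: pd.DataFrame,
    signal_samples: dict[str, set[str]],
    *,
    region: str = "V4",
    mode: str = "disjoint",
    n_boot: int = 10_000,
    seed: int = 0,
    m_tests: int | None = None,
) -> pd.DataFrame:
    """Association tests for every genus with a signal sample set.

    ``abundance`` is the long table from :func:`relative_abundance`;
    ``signal_samples`` maps genus to the samples where it shows a sexual
    signal. ``mode="disjoint"`` compares signal vs non-signal samples
    (the printed group sizes of the source analyses indicate disjoint
    groups); ``mode="all"`` compares signal vs all samples.
    """
    if mode not in ("disjoint", "all"):
        raise ValueError(f"unknown mode {mode!r}")
    m = m_tests if m_tests is not None else len(signal_samples)
    rows = []
    for genus, sig_ids in sorted(signal_samples.items()):
        sub = abundance[abundance["genus"] == genus]
        by_sample = sub.set_index("sample_id")["rel_abund"]
        in_sig = by_sample.index.isin(sig_ids)
        x = by_sample[in_sig].to_numpy()
        y = by_sample.to_numpy() if mode == "all" else by_sample[~in_sig].to_numpy()
        if x.size == 0 or y.size == 0:
            continue
        r = mannwhitney_assoc(
            x, y, genus=genus, region=region, m_tests=m, n_boot=n_boot, seed=seed
        )
        rows.append({
            "genus": genus, "region": region, "n_signal": r.n_signal,
            "n_other": r.n_other, "U": r.u_statistic, "p": r.p_two_sided,
            "p_bonferroni": r.p_bonferroni, "effect_size": r.effect_size,
            "ci_low": r.ci95[0], "ci_high": r.ci95[1],
        })
    return pd.DataFrame(rows)


def filter_asv_table(
    counts: pd.DataFrame,
    taxonomy: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Taxonomy and abundance filtering of an ASV count table.

    ``counts`` is ASV x sample reads; ``taxonomy`` is indexed by ASV id
    with columns kingdom, infrakingdom, phylum and tax_class. ASVs with an
    unidentified kingdom or infrakingdom, the phylum Metazoa, or the
    classes Embryophyceae/Streptophyta are removed; then ASVs whose
    library-wide relative abundance is below ``asv_min_rel_abund``
    (default 1e-7, i.e. 1e-5 %) are removed and relative abundances are
    recomputed. Returns the filtered counts with a ``rel_abund`` column.
    """
    config = config or AnalysisConfig()
    tax = taxonomy.reindex(counts.index)

    def _unidentified(col: pd.Series) -> pd.Series:
        return col.isna() | col.astype(str).str.strip().str.lower().isin(UNIDENTIFIED)

    drop = (
        _unidentified(tax["kingdom"])
        | _unidentified(tax["infrakingdom"])
        | tax["phylum"].isin(REMOVED_PHYLA)
        | tax["tax_class"].isin(REMOVED_CLASSES)
    )
    kept = counts.loc[~drop]
    total = kept.to_numpy().sum()
    if total <= 0:
        return kept.assign(rel_abund=0.0).iloc[0:0]
    rel = kept.sum(axis=1) / total
    kept = kept.loc[rel >= config.asv_min_rel_abund]
    rel = kept.sum(axis=1) / kept.to_numpy().sum()
    out = kept.copy()
    out["rel_abund"] = rel
    return out
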