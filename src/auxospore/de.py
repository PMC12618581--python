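"""Per-stage differential expression, gene-level Sidak aggregation with
stage-wise Holm confirmation, family fold-change profiles and the
cross-species/cross-stage conservation matrices.

The DE engine is a fold-change-threshold ("TREAT"-style) test on
TMM-normalized log2 CPM: the statistic is (|log2FC| - tau) / se floored at
zero, so that evidence is required against the interval |log2FC| <= tau
rather than against zero. By default the per-gene variance is moderated
with an empirical-Bayes mean-variance trend (lowess trend on log residual
variances, prior degrees of freedom from trigamma moment matching), which
shares dispersion information across genes the way small-replicate RNA-seq
analyses must; ``moderate=False`` gives the plain Welch variant.

Externally produced DE tables (gene_id, species, stage, log2fc, se, p_raw)
can be ingested directly by the downstream steps, so a negative-binomial
GLM engine can be dropped in unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .config import AnalysisConfig
from .expression import (
    ExpressionMatrix,
    GeneFamilyTable,
    compute_cpm,
    filter_expressed,
    tmm_factors,
)

DE_RECORD_COLUMNS = ("gene_id", "species", "stage", "log2fc", "se", "df", "p_raw")


# ---------------------------------------------------------------------------
# variance moderation


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x for y > 0 (Newton iterations on 1/trigamma)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.max(np.abs(dif) / y) < 1e-8:
            break
    return y


def squeeze_variances(
    s2: np.ndarray, df: float, covariate: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Empirical-Bayes shrinkage of per-gene variances.

    Returns posterior variances and the prior degrees of freedom ``d0``
    (``np.inf`` when the observed variances are consistent with a single
    shared value). When ``covariate`` (typically mean log expression) is
    given, shrinkage is toward a lowess trend rather than a constant.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return s2.copy(), 0.0
    z = np.log(s2[ok])
    # E[log s^2] = log sigma^2 + digamma(df/2) - log(df/2)
    bias = special.digamma(df / 2.0) - np.log(df / 2.0)
    e = z - bias
    if covariate is not None and ok.sum() >= 30:
        trend = lowess(e, covariate[ok], frac=0.5, return_sorted=False)
    else:
        trend = np.full(ok.sum(), e.mean())
    resid = e - trend
    ev = float(np.var(resid, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if ev <= 1e-10:
        d0 = np.inf
        log_s0 = trend
    else:
        d0 = float(2.0 * _trigamma_inverse(np.array([ev]))[0])
        log_s0 = trend + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
    s0 = np.exp(log_s0)
    post = np.empty_like(s2)
    full_s0 = np.full(s2.shape, np.exp(e.mean() if covariate is None else np.median(trend)))
    full_s0[ok] = s0
    if np.isinf(d0):
        post = full_s0
    else:
        post = (d0 * full_s0 + df * np.where(ok, s2, 0.0)) / (d0 + df)
    return post, d0


# ---------------------------------------------------------------------------
# per-stage test


def de_test_stage(
    matrix: ExpressionMatrix,
    species: str,
    stage: str,
    config: AnalysisConfig | None = None,
    *,
    norm=None,
    moderate: bool = True,
) -> pd.DataFrame:
    """Fold-change-threshold DE test for one (species, stage) contrast.

    Sexual samples of the given stage are contrasted against the species'
    vegetative controls on log2(CPM + 0.5). Returns one record per
    expression-filtered gene with columns gene_id, species, stage, log2fc,
    se, df and p_raw.
    """
    config = config or AnalysisConfig()
    sub = matrix.subset_samples(matrix.samples_where(species=species))
    if not sub.sample_ids:
        raise ValueError(f"no samples for species {species!r}")
    sex_ids = sub.samples_where(condition_class="sexual", stage=stage)
    ctl_ids = sub.samples_where(condition_class="vegetative_control")
    if len(sex_ids) < 2 or len(ctl_ids) < 2:
        raise ValueError(
            f"contrast ({species}, {stage}) needs >=2 sexual and >=2 control "
            f"replicates (found {len(sex_ids)} and {len(ctl_ids)})"
        )
    if norm is None:
        norm = tmm_factors(sub)
    cpm = compute_cpm(sub, norm)
    genes = filter_expressed(cpm, config.min_cpm, min(config.min_samples, cpm.shape[1]))
    x = np.log2(cpm.loc[genes] + 0.5)
    xs = x[sex_ids].to_numpy()
    xc = x[ctl_ids].to_numpy()
    n1, n2 = xs.shape[1], xc.shape[1]
    m1, m2 = xs.mean(axis=1), xc.mean(axis=1)
    v1 = xs.var(axis=1, ddof=1)
    v2 = xc.var(axis=1, ddof=1)
    lfc = m1 - m2
    tau = config.logfc_threshold

    if moderate:
        # pooled residual variance, shrunk toward a mean-variance trend
        df_resid = n1 + n2 - 2
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df_resid
        abundance = (m1 * n1 + m2 * n2) / (n1 + n2)
        s2_post, d0 = squeeze_variances(s2, df_resid, covariate=abundance)
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        df_t = np.full(lfc.shape, min(df_resid + d0, 1e6))
    else:
        se = np.sqrt(v1 / n1 + v2 / n2)
        num = (v1 / n1 + v2 / n2) ** 2
        den = (v1 / n1) ** 2 / max(n1 - 1, 1) + (v2 / n2) ** 2 / max(n2 - 1, 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            df_t = np.where(den > 0, num / den, n1 + n2 - 2)
    se = np.maximum(se, 1e-8)
    t = np.maximum(np.abs(lfc) - tau, 0.0) / se
    p = np.minimum(1.0, 2.0 * stats.t.sf(t, df_t))
    return pd.DataFrame(
        {
            "gene_id": list(genes),
            "species": species,
            "stage": stage,
            "log2fc": lfc,
            "se": se,
            "df": df_t,
            "p_raw": p,
        }
    ).reset_index(drop=True)


def run_species_de(
    matrix: ExpressionMatrix,
    species: str,
    config: AnalysisConfig | None = None,
    *,
    moderate: bool = True,
) -> pd.DataFrame:
    """DE records for every sexual stage sampled in a species."""
    config = config or AnalysisConfig()
    sub = matrix.subset_samples(matrix.samples_where(species=species))
    stages = sorted(set(sub.meta.loc[sub.meta["condition_class"] == "sexual", "stage"]))
    if not stages:
        raise ValueError(f"species {species!r} has no sexual samples")
    norm = tmm_factors(sub)
    records = [
        de_test_stage(sub, species, st, config, norm=norm, moderate=moderate)
        for st in stages
    ]
    return pd.concat(records, ignore_index=True)


# ---------------------------------------------------------------------------
# gene-level aggregation and stage-wise adjustment


def sidak_aggregate(p_values) -> float:
    """Sidak combination over k stage p-values: 1 - (1 - min p)^k."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("sidak_aggregate requires at least one p-value")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return float(1.0 - (1.0 - p.min()) ** p.size)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (vectorised)."""
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


@dataclass
class StagewiseDEResult:
    """Stage-wise testing outcome.

    ``genes`` is indexed by gene_id with columns p_aggregate, q_screen and
    passes_screen; ``stages`` has one row per (gene, stage) with Holm-
    adjusted p-values, significance flags and direction. ``alpha_conf`` is
    the confirmation level alpha * R / m.
    """

    genes: pd.DataFrame
    stages: pd.DataFrame
    alpha: float
    alpha_conf: float
    n_pass: int
    n_tested: int

    def significant_up(self) -> pd.DataFrame:
        s = self.stages
        return s[s["significant"] & (s["log2fc"] > 0)]


def stagewise_adjust(records: pd.DataFrame, alpha: float = 0.05) -> StagewiseDEResult:
    """Two-step stage-wise multiple testing.

    Screening: per-gene Sidak aggregation of the stage p-values, BH
    adjustment across genes at level ``alpha``. Confirmation: for genes
    that pass screening, Holm adjustment of their stage p-values; a stage
    is significant when its Holm p-value is at most alpha * R / m, where R
    genes of m passed screening. A stage can only be significant for a
    gene that passed screening.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    required = {"gene_id", "stage", "p_raw", "log2fc"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    if records.empty:
        raise ValueError("no DE records supplied")

    # gene x stage matrix of raw p-values (NaN where a stage was not tested)
    pmat = records.pivot_table(index="gene_id", columns="stage", values="p_raw")
    pvals = pmat.to_numpy()
    k = (~np.isnan(pvals)).sum(axis=1)
    pmin = np.nanmin(pvals, axis=1)
    p_agg = 1.0 - (1.0 - pmin) ** k
    q = _bh_adjust(p_agg)
    passes = q <= alpha
    m = len(pmat.index)
    r = int(passes.sum())
    alpha_conf = alpha * r / m if m else 0.0

    genes = pd.DataFrame(
        {"p_aggregate": p_agg, "q_screen": q, "passes_screen": passes},
        index=pmat.index,
    )

    # Holm within each gene, vectorised over the gene x stage matrix
    order = np.argsort(np.where(np.isnan(pvals), np.inf, pvals), axis=1)
    sorted_p = np.take_along_axis(pvals, order, axis=1)
    nan_mask = np.isnan(sorted_p)
    mult = k[:, None] - np.arange(pvals.shape[1])[None, :]
    adj = sorted_p * np.maximum(mult, 1)
    run = np.maximum.accumulate(np.where(nan_mask, -np.inf, adj), axis=1)
    adj = np.where(nan_mask, np.nan, np.minimum(run, 1.0))
    p_holm = np.full_like(pvals, np.nan)
    np.put_along_axis(p_holm, order, adj, axis=1)

    holm_df = (
        pd.DataFrame(p_holm, index=pmat.index, columns=pmat.columns)
        .stack()
        .rename("p_holm")
        .reset_index()
    )
    stages_df = records.merge(holm_df, on=["gene_id", "stage"], how="left")
    gene_pass = genes["passes_screen"]
    stages_df["significant"] = (
        stages_df["gene_id"].map(gene_pass).fillna(False).astype(bool)
        & (stages_df["p_holm"] <= alpha_conf)
    )
    stages_df["direction"] = np.where(stages_df["log2fc"] > 0, "up", "down")
    return StagewiseDEResult(
        genes=genes, stages=stages_df, alpha=alpha,
        alpha_conf=alpha_conf, n_pass=r, n_tested=m,
    )


# ---------------------------------------------------------------------------
# family-level profiles and conservation matrices


def family_logfc_profile(
    stages: pd.DataFrame, families: GeneFamilyTable
) -> pd.DataFrame:
    """Mean log2FC of significantly DE member genes per family and cell.

    ``stages`` must carry gene_id, species, stage, log2fc and significant
    (the ``stages`` table of one or more :class:`StagewiseDEResult`,
    concatenated across species). Cells without any significant member
    gene are omitted.
    """
    sig = stages[stages["significant"]].copy()
    if sig.empty:
        return pd.DataFrame(
            columns=["family_id", "species", "stage", "mean_log2fc", "n_de_genes"]
        )
    sig["family_id"] = sig["gene_id"].map(families.family_of())
    sig = sig.dropna(subset=["family_id"])
    out = (
        sig.groupby(["family_id", "species", "stage"], sort=True)
        .agg(mean_log2fc=("log2fc", "mean"), n_de_genes=("gene_id", "nunique"))
        .reset_index()
    )
    return out


def cross_stage_correlation(profile: pd.DataFrame, min_shared: int = 3) -> pd.DataFrame:
    """Pairwise conservation of the sex response across (species, stage) cells.

    For every pair of cells: the number of families with significantly DE
    genes in both, and the Pearson correlation (with two-sided t-based
    p-value) of the family mean log2FCs over those shared families.
    Correlations are reported only when at least ``min_shared`` families
    are shared. The output is a long table (cell_a, cell_b, n_shared, r,
    p); the diagonal rows carry the per-cell family counts and r = 1.
    """
    prof = profile.copy()
    prof["cell"] = list(zip(prof["species"], prof["stage"]))
    cells = sorted(set(prof["cell"]))
    if len(cells) < 2:
        raise ValueError("need at least 2 (species, stage) cells")
    by_cell = {
        c: g.set_index("family_id")["mean_log2fc"] for c, g in prof.groupby("cell")
    }
    rows = []
    for i, a in enumerate(cells):
        for b in cells[i:]:
            fa, fb = by_cell[a], by_cell[b]
            shared = fa.index.intersection(fb.index)
            n_shared = len(shared)
            if a == b:
                rows.append({"cell_a": a, "cell_b": b, "n_shared": n_shared,
                             "r": 1.0, "p": 0.0})
                continue
            if n_shared >= min_shared and fa[shared].std() > 0 and fb[shared].std() > 0:
                r, p = stats.pearsonr(fa[shared], fb[shared])
            else:
                r, p = np.nan, np.nan
            rows.append({"cell_a": a, "cell_b": b, "n_shared": n_shared,
                         "r": r, "p": p})
    return pd.DataFrame(rows)
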