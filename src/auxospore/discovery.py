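"""Data-driven discovery of conserved sex-marker gene families.

The five-step procedure operates on cross-species DE results joined
through homologous gene families:

1. keep diatom-specific families expressed in >= 3 of the sexual species;
2. keep families where every expressed member gene is significantly
   upregulated (and none significantly downregulated) in every species
   where the family is expressed;
3. rank the survivors by the mean log2 fold change over all significant
   (gene, stage) observations;
4. check the top-ranked families for negligible expression in the
   vegetative expression atlas;
5. select the top-k candidates that pass as the marker panel.

A curated selection rule (for flagella genes of centric diatoms) and a
matched control-marker selection complete the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .de import StagewiseDEResult
from .expression import ExpressionMatrix, GeneFamilyTable, tpm_table

STATUS_ORDER = ("excluded_step1", "excluded_step2", "ranked", "specific", "selected")


@dataclass
class MarkerPanel:
    """Ordered marker families with labels and clade applicability.

    ``markers`` maps label (M1..Mk, SPO11-2, flagella names) to family id;
    ``applicability`` maps label to one of raphid_pennate / centric /
    all_diatoms.
    """

    markers: dict[str, str]
    applicability: dict[str, str] = field(default_factory=dict)
    positive_control: str = "SPO11-2"

    def __post_init__(self) -> None:
        for label in self.markers:
            self.applicability.setdefault(label, "all_diatoms")

    @property
    def labels(self) -> list[str]:
        return list(self.markers)


def discover_markers(
    families: GeneFamilyTable,
    stagewise: dict[str, StagewiseDEResult],
    expressed: dict[str, set[str]],
    config: AnalysisConfig | None = None,
    *,
    min_species: int = 3,
    rank_pooling: str = "pooled",
) -> pd.DataFrame:
    """Steps 1-3 of the discovery procedure.

    Parameters
    ----------
    families
        Gene family membership with the diatom-specificity flag.
    stagewise
        Per-species stage-wise DE results.
    expressed
        Per-species sets of expressed gene ids (the CPM presence filter
        applied within each species).
    min_species
        Minimum number of species in which a family must be expressed.
    rank_pooling
        ``pooled`` averages log2FC over all significant (gene, stage,
        species) observations; ``species_mean`` averages within species
        first.

    Returns a DataFrame indexed by family_id with a machine-readable
    ``status`` (excluded_step1 / excluded_step2 / ranked), the exclusion
    step recorded for every dropped family, the number of species in which
    the family is expressed, and the rank score for surviving families,
    sorted by descending score (ties broken by family id).
    """
    config = config or AnalysisConfig()
    if not families.family_ids:
        raise ValueError("empty gene family table")
    if len(expressed) < min_species:
        raise ValueError(
            f"need expression data for >= {min_species} species, got {len(expressed)}"
        )
    if rank_pooling not in ("pooled", "species_mean"):
        raise ValueError(f"unknown rank_pooling {rank_pooling!r}")

    fam_of = families.family_of()
    membership = families.membership

    # per (family, species): expressed member genes
    expressed_by_species = {
        sp: membership[membership["species"].eq(sp) & membership["gene_id"].isin(genes)]
        for sp, genes in expressed.items()
    }
    n_species_expressed = pd.Series(0, index=families.family_info.index, dtype=int)
    for sp, rows in expressed_by_species.items():
        fams = rows["family_id"].unique()
        n_species_expressed.loc[n_species_expressed.index.isin(fams)] += 1

    diatom_specific = families.family_info["diatom_specific"].astype(bool)

    # per-species significance lookups
    sig_up: dict[str, pd.DataFrame] = {}
    sig_down_genes: dict[str, set[str]] = {}
    for sp, res in stagewise.items():
        s = res.stages
        up = s[s["significant"] & (s["log2fc"] > 0)]
        sig_up[sp] = up
        sig_down_genes[sp] = set(s.loc[s["significant"] & (s["log2fc"] <= 0), "gene_id"])

    records = []
    for fam in families.family_info.index:
        status = "ranked"
        if not (diatom_specific.loc[fam] and n_species_expressed.loc[fam] >= min_species):
            status = "excluded_step1"
        else:
            for sp, rows in expressed_by_species.items():
                fam_genes = rows.loc[rows["family_id"] == fam, "gene_id"]
                if fam_genes.empty:
                    continue
                up_genes = set(sig_up.get(sp, pd.DataFrame(columns=["gene_id"]))["gene_id"])
                if not set(fam_genes) <= up_genes:
                    status = "excluded_step2"
                    break
                if set(fam_genes) & sig_down_genes.get(sp, set()):
                    status = "excluded_step2"
                    break
        records.append(
            {"family_id": fam, "status": status,
             "n_species_expressed": int(n_species_expressed.loc[fam])}
        )
    out = pd.DataFrame(records).set_index("family_id")

    # step 3: rank score over significant upregulated observations
    obs = []
    for sp, up in sig_up.items():
        u = up.copy()
        u["family_id"] = u["gene_id"].map(fam_of)
        u["species"] = sp
        obs.append(u.dropna(subset=["family_id"]))
    scores = pd.Series(dtype=float)
    if obs:
        allobs = pd.concat(obs, ignore_index=True)
        if rank_pooling == "pooled":
            scores = allobs.groupby("family_id")["log2fc"].mean()
        else:
            scores = (
                allobs.groupby(["family_id", "species"])["log2fc"].mean()
                .groupby("family_id").mean()
            )
    out["rank_score"] = np.where(
        out["status"].eq("ranked"), out.index.map(scores), np.nan
    )
    # a "ranked" family with no significant observation cannot happen
    # (step 2 demands significance wherever expressed), but guard anyway
    out.loc[out["status"].eq("ranked") & out["rank_score"].isna(), "status"] = (
        "excluded_step2"
    )
    out = out.sort_values(
        ["rank_score"], ascending=False, kind="mergesort", na_position="last"
    )
    ranked = out[out["status"].eq("ranked")].sort_values(
        ["rank_score", "family_id"], ascending=[False, True], kind="mergesort"
    )
    rest = out[~out["status"].eq("ranked")]
    return pd.concat([ranked, rest])


def specificity_filter(
    candidates: pd.DataFrame,
    atlas: ExpressionMatrix,
    sexual: ExpressionMatrix,
    families: GeneFamilyTable,
    config: AnalysisConfig | None = None,
    *,
    top_n: int = 10,
    k: int | None = None,
    eps: float = 1e-3,
) -> pd.DataFrame:
    """Steps 4-5: verify negligible atlas expression and select the top-k.

    For each of the ``top_n`` highest-ranked candidates: the maximum TPM
    over non-sexual atlas samples, the mean TPM over sexual samples of the
    atlas species, and their ratio (fold separation). A candidate passes
    when max_nonsexual <= config.max_nonsexual_tpm OR fold_separation >=
    config.min_fold_separation. Families without a member gene in the
    atlas species are marked ``untestable`` rather than passed silently.
    The k highest-ranked passing candidates get status ``selected``.
    """
    config = config or AnalysisConfig()
    k = config.top_k if k is None else k
    atlas_tpm = tpm_table(atlas)
    atlas_cols = [
        s for s in atlas_tpm.columns
        if atlas.sample_meta.loc[s, "condition_class"] != "sexual"
    ]
    sexual_tpm = tpm_table(sexual)
    sexual_cols = [
        s for s in sexual_tpm.columns
        if sexual.sample_meta.loc[s, "condition_class"] == "sexual"
    ]
    if not atlas_cols:
        raise ValueError("atlas matrix has no non-sexual samples")

    ranked = candidates[candidates["status"].isin(("ranked", "specific", "selected"))]
    top = ranked.head(top_n)
    out = candidates.copy()
    for col, dtype in (
        ("max_nonsexual_tpm", float), ("sexual_mean_tpm", float),
        ("fold_separation", float),
    ):
        if col not in out.columns:
            out[col] = np.nan
    if "specificity" not in out.columns:
        out["specificity"] = None

    membership = families.membership
    for fam in top.index:
        genes_atlas = membership.loc[
            membership["family_id"].eq(fam)
            & membership["gene_id"].isin(atlas_tpm.index), "gene_id"
        ]
        if genes_atlas.empty:
            out.loc[fam, "specificity"] = "untestable"
            continue
        max_ns = float(atlas_tpm.loc[genes_atlas, atlas_cols].to_numpy().max())
        genes_sex = membership.loc[
            membership["family_id"].eq(fam)
            & membership["gene_id"].isin(sexual_tpm.index), "gene_id"
        ]
        sex_mean = (
            float(sexual_tpm.loc[genes_sex, sexual_cols].to_numpy().mean())
            if len(genes_sex) and sexual_cols else np.nan
        )
        fold = sex_mean / (max_ns + eps) if np.isfinite(sex_mean) else np.nan
        passes = (max_ns <= config.max_nonsexual_tpm) or (
            np.isfinite(fold) and fold >= config.min_fold_separation
        )
        out.loc[fam, "max_nonsexual_tpm"] = max_ns
        out.loc[fam, "sexual_mean_tpm"] = sex_mean
        out.loc[fam, "fold_separation"] = fold
        out.loc[fam, "specificity"] = "pass" if passes else "fail"
        if passes:
            out.loc[fam, "status"] = "specific"
    chosen = [f for f in out.index if out.loc[f, "status"] == "specific"][:k]
    out.loc[chosen, "status"] = "selected"
    return out


def build_marker_panel(
    selected: pd.DataFrame,
    *,
    applicability: dict[str, str] | None = None,
    positive_control_family: str | None = None,
    curated: dict[str, str] | None = None,
) -> MarkerPanel:
    """Assemble a panel (M1..Mk labels in rank order) from selected candidates."""
    fams = [f for f in selected.index if selected.loc[f, "status"] == "selected"]
    markers = {f"M{i + 1}": fam for i, fam in enumerate(fams)}
    appl = {lab: "raphid_pennate" for lab in markers}
    if applicability:
        appl.update(applicability)
    if curated:
        for lab, fam in curated.items():
            markers[lab] = fam
            appl.setdefault(lab, "centric")
    panel = MarkerPanel(markers=markers, applicability=appl)
    if positive_control_family is not None:
        panel.markers[panel.positive_control] = positive_control_family
        panel.applicability[panel.positive_control] = "all_diatoms"
    return panel


def select_curated_markers(
    candidate_genes: pd.DataFrame,
    stagewise: StagewiseDEResult,
    expressed_sexual: set[str],
) -> list[str]:
    """Curated (e.g. flagella) marker rule for the designated centric species.

    ``candidate_genes`` has columns gene_id and family_id. A family is
    kept when at least one candidate gene is expressed during sex and
    significantly upregulated in >= 1 stage.
    """
    if candidate_genes.empty:
        raise ValueError("empty curated candidate list")
    up = set(stagewise.significant_up()["gene_id"])
    keep = candidate_genes[
        candidate_genes["gene_id"].isin(expressed_sexual)
        & candidate_genes["gene_id"].isin(up)
    ]
    return sorted(keep["family_id"].unique())


@dataclass
class ControlPanel:
    """Control families matched one-to-one to target markers."""

    controls: dict[str, str]          # control label -> family id
    matched_to: dict[str, str]        # control label -> target marker label
    stats: pd.DataFrame               # per family: mean_tpm, cv, match_distance


def select_control_markers(
    families: GeneFamilyTable,
    stagewise: dict[str, StagewiseDEResult],
    nonsexual_tpm: pd.DataFrame,
    targets: dict[str, str],
    *,
    reference_species: list[str] | None = None,
    exclude: set[str] | None = None,
    max_duplicated_species: int = 1,
    eps: float = 1e-3,
) -> ControlPanel:
    """Match each target marker to a non-sex control family.

    Eligibility: (1) encoded in >= 3 of the reference species; (2) single
    copy everywhere, allowing one duplication in a single species; (3) no
    member gene significantly upregulated during sex in any species; plus
    not on the exclusion list. Matching is greedy in target order, to the
    nearest unused eligible family by Euclidean distance in
    (log10(mean TPM + eps), CV) space.

    ``nonsexual_tpm`` is a gene x sample table of TPM in non-sexual
    conditions, used to place each family in (mean, CV) space.
    """
    exclude = exclude or set()
    cc = families.copy_counts
    species = reference_species or list(cc.columns)
    cc = cc.reindex(columns=species, fill_value=0)

    present = (cc > 0).sum(axis=1)
    n_dup = (cc > 1).sum(axis=1)
    max_copies = cc.max(axis=1)
    eligible_shape = (present >= 3) & (n_dup <= max_duplicated_species) & (max_copies <= 2)

    up_families: set[str] = set()
    fam_of = families.family_of()
    for res in stagewise.values():
        up = res.significant_up()
        up_families |= set(up["gene_id"].map(fam_of).dropna())

    fam_stats = _family_expression_stats(families, nonsexual_tpm, eps)
    eligible = [
        f for f in fam_stats.index
        if f not in exclude
        and f not in up_families
        and f not in set(targets.values())
        and f in eligible_shape.index
        and bool(eligible_shape.loc[f])
    ]
    if len(eligible) < len(targets):
        raise ValueError(
            f"only {len(eligible)} eligible control families for "
            f"{len(targets)} targets: {sorted(set(targets))}"
        )

    target_stats = {}
    for label, fam in targets.items():
        if fam not in fam_stats.index:
            raise ValueError(f"target family {fam} has no non-sexual expression data")
        target_stats[label] = fam_stats.loc[fam]

    used: set[str] = set()
    controls: dict[str, str] = {}
    matched_to: dict[str, str] = {}
    rows = []
    for i, (label, fam) in enumerate(targets.items()):
        t = target_stats[label]
        best, best_d = None, np.inf
        for cand in eligible:
            if cand in used:
                continue
            c = fam_stats.loc[cand]
            d = float(np.hypot(t["log_mean_tpm"] - c["log_mean_tpm"], t["cv"] - c["cv"]))
            if d < best_d or (d == best_d and (best is None or cand < best)):
                best, best_d = cand, d
        assert best is not None
        used.add(best)
        ctrl_label = "PC" if label == "SPO11-2" else f"C{i + 1}"
        controls[ctrl_label] = best
        matched_to[ctrl_label] = label
        rows.append({
            "control": ctrl_label, "family_id": best, "target": label,
            "mean_tpm": float(10 ** fam_stats.loc[best, "log_mean_tpm"] - eps),
            "cv": float(fam_stats.loc[best, "cv"]),
            "match_distance": best_d,
        })
    return ControlPanel(controls=controls, matched_to=matched_to,
                        stats=pd.DataFrame(rows).set_index("control"))


def _family_expression_stats(
    families: GeneFamilyTable, nonsexual_tpm: pd.DataFrame, eps: float
) -> pd.DataFrame:
    """Per-family mean non-sexual TPM (log10) and coefficient of variation."""
    fam_of = families.family_of()
    tpm = nonsexual_tpm.copy()
    tpm["family_id"] = tpm.index.map(fam_of)
    tpm = tpm.dropna(subset=["family_id"])
    value_cols = [c for c in tpm.columns if c != "family_id"]
    long = tpm.melt(id_vars="family_id", value_vars=value_cols, value_name="tpm")
    g = long.groupby("family_id")["tpm"]
    mean = g.mean()
    std = g.std(ddof=1)
    cv = (std / mean.replace(0, np.nan)).fillna(0.0)
    return pd.DataFrame({
        "log_mean_tpm": np.log10(mean + eps),
        "cv": cv,
    })
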