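"""Seeded generators for every input the pipeline consumes, with ground truth.

The generators emulate the statistical structure of multi-species diatom
sex-transcriptome experiments and of MAG-resolved ocean metatranscriptomes:

* log-normal baseline expression (sigma = 1.5 in log10 TPM gives a
  realistic bulk RNA-seq dynamic range) with negative-binomial counts
  (gene-level dispersion 0.1, typical bulk overdispersion across
  biological replicates);
* planted marker families upregulated by a drawn log2 fold change in the
  sexual samples of designated stages of every species carrying them,
  and planted control families that stay flat;
* MAG x sample tables where sexual cells express panel markers strictly
  above the calibrated thresholds while non-sexual cells leak marker
  expression from the very distribution the thresholds are calibrated
  on (so the 95th-percentile rule has a designed 5 % per-draw exceedance);
* annotated trees with a known reference clade and planted inside/outside
  queries, and HMM hit tables with score-separated true and decoy hits.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .events import (
    CENTRIC_MARKERS,
    CONTROL_MARKERS,
    CONTROL_POSITIVE,
    PENNATE_MARKERS,
    POSITIVE_CONTROL,
    MagDataset,
    MagTable,
    percentile_threshold,
)
from .expression import ExpressionMatrix, GeneFamilyTable
from .homologs import HmmHit


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic datasets."""

    # multi-species sex experiment
    n_species: int = 4
    stages: tuple[str, ...] = ("S", "P", "GZ", "A")
    replicates: int = 3
    n_families: int = 500
    n_planted_markers: int = 3
    n_planted_controls: int = 3
    effect_low: float = 3.0
    effect_high: float = 6.0
    marker_stages: tuple[str, ...] = ("S", "P", "GZ", "A")
    presence_prob: float = 0.85
    dup_prob: float = 0.1
    diatom_specific_prob: float = 0.5
    baseline_log10tpm_mean: float = 1.0
    baseline_log10tpm_sd: float = 1.5
    marker_baseline_tpm: float = 10.0
    control_baseline_tpm: float = 15.0
    dispersion: float = 0.1
    library_size: float = 2e6
    # expression atlas
    atlas_conditions: int = 40
    atlas_replicates: int = 3
    atlas_condition_sd: float = 0.3
    marker_atlas_tpm: float = 0.05
    n_leaky_markers: int = 0
    leak_ratio: float = 0.5
    # MAG metatranscriptome
    n_mags: int = 20
    n_mag_samples: int = 40
    genes_per_mag: int = 2000
    sexual_cell_fraction: float = 0.10
    mag_depth_median: float = 2e5
    mag_depth_sigma: float = 0.5
    low_depth_fraction: float = 0.05
    pennate_fraction: float = 0.6
    other_fraction: float = 0.0
    calib_log_tpm_mean: float = math.log(100.0)
    calib_log_tpm_sd: float = 1.0
    n_calibration: int = 140
    sexual_uplift_low: float = 1.0
    sexual_uplift_high: float = 4.0
    # marker tree
    n_refs: int = 6
    n_outgroups: int = 3
    n_queries_inside: int = 4
    n_queries_outside: int = 3
    support: int = 100
    # HMM hit table
    n_true_hits: int = 30
    n_decoy_hits: int = 30
    true_score_mean: float = 120.0
    decoy_score_mean: float = 30.0
    score_sd: float = 12.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sexual_cell_fraction <= 1.0:
            raise ValueError("sexual_cell_fraction must be in [0, 1]")
        if self.n_planted_markers + self.n_planted_controls > self.n_families:
            raise ValueError("more planted families than families")
        if self.effect_high < self.effect_low:
            raise ValueError("effect_high < effect_low")
        for name in ("n_species", "replicates", "n_families", "n_mags",
                     "n_mag_samples", "genes_per_mag", "n_calibration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class GroundTruth:
    """Planted truth emitted alongside each synthetic dataset."""

    marker_families: list[str] = field(default_factory=list)
    control_families: list[str] = field(default_factory=list)
    leaky_families: list[str] = field(default_factory=list)
    effects: dict[str, float] = field(default_factory=dict)
    marker_stages: tuple[str, ...] = ()
    sexual_cells: set[tuple[str, str]] = field(default_factory=set)
    inside_queries: set[str] = field(default_factory=set)
    true_hit_targets: set[str] = field(default_factory=set)


@dataclass
class SimulatedExperiment:
    """Output of :func:`simulate_multispecies`."""

    matrices: dict[str, ExpressionMatrix]
    families: GeneFamilyTable
    truth: GroundTruth
    baselines: dict[str, pd.Series]   # per species: gene -> baseline TPM
    config: SimConfig


def _rng(config: SimConfig, seed: int | None) -> np.random.Generator:
    return np.random.default_rng(config.rng_seed if seed is None else seed)


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with mean mu and dispersion phi (var = mu + phi mu^2)."""
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mu).astype(float)
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p).astype(float)


def simulate_multispecies(
    config: SimConfig | None = None, seed: int | None = None
) -> SimulatedExperiment:
    """Multi-species sex transcriptome experiment with planted markers.

    Families are drawn with per-species presence and copy numbers; the
    planted marker and control families are single-copy, diatom-specific
    and present in every species. Counts are negative binomial around
    condition means; marker families are upregulated by their drawn
    log2FC in the sexual samples of the designated stages.
    """
    config = config or SimConfig()
    rng = _rng(config, seed)
    species = [f"sp{i + 1}" for i in range(config.n_species)]
    fam_ids = [f"fam{i + 1:04d}" for i in range(config.n_families)]

    # planted families are drawn at random positions among all families
    planted_idx = rng.choice(
        config.n_families, config.n_planted_markers + config.n_planted_controls,
        replace=False,
    )
    markers = [fam_ids[i] for i in planted_idx[: config.n_planted_markers]]
    controls = [fam_ids[i] for i in planted_idx[config.n_planted_markers:]]
    planted = set(markers) | set(controls)

    diatom_specific = {}
    presence: dict[str, dict[str, int]] = {}
    for fam in fam_ids:
        if fam in planted:
            diatom_specific[fam] = True
            presence[fam] = {sp: 1 for sp in species}
        else:
            diatom_specific[fam] = bool(rng.random() < config.diatom_specific_prob)
            pres = {}
            for sp in species:
                if rng.random() < config.presence_prob:
                    pres[sp] = 1 + int(rng.random() < config.dup_prob)
            if not pres:  # keep every family represented somewhere
                pres[species[int(rng.integers(len(species)))]] = 1
            presence[fam] = pres

    effects = {fam: float(rng.uniform(config.effect_low, config.effect_high))
               for fam in markers}

    membership_rows = []
    gene_meta: dict[str, list[tuple[str, str]]] = {sp: [] for sp in species}
    for fam in fam_ids:
        for sp, copies in presence[fam].items():
            for c in range(copies):
                gid = f"{sp}_{fam}_c{c + 1}"
                membership_rows.append({"gene_id": gid, "family_id": fam, "species": sp})
                gene_meta[sp].append((gid, fam))
    membership = pd.DataFrame(membership_rows)
    family_info = pd.DataFrame(
        {"diatom_specific": [diatom_specific[f] for f in fam_ids]}, index=fam_ids
    )
    family_info.index.name = "family_id"
    families = GeneFamilyTable(membership=membership, family_info=family_info)

    matrices: dict[str, ExpressionMatrix] = {}
    baselines: dict[str, pd.Series] = {}
    for sp in species:
        genes = [g for g, _ in gene_meta[sp]]
        fams = np.array([f for _, f in gene_meta[sp]])
        n_genes = len(genes)
        base = 10.0 ** rng.normal(
            config.baseline_log10tpm_mean, config.baseline_log10tpm_sd, n_genes
        )
        is_marker = np.isin(fams, markers)
        is_control = np.isin(fams, controls)
        base[is_marker] = config.marker_baseline_tpm * 10.0 ** rng.normal(0, 0.1, is_marker.sum())
        base[is_control] = config.control_baseline_tpm * 10.0 ** rng.normal(0, 0.3, is_control.sum())
        # scale the background so nominal values are true TPM (sum 1e6)
        planted_mask = is_marker | is_control
        bg_total = base[~planted_mask].sum()
        if bg_total > 0:
            base[~planted_mask] *= max(1e6 - base[planted_mask].sum(), 1e5) / bg_total
        lengths = np.exp(rng.normal(math.log(1500.0), 0.4, n_genes))
        fam_effect = np.array([effects.get(f, 0.0) for f in fams])

        sample_ids, meta_rows, cols = [], [], []
        for stage in config.stages:
            up = np.where(
                is_marker & (stage in config.marker_stages), 2.0 ** fam_effect, 1.0
            )
            for r in range(config.replicates):
                w = base * up * lengths
                depth = config.library_size * np.exp(rng.normal(0, 0.1))
                mu = depth * w / w.sum()
                cols.append(_nb_counts(rng, mu, config.dispersion))
                sid = f"{sp}_{stage}_sex{r + 1}"
                sample_ids.append(sid)
                meta_rows.append({
                    "sample_id": sid, "species": sp, "condition_class": "sexual",
                    "stage": stage, "condition_label": f"{stage}_sexual",
                    "replicate": r + 1,
                })
        for r in range(config.replicates):
            w = base * lengths
            depth = config.library_size * np.exp(rng.normal(0, 0.1))
            mu = depth * w / w.sum()
            cols.append(_nb_counts(rng, mu, config.dispersion))
            sid = f"{sp}_ctrl{r + 1}"
            sample_ids.append(sid)
            meta_rows.append({
                "sample_id": sid, "species": sp,
                "condition_class": "vegetative_control", "stage": "none",
                "condition_label": "vegetative", "replicate": r + 1,
            })
        counts = pd.DataFrame(
            np.column_stack(cols), index=genes, columns=sample_ids
        )
        meta = pd.DataFrame(meta_rows).set_index("sample_id")
        matrices[sp] = ExpressionMatrix(
            counts=counts, sample_meta=meta,
            gene_lengths=pd.Series(lengths, index=genes),
        )
        baselines[sp] = pd.Series(base, index=genes)

    truth = GroundTruth(
        marker_families=markers, control_families=controls,
        effects=effects, marker_stages=tuple(config.marker_stages),
    )
    return SimulatedExperiment(
        matrices=matrices, families=families, truth=truth,
        baselines=baselines, config=config,
    )


def simulate_atlas(
    experiment: SimulatedExperiment,
    config: SimConfig | None = None,
    seed: int | None = None,
    *,
    atlas_species: str | None = None,
) -> ExpressionMatrix:
    """Vegetative expression atlas for the designated (first) species.

    Condition means vary per condition label around the vegetative
    baseline; planted marker families are near-silent except the
    configured leaky markers, whose atlas mean is ``leak_ratio`` times
    their sexual mean.
    """
    config = config or experiment.config
    rng = _rng(config, seed if seed is not None else config.rng_seed + 101)
    sp = atlas_species or sorted(experiment.matrices)[0]
    matrix = experiment.matrices[sp]
    base = experiment.baselines[sp].to_numpy().copy()
    genes = list(experiment.baselines[sp].index)
    lengths = matrix.gene_lengths.reindex(genes).to_numpy()
    fam_of = experiment.families.family_of()
    fams = np.array([fam_of.get(g) for g in genes])

    leaky = experiment.truth.marker_families[
        len(experiment.truth.marker_families) - config.n_leaky_markers:
    ] if config.n_leaky_markers else []
    experiment.truth.leaky_families = list(leaky)
    is_marker = np.isin(fams, experiment.truth.marker_families)
    base[is_marker] = config.marker_atlas_tpm
    for fam in leaky:
        sel = fams == fam
        sexual_mean = (
            experiment.config.marker_baseline_tpm
            * 2.0 ** experiment.truth.effects[fam]
        )
        base[sel] = config.leak_ratio * sexual_mean

    sample_ids, meta_rows, cols = [], [], []
    for c in range(config.atlas_conditions):
        cond_factor = 10.0 ** rng.normal(0, config.atlas_condition_sd, base.size)
        for r in range(config.atlas_replicates):
            w = base * cond_factor * lengths
            depth = config.library_size * np.exp(rng.normal(0, 0.1))
            mu = depth * w / w.sum()
            cols.append(_nb_counts(rng, mu, config.dispersion))
            sid = f"{sp}_atlas_c{c + 1}_r{r + 1}"
            sample_ids.append(sid)
            meta_rows.append({
                "sample_id": sid, "species": sp, "condition_class": "atlas",
                "stage": "none", "condition_label": f"cond{c + 1}",
                "replicate": r + 1,
            })
    counts = pd.DataFrame(np.column_stack(cols), index=genes, columns=sample_ids)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return ExpressionMatrix(
        counts=counts, sample_meta=meta,
        gene_lengths=pd.Series(lengths, index=genes),
    )


# ---------------------------------------------------------------------------
# MAG metatranscriptome


@dataclass
class SimulatedMagStudy:
    """Output of :func:`simulate_mag_dataset`."""

    dataset: MagDataset
    assignments: pd.DataFrame          # sex panel incl. SPO11-2
    control_assignments: pd.DataFrame  # C1-C4 + PC
    calibration: dict[str, np.ndarray]
    truth: GroundTruth
    config: SimConfig


def _panel_labels(clade: str) -> tuple[str, ...]:
    return PENNATE_MARKERS if clade == "raphid_pennate" else CENTRIC_MARKERS


GENERA = (
    "Chaetoceros", "Fragilariopsis", "Thalassiosira", "Pseudo-nitzschia",
    "Skeletonema", "Cylindrotheca", "Minidiscus", "Leptocylindrus", "Odontella",
)


def simulate_mag_dataset(
    config: SimConfig | None = None, seed: int | None = None
) -> SimulatedMagStudy:
    """MAG x sample metatranscriptome with planted sexual cells.

    Each MAG carries housekeeping genes plus one homolog per applicable
    panel marker, SPO11-2 and the control markers. Sexual cells draw each
    sex-panel marker's TPM strictly above its calibrated threshold
    (threshold x 2^U(uplift)); non-sexual cells — and control markers
    everywhere — draw from the vegetative calibration distribution itself,
    so marker leakage matches the thresholds' design. Reads are
    multinomial given the TPM-by-length composition and a drawn depth;
    a configured fraction of cells is under-sequenced to exercise the
    coverage filter.
    """
    config = config or SimConfig()
    rng = _rng(config, seed)

    all_labels = sorted(
        set(PENNATE_MARKERS) | set(CENTRIC_MARKERS)
        | {POSITIVE_CONTROL, CONTROL_POSITIVE} | set(CONTROL_MARKERS)
    )
    calibration = {
        lab: rng.lognormal(config.calib_log_tpm_mean, config.calib_log_tpm_sd,
                           config.n_calibration)
        for lab in all_labels
    }
    thresholds = {lab: percentile_threshold(v, 95.0) for lab, v in calibration.items()}

    n_pennate = int(round(config.n_mags * config.pennate_fraction))
    n_other = int(round(config.n_mags * config.other_fraction))
    clades = (["raphid_pennate"] * n_pennate
              + ["other"] * n_other
              + ["centric"] * (config.n_mags - n_pennate - n_other))

    sample_ids = [f"TARA_{j + 1:03d}" for j in range(config.n_mag_samples)]
    sample_meta = pd.DataFrame({
        "sample_id": sample_ids,
        "station": [f"st{j // 2 + 1:03d}" for j in range(config.n_mag_samples)],
        "depth": ["SRF" if j % 2 == 0 else "DCM" for j in range(config.n_mag_samples)],
        "size_fraction": [("0.8-5", "5-20", "20-180")[j % 3]
                          for j in range(config.n_mag_samples)],
        "season": [("spring", "summer", "autumn", "winter")[j % 4]
                   for j in range(config.n_mag_samples)],
    }).set_index("sample_id")

    mags: dict[str, MagTable] = {}
    mag_meta_rows, sex_rows, ctl_rows = [], [], []
    truth = GroundTruth()
    n_s = config.n_mag_samples
    for m in range(config.n_mags):
        mag_id = f"MAG{m + 1:03d}"
        clade = clades[m]
        mag_meta_rows.append({
            "mag_id": mag_id, "clade": clade,
            "genus": GENERA[m % len(GENERA)],
        })
        panel = _panel_labels(clade) if clade != "other" else PENNATE_MARKERS
        special = list(dict.fromkeys(
            (POSITIVE_CONTROL,) + panel + CONTROL_MARKERS + (CONTROL_POSITIVE,)
        ))
        n_hk = config.genes_per_mag
        hk_ids = [f"{mag_id}_g{i + 1:05d}" for i in range(n_hk)]
        sp_ids = [f"{mag_id}_mk{i + 1:02d}" for i in range(len(special))]
        gene_ids = np.array(hk_ids + sp_ids)
        lengths = np.exp(rng.normal(math.log(1500.0), 0.4, gene_ids.size))
        hk_base = 10.0 ** rng.normal(1.0, 0.8, n_hk)

        for gid, lab in zip(sp_ids, special):
            row = {"mag_id": mag_id, "gene_id": gid, "marker_label": lab}
            if lab in CONTROL_MARKERS or lab == CONTROL_POSITIVE:
                ctl_rows.append(row)
            else:
                sex_rows.append(row)

        sexual = (rng.random(n_s) < config.sexual_cell_fraction) & (clade != "other")
        low_depth = rng.random(n_s) < config.low_depth_fraction
        depths = np.where(
            low_depth,
            rng.uniform(2000, 9000, n_s),
            rng.lognormal(math.log(config.mag_depth_median), config.mag_depth_sigma, n_s),
        ).astype(int)

        counts = np.zeros((gene_ids.size, n_s))
        sex_labels = set((POSITIVE_CONTROL,) + panel)
        for j in range(n_s):
            tpm_special = np.empty(len(special))
            for i, lab in enumerate(special):
                if sexual[j] and lab in sex_labels and clade != "other":
                    uplift = 2.0 ** rng.uniform(config.sexual_uplift_low,
                                                config.sexual_uplift_high)
                    tpm_special[i] = thresholds[lab] * uplift
                else:
                    tpm_special[i] = rng.lognormal(config.calib_log_tpm_mean,
                                                   config.calib_log_tpm_sd)
            budget = max(1e6 - tpm_special.sum(), 1e5)
            tpm_hk = hk_base / hk_base.sum() * budget
            tpm = np.concatenate([tpm_hk, tpm_special])
            w = tpm * lengths
            counts[:, j] = rng.multinomial(depths[j], w / w.sum())
            if sexual[j]:
                truth.sexual_cells.add((mag_id, sample_ids[j]))
        mags[mag_id] = MagTable(gene_ids=gene_ids, lengths=lengths, counts=counts)

    dataset = MagDataset(
        mags=mags, sample_ids=sample_ids,
        mag_meta=pd.DataFrame(mag_meta_rows).set_index("mag_id"),
        sample_meta=sample_meta,
    )
    return SimulatedMagStudy(
        dataset=dataset,
        assignments=pd.DataFrame(sex_rows),
        control_assignments=pd.DataFrame(ctl_rows),
        calibration=calibration,
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# trees and hit tables


def _random_binary_tree(
    taxa: list[str], rng: np.random.Generator, namespace: dendropy.TaxonNamespace,
    support: int | None,
) -> dendropy.Node:
    """Random binary subtree over the given tips with U(0.05, 0.3) branch lengths."""
    nodes = []
    for t in taxa:
        leaf = dendropy.Node()
        leaf.taxon = namespace.require_taxon(label=t)
        leaf.edge.length = float(rng.uniform(0.05, 0.3))
        nodes.append(leaf)
    rng.shuffle(nodes)
    while len(nodes) > 1:
        a = nodes.pop()
        b = nodes.pop()
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        parent.edge.length = float(rng.uniform(0.05, 0.3))
        if support is not None:
            parent.label = str(support)
        nodes.insert(int(rng.integers(len(nodes) + 1)), parent)
    return nodes[0]


def simulate_marker_tree(
    config: SimConfig | None = None, seed: int | None = None
) -> tuple[dendropy.Tree, GroundTruth]:
    """Annotated tree whose reference tips form a clade with planted queries.

    Inside queries attach within the reference clade, outside queries
    among the outgroups; the outgroup stem is long so that midpoint
    rooting falls on it and the reference clade stays intact. Internal
    nodes carry the configured support value.
    """
    config = config or SimConfig()
    rng = _rng(config, seed)
    ns = dendropy.TaxonNamespace()
    refs = [f"REF_{i + 1}" for i in range(config.n_refs)]
    inside = [f"Q_in_{i + 1}" for i in range(config.n_queries_inside)]
    outs = [f"OUT_{i + 1}" for i in range(config.n_outgroups)]
    outside = [f"Q_out_{i + 1}" for i in range(config.n_queries_outside)]

    ingroup = _random_binary_tree(refs + inside, rng, ns, config.support)
    outgroup = _random_binary_tree(outs + outside, rng, ns, config.support)
    root = dendropy.Node()
    root.add_child(ingroup)
    root.add_child(outgroup)
    ingroup.edge.length = 0.5
    ingroup.label = str(config.support)
    outgroup.edge.length = 4.0
    outgroup.label = str(config.support)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    tree.is_rooted = True
    truth = GroundTruth(inside_queries=set(inside))
    return tree, truth


def simulate_hit_table(
    config: SimConfig | None = None, seed: int | None = None
) -> tuple[list[HmmHit], GroundTruth]:
    """HMM hit table with true homologs and decoys straddling the score cutoff."""
    config = config or SimConfig()
    rng = _rng(config, seed)
    hits: list[HmmHit] = []
    truth = GroundTruth()
    for i in range(config.n_true_hits):
        score = max(float(rng.normal(config.true_score_mean, config.score_sd)), 1.0)
        tid = f"tara_true_{i + 1}"
        hits.append(HmmHit(
            target_id=tid, marker_label="M1", score=round(score, 1),
            evalue=10.0 ** (-(score - 15.0) / 3.0), source_taxon="diatom_mag",
        ))
        truth.true_hit_targets.add(tid)
    for i in range(config.n_decoy_hits):
        score = max(float(rng.normal(config.decoy_score_mean, config.score_sd)), 1.0)
        hits.append(HmmHit(
            target_id=f"tara_decoy_{i + 1}", marker_label="M1", score=round(score, 1),
            evalue=10.0 ** (-(score - 15.0) / 3.0),
            source_taxon="diatom_mag" if i % 2 == 0 else "non_diatom",
        ))
    order = rng.permutation(len(hits))
    return [hits[i] for i in order], truth
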