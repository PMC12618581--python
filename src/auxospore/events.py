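"""MAG-level sex-event calling from environmental metatranscriptomes.

MAG x sample cells are filtered on coverage, expression is normalized to
MAG-level TPM (so marker expression is measured relative to the MAG's own
transcriptional activity, independent of its abundance), per-marker
thresholds are calibrated as the 95th percentile of laboratory vegetative
TPM, and a cell is called a sexual-reproduction event when the meiotic
positive control SPO11-2 and at least ``min_comarkers`` panel markers pass
the expression rule (TPM strictly above threshold, >= 2 supporting reads).
The same machinery runs on matched control markers to audit the
false-positive rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .expression import ExpressionMatrix, GeneFamilyTable, tpm_table

logger = logging.getLogger(__name__)

PENNATE_MARKERS = ("M1", "M2", "M3", "M4")
CENTRIC_MARKERS = ("M3", "SIG1", "DNAH9/11/17", "DNAH5/8", "DRC4")
CONTROL_MARKERS = ("C1", "C2", "C3", "C4")
POSITIVE_CONTROL = "SPO11-2"
CONTROL_POSITIVE = "PC"


@dataclass(frozen=True)
class EventPanel:
    """Positive-control label plus the co-expression marker labels."""

    positive_control: str
    markers: tuple[str, ...]


DEFAULT_PANELS = {
    "raphid_pennate": EventPanel(POSITIVE_CONTROL, PENNATE_MARKERS),
    "centric": EventPanel(POSITIVE_CONTROL, CENTRIC_MARKERS),
}
CONTROL_PANEL = EventPanel(CONTROL_POSITIVE, CONTROL_MARKERS)


@dataclass
class MagTable:
    """Expression of one MAG: gene ids, gene lengths (bases), counts (genes x samples)."""

    gene_ids: np.ndarray
    lengths: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids)
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")


@dataclass
class MagDataset:
    """MAG x sample metatranscriptome expression.

    ``mags`` maps mag_id to its :class:`MagTable` (shared sample order in
    ``sample_ids``); ``mag_meta`` is indexed by mag_id with at least
    ``clade`` (raphid_pennate / centric / other) and ``genus``;
    ``sample_meta`` is indexed by sample_id with station, depth and
    size_fraction.
    """

    mags: dict[str, MagTable]
    sample_ids: list[str]
    mag_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        """Long-format (mag_id, sample_id, gene_id, count, length) table."""
        frames = []
        for mag_id, t in self.mags.items():
            n_g, n_s = t.counts.shape
            frames.append(pd.DataFrame({
                "mag_id": np.repeat(mag_id, n_g * n_s),
                "sample_id": np.tile(self.sample_ids, n_g),
                "gene_id": np.repeat(t.gene_ids, n_s),
                "count": t.counts.ravel(),
                "length": np.repeat(t.lengths, n_s),
            }))
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_long(cls, long: pd.DataFrame, mag_meta: pd.DataFrame,
                  sample_meta: pd.DataFrame) -> "MagDataset":
        sample_ids = sorted(long["sample_id"].unique())
        mags = {}
        for mag_id, g in long.groupby("mag_id"):
            wide = g.pivot_table(index="gene_id", columns="sample_id",
                                 values="count", fill_value=0.0)
            wide = wide.reindex(columns=sample_ids, fill_value=0.0)
            lengths = g.drop_duplicates("gene_id").set_index("gene_id")["length"]
            mags[str(mag_id)] = MagTable(
                gene_ids=wide.index.to_numpy(),
                lengths=lengths.reindex(wide.index).to_numpy(),
                counts=wide.to_numpy(),
            )
        return cls(mags=mags, sample_ids=sample_ids,
                   mag_meta=mag_meta, sample_meta=sample_meta)


def filter_mag_samples(
    dataset: MagDataset, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Coverage filter: keep cells with >= 10,000 reads and >= 1000 expressed genes.

    Returns one row per MAG x sample cell with total_reads, n_genes and a
    ``kept`` flag (total_reads >= mag_min_reads AND n_genes >=
    mag_min_genes, the strict reading of "less than ... filtered out").
    """
    config = config or AnalysisConfig()
    rows = []
    for mag_id, t in dataset.mags.items():
        total = t.counts.sum(axis=0)
        n_genes = (t.counts >= 1).sum(axis=0)
        for j, s in enumerate(dataset.sample_ids):
            rows.append({
                "mag_id": mag_id, "sample_id": s,
                "total_reads": float(total[j]), "n_genes": int(n_genes[j]),
                "kept": bool(total[j] >= config.mag_min_reads
                             and n_genes[j] >= config.mag_min_genes),
            })
    return pd.DataFrame(rows)


def mag_tpm(counts, lengths) -> np.ndarray:
    """MAG-level TPM of one cell: length-normalized rates scaled to 1e6."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("cell has zero reads; MAG-level TPM undefined")
    rate = counts / (lengths / 1000.0)
    return rate / rate.sum() * 1e6


def percentile_threshold(values, q: float = 95.0) -> float:
    """q-th percentile with linear interpolation between order statistics."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot take a percentile of an empty vector")
    return float(np.percentile(values, q))


def thresholds_from_pooled(
    values_by_label: dict[str, np.ndarray], q: float = 95.0
) -> pd.DataFrame:
    """Threshold table from pre-pooled vegetative TPM vectors per marker."""
    rows = [
        {"marker_label": lab, "threshold": percentile_threshold(v, q),
         "n_pooled": int(np.asarray(v).size)}
        for lab, v in values_by_label.items()
    ]
    return pd.DataFrame(rows).set_index("marker_label")


def calibrate_thresholds(
    reference: dict[str, ExpressionMatrix],
    families: GeneFamilyTable,
    panel_families: dict[str, str],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """95th-percentile vegetative TPM thresholds per marker family.

    For each marker label (mapped to its family), TPM values of all member
    genes over all non-sexual samples of all reference species are pooled
    into one vector; the threshold is its ``percentile_q``-th percentile.
    Returns a table indexed by marker label with threshold, the number of
    pooled values, and per-species sample counts as provenance.
    """
    config = config or AnalysisConfig()
    membership = families.membership
    pooled: dict[str, list[float]] = {lab: [] for lab in panel_families}
    provenance: dict[str, dict[str, int]] = {lab: {} for lab in panel_families}
    for sp, matrix in reference.items():
        veg = [
            s for s in matrix.sample_ids
            if matrix.sample_meta.loc[s, "condition_class"] != "sexual"
        ]
        if not veg:
            raise ValueError(f"species {sp!r} contributes no vegetative samples")
        tpm = tpm_table(matrix.subset_samples(veg))
        for lab, fam in panel_families.items():
            genes = membership.loc[
                membership["family_id"].eq(fam)
                & membership["species"].eq(sp)
                & membership["gene_id"].isin(tpm.index), "gene_id"
            ]
            if genes.empty:
                continue
            pooled[lab].extend(tpm.loc[genes].to_numpy().ravel().tolist())
            provenance[lab][sp] = tpm.shape[1]
    rows = []
    for lab, vals in pooled.items():
        if not vals:
            raise ValueError(
                f"marker {lab!r} (family {panel_families[lab]}) has no member "
                "gene in any reference species"
            )
        rows.append({
            "marker_label": lab,
            "threshold": percentile_threshold(vals, config.percentile_q),
            "n_pooled": len(vals),
            "samples_per_species": ";".join(
                f"{sp}={n}" for sp, n in sorted(provenance[lab].items())
            ),
        })
    return pd.DataFrame(rows).set_index("marker_label")


def call_marker_expression(
    tpm: pd.Series,
    counts: pd.Series,
    assignment: dict[str, str],
    thresholds: pd.Series,
    config: AnalysisConfig | None = None,
) -> dict[str, bool]:
    """Per-marker expressed flags for one MAG x sample cell.

    A marker label is expressed when at least one assigned gene has TPM
    strictly above its threshold AND at least ``min_marker_reads`` reads.
    Assigned genes missing from the cell count as zero (logged).
    """
    config = config or AnalysisConfig()
    flags: dict[str, bool] = {}
    for gene, label in assignment.items():
        if label not in thresholds.index:
            raise ValueError(f"no threshold for marker {label!r}")
        flags.setdefault(label, False)
        if gene not in tpm.index:
            logger.info("assigned gene %s absent from cell; treated as zero", gene)
            continue
        if (tpm[gene] > thresholds[label]) and (counts[gene] >= config.min_marker_reads):
            flags[label] = True
    return flags


def _cell_marker_flags(
    dataset: MagDataset,
    assignments: pd.DataFrame,
    thresholds: pd.Series,
    config: AnalysisConfig,
    kept: pd.DataFrame,
) -> pd.DataFrame:
    """Long table of per-cell per-label expressed flags (vectorised per MAG)."""
    rows = []
    kept_cells = kept[kept["kept"]]
    kept_by_mag = {m: set(g["sample_id"]) for m, g in kept_cells.groupby("mag_id")}
    for mag_id, t in dataset.mags.items():
        if mag_id not in kept_by_mag:
            continue
        asg = assignments[assignments["mag_id"] == mag_id]
        if asg.empty:
            continue
        gene_pos = {g: i for i, g in enumerate(t.gene_ids)}
        rate = t.counts / (t.lengths[:, None] / 1000.0)
        total_rate = rate.sum(axis=0)
        sample_ok = np.array([
            (s in kept_by_mag[mag_id]) and total_rate[j] > 0
            for j, s in enumerate(dataset.sample_ids)
        ])
        for _, row in asg.iterrows():
            gene, label = row["gene_id"], row["marker_label"]
            if label not in thresholds.index:
                raise ValueError(f"no threshold for marker {label!r}")
            if gene not in gene_pos:
                logger.info("assigned gene %s absent from MAG %s", gene, mag_id)
                continue
            i = gene_pos[gene]
            with np.errstate(invalid="ignore", divide="ignore"):
                tpm_row = np.where(total_rate > 0, rate[i] / total_rate * 1e6, 0.0)
            ok = (
                sample_ok
                & (tpm_row > float(thresholds[label]))
                & (t.counts[i] >= config.min_marker_reads)
            )
            for j, s in enumerate(dataset.sample_ids):
                if s in kept_by_mag[mag_id]:
                    rows.append({"mag_id": mag_id, "sample_id": s,
                                 "marker_label": label, "expressed": bool(ok[j]),
                                 "reads": float(t.counts[i, j])})
    flags = pd.DataFrame(rows)
    if flags.empty:
        return pd.DataFrame(columns=["mag_id", "sample_id", "marker_label",
                                     "expressed", "reads"])
    # a marker passes if ANY of its homologs passes
    return (
        flags.groupby(["mag_id", "sample_id", "marker_label"], as_index=False)
        .agg(expressed=("expressed", "any"), reads=("reads", "max"))
    )


def call_events(
    dataset: MagDataset,
    assignments: pd.DataFrame,
    thresholds: pd.DataFrame | pd.Series,
    config: AnalysisConfig | None = None,
    panels: dict[str, EventPanel] | None = None,
) -> pd.DataFrame:
    """Sex-event calls for every retained MAG x sample cell.

    ``assignments`` has columns mag_id, gene_id, marker_label. The panel
    applied to each MAG follows its clade (pennate: M1-M4; centric: M3 +
    flagella markers); MAGs of clade ``other`` are excluded with a log
    entry. A cell is an event when the positive control passes and at
    least ``config.min_comarkers`` distinct panel markers pass. With
    ``config.lenient_spo11`` the positive control only needs >= 1 read.
    """
    config = config or AnalysisConfig()
    panels = panels or DEFAULT_PANELS
    thr = thresholds["threshold"] if isinstance(thresholds, pd.DataFrame) else thresholds
    kept = filter_mag_samples(dataset, config)
    flags = _cell_marker_flags(dataset, assignments, thr, config, kept)

    rows = []
    for (mag_id, sample_id), g in flags.groupby(["mag_id", "sample_id"]):
        clade = dataset.mag_meta.loc[mag_id, "clade"]
        if clade not in panels:
            logger.info("MAG %s of clade %r excluded from event calling", mag_id, clade)
            continue
        panel = panels[clade]
        by_label = g.set_index("marker_label")
        if config.lenient_spo11:
            pc_row = by_label[by_label.index == panel.positive_control]
            spo11 = bool((pc_row["reads"] >= 1).any()) if len(pc_row) else False
        else:
            spo11 = bool(by_label["expressed"].get(panel.positive_control, False))
        passing = sorted(
            lab for lab in panel.markers
            if bool(by_label["expressed"].get(lab, False))
        )
        tier = len(passing)
        rows.append({
            "mag_id": mag_id, "sample_id": sample_id, "mag_clade": clade,
            "panel_used": "pennate" if clade == "raphid_pennate" else clade,
            "spo11_status": spo11,
            "passing_markers": ";".join(passing),
            "tier": tier,
            "is_event": bool(spo11 and tier >= config.min_comarkers),
        })
    return pd.DataFrame(rows, columns=[
        "mag_id", "sample_id", "mag_clade", "panel_used", "spo11_status",
        "passing_markers", "tier", "is_event",
    ])


def tier_sweep(calls: pd.DataFrame, tiers=(1, 2, 3, 4)) -> pd.DataFrame:
    """Event counts when requiring 1..4 co-expressed markers."""
    rows = [
        {"min_comarkers": k,
         "n_events": int((calls["spo11_status"] & (calls["tier"] >= k)).sum())}
        for k in tiers
    ]
    return pd.DataFrame(rows)


def audit_controls(
    dataset: MagDataset,
    control_assignments: pd.DataFrame,
    thresholds: pd.DataFrame | pd.Series,
    config: AnalysisConfig | None = None,
) -> tuple[pd.DataFrame, int]:
    """Repeat the co-expression analysis with control markers.

    PC acts as the positive control and C1-C4 as markers, under the same
    calling rule; returns the per-cell calls and the total number of
    control co-expression cases.
    """
    config = config or AnalysisConfig()
    clades = set(dataset.mag_meta["clade"]) - {"other"}
    panels = {c: CONTROL_PANEL for c in clades}
    calls = call_events(dataset, control_assignments, thresholds, config, panels)
    return calls, int(calls["is_event"].sum())


def summarize_events(
    calls: pd.DataFrame,
    sample_meta: pd.DataFrame,
    mag_meta: pd.DataFrame,
    *,
    n_stations_total: int | None = None,
    n_mags_total: int | None = None,
) -> dict:
    """Case counts, station/MAG coverage fractions and per-genus presence.

    A "case" is a MAG showing a signal in a single sample. Fractions are
    relative to all stations and MAGs in the metadata unless explicit
    totals are supplied.
    """
    if len(calls):
        events = calls[calls["is_event"].astype(bool)].copy()
    else:
        events = calls.iloc[0:0].copy()
    events["station"] = events["sample_id"].map(sample_meta["station"])
    events["genus"] = events["mag_id"].map(mag_meta["genus"])
    n_stations_total = n_stations_total or sample_meta["station"].nunique()
    n_mags_total = n_mags_total or len(mag_meta.index)
    by_clade = events.groupby("mag_clade").size().to_dict() if len(events) else {}
    stations_hit = events["station"].nunique() if len(events) else 0
    mags_hit = events["mag_id"].nunique() if len(events) else 0
    genus_station = (
        events.groupby(["genus", "station"]).size().rename("n_events").reset_index()
        if len(events) else pd.DataFrame(columns=["genus", "station", "n_events"])
    )
    return {
        "n_cases": int(len(events)),
        "cases_by_clade": by_clade,
        "n_stations_with_event": int(stations_hit),
        "station_fraction": stations_hit / n_stations_total if n_stations_total else 0.0,
        "n_mags_with_event": int(mags_hit),
        "mag_fraction": mags_hit / n_mags_total if n_mags_total else 0.0,
        "genus_station_table": genus_station,
    }
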