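"""Readers and writers for the pipeline's plain-text interchange formats.

All tables are tab-separated with a header row. Counts: first column
``gene_id``, remaining columns samples. Sample metadata: sample_id,
species, condition_class, stage, condition_label, replicate. Gene
families: a membership table (gene_id, family_id, species) plus a family
attribute table (family_id, diatom_specific).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from .expression import ExpressionMatrix, GeneFamilyTable
from .simulate import GroundTruth


def write_counts(matrix: ExpressionMatrix, path) -> None:
    out = matrix.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def write_sample_meta(matrix: ExpressionMatrix, path) -> None:
    meta = matrix.meta.copy()
    meta.index.name = "sample_id"
    meta.to_csv(path, sep="\t")


def write_gene_lengths(matrix: ExpressionMatrix, path) -> None:
    if matrix.gene_lengths is None:
        raise ValueError("matrix has no gene lengths")
    s = matrix.gene_lengths.rename("length")
    s.index.name = "gene_id"
    s.to_csv(path, sep="\t")


def read_expression_matrix(counts_path, meta_path, lengths_path=None) -> ExpressionMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
    meta["stage"] = meta["stage"].fillna("none").astype(str)
    lengths = None
    if lengths_path is not None:
        lengths = pd.read_csv(lengths_path, sep="\t", index_col="gene_id")["length"]
    return ExpressionMatrix(counts=counts, sample_meta=meta, gene_lengths=lengths)


def write_gene_families(families: GeneFamilyTable, membership_path, attrs_path) -> None:
    families.membership.to_csv(membership_path, sep="\t", index=False)
    attrs = families.family_info.copy()
    attrs.index.name = "family_id"
    attrs.to_csv(attrs_path, sep="\t")


def read_gene_families(membership_path, attrs_path) -> GeneFamilyTable:
    membership = pd.read_csv(membership_path, sep="\t")
    attrs = pd.read_csv(attrs_path, sep="\t", index_col="family_id")
    attrs["diatom_specific"] = attrs["diatom_specific"].astype(bool)
    return GeneFamilyTable(membership=membership, family_info=attrs)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_ground_truth(truth: GroundTruth, path) -> None:
    data = dataclasses.asdict(truth)
    data["sexual_cells"] = sorted(list(t) for t in truth.sexual_cells)
    data["inside_queries"] = sorted(truth.inside_queries)
    data["true_hit_targets"] = sorted(truth.true_hit_targets)
    data["marker_stages"] = list(truth.marker_stages)
    Path(path).write_text(json.dumps(data, indent=1, sort_keys=True))


def read_ground_truth(path) -> GroundTruth:
    data = json.loads(Path(path).read_text())
    return GroundTruth(
        marker_families=data.get("marker_families", []),
        control_families=data.get("control_families", []),
        leaky_families=data.get("leaky_families", []),
        effects=data.get("effects", {}),
        marker_stages=tuple(data.get("marker_stages", ())),
        sexual_cells={tuple(t) for t in data.get("sexual_cells", [])},
        inside_queries=set(data.get("inside_queries", [])),
        true_hit_targets=set(data.get("true_hit_targets", [])),
    )
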