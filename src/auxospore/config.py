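"""Analysis configuration shared across pipeline stages."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


@dataclass
class AnalysisConfig:
    """Thresholds and knobs used across the pipeline.

    Parameters
    ----------
    fdr_alpha
        Overall false-discovery-rate level of the stage-wise testing
        procedure (screening and confirmation).
    logfc_threshold
        Fold-change threshold ``tau`` (log2 units) of the threshold test:
        differential expression is declared relative to ``|log2FC| > tau``
        rather than zero.
    min_cpm, min_samples
        Expression-presence filter: a gene is "expressed" when its CPM is
        strictly greater than ``min_cpm`` in at least ``min_samples``
        samples. Defaults target laboratory bulk RNA-seq; use
        :meth:`scheldt` for the shallow metatranscriptome preset.
    percentile_q
        Percentile of the pooled vegetative TPM distribution used to
        calibrate per-marker expression thresholds.
    min_marker_reads
        Minimum read support for a marker gene to count as expressed in a
        MAG x sample cell.
    min_comarkers
        Number of sex markers (excluding the positive control SPO11-2)
        that must pass in the same cell to call a sexual-reproduction
        event.
    mag_min_reads, mag_min_genes
        MAG x sample cells with fewer total mapped reads, or fewer genes
        with at least one read, are discarded.
    hmm_min_score, hmm_max_evalue
        Bit-score (inclusive) and E-value (exclusive) cutoffs for profile
        HMM hits.
    asv_min_rel_abund
        Minimum relative abundance (fraction) for an ASV to be retained;
        the default 1e-7 is the fraction form of 1e-5 %.
    max_nonsexual_tpm, min_fold_separation
        Specificity rule for marker candidates against the expression
        atlas: a candidate passes when its maximum TPM over non-sexual
        atlas samples is at most ``max_nonsexual_tpm`` OR its sexual
        mean TPM exceeds that maximum by ``min_fold_separation``-fold.
    top_k
        Number of top-ranked specific candidates retained as markers.
    lenient_spo11
        When True the positive-control prefilter only requires >=1 read
        for SPO11-2, ignoring the TPM threshold.
    """

    fdr_alpha: float = 0.05
    logfc_threshold: float = 1.0
    min_cpm: float = 1.0
    min_samples: int = 3
    percentile_q: float = 95.0
    min_marker_reads: int = 2
    min_comarkers: int = 2
    mag_min_reads: int = 10_000
    mag_min_genes: int = 1_000
    hmm_min_score: float = 50.0
    hmm_max_evalue: float = 1e-10
    asv_min_rel_abund: float = 1e-7
    max_nonsexual_tpm: float = 2.0
    min_fold_separation: float = 5.0
    top_k: int = 4
    lenient_spo11: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ValueError(f"fdr_alpha must be in (0, 1), got {self.fdr_alpha}")
        if not 0.0 < self.percentile_q < 100.0:
            raise ValueError(f"percentile_q must be in (0, 100), got {self.percentile_q}")
        for name in (
            "logfc_threshold", "min_cpm", "min_samples", "min_marker_reads",
            "min_comarkers", "mag_min_reads", "mag_min_genes", "hmm_min_score",
            "hmm_max_evalue", "asv_min_rel_abund", "max_nonsexual_tpm",
            "min_fold_separation", "top_k",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def scheldt(cls, **overrides) -> "AnalysisConfig":
        """Preset for shallow metatranscriptome assemblies (CPM > 0.1 in >= 2 samples)."""
        params = {"min_cpm": 0.1, "min_samples": 2}
        params.update(overrides)
        return cls(**params)

    def replace(self, **changes) -> "AnalysisConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
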