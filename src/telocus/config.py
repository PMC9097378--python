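"""Analysis configuration.

Every numeric threshold used anywhere in the pipeline lives here, so a run
is fully described by one config object plus its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field


@dataclass
class AnalysisConfig:
    """Thresholds and constants for the TE locus-expression pipeline.

    All count/depth thresholds are strict (``>``): e.g. ``min_reads=10``
    means a locus needs at least 11 reads to pass.

    Attributes
    ----------
    min_reads : int
        Per-locus read-count threshold shared by all three short-read
        filters (strict; "more than ten reads").
    min_depth : float
        Mean per-base depth threshold of the coverage filter (strict).
    integrity_threshold : float
        Loci whose genomic span exceeds this fraction of the family's
        canonical element length are called full-length.
    flank_width : int
        Width in bp of the N-/C-flanks placed upstream/downstream of each
        gene unit when compartmentalising the genome.
    gene_expressed_fpkm, gene_expressed_tpm : float
        Strict lower bounds for a gene to count as expressed (short-read
        FPKM; long-read mode additionally requires the TPM bound).
    de_padj, de_lfc : float
        Differential-expression call thresholds: BH-adjusted p below
        ``de_padj`` and |log2 fold change| above ``de_lfc`` at >=1 timepoint.
    breadth_threshold : float
        Breadth-of-coverage bound over the superfamily-specific feature
        (INT / ORF / whole element) for autonomous-transcription candidates.
    mapped_fraction_threshold : float
        Minimum mapped-bases / read-length ratio for a long read to count
        as a full-length transcript ("almost as much as its read length").
    clip_min : int
        Soft-clip length (bp) at or above which a long-read alignment end
        is labelled "clipped" rather than internal/external.
    substitution_rate : float
        Neutral substitution rate r (per site per year) used to convert
        LTR-pair divergence K into insertion time T = K / (2 r).
    chisq_alpha : float
        Significance level of the location-bias chi-square tests.
    dangler_window : int
        Maximum distance (bp) between a dangler alignment and the locus
        boundary for the dangler to be assigned to that side.
    dangler_side_mode : str
        "any": danglers on at least one side must exceed ``min_reads``;
        "both": both sides must.
    de_two_sided : bool
        If True (default) DE calls use |lfc| > de_lfc; if False only
        up-regulation qualifies.
    ptc_junction_rule_nt : int
        A stop codon at least this many nt upstream of the last splice
        junction marks an isoform as PTC (NMD 50-nt convention).
    """

    min_reads: int = 10
    min_depth: float = 5.0
    integrity_threshold: float = 0.9
    flank_width: int = 2000
    gene_expressed_fpkm: float = 1.0
    gene_expressed_tpm: float = 1.0
    de_padj: float = 0.05
    de_lfc: float = 1.0
    breadth_threshold: float = 0.9
    mapped_fraction_threshold: float = 0.9
    clip_min: int = 20
    substitution_rate: float = 1.3e-8
    chisq_alpha: float = 0.01
    dangler_window: int = 1000
    dangler_side_mode: str = "any"
    de_two_sided: bool = True
    ptc_junction_rule_nt: int = 50
    de_pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.dangler_side_mode not in ("any", "both"):
            raise ValueError(f"dangler_side_mode must be 'any' or 'both', got {self.dangler_side_mode!r}")
        for name in ("min_reads", "min_depth", "integrity_threshold", "flank_width",
                     "breadth_threshold", "mapped_fraction_threshold", "clip_min",
                     "substitution_rate", "chisq_alpha", "dangler_window", "de_padj",
                     "de_lfc", "ptc_junction_rule_nt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


DEFAULT_CONFIG = AnalysisConfig()
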