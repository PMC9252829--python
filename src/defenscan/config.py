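"""Default parameters for hit filtering, clustering and the external-tool wrappers.

Every threshold used by the pipeline lives here (or in the per-HMM metadata
table, which overrides these defaults hit by hit) so that a run log can state
the complete effective configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class FilterThresholds:
    """Global hit-filtering defaults, overridable per HMM via the metadata table.

    The E-value ceiling is applied to both the full-sequence E-value and the
    best domain's independent E-value (the stricter reading); the coverage
    floors apply to the fraction of the target protein and of the HMM covered
    by the best domain's alignment.  All comparisons are inclusive.
    """

    evalue_max: float = 1e-5
    target_cov_min: float = 0.4
    hmm_cov_min: float = 0.4

    def __post_init__(self) -> None:
        for name in ("evalue_max", "target_cov_min", "hmm_cov_min"):
            v = getattr(self, name)
            if not (v == v and abs(v) != float("inf")):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if not 0.0 <= self.target_cov_min <= 1.0:
            raise ValueError("target_cov_min must be in [0, 1]")
        if not 0.0 <= self.hmm_cov_min <= 1.0:
            raise ValueError("hmm_cov_min must be in [0, 1]")


#: Maximum number of intervening non-member genes allowed between consecutive
#: members of a candidate cluster, when a system model does not set its own.
DEFAULT_MAX_SEPARATION: int = 4

#: Inclusion threshold for covariance-model ncRNA hits (inclusive comparison).
NCRNA_EVALUE_MAX: float = 0.01

#: Arguments passed through to the CRISPR array finder when it is wrapped.
#: Arrays ingested from a pre-computed GFF are expected to satisfy the same
#: minimum repeat count.
CRISPRDETECT_DEFAULTS: dict[str, float | int] = {
    "array_quality_score_cutoff": 2.5,
    "minimum_word_repeatation": 3,
    "word_length": 11,
    "minimum_no_of_repeats": 3,
    "repeat_length_cutoff": 11,
    "max_gap_between_crisprs": 250,
}

#: Arguments passed through to cmsearch when it is wrapped.
CMSEARCH_DEFAULTS: dict[str, int] = {"Z": 10, "FZ": 500}

#: Gene-caller inputs above this length (nt) are run in single-genome mode;
#: shorter inputs use the anonymous/metagenomic mode.
GENE_CALLER_SINGLE_MODE_MIN_LENGTH: int = 100_000


@dataclass
class RunConfig:
    """Effective configuration of one detection run (echoed into the run log)."""

    db_dir: str = ""
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    max_separation: int | None = None  # None → per-model value or DEFAULT_MAX_SEPARATION
    ncrna_evalue_max: float = NCRNA_EVALUE_MAX
    fix_prodigal: bool = False

    def describe(self) -> dict[str, object]:
        return {
            "db_dir": self.db_dir,
            "evalue_max": self.thresholds.evalue_max,
            "target_cov_min": self.thresholds.target_cov_min,
            "hmm_cov_min": self.thresholds.hmm_cov_min,
            "max_separation": self.max_separation,
            "ncrna_evalue_max": self.ncrna_evalue_max,
            "fix_prodigal": self.fix_prodigal,
            "crispr_finder_args": dict(CRISPRDETECT_DEFAULTS),
            "cmsearch_args": dict(CMSEARCH_DEFAULTS),
        }
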