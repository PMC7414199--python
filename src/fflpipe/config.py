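"""Pipeline configuration.

All thresholds that the analysis applies live here, with the defaults the
published protocol uses: BH-adjusted combined p < 0.05 and |log2FC| > 0.5
for the DEG screen, BH p < 0.05 for gene-set terms, HIPPIE confidence in
[0.63, 1], miRNA-target score >= 0.95, TF evidence p < 0.05 and a 1 kb
upstream binding-site window.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

TEST_MODES = ("student", "moderated")
TOP_N_MODES = ("n_seed_degs", "explicit")


@dataclass
class PipelineConfig:
    """Thresholds and knobs for every pipeline stage.

    Parameters
    ----------
    de_alpha:
        Significance threshold on the BH-adjusted combined p-value
        (strict `<`).
    lfc_cut:
        Absolute log2 fold-change threshold (strict `>`).
    test_mode:
        Per-study two-group test: ``"student"`` (pooled-variance t) or
        ``"moderated"`` (empirical-Bayes shrunken variance, default).
    enrich_alpha:
        BH threshold for calling a gene set significantly enriched.
    hippie_min_score:
        Minimum HIPPIE-style PPI confidence score (kept if
        ``hippie_min_score <= score <= 1``).
    mirna_score_min:
        Minimum miRNA-target confidence score (inclusive).
    tf_p_max:
        Maximum p-value for TF gene-set-library evidence (strict `<`).
    upstream_window_bp:
        TF binding sites at most this far upstream of the TSS are kept.
    epc_reps:
        Monte-Carlo realizations for edge-percolated-component centrality.
    epc_retain_p:
        Per-edge retention probability in each percolation realization.
    rng_seed:
        Seed for the single random generator shared by stochastic stages.
    top_n_mode:
        ``"n_seed_degs"`` sets the hub top-n cutoff to the number of seed
        DEGs present in each network; ``"explicit"`` uses ``explicit_top_n``.
    explicit_top_n:
        Cutoff used when ``top_n_mode == "explicit"``.
    """

    de_alpha: float = 0.05
    lfc_cut: float = 0.5
    test_mode: str = "moderated"
    enrich_alpha: float = 0.05
    hippie_min_score: float = 0.63
    mirna_score_min: float = 0.95
    tf_p_max: float = 0.05
    upstream_window_bp: int = 1000
    epc_reps: int = 1000
    epc_retain_p: float = 0.5
    rng_seed: int = 0
    top_n_mode: str = "n_seed_degs"
    explicit_top_n: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("de_alpha", "enrich_alpha", "hippie_min_score",
                     "mirna_score_min", "tf_p_max", "epc_retain_p"):
            value = getattr(self, name)
            if not (0.0 < value <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {value!r}")
        if self.lfc_cut < 0:
            raise ValueError(f"lfc_cut must be >= 0, got {self.lfc_cut!r}")
        if self.epc_reps < 1:
            raise ValueError(f"epc_reps must be >= 1, got {self.epc_reps!r}")
        if self.upstream_window_bp <= 0:
            raise ValueError(
                f"upstream_window_bp must be > 0, got {self.upstream_window_bp!r}")
        if self.test_mode not in TEST_MODES:
            raise ValueError(
                f"test_mode must be one of {TEST_MODES}, got {self.test_mode!r}")
        if self.top_n_mode not in TOP_N_MODES:
            raise ValueError(
                f"top_n_mode must be one of {TOP_N_MODES}, got {self.top_n_mode!r}")
        if self.top_n_mode == "explicit" and (
                self.explicit_top_n is None or self.explicit_top_n < 1):
            raise ValueError("top_n_mode='explicit' requires explicit_top_n >= 1")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)
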