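"""Configuration dataclasses for the simulator and the pipeline.

All thresholds carry the values used throughout the ceRNA literature as
defaults: miRNA-target anti-correlation r < -0.9, sponge-mRNA co-expression
r > 0.8, correlation p < 0.05, at least three shared miRNAs per ce-mRNA
pair, sponge hypergeometric p < 0.05.  Two DE threshold conventions are in
circulation (padj < 0.1 with log2FC > 1, and padj < 0.05 with
|log2FC| >= 1); the stricter variant is the default and both are reachable
through ``lfc_cut`` / ``padj_cut``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import yaml

from .containers import RNA_CLASSES

SITE_CLASSES = ("6mer", "7mer-A1", "7mer-m8", "8mer")


@dataclass
class SimConfig:
    """Parameters of the two-condition synthetic experiment.

    Counts are negative-binomial with variance ``mu + dispersion * mu**2``
    (dispersion shared across features).  A fraction ``de_fraction`` of each
    class is differentially expressed with |log2FC| =
    ``de_log2fc_magnitude``.  ``n_planted_triplets`` ceRNA triplets
    (sponge, >=3 shared miRNAs, mRNA) are planted on top: sponge and mRNA
    share a latent per-sample factor (amplitude ``sponge_strength``, log2
    scale) that is subtracted from their shared miRNAs, so sponge and mRNA
    co-vary positively and both anti-correlate with the miRNAs.
    """

    samples_per_group: int = 6
    n_mrna: int = 300
    n_lncrna: int = 120
    n_circrna: int = 80
    n_mirna: int = 150
    nb_mean_range: tuple[float, float] = (50.0, 1000.0)
    nb_dispersion: float = 0.02
    de_fraction: float | Mapping[str, float] = 0.3
    de_log2fc_magnitude: float = 2.5
    n_planted_triplets: int = 30
    shared_mirnas_per_triplet: int = 3
    n_shared_mrnas: int = 4
    sponge_strength: float = 1.0
    noise_sd: float = 0.05
    site_class: str = "8mer"
    target_seq_length: int = 500
    mirna_length: int = 22
    group_names: tuple[str, str] = ("BPD", "MSC")
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("samples_per_group", "n_mrna", "n_lncrna", "n_circrna",
                     "n_mirna"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.nb_mean_range
        if not (0 < lo <= hi):
            raise ValueError("nb_mean_range must be positive and ordered")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        for cls in RNA_CLASSES:
            f = self.de_fraction_for(cls)
            if not 0.0 <= f <= 1.0:
                raise ValueError("de_fraction must lie in [0, 1]")
        if self.de_log2fc_magnitude <= 0:
            raise ValueError("de_log2fc_magnitude must be > 0")
        if self.n_planted_triplets < 0:
            raise ValueError("n_planted_triplets must be >= 0")
        if self.n_planted_triplets and self.shared_mirnas_per_triplet < 3:
            # matches the downstream "at least three common miRNAs" rule
            raise ValueError("shared_mirnas_per_triplet must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.site_class not in SITE_CLASSES:
            raise ValueError(f"site_class must be one of {SITE_CLASSES}")
        if self.mirna_length < 8:
            raise ValueError("mirna_length must be >= 8")
        need = self.n_planted_triplets * self.shared_mirnas_per_triplet
        if need > self.n_mirna:
            raise ValueError(
                f"planted triplets need {need} distinct miRNAs but only "
                f"{self.n_mirna} are simulated")

    def de_fraction_for(self, feature_class: str) -> float:
        if isinstance(self.de_fraction, Mapping):
            return float(self.de_fraction.get(feature_class, 0.0))
        return float(self.de_fraction)

    def n_features(self, feature_class: str) -> int:
        return {"mRNA": self.n_mrna, "lncRNA": self.n_lncrna,
                "circRNA": self.n_circrna, "miRNA": self.n_mirna}[feature_class]


@dataclass
class Thresholds:
    """Every filter cutoff of the network-building pipeline."""

    lfc_cut: float = 1.0
    padj_cut: float = 0.05
    r_max: float = -0.9          # miRNA-target Pearson upper bound
    r_min: float = 0.8           # ce-mRNA Pearson lower bound
    p_max: float = 0.05          # correlation p cutoff
    min_shared_mirnas: int = 3
    p_hyper_cut: float = 0.05
    min_class: str = "7mer-A1"   # weakest seed class accepted as evidence
    min_score: float | None = None
    gsea_weight: float = 1.0
    n_perm: int = 1000
    log_expression: bool = True  # Pearson on log2(expr + 1)

    def __post_init__(self) -> None:
        if self.lfc_cut < 0:
            raise ValueError("lfc_cut must be >= 0")
        for name in ("padj_cut", "p_max", "p_hyper_cut"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not -1.0 <= self.r_max <= 1.0 or not -1.0 <= self.r_min <= 1.0:
            raise ValueError("correlation cutoffs must lie in [-1, 1]")
        if self.min_shared_mirnas < 1:
            raise ValueError("min_shared_mirnas must be >= 1")
        if self.min_class not in SITE_CLASSES:
            raise ValueError(f"min_class must be one of {SITE_CLASSES}")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


@dataclass
class PipelineConfig:
    """Inputs, thresholds and output location for one end-to-end run.

    Either ``sim`` is set (fixture mode: data are simulated, written and
    analysed) or ``input_dir`` points at a directory laid out like a
    simulator fixture (counts TSVs, sample sheet, FASTA, GMT).
    """

    outdir: str = "cernapipe_out"
    sim: SimConfig | None = None
    input_dir: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.sim is None and self.input_dir is None:
            raise ValueError("either sim or input_dir must be given")

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if d.get("sim") is not None:
            sim = dict(d["sim"])
            for key in ("nb_mean_range", "group_names"):
                if key in sim and sim[key] is not None:
                    sim[key] = tuple(sim[key])
            d["sim"] = SimConfig(**sim)
        if d.get("thresholds") is not None:
            d["thresholds"] = Thresholds(**dict(d["thresholds"]))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
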