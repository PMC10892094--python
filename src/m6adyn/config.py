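"""Simulation and pipeline configuration.

A single :class:`SimulationConfig` drives the synthetic-data generator; its
defaults encode the study design being emulated: 3 IP + 3 input replicates
per condition for m6A-IP-seq, 3x2 RNA-seq replicates, 2x2 polysome-seq
replicates, ~60% of transcripts methylated with peak classes split roughly
15% stress-only / 18% control-only / 67% shared (the proportions observed
for copper-stressed Arabidopsis), peaks of 150-200 nt with a strong 3'UTR
bias that shifts toward the 5'UTR/start codon for condition-specific peaks,
a sense-strand UGUA (DNA: TGTA) motif enriched inside peaks, and +-0.5 log2
abundance / occupancy effects for hosts of condition-specific peaks.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

#: order of the positional-bias vector entries
BIAS_REGIONS = ("5'UTR", "start", "CDS", "stop", "3'UTR")

PEAK_CLASSES = ("stress-only", "control-only", "shared")


def _default_bias() -> dict[str, tuple[float, ...]]:
    return {
        # strong 3'UTR bias for peaks present in both conditions; plant m6A
        # sits within the 3'UTR rather than centred on the stop codon
        "shared": (0.05, 0.05, 0.15, 0.10, 0.65),
        # condition-specific peaks shift toward 5'UTR / start codon
        "stress-only": (0.20, 0.20, 0.25, 0.10, 0.25),
        "control-only": (0.20, 0.20, 0.25, 0.10, 0.25),
    }


def _default_biotype_shares() -> dict[str, float]:
    # within the non-coding fraction; lncRNA largest, plain ncRNA second
    return {"lncRNA": 0.50, "ncRNA": 0.25, "miRNA_precursor": 0.15, "snoRNA": 0.10}


@dataclass
class SimulationConfig:
    # --- transcriptome ------------------------------------------------
    n_transcripts: int = 2000
    n_chroms: int = 4
    utr5_len: float = 150.0  # mean nt
    cds_len: float = 900.0
    utr3_len: float = 250.0
    noncoding_len: float = 500.0
    noncoding_frac: float = 0.10
    biotype_shares: dict = field(default_factory=_default_biotype_shares)
    intergenic_gap: tuple = (200, 500)
    intron_len: tuple = (60, 200)

    # --- planted methylation ------------------------------------------
    frac_methylated: float = 0.60
    frac_stress_only: float = 0.15
    frac_control_only: float = 0.18
    positional_bias: dict = field(default_factory=_default_bias)
    peak_len_min: int = 150
    peak_len_max: int = 200
    start_stop_flank: int = 50  # "codon-proximal" placement window, nt

    # --- IP / input window tracks -------------------------------------
    window_size: int = 25
    depth: float = 30.0  # mean input reads per window
    ip_enrichment: float = 8.0  # fold increase of IP mean inside active peaks
    window_dispersion: float = 0.005  # NB inverse-size; near-Poisson within-library
    n_ip_reps: int = 3
    # mild CDS enrichment of the background polyA+ coverage (real RNA-seq
    # reads pile up in the CDS relative to the UTRs)
    region_rate_utr5: float = 0.85
    region_rate_cds: float = 1.25
    region_rate_utr3: float = 0.85

    # --- motif --------------------------------------------------------
    motif: str = "TGTA"  # DNA spelling of the RNA motif UGUA, sense strand
    motif_rate_in_peaks: float = 0.8
    motif_rate_background: float = 0.05

    # --- expression / polysome ----------------------------------------
    n_rna_reps: int = 3
    n_poly_reps: int = 2
    expr_mean: float = 200.0  # lognormal mean counts per transcript
    expr_sigma: float = 0.8  # lognormal sigma (natural log)
    dispersion: float = 0.05  # NB inverse-size across biological replicates
    lfc_shift_stress_enriched: float = 0.5  # log2, copper abundance
    lfc_shift_control_enriched: float = -0.5
    lfc_shift_lncrna_stress: float = -0.5  # lncRNA hosts buck the mRNA trend
    occupancy_shift_stress_enriched: float = 0.5  # log2, copper polysome ratio
    library_factor_range: tuple = (0.85, 1.15)

    seed: int = 0

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.n_transcripts < 1:
            raise ValueError("n_transcripts must be positive")
        for name in ("frac_methylated", "frac_stress_only", "frac_control_only",
                     "noncoding_frac", "motif_rate_in_peaks", "motif_rate_background"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.frac_stress_only + self.frac_control_only > 1.0:
            raise ValueError("stress-only + control-only fractions exceed 1")
        for cls, vec in self.positional_bias.items():
            if cls not in PEAK_CLASSES:
                raise ValueError(f"unknown peak class {cls!r}")
            if len(vec) != 5 or abs(sum(vec) - 1.0) > 1e-9 or min(vec) < 0:
                raise ValueError(f"positional_bias[{cls}] must be a 5-probability vector")
        if abs(sum(self.biotype_shares.values()) - 1.0) > 1e-9:
            raise ValueError("biotype_shares must sum to 1")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.ip_enrichment < 1:
            raise ValueError("ip_enrichment must be >= 1")
        if not 0 < self.peak_len_min <= self.peak_len_max:
            raise ValueError("invalid peak length range")
        if self.window_size < 1:
            raise ValueError("window_size must be positive")

    # ------------------------------------------------------------------
    def to_yaml(self, path: str) -> None:
        d = asdict(self)
        d["intergenic_gap"] = list(self.intergenic_gap)
        d["intron_len"] = list(self.intron_len)
        d["library_factor_range"] = list(self.library_factor_range)
        d["positional_bias"] = {k: list(v) for k, v in self.positional_bias.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("intergenic_gap", "intron_len", "library_factor_range"):
            if key in d:
                d[key] = tuple(d[key])
        if "positional_bias" in d:
            d["positional_bias"] = {k: tuple(v) for k, v in d["positional_bias"].items()}
        cfg = cls(**d)
        cfg.validate()
        return cfg
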