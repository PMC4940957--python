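"""Configuration for the synthetic-data generator.

A single :class:`SynthConfig` holds every generative knob: transcript
composition, genome dropout, the genotype/replicate count design, the
small-RNA length and 5'-nucleotide structure, and TE/NAT planting.  One
global integer seed drives everything; each generator stage derives an
independent stream from ``(seed, stage_name)`` so adding a stage never
perturbs the output of another.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field

import numpy as np
import yaml


class ConfigError(ValueError):
    """Raised when a configuration field is invalid; names the field."""


def _default_srna_weights() -> dict[int, float]:
    # 24-nt mode typical of plant siRNA populations; 21 nt second (miRNA-like)
    return {20: 0.08, 21: 0.22, 22: 0.08, 23: 0.10, 24: 0.42, 25: 0.10}


@dataclass
class SynthConfig:
    """Generative parameters for all synthetic pipeline inputs.

    Defaults describe a desk-scale study: 400 transcripts (half with a
    planted ORF), a 3-genotype x 2-replicate count design with a planted
    differentially-expressed fraction, an sRNA population with a 24-nt
    mode and 5'-A bias, and TE/NAT planting into non-coding transcripts.
    """

    n_coding: int = 200
    n_noncoding: int = 200
    length_range: tuple[int, int] = (300, 1500)
    orf_length_mean: int = 600
    noncoding_orf_cap: int = 150  # nt; shuffles are redrawn until below this
    genome_dropout: float = 0.1
    flank_length: int = 300  # random genomic flank on each side of an insert

    # count design
    n_genotypes: int = 3
    n_replicates: int = 2
    n_somatic_replicates: int = 2
    library_size: int = 1_000_000
    de_fraction: float = 0.1
    log2_effect: float = 2.0
    nb_dispersion: float = 0.05
    meiocyte_exclusive_fraction: float = 0.25
    paralog_fraction: float = 0.1  # coding transcripts sharing a peptide id
    db_coverage: float = 0.9  # fraction of coding peptides present in any DB
    db_names: tuple[str, ...] = ("refpep1", "refpep2", "refpep3")

    # small RNA
    n_srna_reads: int = 10_000
    srna_length_weights: dict[int, float] = field(default_factory=_default_srna_weights)
    fiveprime_A_bias: float = 0.6
    srna_precursor_fraction: float = 0.5  # noncoding transcripts emitting sRNAs

    # repeats
    n_te_insertions: int = 50
    te_identity: float = 0.85
    te_retro_fraction: float = 0.91  # retrotransposon share among insertions
    n_nat_pairs: int = 20
    nat_window: int = 150

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_coding", "n_noncoding", "n_genotypes", "n_replicates",
                     "n_srna_reads", "n_te_insertions", "n_nat_pairs"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigError(f"{name} must be a non-negative integer, got {v!r}")
        lo, hi = self.length_range
        if lo <= 200:
            raise ConfigError(f"length_range minimum must exceed 200 nt, got {lo}")
        if hi < lo:
            raise ConfigError(f"length_range maximum {hi} below minimum {lo}")
        for name in ("genome_dropout", "de_fraction", "fiveprime_A_bias",
                     "meiocyte_exclusive_fraction", "paralog_fraction",
                     "db_coverage", "te_identity", "srna_precursor_fraction",
                     "te_retro_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v!r}")
        if self.nb_dispersion < 0:
            raise ConfigError(f"nb_dispersion must be >= 0, got {self.nb_dispersion!r}")
        w = self.srna_length_weights
        if not w or any(not 20 <= k <= 25 for k in w):
            raise ConfigError("srna_length_weights keys must lie in 20..25")
        total = float(sum(w.values()))
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"srna_length_weights must sum to 1, got {total}")
        if max(w, key=w.get) != 24:
            raise ConfigError("srna_length_weights must have its mode at 24 nt")

    def rng(self, stage: str) -> np.random.Generator:
        """Independent deterministic stream for a named generator stage."""
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed) & 0x7FFFFFFF,
                                    zlib.crc32(stage.encode())])
        )

    def replace(self, **kwargs) -> "SynthConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "length_range" in raw:
            raw["length_range"] = tuple(raw["length_range"])
        if "db_names" in raw:
            raw["db_names"] = tuple(raw["db_names"])
        if "srna_length_weights" in raw:
            raw["srna_length_weights"] = {int(k): float(v)
                                          for k, v in raw["srna_length_weights"].items()}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown configuration fields: {sorted(unknown)}")
        return cls(**raw)
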