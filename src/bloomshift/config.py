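"""Configuration objects: simulation parameters, sample metadata, pipeline options.

All user-facing configuration enters through JSON (see ``schema/config.schema.json``)
or is constructed programmatically from the dataclasses here. Validation is eager:
a bad configuration raises :class:`ConfigError` before any stage runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

VALID_BASES = ("A", "C", "G", "T")
VALID_CONDITIONS = ("mid", "late")
VALID_EXPERIMENTS = ("N", "Fe")

#: functional labels the simulator can plant and the biomarker stage understands
MARKER_LABELS = (
    "NRT2",
    "GSII",
    "ISIP1",
    "ISIP2",
    "ISIP3",
    "thiC",
    "flavodoxin",
    "ferredoxin",
    "ferritin",
    "LHC",
)

#: taxon-group vocabulary used when labelling simulated groups
TAXON_LABELS = (
    "centric diatom",
    "pennate diatom",
    "dinoflagellate",
    "chlorophyte",
    "haptophyte",
    "pelagophyte",
    "virus",
    "other",
)


class ConfigError(ValueError):
    """Raised for any invalid configuration value."""


@dataclass
class SampleSpec:
    """One sequencing library in a simulated experiment."""

    name: str
    experiment: str  # "N" or "Fe"
    barrel: str
    condition: str  # "mid" (replete) or "late" (depleted)
    library_size: int
    include_in_de: bool = True

    def validate(self) -> None:
        if self.experiment not in VALID_EXPERIMENTS:
            raise ConfigError(
                f"sample {self.name!r}: experiment must be one of "
                f"{VALID_EXPERIMENTS}, got {self.experiment!r}"
            )
        if self.condition not in VALID_CONDITIONS:
            raise ConfigError(
                f"sample {self.name!r}: condition must be one of "
                f"{VALID_CONDITIONS}, got {self.condition!r}"
            )
        if self.library_size <= 0:
            raise ConfigError(f"sample {self.name!r}: library_size must be > 0")


@dataclass
class PlantedSnv:
    """A variant planted by the simulator with a per-condition allele frequency."""

    orf_id: str
    position: int  # 1-based within the ORF
    ref_allele: str
    alt_allele: str
    freq_by_condition: dict[str, float]

    def validate(self, orf_length: int | None = None) -> None:
        if self.ref_allele not in VALID_BASES or self.alt_allele not in VALID_BASES:
            raise ConfigError(f"SNV at {self.orf_id}:{self.position}: alleles must be A/C/G/T")
        if self.ref_allele == self.alt_allele:
            raise ConfigError(f"SNV at {self.orf_id}:{self.position}: ref == alt")
        if self.position < 1:
            raise ConfigError(f"SNV at {self.orf_id}:{self.position}: position is 1-based")
        if orf_length is not None and self.position > orf_length:
            raise ConfigError(
                f"SNV at {self.orf_id}:{self.position}: position beyond ORF length {orf_length}"
            )
        for cond, f in self.freq_by_condition.items():
            if cond not in VALID_CONDITIONS:
                raise ConfigError(f"SNV at {self.orf_id}:{self.position}: unknown condition {cond!r}")
            if not 0.0 <= f <= 1.0:
                raise ConfigError(f"SNV at {self.orf_id}:{self.position}: frequency {f} not in [0,1]")


@dataclass
class SimConfig:
    """Parameters for a synthetic bloom-community metatranscriptome.

    Expression is negative-binomial with variance ``mu + dispersion * mu**2``.
    ``subpop_mix`` gives the per-condition mixing weight of a reference-diverged
    subpopulation (divergence ``subpop_divergence`` substitutions/site), and
    ``error_rate`` a uniform per-base sequencing error.
    """

    seed: int = 0
    n_taxon_groups: int = 2
    orfs_per_group: int = 50
    orf_length: int = 300
    samples: list[SampleSpec] = field(default_factory=list)
    dispersion: float = 0.05
    expr_log_sd: float = 1.0  # sd of log baseline expression across ORFs
    de_fraction: float = 0.1
    de_log2fc: float = 3.0
    de_sign: str = "both"  # "both" alternates +/-, "up"/"down" plant one direction
    group_bloom_log2fc: list[float] | None = None
    subpop_divergence: float = 0.0
    subpop_mix: dict[str, float] = field(default_factory=lambda: {"mid": 0.0, "late": 0.0})
    snv_spec: list[PlantedSnv] = field(default_factory=list)
    error_rate: float = 0.0
    read_length: int = 100
    # optional per-functional-label planted log2FC overriding the random DE draw,
    # keyed by experiment then label, e.g. {"N": {"NRT2": 3.0, "GSII": -2.0}}
    marker_log2fc: dict[str, dict[str, float]] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_taxon_groups < 1 or self.orfs_per_group < 1:
            raise ConfigError("need at least one taxon group and one ORF per group")
        if self.orf_length % 3 != 0:
            raise ConfigError(f"orf_length must be a multiple of 3, got {self.orf_length}")
        if self.read_length < 30:
            raise ConfigError(f"read_length must be >= 30, got {self.read_length}")
        if self.read_length > self.orf_length:
            raise ConfigError(
                f"read_length {self.read_length} exceeds orf_length {self.orf_length}"
            )
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if self.expr_log_sd < 0:
            raise ConfigError("expr_log_sd must be >= 0")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ConfigError("de_fraction must be in [0,1]")
        if self.de_sign not in ("both", "up", "down"):
            raise ConfigError("de_sign must be 'both', 'up' or 'down'")
        if not 0.0 <= self.subpop_divergence <= 0.3:
            raise ConfigError("subpop_divergence must be in [0, 0.3]")
        for cond, w in self.subpop_mix.items():
            if cond not in VALID_CONDITIONS:
                raise ConfigError(f"subpop_mix: unknown condition {cond!r}")
            if not 0.0 <= w <= 1.0:
                raise ConfigError(f"subpop_mix[{cond!r}] = {w} not in [0,1]")
        if not 0.0 <= self.error_rate <= 0.05:
            raise ConfigError("error_rate must be in [0, 0.05]")
        if self.group_bloom_log2fc is not None and len(self.group_bloom_log2fc) != self.n_taxon_groups:
            raise ConfigError(
                "group_bloom_log2fc must have one entry per taxon group "
                f"({self.n_taxon_groups}), got {len(self.group_bloom_log2fc)}"
            )
        names = [s.name for s in self.samples]
        if len(names) != len(set(names)):
            raise ConfigError("duplicate sample names")
        for s in self.samples:
            s.validate()
        for snv in self.snv_spec:
            snv.validate(self.orf_length)

    @property
    def bloom_log2fc(self) -> list[float]:
        if self.group_bloom_log2fc is None:
            return [0.0] * self.n_taxon_groups
        return list(self.group_bloom_log2fc)

    # ---- JSON round trip -------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = {
            "seed": self.seed,
            "n_taxon_groups": self.n_taxon_groups,
            "orfs_per_group": self.orfs_per_group,
            "orf_length": self.orf_length,
            "dispersion": self.dispersion,
            "expr_log_sd": self.expr_log_sd,
            "de_fraction": self.de_fraction,
            "de_log2fc": self.de_log2fc,
            "de_sign": self.de_sign,
            "group_bloom_log2fc": self.group_bloom_log2fc,
            "subpop_divergence": self.subpop_divergence,
            "subpop_mix": self.subpop_mix,
            "error_rate": self.error_rate,
            "read_length": self.read_length,
            "marker_log2fc": self.marker_log2fc,
            "samples": [
                {
                    "name": s.name,
                    "experiment": s.experiment,
                    "barrel": s.barrel,
                    "condition": s.condition,
                    "library_size": s.library_size,
                    "include_in_de": s.include_in_de,
                }
                for s in self.samples
            ],
            "snv_spec": [
                {
                    "orf_id": v.orf_id,
                    "position": v.position,
                    "ref_allele": v.ref_allele,
                    "alt_allele": v.alt_allele,
                    "freq_by_condition": v.freq_by_condition,
                }
                for v in self.snv_spec
            ],
        }
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        known = {
            "seed",
            "n_taxon_groups",
            "orfs_per_group",
            "orf_length",
            "dispersion",
            "expr_log_sd",
            "de_fraction",
            "de_log2fc",
            "de_sign",
            "group_bloom_log2fc",
            "subpop_divergence",
            "subpop_mix",
            "error_rate",
            "read_length",
            "marker_log2fc",
            "samples",
            "snv_spec",
        }
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown simulation config keys: {sorted(unknown)}")
        samples = [SampleSpec(**s) for s in d.get("samples", [])]
        snvs = [PlantedSnv(**v) for v in d.get("snv_spec", [])]
        kwargs = {k: v for k, v in d.items() if k not in ("samples", "snv_spec")}
        cfg = cls(samples=samples, snv_spec=snvs, **kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


class SampleSheet:
    """Sample metadata table: sample -> experiment, barrel, condition, DE inclusion.

    Conditions are stored as ``replete``/``depleted`` (the simulator's ``mid``
    maps to replete, ``late`` to depleted).
    """

    COLUMNS = ["sample", "experiment", "barrel", "condition", "include_in_de"]

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ConfigError(f"sample sheet missing columns: {sorted(missing)}")
        if df["sample"].duplicated().any():
            dup = df.loc[df["sample"].duplicated(), "sample"].tolist()
            raise ConfigError(f"duplicate samples in sheet: {dup}")
        bad = set(df["condition"]) - {"replete", "depleted"}
        if bad:
            raise ConfigError(f"sample sheet conditions must be replete/depleted, got {sorted(bad)}")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_samples(cls, samples: list[SampleSpec]) -> "SampleSheet":
        rows = [
            {
                "sample": s.name,
                "experiment": s.experiment,
                "barrel": s.barrel,
                "condition": "replete" if s.condition == "mid" else "depleted",
                "include_in_de": s.include_in_de,
            }
            for s in samples
        ]
        return cls(pd.DataFrame(rows, columns=cls.COLUMNS))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t", dtype={"sample": str, "barrel": str})
        df["include_in_de"] = df["include_in_de"].astype(bool)
        return cls(df)

    def write_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @property
    def samples(self) -> list[str]:
        return self.df["sample"].tolist()

    def contrast_samples(self, experiment: str) -> tuple[list[str], list[str]]:
        """(depleted, replete) sample names for one experiment, DE-included only."""
        sub = self.df[(self.df["experiment"] == experiment) & self.df["include_in_de"]]
        depleted = sub.loc[sub["condition"] == "depleted", "sample"].tolist()
        replete = sub.loc[sub["condition"] == "replete", "sample"].tolist()
        return depleted, replete

    def replicate_pairs(self, experiment: str) -> dict[str, tuple[str, str]]:
        """Per-barrel (replete, depleted) sample pairs for one experiment.

        Barrels lacking either stage are skipped.
        """
        pairs: dict[str, tuple[str, str]] = {}
        sub = self.df[self.df["experiment"] == experiment]
        for barrel, grp in sub.groupby("barrel"):
            rep = grp.loc[grp["condition"] == "replete", "sample"].tolist()
            dep = grp.loc[grp["condition"] == "depleted", "sample"].tolist()
            if len(rep) == 1 and len(dep) == 1:
                pairs[str(barrel)] = (rep[0], dep[0])
        return pairs

    def condition_of(self, sample: str) -> str:
        row = self.df[self.df["sample"] == sample]
        if row.empty:
            raise ConfigError(f"unknown sample {sample!r}")
        return str(row["condition"].iloc[0])


def default_demo_samples(library_size: int = 25_000) -> list[SampleSpec]:
    """The eight-sample layout of the two bloom experiments (MB6 excluded from DE)."""
    mk = SampleSpec
    return [
        mk("MB1", "N", "B1", "mid", library_size),
        mk("MB2", "N", "B1", "late", library_size),
        mk("MB3", "N", "B3", "mid", library_size),
        mk("MB4", "N", "B3", "late", library_size),
        mk("MB5", "Fe", "B2", "mid", library_size),
        mk("MB6", "Fe", "B2", "late", library_size, include_in_de=False),
        mk("MB7", "Fe", "B4", "mid", library_size),
        mk("MB8", "Fe", "B4", "late", library_size),
    ]
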