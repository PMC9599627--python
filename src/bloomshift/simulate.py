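"""Synthetic bloom-community metatranscriptomes with planted truth.

The simulator produces ORF references, per-sample reads (FASTQ) with exact
truth alignments (SAM), and truth tables for every planted effect:

* negative-binomial ORF expression with planted log2 fold changes,
* per-taxon-group abundance dynamics (blooming vs static groups),
* a reference-diverged subpopulation per group whose mixture weight changes
  across bloom stages (producing percent-identity shifts),
* planted SNVs with per-condition allele frequencies,
* uniform per-base sequencing error.

Randomness derives from one root seed; each sample gets an independent stream
keyed by a stable hash of its name, so adding a sample never perturbs others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    MARKER_LABELS,
    TAXON_LABELS,
    ConfigError,
    SampleSheet,
    SampleSpec,
    SimConfig,
)
from .formats import AlignmentRecord, write_fasta, write_fastq, write_sam

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {ord(b): i for i, b in enumerate("ACGT")}
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.empty(len(arr), dtype=np.uint8)
    for byte, code in _CODE.items():
        out[arr == byte] = code
    return out


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def _sample_rng(seed: int, name: str, stream: int) -> np.random.Generator:
    """Independent per-sample generator: root seed + stable hash of the name."""
    return np.random.default_rng([seed, zlib.crc32(name.encode()), stream])


@dataclass
class SimRead:
    read_id: str
    orf_id: str
    start: int  # 0-based on the ORF
    seq: str
    nm: int
    from_subpop: bool


@dataclass
class SampleReads:
    sample: str
    reads: list[SimRead]
    counts: np.ndarray  # per-ORF read counts, aligned with bundle.orf_ids


@dataclass
class SimBundle:
    """References, annotation and truth for one simulated community."""

    config: SimConfig
    orf_ids: list[str]
    references: dict[str, str]
    diverged: dict[str, str]
    annotation: pd.DataFrame  # orf_id, taxon_group, genus, gene_family, functional_label
    base_mean: np.ndarray
    true_log2fc: dict[str, np.ndarray]  # experiment -> per-ORF planted log2FC
    group_index: np.ndarray  # per-ORF taxon-group index
    reads: dict[str, SampleReads] = field(default_factory=dict)

    @property
    def sample_sheet(self) -> SampleSheet:
        return SampleSheet.from_samples(self.config.samples)

    def sample_spec(self, name: str) -> SampleSpec:
        for s in self.config.samples:
            if s.name == name:
                return s
        raise ConfigError(f"unknown sample {name!r}")

    def truth_table(self) -> pd.DataFrame:
        bloom = np.asarray(self.config.bloom_log2fc)[self.group_index]
        return pd.DataFrame(
            {
                "orf_id": self.orf_ids,
                "taxon_group": self.annotation["taxon_group"].to_numpy(),
                "log2fc_N": self.true_log2fc["N"],
                "log2fc_Fe": self.true_log2fc["Fe"],
                "group_bloom_log2fc": bloom,
                "base_mean": self.base_mean,
            }
        )

    def snv_truth_table(self) -> pd.DataFrame:
        rows = [
            {
                "orf_id": v.orf_id,
                "position": v.position,
                "ref_allele": v.ref_allele,
                "alt_allele": v.alt_allele,
                "freq_mid": v.freq_by_condition.get("mid", 0.0),
                "freq_late": v.freq_by_condition.get("late", 0.0),
            }
            for v in self.config.snv_spec
        ]
        return pd.DataFrame(
            rows,
            columns=["orf_id", "position", "ref_allele", "alt_allele", "freq_mid", "freq_late"],
        )


def mutate_sequence(seq: str, rate: float, seed: int | np.random.Generator) -> str:
    """Substitute each site independently with probability ``rate``.

    Substitutions go to a uniformly chosen *different* base; length is
    preserved. ``rate`` must be in [0, 0.3].
    """
    if not 0.0 <= rate <= 0.3:
        raise ConfigError(f"divergence rate must be in [0, 0.3], got {rate}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = _encode(seq)
    mask = rng.random(arr.size) < rate
    if mask.any():
        arr = arr.copy()
        shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
        arr[mask] = (arr[mask] + shift) % 4
    return _decode(arr)


def generate_references(config: SimConfig) -> SimBundle:
    """Build ORF references, annotation, planted effects and diverged subpopulations."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    n_codons = config.orf_length // 3
    n_orfs = config.n_taxon_groups * config.orfs_per_group

    codon_arr = np.array([_encode(c) for c in _SENSE_CODONS], dtype=np.uint8)

    orf_ids: list[str] = []
    references: dict[str, str] = {}
    ann_rows: list[dict] = []
    group_index = np.empty(n_orfs, dtype=int)

    k = 0
    for g in range(config.n_taxon_groups):
        taxon = TAXON_LABELS[g % len(TAXON_LABELS)]
        genus = f"Genus{g:02d}"
        for i in range(config.orfs_per_group):
            orf_id = f"G{g:02d}_ORF{i:04d}"
            body_idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons - 2)
            body = codon_arr[body_idx].reshape(-1)
            seq = "ATG" + _decode(body) + "TAA"
            orf_ids.append(orf_id)
            references[orf_id] = seq
            label = MARKER_LABELS[i] if i < len(MARKER_LABELS) else ""
            ann_rows.append(
                {
                    "orf_id": orf_id,
                    "taxon_group": taxon,
                    "genus": genus,
                    "gene_family": f"fam{i % 25:02d}",
                    "functional_label": label,
                }
            )
            group_index[k] = g
            k += 1

    annotation = pd.DataFrame(ann_rows)

    # baseline relative expression (lognormal across ORFs)
    base_mean = rng.lognormal(mean=0.0, sigma=config.expr_log_sd, size=n_orfs)

    # planted differential expression: same random draw for both experiments,
    # then per-experiment marker overrides
    lfc = np.zeros(n_orfs)
    n_de = int(round(config.de_fraction * n_orfs))
    if n_de > 0:
        de_idx = rng.choice(n_orfs, size=n_de, replace=False)
        if config.de_sign == "up":
            signs = np.ones(n_de)
        elif config.de_sign == "down":
            signs = -np.ones(n_de)
        else:
            signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
        lfc[de_idx] = signs * config.de_log2fc
    true_log2fc: dict[str, np.ndarray] = {}
    labels = annotation["functional_label"].to_numpy()
    for exp in ("N", "Fe"):
        lfc_exp = lfc.copy()
        for label, value in config.marker_log2fc.get(exp, {}).items():
            lfc_exp[labels == label] = value
        true_log2fc[exp] = lfc_exp

    diverged: dict[str, str] = {}
    if config.subpop_divergence > 0:
        for j, orf_id in enumerate(orf_ids):
            sub_rng = np.random.default_rng([config.seed, 1, j])
            diverged[orf_id] = mutate_sequence(
                references[orf_id], config.subpop_divergence, sub_rng
            )
    else:
        diverged = dict(references)

    # validate planted SNVs against actual ORF ids and reference bases
    for v in config.snv_spec:
        if v.orf_id not in references:
            raise ConfigError(f"snv_spec references unknown ORF {v.orf_id!r}")

    return SimBundle(
        config=config,
        orf_ids=orf_ids,
        references=references,
        diverged=diverged,
        annotation=annotation,
        base_mean=base_mean,
        true_log2fc=true_log2fc,
        group_index=group_index,
    )


def _expected_means(bundle: SimBundle, spec: SampleSpec) -> np.ndarray:
    """Per-ORF expected relative expression for one sample."""
    cfg = bundle.config
    mu = bundle.base_mean.copy()
    if spec.condition == "late":
        mu *= np.exp2(bundle.true_log2fc[spec.experiment])
        bloom = np.asarray(cfg.bloom_log2fc)[bundle.group_index]
        mu *= np.exp2(bloom)
    return mu


def generate_counts(bundle: SimBundle, sample_name: str) -> np.ndarray:
    """Per-ORF read counts for one sample (gamma-Poisson/multinomial scheme).

    Each ORF's latent intensity is Gamma(1/phi, phi*mu) so counts are
    overdispersed with variance ~ mu + phi*mu^2; the multinomial step pins the
    column total to the configured library size exactly.
    """
    cfg = bundle.config
    spec = bundle.sample_spec(sample_name)
    rng = _sample_rng(cfg.seed, sample_name, 1)
    mu = _expected_means(bundle, spec)
    if cfg.dispersion > 0:
        lam = rng.gamma(shape=1.0 / cfg.dispersion, scale=cfg.dispersion * mu)
    else:
        lam = mu
    total = lam.sum()
    if total <= 0:
        raise ConfigError("all expression intensities are zero")
    return rng.multinomial(spec.library_size, lam / total)


def generate_reads(bundle: SimBundle, sample_name: str) -> SampleReads:
    """Emit reads plus exact truth (start, NM, subpopulation origin) for one sample."""
    cfg = bundle.config
    spec = bundle.sample_spec(sample_name)
    rl = cfg.read_length
    counts = generate_counts(bundle, sample_name)
    rng = _sample_rng(cfg.seed, sample_name, 2)
    mix = cfg.subpop_mix.get(spec.condition, 0.0)

    snvs_by_orf: dict[str, list] = {}
    for v in cfg.snv_spec:
        snvs_by_orf.setdefault(v.orf_id, []).append(v)

    window = np.arange(rl)
    reads: list[SimRead] = []
    for j, orf_id in enumerate(bundle.orf_ids):
        c = int(counts[j])
        if c == 0:
            continue
        ref_arr = _encode(bundle.references[orf_id])
        L = ref_arr.size
        starts = rng.integers(0, L - rl + 1, size=c)
        ref_windows = ref_arr[starts[:, None] + window]
        if mix > 0.0:
            div_arr = _encode(bundle.diverged[orf_id])
            from_sub = rng.random(c) < mix
            emitted = np.where(from_sub[:, None], div_arr[starts[:, None] + window], ref_windows)
        else:
            from_sub = np.zeros(c, dtype=bool)
            emitted = ref_windows.copy()

        for v in snvs_by_orf.get(orf_id, ()):
            p0 = v.position - 1
            freq = v.freq_by_condition.get(spec.condition, 0.0)
            carry_alt = rng.random(c) < freq
            covered = (starts <= p0) & (p0 < starts + rl)
            cols = p0 - starts
            alt_code, ref_code = _CODE[ord(v.alt_allele)], _CODE[ord(v.ref_allele)]
            base = np.where(carry_alt, alt_code, ref_code).astype(np.uint8)
            rows = np.nonzero(covered)[0]
            emitted[rows, cols[rows]] = base[rows]

        if cfg.error_rate > 0.0:
            err = rng.random((c, rl)) < cfg.error_rate
            n_err = int(err.sum())
            if n_err:
                shift = rng.integers(1, 4, size=n_err, dtype=np.uint8)
                emitted[err] = (emitted[err] + shift) % 4

        nm = (emitted != ref_windows).sum(axis=1)
        for r in range(c):
            reads.append(
                SimRead(
                    read_id=f"{sample_name}_{orf_id}_{r}",
                    orf_id=orf_id,
                    start=int(starts[r]),
                    seq=_decode(emitted[r]),
                    nm=int(nm[r]),
                    from_subpop=bool(from_sub[r]),
                )
            )
    return SampleReads(sample=sample_name, reads=reads, counts=counts)


def to_alignment_records(sample_reads: SampleReads) -> list[AlignmentRecord]:
    """Truth alignments for simulated reads (ungapped, CIGAR ``<L>M``)."""
    return [
        AlignmentRecord(
            read_id=r.read_id,
            orf_id=r.orf_id,
            pos=r.start,
            cigar=[("M", len(r.seq))],
            nm=r.nm,
            mapq=60,
            seq=r.seq,
        )
        for r in sample_reads.reads
    ]


def simulate_counts_matrix(bundle: SimBundle) -> pd.DataFrame:
    """ORF x sample count matrix without generating reads (fast path)."""
    data = {s.name: generate_counts(bundle, s.name) for s in bundle.config.samples}
    return pd.DataFrame(data, index=bundle.orf_ids)


def write_bundle(
    bundle: SimBundle,
    outdir: str | Path,
    write_reads: bool = True,
    write_subpop_truth: bool = False,
) -> dict[str, Path]:
    """Materialize a bundle as plain files; returns a name -> path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["references"] = outdir / "references.fasta"
    write_fasta(bundle.references, paths["references"])
    paths["annotation"] = outdir / "annotation.tsv"
    bundle.annotation.to_csv(paths["annotation"], sep="\t", index=False)
    paths["sample_sheet"] = outdir / "sample_sheet.tsv"
    bundle.sample_sheet.write_tsv(paths["sample_sheet"])
    paths["truth_log2fc"] = outdir / "truth_log2fc.tsv"
    bundle.truth_table().to_csv(paths["truth_log2fc"], sep="\t", index=False)
    paths["truth_snv"] = outdir / "truth_snv.tsv"
    bundle.snv_truth_table().to_csv(paths["truth_snv"], sep="\t", index=False)
    if bundle.config.subpop_divergence > 0:
        paths["diverged"] = outdir / "diverged_references.fasta"
        write_fasta(bundle.diverged, paths["diverged"])

    if write_reads:
        for spec in bundle.config.samples:
            sr = bundle.reads.get(spec.name) or generate_reads(bundle, spec.name)
            bundle.reads[spec.name] = sr
            fq = outdir / f"{spec.name}.fastq"
            write_fastq(((r.read_id, r.seq) for r in sr.reads), fq)
            paths[f"fastq:{spec.name}"] = fq
            sam = outdir / f"{spec.name}.sam"
            write_sam(to_alignment_records(sr), bundle.references, sam)
            paths[f"sam:{spec.name}"] = sam
            if write_subpop_truth:
                tp = outdir / f"truth_subpop_{spec.name}.tsv"
                pd.DataFrame(
                    {
                        "read_id": [r.read_id for r in sr.reads],
                        "orf_id": [r.orf_id for r in sr.reads],
                        "from_subpop": [int(r.from_subpop) for r in sr.reads],
                    }
                ).to_csv(tp, sep="\t", index=False)
                paths[f"truth_subpop:{spec.name}"] = tp
    return paths
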