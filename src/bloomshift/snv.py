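"""Gene-level selection: pileup SNV calling, coding effect, density, sweeps.

Calling is per sample; the cross-sample union of called sites is taken
afterwards so allele-frequency trajectories can be followed through samples
where a site was covered but not called.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .config import SampleSheet
from .formats import AlignmentRecord

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


class SnvError(ValueError):
    pass


@dataclass
class SnvCall:
    orf_id: str
    pos: int  # 1-based within the ORF
    ref_allele: str
    alt_allele: str
    samples: dict[str, tuple[int, int]] = field(default_factory=dict)  # sample -> (depth, alt)
    called_in: set[str] = field(default_factory=set)
    codon_index: int | None = None
    codon_pos: int | None = None
    effect: str = "NA"
    codon_change: str | None = None

    def af(self, sample: str) -> float | None:
        st = self.samples.get(sample)
        if st is None or st[0] == 0:
            return None
        return st[1] / st[0]


class Pileup:
    """Per-ORF, per-site base counts (A/C/G/T rows x site columns)."""

    def __init__(self, counts: dict[str, np.ndarray]):
        self.counts = counts

    def depth(self, orf_id: str) -> np.ndarray:
        return self.counts[orf_id].sum(axis=0)

    def mean_coverage(self, orf_id: str) -> float:
        return float(self.depth(orf_id).mean())


def build_pileup(
    alignments: Iterable[AlignmentRecord], references: dict[str, str]
) -> Pileup:
    """Accumulate base counts per reference site from primary alignments.

    CIGAR semantics: M emits read bases onto reference sites, D consumes
    reference without emitting, I and S consume read only. An alignment
    running past the reference end is an error naming the record.
    """
    counts = {
        orf: np.zeros((4, len(seq)), dtype=np.int64) for orf, seq in references.items()
    }
    for a in alignments:
        if not a.is_primary:
            continue
        if a.seq is None:
            raise SnvError(f"record {a.read_id}: no sequence; cannot pile up")
        mat = counts.get(a.orf_id)
        if mat is None:
            raise SnvError(f"record {a.read_id}: unknown reference {a.orf_id!r}")
        ref_len = mat.shape[1]
        if a.pos + a.reference_span > ref_len:
            raise SnvError(
                f"record {a.read_id}: alignment overruns reference {a.orf_id} "
                f"({a.pos}+{a.reference_span} > {ref_len})"
            )
        ref_pos = a.pos
        read_pos = 0
        for op, n in a.cigar:
            if op == "M":
                chunk = a.seq[read_pos : read_pos + n]
                codes = np.frombuffer(chunk.encode(), dtype=np.uint8)
                idx = np.full(n, -1, dtype=np.int64)
                for b, i in _BASE_INDEX.items():
                    idx[codes == ord(b)] = i
                valid = idx >= 0  # skip N or other ambiguity codes
                sites = np.arange(ref_pos, ref_pos + n)
                np.add.at(mat, (idx[valid], sites[valid]), 1)
                ref_pos += n
                read_pos += n
            elif op == "D":
                ref_pos += n
            elif op in ("I", "S"):
                read_pos += n
    return Pileup(counts)


def call_snvs(
    pileup: Pileup,
    references: dict[str, str],
    min_depth: int = 4,
    min_alt: int = 2,
    min_af: float = 0.05,
) -> list[SnvCall]:
    """One call per alternate allele passing depth/count/frequency thresholds."""
    calls: list[SnvCall] = []
    for orf_id, mat in pileup.counts.items():
        ref_seq = references[orf_id]
        depth = mat.sum(axis=0)
        eligible = np.nonzero(depth >= min_depth)[0]
        for site in eligible:
            ref_base = ref_seq[site]
            ref_idx = _BASE_INDEX.get(ref_base)
            d = int(depth[site])
            for alt_idx in range(4):
                if alt_idx == ref_idx:
                    continue
                alt_count = int(mat[alt_idx, site])
                if alt_count >= min_alt and alt_count / d >= min_af:
                    calls.append(
                        SnvCall(
                            orf_id=orf_id,
                            pos=int(site) + 1,
                            ref_allele=ref_base,
                            alt_allele=_BASES[alt_idx],
                        )
                    )
    return calls


def classify_effect(snv: SnvCall, orf_sequence: str) -> str:
    """SYN/NONSYN by substituting the alt allele into its codon (frame 1).

    Stop gain or loss counts as NONSYN. Positions falling in an incomplete
    trailing codon classify as ``NA``. Also fills codon_index/codon_pos and the
    codon-change annotation on the call.
    """
    p0 = snv.pos - 1
    if p0 >= len(orf_sequence):
        raise SnvError(f"SNV position {snv.pos} beyond ORF {snv.orf_id}")
    codon_index = p0 // 3
    codon_start = codon_index * 3
    snv.codon_index = codon_index
    snv.codon_pos = p0 % 3 + 1
    codon = orf_sequence[codon_start : codon_start + 3]
    if len(codon) < 3:
        snv.effect = "NA"
        return "NA"
    offset = p0 - codon_start
    alt_codon = codon[:offset] + snv.alt_allele + codon[offset + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    snv.codon_change = f"{codon}>{alt_codon}"
    snv.effect = "SYN" if aa_ref == aa_alt else "NONSYN"
    return snv.effect


def call_snvs_per_sample(
    pileups: Mapping[str, Pileup],
    references: dict[str, str],
    min_depth: int = 4,
    min_alt: int = 2,
    min_af: float = 0.05,
    classify: bool = True,
) -> list[SnvCall]:
    """Call each sample independently, then merge on (ORF, pos, alt).

    Merged calls carry per-sample depth/alt counts for *all* samples covering
    the site (needed for trajectories), and remember which samples the call
    passed thresholds in.
    """
    merged: dict[tuple[str, int, str], SnvCall] = {}
    for sample, pileup in pileups.items():
        for c in call_snvs(pileup, references, min_depth, min_alt, min_af):
            key = (c.orf_id, c.pos, c.alt_allele)
            call = merged.setdefault(key, c)
            call.called_in.add(sample)
    for call in merged.values():
        alt_idx = _BASE_INDEX[call.alt_allele]
        site = call.pos - 1
        for sample, pileup in pileups.items():
            mat = pileup.counts[call.orf_id]
            depth = int(mat[:, site].sum())
            call.samples[sample] = (depth, int(mat[alt_idx, site]))
        if classify:
            classify_effect(call, references[call.orf_id])
    return sorted(merged.values(), key=lambda c: (c.orf_id, c.pos, c.alt_allele))


@dataclass
class DensityStat:
    taxon_group: str
    sample: str
    n_snvs: int
    n_orfs: int
    density: float | None  # None when no ORF meets the coverage criterion


def snv_density(
    calls: list[SnvCall],
    pileups: Mapping[str, Pileup],
    annotation: pd.DataFrame,
    min_depth: int = 4,
) -> list[DensityStat]:
    """Distinct called sites per eligible ORF, by taxon group and sample.

    The denominator counts the group's ORFs with mean coverage >= ``min_depth``
    in that sample; groups with no eligible ORF report a missing density.
    """
    group_of = annotation.set_index("orf_id")["taxon_group"].to_dict()
    stats: list[DensityStat] = []
    groups = sorted(set(group_of.values()))
    for sample, pileup in pileups.items():
        eligible: dict[str, int] = {g: 0 for g in groups}
        for orf_id in pileup.counts:
            g = group_of.get(orf_id)
            if g is not None and pileup.mean_coverage(orf_id) >= min_depth:
                eligible[g] += 1
        sites: dict[str, set[tuple[str, int]]] = {g: set() for g in groups}
        for c in calls:
            if sample not in c.called_in:
                continue
            g = group_of.get(c.orf_id)
            if g is not None:
                sites[g].add((c.orf_id, c.pos))
        for g in groups:
            n_orfs = eligible[g]
            n_snvs = len(sites[g])
            stats.append(
                DensityStat(
                    taxon_group=g,
                    sample=sample,
                    n_snvs=n_snvs,
                    n_orfs=n_orfs,
                    density=(n_snvs / n_orfs) if n_orfs > 0 else None,
                )
            )
    return stats


@dataclass
class TrajectoryRecord:
    orf_id: str
    pos: int
    ref_allele: str
    alt_allele: str
    experiment: str
    af_mid: float | None
    af_late: float | None
    delta_af: float | None
    sweep: bool


def allele_trajectories(
    calls: list[SnvCall],
    sample_sheet: SampleSheet,
    sweep_hi: float = 0.9,
    sweep_lo: float = 0.5,
) -> list[TrajectoryRecord]:
    """Stage-averaged allele frequencies per experiment with sweep flags.

    Within an experiment, frequencies are averaged over replicates per stage
    (replete = mid, depleted = late). ``sweep`` is set iff af_mid <= sweep_lo
    and af_late >= sweep_hi. Uncovered stages yield missing frequencies, never
    imputed, and cannot sweep.
    """
    df = sample_sheet.df
    records: list[TrajectoryRecord] = []
    for experiment in sorted(df["experiment"].unique()):
        sub = df[df["experiment"] == experiment]
        mids = sub.loc[sub["condition"] == "replete", "sample"].tolist()
        lates = sub.loc[sub["condition"] == "depleted", "sample"].tolist()
        for c in calls:
            def _stage_af(samples: list[str]) -> float | None:
                vals = [c.af(s) for s in samples if c.af(s) is not None]
                return float(np.mean(vals)) if vals else None

            af_mid = _stage_af(mids)
            af_late = _stage_af(lates)
            delta = (af_late - af_mid) if (af_mid is not None and af_late is not None) else None
            sweep = (
                af_mid is not None
                and af_late is not None
                and af_mid <= sweep_lo
                and af_late >= sweep_hi
            )
            records.append(
                TrajectoryRecord(
                    orf_id=c.orf_id,
                    pos=c.pos,
                    ref_allele=c.ref_allele,
                    alt_allele=c.alt_allele,
                    experiment=experiment,
                    af_mid=af_mid,
                    af_late=af_late,
                    delta_af=delta,
                    sweep=sweep,
                )
            )
    return records


def density_frame(stats: list[DensityStat]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "taxon_group": s.taxon_group,
                "sample": s.sample,
                "n_snvs": s.n_snvs,
                "n_orfs": s.n_orfs,
                "density": s.density if s.density is not None else np.nan,
            }
            for s in stats
        ],
        columns=["taxon_group", "sample", "n_snvs", "n_orfs", "density"],
    )


def trajectory_frame(records: list[TrajectoryRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "orf_id": r.orf_id,
                "pos": r.pos,
                "ref_allele": r.ref_allele,
                "alt_allele": r.alt_allele,
                "experiment": r.experiment,
                "af_mid": r.af_mid if r.af_mid is not None else np.nan,
                "af_late": r.af_late if r.af_late is not None else np.nan,
                "delta_af": r.delta_af if r.delta_af is not None else np.nan,
                "sweep": r.sweep,
            }
            for r in records
        ],
        columns=[
            "orf_id", "pos", "ref_allele", "alt_allele", "experiment",
            "af_mid", "af_late", "delta_af", "sweep",
        ],
    )
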