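"""Population-level selection: percent identity of mapped reads and its shifts.

A read's percent identity to the reference summarizes how close its source
population is to the reference strain; per-sample histograms reveal
subpopulation structure, and per-ORF identity changes between bloom stages
that replicate across barrels flag population turnover.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .formats import AlignmentRecord


class PopshiftError(ValueError):
    pass


def percent_identity(alignment: AlignmentRecord) -> float:
    """100 * (1 - NM / aligned_columns); soft clips are not aligned columns."""
    cols = alignment.aligned_columns
    if cols == 0:
        raise PopshiftError(f"record {alignment.read_id}: no aligned columns")
    pid = 100.0 * (1.0 - alignment.nm / cols)
    return min(max(pid, 0.0), 100.0)


@dataclass
class PidSummary:
    """Per-(ORF, sample) read counts/mean identity plus per-group histograms."""

    per_orf: pd.DataFrame  # orf_id, sample, n_reads, mean_pid
    histogram: pd.DataFrame  # sample, reference_group, bin_start, bin_end, count

    def mean_pid(self, orf_id: str, sample: str) -> float | None:
        row = self.per_orf[
            (self.per_orf["orf_id"] == orf_id) & (self.per_orf["sample"] == sample)
        ]
        return None if row.empty else float(row["mean_pid"].iloc[0])


def pid_histogram(
    alignments_by_sample: Mapping[str, Iterable[AlignmentRecord]],
    annotation: pd.DataFrame | None = None,
    bin_width: float = 1.0,
) -> PidSummary:
    """Percent-identity summaries per ORF and binned histograms per reference group.

    Bins are left-closed right-open on [50, 100) with a final closed bin ending
    at 100; identities below 50 go to an ``underflow`` bucket.
    """
    if annotation is not None:
        group_of = annotation.set_index("orf_id")["taxon_group"].to_dict()
    else:
        group_of = {}

    edges = np.arange(50.0, 100.0 + bin_width, bin_width)
    per_orf_rows = []
    hist_rows = []
    for sample, alns in alignments_by_sample.items():
        pid_by_orf: dict[str, list[float]] = {}
        pid_by_group: dict[str, list[float]] = {}
        for a in alns:
            if not a.is_primary:
                continue
            pid = percent_identity(a)
            pid_by_orf.setdefault(a.orf_id, []).append(pid)
            grp = group_of.get(a.orf_id, "all")
            pid_by_group.setdefault(grp, []).append(pid)
        for orf_id, pids in sorted(pid_by_orf.items()):
            per_orf_rows.append(
                {
                    "orf_id": orf_id,
                    "sample": sample,
                    "n_reads": len(pids),
                    "mean_pid": float(np.mean(pids)),
                }
            )
        for grp, pids in sorted(pid_by_group.items()):
            arr = np.asarray(pids)
            under = int((arr < 50.0).sum())
            if under:
                hist_rows.append(
                    {
                        "sample": sample,
                        "reference_group": grp,
                        "bin_start": float("-inf"),
                        "bin_end": 50.0,
                        "count": under,
                    }
                )
            in_range = arr[arr >= 50.0]
            # final bin closed at 100: clip exact 100s into the last bin
            idx = np.minimum(
                np.floor((in_range - 50.0) / bin_width).astype(int), len(edges) - 2
            )
            counts = np.bincount(idx, minlength=len(edges) - 1)
            for b, c in enumerate(counts):
                if c:
                    hist_rows.append(
                        {
                            "sample": sample,
                            "reference_group": grp,
                            "bin_start": float(edges[b]),
                            "bin_end": float(edges[b + 1]),
                            "count": int(c),
                        }
                    )
    per_orf = pd.DataFrame(
        per_orf_rows, columns=["orf_id", "sample", "n_reads", "mean_pid"]
    )
    histogram = pd.DataFrame(
        hist_rows, columns=["sample", "reference_group", "bin_start", "bin_end", "count"]
    )
    return PidSummary(per_orf=per_orf, histogram=histogram)


@dataclass
class ShiftRecord:
    orf_id: str
    log2fc: float
    fdr: float
    delta_pid: dict[str, float]  # barrel -> late - mid identity change
    mean_delta_pid: float
    mean_pid: float
    consistent: bool
    passes_identity: bool
    significant: bool

    @property
    def retained(self) -> bool:
        return self.consistent and self.passes_identity and self.significant


def conserved_shift_table(
    pid_summary: PidSummary,
    de_results: pd.DataFrame,
    replicate_pairs: Mapping[str, tuple[str, str]],
    min_identity: float = 60.0,
    alpha: float = 0.05,
    min_reads: int = 10,
) -> list[ShiftRecord]:
    """ORFs whose identity shift replicates across barrels, joined to DE.

    ``replicate_pairs`` maps barrel id to its (mid, late) sample names. An ORF
    is retained iff it has >= ``min_reads`` reads in every involved sample, all
    per-barrel deltas (late - mid) share a strict sign, the overall mean
    identity is >= ``min_identity``, and its DE FDR < ``alpha``. Sorted by
    |mean_delta_pid| descending.
    """
    involved: list[str] = []
    for barrel, (mid, late) in replicate_pairs.items():
        involved.extend([mid, late])
    known = set(pid_summary.per_orf["sample"].unique())
    unknown = [s for s in involved if s not in known]
    if unknown:
        raise PopshiftError(f"replicate_pairs name samples without alignments: {unknown}")

    stats = pid_summary.per_orf.set_index(["orf_id", "sample"])
    de = de_results.drop_duplicates("orf_id").set_index("orf_id")

    records: list[ShiftRecord] = []
    for orf_id in pid_summary.per_orf["orf_id"].unique():
        cells = {}
        ok = True
        for s in involved:
            try:
                row = stats.loc[(orf_id, s)]
            except KeyError:
                ok = False
                break
            if row["n_reads"] < min_reads:
                ok = False
                break
            cells[s] = float(row["mean_pid"])
        if not ok or orf_id not in de.index:
            continue
        deltas = {
            barrel: cells[late] - cells[mid]
            for barrel, (mid, late) in replicate_pairs.items()
        }
        vals = np.array(list(deltas.values()))
        consistent = bool(np.all(vals > 0) or np.all(vals < 0))
        mean_pid = float(np.mean(list(cells.values())))
        fdr = float(de.loc[orf_id, "fdr"])
        records.append(
            ShiftRecord(
                orf_id=orf_id,
                log2fc=float(de.loc[orf_id, "log2fc"]),
                fdr=fdr,
                delta_pid=deltas,
                mean_delta_pid=float(vals.mean()),
                mean_pid=mean_pid,
                consistent=consistent,
                passes_identity=mean_pid >= min_identity,
                significant=fdr < alpha,
            )
        )
    retained = [r for r in records if r.retained]
    retained.sort(key=lambda r: -abs(r.mean_delta_pid))
    return retained


def shift_table_frame(records: list[ShiftRecord], annotation: pd.DataFrame | None = None) -> pd.DataFrame:
    """Flatten shift records for TSV output, attaching functional labels."""
    label_of = {}
    if annotation is not None:
        label_of = annotation.set_index("orf_id")["functional_label"].to_dict()
    rows = [
        {
            "orf_id": r.orf_id,
            "log2fc": r.log2fc,
            "fdr": r.fdr,
            "mean_delta_pid": r.mean_delta_pid,
            "mean_pid": r.mean_pid,
            "functional_label": label_of.get(r.orf_id, ""),
        }
        for r in records
    ]
    return pd.DataFrame(
        rows, columns=["orf_id", "log2fc", "fdr", "mean_delta_pid", "mean_pid", "functional_label"]
    )
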