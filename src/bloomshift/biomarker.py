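"""Nutrient-status biomarker indices from marker-gene expression ratios.

Four indices are computed per sample and scope (taxon group or genus), each a
log2 ratio of summed within-scope normalized expression:

* ``N_index``   = log2((NRT2 + c) / (GSII + c))
* ``Fe_index``  = log2((ISIP1 + ISIP2 + ISIP3 + c) / (thiC + c))
* ``flav_fd``   = log2((flavodoxin + c) / (ferredoxin + c))
* ``isip2_ferritin`` = log2((ISIP2 + c) / (ferritin + c))

Only *relative* calls between samples are supported; no absolute
replete/depleted threshold exists. Note the Fe index assumes the scope
synthesizes thiamine endogenously; taxa scavenging environmental thiamine may
not express thiC, making the index less informative outside diatoms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import CountMatrix, tmm_factors

log = logging.getLogger(__name__)

#: index name -> (numerator labels, denominator labels)
INDEX_DEFINITIONS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "N_index": (("NRT2",), ("GSII",)),
    "Fe_index": (("ISIP1", "ISIP2", "ISIP3"), ("thiC",)),
    "flav_fd": (("flavodoxin",), ("ferredoxin",)),
    "isip2_ferritin": (("ISIP2",), ("ferritin",)),
}

#: alternate numerator accepted for the nitrogen index (NR = nitrate reductase)
N_INDEX_ALT_NUMERATOR = ("NRT2", "NR")


class BiomarkerError(ValueError):
    pass


@dataclass
class BiomarkerIndex:
    sample: str
    scope: str
    index_name: str
    numerator_expr: float
    denominator_expr: float
    log2_ratio: float
    n_orfs_numerator: int
    n_orfs_denominator: int


def _scope_matrix(matrix: CountMatrix, scope: str, scope_type: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    if matrix.annotation is None:
        raise BiomarkerError("count matrix has no annotation")
    ann = matrix.annotation
    if scope_type not in ("taxon_group", "genus"):
        raise BiomarkerError("scope_type must be 'taxon_group' or 'genus'")
    orfs = ann.loc[ann[scope_type] == scope, "orf_id"]
    sub = matrix.counts.loc[matrix.counts.index.intersection(orfs)]
    if sub.empty:
        raise BiomarkerError(f"no ORFs in scope {scope!r}")
    sub_ann = ann[ann["orf_id"].isin(sub.index)]
    return sub, sub_ann


def _scope_cpm(sub_counts: pd.DataFrame) -> pd.DataFrame:
    """Within-scope TMM-adjusted counts-per-million."""
    lib = sub_counts.sum(axis=0).to_numpy(dtype=float)
    if (lib <= 0).any():
        raise BiomarkerError("scope has a zero-count sample")
    factors = (
        tmm_factors(sub_counts.to_numpy(dtype=float), lib)
        if sub_counts.shape[1] >= 2
        else np.ones(1)
    )
    eff = lib * factors
    return sub_counts / eff[None, :] * 1e6


def marker_expression(
    matrix: CountMatrix,
    scope: str,
    labels: Sequence[str],
    scope_type: str = "taxon_group",
) -> tuple[pd.Series, int]:
    """Summed within-scope CPM over ORFs carrying any of ``labels``, per sample.

    Returns (expression series indexed by sample, number of labeled ORFs).
    Missing labels give zero expression with a warning; the downstream index is
    still computable through its pseudocount.
    """
    sub, sub_ann = _scope_matrix(matrix, scope, scope_type)
    cpm = _scope_cpm(sub)
    labeled = sub_ann.loc[sub_ann["functional_label"].isin(set(labels)), "orf_id"]
    labeled = cpm.index.intersection(labeled)
    if len(labeled) == 0:
        log.warning("no ORFs labeled %s in scope %r", list(labels), scope)
        return pd.Series(0.0, index=cpm.columns), 0
    return cpm.loc[labeled].sum(axis=0), len(labeled)


def nutrient_indices(
    matrix: CountMatrix,
    scope: str,
    scope_type: str = "taxon_group",
    pseudocount: float = 1.0,
    use_nr_numerator: bool = False,
    index_names: Sequence[str] | None = None,
) -> list[BiomarkerIndex]:
    """All biomarker indices for one scope, one record per sample per index."""
    out: list[BiomarkerIndex] = []
    names = list(index_names) if index_names is not None else list(INDEX_DEFINITIONS)
    for name in names:
        num_labels, den_labels = INDEX_DEFINITIONS[name]
        if name == "N_index" and use_nr_numerator:
            num_labels = N_INDEX_ALT_NUMERATOR
        num, n_num = marker_expression(matrix, scope, num_labels, scope_type)
        den, n_den = marker_expression(matrix, scope, den_labels, scope_type)
        ratio = np.log2((num + pseudocount) / (den + pseudocount))
        for sample in num.index:
            out.append(
                BiomarkerIndex(
                    sample=sample,
                    scope=scope,
                    index_name=name,
                    numerator_expr=float(num[sample]),
                    denominator_expr=float(den[sample]),
                    log2_ratio=float(ratio[sample]),
                    n_orfs_numerator=n_num,
                    n_orfs_denominator=n_den,
                )
            )
    return out


def relative_status(
    indices_a: Sequence[BiomarkerIndex],
    indices_b: Sequence[BiomarkerIndex],
    margin: float = 0.5,
) -> list[dict]:
    """Qualitative between-sample calls per (scope, index).

    The call compares sample b against sample a: a positive index difference
    beyond ``margin`` log2 units reads ``more_depleted`` (for b), a negative
    one ``more_replete``, otherwise ``indistinguishable``. Scopes or indices
    present on only one side yield no call.
    """
    def _key(ix: BiomarkerIndex) -> tuple[str, str]:
        return (ix.scope, ix.index_name)

    a_map = {_key(ix): ix for ix in indices_a}
    b_map = {_key(ix): ix for ix in indices_b}
    calls = []
    for key in sorted(set(a_map) & set(b_map)):
        ia, ib = a_map[key], b_map[key]
        delta = ib.log2_ratio - ia.log2_ratio
        if delta > margin:
            status = "more_depleted"
        elif delta < -margin:
            status = "more_replete"
        else:
            status = "indistinguishable"
        calls.append(
            {
                "scope": key[0],
                "index_name": key[1],
                "sample_a": ia.sample,
                "sample_b": ib.sample,
                "delta_log2_ratio": delta,
                "status": status,
            }
        )
    return calls


def index_frame(indices: Sequence[BiomarkerIndex]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": ix.sample,
                "scope": ix.scope,
                "index_name": ix.index_name,
                "log2_ratio": ix.log2_ratio,
                "numerator_expr": ix.numerator_expr,
                "denominator_expr": ix.denominator_expr,
                "n_orfs_numerator": ix.n_orfs_numerator,
                "n_orfs_denominator": ix.n_orfs_denominator,
            }
            for ix in indices
        ],
        columns=[
            "sample", "scope", "index_name", "log2_ratio",
            "numerator_expr", "denominator_expr",
            "n_orfs_numerator", "n_orfs_denominator",
        ],
    )


def indices_for_groups(
    matrix: CountMatrix,
    pseudocount: float = 1.0,
    include_dinoflagellates: bool = False,
) -> list[BiomarkerIndex]:
    """Indices for every annotated taxon group.

    Dinoflagellates are excluded from the nitrogen index by default (their
    transcriptional N response is unreliable); pass
    ``include_dinoflagellates=True`` to keep them.
    """
    if matrix.annotation is None:
        raise BiomarkerError("count matrix has no annotation")
    out: list[BiomarkerIndex] = []
    for group in sorted(matrix.annotation["taxon_group"].unique()):
        names = list(INDEX_DEFINITIONS)
        if group == "dinoflagellate" and not include_dinoflagellates:
            names = [n for n in names if n != "N_index"]
        try:
            out.extend(
                nutrient_indices(matrix, group, pseudocount=pseudocount, index_names=names)
            )
        except BiomarkerError as exc:
            log.warning("skipping scope %r: %s", group, exc)
    return out
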