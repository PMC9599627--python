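"""Count matrices and two-group differential expression under the NB model.

The statistical pipeline is: TMM scaling factors, quantile adjustment of
counts to a common effective library size, conditional-likelihood estimation
of the common dispersion, an exact two-sided test on per-group sums, and
Benjamini-Hochberg FDR control. Three modes are supported: ``global`` (full
library sizes), ``groupwise`` (one taxon group at a time with within-group
library sizes, isolating physiology from abundance change), and
``taxon_proportion`` (counts aggregated per taxon group against full library
sizes, testing abundance change itself).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm, rankdata

from .config import ConfigError, SampleSheet
from .formats import AlignmentRecord

log = logging.getLogger(__name__)

_TIE_REL = 1e-7  # relative tolerance when comparing split probabilities


class ExpressionError(ValueError):
    pass


@dataclass
class DispersionEstimate:
    phi_common: float
    phi_tagwise: np.ndarray | None = None
    method: str = "qcml"


class CountMatrix:
    """ORF x sample integer counts with library sizes and sample metadata."""

    def __init__(
        self,
        counts: pd.DataFrame,
        sample_sheet: SampleSheet | None = None,
        annotation: pd.DataFrame | None = None,
        lib_sizes: pd.Series | None = None,
    ):
        if (counts.to_numpy() < 0).any():
            raise ExpressionError("negative counts")
        self.counts = counts
        self.sample_sheet = sample_sheet
        self.annotation = annotation
        if lib_sizes is None:
            lib_sizes = counts.sum(axis=0)
        self.lib_sizes = lib_sizes.astype(float)
        if sample_sheet is not None:
            sheet_samples = set(sample_sheet.samples)
            extra = set(counts.columns) - sheet_samples
            if extra:
                raise ExpressionError(f"samples missing from sample sheet: {sorted(extra)}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def subset_group(self, taxon_group: str) -> "CountMatrix":
        """Restrict to one taxon group, recomputing library sizes within group."""
        if self.annotation is None:
            raise ExpressionError("no annotation attached")
        orfs = self.annotation.loc[
            self.annotation["taxon_group"] == taxon_group, "orf_id"
        ]
        sub = self.counts.loc[self.counts.index.intersection(orfs)]
        return CountMatrix(sub, self.sample_sheet, self.annotation)

    def aggregate_taxon_groups(self) -> "CountMatrix":
        """Sum counts to taxon-group rows, keeping full library sizes."""
        if self.annotation is None:
            raise ExpressionError("no annotation attached")
        groups = self.annotation.set_index("orf_id")["taxon_group"]
        labels = self.counts.index.map(groups).fillna("unannotated")
        agg = self.counts.groupby(labels.to_numpy()).sum()
        return CountMatrix(agg, self.sample_sheet, None, lib_sizes=self.lib_sizes)

    def write_tsv(self, path) -> None:
        out = self.counts.copy()
        out.index.name = "orf_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path, sample_sheet=None, annotation=None) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="orf_id")
        return cls(df, sample_sheet, annotation)


def count_reads(
    alignments_by_sample: dict[str, Iterable[AlignmentRecord]],
    annotation: pd.DataFrame | None = None,
    sample_sheet: SampleSheet | None = None,
) -> CountMatrix:
    """Count primary alignments per ORF per sample.

    A read with multiple primary records is counted once, on the record with
    the smallest NM; ties go to the lexicographically smallest ORF id.
    """
    per_sample: dict[str, dict[str, int]] = {}
    orf_ids: set[str] = set()
    for sample, alns in alignments_by_sample.items():
        best: dict[str, tuple[int, str]] = {}
        for a in alns:
            if not a.is_primary:
                continue
            key = (a.nm, a.orf_id)
            prev = best.get(a.read_id)
            if prev is None or key < prev:
                best[a.read_id] = key
        col: dict[str, int] = {}
        for _nm, orf in best.values():
            col[orf] = col.get(orf, 0) + 1
        per_sample[sample] = col
        orf_ids.update(col)

    if annotation is not None:
        known = set(annotation["orf_id"])
        unannotated = sorted(orf_ids - known)
        if unannotated:
            log.warning("%d ORFs with counts lack annotation", len(unannotated))
        orf_ids.update(known)

    index = sorted(orf_ids)
    data = {
        sample: [per_sample[sample].get(orf, 0) for orf in index]
        for sample in alignments_by_sample
    }
    counts = pd.DataFrame(data, index=index, dtype=int)
    return CountMatrix(counts, sample_sheet, annotation)


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _tmm_pair(obs, ref, n_obs, n_ref, trim_m, trim_a):
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        return 1.0
    p_obs = obs[pos] / n_obs
    p_ref = ref[pos] / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic binomial variance of M
    v = (n_obs - obs[pos]) / (n_obs * obs[pos]) + (n_ref - ref[pos]) / (n_ref * ref[pos])
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = math.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    counts: pd.DataFrame | np.ndarray,
    lib_sizes: Sequence[float] | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors, geometric mean rescaled to 1.

    The reference sample is the column whose 75th count percentile (scaled by
    library size) is closest to the mean across samples. M/A values use ORFs
    with positive counts in both columns; the top and bottom ``trim_m`` of M
    and ``trim_a`` of A are trimmed and the remainder combined with inverse
    asymptotic-variance weights.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ExpressionError("TMM needs a matrix with at least two samples")
    lib = np.asarray(lib_sizes, dtype=float) if lib_sizes is not None else x.sum(axis=0)
    if np.any(lib <= 0):
        raise ExpressionError("zero library size")
    f75 = np.array([np.quantile(x[:, j], 0.75) / lib[j] for j in range(x.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            _tmm_pair(x[:, j], x[:, ref], lib[j], lib[ref], trim_m, trim_a)
            for j in range(x.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


# ---------------------------------------------------------------------------
# Quantile adjustment to a common library size
# ---------------------------------------------------------------------------

def _q2q_nbinom(x, input_mean, output_mean, phi):
    """Quantile-map counts between NB distributions with different means.

    Average of matched normal and gamma approximations on the appropriate tail.
    """
    x = np.asarray(x, dtype=float)
    input_mean = np.asarray(input_mean, dtype=float).copy()
    output_mean = np.asarray(output_mean, dtype=float).copy()
    eps = 1e-14
    zero = (input_mean < eps) | (output_mean < eps)
    input_mean[zero] += 0.25
    output_mean[zero] += 0.25
    ri = 1.0 + phi * input_mean
    vi = input_mean * ri
    ro = 1.0 + phi * output_mean
    vo = output_mean * ro

    q1 = np.empty_like(x)
    q2 = np.empty_like(x)
    upper = x >= input_mean
    lo = ~upper
    tiny = 1e-300

    if upper.any():
        p = norm.sf(x[upper], loc=input_mean[upper], scale=np.sqrt(vi[upper]))
        q1[upper] = norm.isf(np.clip(p, tiny, 1.0), loc=output_mean[upper], scale=np.sqrt(vo[upper]))
        p = gamma_dist.sf(x[upper], input_mean[upper] / ri[upper], scale=ri[upper])
        q2[upper] = gamma_dist.isf(np.clip(p, tiny, 1.0), output_mean[upper] / ro[upper], scale=ro[upper])
    if lo.any():
        p = norm.cdf(x[lo], loc=input_mean[lo], scale=np.sqrt(vi[lo]))
        q1[lo] = norm.ppf(np.clip(p, tiny, 1.0), loc=output_mean[lo], scale=np.sqrt(vo[lo]))
        p = gamma_dist.cdf(x[lo], input_mean[lo] / ri[lo], scale=ri[lo])
        q2[lo] = gamma_dist.ppf(np.clip(p, tiny, 1.0), output_mean[lo] / ro[lo], scale=ro[lo])
    out = (q1 + q2) / 2.0
    return np.maximum(out, 0.0)


def equalize_library_sizes(
    counts: np.ndarray, eff_lib: np.ndarray, phi: float
) -> tuple[np.ndarray, float]:
    """Pseudo-counts quantile-adjusted to the geometric-mean effective library size."""
    common = float(np.exp(np.mean(np.log(eff_lib))))
    rate = counts.sum(axis=1) / eff_lib.sum()
    input_mean = rate[:, None] * eff_lib[None, :]
    output_mean = rate[:, None] * np.full_like(eff_lib, common)[None, :]
    pseudo = _q2q_nbinom(counts, input_mean, output_mean, phi)
    pseudo[rate == 0] = 0.0
    return pseudo, common


# ---------------------------------------------------------------------------
# qCML common (and tagwise) dispersion
# ---------------------------------------------------------------------------

def _cond_loglik_per_tag(pseudo: np.ndarray, group_cols: list[np.ndarray], phi: float) -> np.ndarray:
    """Per-tag NB conditional log-likelihood (conditioned on group totals)."""
    r = 1.0 / max(phi, 1e-10)
    ll = np.zeros(pseudo.shape[0])
    for cols in group_cols:
        n = cols.size
        if n < 2:
            continue  # single-replicate groups carry no conditional information
        y = pseudo[:, cols]
        z = y.sum(axis=1)
        ll += (
            gammaln(y + r).sum(axis=1)
            + gammaln(n * r)
            - gammaln(z + n * r)
            - n * gammaln(r)
        )
    return ll


def _maximize_phi(objective, lo=1e-6, hi=10.0, grid=25, tol=1e-4) -> float:
    """Maximize over a log-spaced grid, refined by golden-section search."""
    grid_phi = np.geomspace(lo, hi, grid)
    vals = [objective(p) for p in grid_phi]
    i = int(np.argmax(vals))
    a = grid_phi[max(i - 1, 0)]
    b = grid_phi[min(i + 1, grid - 1)]
    # golden-section on log scale
    la, lb = math.log(a), math.log(b)
    gr = (math.sqrt(5) - 1) / 2
    c = lb - gr * (lb - la)
    d = la + gr * (lb - la)
    fc = objective(math.exp(c))
    fd = objective(math.exp(d))
    while lb - la > tol:
        if fc > fd:
            lb, d, fd = d, c, fc
            c = lb - gr * (lb - la)
            fc = objective(math.exp(c))
        else:
            la, c, fc = c, d, fd
            d = la + gr * (lb - la)
            fd = objective(math.exp(d))
    return math.exp((la + lb) / 2)


def estimate_common_dispersion(
    matrix: CountMatrix,
    groups: dict[str, str] | pd.Series,
    phi: float | None = None,
    tagwise: bool = False,
    prior_n: float = 10.0,
    tmm: np.ndarray | None = None,
) -> DispersionEstimate:
    """Estimate the NB dispersion by quantile-adjusted conditional likelihood.

    ``groups`` maps sample name to group label. A supplied ``phi`` bypasses
    estimation. Requires at least one group with two or more replicates.
    """
    if phi is not None:
        if phi < 0:
            raise ExpressionError("phi must be >= 0")
        return DispersionEstimate(phi_common=float(phi), method="supplied")

    samples = matrix.samples
    groups = pd.Series(groups)
    labels = [groups.get(s) for s in samples]
    group_cols = [
        np.array([j for j, g in enumerate(labels) if g == lab])
        for lab in pd.unique(np.array([g for g in labels if g is not None], dtype=object))
    ]
    if not any(cols.size >= 2 for cols in group_cols):
        raise ExpressionError(
            "no group has >= 2 replicates; supply an explicit dispersion (phi=...)"
        )

    x = matrix.counts.to_numpy(dtype=float)
    lib = matrix.lib_sizes.to_numpy(dtype=float)
    if tmm is None:
        tmm = tmm_factors(x, lib) if x.shape[1] >= 2 else np.ones(x.shape[1])
    eff_lib = lib * tmm

    phi_hat = 0.01
    for _ in range(2):
        pseudo, _common = equalize_library_sizes(x, eff_lib, phi_hat)
        phi_hat = _maximize_phi(
            lambda p: _cond_loglik_per_tag(pseudo, group_cols, p).sum()
        )

    est = DispersionEstimate(phi_common=phi_hat)
    if tagwise:
        pseudo, _common = equalize_library_sizes(x, eff_lib, phi_hat)
        n_tags = pseudo.shape[0]
        phi_tag = np.empty(n_tags)
        # weighted likelihood shrinkage toward the common value
        for i in range(n_tags):
            row = pseudo[i : i + 1]

            def obj(p, row=row):
                own = _cond_loglik_per_tag(row, group_cols, p)[0]
                common_part = _cond_loglik_per_tag(pseudo, group_cols, p).mean()
                return own + prior_n * common_part

            phi_tag[i] = _maximize_phi(obj)
        est.phi_tagwise = phi_tag
    return est


# ---------------------------------------------------------------------------
# Exact NB test
# ---------------------------------------------------------------------------

def _nb_logpmf(k, r, mu):
    """log NB pmf with size r and mean mu (k may be an array)."""
    k = np.asarray(k, dtype=float)
    return (
        gammaln(k + r)
        - gammaln(r)
        - gammaln(k + 1)
        + r * (np.log(r) - np.log(r + mu))
        + k * (np.log(mu) - np.log(r + mu))
    )


def exact_test_nb(
    counts_a: Sequence[float] | float,
    counts_b: Sequence[float] | float,
    phi: float,
    eff_lib_a: float | None = None,
    eff_lib_b: float | None = None,
) -> float:
    """Two-sided exact test of equal expression between two NB groups.

    Conditions on the total ``t = a + b`` of the (quantile-adjusted) group
    sums; the p-value is the total conditional probability of all splits of
    ``t`` no more probable than the observed one. ``phi = 0`` degenerates to
    the conditional binomial (Poisson exact) test.
    """
    a_vec = np.atleast_1d(np.asarray(counts_a, dtype=float))
    b_vec = np.atleast_1d(np.asarray(counts_b, dtype=float))
    if (a_vec < 0).any() or (b_vec < 0).any():
        raise ExpressionError("negative counts")
    if phi < 0:
        raise ExpressionError("phi must be >= 0")
    n_a, n_b = a_vec.size, b_vec.size
    if eff_lib_a is None:
        eff_lib_a = float(n_a)
    if eff_lib_b is None:
        eff_lib_b = float(n_b)
    a = int(round(a_vec.sum()))
    b = int(round(b_vec.sum()))
    t = a + b
    if t == 0:
        return 1.0
    pa = eff_lib_a / (eff_lib_a + eff_lib_b)
    pb = 1.0 - pa
    k = np.arange(t + 1)
    if phi < 1e-12:
        # Poisson sums -> binomial split
        logp = (
            gammaln(t + 1)
            - gammaln(k + 1)
            - gammaln(t - k + 1)
            + k * math.log(pa)
            + (t - k) * math.log(pb)
        )
    else:
        n_total = n_a + n_b
        r_a = n_total * pa / phi
        r_b = n_total * pb / phi
        mu_a = t * pa
        mu_b = t * pb
        logp = _nb_logpmf(k, r_a, mu_a) + _nb_logpmf(t - k, r_b, mu_b)
    norm_const = logsumexp(logp)
    keep = logp <= logp[a] + math.log1p(_TIE_REL)
    p = float(np.exp(logsumexp(logp[keep]) - norm_const))
    return min(max(p, np.nextafter(0, 1)), 1.0)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ExpressionError("p-values must lie in [0,1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# Differential expression driver
# ---------------------------------------------------------------------------

VALID_MODES = ("global", "groupwise", "taxon_proportion")


def _de_single(
    matrix: CountMatrix,
    depleted: list[str],
    replete: list[str],
    phi: float | None,
    min_total: int,
    mode: str,
    contrast: str,
) -> pd.DataFrame:
    cols = depleted + replete
    counts = matrix.counts[cols]
    x = counts.to_numpy(dtype=float)
    lib = matrix.lib_sizes[cols].to_numpy(dtype=float)
    if np.any(lib <= 0):
        raise ExpressionError("zero library size in contrast")

    keep = x.sum(axis=1) >= min_total
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info(
            "%s/%s DE: dropped %d ORFs with total count < %d (%d tested)",
            contrast, mode, n_dropped, min_total, int(keep.sum()),
        )
    xk = x[keep]
    ids = counts.index[keep]
    if xk.shape[0] == 0:
        return pd.DataFrame(
            columns=["orf_id", "log2fc", "mean_expr", "p_value", "fdr", "contrast", "mode"]
        )

    tmm = tmm_factors(xk, lib) if len(cols) >= 2 else np.ones(len(cols))
    eff_lib = lib * tmm

    groups = {s: "depleted" for s in depleted}
    groups.update({s: "replete" for s in replete})
    sub = CountMatrix(pd.DataFrame(xk, index=ids, columns=cols), lib_sizes=pd.Series(lib, index=cols))
    disp = estimate_common_dispersion(sub, groups, phi=phi, tmm=tmm)
    phi_used = disp.phi_common

    pseudo, common = equalize_library_sizes(xk, eff_lib, phi_used)
    dep_idx = np.array([cols.index(s) for s in depleted])
    rep_idx = np.array([cols.index(s) for s in replete])
    sum_dep = pseudo[:, dep_idx].sum(axis=1)
    sum_rep = pseudo[:, rep_idx].sum(axis=1)

    eff_a = len(depleted) * common
    eff_b = len(replete) * common
    pvals = np.array(
        [
            exact_test_nb(
                pseudo[i, dep_idx], pseudo[i, rep_idx], phi_used, eff_a, eff_b
            )
            for i in range(pseudo.shape[0])
        ]
    )

    # fold change from TMM-normalized group fractions with a 0.5 pseudocount
    frac_dep = (sum_dep + 0.5) / eff_a
    frac_rep = (sum_rep + 0.5) / eff_b
    log2fc = np.log2(frac_dep / frac_rep)
    cpm = (xk + 0.5) / eff_lib[None, :] * 1e6
    mean_expr = np.log2(cpm).mean(axis=1)

    out = pd.DataFrame(
        {
            "orf_id": ids,
            "log2fc": log2fc,
            "mean_expr": mean_expr,
            "p_value": pvals,
            "fdr": bh_adjust(pvals),
            "contrast": contrast,
            "mode": mode,
        }
    ).reset_index(drop=True)
    out.attrs["phi"] = phi_used
    return out


def differential_expression(
    matrix: CountMatrix,
    contrast: str,
    mode: str = "global",
    phi: float | None = None,
    min_total: int = 5,
) -> pd.DataFrame:
    """Depleted-vs-replete DE table for one contrast (``N`` or ``Fe``).

    log2fc is log2(depleted/replete): positive means up under nutrient
    limitation. FDR is computed within the tested set. In groupwise mode one
    table is returned with ORFs from all annotated taxon groups, each group
    tested against its own within-group library sizes.
    """
    if mode not in VALID_MODES:
        raise ExpressionError(f"mode must be one of {VALID_MODES}")
    if matrix.sample_sheet is None:
        raise ExpressionError("count matrix has no sample sheet")
    depleted, replete = matrix.sample_sheet.contrast_samples(contrast)
    if not depleted or not replete:
        raise ExpressionError(
            f"contrast {contrast!r}: empty depleted ({depleted}) or replete ({replete}) set"
        )

    if mode == "global":
        return _de_single(matrix, depleted, replete, phi, min_total, mode, contrast)
    if mode == "taxon_proportion":
        agg = matrix.aggregate_taxon_groups()
        return _de_single(agg, depleted, replete, phi, min_total, mode, contrast)
    # groupwise
    if matrix.annotation is None:
        raise ExpressionError("groupwise mode requires annotation")
    tables = []
    for group in sorted(matrix.annotation["taxon_group"].unique()):
        sub = matrix.subset_group(group)
        if sub.counts.empty or (sub.lib_sizes[depleted + replete] <= 0).any():
            continue
        tab = _de_single(sub, depleted, replete, phi, min_total, mode, contrast)
        tab["taxon_group"] = group
        tables.append(tab)
    if not tables:
        return pd.DataFrame(
            columns=["orf_id", "log2fc", "mean_expr", "p_value", "fdr", "contrast", "mode", "taxon_group"]
        )
    return pd.concat(tables, ignore_index=True)
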