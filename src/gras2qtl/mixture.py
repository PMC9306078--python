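"""Co-dominant genotype calling from amplicon read depths (the CDG core).

In an F2 population an amplicon tracking one parent's allele yields read
depths whose distribution over individuals is trimodal: near-zero for
individuals lacking the allele, intermediate for heterozygotes, and high for
homozygous carriers.  This module fits a three-component mixture of gamma or
normal distributions to each locus's counts by EM and assigns each
individual the genotype of its maximum-posterior component.

Initialization follows a fixed recipe:

* mixing proportions start at (0.25, 0.50, 0.25), the expected F2 ratio;
* normal family: component means start at 0, the 50% quantile, and the 75%
  quantile of the counts;
* gamma family: pre-initial shape/scale are moment-matched so component
  means are (0, q50, q75) and standard deviations are (sd/3, sd/2, sd/2) of
  the counts, then 1.0 is added to every pre-initial shape and 0.5 to every
  pre-initial scale to give the EM starting values.  The zero-mean
  component's pre-initials are taken as 0, so it starts at shape 1.0,
  scale 0.5.

EM runs to a relative log-likelihood tolerance (default 1e-8) with at most
5000 iterations; non-converged loci carry no calls.  Counts are shifted by
+0.5 before gamma fitting (the gamma density is degenerate at zero); calls
depend only on posteriors, so the shift is never undone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp, polygamma, psi

from .errors import DataFormatError, NonEstimableError

MAX_ITER = 5000
LL_TOL = 1e-8
GAMMA_SHIFT = 0.5
MIN_COUNTS = 20
TIE_TOL = 1e-9

_CODE = np.array(["B", "H", "A"])  # index = seed-parent allele dosage


@dataclass
class DepthMatrix:
    """Per-marker read counts across F2 individuals and both parents."""

    counts: pd.DataFrame  # markers x individuals, non-negative
    parent1_counts: pd.Series  # seed parent (AA side)
    parent2_counts: pd.Series  # pollen parent (BB side)
    source_parent: pd.Series  # 1 or 2: which parent's allele the amplicon tracks

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise DataFormatError("duplicate marker ids in depth matrix")
        if self.counts.columns.has_duplicates:
            raise DataFormatError("duplicate individual ids in depth matrix")
        arr = self.counts.to_numpy()
        if np.any(arr < 0) or np.any(~np.isfinite(arr.astype(float))):
            bad = self.counts.index[np.where((arr < 0).any(axis=1))[0][:1]]
            raise DataFormatError(f"negative or non-finite counts at marker {list(bad)}")
        for s in (self.parent1_counts, self.parent2_counts, self.source_parent):
            if not s.index.equals(self.counts.index):
                raise DataFormatError("parent/source series must share the marker index")
        if not self.source_parent.isin([1, 2]).all():
            raise DataFormatError("source_parent entries must be 1 or 2")

    @property
    def marker_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def individual_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class MixtureInit:
    """EM starting values for one locus."""

    family: str  # 'gamma' or 'normal'
    weights: np.ndarray  # (3,)
    q50: float
    q75: float
    sd_total: float
    # normal family
    means: np.ndarray | None = None
    sds: np.ndarray | None = None
    # gamma family
    pre_shape: np.ndarray | None = None
    pre_scale: np.ndarray | None = None
    shape: np.ndarray | None = None
    scale: np.ndarray | None = None


@dataclass
class MixtureFit:
    """A fitted three-component mixture for one locus."""

    family: str
    weights: np.ndarray
    params: dict[str, np.ndarray]  # shape/scale or mean/sd
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    posteriors: np.ndarray | None  # (n, 3), None if not converged
    shift: float = 0.0

    @property
    def component_means(self) -> np.ndarray:
        """Component means on the raw count scale."""
        if self.family == "gamma":
            return self.params["shape"] * self.params["scale"] - self.shift
        return self.params["mean"].copy()

    @property
    def component_order(self) -> np.ndarray:
        """Component indices sorted by fitted mean (low, mid, high)."""
        return np.argsort(self.component_means, kind="stable")


def initialize_mixture(counts: np.ndarray, family: str) -> MixtureInit:
    """Starting values for the per-locus EM (see module docstring).

    Raises ``NonEstimableError`` for degenerate loci (fewer than 20
    non-missing counts, or zero variance).
    """
    x = np.asarray(counts, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < MIN_COUNTS:
        raise NonEstimableError(f"only {len(x)} non-missing counts (< {MIN_COUNTS})")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise NonEstimableError("all counts equal; mixture not estimable")
    q50, q75 = (float(np.quantile(x, q)) for q in (0.5, 0.75))
    weights = np.array([0.25, 0.50, 0.25])
    if family == "normal":
        return MixtureInit(
            family,
            weights,
            q50,
            q75,
            sd,
            means=np.array([0.0, q50, q75]),
            sds=np.full(3, sd),
        )
    if family != "gamma":
        raise ValueError(f"unknown mixture family {family!r}")
    m = np.array([0.0, q50, q75])
    s = np.array([sd / 3.0, sd / 2.0, sd / 2.0])
    pre_shape = np.zeros(3)
    pre_scale = np.zeros(3)
    nonzero = m > 0
    pre_shape[nonzero] = m[nonzero] ** 2 / s[nonzero] ** 2
    pre_scale[nonzero] = s[nonzero] ** 2 / m[nonzero]
    return MixtureInit(
        family,
        weights,
        q50,
        q75,
        sd,
        pre_shape=pre_shape,
        pre_scale=pre_scale,
        shape=pre_shape + 1.0,
        scale=pre_scale + 0.5,
    )


# ---------------------------------------------------------------------------
# Vectorized EM over a batch of loci
# ---------------------------------------------------------------------------


def _gamma_logpdf(x: np.ndarray, shape: np.ndarray, scale: np.ndarray) -> np.ndarray:
    return (
        (shape - 1.0) * np.log(x)
        - x / scale
        - shape * np.log(scale)
        - gammaln(shape)
    )


def _normal_logpdf(x: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return -0.5 * ((x - mean) / sd) ** 2 - np.log(sd) - 0.5 * np.log(2 * np.pi)


def _solve_gamma_shape(c: np.ndarray, iters: int = 40) -> np.ndarray:
    """Solve ln(a) - digamma(a) = c for a > 0, vectorized (Newton in log a)."""
    c = np.maximum(c, 1e-12)
    a = (3.0 - c + np.sqrt((c - 3.0) ** 2 + 24.0 * c)) / (12.0 * c)
    t = np.log(np.maximum(a, 1e-12))
    for _ in range(iters):
        a = np.exp(t)
        g = t - psi(a) - c
        gp = 1.0 - a * polygamma(1, a)
        step = g / gp
        t = np.clip(t - step, -30.0, 30.0)
    return np.exp(t)


class _BatchState:
    """Mutable per-locus EM bookkeeping shared by both families."""

    def __init__(self, M: int, n: int):
        self.active = np.ones(M, dtype=bool)
        self.converged = np.zeros(M, dtype=bool)
        self.failed = np.zeros(M, dtype=bool)
        self.n_iter = np.zeros(M, dtype=int)
        self.ll_prev = np.full(M, -np.inf)
        self.traces: list[list[float]] = [[] for _ in range(M)]
        self.resp = np.zeros((M, n, 3))


def _em_batch(
    X: np.ndarray,
    family: str,
    pi: np.ndarray,
    par1: np.ndarray,
    par2: np.ndarray,
    max_iter: int = MAX_ITER,
    tol: float = LL_TOL,
) -> tuple[_BatchState, np.ndarray, np.ndarray, np.ndarray]:
    """EM over a (M, n) batch of loci with per-locus convergence tracking.

    ``par1``/``par2`` are (shape, scale) for gamma or (mean, sd) for normal,
    each (M, 3).  Component collapse (weight below 1/(10n) or vanishing
    variance) marks a locus failed rather than raising.
    """
    M, n = X.shape
    st = _BatchState(M, n)
    pi, par1, par2 = pi.copy(), par1.copy(), par2.copy()
    var_floor = 1e-10 * np.maximum(np.var(X, axis=1), 1e-12)
    for _ in range(max_iter):
        idx = np.where(st.active)[0]
        if len(idx) == 0:
            break
        x = X[idx][:, :, None]
        if family == "gamma":
            logpdf = _gamma_logpdf(x, par1[idx][:, None, :], par2[idx][:, None, :])
        else:
            logpdf = _normal_logpdf(x, par1[idx][:, None, :], par2[idx][:, None, :])
        with np.errstate(divide="ignore"):
            logw = np.log(np.maximum(pi[idx][:, None, :], 1e-300)) + logpdf
        norm = logsumexp(logw, axis=2)
        ll = norm.sum(axis=1)
        resp = np.exp(logw - norm[:, :, None])
        st.resp[idx] = resp
        bad = ~np.isfinite(ll)
        for k, i in enumerate(idx):
            st.traces[i].append(float(ll[k]))
        with np.errstate(invalid="ignore"):
            rel = np.abs(ll - st.ll_prev[idx]) / (np.abs(st.ll_prev[idx]) + 1e-300)
        done = np.isfinite(st.ll_prev[idx]) & (rel < tol)
        st.ll_prev[idx] = ll
        st.n_iter[idx] += 1
        st.failed[idx[bad]] = True
        st.converged[idx[done & ~bad]] = True
        st.active[idx[done | bad]] = False
        # M-step for the still-active subset
        idx = np.where(st.active)[0]
        if len(idx) == 0:
            break
        resp_a = st.resp[idx]
        W = resp_a.sum(axis=1)  # (m, 3)
        collapse = (W / n < 1.0 / (10.0 * n)).any(axis=1)
        pi[idx] = W / n
        xa = X[idx]
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_k = (resp_a * xa[:, :, None]).sum(axis=1) / W
            if family == "gamma":
                lbar = (resp_a * np.log(xa)[:, :, None]).sum(axis=1) / W
                c = np.log(mean_k) - lbar
                shape = _solve_gamma_shape(c)
                collapse |= (shape > 1e7).any(axis=1) | ~np.isfinite(shape).all(axis=1)
                par1[idx] = shape
                par2[idx] = mean_k / shape
            else:
                var_k = (resp_a * (xa[:, :, None] - mean_k[:, None, :]) ** 2).sum(
                    axis=1
                ) / W
                collapse |= (var_k < var_floor[idx][:, None]).any(axis=1)
                par1[idx] = mean_k
                par2[idx] = np.sqrt(np.maximum(var_k, 1e-300))
        collapse |= ~np.isfinite(pi[idx]).all(axis=1)
        st.failed[idx[collapse]] = True
        st.active[idx[collapse]] = False
    st.converged[st.failed] = False
    return st, pi, par1, par2


def fit_mixture_em(
    counts: np.ndarray,
    init: MixtureInit,
    max_iter: int = MAX_ITER,
    tol: float = LL_TOL,
) -> MixtureFit:
    """Fit one locus's three-component mixture by EM.

    Numerical failures (NaN likelihood, component collapse) yield a fit with
    ``converged=False`` and no posteriors, never an exception.
    """
    x = np.asarray(counts, dtype=float)
    x = x[np.isfinite(x)]
    shift = GAMMA_SHIFT if init.family == "gamma" else 0.0
    X = (x + shift)[None, :]
    if init.family == "gamma":
        par1, par2 = init.shape[None, :], init.scale[None, :]
    else:
        par1, par2 = init.means[None, :], init.sds[None, :]
    st, pi, par1, par2 = _em_batch(
        X, init.family, init.weights[None, :], par1.copy(), par2.copy(), max_iter, tol
    )
    params = (
        {"shape": par1[0], "scale": par2[0]}
        if init.family == "gamma"
        else {"mean": par1[0], "sd": par2[0]}
    )
    conv = bool(st.converged[0])
    return MixtureFit(
        family=init.family,
        weights=pi[0],
        params=params,
        loglik_trace=np.asarray(st.traces[0]),
        n_iter=int(st.n_iter[0]),
        converged=conv,
        posteriors=st.resp[0] if conv else None,
        shift=shift,
    )


# ---------------------------------------------------------------------------
# Genotype assignment
# ---------------------------------------------------------------------------


def assign_genotypes(fit: MixtureFit, source_parent: int) -> np.ndarray:
    """Maximum-posterior genotype codes for a converged fit.

    Components are sorted by fitted mean; the lowest-mean component is the
    homozygote lacking the source parent's amplicon allele, the middle is
    the heterozygote, the highest the homozygous carrier.  Returned values
    count seed-parent alleles (0/1/2); posterior ties give -1 (missing).
    """
    if not fit.converged or fit.posteriors is None:
        raise NonEstimableError("cannot assign genotypes from a non-converged fit")
    order = fit.component_order
    # dosage of the source-parent allele per sorted component: 0, 1, 2
    dosage_by_component = np.empty(3, dtype=int)
    dosage_by_component[order] = [0, 1, 2]
    post = fit.posteriors
    top = np.argmax(post, axis=1)
    sorted_post = np.sort(post, axis=1)
    tie = sorted_post[:, -1] - sorted_post[:, -2] <= TIE_TOL
    dosage = dosage_by_component[top]
    geno = dosage if source_parent == 1 else 2 - dosage
    geno = geno.astype(np.int8)
    geno[tie] = -1
    return geno


def _posterior_call(
    fit: MixtureFit, count: float, source_parent: int
) -> int:
    """Genotype code for a single extra observation (a parent column)."""
    x = count + fit.shift
    if fit.family == "gamma":
        logpdf = _gamma_logpdf(x, fit.params["shape"], fit.params["scale"])
    else:
        logpdf = _normal_logpdf(x, fit.params["mean"], fit.params["sd"])
    with np.errstate(divide="ignore"):
        logw = np.log(np.maximum(fit.weights, 1e-300)) + logpdf
    post = np.exp(logw - logsumexp(logw))
    order = fit.component_order
    dosage_by_component = np.empty(3, dtype=int)
    dosage_by_component[order] = [0, 1, 2]
    srt = np.sort(post)
    if srt[-1] - srt[-2] <= TIE_TOL or not np.isfinite(post).all():
        return -1
    dosage = int(dosage_by_component[int(np.argmax(post))])
    return dosage if source_parent == 1 else 2 - dosage


# ---------------------------------------------------------------------------
# Marker sets and whole-matrix calling
# ---------------------------------------------------------------------------


@dataclass
class MarkerSet:
    """Co-dominant calls with provenance, QC columns, and filter history."""

    calls: pd.DataFrame  # markers x individuals, codes A/H/B/-
    info: pd.DataFrame  # index markers; columns incl. source, converged, ...
    filter_history: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.calls.index.equals(self.info.index):
            raise DataFormatError("calls and info must share the marker index")

    @property
    def n_markers(self) -> int:
        return len(self.calls)

    def subset(self, marker_ids: Iterable[str], step: str, **details) -> "MarkerSet":
        """A reduced copy with a filter-history entry appended."""
        ids = [m for m in self.calls.index if m in set(marker_ids)]
        history = list(self.filter_history) + [
            {"step": step, "n_before": self.n_markers, "n_after": len(ids), **details}
        ]
        return MarkerSet(self.calls.loc[ids], self.info.loc[ids], history)


def marker_set_from_calls(
    calls: pd.DataFrame, source: str, source_parent: pd.Series | None = None
) -> MarkerSet:
    """Wrap a plain call matrix (e.g. the default caller's output) as a MarkerSet."""
    info = pd.DataFrame(index=calls.index)
    info["source"] = source
    info["converged"] = True
    if source_parent is not None:
        info["source_parent"] = source_parent.reindex(calls.index)
    return MarkerSet(calls.copy(), info)


def call_markers(
    depths: DepthMatrix,
    family: str,
    max_iter: int = MAX_ITER,
    tol: float = LL_TOL,
) -> tuple[MarkerSet, dict[str, MixtureFit]]:
    """Fit every marker's mixture and call genotypes; parents are called too.

    Loci that are non-estimable or whose EM does not converge are retained in
    the output with all-missing calls and ``converged=False`` so the caller
    can drop them explicitly.  All loci are fitted independently.
    """
    X_raw = depths.counts.to_numpy(dtype=float)
    M, n = X_raw.shape
    shift = GAMMA_SHIFT if family == "gamma" else 0.0
    inits: list[MixtureInit | None] = []
    for i in range(M):
        try:
            inits.append(initialize_mixture(X_raw[i], family))
        except NonEstimableError:
            inits.append(None)
    fit_idx = [i for i, ini in enumerate(inits) if ini is not None]
    fits: dict[str, MixtureFit] = {}
    geno = np.full((M, n), -1, dtype=np.int8)
    conv = np.zeros(M, dtype=bool)
    n_iter = np.zeros(M, dtype=int)
    if fit_idx:
        Xb = X_raw[fit_idx] + shift
        pi0 = np.vstack([inits[i].weights for i in fit_idx])
        if family == "gamma":
            p1 = np.vstack([inits[i].shape for i in fit_idx])
            p2 = np.vstack([inits[i].scale for i in fit_idx])
        else:
            p1 = np.vstack([inits[i].means for i in fit_idx])
            p2 = np.vstack([inits[i].sds for i in fit_idx])
        st, pi, p1, p2 = _em_batch(Xb, family, pi0, p1, p2, max_iter, tol)
        for k, i in enumerate(fit_idx):
            params = (
                {"shape": p1[k], "scale": p2[k]}
                if family == "gamma"
                else {"mean": p1[k], "sd": p2[k]}
            )
            fit = MixtureFit(
                family=family,
                weights=pi[k],
                params=params,
                loglik_trace=np.asarray(st.traces[k]),
                n_iter=int(st.n_iter[k]),
                converged=bool(st.converged[k]),
                posteriors=st.resp[k] if st.converged[k] else None,
                shift=shift,
            )
            mid = depths.counts.index[i]
            fits[mid] = fit
            conv[i] = fit.converged
            n_iter[i] = fit.n_iter
            if fit.converged:
                geno[i] = assign_genotypes(fit, int(depths.source_parent.iloc[i]))
    codes = np.where(geno == -1, "-", _CODE[np.maximum(geno, 0)])
    calls = pd.DataFrame(codes, index=depths.counts.index, columns=depths.counts.columns)
    p1_call = np.full(M, -1, dtype=int)
    p2_call = np.full(M, -1, dtype=int)
    for i in range(M):
        mid = depths.counts.index[i]
        if conv[i]:
            sp = int(depths.source_parent.iloc[i])
            p1_call[i] = _posterior_call(fits[mid], float(depths.parent1_counts.iloc[i]), sp)
            p2_call[i] = _posterior_call(fits[mid], float(depths.parent2_counts.iloc[i]), sp)
    info = pd.DataFrame(index=depths.counts.index)
    info["source"] = family
    info["converged"] = conv
    info["n_iter"] = n_iter
    info["source_parent"] = depths.source_parent.to_numpy()
    info["parent1_call"] = p1_call
    info["parent2_call"] = p2_call
    info["parental_ok"] = (p1_call == 2) & (p2_call == 0)
    marker_set = MarkerSet(calls, info)
    marker_set = marker_set.subset(
        marker_set.calls.index[conv], "em_convergence", family=family
    )
    return marker_set, fits


# ---------------------------------------------------------------------------
# Accuracy metrics and filters
# ---------------------------------------------------------------------------


def codominant_accuracy(
    calls: pd.DataFrame, default_codominant: pd.DataFrame
) -> tuple[pd.Series, float]:
    """Percent agreement of three-state calls with the default caller.

    Computed per marker over individuals non-missing in both matrices, on
    the markers both matrices cover; the summary is the unweighted mean over
    markers.  Raises if no markers overlap.
    """
    shared = calls.index.intersection(default_codominant.index)
    if len(shared) == 0:
        raise DataFormatError("no overlapping markers between call sets")
    cols = calls.columns.intersection(default_codominant.columns)
    a = calls.loc[shared, cols].to_numpy()
    b = default_codominant.loc[shared, cols].to_numpy()
    both = (a != "-") & (b != "-")
    agree = (a == b) & both
    with np.errstate(invalid="ignore"):
        pct = 100.0 * agree.sum(axis=1) / both.sum(axis=1)
    per_marker = pd.Series(pct, index=shared, name="codominant_accuracy_pct")
    return per_marker, float(np.nanmean(pct))


def collapse_to_dominant(
    calls: pd.DataFrame, source_parent: pd.Series
) -> pd.DataFrame:
    """Collapse three-state calls to presence/absence of the source allele.

    Heterozygotes merge into the presence class of the marker's source
    parent; codes become 'P'/'A' ('-' stays missing).
    """
    sp = source_parent.reindex(calls.index)
    if sp.isna().any():
        raise DataFormatError("unknown source parent for some markers")
    arr = calls.to_numpy()
    src1 = (sp.to_numpy() == 1)[:, None]
    present = np.where(src1, (arr == "A") | (arr == "H"), (arr == "B") | (arr == "H"))
    out = np.where(arr == "-", "-", np.where(present, "P", "A"))
    return pd.DataFrame(out, index=calls.index, columns=calls.columns)


def dominant_accuracy(
    calls: pd.DataFrame,
    default_dominant: pd.DataFrame,
    source_parent: pd.Series,
) -> tuple[pd.Series, float]:
    """Percent agreement with the default dominant calls after collapsing."""
    collapsed = collapse_to_dominant(calls, source_parent)
    shared = collapsed.index.intersection(default_dominant.index)
    if len(shared) == 0:
        raise DataFormatError("no overlapping markers between call sets")
    cols = collapsed.columns.intersection(default_dominant.columns)
    a = collapsed.loc[shared, cols].to_numpy()
    b = default_dominant.loc[shared, cols].to_numpy()
    both = (a != "-") & (b != "-")
    agree = (a == b) & both
    with np.errstate(invalid="ignore"):
        pct = 100.0 * agree.sum(axis=1) / both.sum(axis=1)
    per_marker = pd.Series(pct, index=shared, name="dominant_consensus_pct")
    return per_marker, float(np.nanmean(pct))


def consensus_filter(
    marker_set: MarkerSet,
    default_dominant: pd.DataFrame | None = None,
    threshold: float = 95.0,
) -> MarkerSet:
    """Retain markers whose dominant consensus strictly exceeds ``threshold``.

    If ``default_dominant`` is given the consensus is (re)computed and stored
    in ``info['consensus_pct']``; otherwise that column must already exist.
    """
    ms = marker_set
    if default_dominant is not None:
        per_marker, _ = dominant_accuracy(
            ms.calls, default_dominant, ms.info["source_parent"]
        )
        ms = MarkerSet(ms.calls.copy(), ms.info.copy(), list(ms.filter_history))
        ms.info["consensus_pct"] = per_marker.reindex(ms.info.index)
    if "consensus_pct" not in ms.info.columns:
        raise DataFormatError("consensus_pct not computed; pass default_dominant")
    keep = ms.info.index[ms.info["consensus_pct"] > threshold]
    return ms.subset(keep, "consensus_filter", threshold=threshold)


def parental_consistency_filter(marker_set: MarkerSet) -> MarkerSet:
    """Retain markers whose parents call as the correct opposite homozygotes.

    Parent 1 must call as the seed-parent homozygote and parent 2 as the
    pollen-parent homozygote; a missing parent call removes the marker.
    """
    info = marker_set.info
    if "parent1_call" not in info.columns:
        raise DataFormatError("parent calls not available for this marker set")
    keep = info.index[(info["parent1_call"] == 2) & (info["parent2_call"] == 0)]
    return marker_set.subset(keep, "parental_consistency")


def priority_merge(*marker_sets: MarkerSet) -> MarkerSet:
    """Merge marker sets, earlier arguments taking priority on shared ids.

    For the three-way caller output the order is (default, gamma, normal).
    The merged size is the size of the union; provenance follows the
    surviving set's ``source`` column.  Associative and idempotent.
    """
    if not marker_sets:
        raise DataFormatError("priority_merge needs at least one marker set")
    seen: dict[str, tuple[int, str]] = {}
    for si, ms in enumerate(marker_sets):
        for m in ms.calls.index:
            if m not in seen:
                seen[m] = (si, m)
    calls_rows = []
    info_rows = []
    order = sorted(seen.values())
    all_cols = marker_sets[0].calls.columns
    for si, m in order:
        calls_rows.append(marker_sets[si].calls.loc[m].reindex(all_cols, fill_value="-"))
        info_rows.append(marker_sets[si].info.loc[m])
    calls = pd.DataFrame(calls_rows, index=[m for _, m in order])
    info = pd.DataFrame(info_rows, index=[m for _, m in order])
    history = [
        {
            "step": "priority_merge",
            "n_before": sum(ms.n_markers for ms in marker_sets),
            "n_after": len(calls),
            "sizes": [ms.n_markers for ms in marker_sets],
        }
    ]
    return MarkerSet(calls, info, history)
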