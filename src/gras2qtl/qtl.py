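"""Interval mapping and composite interval mapping for F2 phenotypes.

Genotype probabilities along each linkage group come from a three-state
Markov chain (genotype classes BB/AB/AA, transition probabilities from the
Kosambi inverse of adjacent distances, no interference between intervals),
conditioned on the observed marker calls by forward-backward; missing calls
and dominant (carrier/recessive) markers are handled through their emission
sets.  At observed marker positions the probabilities are degenerate.

The QTL model is Haley-Knott regression: at each grid position the phenotype
is regressed on the expected additive score x = P(AA) - P(BB) and dominance
score z = P(AB), giving LOD = (n/2) * log10(RSS0 / RSS1).  Composite
interval mapping adds forward-selected marker cofactors, dropping any
cofactor within a window of the tested position.  Genome-wide significance
comes from permutation of the phenotype.

Effect conventions follow the F2 parameterization: additive effect
a = (mu_AA - mu_BB) / 2 (negative means the seed-parent allele decreases the
trait), dominance d = mu_AB - (mu_AA + mu_BB) / 2, and R^2 is the percent of
phenotypic variance explained at the peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidConfigError
from .linkage import CARRIER, MISSING, GeneticMap, encode_genotypes, kosambi_inverse

PEAK_SEPARATION_CM = 20.0
DEFAULT_STEP_CM = 1.0
DEFAULT_LOD_DROP = 1.0


@dataclass
class QTLScanResult:
    """LOD profile, permutation threshold, and peak table for one trait."""

    model: str  # 'im' or 'cim'
    scan: pd.DataFrame  # columns: group, position_cM, lod
    threshold: float | None
    peaks: pd.DataFrame  # QTL table (may be empty)
    n_individuals: int
    step: float
    cofactors: list[str] = field(default_factory=list)

    def group_profile(self, group: str) -> pd.DataFrame:
        return self.scan[self.scan["group"] == group].reset_index(drop=True)


def _transition(r: float) -> np.ndarray:
    """F2 genotype-chain transition matrix, states ordered (0, 1, 2) dosage."""
    s = 1.0 - r
    return np.array(
        [
            [s * s, 2 * r * s, r * r],
            [r * s, s * s + r * r, r * s],
            [r * r, 2 * r * s, s * s],
        ]
    )


_PRIOR = np.array([0.25, 0.5, 0.25])


def _emission(g: np.ndarray) -> np.ndarray:
    """(n, 3) emission indicator for encoded calls at one marker."""
    n = len(g)
    E = np.ones((n, 3))
    for k in (0, 1, 2):
        E[g == k] = 0.0
        E[g == k, k] = 1.0
    E[g == CARRIER] = [0.0, 1.0, 1.0]
    return E


@dataclass
class GroupGenotypeProbs:
    """Conditional genotype-class probabilities on one group's position grid."""

    group: str
    positions: np.ndarray  # (P,)
    probs: np.ndarray  # (P, n, 3) in dosage order (BB, AB, AA)
    is_marker: np.ndarray  # (P,) bool


def genotype_probabilities(
    gmap: GeneticMap,
    genotypes: pd.DataFrame,
    step: float = DEFAULT_STEP_CM,
) -> list[GroupGenotypeProbs]:
    """P(BB/AB/AA) at every grid position given flanking marker genotypes.

    The grid is the union of marker positions and a regular ``step`` grid
    per group.  Probabilities sum to 1 everywhere and are degenerate at
    positions with an observed co-dominant call.
    """
    G = encode_genotypes(genotypes)
    row_of = {m: i for i, m in enumerate(genotypes.index)}
    n = genotypes.shape[1]
    out = []
    for lg in gmap.groups:
        present = [(m, p) for m, p in zip(lg.markers, lg.positions) if m in row_of]
        if not present:
            continue
        mpos = np.array([p for _, p in present])
        grid = np.arange(0.0, lg.length + step / 2, step)
        positions = np.unique(np.round(np.concatenate([grid, mpos]), 9))
        emis = {}
        for m, p in present:
            key = round(p, 9)
            E = _emission(G[row_of[m]])
            emis[key] = emis[key] * E if key in emis else E
        P = len(positions)
        trans = [
            _transition(float(kosambi_inverse(positions[t + 1] - positions[t])))
            for t in range(P - 1)
        ]
        alpha = np.empty((P, n, 3))
        cur = np.tile(_PRIOR, (n, 1))
        for t in range(P):
            if t > 0:
                cur = cur @ trans[t - 1]
            E = emis.get(round(float(positions[t]), 9))
            if E is not None:
                cur = cur * E
            norm = cur.sum(axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            cur = cur / norm
            alpha[t] = cur
        beta = np.empty((P, n, 3))
        cur = np.ones((n, 3))
        for t in range(P - 1, -1, -1):
            beta[t] = cur
            if t > 0:
                E = emis.get(round(float(positions[t]), 9))
                tmp = cur * E if E is not None else cur
                cur = tmp @ trans[t - 1].T
                norm = cur.sum(axis=1, keepdims=True)
                norm[norm == 0] = 1.0
                cur = cur / norm
        probs = alpha * beta
        norm = probs.sum(axis=2, keepdims=True)
        norm[norm == 0] = 1.0
        probs = probs / norm
        is_marker = np.isin(np.round(positions, 9), np.round(mpos, 9))
        out.append(GroupGenotypeProbs(lg.name, positions, probs, is_marker))
    return out


# ---------------------------------------------------------------------------
# Haley-Knott scan engine
# ---------------------------------------------------------------------------


def _rss(D: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of each column of Y regressed on D."""
    beta, *_ = np.linalg.lstsq(D, Y, rcond=None)
    resid = Y - D @ beta
    return (resid**2).sum(axis=0)


class _ScanEngine:
    """Precomputed per-position designs for repeated scans of one dataset."""

    def __init__(
        self,
        gmap: GeneticMap,
        genotypes: pd.DataFrame,
        step: float = DEFAULT_STEP_CM,
    ):
        self.gmap = gmap
        self.individuals = list(genotypes.columns)
        self.n = len(self.individuals)
        self.gp = genotype_probabilities(gmap, genotypes, step)
        rows = []
        xs, zs = [], []
        for gp in self.gp:
            for t, pos in enumerate(gp.positions):
                rows.append((gp.group, float(pos)))
                p = gp.probs[t]
                xs.append(p[:, 2] - p[:, 0])
                zs.append(p[:, 1])
        self.positions = pd.DataFrame(rows, columns=["group", "position_cM"])
        self.x = np.vstack(xs)  # (P, n)
        self.z = np.vstack(zs)
        # marker codings for cofactor selection (additive/dominance per marker)
        G = encode_genotypes(genotypes)
        mapped = [m for m in gmap.marker_ids if m in set(genotypes.index)]
        row_of = {m: i for i, m in enumerate(genotypes.index)}
        self.cof_ids = mapped
        self.cof_pos = {m: gmap.position_of(m) for m in mapped}
        xm = np.empty((len(mapped), self.n))
        zm = np.empty((len(mapped), self.n))
        for k, m in enumerate(mapped):
            g = G[row_of[m]].astype(float)
            add = np.where(g == CARRIER, np.nan, g - 1.0)
            dom = np.where(
                g == MISSING, np.nan, np.where((g == 1) | (g == CARRIER), 1.0, 0.0)
            )
            add[g == MISSING] = np.nan
            for v in (add, dom):
                mean = np.nanmean(v) if np.isfinite(v).any() else 0.0
                v[~np.isfinite(v)] = mean
            xm[k], zm[k] = add, dom
        self.cof_x, self.cof_z = xm, zm

    def lod(
        self,
        Y: np.ndarray,
        cofactors: list[str] | None = None,
        window: float = 10.0,
    ) -> np.ndarray:
        """(P, K) LOD matrix for K phenotype columns."""
        Y = np.atleast_2d(Y.T).T if Y.ndim == 1 else Y
        n = Y.shape[0]
        ones = np.ones((n, 1))
        out = np.empty((len(self.x), Y.shape[1]))
        cof_cols: dict[str, np.ndarray] = {}
        if cofactors:
            for m in cofactors:
                k = self.cof_ids.index(m)
                cof_cols[m] = np.column_stack([self.cof_x[k], self.cof_z[k]])
        rss0_plain = _rss(ones, Y)
        for p in range(len(self.x)):
            grp = self.positions.iloc[p]["group"]
            pos = self.positions.iloc[p]["position_cM"]
            active = [
                m
                for m in (cofactors or [])
                if not (
                    self.cof_pos[m][0] == grp
                    and abs(self.cof_pos[m][1] - pos) <= window
                )
            ]
            if active:
                C = np.column_stack([ones] + [cof_cols[m] for m in active])
                rss0 = _rss(C, Y)
            else:
                C = ones
                rss0 = rss0_plain
            D = np.column_stack([C, self.x[p], self.z[p]])
            rss1 = _rss(D, Y)
            with np.errstate(divide="ignore", invalid="ignore"):
                out[p] = (n / 2.0) * np.log10(np.maximum(rss0, 1e-300) / np.maximum(rss1, 1e-300))
        return np.maximum(out, 0.0)

    def select_cofactors(self, y: np.ndarray, n_cofactors: int) -> list[str]:
        """Forward selection of marker cofactors by residual-SS reduction."""
        chosen: list[str] = []
        n = len(y)
        ones = np.ones((n, 1))
        Y = y[:, None]
        current = ones
        for _ in range(min(n_cofactors, len(self.cof_ids))):
            best, best_rss = None, np.inf
            for k, m in enumerate(self.cof_ids):
                if m in chosen:
                    continue
                D = np.column_stack([current, self.cof_x[k], self.cof_z[k]])
                r = float(_rss(D, Y)[0])
                if r < best_rss - 1e-12:
                    best, best_rss = m, r
            if best is None:
                break
            chosen.append(best)
            k = self.cof_ids.index(best)
            current = np.column_stack([current, self.cof_x[k], self.cof_z[k]])
        return chosen


def _find_peaks(
    scan: pd.DataFrame, threshold: float, separation: float = PEAK_SEPARATION_CM
) -> list[int]:
    """Indices of local maxima above threshold, >= ``separation`` cM apart."""
    candidates = []
    for grp, sub in scan.groupby("group", sort=False):
        lod = sub["lod"].to_numpy()
        pos = sub["position_cM"].to_numpy()
        idx = sub.index.to_numpy()
        for i in range(len(lod)):
            if lod[i] < threshold:
                continue
            left = lod[i - 1] if i > 0 else -np.inf
            right = lod[i + 1] if i < len(lod) - 1 else -np.inf
            if lod[i] >= left and lod[i] > right:
                candidates.append((lod[i], grp, pos[i], idx[i]))
    candidates.sort(reverse=True, key=lambda c: (c[0], str(c[1]), -c[2]))
    accepted: list[tuple[str, float, int]] = []
    for lod, grp, pos, i in candidates:
        if all(g != grp or abs(p - pos) >= separation for g, p, _ in accepted):
            accepted.append((grp, pos, i))
    return [i for _, _, i in accepted]


def support_interval(
    scan: pd.DataFrame, peak_index: int, drop: float = DEFAULT_LOD_DROP
) -> tuple[float, float]:
    """Widest contiguous region around the peak with LOD >= peak LOD - drop."""
    row = scan.loc[peak_index]
    sub = scan[scan["group"] == row["group"]].reset_index()
    i = int(sub.index[sub["index"] == peak_index][0])
    lod = sub["lod"].to_numpy()
    cut = lod[i] - drop
    lo = i
    while lo > 0 and lod[lo - 1] >= cut:
        lo -= 1
    hi = i
    while hi < len(lod) - 1 and lod[hi + 1] >= cut:
        hi += 1
    return float(sub["position_cM"].iloc[lo]), float(sub["position_cM"].iloc[hi])


def _flanking_markers(
    gmap: GeneticMap, group: str, pos: float
) -> tuple[str | None, str | None]:
    for lg in gmap.groups:
        if lg.name != group:
            continue
        left = right = None
        for m, p in zip(lg.markers, lg.positions):
            if p <= pos:
                left = m
            if p >= pos and right is None:
                right = m
        return left, right
    return None, None


def _scan(
    gmap: GeneticMap,
    genotypes: pd.DataFrame,
    phenotype: pd.Series,
    model: str,
    step: float,
    threshold: float | None,
    n_cofactors: int,
    window: float,
    lod_drop: float,
) -> QTLScanResult:
    y_all = phenotype.reindex(genotypes.columns)
    mask = np.isfinite(y_all.to_numpy(dtype=float))
    if mask.sum() < 30:
        raise InvalidConfigError("fewer than 30 phenotyped individuals")
    geno = genotypes.loc[:, genotypes.columns[mask]]
    y = y_all.to_numpy(dtype=float)[mask]
    if np.var(y) == 0:
        raise InvalidConfigError("phenotype has zero variance")
    engine = _ScanEngine(gmap, geno, step)
    cofactors = (
        engine.select_cofactors(y, n_cofactors) if model == "cim" else []
    )
    lod = engine.lod(y[:, None], cofactors, window)[:, 0]
    scan = engine.positions.copy()
    scan["lod"] = lod
    peaks = _peak_table(
        engine, gmap, scan, y, cofactors, window, threshold, lod_drop
    )
    return QTLScanResult(model, scan, threshold, peaks, int(mask.sum()), step, cofactors)


def _peak_table(
    engine: _ScanEngine,
    gmap: GeneticMap,
    scan: pd.DataFrame,
    y: np.ndarray,
    cofactors: list[str],
    window: float,
    threshold: float | None,
    lod_drop: float,
) -> pd.DataFrame:
    cols = [
        "name", "group", "peak_cM", "lod", "additive", "dominance",
        "r2_pct", "ci_lo_cM", "ci_hi_cM", "marker_left", "marker_right",
    ]
    if threshold is None:
        return pd.DataFrame(columns=cols)
    rows = []
    for k, idx in enumerate(_find_peaks(scan, threshold)):
        row = scan.loc[idx]
        a, d, r2 = qtl_effects(engine, int(idx), y, cofactors, window)
        lo, hi = support_interval(scan, int(idx), lod_drop)
        ml, mr = _flanking_markers(gmap, row["group"], row["position_cM"])
        rows.append(
            (
                f"Q{k + 1}_{row['group']}", row["group"], row["position_cM"],
                row["lod"], a, d, r2, lo, hi, ml, mr,
            )
        )
    return pd.DataFrame(rows, columns=cols)


def qtl_effects(
    engine: _ScanEngine,
    position_index: int,
    y: np.ndarray,
    cofactors: list[str] | None = None,
    window: float = 10.0,
) -> tuple[float, float, float]:
    """(a, d, R^2%) from the Haley-Knott regression at one scan position."""
    n = len(y)
    ones = np.ones((n, 1))
    grp = engine.positions.iloc[position_index]["group"]
    pos = engine.positions.iloc[position_index]["position_cM"]
    active = [
        m
        for m in (cofactors or [])
        if not (
            engine.cof_pos[m][0] == grp and abs(engine.cof_pos[m][1] - pos) <= window
        )
    ]
    C = ones
    for m in active:
        k = engine.cof_ids.index(m)
        C = np.column_stack([C, engine.cof_x[k], engine.cof_z[k]])
    D = np.column_stack([C, engine.x[position_index], engine.z[position_index]])
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    rss0 = float(_rss(C, y[:, None])[0])
    rss1 = float(((y - D @ beta) ** 2).sum())
    a = float(beta[-2])
    d = float(beta[-1])
    r2 = 100.0 * (rss0 - rss1) / rss0 if rss0 > 0 else 0.0
    return a, d, r2


def scan_im(
    gmap: GeneticMap,
    genotypes: pd.DataFrame,
    phenotype: pd.Series,
    step: float = DEFAULT_STEP_CM,
    threshold: float | None = None,
    lod_drop: float = DEFAULT_LOD_DROP,
) -> QTLScanResult:
    """Simple interval mapping (Haley-Knott regression) over the whole map."""
    return _scan(gmap, genotypes, phenotype, "im", step, threshold, 0, 0.0, lod_drop)


def scan_cim(
    gmap: GeneticMap,
    genotypes: pd.DataFrame,
    phenotype: pd.Series,
    step: float = DEFAULT_STEP_CM,
    threshold: float | None = None,
    n_cofactors: int = 5,
    window: float = 10.0,
    lod_drop: float = DEFAULT_LOD_DROP,
) -> QTLScanResult:
    """Composite interval mapping with forward-selected marker cofactors."""
    return _scan(
        gmap, genotypes, phenotype, "cim", step, threshold, n_cofactors, window, lod_drop
    )


def threshold_from_max_lods(max_lods: np.ndarray, alpha: float) -> float:
    """The ceil((1-alpha)*n)-th order statistic of permutation maximum LODs."""
    srt = np.sort(np.asarray(max_lods, dtype=float))
    n = len(srt)
    if alpha <= 0:
        return float(srt[-1])
    k = math.ceil((1.0 - alpha) * n)
    return float(srt[k - 1])


def permutation_threshold(
    gmap: GeneticMap,
    genotypes: pd.DataFrame,
    phenotype: pd.Series,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    step: float = DEFAULT_STEP_CM,
    model: str = "im",
    n_cofactors: int = 5,
    window: float = 10.0,
) -> float:
    """Genome-wide LOD threshold from phenotype permutations.

    For CIM the cofactors selected on the observed phenotype are held fixed
    across permutations.  Deterministic under a fixed seed.
    """
    if n_perm < 20:
        raise InvalidConfigError("n_perm below 20 gives a meaningless threshold")
    y_all = phenotype.reindex(genotypes.columns)
    mask = np.isfinite(y_all.to_numpy(dtype=float))
    geno = genotypes.loc[:, genotypes.columns[mask]]
    y = y_all.to_numpy(dtype=float)[mask]
    if np.var(y) == 0:
        raise InvalidConfigError("phenotype has zero variance")
    engine = _ScanEngine(gmap, geno, step)
    cofactors = engine.select_cofactors(y, n_cofactors) if model == "cim" else []
    rng = np.random.default_rng(seed)
    Y = np.column_stack([rng.permutation(y) for _ in range(n_perm)])
    lod = engine.lod(Y, cofactors, window)
    return threshold_from_max_lods(lod.max(axis=0), alpha)


def scan_with_permutations(
    gmap: GeneticMap,
    genotypes: pd.DataFrame,
    phenotype: pd.Series,
    model: str = "cim",
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    step: float = DEFAULT_STEP_CM,
    n_cofactors: int = 5,
    window: float = 10.0,
    lod_drop: float = DEFAULT_LOD_DROP,
) -> QTLScanResult:
    """Permutation threshold followed by the scan, peaks annotated."""
    thr = permutation_threshold(
        gmap, genotypes, phenotype, n_perm, alpha, seed, step, model, n_cofactors, window
    )
    if model == "im":
        return scan_im(gmap, genotypes, phenotype, step, thr, lod_drop)
    return scan_cim(
        gmap, genotypes, phenotype, step, thr, n_cofactors, window, lod_drop
    )
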