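"""Marker QC, recombination estimation, and linkage-map construction for F2 intercrosses.

Genotypes are stored as single-character codes:

====  =============================================================
code  meaning
====  =============================================================
A     homozygous for the seed-parent allele (2 copies)
H     heterozygous
B     homozygous for the pollen-parent allele (0 copies)
-     missing
D     dominant-marker carrier class (genotype A or H, not resolved)
R     dominant-marker recessive class (genotype B)
====  =============================================================

Internally calls are encoded as integers counting seed-parent alleles
(0, 1, 2), with -1 for missing and 3 for the unresolved carrier class of a
dominant marker.  All markers are assumed to be in coupling phase (both
``A`` alleles trace to the seed parent), which holds by construction for an
F2 between fully homozygous parents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataFormatError, InvalidConfigError

MISSING = -1
CARRIER = 3  # dominant marker: A or H, unresolved

CODE_TO_INT = {"A": 2, "H": 1, "B": 0, "-": MISSING, "D": CARRIER, "R": 0}
INT_TO_CODE = {2: "A", 1: "H", 0: "B", MISSING: "-"}


def encode_genotypes(calls: pd.DataFrame) -> np.ndarray:
    """Convert a marker x individual code DataFrame to an int8 array."""
    arr = np.empty(calls.shape, dtype=np.int8)
    values = calls.to_numpy()
    for code, value in CODE_TO_INT.items():
        arr[values == code] = value
    known = np.isin(values, list(CODE_TO_INT))
    if not known.all():
        bad = np.argwhere(~known)[0]
        raise DataFormatError(
            f"illegal genotype code {values[bad[0], bad[1]]!r} at marker "
            f"{calls.index[bad[0]]!r}, individual {calls.columns[bad[1]]!r}"
        )
    return arr


def decode_genotypes(
    arr: np.ndarray,
    marker_ids,
    individual_ids,
    dominant_markers: set[str] | frozenset[str] = frozenset(),
) -> pd.DataFrame:
    """Inverse of :func:`encode_genotypes`.

    Rows listed in ``dominant_markers`` are written with the D/R alphabet.
    """
    out = np.empty(arr.shape, dtype=object)
    for value, code in INT_TO_CODE.items():
        out[arr == value] = code
    out[arr == CARRIER] = "D"
    df = pd.DataFrame(out, index=list(marker_ids), columns=list(individual_ids))
    for m in dominant_markers:
        if m in df.index:
            row = df.loc[m].replace({"B": "R", "A": "D", "H": "D"})
            df.loc[m] = row
    return df


# ---------------------------------------------------------------------------
# Map data structures
# ---------------------------------------------------------------------------


@dataclass
class LinkageGroup:
    """An ordered set of markers with cumulative cM positions (first at 0)."""

    name: str
    markers: list[str]
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.markers) != len(self.positions):
            raise InvalidConfigError("markers and positions differ in length")
        if len(self.positions) and abs(self.positions[0]) > 1e-9:
            raise InvalidConfigError("first position in a group must be 0 cM")
        if np.any(np.diff(self.positions) < -1e-9):
            raise InvalidConfigError("positions must be non-decreasing")

    @property
    def length(self) -> float:
        return float(self.positions[-1]) if len(self.positions) else 0.0

    def __len__(self) -> int:
        return len(self.markers)


@dataclass
class GeneticMap:
    """A collection of linkage groups."""

    groups: list[LinkageGroup]

    def __post_init__(self) -> None:
        ids = [m for g in self.groups for m in g.markers]
        if len(ids) != len(set(ids)):
            raise InvalidConfigError("marker ids must be unique across the map")

    @property
    def n_markers(self) -> int:
        return sum(len(g) for g in self.groups)

    @property
    def total_length(self) -> float:
        return float(sum(g.length for g in self.groups))

    @property
    def marker_ids(self) -> list[str]:
        return [m for g in self.groups for m in g.markers]

    def group_of(self, marker: str) -> str:
        for g in self.groups:
            if marker in g.markers:
                return g.name
        raise KeyError(marker)

    def position_of(self, marker: str) -> tuple[str, float]:
        for g in self.groups:
            if marker in g.markers:
                return g.name, float(g.positions[g.markers.index(marker)])
        raise KeyError(marker)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g.name, m, p)
            for g in self.groups
            for m, p in zip(g.markers, g.positions)
        ]
        return pd.DataFrame(rows, columns=["group", "marker", "position_cM"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GeneticMap":
        groups = []
        for name, sub in frame.groupby("group", sort=False):
            sub = sub.sort_values("position_cM")
            pos = sub["position_cM"].to_numpy(float)
            groups.append(LinkageGroup(str(name), list(sub["marker"]), pos - pos[0]))
        return cls(groups)


@dataclass
class PairwiseLinkage:
    """ML recombination fraction and linkage LOD for one marker pair."""

    marker1: str
    marker2: str
    r: float
    lod: float


# ---------------------------------------------------------------------------
# Kosambi map function
# ---------------------------------------------------------------------------


def kosambi_distance(r) -> float | np.ndarray:
    """Map distance in cM for recombination fraction ``r``: 25*ln((1+2r)/(1-2r))."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise InvalidConfigError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_inverse(d) -> float | np.ndarray:
    """Recombination fraction for a map distance ``d`` in cM: 0.5*tanh(d/50)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise InvalidConfigError("map distance must be non-negative")
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if r.ndim == 0 else r


# ---------------------------------------------------------------------------
# Duplicate collapsing
# ---------------------------------------------------------------------------


def collapse_duplicate_markers(calls: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop markers that duplicate another marker's genotypes.

    Two markers are duplicates when their non-missing calls never conflict.
    Markers are grouped greedily into conflict-free classes (processed in
    order of increasing missingness, ties broken by marker id) and the member
    with the fewest missing values is kept from each class.

    Returns the reduced call matrix and a report with one row per removed
    marker naming its kept representative.
    """
    G = encode_genotypes(calls)
    miss = (G == MISSING).sum(axis=1)
    order = sorted(range(len(calls)), key=lambda i: (miss[i], str(calls.index[i])))
    classes: list[list[int]] = []
    class_matrix: list[np.ndarray] = []  # stacked member rows per class
    for i in order:
        g = G[i]
        placed = False
        for ci, members in enumerate(classes):
            M = class_matrix[ci]
            conflict = (
                (M != g[None, :]) & (M != MISSING) & (g[None, :] != MISSING)
            ).any()
            if not conflict:
                members.append(i)
                class_matrix[ci] = np.vstack([M, g])
                placed = True
                break
        if not placed:
            classes.append([i])
            class_matrix.append(g[None, :].copy())
    keep: list[int] = []
    report_rows = []
    for members in classes:
        rep = min(members, key=lambda i: (miss[i], str(calls.index[i])))
        keep.append(rep)
        for i in members:
            if i != rep:
                report_rows.append((calls.index[i], calls.index[rep]))
    keep_ids = [calls.index[i] for i in sorted(keep)]
    report = pd.DataFrame(report_rows, columns=["removed", "kept_as"])
    return calls.loc[keep_ids], report


# ---------------------------------------------------------------------------
# Segregation distortion
# ---------------------------------------------------------------------------


def segregation_distortion_test(calls_row: np.ndarray) -> tuple[float, float]:
    """Chi-square goodness-of-fit P-value for one marker's genotype counts.

    Co-dominant markers are tested against 1:2:1 (df=2); dominant markers
    (carrier/recessive coding) against 3:1 (df=1).  Missing calls are
    ignored.  Returns (chi2, p).
    """
    g = np.asarray(calls_row)
    if np.any(g == CARRIER):
        n_car = int(np.sum(g == CARRIER))
        n_rec = int(np.sum(g == 0))
        obs = np.array([n_car, n_rec], dtype=float)
        expected = obs.sum() * np.array([0.75, 0.25])
    else:
        obs = np.array([(g == k).sum() for k in (2, 1, 0)], dtype=float)
        expected = obs.sum() * np.array([0.25, 0.5, 0.25])
    if obs.sum() == 0:
        return float("nan"), float("nan")
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=len(obs) - 1))
    return chi2, p


def segregation_distortion_filter(
    calls: pd.DataFrame,
    alpha: float = 0.001,
    min_calls: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove markers whose genotype counts deviate from Mendelian expectation.

    Markers with chi-square P < ``alpha`` are excluded, as are markers with
    fewer than ``min_calls`` non-missing calls.  Returns the retained call
    matrix and a per-marker report (chi2, p, removed, reason).
    """
    G = encode_genotypes(calls)
    rows = []
    keep = []
    for i, mid in enumerate(calls.index):
        g = G[i]
        n_obs = int(np.sum(g != MISSING))
        if n_obs < min_calls:
            rows.append((mid, np.nan, np.nan, True, "too_few_calls"))
            continue
        chi2, p = segregation_distortion_test(g)
        if p < alpha:
            rows.append((mid, chi2, p, True, "distorted"))
        else:
            rows.append((mid, chi2, p, False, ""))
            keep.append(mid)
    report = pd.DataFrame(
        rows, columns=["marker", "chi2", "p_value", "removed", "reason"]
    ).set_index("marker")
    return calls.loc[keep], report


# ---------------------------------------------------------------------------
# Recombination fraction estimation (F2 intercross, coupling phase)
# ---------------------------------------------------------------------------

# Joint genotype cell probabilities.  With parental gamete probability
# p = (1-r)/2 and recombinant q = r/2, the 3x3 table of (g1, g2) genotype
# counts (number of seed-parent alleles) has cells:
#   (2,2)=(0,0)=p^2      (2,0)=(0,2)=q^2      off-by-one cells = 2pq
#   (1,1)=2p^2 + 2q^2  (mixing 0- and 2-recombinant gamete pairs)
# and the number of recombinant gametes per cell is fixed except in (1,1).

_K_FIXED = np.array(
    [  # recombinant gametes by cell [g1][g2], -1 marks the mixed (1,1) cell
        [0, 1, 2],
        [1, -1, 1],
        [2, 1, 0],
    ]
)


def _cell_probs(r: np.ndarray) -> np.ndarray:
    """Cell probabilities, shape (..., 3, 3) indexed by [g1][g2] with g in 0..2."""
    r = np.asarray(r, dtype=float)
    p = (1 - r) / 2.0
    q = r / 2.0
    out = np.empty(r.shape + (3, 3))
    out[..., 0, 0] = out[..., 2, 2] = p**2
    out[..., 0, 2] = out[..., 2, 0] = q**2
    out[..., 0, 1] = out[..., 1, 0] = out[..., 1, 2] = out[..., 2, 1] = 2 * p * q
    out[..., 1, 1] = 2 * p**2 + 2 * q**2
    return out


def _table_em(tables: np.ndarray, max_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    """Vectorized EM for r over a stack of 3x3 joint genotype count tables.

    The only latent structure is the double-heterozygote cell, which mixes
    gamete pairs carrying 0 or 2 recombinations; its expected recombinant
    count at the current r is 2 r^2 / ((1-r)^2 + r^2).
    """
    tables = np.asarray(tables, dtype=float)
    n = tables.sum(axis=(-2, -1))
    n = np.where(n == 0, np.nan, n)
    fixed = np.where(_K_FIXED >= 0, _K_FIXED, 0)
    base = (tables * fixed).sum(axis=(-2, -1))
    n11 = tables[..., 1, 1]
    r = np.full(tables.shape[:-2], 0.25)
    for _ in range(max_iter):
        e11 = 2 * r**2 / ((1 - r) ** 2 + r**2)
        r_new = (base + n11 * e11) / (2 * n)
        r_new = np.clip(r_new, 0.0, 0.5)
        if np.all(np.abs(r_new - r) < tol):
            r = r_new
            break
        r = r_new
    return r


def _table_lod(tables: np.ndarray, r: np.ndarray) -> np.ndarray:
    """log10 likelihood ratio of r versus r=0.5 for a stack of count tables."""
    tables = np.asarray(tables, dtype=float)
    pr = _cell_probs(np.asarray(r))
    p5 = _cell_probs(np.full(np.shape(r), 0.5))
    with np.errstate(divide="ignore", invalid="ignore"):
        term = tables * (np.log10(pr) - np.log10(p5))
    term = np.where(tables > 0, term, 0.0)
    return term.sum(axis=(-2, -1))


def _joint_table(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    ok = (g1 >= 0) & (g1 <= 2) & (g2 >= 0) & (g2 <= 2)
    t = np.zeros((3, 3))
    np.add.at(t, (g1[ok], g2[ok]), 1)
    return t


def _pair_em_generic(g1: np.ndarray, g2: np.ndarray) -> tuple[float, float]:
    """Scalar EM for a pair where either marker may be dominant-coded.

    Observations constrain the joint genotype to a set of cells (the carrier
    class maps to genotypes {1, 2}); the E-step distributes each observation
    over its compatible cells and, within the double-het cell, over the
    0- and 2-recombinant gamete configurations.
    """
    compat = {0: [0], 1: [1], 2: [2], CARRIER: [1, 2]}
    obs: dict[tuple[int, int], int] = {}
    for a, b in zip(g1, g2):
        if a == MISSING or b == MISSING:
            continue
        obs[(int(a), int(b))] = obs.get((int(a), int(b)), 0) + 1
    n = sum(obs.values())
    if n < 2:
        raise DataFormatError("fewer than 2 jointly non-missing individuals")
    r = 0.25
    for _ in range(500):
        cp = _cell_probs(np.array(r))
        e11 = 2 * r**2 / ((1 - r) ** 2 + r**2)
        num = 0.0
        for (a, b), cnt in obs.items():
            cells = [(i, j) for i in compat[a] for j in compat[b]]
            probs = np.array([cp[i, j] for i, j in cells])
            ks = np.array(
                [_K_FIXED[i, j] if _K_FIXED[i, j] >= 0 else e11 for i, j in cells],
                dtype=float,
            )
            tot = probs.sum()
            if tot <= 0:
                continue
            num += cnt * float((probs * ks).sum() / tot)
        r_new = min(max(num / (2 * n), 0.0), 0.5)
        if abs(r_new - r) < 1e-10:
            r = r_new
            break
        r = r_new
    # class-likelihood LOD vs r = 0.5
    lod = 0.0
    cp = _cell_probs(np.array(r))
    c5 = _cell_probs(np.array(0.5))
    for (a, b), cnt in obs.items():
        cells = [(i, j) for i in compat[a] for j in compat[b]]
        pr = sum(cp[i, j] for i, j in cells)
        p5 = sum(c5[i, j] for i, j in cells)
        if pr > 0:
            lod += cnt * (np.log10(pr) - np.log10(p5))
    return float(r), float(max(lod, 0.0))


def estimate_recombination(
    g1: np.ndarray | pd.Series,
    g2: np.ndarray | pd.Series,
    marker1: str = "m1",
    marker2: str = "m2",
) -> PairwiseLinkage:
    """ML recombination fraction between two markers in an F2 intercross.

    Both markers may be co-dominant (codes 0/1/2) or dominant (carrier code
    3 vs 0).  The double-heterozygote phase ambiguity is handled by EM.
    Raises ``DataFormatError`` with fewer than 2 jointly observed individuals.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    if g1.dtype.kind in "OU":
        g1 = encode_genotypes(pd.DataFrame([g1]))[0]
    if g2.dtype.kind in "OU":
        g2 = encode_genotypes(pd.DataFrame([g2]))[0]
    if np.any(g1 == CARRIER) or np.any(g2 == CARRIER):
        r, lod = _pair_em_generic(g1, g2)
        return PairwiseLinkage(marker1, marker2, r, lod)
    ok = (g1 != MISSING) & (g2 != MISSING)
    if ok.sum() < 2:
        raise DataFormatError("fewer than 2 jointly non-missing individuals")
    t = _joint_table(g1, g2)
    r = float(_table_em(t[None])[0])
    lod = float(max(_table_lod(t[None], np.array([r]))[0], 0.0))
    return PairwiseLinkage(marker1, marker2, r, lod)


def pairwise_recombination(
    G: np.ndarray, chunk: int = 2_000_000
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs r and LOD matrices for an encoded genotype matrix (M x n).

    Co-dominant pairs are processed in a single vectorized EM over their
    joint count tables; pairs involving a dominant-coded marker fall back to
    the scalar EM.
    """
    M = G.shape[0]
    R = np.full((M, M), 0.5)
    LOD = np.zeros((M, M))
    np.fill_diagonal(R, 0.0)
    dominant = np.where((G == CARRIER).any(axis=1))[0]
    codom = np.setdiff1d(np.arange(M), dominant)
    if len(codom) > 1:
        sub = G[codom]
        onehot = np.zeros((len(codom), 3, sub.shape[1]))
        for k in range(3):
            onehot[:, k, :] = sub == k
        # tables[a, b, i, j] = #individuals with genotype i at a and j at b
        tables = np.einsum("ain,bjn->abij", onehot, onehot)
        iu, ju = np.triu_indices(len(codom), k=1)
        flat = tables[iu, ju]
        r = _table_em(flat)
        lod = np.maximum(_table_lod(flat, r), 0.0)
        R[codom[iu], codom[ju]] = R[codom[ju], codom[iu]] = r
        LOD[codom[iu], codom[ju]] = LOD[codom[ju], codom[iu]] = lod
    for i in dominant:
        for j in range(M):
            if j == i:
                continue
            r, lod = _pair_em_generic(G[i], G[j])
            R[i, j] = R[j, i] = r
            LOD[i, j] = LOD[j, i] = lod
    return R, LOD


# ---------------------------------------------------------------------------
# Grouping and ordering
# ---------------------------------------------------------------------------


def group_markers(
    R: np.ndarray,
    LOD: np.ndarray,
    marker_ids: list[str],
    r_max: float = 0.35,
    lod_min: float = 3.0,
) -> list[list[str]]:
    """Partition markers into linkage groups by single-linkage closure.

    Two markers are linked when r <= ``r_max`` and LOD >= ``lod_min``;
    groups are the connected components of the linkage graph, returned
    largest first (ties broken by first marker id).
    """
    M = len(marker_ids)
    parent = list(range(M))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    linked = (R <= r_max) & (LOD >= lod_min)
    iu, ju = np.where(np.triu(linked, k=1))
    for a, b in zip(iu, ju):
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[rb] = ra
    comps: dict[int, list[int]] = {}
    for i in range(M):
        comps.setdefault(find(i), []).append(i)
    groups = [[marker_ids[i] for i in sorted(c)] for c in comps.values()]
    groups.sort(key=lambda g: (-len(g), g[0]))
    return groups


def _path_cost(order: np.ndarray, R: np.ndarray) -> float:
    return float(R[order[:-1], order[1:]].sum())


def _greedy_chain(R: np.ndarray, start: int) -> list[int]:
    m = R.shape[0]
    used = np.zeros(m, dtype=bool)
    chain = [start]
    used[start] = True
    while not used.all():
        left, right = chain[0], chain[-1]
        cand = np.where(~used)[0]
        dl = R[left, cand]
        dr = R[right, cand]
        if dl.min() < dr.min():
            k = cand[int(np.argmin(dl))]
            chain.insert(0, int(k))
        else:
            k = cand[int(np.argmin(dr))]
            chain.append(int(k))
        used[k] = True
    return chain


def _two_opt(order: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Reversal moves until no move reduces the sum of adjacent r."""
    order = order.copy()
    m = len(order)
    improved = True
    while improved:
        improved = False
        for i in range(m - 1):
            for j in range(i + 1, m):
                before = 0.0
                after = 0.0
                if i > 0:
                    before += R[order[i - 1], order[i]]
                    after += R[order[i - 1], order[j]]
                if j < m - 1:
                    before += R[order[j], order[j + 1]]
                    after += R[order[i], order[j + 1]]
                if after < before - 1e-12:
                    order[i : j + 1] = order[i : j + 1][::-1]
                    improved = True
    return order


def order_markers(
    marker_ids: list[str],
    R: np.ndarray,
    runs: int = 50,
    seed: int = 0,
) -> tuple[list[str], np.ndarray]:
    """Order a linkage group minimizing the sum of adjacent recombination fractions.

    Greedy double-ended seriation from a random start followed by 2-opt
    refinement, restarted ``runs`` times; the lowest-cost order is kept
    (ties broken lexicographically on the canonical orientation).  Positions
    are cumulative Kosambi distances of adjacent r, with r capped just below
    0.5 so unlinked neighbours get a large finite gap.
    """
    m = len(marker_ids)
    if m == 1:
        return list(marker_ids), np.zeros(1)
    rng = np.random.default_rng(seed)
    best: np.ndarray | None = None
    best_cost = np.inf
    best_key: tuple[str, ...] | None = None
    for _ in range(max(1, runs)):
        start = int(rng.integers(m))
        order = _two_opt(np.array(_greedy_chain(R, start)), R)
        if str(marker_ids[order[-1]]) < str(marker_ids[order[0]]):
            order = order[::-1]
        cost = _path_cost(order, R)
        key = tuple(str(marker_ids[i]) for i in order)
        if cost < best_cost - 1e-12 or (
            abs(cost - best_cost) <= 1e-12 and (best_key is None or key < best_key)
        ):
            best, best_cost, best_key = order, cost, key
    assert best is not None
    adj_r = np.minimum(R[best[:-1], best[1:]], 0.4999)
    positions = np.concatenate([[0.0], np.cumsum(kosambi_distance(adj_r))])
    return [marker_ids[i] for i in best], positions


def build_map(
    calls: pd.DataFrame,
    r_max: float = 0.35,
    lod_min: float = 3.0,
    runs: int = 50,
    seed: int = 0,
    min_group_size: int = 2,
) -> GeneticMap:
    """Group and order markers from a call matrix into a genetic map.

    Groups smaller than ``min_group_size`` (default 2: singletons) are
    dropped.  Group names LG1, LG2, ... are assigned largest group first.
    """
    G = encode_genotypes(calls)
    ids = [str(m) for m in calls.index]
    R, LOD = pairwise_recombination(G)
    idx = {m: i for i, m in enumerate(ids)}
    groups = group_markers(R, LOD, ids, r_max=r_max, lod_min=lod_min)
    out = []
    rng = np.random.default_rng(seed)
    for gi, members in enumerate(groups):
        if len(members) < min_group_size:
            continue
        sub = np.array([idx[m] for m in members])
        order, pos = order_markers(
            members, R[np.ix_(sub, sub)], runs=runs, seed=int(rng.integers(2**31))
        )
        out.append(LinkageGroup(f"LG{len(out) + 1}", order, pos))
    return GeneticMap(out)


# ---------------------------------------------------------------------------
# Gap filter and summaries
# ---------------------------------------------------------------------------


def gap_filter(
    gmap: GeneticMap, max_gap: float = 20.0
) -> tuple[GeneticMap, pd.DataFrame]:
    """Iteratively drop markers flanking gaps larger than ``max_gap`` cM.

    At each oversized gap the marker on the side with fewer markers is
    removed (right side on ties); gaps are re-evaluated until none exceeds
    the limit.  Idempotent.  Returns the filtered map and a removal log.
    """
    removed_rows = []
    new_groups = []
    for g in gmap.groups:
        markers = list(g.markers)
        pos = list(map(float, g.positions))
        while len(markers) > 1:
            gaps = np.diff(pos)
            if np.all(gaps <= max_gap):
                break
            i = int(np.argmax(gaps))  # gap between markers i and i+1
            left_n, right_n = i + 1, len(markers) - i - 1
            drop = i if left_n < right_n else i + 1
            removed_rows.append((g.name, markers[drop], gaps[i]))
            del markers[drop], pos[drop]
        new_groups.append(
            LinkageGroup(g.name, markers, np.asarray(pos) - (pos[0] if pos else 0.0))
        )
    log = pd.DataFrame(removed_rows, columns=["group", "marker", "gap_cM"])
    return GeneticMap(new_groups), log


def summarize_map(gmap: GeneticMap) -> dict:
    """Map summary: group count, marker count, total length, L/N marker spacing."""
    if not gmap.groups:
        raise InvalidConfigError("cannot summarize an empty map")
    n = gmap.n_markers
    length = gmap.total_length
    return {
        "n_groups": len(gmap.groups),
        "n_markers": n,
        "total_length_cM": round(length, 1),
        "average_marker_distance_cM": round(length / n, 2) if n else float("nan"),
    }


# ---------------------------------------------------------------------------
# Cross-population bridging
# ---------------------------------------------------------------------------


@dataclass
class BridgeReport:
    """Shared-marker correspondence between two maps."""

    table: pd.DataFrame
    correspondence: pd.DataFrame
    n_shared: int
    n_inconsistent: int
    inconsistent_markers: list[str] = field(default_factory=list)


def bridge_maps(
    map_a: GeneticMap,
    map_b: GeneticMap,
    shared_marker_ids: list[str] | None = None,
) -> BridgeReport:
    """Relate two maps through markers they share.

    For every shared marker the report lists its group and position in each
    map.  Group correspondence is the modal B-group per A-group; markers
    whose B-group differs from their A-group's modal partner are counted as
    inconsistent.
    """
    ids_a = set(map_a.marker_ids)
    ids_b = set(map_b.marker_ids)
    shared = sorted(ids_a & ids_b)
    if shared_marker_ids is not None:
        shared = [m for m in shared_marker_ids if m in ids_a and m in ids_b]
    rows = []
    for m in shared:
        ga, pa = map_a.position_of(m)
        gb, pb = map_b.position_of(m)
        rows.append((m, ga, pa, gb, pb))
    table = pd.DataFrame(
        rows, columns=["marker", "group_a", "pos_a", "group_b", "pos_b"]
    )
    if table.empty:
        corr = pd.DataFrame(columns=["group_a", "group_b", "n_shared"])
        return BridgeReport(table, corr, 0, 0, [])
    modal = (
        table.groupby("group_a")["group_b"]
        .agg(lambda s: s.value_counts().index[0])
        .rename("group_b")
    )
    counts = table.groupby("group_a")["group_b"].size().rename("n_shared")
    corr = pd.concat([modal, counts], axis=1).reset_index()
    bad = [
        row.marker
        for row in table.itertuples()
        if row.group_b != modal.loc[row.group_a]
    ]
    return BridgeReport(table, corr, len(table), len(bad), bad)
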