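"""Synthetic F2 populations with amplicon read-depth matrices and phenotypes.

The generator emulates the data an amplicon presence/absence genotyping
pipeline yields on an F2 intercross between two fully homozygous parents:

* genotypes segregating 1:2:1, produced by two independent gametes per
  individual, each a Markov chain along ordered loci with adjacent
  recombination probabilities from the Kosambi inverse (no interference
  between intervals);
* per-locus trimodal read depths whose class means rise with the dosage of
  the amplicon-source parent's allele, drawn from a gamma-mixed Poisson
  (negative-binomial-like) count model with a per-marker scale factor;
* an emulated default caller: dominant presence/absence calls from a depth
  threshold, plus co-dominant calls for a minority of loci, lightly
  corrupted at a configurable error rate;
* quantitative phenotypes (days after sowing to maturity and to flowering)
  driven by planted QTLs with additive/dominance effects, right-censored at
  the experiment end day;
* a dominant morphological marker segregating 3:1.

Every draw flows from ``SimConfig.seed`` through fixed substream offsets, so
a full dataset is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidConfigError
from .linkage import GeneticMap, LinkageGroup, kosambi_inverse
from .mixture import DepthMatrix

PARENT1 = "P1"  # seed parent, AA side
PARENT2 = "P2"  # pollen parent, BB side

_CODES = np.array(["B", "H", "A"])  # index = number of seed-parent alleles


@dataclass(frozen=True)
class QTLEffect:
    """One planted QTL: linkage group (1-based), position (cM), effects (trait units).

    A homozygote for the seed-parent allele deviates by ``+additive`` from
    the baseline, the other homozygote by ``-additive``, and the
    heterozygote by ``dominance``.
    """

    group: int
    position: float
    additive: float
    dominance: float


@dataclass(frozen=True)
class DepthModel:
    """Read-depth class means, overdispersion, and per-marker scale spread.

    Means are reads for 0, 1, and 2 copies of the amplicon allele; the count
    for an individual is Poisson with a gamma-distributed rate
    (``var = mu + dispersion * mu^2``), times a log-normal per-marker scale
    with log-sd ``per_marker_scale_sd``.  ``dispersion = 0`` is plain Poisson.
    """

    mu_absent: float = 2.0
    mu_het: float = 60.0
    mu_hom: float = 120.0
    dispersion: float = 0.02
    per_marker_scale_sd: float = 0.25


@dataclass(frozen=True)
class DefaultCaller:
    """Emulated behaviour of the vendor genotyping software's output.

    Dominant calls mark presence when the read count reaches
    ``presence_threshold``; a fraction ``codominant_fraction`` of loci also
    carry three-state calls equal to the true genotype corrupted at rate
    ``error_rate``.
    """

    presence_threshold: int = 10
    codominant_fraction: float = 0.12
    error_rate: float = 0.02


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for one synthetic F2 dataset.

    Defaults mirror the larger mapping population of the study system: 150
    individuals, 8 linkage groups (the buckwheat chromosome number), one
    major maturity QTL (a = -7.19, d = -3.28 DAS, explaining ~21% of the
    variance) and one flowering QTL, with maturity censored at 105 DAS.
    """

    n_individuals: int = 150
    n_linkage_groups: int = 8
    markers_per_group: int = 20
    marker_spacing: float = 5.0
    qtl_spec: tuple[QTLEffect, ...] = (QTLEffect(6, 47.5, -7.19, -3.28),)
    flowering_qtl_spec: tuple[QTLEffect, ...] = (QTLEffect(3, 42.5, -6.52, -0.03),)
    heritability: float = 0.21
    flowering_heritability: float = 0.154
    baseline_maturity: float = 84.0
    baseline_flowering: float = 36.0
    residual_sd: float = 8.0  # used when the planted QTLs carry no variance
    censor_day: float = 105.0
    depth_model: DepthModel = field(default_factory=DepthModel)
    default_caller: DefaultCaller = field(default_factory=DefaultCaller)
    seed: int = 0

    @property
    def group_length(self) -> float:
        return (self.markers_per_group - 1) * self.marker_spacing

    def validate(self) -> None:
        dm = self.depth_model
        if not (0 <= dm.mu_absent < dm.mu_het < dm.mu_hom):
            raise InvalidConfigError(
                "depth means must satisfy 0 <= mu_absent < mu_het < mu_hom"
            )
        if dm.dispersion < 0 or dm.per_marker_scale_sd < 0:
            raise InvalidConfigError("dispersion and scale sd must be non-negative")
        for name, h in (
            ("heritability", self.heritability),
            ("flowering_heritability", self.flowering_heritability),
        ):
            if not 0.0 <= h <= 1.0:
                raise InvalidConfigError(f"{name} must lie in [0, 1]")
        if self.n_individuals < 1 or self.markers_per_group < 1:
            raise InvalidConfigError("population and marker counts must be positive")
        if self.marker_spacing <= 0:
            raise InvalidConfigError("marker spacing must be positive")
        if kosambi_inverse(self.marker_spacing) >= 0.5:
            raise InvalidConfigError("marker spacing implies r >= 0.5")
        for q in tuple(self.qtl_spec) + tuple(self.flowering_qtl_spec):
            if not 1 <= q.group <= self.n_linkage_groups:
                raise InvalidConfigError(f"QTL group {q.group} outside the genome")
            if not 0 <= q.position <= self.group_length:
                raise InvalidConfigError(
                    f"QTL position {q.position} cM outside its group (length "
                    f"{self.group_length} cM)"
                )
        if not 0 <= self.default_caller.error_rate <= 1:
            raise InvalidConfigError("default caller error rate must lie in [0, 1]")
        if not 0 <= self.default_caller.codominant_fraction <= 1:
            raise InvalidConfigError("codominant fraction must lie in [0, 1]")


@dataclass
class PhenotypeTable:
    """Per-individual flowering and maturity phenotypes (DAS) with censor flags."""

    frame: pd.DataFrame  # columns: individual, flowering_time, maturity_time, censored

    def __post_init__(self) -> None:
        required = {"individual", "flowering_time", "maturity_time", "censored"}
        missing = required - set(self.frame.columns)
        if missing:
            raise InvalidConfigError(f"phenotype table missing columns {sorted(missing)}")

    @property
    def individuals(self) -> list[str]:
        return list(self.frame["individual"])

    def trait(self, name: str) -> pd.Series:
        return self.frame.set_index("individual")[name]


@dataclass
class SimTruth:
    """Ground truth for one simulated dataset."""

    genotypes: pd.DataFrame  # marker x individual, codes A/H/B
    map: GeneticMap
    qtl_genotypes: dict[tuple[int, float], np.ndarray]  # allele-dosage vectors
    config: SimConfig
    phenotypes_uncensored: PhenotypeTable | None = None

    @property
    def individuals(self) -> list[str]:
        return list(self.genotypes.columns)


def _individual_ids(n: int) -> list[str]:
    return [f"F2_{i + 1:03d}" for i in range(n)]


def simulate_f2_genotypes(config: SimConfig) -> SimTruth:
    """Draw F2 genotypes by simulating two gametes per individual.

    Each gamete is a Markov chain along the ordered loci of a group, flipping
    parental origin between adjacent loci with probability
    ``kosambi_inverse(spacing)``.  QTL positions from the config are inserted
    as extra (unobserved) loci so their genotypes co-segregate correctly with
    flanking markers.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_individuals
    all_qtls = sorted(
        {(q.group, q.position) for q in tuple(config.qtl_spec) + tuple(config.flowering_qtl_spec)}
    )
    marker_rows = []
    marker_ids: list[str] = []
    groups = []
    qtl_geno: dict[tuple[int, float], np.ndarray] = {}
    for g in range(1, config.n_linkage_groups + 1):
        marker_pos = [j * config.marker_spacing for j in range(config.markers_per_group)]
        qtl_pos = [p for (grp, p) in all_qtls if grp == g]
        loci = sorted(set(marker_pos) | set(qtl_pos))
        r_adj = kosambi_inverse(np.diff(loci)) if len(loci) > 1 else np.empty(0)
        if np.any(r_adj >= 0.5):
            raise InvalidConfigError("adjacent locus spacing implies r >= 0.5")
        hap = np.empty((2 * n, len(loci)), dtype=np.int8)
        hap[:, 0] = rng.random(2 * n) < 0.5
        for j, r in enumerate(r_adj):
            flip = rng.random(2 * n) < r
            hap[:, j + 1] = hap[:, j] ^ flip
        geno = hap[0::2] + hap[1::2]  # (n, n_loci) dosage of seed-parent allele
        pos_index = {p: k for k, p in enumerate(loci)}
        ids = [f"LG{g}M{j + 1:03d}" for j in range(len(marker_pos))]
        for j, p in enumerate(marker_pos):
            marker_rows.append(geno[:, pos_index[p]])
            marker_ids.append(ids[j])
        for p in qtl_pos:
            qtl_geno[(g, p)] = geno[:, pos_index[p]].astype(np.int8)
        groups.append(LinkageGroup(f"LG{g}", ids, np.asarray(marker_pos, float)))
    calls = pd.DataFrame(
        _CODES[np.vstack(marker_rows)], index=marker_ids, columns=_individual_ids(n)
    )
    return SimTruth(calls, GeneticMap(groups), qtl_geno, config)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    lam = np.asarray(mean, dtype=float)
    if dispersion > 0:
        positive = lam > 0
        mixed = np.zeros_like(lam)
        if positive.any():
            mixed[positive] = rng.gamma(
                1.0 / dispersion, lam[positive] * dispersion
            )
        lam = mixed
    return rng.poisson(lam)


def simulate_read_depths(truth: SimTruth, config: SimConfig | None = None) -> DepthMatrix:
    """Amplicon read counts for every marker, individual, and both parents.

    Each marker tracks the allele of one source parent (alternating by
    marker index); an individual's expected depth is the class mean for its
    dosage of that allele times the marker's log-normal scale factor.
    """
    config = config or truth.config
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    dm = config.depth_model
    dosage_a = np.array(
        [[{"B": 0, "H": 1, "A": 2}[c] for c in row] for row in truth.genotypes.to_numpy()],
        dtype=np.int8,
    )
    n_markers = dosage_a.shape[0]
    source = np.where(np.arange(n_markers) % 2 == 0, 1, 2)
    dosage = np.where(source[:, None] == 1, dosage_a, 2 - dosage_a)
    mus = np.array([dm.mu_absent, dm.mu_het, dm.mu_hom])
    scale = np.exp(rng.normal(0.0, dm.per_marker_scale_sd, size=n_markers))
    mean = mus[dosage] * scale[:, None]
    counts = _nb_counts(rng, mean, dm.dispersion)
    p1_dosage = np.where(source == 1, 2, 0)
    p2_dosage = 2 - p1_dosage
    p1 = _nb_counts(rng, mus[p1_dosage] * scale, dm.dispersion)
    p2 = _nb_counts(rng, mus[p2_dosage] * scale, dm.dispersion)
    idx = truth.genotypes.index
    return DepthMatrix(
        counts=pd.DataFrame(counts, index=idx, columns=truth.genotypes.columns),
        parent1_counts=pd.Series(p1, index=idx, name=PARENT1),
        parent2_counts=pd.Series(p2, index=idx, name=PARENT2),
        source_parent=pd.Series(source, index=idx, name="source_parent"),
    )


def simulate_default_calls(
    depths: DepthMatrix,
    truth: SimTruth,
    config: SimConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emulated vendor-caller output: dominant calls and partial co-dominant calls.

    Dominant calls mark presence ('P') when the count reaches the threshold,
    absence ('A') otherwise.  A random ``codominant_fraction`` of markers
    additionally carry three-state calls equal to the true genotype corrupted
    at rate ``error_rate`` (each error drawn uniformly from the two wrong
    codes).
    """
    config = config or truth.config
    rng = np.random.default_rng([config.seed, 2])
    dc = config.default_caller
    present = depths.counts.to_numpy() >= dc.presence_threshold
    dominant = pd.DataFrame(
        np.where(present, "P", "A"), index=depths.counts.index, columns=depths.counts.columns
    )
    n_markers = len(depths.counts)
    n_codom = int(round(dc.codominant_fraction * n_markers))
    chosen = rng.choice(n_markers, size=n_codom, replace=False)
    chosen_ids = depths.counts.index[np.sort(chosen)]
    codes = truth.genotypes.loc[chosen_ids].to_numpy().copy()
    if dc.error_rate > 0 and codes.size:
        flip = rng.random(codes.shape) < dc.error_rate
        alphabet = np.array(["A", "H", "B"])
        for i, j in zip(*np.where(flip)):
            others = alphabet[alphabet != codes[i, j]]
            codes[i, j] = rng.choice(others)
    codominant = pd.DataFrame(codes, index=chosen_ids, columns=truth.genotypes.columns)
    return dominant, codominant


def _genetic_values(
    truth: SimTruth, spec: tuple[QTLEffect, ...], baseline: float
) -> np.ndarray:
    g = np.full(len(truth.individuals), baseline, dtype=float)
    for q in spec:
        dosage = truth.qtl_genotypes[(q.group, q.position)]
        g += np.where(dosage == 2, q.additive, 0.0)
        g += np.where(dosage == 0, -q.additive, 0.0)
        g += np.where(dosage == 1, q.dominance, 0.0)
    return g


def _noise_sd(genetic: np.ndarray, heritability: float, fallback_sd: float) -> float:
    var_g = float(np.var(genetic))
    if heritability == 1.0:
        if var_g == 0:
            raise InvalidConfigError(
                "heritability 1 with zero genetic variance is undefined"
            )
        return 0.0
    if var_g == 0 or heritability == 0.0:
        return fallback_sd
    return float(np.sqrt(var_g * (1.0 - heritability) / heritability))


def simulate_phenotypes(truth: SimTruth, config: SimConfig | None = None) -> PhenotypeTable:
    """Flowering and maturity phenotypes with right-censoring of maturity.

    Phenotype = baseline + QTL effects + Gaussian noise scaled so the
    genetic variance fraction equals the configured heritability.  Maturity
    values past ``censor_day`` are truncated there and flagged censored; the
    uncensored table is stored on ``truth.phenotypes_uncensored``.
    """
    config = config or truth.config
    config.validate()
    rng = np.random.default_rng([config.seed, 3])
    n = len(truth.individuals)
    g_mat = _genetic_values(truth, tuple(config.qtl_spec), config.baseline_maturity)
    g_flo = _genetic_values(
        truth, tuple(config.flowering_qtl_spec), config.baseline_flowering
    )
    maturity = g_mat + rng.normal(
        0.0, _noise_sd(g_mat, config.heritability, config.residual_sd), n
    )
    flowering = g_flo + rng.normal(
        0.0, _noise_sd(g_flo, config.flowering_heritability, config.residual_sd), n
    )
    raw = pd.DataFrame(
        {
            "individual": truth.individuals,
            "flowering_time": flowering,
            "maturity_time": maturity,
            "censored": False,
        }
    )
    truth.phenotypes_uncensored = PhenotypeTable(raw.copy())
    censored = raw["maturity_time"] > config.censor_day
    out = raw.copy()
    out.loc[censored, "maturity_time"] = config.censor_day
    out.loc[censored, "censored"] = True
    return PhenotypeTable(out)


def simulate_morphological_marker(
    truth: SimTruth,
    config: SimConfig | None = None,
    locus: str | None = None,
    name: str = "Flower_type",
) -> pd.Series:
    """Dominant morphological marker (e.g. floral morph) at a designated locus.

    Carriers of the seed-parent allele (AA or AB) show the dominant class
    'D'; the recessive homozygote shows 'R'.  Segregates 3:1 and, sharing
    its locus genotypes with the map, is mappable like any dominant marker.
    """
    config = config or truth.config
    if locus is None:
        locus = truth.genotypes.index[0]
    codes = truth.genotypes.loc[locus]
    out = codes.map(lambda c: "R" if c == "B" else "D")
    out.name = name
    return out


@dataclass
class SimDataset:
    """A complete simulated dataset: truth plus everything the pipeline consumes."""

    truth: SimTruth
    depths: DepthMatrix
    default_dominant: pd.DataFrame
    default_codominant: pd.DataFrame
    phenotypes: PhenotypeTable
    morphological: pd.Series


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Run the full generator under one seed."""
    truth = simulate_f2_genotypes(config)
    depths = simulate_read_depths(truth, config)
    dom, codom = simulate_default_calls(depths, truth, config)
    pheno = simulate_phenotypes(truth, config)
    morph = simulate_morphological_marker(truth, config)
    return SimDataset(truth, depths, dom, codom, pheno, morph)


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """A copy of ``config`` under a different seed."""
    return replace(config, seed=seed)
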