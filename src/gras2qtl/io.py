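"""TSV and YAML interchange for every pipeline artifact.

All tables are tab-separated with a single header row; lines starting with
'#' are metadata comments (the writing seed is recorded there).  Genotype
matrices use the codes A/H/B/- (plus D/R for dominant morphological
markers); dominant call matrices use P/A.  ``write_x`` followed by
``read_x`` is an identity for every format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import DataFormatError
from .linkage import GeneticMap
from .mixture import DepthMatrix
from .simulate import PhenotypeTable

_GENO_ALPHABET = {"A", "H", "B", "-", "D", "R"}
_DOM_ALPHABET = {"P", "A", "-"}


def _read_tsv(path, **kw) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"{path}: file not found")
    try:
        df = pd.read_csv(path, sep="\t", comment="#", **kw)
    except pd.errors.EmptyDataError:
        raise DataFormatError(f"{path}: file is empty") from None
    if df.empty and df.columns.empty:
        raise DataFormatError(f"{path}: no data rows")
    return df


def _header(seed: int | None) -> str:
    return f"# gras2qtl\n# seed={seed}\n" if seed is not None else "# gras2qtl\n"


def _data_line_numbers(path: Path) -> list[int]:
    """1-based file line numbers of non-comment data rows (after the header)."""
    nums = []
    seen_header = False
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            if not seen_header:
                seen_header = True
                continue
            nums.append(i)
    return nums


# -- depth matrix -----------------------------------------------------------


def write_depth_matrix(depths: DepthMatrix, path, seed: int | None = None) -> None:
    df = depths.counts.copy()
    df.insert(0, "source_parent", depths.source_parent)
    df.insert(1, "P1", depths.parent1_counts)
    df.insert(2, "P2", depths.parent2_counts)
    df.index.name = "marker"
    with open(path, "w") as fh:
        fh.write(_header(seed))
        df.to_csv(fh, sep="\t")


def read_depth_matrix(path) -> DepthMatrix:
    df = _read_tsv(path, index_col=0)
    for col in ("source_parent", "P1", "P2"):
        if col not in df.columns:
            raise DataFormatError(f"{path}: missing required column {col!r}")
    counts = df.drop(columns=["source_parent", "P1", "P2"])
    bad = counts[(counts < 0).any(axis=1)]
    if not bad.empty:
        lines = _data_line_numbers(Path(path))
        row = counts.index.get_loc(bad.index[0])
        raise DataFormatError(
            f"{path}:{lines[row]}: negative count at marker {bad.index[0]!r}"
        )
    return DepthMatrix(
        counts=counts,
        parent1_counts=df["P1"],
        parent2_counts=df["P2"],
        source_parent=df["source_parent"].astype(int),
    )


# -- genotype matrices ------------------------------------------------------


def write_genotype_matrix(calls: pd.DataFrame, path, seed: int | None = None) -> None:
    out = calls.copy()
    out.index.name = "marker"
    with open(path, "w") as fh:
        fh.write(_header(seed))
        out.to_csv(fh, sep="\t")


def read_genotype_matrix(path, alphabet: set[str] = _GENO_ALPHABET) -> pd.DataFrame:
    df = _read_tsv(path, index_col=0, dtype=str)
    if df.empty:
        raise DataFormatError(f"{path}: genotype matrix has no markers")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise DataFormatError(f"{path}: duplicate marker id {dup!r}")
    values = df.to_numpy()
    lines = _data_line_numbers(Path(path))
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            if values[i, j] not in alphabet:
                raise DataFormatError(
                    f"{path}:{lines[i]}: illegal genotype code {values[i, j]!r} "
                    f"(marker {df.index[i]!r}, individual {df.columns[j]!r})"
                )
    return df


def read_dominant_matrix(path) -> pd.DataFrame:
    return read_genotype_matrix(path, alphabet=_DOM_ALPHABET)


# -- genetic map ------------------------------------------------------------


def write_map(gmap: GeneticMap, path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed))
        gmap.to_frame().to_csv(fh, sep="\t", index=False)


def read_map(path) -> GeneticMap:
    df = _read_tsv(path)
    required = {"group", "marker", "position_cM"}
    if not required <= set(df.columns):
        raise DataFormatError(f"{path}: map needs columns {sorted(required)}")
    if df["marker"].duplicated().any():
        dup = df.loc[df["marker"].duplicated(), "marker"].iloc[0]
        raise DataFormatError(f"{path}: duplicate marker {dup!r} in map")
    return GeneticMap.from_frame(df)


# -- phenotypes -------------------------------------------------------------


def write_phenotypes(pheno: PhenotypeTable, path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed))
        pheno.frame.to_csv(fh, sep="\t", index=False)


def read_phenotypes(path) -> PhenotypeTable:
    df = _read_tsv(path)
    required = {"individual", "flowering_time", "maturity_time", "censored"}
    if not required <= set(df.columns):
        raise DataFormatError(f"{path}: phenotype table needs {sorted(required)}")
    if df["individual"].duplicated().any():
        dup = df.loc[df["individual"].duplicated(), "individual"].iloc[0]
        raise DataFormatError(f"{path}: duplicate individual {dup!r}")
    df["censored"] = df["censored"].astype(bool)
    return PhenotypeTable(df)


# -- generic tables ---------------------------------------------------------


def write_table(df: pd.DataFrame, path, seed: int | None = None, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed))
        df.to_csv(fh, sep="\t", index=index)


def read_table(path) -> pd.DataFrame:
    return _read_tsv(path)


# -- run configuration ------------------------------------------------------

_KNOWN_SECTIONS = {
    "seed",
    "out_dir",
    "log_level",
    "simulate",
    "call",
    "map",
    "scan",
    "assoc",
}


@dataclass
class RunConfig:
    """Resolved pipeline configuration (unknown keys are rejected on load)."""

    seed: int = 0
    out_dir: str = "gras2qtl_run"
    log_level: str = "INFO"
    simulate: dict = field(default_factory=dict)
    call: dict = field(default_factory=dict)
    map: dict = field(default_factory=dict)
    scan: dict = field(default_factory=dict)
    assoc: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise DataFormatError(f"{path}: config must be a mapping")
        unknown = set(raw) - _KNOWN_SECTIONS
        if unknown:
            raise DataFormatError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "log_level": self.log_level,
            "simulate": self.simulate,
            "call": self.call,
            "map": self.map,
            "scan": self.scan,
            "assoc": self.assoc,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
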