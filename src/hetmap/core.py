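"""Core data containers shared across the pipeline.

Coordinate conventions: all internal interval arithmetic is 0-based,
half-open.  Marker positions (``pos_bp``) are 1-based single-base
coordinates, as in PLINK MAP files; they are converted where interval
logic needs them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # genotype missing code (dosage matrices are int8)

#: default macro-chromosome set for a passerine-like karyotype
DEFAULT_MACRO = frozenset({"1", "1A", "2", "3", "4", "4A", "5", "6", "7"})


@dataclass(frozen=True)
class Chromosome:
    name: str
    length_bp: int
    is_macro: bool

    @property
    def length_mb(self) -> float:
        return self.length_bp / 1e6


@dataclass
class GenomeSpec:
    """Ordered chromosome catalogue anchoring all physical coordinates.

    ``macro_names`` follows the avian convention where a handful of
    large chromosomes (here 1-7 and 1A) are "macro" and the rest are
    small, gene-dense micro-chromosomes.  The Z sex chromosome is
    identified by name.
    """

    chromosomes: list[Chromosome] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for c in self.chromosomes:
            if c.length_bp <= 0:
                raise ValueError(f"chromosome {c.name}: length_bp must be > 0")

    @classmethod
    def from_lengths(
        cls,
        lengths: dict[str, int],
        macro_names: frozenset[str] | set[str] = DEFAULT_MACRO,
    ) -> "GenomeSpec":
        chroms = [
            Chromosome(name, int(length), name in macro_names)
            for name, length in lengths.items()
        ]
        return cls(chroms)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def __getitem__(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.chromosomes)

    def __iter__(self):
        return iter(self.chromosomes)

    def is_autosome(self, name: str) -> bool:
        return name.upper() not in ("Z", "W")

    def autosomes(self) -> list[Chromosome]:
        return [c for c in self.chromosomes if self.is_autosome(c.name)]


class MarkerPanel:
    """Biallelic SNP panel on a fixed physical order.

    Wraps a DataFrame with columns ``id, chrom, pos_bp, allele_freq``;
    within each chromosome positions are strictly increasing.
    """

    COLUMNS = ["id", "chrom", "pos_bp", "allele_freq"]

    def __init__(self, df: pd.DataFrame, genome: GenomeSpec | None = None):
        df = df.reset_index(drop=True)
        missing_cols = set(("id", "chrom", "pos_bp")) - set(df.columns)
        if missing_cols:
            raise ValueError(f"marker table missing columns: {sorted(missing_cols)}")
        if "allele_freq" not in df.columns:
            df = df.assign(allele_freq=np.nan)
        if df["id"].duplicated().any():
            raise ValueError("duplicate marker ids")
        for chrom, sub in df.groupby("chrom", sort=False):
            pos = sub["pos_bp"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"marker positions not strictly increasing on {chrom}")
            if genome is not None and chrom in genome:
                L = genome[chrom].length_bp
                if pos[0] < 1 or pos[-1] > L:
                    raise ValueError(f"marker position outside chromosome {chrom}")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def chrom_index(self, chrom: str) -> np.ndarray:
        """Row indices (into the panel order) of one chromosome's markers."""
        return np.flatnonzero((self.df["chrom"] == chrom).to_numpy())

    def positions(self, chrom: str) -> np.ndarray:
        return self.df.loc[self.df["chrom"] == chrom, "pos_bp"].to_numpy()


class GeneAnnotation:
    """Gene catalogue; ``named=False`` rows mimic annotations lacking a
    recognised gene symbol and are ignored by gene-density counting."""

    COLUMNS = ["id", "chrom", "start_bp", "end_bp", "named"]

    def __init__(self, df: pd.DataFrame, genome: GenomeSpec | None = None):
        df = df.reset_index(drop=True)
        missing_cols = set(self.COLUMNS) - set(df.columns)
        if missing_cols:
            raise ValueError(f"gene table missing columns: {sorted(missing_cols)}")
        if len(df) and not (df["start_bp"] < df["end_bp"]).all():
            raise ValueError("gene start_bp must be < end_bp")
        if genome is not None and len(df):
            for chrom, sub in df.groupby("chrom", sort=False):
                if chrom not in genome:
                    raise ValueError(f"gene on unknown chromosome {chrom}")
                L = genome[chrom].length_bp
                if (sub["start_bp"] < 0).any() or (sub["end_bp"] > L).any():
                    raise ValueError(f"gene outside chromosome {chrom}")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class GenotypeData:
    """Pedigreed genotype matrix.

    genotypes : int8 array (n_samples, n_markers) of alternate-allele
        dosages 0/1/2, with -1 for missing.
    samples : DataFrame with columns fid, iid, father, mother, sex
        ('M'/'F'), where '0' denotes an unknown parent.
    markers : marker table aligned with the genotype columns
        (id, chrom, pos_bp at minimum).
    """

    genotypes: np.ndarray
    samples: pd.DataFrame
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.samples = self.samples.reset_index(drop=True)
        self.markers = self.markers.reset_index(drop=True)
        if self.genotypes.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        if self.samples["iid"].duplicated().any():
            raise ValueError("duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def sample_index(self) -> dict[str, int]:
        return {iid: i for i, iid in enumerate(self.samples["iid"])}

    def is_founder(self) -> np.ndarray:
        """Founders are samples whose parents are both outside the dataset."""
        ids = set(self.samples["iid"])
        father_in = self.samples["father"].isin(ids)
        mother_in = self.samples["mother"].isin(ids)
        return ~(father_in | mother_in).to_numpy()

    def subset(self, sample_mask=None, marker_mask=None) -> "GenotypeData":
        g = self.genotypes
        s = self.samples
        m = self.markers
        if sample_mask is not None:
            g = g[sample_mask, :]
            s = s.loc[sample_mask]
        if marker_mask is not None:
            g = g[:, marker_mask]
            m = m.loc[marker_mask]
        return GenotypeData(g.copy(), s.reset_index(drop=True), m.reset_index(drop=True))


# column schema for sex-specific linkage maps exchanged between stages
SEXMAP_COLUMNS = ["chrom", "marker", "pos_bp", "cM_avg", "cM_female", "cM_male"]


def validate_sexmap(df: pd.DataFrame) -> pd.DataFrame:
    """Check the SexMap invariants: schema, 0 at first marker, monotone cM."""
    missing = set(SEXMAP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sex map missing columns: {sorted(missing)}")
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["pos_bp"].to_numpy()
        if not np.all(np.diff(pos) > 0):
            raise ValueError(f"{chrom}: pos_bp not strictly increasing")
        for col in ("cM_avg", "cM_female", "cM_male"):
            cm = sub[col].to_numpy(dtype=float)
            if cm[0] != 0:
                raise ValueError(f"{chrom}: {col} does not start at 0")
            if np.any(np.diff(cm) < -1e-9):
                raise ValueError(f"{chrom}: {col} not non-decreasing")
    return df
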