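"""Core data model for mixed-ploidy microsatellite and AFLP datasets.

The unisexual *Ambystoma laterale*–*jeffersonianum* complex combines haplomes
(haploid chromosome sets) of two species — L (*A. laterale*) and
J (*A. jeffersonianum*) — in individuals of different ploidy (LL hosts and
LJ / LLJ / LLLJ unisexuals).  A microsatellite genotype is therefore a
multiset of allele sizes whose multiplicities may be unresolved (dominance in
"partial heterozygotes": an AAB triploid and an ABB triploid are both scored
AB).  The classes below carry exactly that structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MAX_PLOIDY = 4

BIOTYPES = ("LL", "LJ", "LLJ", "LLLJ", "UNCALLED")
GROUPS = ("A", "B", "C", "D", "E", "X", "UNASSIGNED")

#: L- and J-haplome dose for each called biotype.
BIOTYPE_DOSE: dict[str, tuple[int, int]] = {
    "LL": (2, 0),
    "LJ": (1, 1),
    "LLJ": (2, 1),
    "LLLJ": (3, 1),
}


class KleptopopError(ValueError):
    """Domain validation failure."""


@dataclass(frozen=True)
class LocusDef:
    """Definition of one microsatellite locus.

    Parameters
    ----------
    name : str
        Locus identifier (e.g. ``"AmaD42"``).
    motif_length : int
        Length of the repeat motif in bp; mutation "steps" are counted in
        units of this length.
    j_range, l_range : tuple of (int, int) or None
        Closed allele-size intervals (bp) diagnostic of the J and L haplome.
        ``None`` means the species does not amplify, or sizes overlap.
    u_range : tuple of (int, int) or None
        Overall allele-size interval for non-discriminating loci (used as the
        mutation reflection bound by the simulator).
    """

    name: str
    motif_length: int
    j_range: tuple[int, int] | None = None
    l_range: tuple[int, int] | None = None
    u_range: tuple[int, int] | None = None

    def __post_init__(self):
        if self.motif_length < 1:
            raise KleptopopError(f"{self.name}: motif_length must be >= 1")
        for rng in (self.j_range, self.l_range, self.u_range):
            if rng is not None and rng[0] > rng[1]:
                raise KleptopopError(f"{self.name}: empty allele-size range {rng}")
        if self.j_range is not None and self.l_range is not None:
            lo = max(self.j_range[0], self.l_range[0])
            hi = min(self.j_range[1], self.l_range[1])
            if lo <= hi:
                raise KleptopopError(
                    f"{self.name}: j_range and l_range overlap on [{lo}, {hi}]"
                )

    @property
    def discriminating(self) -> bool:
        """True iff alleles can be assigned to a haplome by size."""
        return self.j_range is not None or self.l_range is not None


@dataclass(frozen=True)
class MultisetGenotype:
    """Observed alleles of one individual at one locus.

    ``observed_alleles`` are the *distinct* allele sizes (bp), sorted.  The
    true copy number may exceed their count (partial heterozygote); it is
    ``None`` when unresolved.
    """

    locus: str
    observed_alleles: tuple[int, ...] = ()
    copy_number: int | None = None

    def __post_init__(self):
        alleles = tuple(sorted(set(int(a) for a in self.observed_alleles)))
        if any(a < 0 for a in alleles):
            raise KleptopopError(f"{self.locus}: negative allele size")
        object.__setattr__(self, "observed_alleles", alleles)
        if self.copy_number is not None and self.copy_number < len(alleles):
            raise KleptopopError(
                f"{self.locus}: copy_number {self.copy_number} < "
                f"{len(alleles)} distinct alleles"
            )

    @property
    def is_missing(self) -> bool:
        return len(self.observed_alleles) == 0


@dataclass
class IndividualRecord:
    """One sampled salamander: genotypes plus pipeline outputs."""

    id: str
    site: str
    genotypes: dict[str, MultisetGenotype] = field(default_factory=dict)
    mtdna_unisexual: bool | None = None
    biotype: str = "UNCALLED"
    group: str = "UNASSIGNED"
    #: isolocus name -> distinct alleles, filled by split_isoloci
    isoloci: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def copy(self) -> "IndividualRecord":
        out = replace(self)
        out.genotypes = dict(self.genotypes)
        out.isoloci = dict(self.isoloci)
        return out


@dataclass
class Dataset:
    """A collection of individuals genotyped at a shared locus panel."""

    individuals: list[IndividualRecord]
    loci: list[LocusDef]
    sites: pd.DataFrame | None = None  # columns: site, latitude, longitude

    def __post_init__(self):
        ids = [ind.id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise KleptopopError(f"duplicate individual ids: {dup}")
        known = {l.name for l in self.loci}
        for ind in self.individuals:
            unknown = set(ind.genotypes) - known
            if unknown:
                raise KleptopopError(
                    f"individual {ind.id}: genotypes at undeclared loci {sorted(unknown)}"
                )
        self._warn_sparse_loci()
        self._check_max_ploidy()

    def _warn_sparse_loci(self):
        n = len(self.individuals)
        if n == 0:
            return
        for locus in self.loci:
            missing = sum(
                1
                for ind in self.individuals
                if locus.name not in ind.genotypes
                or ind.genotypes[locus.name].is_missing
            )
            if missing / n > 0.5:
                warnings.warn(
                    f"locus {locus.name} missing in {missing}/{n} individuals",
                    stacklevel=3,
                )

    def _check_max_ploidy(self):
        for ind in self.individuals:
            for locus in self.loci:
                g = ind.genotypes.get(locus.name)
                if g is None or not locus.discriminating:
                    continue
                if len(g.observed_alleles) > MAX_PLOIDY:
                    raise KleptopopError(
                        f"individual {ind.id}, locus {locus.name}: "
                        f"{len(g.observed_alleles)} alleles exceeds max ploidy "
                        f"{MAX_PLOIDY}"
                    )

    @property
    def locus_map(self) -> dict[str, LocusDef]:
        return {l.name: l for l in self.loci}

    def by_id(self, ind_id: str) -> IndividualRecord:
        for ind in self.individuals:
            if ind.id == ind_id:
                return ind
        raise KeyError(ind_id)


@dataclass
class AflpMatrix:
    """AFLP presence/absence scores: individuals x bands, binary."""

    individuals: list[str]
    bands: list[str]
    presence: np.ndarray

    def __post_init__(self):
        self.presence = np.asarray(self.presence)
        if self.presence.shape != (len(self.individuals), len(self.bands)):
            raise KleptopopError(
                f"AFLP matrix shape {self.presence.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.bands)} bands"
            )
        if not np.isin(self.presence, (0, 1)).all():
            raise KleptopopError("AFLP matrix entries must be 0 or 1")
        self.presence = self.presence.astype(np.int8)


class DistanceMatrix:
    """Symmetric pairwise dissimilarity matrix with individual labels."""

    def __init__(self, labels, values, check: bool = True):
        self.labels = list(labels)
        self.values = np.asarray(values, dtype=float)
        if check:
            n = len(self.labels)
            if self.values.shape != (n, n):
                raise KleptopopError("distance matrix shape does not match labels")
            if not np.allclose(self.values, self.values.T, atol=1e-10):
                raise KleptopopError("distance matrix is not symmetric")
            if not np.allclose(np.diag(self.values), 0, atol=1e-10):
                raise KleptopopError("distance matrix diagonal is not zero")
            if (self.values < -1e-10).any():
                raise KleptopopError("negative dissimilarities")
            self.values = (self.values + self.values.T) / 2
            np.fill_diagonal(self.values, 0.0)

    def __len__(self):
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy ``squareform`` order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def submatrix(self, labels) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels, self.values[np.ix_(idx, idx)], check=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DistanceMatrix":
        return cls(list(df.index), df.to_numpy(dtype=float))
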