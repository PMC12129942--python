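"""Core in-memory containers shared by every pipeline stage.

The pipeline moves four kinds of data around: diploid SNP dosages
(individuals x biallelic sites), ancestry-coefficient matrices
(individuals x K gene pools), mixed quantitative/qualitative trait
tables, and the sample -> population -> taxon bookkeeping that ties
genetic and morphological observations to named taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel for an unobserved diploid dosage.
MISSING: int = -9

SPECIES = "species"
INFRASPECIFIC = "infraspecific"


@dataclass(frozen=True)
class Site:
    """A biallelic SNP site (1-based VCF coordinates)."""

    chrom: str
    pos: int
    ref: str = "A"
    alt: str = "T"


class GenotypeMatrix:
    """Individuals x biallelic sites, dosage-coded 0/1/2 with ``MISSING``.

    Dosage is the count of alternate alleles of a diploid genotype.
    Site order follows input order and must be positionally sorted
    within each chromosome.
    """

    def __init__(self, samples: Sequence[str], sites: Sequence[Site],
                 dosages: np.ndarray):
        samples = list(samples)
        sites = list(sites)
        dosages = np.asarray(dosages, dtype=np.int16)
        if dosages.shape != (len(samples), len(sites)):
            raise ValueError(
                f"dosage shape {dosages.shape} does not match "
                f"{len(samples)} samples x {len(sites)} sites")
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample identifiers")
        valid = (dosages == MISSING) | ((dosages >= 0) & (dosages <= 2))
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ValueError(
                f"dosage out of {{0,1,2,MISSING}} at sample "
                f"{samples[bad[0]]!r}, site index {bad[1]}")
        last: dict[str, int] = {}
        for s in sites:
            if s.chrom in last and s.pos <= last[s.chrom]:
                raise ValueError(
                    f"site positions not strictly increasing on {s.chrom} "
                    f"at {s.pos}")
            last[s.chrom] = s.pos
        self.samples = samples
        self.sites = sites
        self.dosages = dosages

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def take_sites(self, index: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(self.samples,
                              [self.sites[i] for i in index],
                              self.dosages[:, index])

    def take_samples(self, keep: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in keep]
        return GenotypeMatrix(list(keep), self.sites, self.dosages[idx, :])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<GenotypeMatrix {self.n_samples} samples x "
                f"{self.n_sites} sites>")


class AncestryMatrix:
    """Per-individual ancestry fractions over K gene pools (rows sum to 1)."""

    ROW_SUM_TOL = 1e-6

    def __init__(self, samples: Sequence[str], q: np.ndarray,
                 meta: Mapping[str, object] | None = None):
        samples = list(samples)
        q = np.asarray(q, dtype=float)
        if q.ndim != 2 or q.shape[0] != len(samples):
            raise ValueError("q must be (n_samples, K)")
        if (q < -1e-12).any() or (q > 1 + 1e-12).any():
            raise ValueError("ancestry fractions outside [0, 1]")
        sums = q.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=self.ROW_SUM_TOL):
            i = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(
                f"q row for sample {samples[i]!r} sums to {sums[i]:.6f}")
        self.samples = samples
        self.q = q
        self.meta = dict(meta or {})

    @property
    def K(self) -> int:
        return self.q.shape[1]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<AncestryMatrix {len(self.samples)} samples, K={self.K}>"


@dataclass
class SampleMap:
    """Sample -> population -> taxon assignment table.

    Every sample belongs to exactly one population and every population
    to exactly one taxon; taxa carry a rank (``species`` or
    ``infraspecific``) and an optional series label.
    """

    table: pd.DataFrame

    REQUIRED = ("sample", "population", "taxon", "rank")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"sample map missing column {col!r}")
        if self.table["sample"].duplicated().any():
            dup = self.table.loc[self.table["sample"].duplicated(), "sample"]
            raise ValueError(f"duplicate sample id {dup.iloc[0]!r}")
        pops = self.table.groupby("population")["taxon"].nunique()
        if (pops > 1).any():
            bad = pops[pops > 1].index[0]
            raise ValueError(
                f"population {bad!r} maps to more than one taxon")
        bad_rank = set(self.table["rank"]) - {SPECIES, INFRASPECIFIC}
        if bad_rank:
            raise ValueError(f"unknown rank(s) {sorted(bad_rank)}")

    @classmethod
    def from_records(cls, rows: Iterable[tuple]) -> "SampleMap":
        cols = ["sample", "population", "taxon", "rank", "series"]
        rows = [tuple(r) + (None,) * (5 - len(r)) for r in rows]
        return cls(pd.DataFrame(rows, columns=cols))

    @property
    def taxa(self) -> list[str]:
        return list(dict.fromkeys(self.table["taxon"]))

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.table["population"]))

    def taxon_of_sample(self) -> dict[str, str]:
        return dict(zip(self.table["sample"], self.table["taxon"]))

    def taxon_of_population(self) -> dict[str, str]:
        sub = self.table.drop_duplicates("population")
        return dict(zip(sub["population"], sub["taxon"]))

    def rank_of_taxon(self) -> dict[str, str]:
        sub = self.table.drop_duplicates("taxon")
        return dict(zip(sub["taxon"], sub["rank"]))

    def samples_of_taxon(self, taxon: str) -> list[str]:
        return list(self.table.loc[self.table["taxon"] == taxon, "sample"])

    def populations_of_taxon(self, taxon: str) -> list[str]:
        sub = self.table.loc[self.table["taxon"] == taxon]
        return list(dict.fromkeys(sub["population"]))

    def restrict_to_taxa(self, taxa: Iterable[str]) -> "SampleMap":
        keep = self.table["taxon"].isin(set(taxa))
        return SampleMap(self.table.loc[keep].reset_index(drop=True))


QUANTITATIVE = "quantitative"
QUALITATIVE = "qualitative"


@dataclass(frozen=True)
class Trait:
    """Schema entry for one trait column.

    ``unit`` documents the unit of measure of a quantitative trait;
    ``states`` is the declared integer state set of a qualitative one.
    """

    name: str
    kind: str
    unit: str | None = None
    states: frozenset[int] | None = None

    def __post_init__(self) -> None:
        if self.kind not in (QUANTITATIVE, QUALITATIVE):
            raise ValueError(f"unknown trait kind {self.kind!r}")


class TraitTable:
    """Operational units x traits with typed columns and NaN for missing."""

    def __init__(self, values: pd.DataFrame, traits: Sequence[Trait]):
        traits = list(traits)
        names = [t.name for t in traits]
        if list(values.columns) != names:
            raise ValueError("trait schema does not match value columns")
        values = values.astype(float)
        for t in traits:
            col = values[t.name]
            obs = col.dropna()
            if t.kind == QUANTITATIVE and not np.isfinite(obs).all():
                raise ValueError(f"non-finite value in quantitative {t.name!r}")
            if t.kind == QUALITATIVE:
                if not (obs == obs.round()).all():
                    raise ValueError(
                        f"non-integer state in qualitative {t.name!r}")
                if t.states is not None:
                    bad = set(obs.astype(int)) - set(t.states)
                    if bad:
                        raise ValueError(
                            f"state(s) {sorted(bad)} of {t.name!r} outside "
                            f"declared set")
        self.values = values
        self.traits = traits
        self.schema = {t.name: t for t in traits}

    @property
    def units(self) -> list[str]:
        return list(self.values.index)

    def subset_traits(self, names: Sequence[str]) -> "TraitTable":
        return TraitTable(self.values[list(names)],
                          [self.schema[n] for n in names])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<TraitTable {len(self.values)} units x "
                f"{len(self.traits)} traits>")


@dataclass
class CladeMap:
    """Population -> backbone clade label (populations may be unassigned)."""

    assignments: dict[str, str] = field(default_factory=dict)

    def labels(self) -> list[str]:
        return sorted(set(self.assignments.values()))

    def restrict(self, populations: Iterable[str]) -> "CladeMap":
        keep = set(populations)
        return CladeMap({p: c for p, c in self.assignments.items()
                         if p in keep})
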