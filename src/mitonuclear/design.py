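"""Factorial mtDNA x nuclear strain-collection design.

A cybrid collection crosses every nuclear background with every mitochondrial
haplotype (mitotype) from a panel of parental isolates.  A panel of k parental
strains yields k^2 mitonuclear genotypes, k of which are the original
(coadapted) pairings.  Pairwise mtDNA exchanges between non-mosaic parental
strains are classified as within- or between-clade, which is the unit of the
downstream epistasis comparison.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

MOSAIC = "mosaic"

PANEL_COLUMNS = ["strain_id", "nuclear_id", "mitotype_id", "clade", "source_niche"]


class DesignError(ValueError):
    """Raised when a strain panel or fitness table violates the factorial design."""


@dataclass(frozen=True)
class Strain:
    """One parental isolate: its own nucleus paired with its own mtDNA."""

    strain_id: str
    nuclear_id: str
    mitotype_id: str
    clade: str
    source_niche: str = ""

    @property
    def is_mosaic(self) -> bool:
        return self.clade == MOSAIC


@dataclass(frozen=True)
class MitonuclearGenotype:
    """One nuclear background paired with one mitotype."""

    nuclear_id: str
    mitotype_id: str

    @property
    def is_original(self) -> bool:
        return self.nuclear_id == self.mitotype_id


@dataclass(frozen=True)
class ExchangePair:
    """An unordered pair of parental strains whose mtDNAs are swapped."""

    strain_i: str
    strain_j: str
    scope: str  # "within_clade" | "between_clade"

    def __post_init__(self):
        if self.strain_i == self.strain_j:
            raise DesignError("an exchange needs two distinct strains")
        # canonical ordering so (i, j) == (j, i)
        if self.strain_i > self.strain_j:
            i, j = self.strain_i, self.strain_j
            object.__setattr__(self, "strain_i", j)
            object.__setattr__(self, "strain_j", i)


@dataclass
class StrainPanel:
    """The parental isolates plus the reference strain used for normalization."""

    strains: list[Strain]
    reference_strain_id: str = "DAU2"

    def __post_init__(self):
        ids = [s.strain_id for s in self.strains]
        if len(set(ids)) != len(ids):
            raise DesignError("duplicate strain_id in panel")
        for s in self.strains:
            if not (s.nuclear_id == s.mitotype_id == s.strain_id):
                raise DesignError(
                    f"parental strain {s.strain_id!r} must satisfy "
                    "nuclear_id == mitotype_id == strain_id"
                )

    def __len__(self) -> int:
        return len(self.strains)

    @property
    def strain_ids(self) -> list[str]:
        return [s.strain_id for s in self.strains]

    @property
    def non_mosaic(self) -> list[Strain]:
        return [s for s in self.strains if not s.is_mosaic]

    def clade_of(self, strain_id: str) -> str:
        for s in self.strains:
            if s.strain_id == strain_id:
                return s.clade
        raise KeyError(strain_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.strain_id, s.nuclear_id, s.mitotype_id, s.clade, s.source_niche) for s in self.strains],
            columns=PANEL_COLUMNS,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, reference_strain_id: str = "DAU2") -> "StrainPanel":
        missing = set(PANEL_COLUMNS[:4]) - set(df.columns)
        if missing:
            raise DesignError(f"panel table missing columns: {sorted(missing)}")
        strains = [
            Strain(
                strain_id=str(r.strain_id),
                nuclear_id=str(r.nuclear_id),
                mitotype_id=str(r.mitotype_id),
                clade=str(r.clade),
                source_niche=str(getattr(r, "source_niche", "")),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(strains=strains, reference_strain_id=reference_strain_id)

    @classmethod
    def from_tsv(cls, path, reference_strain_id: str = "DAU2") -> "StrainPanel":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        return cls.from_frame(df, reference_strain_id=reference_strain_id)


def _parental(strain_id: str, clade: str, niche: str) -> Strain:
    return Strain(strain_id, strain_id, strain_id, clade, niche)


def example_panel() -> StrainPanel:
    """A 15-isolate S. cerevisiae panel spanning the major population clades.

    Composition: 5 mosaic, 5 wine/European, 3 West African, 1 Sake and
    1 North American isolate, with niches ranging from vineyard fermentations
    to oak exudate and the laboratory.  Strain names follow the public SGRP
    haploid derivatives commonly used in population surveys.
    """
    return StrainPanel(
        strains=[
            _parental("BC187", "wine/European", "fermentation"),
            _parental("L-1528", "wine/European", "fermentation"),
            _parental("DBVPG1373", "wine/European", "soil"),
            _parental("YJM975", "wine/European", "clinical"),
            _parental("YJM981", "wine/European", "clinical"),
            _parental("DBVPG6044", "West African", "fermentation"),
            _parental("NCYC110", "West African", "fermentation"),
            _parental("SK1", "West African", "lab"),
            _parental("Y12", "Sake", "fermentation"),
            _parental("YPS606", "North American", "oak"),
            _parental("W303", MOSAIC, "lab"),
            _parental("YIIc17_E5", MOSAIC, "fermentation"),
            _parental("273614N", MOSAIC, "clinical"),
            _parental("322136S", MOSAIC, "clinical"),
            _parental("YS2", MOSAIC, "baking"),
        ],
        reference_strain_id="DAU2",
    )


def enumerate_genotypes(panel: StrainPanel) -> list[MitonuclearGenotype]:
    """Full factorial nuclear x mitotype set: k^2 genotypes, k of them original."""
    if len(panel) == 0:
        raise DesignError("cannot enumerate genotypes of an empty panel")
    ids = panel.strain_ids
    return [MitonuclearGenotype(n, m) for n in ids for m in ids]


def count_clade_exchanges(
    panel: StrainPanel, exclude: tuple[str, ...] = ()
) -> tuple[int, int, list[ExchangePair]]:
    """Enumerate pairwise mtDNA exchanges among non-mosaic strains.

    Mosaic-lineage strains have no single clade assignment and are excluded;
    `exclude` drops additional strains (e.g. isolates never phenotyped).
    Returns (within-clade count, between-clade count, pairs).
    """
    eligible = [s for s in panel.non_mosaic if s.strain_id not in exclude]
    if len(eligible) < 2:
        raise DesignError("need at least 2 non-mosaic strains to enumerate exchanges")
    pairs = []
    for a, b in itertools.combinations(eligible, 2):
        scope = "within_clade" if a.clade == b.clade else "between_clade"
        pairs.append(ExchangePair(a.strain_id, b.strain_id, scope))
    within = sum(p.scope == "within_clade" for p in pairs)
    return within, len(pairs) - within, pairs


@dataclass
class DesignReport:
    """Replicate accounting for a fitness table against the factorial design."""

    balanced: bool
    n_genotypes_expected: int
    n_missing_cells: int
    missing_cells: list[tuple[str, str, str]]  # (nuclear, mitotype, environment)
    replicate_counts: pd.DataFrame  # nuclear_id, mitotype_id, environment_id, n_reps
    max_replicate_spread: int


def validate_design(fitness: pd.DataFrame, panel: StrainPanel) -> DesignReport:
    """Check a fitness table covers the factorial and count replicates per cell.

    A design is balanced when, within each environment, every genotype carries
    the same number of replicate fitness values.
    """
    genotypes = {(g.nuclear_id, g.mitotype_id) for g in enumerate_genotypes(panel)}
    observed = set(zip(fitness["nuclear_id"], fitness["mitotype_id"]))
    offenders = sorted(observed - genotypes)
    if offenders:
        raise DesignError(f"fitness table contains genotypes outside the factorial: {offenders}")

    counts = (
        fitness.groupby(["nuclear_id", "mitotype_id", "environment_id"], sort=True)
        .size()
        .rename("n_reps")
        .reset_index()
    )
    envs = sorted(fitness["environment_id"].unique())
    missing = [
        (n, m, e)
        for e in envs
        for (n, m) in sorted(genotypes)
        if (n, m) not in set(
            zip(
                counts.loc[counts.environment_id == e, "nuclear_id"],
                counts.loc[counts.environment_id == e, "mitotype_id"],
            )
        )
    ]
    spread = 0
    balanced = not missing
    for _, env_counts in counts.groupby("environment_id"):
        s = int(env_counts.n_reps.max() - env_counts.n_reps.min())
        spread = max(spread, s)
        if s > 0:
            balanced = False
    return DesignReport(
        balanced=balanced,
        n_genotypes_expected=len(genotypes),
        n_missing_cells=len(missing),
        missing_cells=missing,
        replicate_counts=counts,
        max_replicate_spread=spread,
    )
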