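"""Mitochondrial SNP extraction, nucleotide diversity, and phenotype association.

Works from a gapped multi-FASTA alignment of mitochondrial coding sequences,
one record per mitotype.  Polymorphic columns become factor-coded SNPs
(allele numbering is arbitrary); nucleotide diversity pi is the average
per-site pairwise difference with pairwise gap deletion.  Association tests
regress a per-mitotype phenotype on each SNP as an unordered factor — a
one-way fixed-effect ANOVA — with a Bonferroni family threshold alpha/m.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats

GAP_CHARS = frozenset("-.")

LOW_POWER_N = 20  # below this many strains, flag association tests as low power


class AlignmentError(ValueError):
    pass


class AssociationError(ValueError):
    pass


@dataclass
class SnpTable:
    """Factor-coded polymorphic sites: alleles x strains."""

    positions: np.ndarray  # 1-based alignment positions
    alleles: np.ndarray  # (n_sites, n_strains) integer codes
    mitotype_ids: list[str]
    genes: list[str] | None = None

    def __len__(self) -> int:
        return len(self.positions)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.alleles.T, index=self.mitotype_ids, columns=self.positions)
        df.index.name = "mitotype_id"
        return df


def read_alignment(path) -> dict[str, str]:
    """Read a gapped multi-FASTA alignment keyed by record id (mitotype)."""
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise AlignmentError(f"duplicate mitotype id {rec.id!r} in alignment")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise AlignmentError(f"no sequences found in {path}")
    return seqs


def _alignment_matrix(seqs: dict[str, str]):
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise AlignmentError(f"aligned sequences differ in length: {sorted(lengths)}")
    ids = list(seqs)
    mat = np.array([list(seqs[i].upper()) for i in ids])
    return ids, mat


def snps_from_alignment(seqs: dict[str, str], gap_policy: str = "drop") -> SnpTable:
    """Extract polymorphic columns as factor-coded SNPs.

    gap_policy 'drop' excludes any column containing a gap character (the
    default, conservative reading); 'as_allele' keeps such columns and treats
    the gap as one more allele class.
    """
    ids, mat = _alignment_matrix(seqs)
    if gap_policy not in ("drop", "as_allele"):
        raise ValueError("gap_policy must be 'drop' or 'as_allele'")
    positions, codes = [], []
    for col in range(mat.shape[1]):
        column = mat[:, col]
        has_gap = np.isin(column, list(GAP_CHARS))
        if has_gap.all():
            continue
        if gap_policy == "drop" and has_gap.any():
            continue
        uniq, coded = np.unique(column, return_inverse=True)
        if len(uniq) < 2:
            continue
        positions.append(col + 1)
        codes.append(coded)
    return SnpTable(
        positions=np.asarray(positions, dtype=int),
        alleles=np.asarray(codes, dtype=int).reshape(len(positions), len(ids)),
        mitotype_ids=ids,
    )


def nucleotide_diversity(seqs: dict[str, str]) -> float:
    """Average pairwise per-site difference (pi), gaps excluded pairwise.

    For each sequence pair, the proportion of differing sites among sites
    where neither sequence has a gap; pi is the mean over all pairs.
    """
    ids, mat = _alignment_matrix(seqs)
    if len(ids) < 2:
        raise ValueError("nucleotide diversity needs at least 2 sequences")
    is_gap = np.isin(mat, list(GAP_CHARS))
    total = 0.0
    n_pairs = 0
    for i, j in itertools.combinations(range(len(ids)), 2):
        valid = ~(is_gap[i] | is_gap[j])
        n_valid = int(valid.sum())
        if n_valid == 0:
            continue
        diffs = int(np.sum(mat[i, valid] != mat[j, valid]))
        total += diffs / n_valid
        n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no comparable (gap-free) site pairs in the alignment")
    return total / n_pairs


@dataclass
class AssociationResult:
    table: pd.DataFrame  # position, statistic, p, significant, n_classes
    m: int  # number of tests performed
    alpha: float
    bonferroni_threshold: float
    n_skipped: int

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def associate(
    snps: SnpTable,
    phenotypes: pd.Series | dict,
    alpha: float = 0.05,
    min_class_size: int = 2,
) -> AssociationResult:
    """Per-SNP one-way ANOVA of phenotype on allele class, Bonferroni-controlled.

    `phenotypes` maps mitotype_id -> one phenotype value (typically the
    genotype mean fitness within the environment of interest).  SNPs without
    at least two allele classes of `min_class_size` strains are skipped and
    do not count toward the Bonferroni m.
    """
    pheno = pd.Series(phenotypes, dtype=float)
    missing = [s for s in snps.mitotype_ids if s not in pheno.index]
    if missing:
        raise AssociationError(f"phenotype missing for mitotypes: {missing}")
    y = pheno.loc[snps.mitotype_ids].to_numpy()
    if len(y) < LOW_POWER_N:
        warnings.warn(
            f"association with only {len(y)} strains has low power; "
            "null results are weak evidence of absence",
            stacklevel=2,
        )

    rows, n_skipped = [], 0
    for pos, alleles in zip(snps.positions, snps.alleles):
        groups = [y[alleles == a] for a in np.unique(alleles)]
        groups = [g for g in groups if len(g) >= min_class_size]
        if len(groups) < 2:
            n_skipped += 1
            continue
        if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
            stat, p = 0.0, 1.0  # zero variance everywhere
        else:
            stat, p = stats.f_oneway(*groups)
        rows.append((int(pos), float(stat), float(p), len(groups)))

    if not rows:
        raise AssociationError("no testable SNPs (all skipped)")
    m = len(rows)
    threshold = alpha / m
    table = pd.DataFrame(rows, columns=["position", "statistic", "p", "n_classes"])
    table["bonferroni_threshold"] = threshold
    table["significant"] = table["p"] < threshold
    return AssociationResult(table, m, alpha, threshold, n_skipped)
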