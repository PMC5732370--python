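"""Genotype tables and centred allele-frequency matrices.

The analysis operates on a table of allele frequencies per analysis unit
(diploid individuals carrying 0/1/2 copies of the counted allele, or
populations carrying frequencies in [0, 1]), centred so every column has
mean zero.  The centred matrix is the ``X`` of the spatial PCA
eigen-problem.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeTable",
    "CentredFreqMatrix",
    "read_genotypes",
    "centre_frequencies",
    "population_frequencies",
]


class ValidationError(ValueError):
    """Input fails a documented precondition."""


class ParseError(ValueError):
    """A cell or record of an input file could not be interpreted."""


@dataclass
class GenotypeTable:
    """Allele counts (or frequencies) per analysis unit and locus.

    ``ploidy`` is 2 for diploid individual dosages in {0, 1, 2} and 1 for
    population-level allele frequencies in [0, 1]; the per-unit allele
    frequency used downstream is ``dosages / ploidy``.
    """

    unit_ids: list[str]
    dosages: np.ndarray  # (n, m)
    locus_ids: list[str]
    ploidy: int = 2

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValidationError("dosages must be a 2-D array")
        n, m = self.dosages.shape
        if len(self.unit_ids) != n or len(self.locus_ids) != m:
            raise ValidationError("unit_ids/locus_ids do not match dosage shape")
        if len(set(self.unit_ids)) != n:
            raise ValidationError("unit_ids contain duplicates or blanks")
        if not np.all(np.isfinite(self.dosages)):
            raise ValidationError("dosages contain missing or non-finite values")
        if self.ploidy == 2:
            # mean-imputed cells are fractional by design; only reject
            # values outside the admissible dosage range
            if np.any((self.dosages < 0) | (self.dosages > 2)):
                raise ValidationError("diploid dosages must lie in [0, 2]")
        elif self.ploidy == 1:
            if np.any((self.dosages < 0) | (self.dosages > 1)):
                raise ValidationError("frequencies must lie in [0, 1]")
        else:
            raise ValidationError("ploidy must be 1 or 2")

    @property
    def n_units(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    @property
    def frequencies(self) -> np.ndarray:
        """Per-unit allele frequencies in [0, 1]."""
        return self.dosages / self.ploidy

    @property
    def monomorphic_mask(self) -> np.ndarray:
        """Boolean mask of loci with a single observed state across units."""
        return np.ptp(self.dosages, axis=0) == 0


@dataclass
class CentredFreqMatrix:
    """Column-centred allele-frequency matrix; monomorphic columns removed."""

    X: np.ndarray  # (n, p)
    unit_ids: list[str]
    column_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        n, p = self.X.shape
        if n < 3:
            raise ValidationError("at least 3 analysis units are required")
        if len(self.unit_ids) != n or len(self.column_ids) != p:
            raise ValidationError("ids do not match matrix shape")
        colmeans = self.X.mean(axis=0)
        if p and np.max(np.abs(colmeans)) > 1e-10:
            raise ValidationError("columns are not centred (|mean| > 1e-10)")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


# ---------------------------------------------------------------------------
# reading


def _read_dosage_csv(path: Path, impute_mean: bool) -> GenotypeTable:
    df = pd.read_csv(path, index_col=0)
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no locus columns found")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna() & (df[col].astype(str).str.upper() != "NA")
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(f"{path}: non-numeric dosage at unit {row!r}, locus {col!r}")
        values[:, j] = parsed.to_numpy(dtype=float)
    if np.isnan(values).any():
        if not impute_mean:
            i, j = np.argwhere(np.isnan(values))[0]
            raise ParseError(
                f"{path}: missing dosage at unit {df.index[i]!r}, locus "
                f"{df.columns[j]!r} (use mean imputation to fill)"
            )
        colmeans = np.nanmean(values, axis=0)
        idx = np.where(np.isnan(values))
        values[idx] = colmeans[idx[1]]
    return GenotypeTable(
        unit_ids=[str(u) for u in df.index],
        dosages=values,
        locus_ids=[str(c) for c in df.columns],
    )


def _read_vcf(path: Path) -> GenotypeTable:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    loci: list[str] = []
    rows: list[np.ndarray] = []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            skipped += 1
            continue
        # ALT-allele dosage per sample; missing genotypes are not supported
        gts = np.asarray(var.genotype.array())[:, :2]
        if np.any(gts < 0):
            raise ParseError(f"{path}: missing genotype at {var.CHROM}:{var.POS}")
        rows.append(gts.sum(axis=1).astype(float))
        loci.append(f"{var.CHROM}:{var.POS}")
    if skipped:
        logger.warning("%s: skipped %d non-biallelic/non-SNP site(s)", path, skipped)
    if not loci:
        raise ValidationError(f"{path}: no biallelic SNPs found")
    return GenotypeTable(unit_ids=samples, dosages=np.column_stack(rows), locus_ids=loci)


def read_genotypes(
    path: str | Path,
    format: str = "dosage_csv",
    impute_mean: bool = False,
) -> GenotypeTable:
    """Read a genotype table from a dosage CSV or a VCF file.

    The dosage CSV has a header row of locus ids and a first column of unit
    ids.  In VCF input only biallelic SNPs are retained (others skipped with
    a warning) and the counted allele is ALT.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"genotype file not found: {path}")
    if format in ("dosage_csv", "csv"):
        table = _read_dosage_csv(path, impute_mean)
    elif format == "vcf":
        table = _read_vcf(path)
    else:
        raise ValidationError(f"unknown genotype format: {format!r}")
    if table.monomorphic_mask.all():
        raise ValidationError(f"{path}: every locus is monomorphic")
    return table


# ---------------------------------------------------------------------------
# centring and aggregation


def centre_frequencies(g: GenotypeTable, scale: bool = False) -> CentredFreqMatrix:
    """Build the centred allele-frequency matrix X.

    Each retained column is ``dosage/ploidy`` minus its mean across units
    (one column per biallelic locus); monomorphic columns are dropped.  With
    ``scale`` the columns are additionally divided by their standard
    deviation (population divisor).
    """
    if g.n_units < 3:
        raise ValidationError("at least 3 analysis units are required")
    keep = ~g.monomorphic_mask
    if not keep.any():
        raise ValidationError("no polymorphic locus available")
    if not keep.all():
        logger.info("dropping %d monomorphic locus/loci", int((~keep).sum()))
    freq = g.frequencies[:, keep]
    X = freq - freq.mean(axis=0)
    if scale:
        X = X / X.std(axis=0)
    return CentredFreqMatrix(
        X=X,
        unit_ids=list(g.unit_ids),
        column_ids=[lid for lid, k in zip(g.locus_ids, keep) if k],
    )


def population_frequencies(
    g: GenotypeTable, assignment: Mapping[str, str]
) -> GenotypeTable:
    """Aggregate unit-level genotypes to per-population allele frequencies.

    Every unit must be mapped to a population; the output table carries
    frequencies in [0, 1] (ploidy 1), so centring uses the frequency
    directly rather than halving a diploid dosage.
    """
    missing = [u for u in g.unit_ids if u not in assignment]
    if missing:
        raise ValidationError(f"units without population assignment: {missing[:5]}")
    pops = sorted(set(assignment[u] for u in g.unit_ids))
    freq = g.frequencies
    out = np.empty((len(pops), g.n_loci))
    for i, pop in enumerate(pops):
        members = [k for k, u in enumerate(g.unit_ids) if assignment[u] == pop]
        if not members:
            raise ValidationError(f"population {pop!r} has no member units")
        out[i] = freq[members].mean(axis=0)
    return GenotypeTable(unit_ids=pops, dosages=out, locus_ids=list(g.locus_ids), ploidy=1)
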