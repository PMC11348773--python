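"""Genotype data I/O, conversion, and quality control.

Genotypes are allele dosages: 0 = homozygous reference, 1 = heterozygous,
2 = homozygous alternate.  Missing calls are held internally as the
sentinel :data:`MISSING` (-1) and serialized as ``"NA"``.

The tabular dialect is a plain TSV: a header row of locus identifiers, a
first column of sample identifiers, and 0/1/2/NA cells.  VCF input is read
with cyvcf2; haploid callsets (e.g. drone sequencing) can be "diplotized"
by doubling the single allele, so a haploid ALT call becomes dosage 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Internal sentinel for a missing genotype call.
MISSING: int = -1

_VALID = frozenset({-1, 0, 1, 2})

#: GATK-style hard-filter thresholds: annotation -> (comparison, cutoff).
#: A record is rejected when *any* rule fires; all comparisons are strict.
DEFAULT_HARD_FILTERS: dict[str, tuple[str, float]] = {
    "QUAL": ("<", 30.0),
    "QD": ("<", 2.0),
    "MQ": ("<", 4.0),
    "MQRankSum": ("<", -12.4),
    "ReadPosRankSum": ("<", -8.0),
    "FS": (">", 60.0),
    "SOR": (">", 3.0),
}


class GenotypeError(ValueError):
    """Raised on malformed genotype tables or VCF content."""


@dataclass
class GenotypeMatrix:
    """Samples x loci matrix of allele dosages over {0, 1, 2, MISSING}.

    Parameters
    ----------
    sample_ids, locus_ids
        Unique row / column identifiers.
    values
        ``(n_samples, n_loci)`` integer array; entries in {-1, 0, 1, 2}.
    sample_meta
        Optional per-sample metadata (country, region, free-text label).
    """

    sample_ids: list[str]
    locus_ids: list[str]
    values: np.ndarray
    sample_meta: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.locus_ids = [str(l) for l in self.locus_ids]
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise GenotypeError("values must be a 2-D array")
        n, p = self.values.shape
        if n != len(self.sample_ids) or p != len(self.locus_ids):
            raise GenotypeError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        if len(set(self.sample_ids)) != n:
            raise GenotypeError("duplicate sample ids")
        if len(set(self.locus_ids)) != p:
            raise GenotypeError("duplicate locus ids")
        bad = ~np.isin(self.values, list(_VALID))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise GenotypeError(
                f"illegal genotype {self.values[i, j]} at sample "
                f"{self.sample_ids[i]!r}, locus {self.locus_ids[j]!r}"
            )

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def missing_mask(self) -> np.ndarray:
        """Boolean mask of missing cells."""
        return self.values == MISSING

    def missing_per_sample(self) -> np.ndarray:
        return self.missing_mask().sum(axis=1)

    def to_dataframe(self, missing_token: str = "NA") -> pd.DataFrame:
        df = pd.DataFrame(
            self.values.astype(object), index=self.sample_ids, columns=self.locus_ids
        )
        return df.where(self.values != MISSING, missing_token)

    def subset(
        self,
        samples: Sequence[str] | None = None,
        loci: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        """Return a sub-matrix restricted to the given ids (order preserved)."""
        srow = {s: i for i, s in enumerate(self.sample_ids)}
        lcol = {l: j for j, l in enumerate(self.locus_ids)}
        sids = list(samples) if samples is not None else self.sample_ids
        lids = list(loci) if loci is not None else self.locus_ids
        try:
            ri = [srow[s] for s in sids]
        except KeyError as e:
            raise GenotypeError(f"unknown sample id {e.args[0]!r}") from None
        try:
            cj = [lcol[l] for l in lids]
        except KeyError as e:
            raise GenotypeError(f"unknown locus id {e.args[0]!r}") from None
        meta = {s: self.sample_meta[s] for s in sids if s in self.sample_meta}
        return GenotypeMatrix(sids, lids, self.values[np.ix_(ri, cj)], meta)

    def as_float(self, fill: str | None = None) -> np.ndarray:
        """Float copy with missing cells as NaN, or mean-filled per locus."""
        X = self.values.astype(float)
        X[self.values == MISSING] = np.nan
        if fill == "mean":
            mu = np.nanmean(X, axis=0)
            mu = np.where(np.isnan(mu), 0.0, mu)
            idx = np.where(np.isnan(X))
            X[idx] = mu[idx[1]]
        return X


@dataclass
class LocusMeta:
    """Genomic coordinates and alleles for a panel locus.

    ``flanking_variants`` lists the positions (same chromosome) of other
    variants near the locus; used by :func:`flank_filter` to enforce a
    SNP-free flanking window for assay primer design.
    """

    locus_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    flanking_variants: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise GenotypeError(f"{self.locus_id}: position must be >= 1")
        if self.ref == self.alt:
            raise GenotypeError(f"{self.locus_id}: ref == alt")


@dataclass
class VariantRecord:
    """A biallelic variant with filter annotations and per-sample GT calls."""

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float | None = None
    annotations: dict[str, float] = field(default_factory=dict)
    genotypes: list[str] = field(default_factory=list)

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}"


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------


def read_genotype_table(path, missing_token: str = "NA") -> GenotypeMatrix:
    """Read a TSV genotype table (header = locus ids, first col = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")
    sample_ids = [str(s) for s in df.index]
    locus_ids = [str(l) for l in df.columns]
    if len(set(sample_ids)) != len(sample_ids):
        raise GenotypeError(f"{path}: duplicate sample ids")
    if len(set(locus_ids)) != len(locus_ids):
        raise GenotypeError(f"{path}: duplicate locus ids")
    values = np.empty(df.shape, dtype=np.int8)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j]
            cell = "" if cell is None or (isinstance(cell, float)) else str(cell).strip()
            if cell == missing_token or cell == "":
                values[i, j] = MISSING
            elif cell in ("0", "1", "2"):
                values[i, j] = int(cell)
            else:
                raise GenotypeError(
                    f"{path}: unparseable cell {cell!r} at sample "
                    f"{sample_ids[i]!r}, locus {locus_ids[j]!r}"
                )
    return GenotypeMatrix(sample_ids, locus_ids, values)


def write_genotype_table(gm: GenotypeMatrix, path, missing_token: str = "NA") -> None:
    gm.to_dataframe(missing_token).to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# VCF conversion and filtering
# ---------------------------------------------------------------------------


def vcf_to_genotypes(
    vcf_path,
    diplotize: bool = False,
    on_multiallelic: str = "error",
) -> GenotypeMatrix:
    """Convert VCF GT fields to a 0/1/2 dosage matrix.

    GT ``0/0 -> 0``, ``0/1`` or ``1/0 -> 1``, ``1/1 -> 2``, ``./. -> MISSING``.
    With ``diplotize``, haploid calls are doubled: ``0 -> 0``, ``1 -> 2``.
    Locus ids are ``chrom:pos``.

    Parameters
    ----------
    on_multiallelic
        ``"error"`` (default) or ``"skip"`` records with >1 ALT allele.
    """
    from cyvcf2 import VCF

    if on_multiallelic not in ("error", "skip"):
        raise ValueError("on_multiallelic must be 'error' or 'skip'")
    vcf = VCF(str(vcf_path))
    sample_ids = list(vcf.samples)
    if not sample_ids:
        raise GenotypeError(f"{vcf_path}: no samples / GT fields in VCF")
    locus_ids: list[str] = []
    columns: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            if on_multiallelic == "skip":
                continue
            raise GenotypeError(
                f"{vcf_path}: multiallelic record at {var.CHROM}:{var.POS}"
            )
        col = np.empty(len(sample_ids), dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1] if a is not None and a >= 0]
            raw = [a for a in gt[:-1]]
            if not alleles or any(a is None or a < 0 for a in raw):
                col[i] = MISSING
            elif len(raw) == 1:
                col[i] = 2 * raw[0] if diplotize else raw[0]
            else:
                col[i] = sum(raw)
        locus_ids.append(f"{var.CHROM}:{var.POS}")
        columns.append(col)
    vcf.close()
    values = (
        np.stack(columns, axis=1) if columns else np.empty((len(sample_ids), 0), np.int8)
    )
    return GenotypeMatrix(sample_ids, locus_ids, values)


def read_vcf_records(vcf_path) -> list[VariantRecord]:
    """Read VCF records with the annotations used by :func:`hard_filter_variants`."""
    from cyvcf2 import VCF

    records = []
    vcf = VCF(str(vcf_path))
    fields = [k for k in DEFAULT_HARD_FILTERS if k != "QUAL"]
    for var in vcf:
        ann = {}
        for k in fields:
            v = var.INFO.get(k)
            if v is not None:
                ann[k] = float(v)
        records.append(
            VariantRecord(
                chrom=var.CHROM,
                pos=var.POS,
                ref=var.REF,
                alt=var.ALT[0] if var.ALT else ".",
                qual=None if var.QUAL is None else float(var.QUAL),
                annotations=ann,
            )
        )
    vcf.close()
    return records


def hard_filter_variants(
    records: Iterable[VariantRecord],
    thresholds: Mapping[str, tuple[str, float]] | None = None,
    strict: bool = False,
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, list[str]]]]:
    """Partition variants into (kept, rejected-with-reasons) by hard filters.

    A record is rejected iff any rule fires; the rejection lists every fired
    rule.  A missing annotation does not fire its rule (lenient mode); with
    ``strict=True`` a missing annotation raises instead.
    """
    rules = dict(DEFAULT_HARD_FILTERS if thresholds is None else thresholds)
    kept: list[VariantRecord] = []
    rejected: list[tuple[VariantRecord, list[str]]] = []
    for rec in records:
        fired: list[str] = []
        for name, (op, cutoff) in rules.items():
            value = rec.qual if name == "QUAL" else rec.annotations.get(name)
            if value is None:
                if strict:
                    raise GenotypeError(
                        f"{rec.key}: annotation {name!r} absent in strict mode"
                    )
                continue
            if (op == "<" and value < cutoff) or (op == ">" and value > cutoff):
                fired.append(name)
        if fired:
            rejected.append((rec, fired))
        else:
            kept.append(rec)
    return kept, rejected


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------


def qc_samples(
    gm: GenotypeMatrix,
    max_missing_count: int | None = None,
    max_missing_frac: float | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop samples with too many missing genotypes.

    A sample is dropped iff its missing count exceeds ``max_missing_count``
    OR its missing fraction exceeds ``max_missing_frac`` (both cutoffs are
    inclusive-keep: a sample exactly at the cutoff is retained).
    """
    if max_missing_count is None and max_missing_frac is None:
        raise ValueError("at least one threshold must be supplied")
    if max_missing_count is not None and max_missing_count < 0:
        raise ValueError("max_missing_count must be >= 0")
    if max_missing_frac is not None and max_missing_frac < 0:
        raise ValueError("max_missing_frac must be >= 0")
    counts = gm.missing_per_sample()
    fracs = counts / max(gm.n_loci, 1)
    drop = np.zeros(gm.n_samples, dtype=bool)
    if max_missing_count is not None:
        drop |= counts > max_missing_count
    if max_missing_frac is not None:
        drop |= fracs > max_missing_frac
    report = pd.DataFrame(
        {
            "sample": np.array(gm.sample_ids)[drop],
            "n_missing": counts[drop],
            "frac_missing": fracs[drop],
        }
    )
    kept_ids = [s for s, d in zip(gm.sample_ids, drop) if not d]
    return gm.subset(samples=kept_ids), report


def qc_loci(gm: GenotypeMatrix) -> tuple[GenotypeMatrix, list[str]]:
    """Drop monomorphic loci (all non-missing genotypes identical).

    Loci with no non-missing calls at all are likewise dropped as
    uninformative.  Returns the filtered matrix and the dropped locus ids.
    """
    dropped: list[str] = []
    for j, lid in enumerate(gm.locus_ids):
        col = gm.values[:, j]
        obs = col[col != MISSING]
        if obs.size == 0 or np.all(obs == obs[0]):
            dropped.append(lid)
    kept = [l for l in gm.locus_ids if l not in set(dropped)]
    return gm.subset(loci=kept), dropped


def flank_filter(loci: Sequence[LocusMeta], window_bases: int = 32) -> list[str]:
    """Keep loci with no other variant within ``window_bases`` on either side.

    The window is closed: a neighbor at exactly ``window_bases`` away
    excludes the locus.  Flanking-variant positions must be populated.
    """
    if window_bases < 0:
        raise ValueError("window_bases must be >= 0")
    kept = []
    for lm in loci:
        if all(abs(p - lm.pos) > window_bases for p in lm.flanking_variants):
            kept.append(lm.locus_id)
    return kept
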