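"""Deletion-call ingestion, filtering and carrier-matrix construction.

A deletion structural variant (DSV) enters the pipeline as a VCF record with
``SVTYPE=DEL`` and per-sample genotypes.  Coordinates follow the convention
that ``start`` is the 1-based position of the first deleted base and
``end - start`` is the deletion length, matching VCF ``POS``/``END``
semantics.  Downstream stages work with a binary carrier matrix: a sample
carries a DSV iff it has at least one deleted copy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

AUTOSOMES = {str(i) for i in range(1, 23)} | {f"chr{i}" for i in range(1, 23)}

MISSING = -1  # sentinel for a missing genotype in the copy-count vector

#: required columns of a cohort table
COHORT_COLUMNS = (
    "sample_id",
    "cohort_label",   # "cancer" | "non-cancer"
    "fch",            # "yes" | "no" | "unknown"
    "sex",
    "age",
    "cancer_type",
    "recurrence",     # "yes" | "no" | "not-applicable"
    "rfs_time",       # months, NaN when not recurrence-evaluable
    "rfs_event",      # 0/1, NaN when not recurrence-evaluable
)


@dataclass
class DeletionRecord:
    """One called deletion with per-sample deleted-copy counts.

    ``genotypes`` holds 0/1/2 deleted copies, or :data:`MISSING`.
    """

    dsv_id: str
    chromosome: str
    start: int  # 1-based first deleted base
    end: int    # exclusive; length = end - start
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.end <= self.start:
            raise ValueError(
                f"{self.dsv_id}: end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def deletion_length(rec: DeletionRecord) -> int:
    """Length of a deletion in base pairs (``end - start``)."""
    return rec.length


@dataclass
class CarrierMatrix:
    """Samples x DSVs binary carrier indicators plus per-DSV metadata."""

    data: pd.DataFrame           # index = sample ids, columns = dsv ids, values 0/1
    metadata: pd.DataFrame       # one row per DSV: dsv_id, chromosome, start, end
    genes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.data.isin([0, 1]).all().all():
            raise ValueError("carrier matrix entries must be binary")
        if list(self.data.columns) != list(self.metadata["dsv_id"]):
            raise ValueError("column order must match metadata order")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def dsv_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class FilterParams:
    """Thresholds of the deletion-retention filter."""

    min_len: int = 500
    max_len: int = 10_000
    min_maf: float = 0.05
    min_carrier_frac_per_cohort: float = 0.01
    autosomes_only: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("need 0 < min_len <= max_len")
        if not (0 <= self.min_maf <= 0.5):
            raise ValueError("min_maf must lie in [0, 0.5]")
        if not (0 <= self.min_carrier_frac_per_cohort <= 1):
            raise ValueError("min_carrier_frac_per_cohort must lie in [0, 1]")


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated cohort table, validating required columns."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in cohort table")
    return df


# cyvcf2 gt_types codes
_GT_HOM_REF, _GT_HET, _GT_UNKNOWN, _GT_HOM_ALT = 0, 1, 2, 3


def read_deletions_vcf(path: str | Path) -> list[DeletionRecord]:
    """Read ``SVTYPE=DEL`` records from a VCF into :class:`DeletionRecord`.

    Non-deletion records are skipped (count logged).  ``END`` and ``SVLEN``
    must agree when both are present.  Missing genotypes are preserved as
    :data:`MISSING`.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    records: list[DeletionRecord] = []
    skipped = 0
    for i, var in enumerate(vcf):
        svtype = var.INFO.get("SVTYPE")
        if svtype != "DEL":
            skipped += 1
            continue
        pos = var.POS
        end = var.INFO.get("END")
        svlen = var.INFO.get("SVLEN")
        if end is None:
            if svlen is None:
                raise ValueError(f"record {i} ({var.ID}): neither END nor SVLEN present")
            end = pos + abs(int(svlen))
        end = int(end)
        if svlen is not None and abs(int(svlen)) != end - pos:
            raise ValueError(
                f"record {i} ({var.ID}): SVLEN {svlen} inconsistent with END-POS {end - pos}"
            )
        if end < pos:
            raise ValueError(f"record {i} ({var.ID}): END ({end}) < POS ({pos})")
        gt = np.asarray(var.gt_types)
        copies = np.full(gt.shape, MISSING, dtype=np.int8)
        copies[gt == _GT_HOM_REF] = 0
        copies[gt == _GT_HET] = 1
        copies[gt == _GT_HOM_ALT] = 2
        records.append(
            DeletionRecord(
                dsv_id=var.ID or f"DSV{i}",
                chromosome=var.CHROM,
                start=pos,
                end=end,
                genotypes=copies,
            )
        )
    if skipped:
        logger.info("skipped %d non-DEL records", skipped)
    return records


def _allele_freq(genotypes: np.ndarray) -> float:
    called = genotypes[genotypes != MISSING]
    if called.size == 0:
        return 0.0
    return float(called.sum()) / (2 * called.size)


def filter_deletions(
    records: Sequence[DeletionRecord],
    cohort: pd.DataFrame,
    params: FilterParams | None = None,
) -> tuple[list[DeletionRecord], dict[str, int]]:
    """Apply the four retention criteria; return survivors and a rejection tally.

    Criteria, applied in order with a record tallied against the first one it
    fails: (i) autosomal; (ii) length within ``[min_len, max_len]``;
    (iii) minor allele frequency over the combined cohort >= ``min_maf``,
    where the deletion-allele frequency is folded at 0.5 and missing
    genotypes are excluded from the denominator; (iv) carrier fraction >=
    ``min_carrier_frac_per_cohort`` within the cancer cohort *and* within
    the non-cancer cohort.
    """
    if params is None:
        params = FilterParams()
    labels = np.asarray(cohort["cohort_label"])
    is_cancer = labels == "cancer"
    is_control = labels == "non-cancer"
    if is_cancer.sum() == 0 or is_control.sum() == 0:
        raise ValueError("cohort must contain both cancer and non-cancer samples")

    tally = {"non_autosomal": 0, "length": 0, "maf": 0, "carrier_fraction": 0}
    kept: list[DeletionRecord] = []
    for rec in records:
        if params.autosomes_only and rec.chromosome not in AUTOSOMES:
            tally["non_autosomal"] += 1
            continue
        if not (params.min_len <= rec.length <= params.max_len):
            tally["length"] += 1
            continue
        f = _allele_freq(rec.genotypes)
        if min(f, 1 - f) < params.min_maf:
            tally["maf"] += 1
            continue
        carrier = rec.genotypes >= 1  # missing (-1) counts as non-carrier
        frac_cancer = carrier[is_cancer].mean()
        frac_control = carrier[is_control].mean()
        if (
            frac_cancer < params.min_carrier_frac_per_cohort
            or frac_control < params.min_carrier_frac_per_cohort
        ):
            tally["carrier_fraction"] += 1
            continue
        kept.append(rec)
    return kept, tally


def build_carrier_matrix(
    records: Sequence[DeletionRecord], cohort: pd.DataFrame
) -> CarrierMatrix:
    """Binarise genotypes: carrier iff >= 1 deleted copy; missing -> 0 (logged)."""
    ids = [r.dsv_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate dsv ids: {dupes}")
    samples = list(cohort["sample_id"])
    n_missing = 0
    cols = {}
    for rec in records:
        if len(rec.genotypes) != len(samples):
            raise ValueError(
                f"{rec.dsv_id}: genotype vector length {len(rec.genotypes)} "
                f"!= cohort size {len(samples)}"
            )
        n_missing += int((rec.genotypes == MISSING).sum())
        cols[rec.dsv_id] = (rec.genotypes >= 1).astype(np.int8)
    if n_missing:
        logger.info("%d missing genotypes treated as non-carriers", n_missing)
    data = pd.DataFrame(cols, index=pd.Index(samples, name="sample_id"), dtype=np.int8)
    if not records:
        data = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    meta = pd.DataFrame(
        {
            "dsv_id": ids,
            "chromosome": [r.chromosome for r in records],
            "start": [r.start for r in records],
            "end": [r.end for r in records],
        }
    )
    return CarrierMatrix(data=data, metadata=meta)


def read_gene_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3+name file (0-based half-open) of gene models."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chromosome", "start", "end", "name"],
        dtype={"chromosome": str},
        comment="#",
    )
    if (df["end"] <= df["start"]).any():
        raise ValueError("BED intervals must have end > start")
    return df


def annotate_genes(
    records: Sequence[DeletionRecord],
    gene_bed: pd.DataFrame | str | Path,
) -> dict[str, list[str]]:
    """Map each DSV to the genes whose interval it overlaps by >= 1 bp.

    Gene intervals come from a BED table (0-based half-open) and are compared
    against the DSV's half-open span with interval trees, so an abutting DSV
    (deletion end equal to gene start) does not map.  A chr-prefix mismatch
    between the two sources raises with a hint rather than silently mapping
    nothing.
    """
    if not isinstance(gene_bed, pd.DataFrame):
        gene_bed = read_gene_bed(gene_bed)
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in gene_bed.groupby("chromosome"):
        tree = IntervalTree()
        for s, e, name in zip(grp["start"], grp["end"], grp["name"]):
            # BED 0-based half-open -> 1-based half-open
            tree.addi(int(s) + 1, int(e) + 1, name)
        trees[str(chrom)] = tree

    def _alt(chrom: str) -> str:
        return chrom[3:] if chrom.startswith("chr") else "chr" + chrom

    out: dict[str, list[str]] = {}
    for rec in records:
        tree = trees.get(rec.chromosome)
        if tree is None:
            if _alt(rec.chromosome) in trees:
                raise ValueError(
                    f"chromosome naming mismatch: DSVs use {rec.chromosome!r} but the "
                    f"gene file uses {_alt(rec.chromosome)!r}; harmonise the 'chr' prefix"
                )
            out[rec.dsv_id] = []
            continue
        hits = tree.overlap(rec.start, rec.end)
        out[rec.dsv_id] = sorted({h.data for h in hits})
    return out


def write_carrier_matrix(cm: CarrierMatrix, path: str | Path) -> None:
    cm.data.to_csv(path, sep="\t")


def read_carrier_matrix(path: str | Path, metadata: pd.DataFrame | None = None) -> CarrierMatrix:
    data = pd.read_csv(path, sep="\t", index_col="sample_id")
    if metadata is None:
        metadata = pd.DataFrame(
            {
                "dsv_id": list(data.columns),
                "chromosome": "",
                "start": 0,
                "end": 1,
            }
        )
    return CarrierMatrix(data=data.astype(np.int8), metadata=metadata)
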