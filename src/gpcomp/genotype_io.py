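"""Genotype and phenotype I/O, validation, and marker quality control.

Dosages are alt-allele counts in {0, 1, 2}; missing entries carry the
sentinel :data:`MISSING` (-1).  Quality control removes markers by call
rate, minor allele frequency, and a 1-df chi-square Hardy-Weinberg test,
attributing each removal to the first failing filter in that order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from gpcomp.errors import ConsistencyError, EmptyDataError, InputError

logger = logging.getLogger(__name__)

#: Sentinel for a missing dosage; any negative value outside {0,1,2} works,
#: -1 keeps int8 storage.
MISSING: int = -1


@dataclass(frozen=True)
class Marker:
    """Per-SNP metadata; only ``id`` is required for plain-matrix input."""

    id: str
    chrom: str | None = None
    pos: int | None = None
    ref: str | None = None
    alt: str | None = None


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with marker metadata.

    Invariants (checked on construction): every non-missing entry is
    0/1/2, dimensions match the id lists, and individual ids are unique.
    """

    values: np.ndarray
    individual_ids: list[str]
    markers: list[Marker]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ConsistencyError("genotype values must be a 2-D array")
        n, m = self.values.shape
        if n != len(self.individual_ids):
            raise ConsistencyError(
                f"{n} rows but {len(self.individual_ids)} individual ids"
            )
        if m != len(self.markers):
            raise ConsistencyError(f"{m} columns but {len(self.markers)} markers")
        if len(set(self.individual_ids)) != n:
            raise ConsistencyError("individual ids are not unique")
        valid = (self.values == MISSING) | np.isin(self.values, (0, 1, 2))
        if not valid.all():
            i, j = np.argwhere(~valid)[0]
            raise InputError(
                f"invalid dosage {self.values[i, j]!r} for individual "
                f"{self.individual_ids[i]!r}, marker {self.markers[j].id!r}"
            )

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def marker_ids(self) -> list[str]:
        return [m.id for m in self.markers]

    def subset_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix keeping the marker columns in ``index`` (input order)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            self.values[:, index],
            list(self.individual_ids),
            [self.markers[j] for j in index],
        )

    def subset_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.values[index, :],
            [self.individual_ids[i] for i in index],
            list(self.markers),
        )


@dataclass
class PhenotypeTable:
    """Trait values per individual; missing values allowed (NaN)."""

    data: pd.DataFrame  # index = individual id, one column per trait

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ConsistencyError("duplicate individual ids in phenotype table")

    @property
    def individual_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def traits(self) -> list[str]:
        return list(self.data.columns)

    def trait_vector(self, trait: str, ids: Sequence[str]) -> np.ndarray:
        """Trait values aligned to ``ids``; absent individuals become NaN."""
        if trait not in self.data.columns:
            raise InputError(f"unknown trait {trait!r}")
        s = self.data[trait].reindex(list(ids))
        v = s.to_numpy(dtype=float)
        if np.isnan(v).all():
            raise EmptyDataError(f"trait {trait!r} has no values for these ids")
        return v


@dataclass
class QCReport:
    """Per-filter removal counts; removed + retained == input markers."""

    n_input: int
    removed_call_rate: int
    removed_maf: int
    removed_hwe: int
    retained: int
    thresholds: dict = field(default_factory=dict)
    removed_marker_ids: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        removed = self.removed_call_rate + self.removed_maf + self.removed_hwe
        if removed + self.retained != self.n_input:
            raise ConsistencyError("QC accounting does not add up")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


# ---------------------------------------------------------------------------
# readers / writers


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read hard-called GT fields from a VCF into a dosage matrix.

    Multi-allelic records are skipped with a warning; missing genotypes
    map to :data:`MISSING`.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError subclasses
        raise InputError(f"cannot read VCF {path}: {exc}") from exc

    individual_ids = list(vcf.samples)
    rows: list[np.ndarray] = []
    markers: list[Marker] = []
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_skipped += 1
            continue
        # gts012=True: 0/1/2 = alt dosage, 3 = unknown
        gt = np.asarray(variant.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        rows.append(gt)
        vid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        markers.append(
            Marker(vid, variant.CHROM, variant.POS, variant.REF, variant.ALT[0])
        )
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} non-biallelic records", stacklevel=2)
    if not markers:
        raise EmptyDataError(f"no biallelic sites in {path}")
    values = np.stack(rows, axis=1)  # sites were rows -> transpose to n x m
    return GenotypeMatrix(values, individual_ids, markers)


def read_matrix(
    path: str | Path,
    orientation: str = "individuals",
    sep: str | None = None,
    missing_code: str = "NA",
) -> GenotypeMatrix:
    """Read a delimited dosage table with an id header row and column.

    ``orientation`` is ``"individuals"`` (rows are individuals) or
    ``"snps"`` (rows are SNPs; the matrix is transposed on read).
    """
    if orientation not in ("individuals", "snps"):
        raise InputError(f"unknown orientation {orientation!r}")
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if sep is None:
        sep = "\t" if "\t" in path.open().readline() else ","
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if orientation == "snps":
        df = df.T
    raw = df.to_numpy()
    values = np.full(raw.shape, MISSING, dtype=np.int8)
    for (i, j), tok in np.ndenumerate(raw):
        tok = str(tok).strip()
        if tok == missing_code or tok.lower() == "nan":
            continue
        try:
            v = int(tok)
        except ValueError:
            raise InputError(
                f"non-integer token {tok!r} at row {df.index[i]!r}, "
                f"column {df.columns[j]!r}"
            ) from None
        if v not in (0, 1, 2):
            raise InputError(
                f"dosage out of range: {v} at row {df.index[i]!r}, "
                f"column {df.columns[j]!r}"
            )
        values[i, j] = v
    markers = [Marker(str(c)) for c in df.columns]
    return GenotypeMatrix(values, [str(i) for i in df.index], markers)


def write_matrix(
    g: GenotypeMatrix, path: str | Path, sep: str = "\t", missing_code: str = "NA"
) -> None:
    """Write individuals x SNPs dosages as delimited text (NA for missing)."""
    df = pd.DataFrame(
        g.values.astype(object), index=g.individual_ids, columns=g.marker_ids
    )
    df = df.where(g.values != MISSING, missing_code)
    df.to_csv(path, sep=sep, index_label="id")


def read_phenotypes(path: str | Path, sep: str | None = None) -> PhenotypeTable:
    """Read a phenotype table: first column is the individual id."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if sep is None:
        sep = "\t" if "\t" in path.open().readline() else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    if df.shape[1] == 0:
        raise EmptyDataError(f"no trait columns in {path}")
    return PhenotypeTable(df.astype(float))


def write_phenotypes(pt: PhenotypeTable, path: str | Path, sep: str = "\t") -> None:
    pt.data.to_csv(path, sep=sep, index_label="id")


# ---------------------------------------------------------------------------
# marker statistics and QC


def compute_call_rate(g: GenotypeMatrix) -> np.ndarray:
    """Fraction of non-missing entries per marker, in [0, 1]."""
    return (g.values != MISSING).mean(axis=0)


def compute_maf(g: GenotypeMatrix) -> np.ndarray:
    """Minor allele frequency per marker; NaN where all entries are missing."""
    vals = np.ma.masked_equal(g.values, MISSING)
    p = vals.mean(axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    return maf.filled(np.nan)


def hwe_test(n0: int, n1: int, n2: int) -> tuple[float, float]:
    """1-df chi-square goodness-of-fit test against Hardy-Weinberg counts.

    Expected counts use the sample allele frequency.  Monomorphic input
    returns ``(0.0, 1.0)``.
    """
    n = n0 + n1 + n2
    if n <= 0:
        raise InputError("hwe_test needs at least one genotype")
    p = (2 * n2 + n1) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 0.0, 1.0
    expected = np.array([n * q * q, 2 * n * p * q, n * p * p])
    observed = np.array([n0, n1, n2], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    pval = float(stats.chi2.sf(chi2, df=1))
    return chi2, pval


def hwe_pvalues(g: GenotypeMatrix) -> np.ndarray:
    """HWE test p-value per marker (missing entries ignored)."""
    out = np.ones(g.n_snps)
    for j in range(g.n_snps):
        col = g.values[:, j]
        col = col[col != MISSING]
        if col.size == 0:
            out[j] = np.nan
            continue
        n0 = int((col == 0).sum())
        n1 = int((col == 1).sum())
        n2 = int((col == 2).sum())
        out[j] = hwe_test(n0, n1, n2)[1]
    return out


def apply_qc(
    g: GenotypeMatrix,
    min_call_rate: float = 0.90,
    min_maf: float = 0.05,
    hwe_p: float = 1e-7,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove markers failing call-rate, MAF, or HWE filters.

    Boundaries are strict: a marker is removed only if call rate <
    ``min_call_rate``, MAF < ``min_maf``, or HWE p < ``hwe_p``.  A marker
    failing several filters counts against the first in that order.
    Columns whose frequency is undefined (all missing) fail call rate.
    """
    if not (0.0 <= min_call_rate <= 1.0 and 0.0 <= min_maf <= 0.5):
        raise InputError("QC thresholds out of range")
    call = compute_call_rate(g)
    maf = compute_maf(g)
    hwe = hwe_pvalues(g)

    fail_call = call < min_call_rate
    fail_maf = ~fail_call & (np.isnan(maf) | (maf < min_maf))
    fail_hwe = ~fail_call & ~fail_maf & ~np.isnan(hwe) & (hwe < hwe_p)
    keep = ~(fail_call | fail_maf | fail_hwe)

    if not keep.any():
        raise EmptyDataError("quality control removed every marker")

    ids = np.array(g.marker_ids)
    report = QCReport(
        n_input=g.n_snps,
        removed_call_rate=int(fail_call.sum()),
        removed_maf=int(fail_maf.sum()),
        removed_hwe=int(fail_hwe.sum()),
        retained=int(keep.sum()),
        thresholds={
            "min_call_rate": min_call_rate,
            "min_maf": min_maf,
            "hwe_p": hwe_p,
        },
        removed_marker_ids={
            "call_rate": ids[fail_call].tolist(),
            "maf": ids[fail_maf].tolist(),
            "hwe": ids[fail_hwe].tolist(),
        },
    )
    logger.info(
        "QC: %d markers in, removed %d (call rate) + %d (MAF) + %d (HWE), %d retained",
        report.n_input, report.removed_call_rate, report.removed_maf,
        report.removed_hwe, report.retained,
    )
    return g.subset_markers(np.flatnonzero(keep)), report


def impute_mean(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages with the rounded per-marker mean.

    Off by default in the pipeline; compression requires a complete
    matrix, and upstream imputation is assumed done externally.
    """
    vals = np.ma.masked_equal(g.values, MISSING)
    means = vals.mean(axis=0)
    if np.ma.is_masked(means) and means.mask.any():
        raise EmptyDataError("cannot impute a marker with no observed genotypes")
    fill = np.clip(np.rint(np.asarray(means)), 0, 2).astype(np.int8)
    out = g.values.copy()
    miss = out == MISSING
    out[miss] = np.broadcast_to(fill, out.shape)[miss]
    return GenotypeMatrix(out, list(g.individual_ids), list(g.markers))
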