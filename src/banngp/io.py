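"""Readers, writers and quality control for genotype, annotation and trait data.

Supported formats: PLINK 1.9 binary triplets (.bed/.bim/.fam), plain
allele-dosage CSV (with a sidecar variant-map CSV), GTF/GFF3 gene
annotations, and trait tables of de-regressed proofs (DRPs) with
per-animal EBV reliabilities.

Coordinates are 1-based inclusive throughout (GTF convention); a dosage is
the count of ``allele_b`` at a variant, taking values in {0, 1, 2}.
"""

from __future__ import annotations

import io as _io
import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats


class GenotypeFormatError(ValueError):
    """Malformed or mutually inconsistent genotype files."""


class EmptyAnnotationError(ValueError):
    """Annotation file contains no gene features."""


class EmptyPanelError(ValueError):
    """Quality control removed every SNP."""


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic variant: identifier, chromosome, 1-based position, alleles."""

    variant_id: str
    chrom: str
    pos_bp: int
    allele_a: str = "A"
    allele_b: str = "B"

    def __post_init__(self):
        if self.pos_bp < 1:
            raise ValueError(f"pos_bp must be >= 1, got {self.pos_bp} for {self.variant_id}")


def _chrom_key(chrom: str):
    """Sort chromosomes numerically where possible, lexicographically otherwise."""
    c = chrom.lower().removeprefix("chr")
    try:
        return (0, int(c), "")
    except ValueError:
        return (1, 0, c)


@dataclass
class GenotypeMatrix:
    """n x J allele-dosage matrix with its variant map.

    ``dosages[i, j]`` is the count of ``variants[j].allele_b`` carried by
    ``sample_ids[i]``. Missing genotypes (NaN) are only allowed before QC.
    """

    dosages: np.ndarray
    sample_ids: list[str]
    variants: list[VariantRecord]

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise GenotypeFormatError("dosages must be a 2-D matrix")
        n, j = self.dosages.shape
        if n < 1 or j < 1:
            raise GenotypeFormatError("need at least one sample and one variant")
        if len(self.sample_ids) != n:
            raise GenotypeFormatError(
                f"{len(self.sample_ids)} sample ids for {n} dosage rows"
            )
        if len(self.variants) != j:
            raise GenotypeFormatError(
                f"{len(self.variants)} variant records for {j} dosage columns"
            )
        seen = set()
        for v in self.variants:
            key = (v.chrom, v.pos_bp)
            if key in seen:
                raise GenotypeFormatError(f"duplicate variant position {key}")
            seen.add(key)

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def sorted_by_position(self) -> "GenotypeMatrix":
        order = sorted(
            range(len(self.variants)),
            key=lambda j: (_chrom_key(self.variants[j].chrom), self.variants[j].pos_bp),
        )
        if order == list(range(len(self.variants))):
            return self
        return GenotypeMatrix(
            dosages=self.dosages[:, order],
            sample_ids=list(self.sample_ids),
            variants=[self.variants[j] for j in order],
        )

    def allele_freqs(self) -> np.ndarray:
        """Frequency of allele_b per variant (ignores NaN)."""
        return np.nanmean(self.dosages, axis=0) / 2.0


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    start_bp: int
    end_bp: int
    strand: str = "+"

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ValueError(f"gene {self.gene_id}: start {self.start_bp} > end {self.end_bp}")


@dataclass
class GeneAnnotation:
    """Gene intervals, 1-based inclusive."""

    records: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.gene_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("gene_id values must be unique")

    def __len__(self):
        return len(self.records)

    def by_chrom(self) -> dict[str, list[GeneRecord]]:
        out: dict[str, list[GeneRecord]] = {}
        for r in self.records:
            out.setdefault(r.chrom, []).append(r)
        for recs in out.values():
            recs.sort(key=lambda r: (r.start_bp, r.end_bp, r.gene_id))
        return out


# ---------------------------------------------------------------------------
# PLINK 1.9 binary triplet
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major mode
# 2-bit codes: 00 hom allele_a, 01 missing, 10 het, 11 hom allele_b
_BED_DECODE = np.array([0.0, np.nan, 1.0, 2.0])


def _plink_prefix(path: str) -> str:
    base, ext = os.path.splitext(path)
    return base if ext in {".bed", ".bim", ".fam"} else path


def _read_plink(path: str) -> GenotypeMatrix:
    prefix = _plink_prefix(path)
    try:
        bim = pd.read_csv(
            prefix + ".bim", sep=r"\s+", header=None,
            names=["chrom", "variant_id", "cm", "pos", "a1", "a2"],
            dtype={"chrom": str, "variant_id": str, "a1": str, "a2": str},
        )
        fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None, dtype=str)
    except FileNotFoundError as exc:
        raise GenotypeFormatError(f"missing PLINK file: {exc.filename}") from exc
    sample_ids = fam.iloc[:, 1].tolist()
    n, j = len(sample_ids), len(bim)
    raw = np.fromfile(prefix + ".bed", dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise GenotypeFormatError(f"{prefix}.bed: bad magic bytes (not SNP-major PLINK 1.9)")
    payload = raw[3:]
    bytes_per_snp = (n + 3) // 4
    if payload.size != bytes_per_snp * j:
        raise GenotypeFormatError(
            f"{prefix}.bed payload holds {payload.size} bytes but "
            f"{j} variants x {n} samples need {bytes_per_snp * j}"
        )
    blocks = payload.reshape(j, bytes_per_snp)
    # expand each byte into four 2-bit codes, low bits = first sample
    codes = np.stack(
        [(blocks >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=-1
    ).reshape(j, -1)[:, :n]
    for bad in ("a1", "a2"):
        if (bim[bad].str.len() != 1).any():
            raise GenotypeFormatError("allele codes in .bim must be single characters")
    dosages = _BED_DECODE[codes].T
    variants = [
        VariantRecord(r.variant_id, str(r.chrom), int(r.pos), r.a1, r.a2)
        for r in bim.itertuples()
    ]
    return GenotypeMatrix(dosages, sample_ids, variants)


def _write_plink(g: GenotypeMatrix, path: str) -> None:
    prefix = _plink_prefix(path)
    n = g.n
    d = g.dosages
    codes = np.full(d.T.shape, 1, dtype=np.uint8)  # missing
    codes[d.T == 0] = 0
    codes[d.T == 1] = 2
    codes[d.T == 2] = 3
    pad = (-n) % 4
    if pad:
        codes = np.concatenate([codes, np.zeros((codes.shape[0], pad), np.uint8)], axis=1)
    packed = (
        codes[:, 0::4] | (codes[:, 1::4] << 2) | (codes[:, 2::4] << 4) | (codes[:, 3::4] << 6)
    ).astype(np.uint8)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())
    with open(prefix + ".bim", "w") as fh:
        for v in g.variants:
            fh.write(f"{v.chrom}\t{v.variant_id}\t0\t{v.pos_bp}\t{v.allele_a}\t{v.allele_b}\n")
    with open(prefix + ".fam", "w") as fh:
        for s in g.sample_ids:
            fh.write(f"{s}\t{s}\t0\t0\t0\t-9\n")


# ---------------------------------------------------------------------------
# Dosage CSV (wide table + sidecar variant map)
# ---------------------------------------------------------------------------

def _variants_sidecar(path: str) -> str:
    base, _ = os.path.splitext(path)
    return base + ".variants.csv"


def _read_dosage_csv(path: str) -> GenotypeMatrix:
    table = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in table.columns:
        raise GenotypeFormatError(f"{path}: first column must be 'sample_id'")
    vmap_path = _variants_sidecar(path)
    if not os.path.exists(vmap_path):
        raise GenotypeFormatError(f"variant map {vmap_path} not found beside {path}")
    vmap = pd.read_csv(vmap_path, dtype={"variant_id": str, "chrom": str})
    variant_cols = [c for c in table.columns if c != "sample_id"]
    mapped = set(vmap["variant_id"])
    if set(variant_cols) != mapped:
        raise GenotypeFormatError(
            f"{path}: dosage columns and variant map disagree "
            f"({len(variant_cols)} columns vs {len(mapped)} mapped variants)"
        )
    vmap = vmap.set_index("variant_id").loc[variant_cols].reset_index()
    dosages = table[variant_cols].to_numpy(dtype=float)
    valid = np.isnan(dosages) | np.isin(dosages, (0.0, 1.0, 2.0))
    if not valid.all():
        bad = dosages[~valid].flat[0]
        raise GenotypeFormatError(f"{path}: dosage {bad!r} is not in {{0,1,2}} or missing")
    variants = [
        VariantRecord(r.variant_id, str(r.chrom), int(r.pos_bp),
                      str(r.allele_a), str(r.allele_b))
        for r in vmap.itertuples()
    ]
    return GenotypeMatrix(dosages, table["sample_id"].tolist(), variants)


def _write_dosage_csv(g: GenotypeMatrix, path: str) -> None:
    table = pd.DataFrame(g.dosages, columns=[v.variant_id for v in g.variants])
    table.insert(0, "sample_id", g.sample_ids)
    table.to_csv(path, index=False)
    vmap = pd.DataFrame(
        [
            (v.variant_id, v.chrom, v.pos_bp, v.allele_a, v.allele_b)
            for v in g.variants
        ],
        columns=["variant_id", "chrom", "pos_bp", "allele_a", "allele_b"],
    )
    vmap.to_csv(_variants_sidecar(path), index=False)


def read_genotypes(path: str, format: str = "auto", missing: str = "error") -> GenotypeMatrix:
    """Read a genotype matrix; variants are returned sorted by (chrom, pos).

    Parameters
    ----------
    path
        A .bed/.bim/.fam prefix (or any member of the triplet) or a
        dosage-CSV path with its ``*.variants.csv`` sidecar.
    format
        ``plink-bed``, ``dosage-csv`` or ``auto`` (by extension).
    missing
        ``error`` rejects missing genotypes; ``mean`` fills each missing
        value with the per-SNP mean dosage. Imputation from linkage is out
        of scope, so the default is to reject.
    """
    if format == "auto":
        format = "dosage-csv" if path.endswith(".csv") else "plink-bed"
    if format == "plink-bed":
        g = _read_plink(path)
    elif format == "dosage-csv":
        g = _read_dosage_csv(path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    nan_mask = np.isnan(g.dosages)
    if nan_mask.any():
        if missing == "error":
            raise GenotypeFormatError(
                f"{path}: {int(nan_mask.sum())} missing genotypes "
                "(pass missing='mean' to fill with per-SNP means)"
            )
        if missing == "mean":
            col_means = np.nanmean(g.dosages, axis=0)
            g.dosages[nan_mask] = np.take(col_means, np.nonzero(nan_mask)[1])
        else:
            raise ValueError(f"unknown missing policy {missing!r}")
    return g.sorted_by_position()


def write_genotypes(g: GenotypeMatrix, path: str, format: str = "auto") -> None:
    if format == "auto":
        format = "dosage-csv" if path.endswith(".csv") else "plink-bed"
    if format == "plink-bed":
        _write_plink(g, path)
    elif format == "dosage-csv":
        _write_dosage_csv(g, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# Gene annotation (GTF / GFF3 via gffutils)
# ---------------------------------------------------------------------------

def read_gene_annotation(path: str) -> GeneAnnotation:
    """Parse gene features from a GTF or GFF3 file (1-based inclusive)."""
    import gffutils

    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    records = []
    for f in db.features_of_type("gene"):
        attrs = dict(f.attributes)
        gene_id = (attrs.get("gene_id") or attrs.get("ID") or [f.id])[0]
        records.append(GeneRecord(gene_id, f.seqid, f.start, f.end, f.strand or "+"))
    if not records:
        raise EmptyAnnotationError(f"{path}: no features of type 'gene'")
    return GeneAnnotation(records)


def write_gene_annotation(ann: GeneAnnotation, path: str) -> None:
    """Write genes as minimal GTF."""
    with open(path, "w") as fh:
        for r in ann.records:
            fh.write(
                f"{r.chrom}\tbanngp\tgene\t{r.start_bp}\t{r.end_bp}\t.\t{r.strand}\t.\t"
                f'gene_id "{r.gene_id}";\n'
            )


# ---------------------------------------------------------------------------
# Genotype quality control
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    removed: pd.DataFrame  # variant_id, reason, maf, hwe_p
    n_before: int
    n_after: int

    def to_tsv(self, path: str) -> None:
        self.removed.to_csv(path, sep="\t", index=False)


def hwe_chisq_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    """1-df chi-square goodness-of-fit test for Hardy-Weinberg proportions.

    An asymptotic approximation to PLINK's exact test, adequate at the
    sample sizes this package simulates.
    """
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    p = (2 * n_bb + n_ab) / (2 * n)
    q = 1.0 - p
    if p <= 0.0 or q <= 0.0:
        return 1.0  # monomorphic: HW holds trivially
    expected = np.array([q * q, 2 * p * q, p * p]) * n
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chisq = float(np.sum((observed - expected) ** 2 / expected))
    return float(stats.chi2.sf(chisq, df=1))


def apply_qc(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    hwe_alpha: float = 1e-6,
    chromosomes: list[str] | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove SNPs with MAF < ``maf_min`` or an HWE test P < ``hwe_alpha``.

    ``chromosomes`` optionally whitelists chromosomes (e.g. autosomes);
    by default every chromosome present is kept.
    """
    if np.isnan(g.dosages).any():
        raise ValueError("apply_qc requires complete genotypes; handle missing at load time")
    keep = np.ones(g.n_variants, dtype=bool)
    rows = []
    for j, v in enumerate(g.variants):
        col = g.dosages[:, j]
        if chromosomes is not None and v.chrom not in chromosomes:
            keep[j] = False
            rows.append((v.variant_id, "chromosome", np.nan, np.nan))
            continue
        p = col.mean() / 2.0
        maf = min(p, 1.0 - p)
        n_bb = int((col == 2).sum())
        n_ab = int((col == 1).sum())
        n_aa = int((col == 0).sum())
        hwe_p = hwe_chisq_pvalue(n_aa, n_ab, n_bb)
        if maf < maf_min:
            keep[j] = False
            rows.append((v.variant_id, "maf", maf, hwe_p))
        elif hwe_p < hwe_alpha:
            keep[j] = False
            rows.append((v.variant_id, "hwe", maf, hwe_p))
    if not keep.any():
        raise EmptyPanelError("QC removed every SNP")
    report = QCReport(
        removed=pd.DataFrame(rows, columns=["variant_id", "reason", "maf", "hwe_p"]),
        n_before=g.n_variants,
        n_after=int(keep.sum()),
    )
    kept = GenotypeMatrix(
        g.dosages[:, keep],
        list(g.sample_ids),
        [v for v, k in zip(g.variants, keep) if k],
    )
    return kept, report


# ---------------------------------------------------------------------------
# Trait tables: de-regressed proofs and reliability bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class TraitRecord:
    """One animal's de-regressed proof with its reliability bookkeeping.

    ``lambda_shrink`` = (1 - h^2)/h^2, ``erc`` = lambda * REL/(1 - REL)
    (the effective record contribution), and the DRP reliability
    ``r2_drp`` = ERC/(ERC + lambda). The chain algebraically collapses to
    r2_drp == rel_ebv; it is carried verbatim for transparency.
    """

    sample_id: str
    drp: float
    rel_ebv: float
    h2: float
    lambda_shrink: float | None = None
    erc: float | None = None
    r2_drp: float | None = None


def derive_trait_weights(records: list[TraitRecord]) -> list[TraitRecord]:
    """Fill lambda_shrink, erc and r2_drp for each record."""
    out = []
    for t in records:
        if not 0.0 < t.h2 < 1.0:
            raise ValueError(f"{t.sample_id}: heritability {t.h2} outside (0, 1)")
        if t.rel_ebv >= 1.0:
            raise ZeroDivisionError(
                f"{t.sample_id}: REL = {t.rel_ebv} would divide by zero in the "
                "effective record contribution; reliabilities must be < 1"
            )
        if t.rel_ebv <= 0.0:
            raise ValueError(f"{t.sample_id}: REL = {t.rel_ebv} must be > 0")
        lam = (1.0 - t.h2) / t.h2
        erc = lam * t.rel_ebv / (1.0 - t.rel_ebv)
        r2 = erc / (erc + lam)
        out.append(replace(t, lambda_shrink=lam, erc=erc, r2_drp=r2))
    return out


def read_trait_table(path: str, h2: float | None = None) -> list[TraitRecord]:
    """Read a trait CSV (sample_id, drp, rel_ebv[, h2]) and derive weights."""
    table = pd.read_csv(path, dtype={"sample_id": str})
    need = {"sample_id", "drp", "rel_ebv"}
    if not need.issubset(table.columns):
        raise ValueError(f"{path}: trait table needs columns {sorted(need)}")
    if h2 is None:
        if "h2" not in table.columns:
            raise ValueError(f"{path}: no h2 column and no h2 argument supplied")
        h2_col = table["h2"].astype(float)
    else:
        h2_col = pd.Series([h2] * len(table))
    records = [
        TraitRecord(str(r.sample_id), float(r.drp), float(r.rel_ebv), float(h))
        for r, h in zip(table.itertuples(), h2_col)
    ]
    return derive_trait_weights(records)


def write_trait_table(records: list[TraitRecord], path: str) -> None:
    pd.DataFrame(
        [(t.sample_id, t.drp, t.rel_ebv, t.h2) for t in records],
        columns=["sample_id", "drp", "rel_ebv", "h2"],
    ).to_csv(path, index=False)
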