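"""Partition SNPs into SNP-sets by gene annotation or fixed genomic windows.

A SNP-set is the receptive field of one hidden-layer neuron in the
annotated network: either the SNPs inside one gene, the unannotated SNPs
sharing one intergenic interval, or the SNPs inside one fixed-width
window. Every SNP belongs to exactly one set.
"""

from __future__ import annotations

from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass, field

from .io import GeneAnnotation, VariantRecord, _chrom_key


@dataclass(frozen=True)
class SNPSet:
    set_id: str
    label: str
    kind: str  # gene | intergenic | window
    snp_indices: tuple[int, ...]

    def __post_init__(self):
        if self.kind not in {"gene", "intergenic", "window"}:
            raise ValueError(f"unknown SNP-set kind {self.kind!r}")
        if not self.snp_indices:
            raise ValueError(f"SNP-set {self.set_id} is empty")


@dataclass
class SNPSetPartition:
    """Disjoint, covering assignment of J SNP indices to G SNP-sets."""

    sets: list[SNPSet]
    n_snps: int

    def __post_init__(self):
        seen: set[int] = set()
        for s in self.sets:
            for j in s.snp_indices:
                if j in seen:
                    raise ValueError(f"SNP index {j} assigned to more than one set")
                seen.add(j)
        if seen != set(range(self.n_snps)):
            missing = sorted(set(range(self.n_snps)) - seen)[:5]
            raise ValueError(f"partition does not cover all SNPs (e.g. {missing})")

    @property
    def G(self) -> int:
        return len(self.sets)

    def assignments(self) -> list[int]:
        """Set index per SNP, length n_snps."""
        out = [-1] * self.n_snps
        for g, s in enumerate(self.sets):
            for j in s.snp_indices:
                out[j] = g
        return out


def _check_sorted(variants: list[VariantRecord]) -> None:
    keys = [(_chrom_key(v.chrom), v.pos_bp) for v in variants]
    if keys != sorted(keys):
        raise ValueError("variants must be sorted by (chrom, pos_bp)")


def partition_by_window(
    variants: list[VariantRecord], window_bp: int = 100_000
) -> SNPSetPartition:
    """Tile each chromosome into fixed windows anchored at coordinate 1.

    A SNP at position p belongs to window floor((p-1)/window_bp), i.e.
    windows cover [1, w], [w+1, 2w], ... Empty windows are not emitted.
    """
    if window_bp < 1:
        raise ValueError(f"window_bp must be >= 1, got {window_bp}")
    _check_sorted(variants)
    buckets: dict[tuple[str, int], list[int]] = {}
    for j, v in enumerate(variants):
        buckets.setdefault((v.chrom, (v.pos_bp - 1) // window_bp), []).append(j)
    sets = [
        SNPSet(
            set_id=f"{chrom}:win{widx}",
            label=f"{chrom}:{widx * window_bp + 1}-{(widx + 1) * window_bp}",
            kind="window",
            snp_indices=tuple(idx),
        )
        for (chrom, widx), idx in sorted(
            buckets.items(), key=lambda kv: (_chrom_key(kv[0][0]), kv[0][1])
        )
    ]
    return SNPSetPartition(sets, n_snps=len(variants))


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def partition_by_gene(
    variants: list[VariantRecord], ann: GeneAnnotation
) -> SNPSetPartition:
    """Gene-based SNP-sets: in-gene SNPs join the containing gene's set;
    every other SNP is grouped with the unannotated SNPs sharing its
    intergenic interval on that chromosome.

    A SNP covered by overlapping genes goes to the gene whose midpoint is
    nearest; ties break on the lexicographically smaller gene_id. SNPs on
    chromosomes absent from the annotation form one whole-chromosome
    intergenic set.
    """
    _check_sorted(variants)
    genes_by_chrom = ann.by_chrom()
    gene_members: dict[str, list[int]] = {}
    intergenic_members: dict[tuple[str, int], list[int]] = {}
    # per-chromosome merged gene coverage defines the intergenic intervals
    merged_by_chrom = {
        chrom: _merge_intervals([(g.start_bp, g.end_bp) for g in recs])
        for chrom, recs in genes_by_chrom.items()
    }
    for j, v in enumerate(variants):
        genes = genes_by_chrom.get(v.chrom, [])
        containing = [g for g in genes if g.start_bp <= v.pos_bp <= g.end_bp]
        if containing:
            best = min(
                containing,
                key=lambda g: (abs((g.start_bp + g.end_bp) / 2.0 - v.pos_bp), g.gene_id),
            )
            gene_members.setdefault(best.gene_id, []).append(j)
        else:
            merged = merged_by_chrom.get(v.chrom, [])
            # gap index = number of merged gene blocks entirely left of the SNP
            gap = bisect_right([e for _, e in merged], v.pos_bp)
            intergenic_members.setdefault((v.chrom, gap), []).append(j)

    gene_info = {g.gene_id: g for g in ann.records}
    sets: list[SNPSet] = []
    for gene_id in sorted(gene_members):
        g = gene_info[gene_id]
        sets.append(
            SNPSet(
                set_id=f"gene:{gene_id}",
                label=f"{g.chrom}:{g.start_bp}-{g.end_bp}",
                kind="gene",
                snp_indices=tuple(sorted(gene_members[gene_id])),
            )
        )
    for (chrom, gap) in sorted(
        intergenic_members, key=lambda k: (_chrom_key(k[0]), k[1])
    ):
        sets.append(
            SNPSet(
                set_id=f"{chrom}:intergenic{gap}",
                label=f"{chrom} intergenic interval {gap}",
                kind="intergenic",
                snp_indices=tuple(sorted(intergenic_members[(chrom, gap)])),
            )
        )
    return SNPSetPartition(sets, n_snps=len(variants))


def partition_summary(p: SNPSetPartition) -> dict:
    """Set-size histogram and counts by kind; histogram totals equal G."""
    sizes = Counter(len(s.snp_indices) for s in p.sets)
    kinds = Counter(s.kind for s in p.sets)
    return {
        "G": p.G,
        "n_snps": p.n_snps,
        "size_histogram": dict(sorted(sizes.items())),
        "counts_by_kind": dict(sorted(kinds.items())),
        "max_set_size": max(sizes),
    }
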