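"""Gene/TSS annotation and promoter-set construction.

A promoter is a TSS expanded symmetrically (default 2 kb each side);
overlapping promoters are merged into non-overlapping regions, and each
merged region remembers every gene whose TSS falls inside it.  These
merged promoter regions are both the substrate of the promoter-occupancy
correlation analysis and the denominator of the promoter-anchored
normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .intervals import GenomicInterval, merge_intervals

__all__ = ["TSS", "GeneAnnotation", "PromoterSet", "build_promoters",
           "read_annotation_tsv", "write_annotation_tsv"]


@dataclass(frozen=True)
class TSS:
    chrom: str
    position: int
    strand: str = "."

    def __post_init__(self):
        if self.position < 0:
            raise ValueError(f"TSS position must be >= 0, got {self.position}")


@dataclass
class GeneAnnotation:
    """gene_id -> list of transcription start sites."""

    genes: dict[str, list[TSS]] = field(default_factory=dict)

    def __post_init__(self):
        for gid, tss_list in self.genes.items():
            if not tss_list:
                raise ValueError(f"gene {gid} has no TSS")

    def __len__(self) -> int:
        return len(self.genes)

    def n_tss(self) -> int:
        return sum(len(v) for v in self.genes.values())

    def exclude_chrom(self, chrom: str = "chrY") -> "GeneAnnotation":
        """Drop TSSs on one chromosome (default chrY, as in the promoter
        and clustering analyses); genes left without a TSS are dropped."""
        genes = {}
        for gid, tss_list in self.genes.items():
            kept = [t for t in tss_list if t.chrom != chrom]
            if kept:
                genes[gid] = kept
        return GeneAnnotation(genes)

    def tss_items(self) -> list[tuple[str, TSS]]:
        out = []
        for gid in sorted(self.genes):
            out.extend((gid, t) for t in self.genes[gid])
        return out


@dataclass
class PromoterSet:
    """Sorted, disjoint promoter regions with a region -> genes mapping."""

    regions: list[GenomicInterval]
    region_genes: list[list[str]]

    def __len__(self) -> int:
        return len(self.regions)

    def genes_of(self, i: int) -> list[str]:
        return self.region_genes[i]


def build_promoters(
    annotation: GeneAnnotation,
    flank: int = 2000,
    exclude_chrY: bool = True,
    merge_abutting: bool = True,
) -> PromoterSet:
    """Expand every TSS by ``flank`` bp in both directions and merge overlaps.

    Positions closer than ``flank`` to the chromosome start are clipped at 0.
    The gene mapping is retained through the merge: a merged region carries
    every gene with a TSS inside it.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    ann = annotation.exclude_chrom("chrY") if exclude_chrY else annotation
    items = ann.tss_items()
    if not items:
        warnings.warn("empty annotation: promoter set is empty")
        return PromoterSet(regions=[], region_genes=[])
    raw = [
        GenomicInterval(t.chrom, max(0, t.position - flank), t.position + flank)
        for _, t in items
    ]
    merged = merge_intervals(raw, merge_abutting=merge_abutting)
    # map each TSS into its (unique, by disjointness) merged region
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for i, r in enumerate(merged):
        by_chrom.setdefault(r.chrom, []).append(i)
    region_genes: list[set[str]] = [set() for _ in merged]
    import bisect
    starts_by_chrom = {
        c: [merged[i].start for i in idxs] for c, idxs in by_chrom.items()
    }
    for gid, t in items:
        idxs = by_chrom[t.chrom]
        j = bisect.bisect_right(starts_by_chrom[t.chrom], t.position) - 1
        i = idxs[j]
        assert merged[i].start <= t.position < merged[i].end
        region_genes[i].add(gid)
    return PromoterSet(regions=merged, region_genes=[sorted(s) for s in region_genes])


def read_annotation_tsv(path) -> GeneAnnotation:
    """Read a gene annotation as TSV: gene_id, chrom, tss, strand.

    A header line starting with 'gene_id' is skipped.
    """
    genes: dict[str, list[TSS]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if lineno == 1 and fields[0] == "gene_id":
                continue
            if len(fields) < 3:
                raise ValueError(f"malformed annotation line {lineno}: {line!r}")
            strand = fields[3] if len(fields) > 3 else "."
            genes.setdefault(fields[0], []).append(
                TSS(fields[1], int(fields[2]), strand)
            )
    return GeneAnnotation(genes)


def write_annotation_tsv(path, annotation: GeneAnnotation) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\ttss\tstrand\n")
        for gid, t in annotation.tss_items():
            fh.write(f"{gid}\t{t.chrom}\t{t.position}\t{t.strand}\n")
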