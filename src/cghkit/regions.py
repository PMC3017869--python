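"""Region-of-difference detection and gene absence calling.

A "region of difference" is a maximal run of at least three
consecutive coordinate-ordered probes called absent; shorter runs are
tallied as single or double probe absences and never contribute to gene
calls. A gene is called absent iff its strand-aware translational start
coordinate lies inside some region's genomic span (boundaries
inclusive). This is deliberately conservative: a gene whose 5' end
survives is called present even when most of its body is missing, and
conversely a present gene whose start codon sits in an absent run is
called absent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from cghkit.simulate import GeneAnnotation

MIN_REGION_PROBES = 3


@dataclass
class RegionOfDifference:
    """Maximal run of >= 3 consecutive absent probes. 1-based inclusive span."""

    first_probe: str
    last_probe: str
    start: int  # start of first absent probe
    end: int    # end of last absent probe
    probe_count: int


@dataclass
class RunSummary:
    singles: list[tuple[int, int]]   # (start, end) spans of length-1 runs
    doubles: list[tuple[int, int]]
    regions: list[RegionOfDifference]

    @property
    def counts(self) -> dict[str, int]:
        return {"singles": len(self.singles), "doubles": len(self.doubles),
                "regions": len(self.regions)}


def find_runs(calls: pd.DataFrame) -> RunSummary:
    """Partition maximal runs of call=0 by length (1 / 2 / >= 3).

    ``calls`` must hold probe_id, start, end, call, sorted by start
    (ties by end); gaps left by filtered-out probes do not break runs —
    consecutiveness is over retained probes in coordinate order.
    """
    starts = calls["start"].to_numpy()
    ends = calls["end"].to_numpy()
    order_key = list(zip(starts.tolist(), ends.tolist()))
    if order_key != sorted(order_key):
        raise ValueError("calls must be sorted by start coordinate (ties by end)")

    summary = RunSummary([], [], [])
    vals = calls["call"].to_numpy()
    ids = calls["probe_id"].to_numpy()
    i = 0
    n = len(calls)
    while i < n:
        if vals[i] != 0:
            i += 1
            continue
        j = i
        while j + 1 < n and vals[j + 1] == 0:
            j += 1
        span = (int(starts[i]), int(ends[j]))
        length = j - i + 1
        if length == 1:
            summary.singles.append(span)
        elif length == 2:
            summary.doubles.append(span)
        else:
            summary.regions.append(RegionOfDifference(
                first_probe=str(ids[i]), last_probe=str(ids[j]),
                start=span[0], end=span[1], probe_count=length))
        i = j + 1
    return summary


def call_genes(regions: list[RegionOfDifference],
               annotations: list[GeneAnnotation],
               covered_span: tuple[int, int] | None = None) -> pd.DataFrame:
    """Per-gene present/absent calls from the translational-start rule.

    A gene is absent iff its strand-aware translational start (low
    coordinate on +, high on -) falls within [region.start, region.end]
    of some region, endpoints included. Genes outside the probe-covered
    span (when given) are called present with a warning flag.
    """
    rows = []
    for gene in annotations:
        ts = gene.translational_start
        outside = (covered_span is not None
                   and not covered_span[0] <= ts <= covered_span[1])
        absent = any(r.start <= ts <= r.end for r in regions) and not outside
        rows.append({"gene_id": gene.gene_id, "start": gene.start, "end": gene.end,
                     "strand": gene.strand, "translational_start": ts,
                     "call": "absent" if absent else "present",
                     "outside_coverage": int(outside)})
    return pd.DataFrame(rows, columns=["gene_id", "start", "end", "strand",
                                       "translational_start", "call",
                                       "outside_coverage"])


def summarize(runs: RunSummary, gene_calls: pd.DataFrame) -> dict[str, int]:
    return {**runs.counts,
            "absent_genes": int((gene_calls["call"] == "absent").sum()),
            "total_genes": int(len(gene_calls))}


def write_regions_bed(regions: list[RegionOfDifference], path: str | Path,
                      chrom: str = "reference") -> None:
    """Regions as BED (0-based half-open; internal spans are 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tprobe_count\n")
        for i, r in enumerate(regions, 1):
            fh.write(f"{chrom}\t{r.start - 1}\t{r.end}\tROD{i:04d}\t{r.probe_count}\n")


def read_regions_bed(path: str | Path) -> list[RegionOfDifference]:
    regions = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            _chrom, start, end, _name, count = line.rstrip("\n").split("\t")
            regions.append(RegionOfDifference("", "", int(start) + 1, int(end),
                                              int(count)))
    return regions


def export_tracks(runs: RunSummary, gene_calls: pd.DataFrame, outdir: str | Path,
                  chrom: str = "reference") -> dict[str, int]:
    """Write regions.bed, gene_calls.tsv and summary.json; return the counts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_regions_bed(runs.regions, outdir / "regions.bed", chrom=chrom)
    gene_calls.to_csv(outdir / "gene_calls.tsv", sep="\t", index=False)
    counts = summarize(runs, gene_calls)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(counts, fh, indent=1)
    return counts


def read_gene_annotations(gff_path: str | Path) -> list[GeneAnnotation]:
    """Read CDS features with ID attributes from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(str(gff_path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    genes = []
    for feat in db.features_of_type("CDS", order_by="start"):
        genes.append(GeneAnnotation(feat.attributes["ID"][0], feat.start,
                                    feat.end, feat.strand))
    return genes


def read_gene_calls(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
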