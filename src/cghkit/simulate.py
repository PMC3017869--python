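"""Synthetic CGH study generator.

Builds a reference genome with non-overlapping genes, derives a query
genome by deleting gene islands / single genes and mutating "divergent"
genes, tiles the reference with 60-mer probes at a fixed spacing, and
simulates replicated, dye-swapped two-colour feature tables whose
oriented log2(query/reference) ratios follow a two-component mixture:
binding probes symmetric around 0, non-binding probes strongly negative.

A probe is recorded as non-binding when its target carries >= 3
mismatches against the query (or is deleted), emulating arrays whose
probes were validated to lose signal at a three-nucleotide mismatch.

Coordinates are 1-based inclusive throughout, matching EMBL-style
annotation; the BED writer converts to 0-based half-open.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

BASES = np.array(list("ACGT"))

FLAG_COLUMNS = [
    "gIsFeatNonUnifOL", "rIsFeatNonUnifOL",
    "gIsBGNonUnifOL", "rIsBGNonUnifOL",
    "gIsFeatPopnOL", "rIsFeatPopnOL",
    "gIsBGPopnOL", "rIsBGPopnOL",
]

#: g/r flag pairs; a feature is poor-quality when BOTH members of a pair are set
FLAG_PAIRS = [
    ("gIsFeatNonUnifOL", "rIsFeatNonUnifOL"),
    ("gIsBGNonUnifOL", "rIsBGNonUnifOL"),
    ("gIsFeatPopnOL", "rIsFeatPopnOL"),
    ("gIsBGPopnOL", "rIsBGPopnOL"),
]

MISMATCH_BINDING_LIMIT = 3  # probe fails to bind at >= 3 mismatches


class ConfigurationError(ValueError):
    """Simulation demands exceed genome capacity or violate invariants."""


@dataclass
class SimConfig:
    """Parameters of one synthetic CGH study.

    Defaults describe a scaled-down high-GC actinomycete comparison:
    a 72% G+C reference tiled by 60-mers every 30 bp, a query lacking a
    few multi-gene islands plus isolated genes, two dye-balanced
    replicate pairs, and a present/absent log-ratio mixture separated by
    ~8 standard deviations.
    """

    genome_length: int = 240_000
    gc_content: float = 0.72
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (300, 900)
    probe_length: int = 60
    probe_spacing: int = 30
    n_islands: int = 4
    island_gene_span: tuple[int, int] = (3, 6)
    n_single_deletions: int = 6
    n_divergent: int = 6
    divergence_rate: float = 0.15
    present_ratio_sd: float = 0.25
    absent_ratio_mean: float = -4.0
    absent_ratio_sd: float = 0.5
    n_replicates: int = 2
    flag_rate: float = 0.01
    seed: int = 0
    # composition of genes destined absent/divergent (None = background GC);
    # lets the generator emulate AT-rich recently acquired genes
    absent_gc: float | None = 0.55
    intergenic_both_strand_fraction: float = 0.15
    dye_bias: float = 0.0  # slope of an injected linear M ~ (A - mean A) trend

    def validate(self) -> None:
        if not 0.0 < self.gc_content < 1.0:
            raise ConfigurationError("gc_content must be in (0, 1)")
        if self.probe_length <= 0 or self.probe_spacing <= 0:
            raise ConfigurationError("probe length and spacing must be positive")
        if self.absent_ratio_mean >= -2.0 * self.present_ratio_sd:
            raise ConfigurationError(
                "absent_ratio_mean must be < -2 * present_ratio_sd for the "
                "mixture components to be distinguishable"
            )
        if self.gene_length_range[0] < 3 or self.gene_length_range[0] > self.gene_length_range[1]:
            raise ConfigurationError("invalid gene_length_range")
        if self.n_replicates < 1:
            raise ConfigurationError("need at least one replicate pair")


@dataclass
class GeneAnnotation:
    """One CDS on the reference. 1-based inclusive span."""

    gene_id: str
    start: int
    end: int
    strand: str  # '+' or '-'

    @property
    def translational_start(self) -> int:
        """Strand-aware start-codon coordinate (low end on +, high end on -)."""
        return self.start if self.strand == "+" else self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Probe:
    probe_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str


@dataclass
class GenomePair:
    reference: str
    query: str
    annotations: list[GeneAnnotation]
    probes: list[Probe]


@dataclass
class TruthTable:
    gene_status: dict[str, str]  # gene_id -> present | deleted | divergent
    probe_mismatches: dict[str, int]  # probe_id -> mismatch count vs query
    probe_binds: dict[str, bool]
    # merged 1-based inclusive reference spans removed from the query
    # (island spans include the intergenic DNA between their genes)
    deleted_spans: list[tuple[int, int]] = field(default_factory=list)


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=length, p=p)


def _place_genes(cfg: SimConfig, rng: np.random.Generator) -> list[GeneAnnotation]:
    """Place n_genes non-overlapping genes left to right with random gaps."""
    lo, hi = cfg.gene_length_range
    # gene lengths forced to codon multiples so CDS extraction is clean
    lengths = rng.integers(lo // 3, hi // 3 + 1, size=cfg.n_genes) * 3
    total = int(lengths.sum())
    slack = cfg.genome_length - total
    if slack < cfg.n_genes + 1:
        raise ConfigurationError(
            f"{cfg.n_genes} genes of total {total} bp do not fit in "
            f"{cfg.genome_length} bp with intergenic gaps"
        )
    # n_genes+1 gaps sharing the slack, each >= 1 bp
    cuts = np.sort(rng.choice(np.arange(1, slack), size=cfg.n_genes, replace=False))
    gaps = np.diff(np.concatenate([[0], cuts, [slack]]))
    genes = []
    pos = 0
    for i in range(cfg.n_genes):
        pos += int(gaps[i])
        start = pos + 1
        end = pos + int(lengths[i])
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneAnnotation(f"GENE{i + 1:04d}", start, end, strand))
        pos = end
    return genes


def _tile_probes(cfg: SimConfig, genes: list[GeneAnnotation],
                 rng: np.random.Generator) -> list[Probe]:
    """Tile plus-strand probes genome-wide; add minus-strand complements
    for a fraction of fully intergenic probes."""
    in_gene = np.zeros(cfg.genome_length + 2, dtype=bool)
    for g in genes:
        in_gene[g.start:g.end + 1] = True
    probes = []
    idx = 1
    start = 1
    while start + cfg.probe_length - 1 <= cfg.genome_length:
        end = start + cfg.probe_length - 1
        probes.append(Probe(f"PR{idx:06d}", start, end, "+"))
        idx += 1
        if (not in_gene[start:end + 1].any()
                and rng.random() < cfg.intergenic_both_strand_fraction):
            probes.append(Probe(f"PR{idx:06d}", start, end, "-"))
            idx += 1
        start += cfg.probe_spacing
    return probes


def _assign_statuses(cfg: SimConfig, genes: list[GeneAnnotation],
                     rng: np.random.Generator
                     ) -> tuple[dict[str, str], list[tuple[int, int]]]:
    """Pick island blocks, single deletions and divergent genes, mutually
    disjoint, with at least one present gene separating selections so
    islands stay maximal runs. Returns the status map and the island
    blocks as (first_gene_index, last_gene_index) pairs."""
    status = {g.gene_id: "present" for g in genes}
    taken = np.zeros(len(genes), dtype=bool)
    islands: list[tuple[int, int]] = []

    def block_free(i: int, k: int) -> bool:
        # require a present flank so distinct islands never merge
        lo = max(0, i - 1)
        hi = min(len(genes), i + k + 1)
        return not taken[lo:hi].any()

    spans = rng.integers(cfg.island_gene_span[0], cfg.island_gene_span[1] + 1,
                         size=cfg.n_islands)
    for k in spans:
        placed = False
        for _ in range(1000):
            i = int(rng.integers(0, len(genes) - int(k) + 1))
            if block_free(i, int(k)):
                taken[i:i + int(k)] = True
                for g in genes[i:i + int(k)]:
                    status[g.gene_id] = "deleted"
                islands.append((i, i + int(k) - 1))
                placed = True
                break
        if not placed:
            raise ConfigurationError("could not place deletion islands; genome too crowded")

    def pick_singles(n: int, label: str) -> None:
        for _ in range(n):
            for _ in range(1000):
                i = int(rng.integers(0, len(genes)))
                if block_free(i, 1):
                    taken[i] = True
                    status[genes[i].gene_id] = label
                    break
            else:
                raise ConfigurationError(f"could not place {label} genes")

    pick_singles(cfg.n_single_deletions, "deleted")
    pick_singles(cfg.n_divergent, "divergent")
    return status, islands


def _probe_truth(cfg: SimConfig, ref: np.ndarray, query: np.ndarray,
                 probes: list[Probe], deleted_mask: np.ndarray,
                 shift: np.ndarray) -> tuple[dict[str, int], dict[str, bool]]:
    """Per-probe mismatch counts against the query.

    Deleted bases inside the probe interval count as mismatches; the
    surviving part is compared base-by-base against the query at its
    mapped (deletion-shifted) coordinates.
    """
    mismatches: dict[str, int] = {}
    binds: dict[str, bool] = {}
    for p in probes:
        sl = slice(p.start - 1, p.end)
        del_in = int(deleted_mask[sl].sum())
        mm = del_in
        if del_in < cfg.probe_length:
            keep = ~deleted_mask[sl]
            ref_part = ref[sl][keep]
            qpos = (np.arange(p.start - 1, p.end)[keep] - shift[sl][keep])
            mm += int((ref_part != query[qpos]).sum())
        mismatches[p.probe_id] = mm
        binds[p.probe_id] = mm < MISMATCH_BINDING_LIMIT
    return mismatches, binds


def generate_genome_pair(config: SimConfig) -> tuple[GenomePair, TruthTable]:
    """Build the reference/query pair, probe design and truth table.

    Deterministic under ``config.seed``: identical configs give
    byte-identical sequences, annotations and truth records.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = _place_genes(config, rng)
    ref = _random_sequence(rng, config.genome_length, config.gc_content)
    status, islands = _assign_statuses(config, genes, rng)

    # regenerate absent/divergent genes at their own composition (AT-rich
    # horizontally acquired material) before deriving the query
    if config.absent_gc is not None:
        for g in genes:
            if status[g.gene_id] != "present":
                ref[g.start - 1:g.end] = _random_sequence(rng, g.length, config.absent_gc)

    probes = _tile_probes(config, genes, rng)

    # islands delete the whole block span, intergenic DNA included;
    # single deletions remove just the gene span
    deleted_mask = np.zeros(config.genome_length, dtype=bool)
    island_genes = {genes[i].gene_id
                    for lo, hi in islands for i in range(lo, hi + 1)}
    for lo, hi in islands:
        deleted_mask[genes[lo].start - 1:genes[hi].end] = True
    for g in genes:
        if status[g.gene_id] == "deleted" and g.gene_id not in island_genes:
            deleted_mask[g.start - 1:g.end] = True

    query = ref.copy()
    for g in genes:
        if status[g.gene_id] == "divergent" and config.divergence_rate > 0:
            hit = rng.random(g.length) < config.divergence_rate
            pos = np.arange(g.start - 1, g.end)[hit]
            for j in pos:
                alt = [b for b in "ACGT" if b != query[j]]
                query[j] = alt[int(rng.integers(0, 3))]
    query = query[~deleted_mask]

    # query coordinate of surviving ref position i is i - shift[i] (0-based);
    # deleted positions are masked out before dereferencing
    shift = np.cumsum(deleted_mask) - deleted_mask.astype(int)

    mismatches, binds = _probe_truth(config, ref, query, probes, deleted_mask, shift)

    edges = np.flatnonzero(np.diff(np.concatenate([[0], deleted_mask.view(np.int8), [0]])))
    deleted_spans = [(int(s) + 1, int(e)) for s, e in zip(edges[::2], edges[1::2])]

    pair = GenomePair("".join(ref), "".join(query), genes, probes)
    truth = TruthTable(status, mismatches, binds, deleted_spans)
    return pair, truth


def simulate_signal_tables(pair: GenomePair, truth: TruthTable,
                           config: SimConfig) -> tuple[list["pd.DataFrame"], "pd.DataFrame"]:
    """Simulate per-array two-channel feature tables.

    For each replicate a dye-balanced pair of arrays is produced (query
    labelled red, then green). The biological log-ratio of each probe is
    drawn per array from the binding / non-binding mixture component;
    channel intensities are back-computed from (M, A) so that the
    oriented ratio recovers the sampled M. ``flag_rate`` of features per
    array receive a both-channel outlier flag pair (excluded downstream);
    the same rate again receive a single-channel flag (retained).

    Returns (list of feature tables, array manifest with dye
    orientations). Sampling order is fixed: arrays in manifest order,
    per-array vectors probe-major, so output is seed-deterministic.
    """
    import pandas as pd

    rng = np.random.default_rng(config.seed + 1)
    probe_ids = [p.probe_id for p in pair.probes]
    binding = np.array([truth.probe_binds[pid] for pid in probe_ids])
    n = len(probe_ids)

    manifest_rows = []
    tables = []
    for rep in range(1, config.n_replicates + 1):
        for orientation in ("query_in_red", "query_in_green"):
            array_id = f"array{len(manifest_rows) + 1:02d}"
            manifest_rows.append(
                {"array_id": array_id, "replicate": rep, "dye_orientation": orientation})

            m = np.where(
                binding,
                rng.normal(0.0, config.present_ratio_sd, size=n),
                rng.normal(config.absent_ratio_mean, config.absent_ratio_sd, size=n),
            )
            a = rng.normal(10.0, 1.0, size=n)
            if config.dye_bias:
                m = m + config.dye_bias * (a - a.mean())
            log_q = a + m / 2.0
            log_ref = a - m / 2.0
            if orientation == "query_in_red":
                r_sig, g_sig = 2.0 ** log_q, 2.0 ** log_ref
            else:
                g_sig, r_sig = 2.0 ** log_q, 2.0 ** log_ref

            table = pd.DataFrame({"ProbeID": probe_ids,
                                  "gSignal": g_sig, "rSignal": r_sig})
            for col in FLAG_COLUMNS:
                table[col] = 0
            bad = rng.random(n) < config.flag_rate
            pair_idx = rng.integers(0, len(FLAG_PAIRS), size=n)
            for k, (gcol, rcol) in enumerate(FLAG_PAIRS):
                sel = bad & (pair_idx == k)
                table.loc[sel, gcol] = 1
                table.loc[sel, rcol] = 1
            single = (rng.random(n) < config.flag_rate) & ~bad
            scol = rng.integers(0, len(FLAG_COLUMNS), size=n)
            for k, col in enumerate(FLAG_COLUMNS):
                table.loc[single & (scol == k), col] = 1
            tables.append(table)

    manifest = pd.DataFrame(manifest_rows)
    return tables, manifest


# ---------------------------------------------------------------------------
# writers (1-based internal coordinates; BED output converts to 0-based
# half-open)

def write_fasta(path: Path, name: str, sequence: str) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqio_write([SeqRecord(Seq(sequence), id=name, description="")], str(path), "fasta")


def write_gff(path: Path, genes: list[GeneAnnotation], seqid: str = "reference") -> None:
    """GFF3 with one CDS feature per gene; coordinates 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{seqid}\tcghkit\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t"
                     f"ID={g.gene_id}\n")


def write_bed(path: Path, probes: list[Probe], seqid: str = "reference") -> None:
    """BED6; internal 1-based inclusive [start, end] becomes [start-1, end)."""
    with open(path, "w") as fh:
        for p in probes:
            fh.write(f"{seqid}\t{p.start - 1}\t{p.end}\t{p.probe_id}\t0\t{p.strand}\n")


def write_truth(outdir: Path, pair: GenomePair, truth: TruthTable) -> None:
    import pandas as pd

    pd.DataFrame(
        [{"gene_id": g.gene_id, "status": truth.gene_status[g.gene_id]}
         for g in pair.annotations]
    ).to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"probe_id": p.probe_id,
          "mismatch_count": truth.probe_mismatches[p.probe_id],
          "binds": int(truth.probe_binds[p.probe_id])}
         for p in pair.probes]
    ).to_csv(outdir / "truth_probes.tsv", sep="\t", index=False)


def simulate_study(config: SimConfig, outdir: Path) -> tuple[GenomePair, TruthTable]:
    """Run the full generator and write every artifact under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pair, truth = generate_genome_pair(config)
    write_fasta(outdir / "reference.fasta", "reference", pair.reference)
    write_fasta(outdir / "query.fasta", "query", pair.query)
    write_gff(outdir / "genes.gff", pair.annotations)
    write_bed(outdir / "probes.bed", pair.probes)
    write_truth(outdir, pair, truth)
    tables, manifest = simulate_signal_tables(pair, truth, config)
    arrays_dir = outdir / "arrays"
    arrays_dir.mkdir(exist_ok=True)
    for row, table in zip(manifest.itertuples(), tables):
        table.to_csv(arrays_dir / f"{row.array_id}.tsv", sep="\t", index=False,
                     float_format="%.6f")
    manifest.to_csv(arrays_dir / "arrays.tsv", sep="\t", index=False)
    with open(outdir / "sim_config.json", "w") as fh:
        import json
        json.dump(dataclasses.asdict(config), fh, indent=1)
    return pair, truth
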