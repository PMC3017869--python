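"""Sequence-composition statistics of gene sets.

Per-gene %G+C and Codon Adaptation Index (CAI, Sharp & Li) against a
genome-background codon usage table. CAI is the geometric mean, over a
gene's sense codons, of relative adaptiveness values w_c = f_c /
max(f_c') within each synonymous family, computed from the frequency of
every codon across all coding sequences of the genome (not from a
highly-expressed reference set). Absent/divergent genes with atypical
composition — AT-rich, non-optimal codon usage — stand out in both
distributions, the signature of recently acquired material in a
high-GC genome.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

_STANDARD_TABLE = unambiguous_dna_by_id[1]
STOP_CODONS = set(_STANDARD_TABLE.stop_codons)
SENSE_CODONS = sorted(_STANDARD_TABLE.forward_table)

#: amino acid -> synonymous codon family (stops excluded)
FAMILIES: dict[str, list[str]] = {}
for _codon, _aa in _STANDARD_TABLE.forward_table.items():
    FAMILIES.setdefault(_aa, []).append(_codon)

ZERO_COUNT_W = 0.01  # floor for codons never observed in the background


class SequenceError(ValueError):
    pass


def _validate(seq: str) -> str:
    seq = seq.upper()
    if not seq:
        raise SequenceError("empty sequence")
    if set(seq) - set("ACGT"):
        raise SequenceError(f"ambiguity codes not supported: "
                            f"{sorted(set(seq) - set('ACGT'))}")
    return seq


def gc_content(seq: str) -> float:
    """Fraction of G+C bases; strict ACGT alphabet."""
    seq = _validate(seq)
    return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass
class CodonUsageTable:
    counts: dict[str, int]          # all 64 codons
    frequencies: dict[str, float]   # within-family relative frequencies (sense only)

    @classmethod
    def from_sequences(cls, sequences: dict[str, str]) -> "CodonUsageTable":
        """Aggregate codon counts over CDS sequences (lengths % 3 == 0).

        Genes whose length is not a codon multiple are skipped with a
        warning. Stop codons are tallied but excluded from the families
        used for adaptiveness.
        """
        import warnings

        counts: Counter[str] = Counter()
        for gene_id, seq in sequences.items():
            seq = _validate(seq)
            if len(seq) % 3:
                warnings.warn(f"{gene_id}: length {len(seq)} not divisible by 3; skipped")
                continue
            counts.update(seq[i:i + 3] for i in range(0, len(seq), 3))
        full = {c: counts.get(c, 0) for c in SENSE_CODONS + sorted(STOP_CODONS)}
        freqs: dict[str, float] = {}
        for fam in FAMILIES.values():
            total = sum(full[c] for c in fam)
            for c in fam:
                freqs[c] = full[c] / total if total else 0.0
        return cls(counts=full, frequencies=freqs)


def adaptiveness(table: CodonUsageTable) -> dict[str, float]:
    """Relative adaptiveness w_c = f_c / max f within each synonymous family.

    Zero-count codons get the floor w=0.01; a family with no
    observations at all is uninformative and every member gets w=1.
    """
    w: dict[str, float] = {}
    for fam in FAMILIES.values():
        fam_counts = [table.counts[c] for c in fam]
        fam_max = max(fam_counts)
        for c, n in zip(fam, fam_counts):
            if fam_max == 0:
                w[c] = 1.0
            elif n == 0:
                w[c] = ZERO_COUNT_W
            else:
                w[c] = n / fam_max
    return w


def cai(seq: str, w: dict[str, float]) -> float:
    """Codon Adaptation Index: geometric mean of w over sense codons.

    The terminal stop codon (and any internal stops, for robustness on
    pseudogenes) is excluded.
    """
    seq = _validate(seq)
    if len(seq) % 3:
        raise SequenceError(f"length {len(seq)} not divisible by 3")
    logs = [np.log(w[seq[i:i + 3]])
            for i in range(0, len(seq), 3) if seq[i:i + 3] not in STOP_CODONS]
    if not logs:
        raise SequenceError("no countable (non-stop) codons")
    return float(np.exp(np.mean(logs)))


def extract_cds(genome: str, annotations) -> dict[str, str]:
    """Strand-aware CDS extraction (reverse complement on the minus strand)."""
    out = {}
    for g in annotations:
        sub = genome[g.start - 1:g.end]
        out[g.gene_id] = str(Seq(sub).reverse_complement()) if g.strand == "-" else sub
    return out


def gene_stats(cds: dict[str, str],
               usage: CodonUsageTable | None = None) -> pd.DataFrame:
    """Per-gene gc, cai and codon count against the genome background."""
    if usage is None:
        usage = CodonUsageTable.from_sequences(cds)
    w = adaptiveness(usage)
    rows = []
    for gene_id, seq in cds.items():
        n_codons = sum(1 for i in range(0, len(seq) - len(seq) % 3, 3)
                       if seq[i:i + 3].upper() not in STOP_CODONS)
        rows.append({"gene_id": gene_id, "gc": gc_content(seq),
                     "cai": cai(seq, w), "n_codons_counted": n_codons})
    return pd.DataFrame(rows)


def compare_distributions(stats: pd.DataFrame, absent_gene_ids: set[str],
                          bins: int = 20) -> dict:
    """Histogram summaries of gc and cai for all genes vs the absent set.

    Returns, per metric, shared-bin histograms for both groups, the
    group means and the mean difference (absent minus all).
    """
    unknown = absent_gene_ids - set(stats["gene_id"])
    if unknown:
        raise ValueError(f"absent ids outside the gene universe: {sorted(unknown)[:5]}")
    absent = stats[stats["gene_id"].isin(absent_gene_ids)]
    out: dict = {"n_all": int(len(stats)), "n_absent": int(len(absent))}
    for metric in ("gc", "cai"):
        all_vals = stats[metric].to_numpy()
        edges = np.histogram_bin_edges(all_vals, bins=bins)
        h_all, _ = np.histogram(all_vals, bins=edges)
        if len(absent):
            abs_vals = absent[metric].to_numpy()
            h_abs, _ = np.histogram(abs_vals, bins=edges)
            mean_abs = float(abs_vals.mean())
        else:
            h_abs, mean_abs = np.zeros(bins, dtype=int), None
        out[metric] = {
            "bin_edges": edges.tolist(),
            "hist_all": h_all.tolist(),
            "hist_absent": h_abs.tolist(),
            "mean_all": float(all_vals.mean()),
            "mean_absent": mean_abs,
            "mean_difference": None if mean_abs is None
            else mean_abs - float(all_vals.mean()),
        }
    return out
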