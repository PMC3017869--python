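"""Reciprocal-BLAST cross-validation of array gene calls.

A gene is present in the other genome iff each direction of a pairwise
nucleotide search contains a hit for it with alignment length > 60 nt,
identity > 60% and E-value < 0.01 (any qualifying hit suffices, not
only the best). Array calls are then compared against these BLAST calls
in a confusion matrix with BLAST as the reference: TP = present by
both, TN = absent by both, FN = array-absent / BLAST-present, FP =
array-present / BLAST-absent; sensitivity TP/(TP+FN), specificity
TN/(TN+FP), accuracy (TP+TN)/total, reported as half-up-rounded
percentages.

Hit tables are consumed as BLAST tabular (outfmt 6) files; a bundled
exact-seed, ungapped-extension aligner can generate such tables for
synthetic genomes so no BLAST executable is required.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

OUTFMT6_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
                   "qstart", "qend", "sstart", "send", "evalue", "bitscore"]

MIN_ALIGN_LENGTH = 60   # strict: length must exceed this
MIN_IDENTITY = 60.0     # strict: identity must exceed this
MAX_EVALUE = 0.01       # strict: evalue must be below this


def read_hits(path: str | Path) -> pd.DataFrame:
    """Read a BLAST outfmt-6 tabular hit file."""
    hits = pd.read_csv(path, sep="\t", names=OUTFMT6_COLUMNS, comment="#")
    if len(hits) and ((hits["pident"] < 0).any() or (hits["pident"] > 100).any()
                      or (hits["length"] < 1).any() or (hits["evalue"] < 0).any()):
        raise ValueError(f"{path}: hit fields out of range")
    return hits


def _qualifying(hits: pd.DataFrame) -> pd.DataFrame:
    return hits[(hits["length"] > MIN_ALIGN_LENGTH)
                & (hits["pident"] > MIN_IDENTITY)
                & (hits["evalue"] < MAX_EVALUE)]


def classify_presence_reciprocal(hits_fwd: pd.DataFrame, hits_rev: pd.DataFrame,
                                 gene_id: str) -> str:
    """Present iff the gene has a qualifying hit in BOTH directions.

    Forward hits are keyed by query id, reverse hits by subject id (the
    gene's homologue aligned back against the gene's own genome). A gene
    missing from either table is absent.
    """
    fwd_ok = gene_id in set(_qualifying(hits_fwd)["qseqid"])
    rev_ok = gene_id in set(_qualifying(hits_rev)["sseqid"])
    return "present" if fwd_ok and rev_ok else "absent"


def classify_all(hits_fwd: pd.DataFrame, hits_rev: pd.DataFrame,
                 gene_ids: list[str]) -> pd.Series:
    """Vectorized reciprocal classification over a gene universe."""
    fwd_ok = set(_qualifying(hits_fwd)["qseqid"])
    rev_ok = set(_qualifying(hits_rev)["sseqid"])
    return pd.Series({g: "present" if g in fwd_ok and g in rev_ok else "absent"
                      for g in gene_ids}, name="blast_call")


@dataclass
class ConfusionMatrix:
    tp: int  # present by array AND by BLAST
    tn: int  # absent by both
    fn: int  # array absent, BLAST present
    fp: int  # array present, BLAST absent

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fn + self.fp

    def as_dict(self) -> dict[str, int]:
        return {"TP": self.tp, "TN": self.tn, "FN": self.fn, "FP": self.fp,
                "total": self.total}


def confusion(array_calls: pd.Series, blast_calls: pd.Series) -> ConfusionMatrix:
    """Cross-tabulate array vs BLAST calls (BLAST as the reference).

    Both inputs map gene_id -> 'present'/'absent' over the same gene
    universe; a universe mismatch raises with the symmetric difference.
    """
    a_idx, b_idx = set(array_calls.index), set(blast_calls.index)
    if a_idx != b_idx:
        diff = sorted(a_idx ^ b_idx)
        raise ValueError(f"gene universes differ; symmetric difference: {diff[:10]}"
                         f"{'...' if len(diff) > 10 else ''}")
    arr = array_calls.reindex(blast_calls.index)
    tp = int(((arr == "present") & (blast_calls == "present")).sum())
    tn = int(((arr == "absent") & (blast_calls == "absent")).sum())
    fn = int(((arr == "absent") & (blast_calls == "present")).sum())
    fp = int(((arr == "present") & (blast_calls == "absent")).sum())
    return ConfusionMatrix(tp=tp, tn=tn, fn=fn, fp=fp)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def performance(cm: ConfusionMatrix) -> dict[str, object]:
    """Sensitivity, specificity and accuracy of the array calls.

    Percentages are rounded half-up to integers for reporting; the
    exact values are returned alongside. Zero denominators yield None.
    """
    def rate(num: int, den: int) -> float | None:
        return 100.0 * num / den if den > 0 else None

    sens = rate(cm.tp, cm.tp + cm.fn)
    spec = rate(cm.tn, cm.tn + cm.fp)
    acc = rate(cm.tp + cm.tn, cm.total)
    out: dict[str, object] = {}
    for name, val in [("sensitivity", sens), ("specificity", spec), ("accuracy", acc)]:
        out[name] = None if val is None else _round_half_up(val)
        out[name + "_exact"] = val
    return out


def venn(sets: dict[str, set[str]]) -> dict[str, int]:
    """Exact region cardinalities for 2 or 3 absence sets.

    Keys are '+'-joined sorted combinations of set labels, e.g. for
    sets A, B, C: 'A', 'B', 'C' (exclusive), 'A+B', ..., 'A+B+C'.
    """
    if len(sets) not in (2, 3):
        raise ValueError("venn partitioning supports 2 or 3 sets")
    labels = sorted(sets)
    universe = set().union(*sets.values())
    regions: dict[str, int] = {}
    from itertools import combinations
    for k in range(1, len(labels) + 1):
        for combo in combinations(labels, k):
            inside = set.intersection(*(sets[l] for l in combo))
            outside = set().union(*(sets[l] for l in labels if l not in combo))
            regions["+".join(combo)] = len(inside - outside)
    regions["union"] = len(universe)
    return regions


# ---------------------------------------------------------------------------
# naive local aligner (exact-seed + ungapped extension) for fixture hit tables

# Karlin-Altschul parameters for blastn defaults (match +1 / mismatch -2,
# ungapped); used only to attach a plausible E-value to fixture hits
_KA_LAMBDA = 1.33
_KA_K = 0.621
_MATCH, _MISMATCH = 1, -2


def _extend(q: str, s: str, qi: int, si: int, k: int,
            xdrop: int = 20) -> tuple[int, int, int, int]:
    """Ungapped X-drop extension of a k-mer seed; returns
    (qstart, qend, matches, length), 0-based half-open in the query."""
    def scan(step: int, q0: int, s0: int) -> int:
        best, cur, ext, best_ext = 0, 0, 0, 0
        i = 1
        while 0 <= q0 + step * i < len(q) and 0 <= s0 + step * i < len(s):
            cur += _MATCH if q[q0 + step * i] == s[s0 + step * i] else _MISMATCH
            ext = i
            if cur > best:
                best, best_ext = cur, ext
            if cur < best - xdrop:
                break
            i += 1
        return best_ext

    left = scan(-1, qi, si)
    right = scan(+1, qi + k - 1, si + k - 1)
    qstart, qend = qi - left, qi + k + right
    sstart = si - left
    matches = sum(1 for a, b in zip(q[qstart:qend], s[sstart:sstart + (qend - qstart)])
                  if a == b)
    return qstart, qend, matches, qend - qstart


def seed_extend_hits(queries: dict[str, str], subjects: dict[str, str],
                     k: int = 12) -> pd.DataFrame:
    """Approximate blastn: exact k-mer seeds, ungapped X-drop extension.

    Returns an outfmt-6-shaped table with one best hit per
    (query, subject) pair that shares a seed. E-values use ungapped
    Karlin-Altschul statistics on the raw match/mismatch score.
    """
    index: dict[str, list[tuple[str, int]]] = {}
    for sid, seq in subjects.items():
        for i in range(0, len(seq) - k + 1):
            index.setdefault(seq[i:i + k], []).append((sid, i))

    total_subject = sum(len(s) for s in subjects.values())
    rows = []
    for qid, q in queries.items():
        best: dict[str, tuple] = {}
        seen: set[tuple[str, int, int]] = set()
        for i in range(0, len(q) - k + 1):
            for sid, j in index.get(q[i:i + k], []):
                diag = j - i
                key = (sid, diag, i // 50)  # one extension per diagonal stripe
                if key in seen:
                    continue
                seen.add(key)
                qs, qe, matches, length = _extend(q, subjects[sid], i, j, k)
                score = matches * _MATCH + (length - matches) * _MISMATCH
                if sid not in best or score > best[sid][0]:
                    bits = (_KA_LAMBDA * score - math.log(_KA_K)) / math.log(2)
                    evalue = len(q) * total_subject * 2.0 ** (-bits)
                    pident = 100.0 * matches / length
                    ss = j - (i - qs)
                    best[sid] = (score, qs, qe, matches, length, pident, evalue, ss)
        for sid, (score, qs, qe, matches, length, pident, evalue, ss) in best.items():
            rows.append({"qseqid": qid, "sseqid": sid,
                         "pident": round(pident, 3), "length": length,
                         "mismatch": length - matches, "gapopen": 0,
                         "qstart": qs + 1, "qend": qe,
                         "sstart": ss + 1, "send": ss + length,
                         "evalue": evalue, "bitscore": round(
                             (_KA_LAMBDA * score - math.log(_KA_K)) / math.log(2), 1)})
    return pd.DataFrame(rows, columns=OUTFMT6_COLUMNS)


def write_hits(hits: pd.DataFrame, path: str | Path) -> None:
    hits.to_csv(path, sep="\t", index=False, header=False)
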