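"""Two-colour feature-table processing.

Turns per-array Agilent-style feature tables into one summarized log2
ratio per probe: QC filtering on paired outlier flags, dye-orientation
correction, within-array loess normalization of M against A, between-
array scale (MAD) normalization, dye-balanced replicate selection, per-
probe replicate medians, and averaging of complementary strand-paired
probes.

The fixed stage order is flag_poor -> orient_and_log -> loess (per
array) -> scale across arrays -> select_replicates -> summarize_median
-> average_complementary; `process_arrays` runs all of it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from cghkit.simulate import FLAG_COLUMNS, FLAG_PAIRS, Probe

REQUIRED_COLUMNS = ["ProbeID", "gSignal", "rSignal", *FLAG_COLUMNS]

INTENSITY_FLOOR = 0.5  # zero intensities floored before log2 to avoid -inf

LOESS_SPAN = 0.3
LOESS_ITERATIONS = 3


class SchemaError(ValueError):
    """Feature table lacks required columns or contains malformed rows."""


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read one feature TSV; error on missing columns rather than defaulting.

    Returns the table with ProbeID, gSignal, rSignal and the eight
    outlier-flag columns. Malformed numeric fields raise SchemaError
    naming the offending line.
    """
    table = pd.read_csv(path, sep="\t", dtype={"ProbeID": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    for col in ["gSignal", "rSignal", *FLAG_COLUMNS]:
        coerced = pd.to_numeric(table[col], errors="coerce")
        if coerced.isna().any():
            line = int(coerced.isna().idxmax()) + 2  # header + 1-based
            raise SchemaError(f"{path}: malformed value in column {col} at line {line}")
        table[col] = coerced
    if (table[["gSignal", "rSignal"]].to_numpy() < 0).any():
        raise SchemaError(f"{path}: negative intensity")
    return table[REQUIRED_COLUMNS].copy()


def read_array_dir(arrays_dir: str | Path) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Read every array table plus the arrays.tsv manifest from a directory."""
    arrays_dir = Path(arrays_dir)
    manifest = pd.read_csv(arrays_dir / "arrays.tsv", sep="\t")
    tables = {row.array_id: read_feature_table(arrays_dir / f"{row.array_id}.tsv")
              for row in manifest.itertuples()}
    return tables, manifest


def flag_poor(table: pd.DataFrame) -> pd.Series:
    """Boolean mask of poor-quality features.

    A feature is excluded iff, for at least one of the four outlier
    variables, BOTH the green and red channel flags are set; a flag in
    one channel only is tolerated.
    """
    bad = np.zeros(len(table), dtype=bool)
    for gcol, rcol in FLAG_PAIRS:
        bad |= (table[gcol].to_numpy() != 0) & (table[rcol].to_numpy() != 0)
    return pd.Series(bad, index=table.index, name="poor")


def orient_and_log(table: pd.DataFrame, dye_orientation: str,
                   floor: float = INTENSITY_FLOOR) -> pd.DataFrame:
    """Compute oriented M = log2(query/reference) and A per feature.

    ``dye_orientation`` names the channel carrying the query sample;
    intensities are floored at ``floor`` before taking logs.
    """
    if dye_orientation not in ("query_in_red", "query_in_green"):
        raise ValueError(f"unknown dye orientation: {dye_orientation}")
    g = np.maximum(table["gSignal"].to_numpy(dtype=float), floor)
    r = np.maximum(table["rSignal"].to_numpy(dtype=float), floor)
    if dye_orientation == "query_in_red":
        m = np.log2(r) - np.log2(g)
    else:
        m = np.log2(g) - np.log2(r)
    a = (np.log2(g) + np.log2(r)) / 2.0
    return pd.DataFrame({"probe_id": table["ProbeID"].to_numpy(), "M": m, "A": a})


def loess_normalize_within_array(ratios: pd.DataFrame, span: float = LOESS_SPAN,
                                 iterations: int = LOESS_ITERATIONS) -> pd.DataFrame:
    """Subtract a robust loess fit of M on A from each feature's M."""
    if len(ratios) < 50:
        raise ValueError(f"loess normalization needs >= 50 features, got {len(ratios)}")
    fitted = lowess(ratios["M"].to_numpy(), ratios["A"].to_numpy(),
                    frac=span, it=iterations, return_sorted=False)
    out = ratios.copy()
    out["M"] = ratios["M"].to_numpy() - fitted
    return out


def scale_normalize_between_arrays(per_array: dict[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Equalize the spread of M across arrays.

    Each array's M is divided by its median absolute deviation and
    multiplied by the geometric mean of all arrays' MADs, so every array
    ends with the same MAD while rankings within arrays are preserved.
    """
    if len(per_array) < 2:
        raise ValueError("between-array scale normalization needs >= 2 arrays")
    mads = {}
    for aid, df in per_array.items():
        m = df["M"].to_numpy()
        mad = np.median(np.abs(m - np.median(m)))
        if mad == 0:
            raise ValueError(f"array {aid} has zero MAD; cannot scale-normalize")
        mads[aid] = mad
    target = float(np.exp(np.mean(np.log(list(mads.values())))))
    out = {}
    for aid, df in per_array.items():
        scaled = df.copy()
        scaled["M"] = df["M"].to_numpy() * (target / mads[aid])
        out[aid] = scaled
    return out


def select_replicates(values: pd.DataFrame,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Apply the dye-balanced replicate-selection rule per probe.

    ``values`` has columns probe_id, array_id, dye_orientation, M over
    good-quality features only. A probe is retained iff it has at least
    one good value in each dye orientation (hence >= 2 values after
    balancing); where one orientation is over-represented, values from
    the over-represented side are dropped at random (seeded ``rng``)
    until both sides are equal.
    """
    kept = []
    for probe_id, grp in values.groupby("probe_id", sort=True):
        red = grp[grp["dye_orientation"] == "query_in_red"]
        green = grp[grp["dye_orientation"] == "query_in_green"]
        k = min(len(red), len(green))
        if k == 0:
            continue
        for side in (red, green):
            if len(side) > k:
                take = rng.choice(len(side), size=k, replace=False)
                kept.append(side.iloc[np.sort(take)])
            else:
                kept.append(side)
    if not kept:
        return values.iloc[0:0]
    return pd.concat(kept, ignore_index=True)


def summarize_median(selected: pd.DataFrame) -> pd.DataFrame:
    """Median oriented M per retained probe, with the replicate count used."""
    grouped = selected.groupby("probe_id", sort=True)["M"]
    out = grouped.median().rename("M").reset_index()
    out["n_used"] = grouped.size().to_numpy()
    return out


def average_complementary(summary: pd.DataFrame, probes: list[Probe]) -> pd.DataFrame:
    """Merge strand-paired probes (identical coordinates, opposite strand).

    Both samples are DNA, so complementary probes interrogate the same
    locus; their median ratios are replaced by one record with the
    arithmetic-mean M at the shared coordinates. If one member of a pair
    was dropped upstream the survivor passes through unaveraged.
    Unpaired probes pass through. Output is coordinate-sorted.
    """
    design = pd.DataFrame(
        [{"probe_id": p.probe_id, "start": p.start, "end": p.end, "strand": p.strand}
         for p in probes])
    merged = summary.merge(design, on="probe_id", how="left")
    if merged["start"].isna().any():
        missing = merged.loc[merged["start"].isna(), "probe_id"].tolist()[:5]
        raise ValueError(f"probes absent from design: {missing}")
    rows = []
    for (start, end), grp in merged.groupby(["start", "end"], sort=True):
        if len(grp) == 1:
            rows.append(grp.iloc[0].to_dict())
        else:
            lead = grp.sort_values("probe_id").iloc[0].to_dict()
            lead["M"] = float(grp["M"].mean())
            lead["n_used"] = int(grp["n_used"].sum())
            rows.append(lead)
    out = pd.DataFrame(rows).sort_values(["start", "end"], kind="mergesort")
    out["start"] = out["start"].astype(int)
    out["end"] = out["end"].astype(int)
    return out[["probe_id", "start", "end", "M", "n_used"]].reset_index(drop=True)


def process_arrays(tables: dict[str, pd.DataFrame], manifest: pd.DataFrame,
                   probes: list[Probe], span: float = LOESS_SPAN,
                   seed: int = 0) -> pd.DataFrame:
    """Full signal pipeline: feature tables -> summarized probe track.

    Returns a coordinate-sorted DataFrame (probe_id, start, end, M,
    n_used) with one row per retained probe/locus.
    """
    orientation = dict(zip(manifest["array_id"], manifest["dye_orientation"]))
    per_array = {}
    good_rows = []
    for aid in manifest["array_id"]:
        table = tables[aid]
        poor = flag_poor(table)
        ratios = orient_and_log(table, orientation[aid])
        ratios = loess_normalize_within_array(ratios, span=span)
        ratios["poor"] = poor.to_numpy()
        per_array[aid] = ratios
    scaled = scale_normalize_between_arrays(
        {aid: df[["probe_id", "M", "A"]] for aid, df in per_array.items()})
    for aid, df in scaled.items():
        df = df.copy()
        df["array_id"] = aid
        df["dye_orientation"] = orientation[aid]
        df["poor"] = per_array[aid]["poor"].to_numpy()
        good_rows.append(df[~df["poor"]])
    values = pd.concat(good_rows, ignore_index=True)
    rng = np.random.default_rng(seed)
    selected = select_replicates(
        values[["probe_id", "array_id", "dye_orientation", "M"]], rng)
    summary = summarize_median(selected)
    return average_complementary(summary, probes)


def read_probes_bed(path: str | Path) -> list[Probe]:
    """Read a BED6 probe design; converts 0-based half-open to 1-based inclusive."""
    probes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, name, _score, strand = line.rstrip("\n").split("\t")[:6]
            probes.append(Probe(name, int(start) + 1, int(end), strand))
    return probes


def write_track(track: pd.DataFrame, path: str | Path, chrom: str = "reference") -> None:
    out = track.copy()
    out.insert(1, "chrom", chrom)
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_track(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
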