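"""End-to-end pipeline orchestration.

Runs simulate -> normalize -> genomotype -> regions -> validate ->
seqstats -> fba from a single config, writing each stage's artifacts
into a run directory plus a manifest (seed, parameter hash, stage
outputs) that makes a byte-identical re-run possible. A failure in
stage k leaves the outputs of earlier stages in place.

The validate stage builds reciprocal hit tables between the reference
and query gene sets with the bundled seed-and-extend aligner, so no
BLAST executable is needed; the fba stage runs the glyoxylate-shunt
growth experiment on the shipped toy network with the nine CGH-absent
metabolic genes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from cghkit import crossval, fba, genomotype, models, regions, seqstats, signal
from cghkit.simulate import SimConfig, simulate_study

log = logging.getLogger("cghkit")

STAGES = ["simulate", "normalize", "genomotype", "regions", "validate",
          "seqstats", "fba"]


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0
    epp_threshold: float = genomotype.DEFAULT_THRESHOLD
    loess_span: float = signal.LOESS_SPAN
    stages: list[str] = field(default_factory=lambda: list(STAGES))

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        # one global seed drives every stochastic stage
        self.sim.seed = self.seed

    def parameter_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the configured stages in fixed order; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed,
                      "parameter_hash": config.parameter_hash(),
                      "stages_run": [], "outputs": {}}
    state: dict = {}

    for stage in STAGES:
        if stage not in config.stages:
            continue
        log.info("stage %s", stage)
        _RUNNERS[stage](config, outdir, state)
        manifest["stages_run"].append(stage)
        manifest["outputs"][stage] = state.get(f"{stage}_outputs", [])
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    return manifest


def _run_simulate(config: PipelineConfig, outdir: Path, state: dict) -> None:
    pair, truth = simulate_study(config.sim, outdir / "sim")
    state["pair"], state["truth"] = pair, truth
    state["simulate_outputs"] = ["sim/reference.fasta", "sim/query.fasta",
                                 "sim/genes.gff", "sim/probes.bed",
                                 "sim/arrays", "sim/truth_genes.tsv",
                                 "sim/truth_probes.tsv"]


def _run_normalize(config: PipelineConfig, outdir: Path, state: dict) -> None:
    tables, manifest = signal.read_array_dir(outdir / "sim" / "arrays")
    probes = signal.read_probes_bed(outdir / "sim" / "probes.bed")
    track = signal.process_arrays(tables, manifest, probes,
                                  span=config.loess_span, seed=config.seed)
    signal.write_track(track, outdir / "track.tsv")
    state["track"] = track
    state["normalize_outputs"] = ["track.tsv"]


def _run_genomotype(config: PipelineConfig, outdir: Path, state: dict) -> None:
    calls = genomotype.binary_call(state["track"], threshold=config.epp_threshold)
    genomotype.write_calls(calls, outdir / "calls.tsv")
    state["calls"] = calls
    state["genomotype_outputs"] = ["calls.tsv"]


def _run_regions(config: PipelineConfig, outdir: Path, state: dict) -> None:
    calls = state["calls"].sort_values(["start", "end"], kind="mergesort")
    runs = regions.find_runs(calls)
    annotations = regions.read_gene_annotations(outdir / "sim" / "genes.gff")
    covered = (int(calls["start"].min()), int(calls["end"].max()))
    gene_calls = regions.call_genes(runs.regions, annotations, covered_span=covered)
    counts = regions.export_tracks(runs, gene_calls, outdir)
    state["gene_calls"], state["runs"], state["counts"] = gene_calls, runs, counts
    state["annotations"] = annotations
    state["regions_outputs"] = ["regions.bed", "gene_calls.tsv", "summary.json"]


def _query_gene_sequences(state: dict) -> dict[str, str]:
    """CDS set of the query genome: surviving genes, mutations included."""
    pair, truth = state["pair"], state["truth"]
    deleted_spans = truth.deleted_spans

    def q_coord(ref_pos: int) -> int:
        return ref_pos - sum(min(e, ref_pos) - s + 1
                             for s, e in deleted_spans if s <= ref_pos)

    out = {}
    for g in pair.annotations:
        if truth.gene_status[g.gene_id] == "deleted":
            continue
        qs, qe = q_coord(g.start), q_coord(g.end)
        sub = pair.query[qs - 1:qe]
        if g.strand == "-":
            from Bio.Seq import Seq
            sub = str(Seq(sub).reverse_complement())
        out[g.gene_id + "_q"] = sub
    return out


def _run_validate(config: PipelineConfig, outdir: Path, state: dict) -> None:
    pair = state["pair"]
    ref_cds = seqstats.extract_cds(pair.reference, pair.annotations)
    query_cds = _query_gene_sequences(state)
    fwd = crossval.seed_extend_hits(ref_cds, query_cds)
    rev = crossval.seed_extend_hits(query_cds, {g: s for g, s in ref_cds.items()})
    crossval.write_hits(fwd, outdir / "fwd.tab")
    crossval.write_hits(rev, outdir / "rev.tab")
    # reverse direction: the query homologue of gene G is named G_q, so a
    # reverse qualifying hit must land back on G
    rev_mapped = rev.copy()
    blast_calls = pd.Series({
        g: "present"
        if (g in set(crossval._qualifying(fwd)["qseqid"])
            and g in set(crossval._qualifying(
                rev_mapped[rev_mapped["qseqid"] == g + "_q"])["sseqid"]))
        else "absent"
        for g in ref_cds})
    array_calls = state["gene_calls"].set_index("gene_id")["call"]
    cm = crossval.confusion(array_calls, blast_calls)
    perf = crossval.performance(cm)
    with open(outdir / "confusion.json", "w") as fh:
        json.dump(cm.as_dict(), fh, indent=1)
    with open(outdir / "performance.json", "w") as fh:
        json.dump(perf, fh, indent=1)
    state["confusion"], state["performance"] = cm, perf
    state["blast_calls"] = blast_calls
    state["validate_outputs"] = ["fwd.tab", "rev.tab", "confusion.json",
                                 "performance.json"]


def _run_seqstats(config: PipelineConfig, outdir: Path, state: dict) -> None:
    pair = state["pair"]
    cds = seqstats.extract_cds(pair.reference, pair.annotations)
    stats = seqstats.gene_stats(cds)
    absent = set(state["gene_calls"].loc[
        state["gene_calls"]["call"] == "absent", "gene_id"])
    hist = seqstats.compare_distributions(stats, absent)
    stats.to_csv(outdir / "seqstats.tsv", sep="\t", index=False,
                 float_format="%.6f")
    with open(outdir / "histograms.json", "w") as fh:
        json.dump(hist, fh, indent=1)
    state["seqstats"] = stats
    state["seqstats_outputs"] = ["seqstats.tsv", "histograms.json"]


def _run_fba(config: PipelineConfig, outdir: Path, state: dict) -> None:
    model = models.toy_model()
    reduced, removed = fba.remove_reactions_for_absent_genes(
        model, set(models.CGH_ABSENT_METABOLIC_GENES))
    screen = fba.growth_phenotype_screen(
        model,
        media={"glucose": models.glucose_minimal_medium(),
               "palmitate": models.palmitate_minimal_medium()},
        deletion_sets={"wild_type": set(),
                       "cgh_reduced": set(models.CGH_ABSENT_METABOLIC_GENES)})
    result = fba.maximize_biomass(reduced, models.palmitate_minimal_medium())
    fba.write_result(result, outdir / "fba_result.json")
    pd.DataFrame({"removed_reaction": removed}).to_csv(
        outdir / "removal_report.tsv", sep="\t", index=False)
    screen.to_csv(outdir / "growth_screen.tsv", sep="\t")
    state["fba_result"], state["growth_screen"] = result, screen
    state["fba_outputs"] = ["fba_result.json", "removal_report.tsv",
                            "growth_screen.tsv"]


_RUNNERS = {
    "simulate": _run_simulate,
    "normalize": _run_normalize,
    "genomotype": _run_genomotype,
    "regions": _run_regions,
    "validate": _run_validate,
    "seqstats": _run_seqstats,
    "fba": _run_fba,
}


def recovery_metrics(gene_calls: pd.DataFrame, truth) -> dict[str, float]:
    """Gene-level sensitivity/specificity of pipeline calls vs the truth
    table (truth 'absent' = deleted or divergent)."""
    calls = gene_calls.set_index("gene_id")["call"]
    truth_absent = {g for g, s in truth.gene_status.items() if s != "present"}
    tp = sum(1 for g in calls.index if g in truth_absent and calls[g] == "absent")
    fn = sum(1 for g in calls.index if g in truth_absent and calls[g] == "present")
    tn = sum(1 for g in calls.index if g not in truth_absent and calls[g] == "present")
    fp = sum(1 for g in calls.index if g not in truth_absent and calls[g] == "absent")
    return {"sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
            "specificity": tn / (tn + fp) if tn + fp else float("nan"),
            "tp": tp, "fn": fn, "tn": tn, "fp": fp}
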