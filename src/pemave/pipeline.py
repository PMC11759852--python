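"""End-to-end orchestration: synthetic study -> designs -> counts -> scores.

This module wires the stages together the way a real run flows: catalogs
are written to disk and re-read through the parsers, libraries are designed
per editing window, reads are simulated and counted per amplicon, and the
per-library score tables are normalized and evaluated jointly. It exists so
tests, the acceptance script and the CLI all exercise one code path.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .catalogs import (
    TruthSetReport,
    classify_variants,
    generate_ptc_controls,
    parse_clinvar_export,
    parse_gnomad_export,
    validate_truth_sets,
)
from .design import DesignParams, LibraryDesign, design_library
from .kmers import CountTable, SampleFiles, build_dictionary, counts_to_table, depth_qc
from .scoring import (
    SeparationReport,
    evaluate_truth_sets,
    normalize_scores,
    score_table,
)
from .simulate import (
    PoolSim,
    SimulationConfig,
    SyntheticLocus,
    amplicon_window,
    make_synthetic_locus,
    simulate_pools,
    write_fastq_pair,
)


@dataclass
class PipelineResult:
    """Everything a full synthetic run produced."""

    locus: SyntheticLocus
    truth_report: TruthSetReport
    library: LibraryDesign
    pools: dict[str, PoolSim]
    tables: dict[str, CountTable]
    depth_reports: dict[str, pd.DataFrame]
    scores: dict[str, pd.DataFrame]
    normalized: dict[str, pd.DataFrame]
    combined: pd.DataFrame
    separation: SeparationReport


def prepare_records(config: SimulationConfig, workdir: Path):
    """Generate the locus, round-trip catalogs through their file formats
    and parsers, add PTC controls and classify."""
    locus = make_synthetic_locus(config)
    paths = locus.write(workdir)
    clinvar_recs, cv_rejects = parse_clinvar_export(paths["clinvar"])
    gnomad_recs, gn_rejects = parse_gnomad_export(paths["gnomad"])
    if cv_rejects or gn_rejects:
        raise RuntimeError(
            f"synthetic catalogs produced rejects: {cv_rejects + gn_rejects}"
        )
    ptc = []
    for interval in locus.hotspots:
        ptc.extend(generate_ptc_controls(locus.ctx, interval))
    records = classify_variants(clinvar_recs + gnomad_recs + ptc, ac_min=config.ac_min)
    return locus, records


def run_end_to_end(
    config: SimulationConfig,
    workdir=None,
    params: DesignParams | None = None,
    strategy: str = "vus",
    n_windows: int = 2,
    k: int = 25,
    af_threshold: float = 0.001,
) -> PipelineResult:
    """Run the whole pipeline on a synthetic study.

    One amplicon library is simulated, sequenced and scored per selected
    editing window; scores are then centered across libraries and the
    truth-set separation evaluated on the combined table. All randomness
    derives from ``config.seed``.
    """
    params = params or DesignParams()
    tmp_ctx = None
    if workdir is None:
        tmp_ctx = tempfile.TemporaryDirectory(prefix="pemave_")
        workdir = tmp_ctx.name
    workdir = Path(workdir)
    try:
        locus, records = prepare_records(config, workdir)
        truth_report = validate_truth_sets(records)
        library = design_library(
            locus.ctx, records, params=params, strategy=strategy, n_target=n_windows
        )
        classes = {r.variant_id: r.class_label for r in records}

        seedseq = np.random.SeedSequence([config.seed, 0xE2E])
        pools: dict[str, PoolSim] = {}
        tables: dict[str, CountTable] = {}
        depth_reports: dict[str, pd.DataFrame] = {}
        scores: dict[str, pd.DataFrame] = {}
        for w in library.windows:
            designs = library.designs[w.window_id]
            if not designs:
                continue
            child = np.random.default_rng(seedseq.spawn(1)[0])
            pools[w.window_id] = simulate_pools(config, designs, rng=child)
            entries = build_dictionary(designs, locus.ctx, k=k)
            amp = amplicon_window(locus.ctx, w.edit_interval, config.amplicon_len)
            var_pos = {
                d.variant.variant_id: (d.variant.pos - 1, d.variant.alt)
                for d in designs
            }
            samples = []
            for cond in ("control", "selected"):
                for rep in range(1, config.replicates + 1):
                    r1 = workdir / f"{w.window_id}_{cond}_rep{rep}_R1.fastq.gz"
                    r2 = workdir / f"{w.window_id}_{cond}_rep{rep}_R2.fastq.gz"
                    write_fastq_pair(
                        pools[w.window_id].fractions[(cond, rep)],
                        var_pos,
                        locus.ctx,
                        amp,
                        config,
                        r1,
                        r2,
                        rng=np.random.default_rng(seedseq.spawn(1)[0]),
                    )
                    samples.append(
                        SampleFiles(
                            sample_id=f"{w.window_id}_{cond}_rep{rep}",
                            condition=cond,
                            replicate=rep,
                            r1=r1,
                            r2=r2,
                        )
                    )
            table = counts_to_table(samples, entries)
            tables[w.window_id] = table
            depth_reports[w.window_id] = depth_qc(table)
            result = score_table(table, classes=classes, threshold=af_threshold)
            scores[w.window_id] = result.scores

        normalized = normalize_scores(scores)
        combined = pd.concat(normalized.values()) if normalized else pd.DataFrame()
        separation = evaluate_truth_sets(combined)
        return PipelineResult(
            locus=locus,
            truth_report=truth_report,
            library=library,
            pools=pools,
            tables=tables,
            depth_reports=depth_reports,
            scores=scores,
            normalized=normalized,
            combined=combined,
            separation=separation,
        )
    finally:
        if tmp_ctx is not None:
            tmp_ctx.cleanup()


def dropout_fraction_for_seed(seed: int, config: SimulationConfig | None = None):
    """Designed-variant dropout for one seed: design the default libraries
    on the synthetic locus, simulate pools, and report the fraction of
    designed variants with zero control-pool frequency."""
    import dataclasses

    config = dataclasses.replace(config or SimulationConfig(), seed=seed)
    with tempfile.TemporaryDirectory(prefix="pemave_drop_") as tmp:
        locus, records = prepare_records(config, Path(tmp))
        library = design_library(locus.ctx, records, strategy="vus", n_target=2)
    n_total, n_dropped = 0, 0
    seedseq = np.random.SeedSequence([config.seed, 0xD20])
    for w in library.windows:
        designs = library.designs[w.window_id]
        if not designs:
            continue
        pool = simulate_pools(
            config, designs, rng=np.random.default_rng(seedseq.spawn(1)[0])
        )
        n_total += len(pool.variant_ids)
        n_dropped += sum(pool.dropped.values())
    return n_dropped, n_total
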