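"""End-to-end driver: simulate -> quantify -> DE -> gradient -> qPCR.

``run_all`` executes the whole workflow on synthetic data and writes a
versioned, machine-readable JSON report of every threshold applied and
the record counts surviving each stage. All randomness flows from the
single design seed, so repeated runs are byte-identical.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io, qpcr, quantify, simulate
from .diffexpr import DEConfig, compare_samples
from .gradient import cpm_table, gradient_table, venn_partition
from .simulate import SimulationDesign

logger = logging.getLogger("mirgrad")

REPORT_SCHEMA_VERSION = 1

COMPARISONS = (
    ("tumor_vs_normal", "normal", "tumor"),
    ("adjacent_vs_normal", "normal", "adjacent"),
    ("tumor_vs_adjacent", "adjacent", "tumor"),
)


@dataclass
class PipelineConfig:
    """Everything run_all needs: design, thresholds, options, output dir."""

    design: SimulationDesign = field(default_factory=SimulationDesign)
    de: DEConfig = field(default_factory=DEConfig)
    strict_gradient: bool = False
    qpcr_samples: int = 9
    qpcr_noise_sd: float = 0.1
    qpcr_paired: bool = False
    n_demo_reads: int = 2000

    @classmethod
    def from_file(cls, path, seed: int | None = None) -> "PipelineConfig":
        """Build a config from a flat key-value file.

        Keys matching SimulationDesign fields go to the design, keys
        matching DEConfig fields to the thresholds, the rest to pipeline
        options; unknown keys raise.
        """
        raw = io.read_config(path)
        if seed is not None:
            raw["seed"] = seed
        design_fields = {f.name for f in dataclasses.fields(SimulationDesign)}
        de_fields = {f.name for f in dataclasses.fields(DEConfig)}
        own_fields = {
            f.name for f in dataclasses.fields(cls) if f.name not in ("design", "de")
        }
        design_kw, de_kw, own_kw = {}, {}, {}
        for key, value in raw.items():
            if key in design_fields:
                design_kw[key] = value
            elif key in de_fields:
                de_kw[key] = value
            elif key in own_fields:
                own_kw[key] = value
            else:
                raise ValueError(f"unknown configuration key {key!r}")
        return cls(
            design=SimulationDesign(**design_kw), de=DEConfig(**de_kw), **own_kw
        )


def run_all(config: PipelineConfig, out_dir) -> dict:
    """Run the full synthetic workflow; returns the report dict.

    Stages (in report order): simulate, quantify (one demo FASTQ sample),
    one DE block per comparison with survivor counts for the filter, the
    FDR cut and the fold-change gate, the Venn partition of the two
    normal-referenced DE sets, gradient calls, and qPCR validation of up
    to three called gradient miRNAs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = config.design
    outputs: dict[str, str] = {}
    stages: list[dict] = []

    # --- simulation -------------------------------------------------------
    logger.info("simulating %d precursors", design.n_mirnas)
    precursors = simulate.simulate_precursors(
        design.n_mirnas, design.seed, design.read_length_weights
    )
    io.write_fasta([(p.id, p.sequence) for p in precursors], out / "precursors.fasta")
    io.write_mature_gff(precursors, out / "mature.gff3")
    outputs["precursors"] = "precursors.fasta"
    outputs["annotations"] = "mature.gff3"

    reads, _ = simulate.simulate_reads(
        precursors, design, n_reads=config.n_demo_reads
    )
    io.write_fastq(reads, out / "reads_demo.fastq")
    outputs["reads"] = "reads_demo.fastq"

    mature_ids = [pre.mature_arms[0].mature_id for pre in precursors]
    matrix, truth = simulate.simulate_counts(design, mirna_ids=mature_ids)
    io.write_counts(matrix, out / "counts.tsv")
    io.write_table(truth.reset_index(), out / "truth.tsv")
    outputs["counts"] = "counts.tsv"
    outputs["truth"] = "truth.tsv"
    stages.append(
        {
            "stage": "simulate",
            "n_precursors": len(precursors),
            "n_reads": len(reads),
            "n_mirnas": design.n_mirnas,
            "seed": design.seed,
        }
    )

    # --- quantification of the demo reads ---------------------------------
    quant = quantify.quantify_sample(reads, precursors)
    io.write_table(
        quant.counts.rename_axis("mature_id").reset_index(), out / "demo_counts.tsv"
    )
    io.write_table(quantify.profile_table({"demo": quant}), out / "demo_isomirs.tsv")
    io.write_table(
        quant.length_hist.rename_axis("length").reset_index(), out / "demo_lengths.tsv"
    )
    outputs["demo_counts"] = "demo_counts.tsv"
    outputs["demo_isomirs"] = "demo_isomirs.tsv"
    outputs["demo_lengths"] = "demo_lengths.tsv"
    stages.append(
        {
            "stage": "quantify",
            "n_reads": quant.n_reads,
            "n_assigned": quant.n_assigned,
            "n_unassigned": quant.n_unassigned,
            "n_multi_assigned": len(quant.multi_assignments),
        }
    )

    # --- differential expression ------------------------------------------
    de_tables: dict[str, pd.DataFrame] = {}
    for name, sample_a, sample_b in COMPARISONS:
        table = compare_samples(matrix, sample_a, sample_b, config.de)
        de_tables[name] = table
        filename = f"de_{name}.tsv"
        io.write_table(table.reset_index(drop=True), out / filename)
        outputs[f"de_{name}"] = filename
        n_fdr = int(
            (table["kept"] & (table["q_value"] < config.de.q_threshold)).sum()
        )
        stages.append(
            {
                "stage": "de",
                "comparison": name,
                "n_total": int(len(table)),
                "n_filter": int(table["kept"].sum()),
                "n_fdr": n_fdr,
                "n_fold_change": int(table["called"].sum()),
            }
        )

    called_t = set(de_tables["tumor_vs_normal"].loc[lambda t: t["called"], "mirna_id"])
    called_a = set(
        de_tables["adjacent_vs_normal"].loc[lambda t: t["called"], "mirna_id"]
    )
    tumor_only, adjacent_only, shared = venn_partition(called_t, called_a)
    stages.append(
        {
            "stage": "venn",
            "tumor_only": len(tumor_only),
            "adjacent_only": len(adjacent_only),
            "shared": len(shared),
        }
    )

    # --- gradient calling ---------------------------------------------------
    cpm = cpm_table(matrix)
    gradients = gradient_table(
        cpm,
        de_tables["tumor_vs_normal"],
        de_tables["adjacent_vs_normal"],
        de_ta=de_tables["tumor_vs_adjacent"],
        strict=config.strict_gradient,
    )
    io.write_table(gradients.reset_index(drop=True), out / "gradient.tsv")
    outputs["gradient"] = "gradient.tsv"
    class_counts = gradients["class"].value_counts()
    stages.append(
        {
            "stage": "gradient",
            "up_gradient": int(class_counts.get("up_gradient", 0)),
            "down_gradient": int(class_counts.get("down_gradient", 0)),
            "none": int(class_counts.get("none", 0)),
            "strict": config.strict_gradient,
        }
    )

    # --- qPCR validation of called gradient miRNAs --------------------------
    called_gradients = sorted(
        gradients.loc[gradients["class"] != "none", "mirna_id"]
    )
    targets = called_gradients[:3]
    if targets:
        qpcr_table = simulate.simulate_qpcr(
            truth,
            n_samples=config.qpcr_samples,
            noise_sd=config.qpcr_noise_sd,
            seed=design.seed + 1,
            targets=targets,
        )
        io.write_table(qpcr_table, out / "qpcr.tsv")
        summary, contrasts = qpcr.analyze_qpcr(
            qpcr_table, paired=config.qpcr_paired
        )
        io.write_table(summary, out / "qpcr_summary.tsv")
        io.write_table(contrasts, out / "qpcr_contrasts.tsv")
        outputs["qpcr"] = "qpcr.tsv"
        outputs["qpcr_summary"] = "qpcr_summary.tsv"
        outputs["qpcr_contrasts"] = "qpcr_contrasts.tsv"
    stages.append(
        {
            "stage": "qpcr",
            "n_targets": len(targets),
            "n_samples": config.qpcr_samples if targets else 0,
        }
    )

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": design.seed,
        "thresholds": {
            "min_count": config.de.min_count,
            "q_threshold": config.de.q_threshold,
            "fc_threshold": config.de.fc_threshold,
            "pseudocount_cpm": config.de.pseudocount_cpm,
            "strict_gradient": config.strict_gradient,
        },
        "stages": stages,
        "outputs": outputs,
    }
    with open(out / "report.json", "w") as handle:
        json.dump(report, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return report
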