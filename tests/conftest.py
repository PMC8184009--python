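"""Shared fixtures: tiny hand-built annotations and session-scoped
simulated datasets with full pipeline runs."""

from __future__ import annotations

from pathlib import Path

import pytest

from crypticsplice.annotation_io import (
    GenomeAnnotation,
    TranscriptModel,
    load_annotation,
    load_genome,
)
from crypticsplice.cli import load_pipeline_config, run_quantify, run_discover, run_resplice
from crypticsplice.cryptic_discovery import ExperimentDesign
from crypticsplice.splice_motifs import train_splice_models
from crypticsplice.synthetic_data import SimulationConfig, generate, plant_resplice_fixture


def write_genome(tmp: Path, chroms: dict[str, str]):
    """Write a FASTA and open it as a GenomeSequence."""
    path = tmp / "genome.fa"
    with open(path, "w") as fh:
        for name, seq in chroms.items():
            fh.write(f">{name}\n{seq}\n")
    return load_genome(path)


def edit_distance(a: str, b: str) -> int:
    dp = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        prev, dp[0] = dp[0], i
        for j, cb in enumerate(b, 1):
            prev, dp[j] = dp[j], min(dp[j] + 1, dp[j - 1] + 1, prev + (ca != cb))
    return dp[-1]


def write_sample_sheet(ds, path: Path, control: str) -> Path:
    with open(path, "w") as fh:
        fh.write("path\tsample_id\tcondition\tis_control\n")
        for sid, cond in ds.samples.items():
            fh.write(f"{ds.sams[sid]}\t{sid}\t{cond}\t{int(cond == control)}\n")
    return path


class PipelineRun:
    """Full pipeline products on one simulated dataset."""

    def __init__(self, ds, outdir: Path, seed: int):
        self.ds = ds
        cfg = load_pipeline_config(None, seed=seed)
        self.cfg = cfg
        self.genome = load_genome(ds.fasta)
        self.ann = load_annotation(ds.gtf, self.genome)
        paths = {sid: str(p) for sid, p in ds.sams.items()}
        self.matrix = run_quantify(paths, dict(ds.samples), self.genome, cfg)
        design = ExperimentDesign.from_conditions(dict(ds.samples), ds.config.control)
        self.donor_pwm, self.acceptor_pwm = train_splice_models(self.ann, self.genome)
        self.calls, self.waterfall = run_discover(
            self.matrix, self.ann, design, cfg, self.genome,
            self.donor_pwm, self.acceptor_pwm)
        self.events = run_resplice(self.calls, self.ann, self.genome,
                                   self.donor_pwm, self.acceptor_pwm)


@pytest.fixture(scope="session")
def noise_free_run(tmp_path_factory) -> PipelineRun:
    """Default 100-gene noise-free dataset, full pipeline."""
    out = tmp_path_factory.mktemp("simfull")
    ds = generate(SimulationConfig(seed=11), out)
    return PipelineRun(ds, out, seed=11)


@pytest.fixture(scope="session")
def resplice_run(tmp_path_factory) -> PipelineRun:
    """Hand-designed re-splicing fixture, full pipeline."""
    out = tmp_path_factory.mktemp("simresplice")
    ds = plant_resplice_fixture(SimulationConfig(seed=3), outdir=out)
    return PipelineRun(ds, out, seed=3)


def build_classification_toy():
    """Annotation whose geometry realises every discovery class.

    Gene gA (+, chr1): exons [0,100) [200,300) [400,500) [600,700).
    Gene gB (-, chr1): exons [1000,1100) [1200,1300) [1400,1500).
    """
    tA = TranscriptModel("tA", "gA", "chr1", "+",
                         exons=((0, 100), (200, 300), (400, 500), (600, 700)))
    tB = TranscriptModel("tB", "gB", "chr1", "-",
                         exons=((1000, 1100), (1200, 1300), (1400, 1500)))
    ann = GenomeAnnotation.from_transcripts([tA, tB])
    from crypticsplice.junction_quant import Junction

    labelled = [
        # annotated pair -> not novel at all
        (Junction("chr1", "+", 100, 200), "annotated", "neither"),
        # both ends annotated, non-adjacent pairing (skips exon 2)
        (Junction("chr1", "+", 100, 400), "novel_alternative", "neither"),
        # novel donor inside exon 1 joined to annotated acceptor
        (Junction("chr1", "+", 50, 200), "exonic_5ss", "donor"),
        # annotated donor joined to novel acceptor inside exon 2
        (Junction("chr1", "+", 100, 250), "exonic_3ss", "acceptor"),
        # novel donor inside intron 1 joined to annotated acceptor of intron 1
        (Junction("chr1", "+", 150, 200), "intronic_5ss", "donor"),
        # annotated donor joined to novel acceptor inside intron 1
        (Junction("chr1", "+", 100, 160), "intronic_3ss", "acceptor"),
        # both ends novel
        (Junction("chr1", "+", 130, 170), "unclassified", "both"),
        # minus strand: donor of gB intron = right boundary
        (Junction("chr1", "-", 1100, 1200), "annotated", "neither"),
        # minus, novel donor inside exon (transcript-upstream exon is right)
        (Junction("chr1", "-", 1100, 1250), "exonic_5ss", "donor"),
        # minus, novel acceptor inside exon 1 (genomically left)
        (Junction("chr1", "-", 1050, 1200), "exonic_3ss", "acceptor"),
        # minus, novel acceptor inside the intron
        (Junction("chr1", "-", 1150, 1200), "intronic_3ss", "acceptor"),
        # minus, novel donor inside the intron
        (Junction("chr1", "-", 1100, 1150), "intronic_5ss", "donor"),
    ]
    return ann, labelled
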