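"""Shared fixtures: synthetic designs and one full pipeline run.

The expensive fixture (``nnk_pipeline_run``) simulates the extended-motif
NNK library at full study scale (3 replicates, 100k reads per sample),
emits FASTQ, and runs demultiplexing, variant calling and scoring once
per session; several tests share it.
"""

from __future__ import annotations

import numpy as np
import pytest

from motifdms import scoring, synthetic_data as sd, variant_calling as vc
from motifdms.library_design import LibraryDesign

SESSION_SEED = 11


@pytest.fixture(scope="session")
def nnk_design() -> LibraryDesign:
    """16-codon NNK scan of the extended motif (ORF codons 85-100)."""
    return sd.example_design("NNK", (85, 100))


@pytest.fixture(scope="session")
def tiny_design() -> LibraryDesign:
    """A 4-codon NNN design on a 27-nt synthetic ORF fragment."""
    return LibraryDesign(
        wt_nt_seq="ATGAAACCATTGCCACCATTGCCAGAA",
        orf_codon_offset=1,
        region_start_codon=3,
        region_end_codon=6,
        scheme="NNN",
    )


@pytest.fixture(scope="session")
def nnk_pipeline_run(nnk_design, tmp_path_factory):
    """Error-free full-scale run: simulate -> reads -> call -> score."""
    params = sd.SimulationParams(
        seed=SESSION_SEED,
        read_depth=100_000,
        n_replicates=3,
        conditions=("MTX+sorbitol",),
        baits=("Sho1",),
        error_rate=0.0,
    )
    effects = sd.EffectModel.classes(nnk_design, seed=SESSION_SEED)
    truth = sd.simulate_counts(nnk_design, params, effects)
    manifest = sd.default_manifest(truth, params)
    fastq = tmp_path_factory.mktemp("nnk_run") / "reads.fastq"
    sd.emit_reads(nnk_design, truth, params, manifest, fastq)
    counts = vc.count_reads(fastq, nnk_design, manifest)
    scores = scoring.score_counts(counts, nnk_design)
    return {
        "design": nnk_design,
        "params": params,
        "effects": effects,
        "truth": truth,
        "manifest": manifest,
        "fastq": fastq,
        "counts": counts,
        "scores": scores,
    }


def aa_key(design: LibraryDesign, pos: int, mut_aa: str) -> str:
    return f"{design.wt_aa(pos)}-{pos}-{mut_aa}"


def planted_keys(design, table, predicate):
    """aa_change_keys of planted effects satisfying a predicate on (b, a)."""
    return {aa_key(design, pos, aa) for (pos, aa), v in table.items() if predicate(v)}
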