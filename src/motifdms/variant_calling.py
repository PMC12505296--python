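"""From amplicon reads to a per-sample codon-variant count table.

The stages mirror a standard targeted-DMS counting workflow: demultiplex
on row/column sample barcodes (one substitution tolerated per side, the
assignment must be unique), collapse identical reads, globally align each
unique read to the wild-type reference (Needleman-Wunsch with affine gaps
at EMBOSS-needle-like DNA defaults), and call a single-codon variant when
all mismatches fall inside exactly one codon of the mutagenized region.

Reads whose mismatches span two or more codons are tallied as
``multi_codon`` and reads with gaps as ``indel_other``; neither enters the
per-sample depth over which frequencies are computed, so sequencing
errors do not deflate the frequencies of interpretable molecules.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .library_design import LibraryDesign, VariantKey, annotate_variant

__all__ = [
    "make_aligner",
    "align_to_reference",
    "validate_manifest",
    "demultiplex",
    "collapse_reads",
    "call_variant",
    "call_sequence",
    "tabulate",
    "count_reads",
    "read_fastq",
]

ASSIGNED_CLASSES = ("variant", "wt_identical")
SPECIAL_CLASSES = ("wt_identical", "multi_codon", "indel_other", "unassigned")

# EMBOSS-needle-like DNA scoring: match +5, mismatch -4, gap open 10,
# gap extend 0.5, end gaps free.  N is mismatch-neutral (score 0).
MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 5.0, -4.0, 10.0, 0.5


def make_aligner() -> Align.PairwiseAligner:
    mat = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for a in "ACGT":
        for b in "ACGT":
            mat[a, b] = MATCH if a == b else MISMATCH
    for b in "ACGTN":
        mat["N", b] = 0.0
        mat[b, "N"] = 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    # gap of length L costs GAP_OPEN + (L - 1) * GAP_EXTEND
    aligner.open_gap_score = -GAP_OPEN
    aligner.extend_gap_score = -GAP_EXTEND
    try:  # end gaps are free, as in EMBOSS needle's default endweight
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Bio.Align attribute names
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


_ALIGNER = None


def _aligner() -> Align.PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        _ALIGNER = make_aligner()
    return _ALIGNER


def align_to_reference(seq: str, wt_nt_seq: str):
    """Global alignment of a read against the wild-type sequence.

    Returns a Bio.Align.Alignment (reference is the target, read the
    query).  Non-ACGTN characters are rejected.
    """
    if not seq or not wt_nt_seq:
        raise ValueError("sequences must be nonempty")
    for s in (seq, wt_nt_seq):
        if any(c not in "ACGTN" for c in s):
            raise ValueError("sequences must contain only A/C/G/T/N")
    return _aligner().align(wt_nt_seq, seq)[0]


# --------------------------------------------------------------------------
# Demultiplexing
# --------------------------------------------------------------------------


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "bait", "condition", "replicate", "timepoint",
                "barcode_row", "barcode_col"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    pairs = manifest[["barcode_row", "barcode_col"]].apply(tuple, axis=1)
    if pairs.duplicated().any():
        raise ValueError("duplicate barcode pairs in manifest")
    if manifest["barcode_row"].str.len().nunique() > 1 or \
            manifest["barcode_col"].str.len().nunique() > 1:
        raise ValueError("barcodes must have equal length per side")
    return manifest


def _barcode_matches(observed: str, barcodes: Iterable[str]) -> list[str]:
    """Barcodes within Hamming distance 1 of the observed sequence."""
    hits = []
    for bc in barcodes:
        d = 0
        for a, b in zip(observed, bc):
            if a != b:
                d += 1
                if d > 1:
                    break
        if d <= 1:
            hits.append(bc)
    return hits


def demultiplex(reads: Iterable[str], manifest: pd.DataFrame) -> dict[str, list[str]]:
    """Assign reads to samples by their row/column barcode pair.

    A read is assigned iff both barcodes match within at most one
    substitution and the (row, column) pair identifies exactly one manifest
    entry; otherwise it lands in ``"unassigned"``.  Barcodes are stripped
    from assigned reads.
    """
    validate_manifest(manifest)
    len_row = len(manifest["barcode_row"].iloc[0])
    len_col = len(manifest["barcode_col"].iloc[0])
    row_bcs = sorted(set(manifest["barcode_row"]))
    col_bcs = sorted(set(manifest["barcode_col"]))
    pair_to_sample = {
        (r, c): s
        for r, c, s in zip(manifest["barcode_row"], manifest["barcode_col"],
                           manifest["sample_id"])
    }
    out: dict[str, list[str]] = {s: [] for s in manifest["sample_id"]}
    out["unassigned"] = []
    cache: dict[tuple[str, str], str | None] = {}
    for read in reads:
        if len(read) <= len_row + len_col:
            out["unassigned"].append(read)
            continue
        obs = (read[:len_row], read[-len_col:])
        sample = cache.get(obs, "?")
        if sample == "?":
            rows = _barcode_matches(obs[0], row_bcs)
            cols = _barcode_matches(obs[1], col_bcs)
            candidates = {
                pair_to_sample[(r, c)]
                for r in rows for c in cols
                if (r, c) in pair_to_sample
            }
            sample = candidates.pop() if len(candidates) == 1 else None
            cache[obs] = sample
        if sample is None:
            out["unassigned"].append(read)
        else:
            out[sample].append(read[len_row:-len_col])
    return out


def collapse_reads(reads: Iterable[str]) -> list[tuple[str, int]]:
    """Unique sequences with multiplicities, descending then lexicographic."""
    counts = Counter(reads)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


# --------------------------------------------------------------------------
# Variant calling
# --------------------------------------------------------------------------


def _call_from_mismatches(mismatch_nt: list[int], observed, design: LibraryDesign):
    """Resolve a gapless set of mismatched reference positions to a call."""
    if not mismatch_nt:
        return "wt_identical"
    codons = {design.codon_of_nt(i) for i in mismatch_nt}
    if len(codons) > 1:
        return "multi_codon"
    pos = codons.pop()
    if not (design.region_start_codon <= pos <= design.region_end_codon):
        return "unassigned"  # single mutated codon outside the mutagenized window
    a, b = design.codon_slice(pos)
    codon = "".join(observed(i) for i in range(a, b))
    if any(c not in "ACGT" for c in codon):
        return "unassigned"
    return VariantKey(pos, codon)


def call_variant(alignment, design: LibraryDesign):
    """Call a single-codon variant from a global alignment to the reference.

    Returns a VariantKey, or one of ``wt_identical``, ``multi_codon``,
    ``indel_other``, ``unassigned``.  Any gap (in read or reference) makes
    the read ``indel_other``; mismatches in more than one codon make it
    ``multi_codon``.
    """
    ref_aln, read_aln = alignment[0], alignment[1]
    ref_len = len(alignment.target)
    # positions of the reference consumed and the read base facing them
    facing: list[str] = [""] * ref_len
    ref_i = 0
    has_gap = False
    for r, q in zip(ref_aln, read_aln):
        if r == "-":
            has_gap = True  # insertion in the read
            continue
        facing[ref_i] = q
        ref_i += 1
    if ref_i != ref_len:
        return "indel_other"
    interior = [i for i, q in enumerate(facing) if q == "-"]
    if interior:
        # deletions: end gaps (read shorter than reference at the edges)
        # also make the read uninterpretable for single-codon calling
        return "indel_other"
    if has_gap:
        return "indel_other"
    mism = [i for i, q in enumerate(facing) if q != design.wt_nt_seq[i] and q != "N"]
    return _call_from_mismatches(mism, lambda i: facing[i], design)


# conservative bound: with <= _FAST_PATH_MAX_DIFF mismatches on an
# equal-length read, the gapless alignment strictly beats any gapped one
# under the scoring above, so the DP can be skipped.
_FAST_PATH_MAX_DIFF = 6


def call_sequence(seq: str, design: LibraryDesign):
    """Call a barcode-stripped read, using a gapless fast path when exact."""
    wt = design.wt_nt_seq
    if len(seq) == len(wt):
        mism = [i for i in range(len(wt)) if seq[i] != wt[i] and seq[i] != "N"]
        if len(mism) <= _FAST_PATH_MAX_DIFF:
            return _call_from_mismatches(mism, seq.__getitem__, design)
    return call_variant(align_to_reference(seq, wt), design)


def call_sample(reads: Iterable[str], design: LibraryDesign) -> Counter:
    """Collapse reads and call each unique sequence; returns call -> count."""
    calls: Counter = Counter()
    for seq, mult in collapse_reads(reads):
        calls[call_sequence(seq, design)] += mult
    return calls


# --------------------------------------------------------------------------
# Tabulation
# --------------------------------------------------------------------------


def tabulate(calls_by_sample: Mapping[str, Counter], design: LibraryDesign,
             manifest: pd.DataFrame | None = None) -> pd.DataFrame:
    """Build the per-sample count table with depths and frequencies.

    Depth D counts assigned reads only (single-codon variants plus
    wild-type-identical); frequencies are counts over D.  Variants
    enumerated by the design but never observed get count 0.  Samples
    whose depth is 0 have all frequencies missing.
    """
    from .library_design import enumerate_variants

    enumerated = [key for key, ann in enumerate_variants(design)
                  if ann.variant_class != "wt_identical"]
    meta = None
    if manifest is not None:
        meta = manifest.set_index("sample_id")[["bait", "condition", "replicate", "timepoint"]]
    rows = []
    for sample_id, calls in calls_by_sample.items():
        observed_keys = sorted(
            (k for k in calls if isinstance(k, VariantKey)),
            key=lambda k: (k.codon_position, k.mutant_codon),
        )
        all_keys = sorted(set(enumerated) | set(observed_keys),
                          key=lambda k: (k.codon_position, k.mutant_codon))
        depth = calls.get("wt_identical", 0) + sum(calls[k] for k in observed_keys)
        base = {"sample_id": sample_id}
        if meta is not None and sample_id in meta.index:
            base.update(meta.loc[sample_id].to_dict())
        for key in all_keys:
            c = calls.get(key, 0)
            rows.append({**base, "class": "variant",
                         "codon_position": key.codon_position,
                         "mutant_codon": key.mutant_codon,
                         "count": c, "depth": depth,
                         "frequency": c / depth if depth else np.nan})
        for cls in SPECIAL_CLASSES:
            c = calls.get(cls, 0)
            in_depth = cls == "wt_identical"
            rows.append({**base, "class": cls,
                         "codon_position": pd.NA, "mutant_codon": pd.NA,
                         "count": c, "depth": depth,
                         "frequency": (c / depth if depth else np.nan) if in_depth else np.nan})
    table = pd.DataFrame(rows)
    table["codon_position"] = table["codon_position"].astype("Int64")
    return table


def read_fastq(path) -> "Iterable[str]":
    """Yield read sequences from a (possibly gzipped) FASTQ file."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    path = str(path)
    if path.endswith(".gz"):
        import gzip

        with gzip.open(path, "rt") as fh:
            for _, seq, _ in FastqGeneralIterator(fh):
                yield seq
    else:
        with open(path) as fh:
            for _, seq, _ in FastqGeneralIterator(fh):
                yield seq


def count_reads(fastq_path, design: LibraryDesign, manifest: pd.DataFrame) -> pd.DataFrame:
    """Full counting pipeline: demultiplex, collapse, align, call, tabulate."""
    grouped = demultiplex(read_fastq(fastq_path), manifest)
    calls = {}
    for sample_id, reads in grouped.items():
        if sample_id == "unassigned":
            continue
        calls[sample_id] = call_sample(reads, design)
        calls[sample_id]["unassigned"] += 0
    table = tabulate(calls, design, manifest)
    return table
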