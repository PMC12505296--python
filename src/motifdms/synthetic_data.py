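"""Seeded synthetic inputs with the statistical structure the analysis assumes.

The generator emulates a pooled DHFR protein-fragment complementation
(PCA) competition on a single-codon variant library: each variant ``v``
carries a binding-specific fitness effect ``b_v`` (expressed only under
methotrexate selection with the SH3-carrying bait, Sho1) and an abundance
effect ``a_v`` (expressed with either bait, because it changes how much
prey-DHFR fusion is present).  Selection is multiplicative per generation,
so after ``G = generations_per_cycle * n_cycles`` generations the expected
frequency of a variant is

    f_post(v)  proportional to  f_pre(v) * 2**(s_v * G)

with ``s_v = b_v * [MTX & Sho1 bait] * (sorbitol multiplier) + a_v``.
Read counts are multinomial draws at a configurable depth; amplicon reads
can be emitted as FASTQ with row/column sample barcodes and a uniform
per-base error rate.  Optical-density trajectories and replicated colony
grids with plate/row/column bias are generated for the growth-curve and
solid-media stages.

Nonsense variants truncate the prey upstream of its C-terminal DHFR
fragment, abolishing the PCA signal for both baits; the generator models
this as an abundance effect ``a = -s_null`` so that the nonsense floor is
seen in both the Sho1 and the Hog1 (abundance control) libraries, as it is
in the real assay.

All randomness flows from one named seed.  The defaults are the study
conditions: 3 replicate pools, 4 conditions (plus/minus MTX crossed with
plus/minus 1 M sorbitol), 2 selection cycles, and a sorbitol multiplier
greater than 1 because osmotic stress strengthens the motif interaction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .library_design import (
    STOP,
    LibraryDesign,
    VariantKey,
    annotate_variant,
    enumerate_variants,
    mutant_sequence,
    translate_codon,
)

__all__ = [
    "CONDITIONS",
    "SimulationParams",
    "EffectModel",
    "example_design",
    "condition_has_mtx",
    "condition_has_sorbitol",
    "simulate_counts",
    "default_manifest",
    "emit_reads",
    "simulate_od",
    "simulate_colony_grid",
    "default_colony_layout",
]

#: the four selection conditions of the competition assay
CONDITIONS = ("MTX+sorbitol", "MTX", "noMTX+sorbitol", "noMTX")

WT_CLASS = "wt_identical"


def condition_has_mtx(condition: str) -> bool:
    return condition.split("+")[0] == "MTX"


def condition_has_sorbitol(condition: str) -> bool:
    return condition.endswith("+sorbitol")


# --------------------------------------------------------------------------
# Synthetic wild-type reference
# --------------------------------------------------------------------------

# One deterministic codon per amino acid (common yeast codons) used to
# reverse-translate the synthetic reference ORF.
_PREFERRED_CODON = {
    "A": "GCT", "R": "AGA", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "TTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCA",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}

# Synthetic stand-in for the mutagenized MAPKK region, ORF codons 71-126.
# The canonical SH3-binding motif KPLPPLP sits at codons 93-99 and the
# extended-motif flank (85-92) carries the hydrophobic positions (87, 90,
# 91) the assay probes.  Everything outside those anchors is invented.
_SYNTHETIC_AA_71_126 = (
    "SMSKSERANLSPAT"   # 71-84, flank
    "THIQQLVN"         # 85-92, extended-motif flank
    "KPLPPLP"          # 93-99, canonical motif
    "A"                # 100
    "GSGSDMSAAQLANRSTVDTSKEALNK"  # 101-126, flank
)


def example_design(scheme: str = "NNK", region: tuple[int, int] = (85, 100)) -> LibraryDesign:
    """A synthetic motif-carrying design (ORF codons 71-126, motif at 93-99).

    The default is the extended-motif library: a 16-codon NNK scan of
    codons 85-100.  ``region=(71, 126)`` with ``scheme="NNN"`` gives the
    full surrounding-region library.
    """
    seq = "".join(_PREFERRED_CODON[aa] for aa in _SYNTHETIC_AA_71_126)
    return LibraryDesign(
        wt_nt_seq=seq,
        orf_codon_offset=71,
        region_start_codon=region[0],
        region_end_codon=region[1],
        scheme=scheme,
    )


# --------------------------------------------------------------------------
# Parameters and effect model
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for the pooled competition simulation.

    ``generations_per_cycle`` is the number of doublings per selection
    cycle (the assay dilutes to 0.1 OD and grows to saturation, roughly
    4 doublings at the scale simulated here); two cycles of selection are
    run.  ``sorbitol_multiplier`` scales binding effects under osmotic
    stress (>1: binding differences are amplified).  ``error_rate`` is the
    uniform per-base sequencing error probability.
    """

    seed: int
    read_depth: int = 100_000
    n_replicates: int = 3
    conditions: tuple[str, ...] = CONDITIONS
    baits: tuple[str, ...] = ("Sho1", "Hog1")
    generations_per_cycle: float = 4.0
    n_cycles: int = 2
    sorbitol_multiplier: float = 1.5
    error_rate: float = 0.0
    dirichlet_concentration: float = 200.0
    couple_abundance_to_growth: bool = False
    phred_quality: int = 30
    barcode_length: int = 8

    def __post_init__(self) -> None:
        if self.read_depth <= 0:
            raise ValueError("read_depth must be positive")
        if self.generations_per_cycle <= 0:
            raise ValueError("generations_per_cycle must be positive")
        if not 0.0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions: {sorted(unknown)}")

    @property
    def total_generations(self) -> float:
        return self.generations_per_cycle * self.n_cycles


@dataclass
class EffectModel:
    """Per-variant fitness effects, assigned at the amino-acid-change level.

    ``binding`` and ``abundance`` map ``(codon_position, mut_aa)`` to the
    per-generation selection coefficients b and a.  Synonymous codons of
    the same amino-acid change share one effect, as they must if scores
    aggregated over codons are to mean anything.  Wild-type-identical and
    silent variants have b = a = 0; nonsense variants have a = -s_null
    (PCA signal abolished for both baits) and define the score floor.
    """

    design: LibraryDesign
    binding: dict[tuple[int, str], float] = field(default_factory=dict)
    abundance: dict[tuple[int, str], float] = field(default_factory=dict)
    s_null: float = 0.25

    def _lookup(self, table, key: VariantKey) -> float:
        ann = annotate_variant(self.design, key)
        if ann.variant_class in ("wt_identical", "silent"):
            return 0.0
        if ann.variant_class == "nonsense":
            return -self.s_null if table is self.abundance else 0.0
        try:
            return table[(key.codon_position, ann.mut_aa)]
        except KeyError:
            raise KeyError(f"no effect defined for {ann.aa_change_key}") from None

    def b(self, key: VariantKey) -> float:
        """Binding effect per generation (Sho1 bait, MTX)."""
        return self._lookup(self.binding, key)

    def a(self, key: VariantKey) -> float:
        """Abundance effect per generation (both baits)."""
        return self._lookup(self.abundance, key)

    def selection_rate(self, key: VariantKey, bait: str, condition: str,
                       params: SimulationParams) -> float:
        """Total per-generation selection coefficient in one sample."""
        a = self.a(key)
        if condition_has_mtx(condition):
            s = a
            if bait == "Sho1":
                mult = params.sorbitol_multiplier if condition_has_sorbitol(condition) else 1.0
                s += self.b(key) * mult
            return s
        return a if params.couple_abundance_to_growth else 0.0

    # -- constructors -------------------------------------------------------

    @classmethod
    def _missense_changes(cls, design: LibraryDesign) -> list[tuple[int, str]]:
        seen = []
        got = set()
        for key, ann in enumerate_variants(design):
            if ann.variant_class == "missense":
                k = (key.codon_position, ann.mut_aa)
                if k not in got:
                    got.add(k)
                    seen.append(k)
        return seen

    @classmethod
    def neutral(cls, design: LibraryDesign, s_null: float = 0.25) -> "EffectModel":
        """All missense effects zero (b = a = 0)."""
        changes = cls._missense_changes(design)
        zeros = {k: 0.0 for k in changes}
        return cls(design, binding=zeros, abundance={k: 0.0 for k in changes}, s_null=s_null)

    @classmethod
    def continuous(cls, design: LibraryDesign, seed: int,
                   low: float = -0.25, high: float = 0.125,
                   s_null: float = 0.25) -> "EffectModel":
        """Binding effects drawn uniformly on [low, high]; no abundance effects.

        A continuous landscape, used when rank recovery of planted effects
        is the question (ranks of exactly tied effects are not recoverable).
        """
        rng = np.random.default_rng(seed)
        changes = cls._missense_changes(design)
        b = {k: float(x) for k, x in zip(changes, rng.uniform(low, high, size=len(changes)))}
        return cls(design, binding=b, abundance={k: 0.0 for k in changes}, s_null=s_null)

    @classmethod
    def classes(cls, design: LibraryDesign, seed: int,
                frac_stronger: float = 0.10, frac_weaker: float = 0.60,
                frac_abundance: float = 0.0,
                stronger_range: tuple[float, float] = (0.05, 0.15),
                weaker_range: tuple[float, float] = (-0.25, -0.05),
                abundance_range: tuple[float, float] = (-0.35, -0.25),
                s_null: float = 0.25) -> "EffectModel":
        """A class-structured landscape: stronger / weaker / neutral binders.

        A fraction ``frac_abundance`` of the missense changes additionally
        get a pure abundance defect (a < 0, b = 0), which should be caught
        by the Hog1 control filter and not by anything binding-specific.
        """
        rng = np.random.default_rng(seed)
        changes = cls._missense_changes(design)
        n = len(changes)
        order = rng.permutation(n)
        n_ab = int(round(frac_abundance * n))
        n_str = int(round(frac_stronger * n))
        n_weak = int(round(frac_weaker * n))
        b = {k: 0.0 for k in changes}
        a = {k: 0.0 for k in changes}
        idx = 0
        for i in order[:n_ab]:
            a[changes[i]] = float(rng.uniform(*abundance_range))
        rest = order[n_ab:]
        for i in rest[:n_str]:
            b[changes[i]] = float(rng.uniform(*stronger_range))
        for i in rest[n_str:n_str + n_weak]:
            b[changes[i]] = float(rng.uniform(*weaker_range))
        return cls(design, binding=b, abundance=a, s_null=s_null)


# --------------------------------------------------------------------------
# Pooled competition counts
# --------------------------------------------------------------------------


def _library_members(design: LibraryDesign) -> list[tuple]:
    """Distinct library molecules: non-WT codon variants plus one WT class.

    Every per-position WT-sentinel codon produces the same molecule, so the
    pool has a single wild-type member carrying their combined frequency
    mass.
    """
    members = []
    for key, ann in enumerate_variants(design):
        if ann.variant_class != "wt_identical":
            members.append((key, ann))
    return members


def simulate_counts(design: LibraryDesign, params: SimulationParams,
                    effects: EffectModel) -> pd.DataFrame:
    """Pre/post-selection multinomial read counts per bait/condition/replicate.

    Returns a long table with columns ``sample_id, bait, condition,
    replicate, timepoint, class, codon_position, mutant_codon, count``.
    The pre-selection sample (the pool after diploid/transformant
    selection, before MTX) is shared by all conditions of a replicate, so
    it is emitted once per (bait, replicate) with condition ``"pre"``.
    """
    rng = np.random.default_rng([params.seed, 101])
    members = _library_members(design)
    n = len(members) + 1  # + wild type
    g_total = params.total_generations

    # per-member selection rates per (bait, condition); WT is the last slot
    rows = []
    for bait in params.baits:
        rates = {
            cond: np.array(
                [effects.selection_rate(key, bait, cond, params) for key, _ in members] + [0.0]
            )
            for cond in params.conditions
        }
        for rep in range(1, params.n_replicates + 1):
            f0 = rng.dirichlet(np.full(n, params.dirichlet_concentration))
            pre_counts = rng.multinomial(params.read_depth, f0)
            rows.append((f"{bait}_r{rep}_pre", bait, "pre", rep, "pre", pre_counts))
            for cond in params.conditions:
                w = f0 * np.exp2(rates[cond] * g_total)
                f1 = w / w.sum()
                post_counts = rng.multinomial(params.read_depth, f1)
                rows.append(
                    (f"{bait}_{cond}_r{rep}_post", bait, cond, rep, "post", post_counts)
                )

    positions = [key.codon_position for key, _ in members] + [pd.NA]
    codons = [key.mutant_codon for key, _ in members] + [pd.NA]
    classes = [ann.variant_class for _, ann in members] + [WT_CLASS]
    out = []
    for sample_id, bait, cond, rep, tp, counts in rows:
        out.append(
            pd.DataFrame(
                {
                    "sample_id": sample_id,
                    "bait": bait,
                    "condition": cond,
                    "replicate": rep,
                    "timepoint": tp,
                    "class": classes,
                    "codon_position": positions,
                    "mutant_codon": codons,
                    "count": counts,
                }
            )
        )
    table = pd.concat(out, ignore_index=True)
    table["codon_position"] = table["codon_position"].astype("Int64")
    return table


# --------------------------------------------------------------------------
# Reads
# --------------------------------------------------------------------------

_BASE_ARR = np.frombuffer(b"ACGT", dtype="S1")


def _make_barcodes(n: int, length: int, rng: np.random.Generator,
                   min_dist: int = 3) -> list[str]:
    """Deterministic random barcodes with pairwise Hamming distance >= min_dist."""
    out: list[str] = []
    while len(out) < n:
        cand = "".join(rng.choice(list("ACGT"), size=length))
        if all(sum(a != b for a, b in zip(cand, bc)) >= min_dist for bc in out):
            out.append(cand)
    return out


def default_manifest(counts: pd.DataFrame, params: SimulationParams) -> pd.DataFrame:
    """A sample manifest (row/column barcodes) covering every sample in counts."""
    samples = (
        counts[["sample_id", "bait", "condition", "replicate", "timepoint"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )
    rng = np.random.default_rng([params.seed, 202])
    n = len(samples)
    n_rows = int(np.ceil(np.sqrt(n)))
    n_cols = int(np.ceil(n / n_rows))
    row_bcs = _make_barcodes(n_rows, params.barcode_length, rng)
    col_bcs = _make_barcodes(n_cols, params.barcode_length, rng)
    samples["barcode_row"] = [row_bcs[i // n_cols] for i in range(n)]
    samples["barcode_col"] = [col_bcs[i % n_cols] for i in range(n)]
    return samples


def _mutate(seq: str, n_err: int, rng: np.random.Generator) -> str:
    pos = rng.choice(len(seq), size=n_err, replace=False)
    s = list(seq)
    for p in pos:
        choices = [b for b in "ACGT" if b != s[p]]
        s[p] = choices[rng.integers(3)]
    return "".join(s)


def emit_reads(design: LibraryDesign, counts: pd.DataFrame, params: SimulationParams,
               manifest: pd.DataFrame, fastq_path) -> None:
    """Write one full-length barcoded amplicon read per counted molecule.

    Reads are ``row_barcode + variant_sequence + column_barcode`` with
    constant Phred qualities and independent per-base substitution errors
    at ``params.error_rate``.  Counts of zero emit nothing.
    """
    rng = np.random.default_rng([params.seed, 303])
    bc = manifest.set_index("sample_id")[["barcode_row", "barcode_col"]]
    qual_line = None
    fastq_path = str(fastq_path)
    opener = open
    if fastq_path.endswith(".gz"):
        import gzip

        opener = gzip.open
    with opener(fastq_path, "wt") as fh:
        read_no = 0
        for sample_id, grp in counts.groupby("sample_id", sort=True):
            if sample_id not in bc.index:
                raise KeyError(f"sample {sample_id!r} missing from manifest")
            row_bc, col_bc = bc.loc[sample_id]
            records = zip(
                grp["class"].to_numpy(),
                grp["count"].to_numpy(),
                grp["codon_position"].to_numpy(),
                grp["mutant_codon"].to_numpy(),
            )
            for cls, c, position, codon in records:
                c = int(c)
                if c == 0:
                    continue
                if cls == WT_CLASS:
                    amplicon = design.wt_nt_seq
                elif cls in ("multi_codon", "indel_other", "unassigned"):
                    continue
                else:
                    amplicon = mutant_sequence(design, VariantKey(int(position), codon))
                seq = row_bc + amplicon + col_bc
                if qual_line is None or len(qual_line) != len(seq):
                    qual_line = chr(33 + params.phred_quality) * len(seq)
                if params.error_rate > 0:
                    n_err = rng.binomial(len(seq), params.error_rate, size=c)
                else:
                    n_err = np.zeros(c, dtype=int)
                for k in n_err:
                    read_no += 1
                    out_seq = seq if k == 0 else _mutate(seq, int(k), rng)
                    fh.write(f"@read{read_no} {sample_id}\n{out_seq}\n+\n{qual_line}\n")


# --------------------------------------------------------------------------
# Optical density trajectories
# --------------------------------------------------------------------------


def simulate_od(rate: float, od0: float = 0.05, duration_h: float = 72.0,
                interval_min: float = 15.0, noise_sd: float = 0.0,
                carrying_capacity: float = 1.0, floor: float = 1e-3,
                rng=None) -> pd.DataFrame:
    """Exponential-to-saturation OD trajectory with additive Gaussian noise.

    ``OD(t) = min(od0 * 2**(rate*t), carrying_capacity) + noise``, floored
    at a small positive value.  ``rate`` is in log2 OD per hour.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if od0 <= 0:
        raise ValueError("od0 must be positive")
    t = np.arange(0.0, duration_h + 1e-9, interval_min / 60.0)
    od = np.minimum(od0 * np.exp2(rate * t), carrying_capacity)
    if noise_sd > 0:
        rng = np.random.default_rng(rng)
        od = od + rng.normal(0.0, noise_sd, size=od.shape)
    od = np.maximum(od, floor)
    return pd.DataFrame({"time_h": t, "od": od})


# --------------------------------------------------------------------------
# Colony grids
# --------------------------------------------------------------------------


def default_colony_layout(baits: Sequence[str], preys: Sequence[str] = ("Pbs2", "Pbs2-stuffer"),
                          n_rows: int = 32, n_cols: int = 48,
                          border_pair: tuple[str, str] = ("LSM8", "CDC39"),
                          seed: int = 0) -> pd.DataFrame:
    """A 1,536-format layout: 2 border rows/columns of control colonies and a
    randomized bait x prey pattern repeated over the interior."""
    rng = np.random.default_rng([seed, 404])
    pairs = [(b, p) for b in baits for p in preys]
    rows = []
    interior = [
        (r, c)
        for r in range(1, n_rows + 1)
        for c in range(1, n_cols + 1)
        if 2 < r <= n_rows - 2 and 2 < c <= n_cols - 2
    ]
    # repeat the randomized pattern to fill the interior
    reps = int(np.ceil(len(interior) / len(pairs)))
    pattern = []
    for _ in range(reps):
        pattern.extend(rng.permutation(len(pairs)))
    for (r, c), pi in zip(interior, pattern):
        b, p = pairs[pi]
        rows.append({"row": r, "col": c, "bait": b, "prey": p, "border": False})
    for r in range(1, n_rows + 1):
        for c in range(1, n_cols + 1):
            if not (2 < r <= n_rows - 2 and 2 < c <= n_cols - 2):
                rows.append({"row": r, "col": c, "bait": border_pair[0],
                             "prey": border_pair[1], "border": True})
    return pd.DataFrame(rows).sort_values(["row", "col"]).reset_index(drop=True)


def simulate_colony_grid(n_plates: int, layout: pd.DataFrame,
                         true_scores: Mapping[tuple[str, str], float],
                         row_bias_sd: float = 0.0, col_bias_sd: float = 0.0,
                         plate_factor_sd: float = 0.0, noise_sd: float = 0.1,
                         base_size: float = 400.0, grew_fraction: float = 1.0,
                         seed: int = 0) -> pd.DataFrame:
    """Colony sizes with multiplicative plate / row / column bias.

    ``size = base * 2**true_score * row_bias * col_bias * plate_factor *
    lognormal(noise)``.  Border positions carry the control pair (their
    score defaults to the WT reference level, 1.0).  A fraction of
    colonies can be marked as failed diploid selection (``grew=False``).
    """
    if {"row", "col", "bait", "prey", "border"} - set(layout.columns):
        raise ValueError("layout needs columns row, col, bait, prey, border")
    rng = np.random.default_rng([seed, 505])
    out = []
    for plate in range(1, n_plates + 1):
        g = layout.copy()
        g.insert(0, "plate", plate)
        score = np.array(
            [
                true_scores.get((b, p), 1.0 if border else 0.0)
                for b, p, border in zip(g["bait"], g["prey"], g["border"])
            ]
        )
        rows = g["row"].to_numpy()
        cols = g["col"].to_numpy()
        row_bias = np.exp2(rng.normal(0.0, row_bias_sd, rows.max() + 1))[rows] if row_bias_sd > 0 else 1.0
        col_bias = np.exp2(rng.normal(0.0, col_bias_sd, cols.max() + 1))[cols] if col_bias_sd > 0 else 1.0
        plate_factor = float(np.exp2(rng.normal(0.0, plate_factor_sd))) if plate_factor_sd > 0 else 1.0
        noise = np.exp2(rng.normal(0.0, noise_sd, len(g))) if noise_sd > 0 else 1.0
        g["size"] = base_size * np.exp2(score) * row_bias * col_bias * plate_factor * noise
        g["grew"] = rng.random(len(g)) < grew_fraction
        g.loc[~g["grew"], "size"] = 0.0
        out.append(g)
    return pd.concat(out, ignore_index=True)
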