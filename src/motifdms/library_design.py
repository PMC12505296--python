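"""Degenerate single-codon variant libraries of a mutagenized coding region.

A deep mutational scanning (DMS) library replaces each codon of a target
region, one at a time, with a degenerate codon: either ``NNN`` (all 64
codons) or ``NNK`` (the 32 codons whose third base is G or T, which cover
all 20 amino acids plus a single stop, TAG).  This module represents such a
design, enumerates every single-codon variant it contains, and annotates
each variant with its amino-acid consequence under the standard genetic
code.

Coordinates follow the conventions of protein mutagenesis studies: codon
positions are 1-based indices into the full open reading frame (so they
match residue numbering such as "I87W"), while nucleotide coordinates are
0-based half-open internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "LibraryDesign",
    "VariantKey",
    "VariantAnnotation",
    "SCHEMES",
    "STOP",
    "translate_codon",
    "scheme_codons",
    "enumerate_variants",
    "annotate_variant",
    "mutant_sequence",
    "variant_table",
    "write_variant_table",
    "load_design",
]

STOP = "*"
_BASES = "ACGT"

#: degenerate codon schemes -> allowed third bases
SCHEMES = {"NNN": "ACGT", "NNK": "GT"}

_CODON_CACHE: dict[str, str] = {}


def translate_codon(codon: str) -> str:
    """Translate a single DNA codon with the standard genetic code ('*' = stop)."""
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"not an unambiguous DNA codon: {codon!r}")
    try:
        return _CODON_CACHE[codon]
    except KeyError:
        aa = str(Seq(codon).translate())
        _CODON_CACHE[codon] = aa
        return aa


def scheme_codons(scheme: str) -> list[str]:
    """All codons of a degeneracy scheme, in lexicographic order."""
    try:
        third = SCHEMES[scheme]
    except KeyError:
        raise ValueError(f"unknown degeneracy scheme {scheme!r}; expected one of {sorted(SCHEMES)}")
    return [a + b + c for a in _BASES for b in _BASES for c in third]


@dataclass(frozen=True)
class LibraryDesign:
    """A single-codon mutagenesis design over a region of an ORF.

    Parameters
    ----------
    wt_nt_seq
        Wild-type nucleotide sequence (uppercase ACGT, length divisible
        by 3).  The sequence may cover more than the mutagenized region,
        e.g. a full amplicon.
    orf_codon_offset
        1-based ORF codon index of the first full codon in ``wt_nt_seq``.
    region_start_codon, region_end_codon
        1-based inclusive ORF codon indices of the mutagenized window.
    scheme
        ``"NNN"`` or ``"NNK"``.
    """

    wt_nt_seq: str
    orf_codon_offset: int
    region_start_codon: int
    region_end_codon: int
    scheme: str = "NNN"

    def __post_init__(self) -> None:
        seq = self.wt_nt_seq.upper()
        object.__setattr__(self, "wt_nt_seq", seq)
        if len(seq) == 0 or len(seq) % 3 != 0:
            raise ValueError("wt_nt_seq length must be a positive multiple of 3")
        if any(b not in _BASES for b in seq):
            raise ValueError("wt_nt_seq must contain only A/C/G/T")
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown degeneracy scheme {self.scheme!r}")
        if self.region_start_codon > self.region_end_codon:
            raise ValueError("region_start_codon must be <= region_end_codon")
        last = self.orf_codon_offset + len(seq) // 3 - 1
        if self.region_start_codon < self.orf_codon_offset or self.region_end_codon > last:
            raise ValueError(
                f"region {self.region_start_codon}-{self.region_end_codon} outside "
                f"sequence codons {self.orf_codon_offset}-{last}"
            )
        for pos in self.region_positions():
            if translate_codon(self.wt_codon(pos)) == STOP:
                raise ValueError(f"wild-type sequence has an internal stop at codon {pos}")

    # -- coordinate helpers -------------------------------------------------
    def codon_slice(self, codon_position: int) -> tuple[int, int]:
        """0-based half-open nucleotide slice of a 1-based ORF codon index."""
        i = (codon_position - self.orf_codon_offset) * 3
        if i < 0 or i + 3 > len(self.wt_nt_seq):
            raise ValueError(f"codon {codon_position} outside the design sequence")
        return i, i + 3

    def wt_codon(self, codon_position: int) -> str:
        a, b = self.codon_slice(codon_position)
        return self.wt_nt_seq[a:b]

    def wt_aa(self, codon_position: int) -> str:
        return translate_codon(self.wt_codon(codon_position))

    def region_positions(self) -> range:
        return range(self.region_start_codon, self.region_end_codon + 1)

    @property
    def n_region_codons(self) -> int:
        return self.region_end_codon - self.region_start_codon + 1

    def codon_of_nt(self, nt_index: int) -> int:
        """1-based ORF codon index containing a 0-based nucleotide index."""
        return self.orf_codon_offset + nt_index // 3


@dataclass(frozen=True)
class VariantKey:
    """A single-codon substitution: which codon position carries which codon."""

    codon_position: int
    mutant_codon: str


@dataclass(frozen=True)
class VariantAnnotation:
    wt_aa: str
    mut_aa: str
    variant_class: str  # wt_identical | silent | missense | nonsense
    aa_change_key: str  # e.g. "I-87-W"


def annotate_variant(design: LibraryDesign, key: VariantKey) -> VariantAnnotation:
    """Classify a codon variant (wt_identical / silent / missense / nonsense)."""
    wt_codon = design.wt_codon(key.codon_position)
    wt_aa = translate_codon(wt_codon)
    mut_aa = translate_codon(key.mutant_codon)
    if key.mutant_codon == wt_codon:
        cls = "wt_identical"
    elif mut_aa == wt_aa:
        cls = "silent"
    elif mut_aa == STOP:
        cls = "nonsense"
    else:
        cls = "missense"
    return VariantAnnotation(
        wt_aa=wt_aa,
        mut_aa=mut_aa,
        variant_class=cls,
        aa_change_key=f"{wt_aa}-{key.codon_position}-{mut_aa}",
    )


def enumerate_variants(design: LibraryDesign) -> list[tuple[VariantKey, VariantAnnotation]]:
    """Every codon of the region substituted by every codon of the scheme.

    The wild-type codon of each position is retained (labeled
    ``wt_identical``) because downstream scoring normalizes against it.
    Ordering is deterministic: by position, then codon lexicographic.
    """
    codons = scheme_codons(design.scheme)
    out = []
    for pos in design.region_positions():
        for codon in codons:
            key = VariantKey(pos, codon)
            out.append((key, annotate_variant(design, key)))
    return out


def mutant_sequence(design: LibraryDesign, key: VariantKey) -> str:
    """Full nucleotide sequence of a variant (WT with one codon substituted)."""
    a, b = design.codon_slice(key.codon_position)
    return design.wt_nt_seq[:a] + key.mutant_codon + design.wt_nt_seq[b:]


def variant_table(design: LibraryDesign) -> pd.DataFrame:
    """Enumerated variants as a table (one row per codon variant)."""
    rows = [
        {
            "codon_position": key.codon_position,
            "wt_codon": design.wt_codon(key.codon_position),
            "mutant_codon": key.mutant_codon,
            "wt_aa": ann.wt_aa,
            "mut_aa": ann.mut_aa,
            "variant_class": ann.variant_class,
            "aa_change_key": ann.aa_change_key,
        }
        for key, ann in enumerate_variants(design)
    ]
    return pd.DataFrame(rows)


def write_variant_table(design: LibraryDesign, path) -> None:
    variant_table(design).to_csv(path, sep="\t", index=False)


def load_design(source) -> LibraryDesign:
    """Build a LibraryDesign from a mapping or a YAML config file path.

    Expected keys: ``wt_nt_seq`` (inline) or ``wt_fasta`` (path to a FASTA
    file whose first record is the wild-type sequence), ``orf_codon_offset``,
    ``region_start_codon``, ``region_end_codon``, ``scheme``.
    """
    if not isinstance(source, dict):
        import yaml

        with open(source) as fh:
            source = yaml.safe_load(fh)
    cfg = dict(source)
    if "wt_nt_seq" not in cfg:
        from Bio import SeqIO

        path = cfg.pop("wt_fasta", None)
        if path is None:
            raise ValueError("design config needs either wt_nt_seq or wt_fasta")
        record = next(SeqIO.parse(path, "fasta"))
        cfg["wt_nt_seq"] = str(record.seq)
    return LibraryDesign(
        wt_nt_seq=cfg["wt_nt_seq"],
        orf_codon_offset=int(cfg["orf_codon_offset"]),
        region_start_codon=int(cfg["region_start_codon"]),
        region_end_codon=int(cfg["region_end_codon"]),
        scheme=cfg.get("scheme", "NNN"),
    )
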