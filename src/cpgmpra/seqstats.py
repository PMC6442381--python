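"""Dinucleotide and composition statistics for promoter sequences.

The central quantity is the normalized CpG density, the classical
"observed over expected" (OE) ratio

    OE = (n_CpG / (n_C * n_G)) * L

for a region of length ``L`` nucleotides.  Together with G+C content it
drives the textbook CpG-island (CGI) classification: a region of at
least 200 bp with G+C content above 50% and OE of at least 0.6.
Mammalian promoters show a bimodal OE distribution, and the CGI class
(roughly two thirds of promoters) is the transcriptionally active mode
this package's reporter-assay analyses revolve around.

Coordinates are 0-based half-open throughout.  Sequences are uppercased
on ingest; only the unambiguous alphabet {A, C, G, T} is accepted, since
designed reporter constructs never contain Ns.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "PromoterRecord",
    "MotifAnnotation",
    "CompositionStats",
    "InvalidAlphabetError",
    "count_cpgs",
    "cpg_positions",
    "normalized_cpg_density",
    "gc_content",
    "classify_cgi",
    "composition_stats",
    "read_promoters_fasta",
    "write_promoters_fasta",
    "write_composition_table",
]

_VALID_BASES = frozenset("ACGT")


class InvalidAlphabetError(ValueError):
    """Raised when a sequence contains characters outside {A, C, G, T}."""


def _clean(sequence: str) -> str:
    """Uppercase and validate a DNA sequence."""
    seq = str(sequence).upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - _VALID_BASES
    if bad:
        raise InvalidAlphabetError(
            f"sequence contains non-ACGT characters: {sorted(bad)}"
        )
    return seq


@dataclass(frozen=True)
class MotifAnnotation:
    """A transcription-factor motif instance on a promoter.

    ``bound`` marks motifs supported by a ChIP peak at the promoter;
    only bound motifs shield their CpGs from mutagenesis in library
    design.  ``score`` is an optional motif log-odds (log2 scale).
    """

    tf: str
    start: int
    end: int  # half-open
    bound: bool = False
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid motif interval [{self.start}, {self.end})")

    def overlaps(self, start: int, end: int) -> bool:
        """True if [start, end) intersects this motif's interval."""
        return self.start < end and start < self.end


@dataclass
class PromoterRecord:
    """A named reference promoter sequence.

    ``tss_offset`` is the 0-based position of the transcription start
    site within the sequence (promoters are typically taken 400 bp
    upstream to 200 bp downstream of the TSS, giving an offset of 400).
    """

    id: str
    sequence: str
    tss_offset: int | None = None
    motif_annotations: list[MotifAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = _clean(self.sequence)
        if self.tss_offset is not None and not (
            0 <= self.tss_offset < len(self.sequence)
        ):
            raise ValueError("tss_offset outside sequence")
        for m in self.motif_annotations:
            if m.end > len(self.sequence):
                raise ValueError(f"motif {m} extends past sequence end")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CompositionStats:
    """Composition summary of one sequence: CpG/C/G counts, OE, GC."""

    n_cpg: int
    n_c: int
    n_g: int
    length: int
    oe: float
    gc: float


def count_cpgs(sequence: str) -> int:
    """Number of CG dinucleotides on the forward strand.

    CpG is strand-symmetric as a site, so the forward-strand count is
    the site count.  CG occurrences cannot overlap, so counting is
    unambiguous.
    """
    return _clean(sequence).count("CG")


def cpg_positions(sequence: str) -> list[int]:
    """0-based positions of the C of each CpG, strictly increasing."""
    seq = _clean(sequence)
    out = []
    start = 0
    while True:
        i = seq.find("CG", start)
        if i == -1:
            return out
        out.append(i)
        start = i + 1


def normalized_cpg_density(sequence: str) -> float:
    """Observed/expected CpG ratio: (n_CpG / (n_C * n_G)) * length.

    Returns 0.0 when the sequence contains no C or no G (no CpG is
    possible, and the expected count is degenerate).
    """
    seq = _clean(sequence)
    n_c = seq.count("C")
    n_g = seq.count("G")
    if n_c == 0 or n_g == 0:
        return 0.0
    return seq.count("CG") / (n_c * n_g) * len(seq)


def gc_content(sequence: str) -> float:
    """Fraction of G+C bases, in [0, 1]."""
    seq = _clean(sequence)
    return (seq.count("C") + seq.count("G")) / len(seq)


def classify_cgi(
    sequence: str,
    min_length: int = 200,
    min_gc: float = 0.5,
    min_oe: float = 0.6,
) -> bool:
    """CpG-island call: length >= 200, GC strictly > 0.5, OE >= 0.6.

    The G+C gate is strict (">50%") while the OE gate is inclusive
    ("at least 0.6"), matching the standard definition.
    """
    seq = _clean(sequence)
    return (
        len(seq) >= min_length
        and gc_content(seq) > min_gc
        and normalized_cpg_density(seq) >= min_oe
    )


def composition_stats(sequence: str) -> CompositionStats:
    seq = _clean(sequence)
    return CompositionStats(
        n_cpg=seq.count("CG"),
        n_c=seq.count("C"),
        n_g=seq.count("G"),
        length=len(seq),
        oe=normalized_cpg_density(seq),
        gc=gc_content(seq),
    )


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_promoters_fasta(path: str | Path) -> list[PromoterRecord]:
    """Load promoters from FASTA (sequences uppercased and validated)."""
    return [
        PromoterRecord(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_promoters_fasta(
    records: Iterable[PromoterRecord], path: str | Path
) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def write_composition_table(
    records: Sequence[PromoterRecord], path: str | Path
) -> pd.DataFrame:
    """Per-record composition TSV: id, length, counts, oe, gc, is_cgi."""
    rows = []
    for r in records:
        st = composition_stats(r.sequence)
        rows.append(
            {
                "id": r.id,
                **dataclasses.asdict(st),
                "is_cgi": classify_cgi(r.sequence),
            }
        )
    df = pd.DataFrame(
        rows, columns=["id", "n_cpg", "n_c", "n_g", "length", "oe", "gc", "is_cgi"]
    )
    df.to_csv(path, sep="\t", index=False)
    return df
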