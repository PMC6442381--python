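"""Promoter mutant-library design.

Five complementary mutagenesis strategies dissect how CpG density and
transcription-factor motifs contribute to promoter activity:

* ``window_combination_library`` — partition the promoter into a few
  windows and build every WT/mutant window combination (2^k constructs),
  where a "mutant" window has the C of every non-motif CpG substituted.
* ``density_series_library`` — randomly retain a chosen fraction of the
  mutable (non-motif) CpGs, producing a series of constructs spanning a
  range of normalized CpG densities.
* ``motif_mutation_library`` — scramble individual motif instances, and
  all instances of each factor, into CpG-free motif-dead sequence.
* ``tiling_replacement_library`` — replace each consecutive fixed-size
  tile with random CpG-free sequence, to map which short blocks carry
  activity.
* ``addback_library`` — replace low-effect blocks wholesale with
  CpG-free sequence, then re-introduce increasing numbers of CpGs at
  their original WT positions, isolating the density effect from any
  other sequence feature.

Every design is substitution-only (construct length equals parent
length) and never touches a CpG inside a ChIP-supported ("bound") motif
unless motif mutation is the explicit goal.  All randomness flows from
an integer seed, so libraries are byte-identical across runs.

Barcodes follow the degenerate-oligo pattern used in reporter cloning
(N = any base, W = A/T); the default 15-mer pattern NNNNWNNNNWNNNNN has
a space of 4^13 * 2^2 ≈ 2.7e8 sequences, and generated sets keep a
minimum pairwise Hamming distance so single sequencing errors cannot
collide barcodes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .seqstats import (
    MotifAnnotation,
    PromoterRecord,
    cpg_positions,
    gc_content,
    normalized_cpg_density,
)

__all__ = [
    "DesignError",
    "MutantConstruct",
    "BarcodePattern",
    "PAPER_BARCODE_PATTERN",
    "mutable_cpgs",
    "window_combination_library",
    "density_series_library",
    "motif_mutation_library",
    "tiling_replacement_library",
    "addback_library",
    "generate_barcodes",
    "random_cpg_free_replacement",
]

BASES = "ACGT"
_DEGENERATE = {"N": "ACGT", "W": "AT"}


class DesignError(ValueError):
    """A library request violates a design precondition."""


@dataclass
class MutantConstruct:
    """A designed promoter variant with provenance."""

    parent_id: str
    construct_id: str
    strategy: str
    sequence: str
    mutated_positions: list[int] = field(default_factory=list)
    retained_cpg_fraction: float | None = None
    barcodes: list[str] = field(default_factory=list)

    @property
    def oe(self) -> float:
        return normalized_cpg_density(self.sequence)

    @property
    def gc(self) -> float:
        return gc_content(self.sequence)


@dataclass(frozen=True)
class BarcodePattern:
    """Degenerate barcode pattern with fixed flanking anchors."""

    pattern: str = "NNNNWNNNNWNNNNN"
    anchor_up: str = "CGCCGAA"
    anchor_down: str = "AGCTCGG"

    def __post_init__(self) -> None:
        bad = set(self.pattern) - set(_DEGENERATE)
        if bad:
            raise ValueError(f"pattern may only contain N/W, got {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.pattern)

    @property
    def space_size(self) -> int:
        n = 1
        for c in self.pattern:
            n *= len(_DEGENERATE[c])
        return n

    def matches(self, barcode: str) -> bool:
        return len(barcode) == self.length and all(
            b in _DEGENERATE[c] for b, c in zip(barcode, self.pattern)
        )


#: The pattern from the reporter cloning oligo CGCCGAA-NNNNWNNNNWNNNNN-AGCTCGG.
PAPER_BARCODE_PATTERN = BarcodePattern()


def mutable_cpgs(promoter: PromoterRecord) -> list[int]:
    """CpG positions free to mutate: those not overlapping a bound motif.

    A CpG at position ``p`` spans [p, p+2); it is shielded iff that
    interval intersects any annotation with ``bound=True``.  Motifs
    without ChIP support do not shield.
    """
    bound = [m for m in promoter.motif_annotations if m.bound]
    return [
        p
        for p in cpg_positions(promoter.sequence)
        if not any(m.overlaps(p, p + 2) for m in bound)
    ]


def _substitute(sequence: str, positions: list[int], base: str) -> str:
    seq = list(sequence)
    for p in positions:
        seq[p] = base
    return "".join(seq)


def window_combination_library(
    promoter: PromoterRecord,
    windows: list[tuple[int, int]],
    substitution_base: str = "A",
    seed: int = 0,
) -> list[MutantConstruct]:
    """All 2^k WT/mutant window combinations.

    In a mutant window every mutable CpG has its C replaced by
    ``substitution_base``; the all-WT combination is the parent
    sequence.  ``seed`` is accepted for interface uniformity; the design
    itself is deterministic.
    """
    if substitution_base not in ("A", "T"):
        raise DesignError("substitution base must be A or T")
    ordered = sorted(windows)
    for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
        if s2 < e1:
            raise DesignError(f"overlapping windows [{s1},{e1}) and [{s2},{e2})")
    for s, e in ordered:
        if not (0 <= s < e <= len(promoter)):
            raise DesignError(f"window [{s},{e}) outside promoter")

    mutable = set(mutable_cpgs(promoter))
    per_window = [
        [p for p in sorted(mutable) if s <= p < e] for s, e in windows
    ]
    constructs = []
    for combo in itertools.product((0, 1), repeat=len(windows)):
        positions = sorted(
            itertools.chain.from_iterable(
                pw for flag, pw in zip(combo, per_window) if flag
            )
        )
        label = "".join("M" if f else "W" for f in combo) or "WT"
        constructs.append(
            MutantConstruct(
                parent_id=promoter.id,
                construct_id=f"{promoter.id}_comb_{label}",
                strategy="window_combination",
                sequence=_substitute(promoter.sequence, positions, substitution_base),
                mutated_positions=positions,
            )
        )
    return constructs


def _round_half_away(x: float) -> int:
    """Round half away from zero (so 2.5 -> 3), unlike banker's rounding."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def density_series_library(
    promoter: PromoterRecord,
    retention_fractions: list[float],
    substitution_base: str = "A",
    seed: int = 0,
) -> list[MutantConstruct]:
    """Constructs retaining a fraction of mutable CpGs, rest mutated.

    For fraction ``p``, round(p * n_mutable) CpGs (half away from zero)
    are randomly retained and the remainder have their C substituted.
    The random subset is drawn independently per density level.
    """
    if substitution_base not in ("A", "T"):
        raise DesignError("substitution base must be A or T")
    mutable = mutable_cpgs(promoter)
    if not mutable:
        raise DesignError(f"promoter {promoter.id} has no mutable CpGs")
    if any(not 0 <= p <= 1 for p in retention_fractions):
        raise DesignError("retention fractions must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    constructs = []
    for i, p in enumerate(retention_fractions):
        n_retain = _round_half_away(p * len(mutable))
        retained = set(
            rng.choice(mutable, size=n_retain, replace=False).tolist()
        )
        positions = sorted(set(mutable) - retained)
        constructs.append(
            MutantConstruct(
                parent_id=promoter.id,
                construct_id=f"{promoter.id}_dens_{i}_p{p:g}",
                strategy="density_series",
                sequence=_substitute(promoter.sequence, positions, substitution_base),
                mutated_positions=positions,
                retained_cpg_fraction=p,
            )
        )
    return constructs


def random_cpg_free_replacement(
    length: int,
    left_context: str,
    right_context: str,
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> str:
    """Random sequence of ``length`` with no CG inside or at junctions.

    ``left_context``/``right_context`` are the bases flanking the
    replaced interval (empty at sequence ends).  Bases are drawn
    sequentially, excluding G whenever the previous base (junction
    included) is C, and excluding C at the final position when the right
    context starts with G — so no CG can occur inside or across either
    junction regardless of length.
    """
    del max_tries  # kept for interface stability
    prev = left_context[-1:] or "A"
    out = []
    for i in range(length):
        allowed = BASES
        if prev == "C":
            allowed = allowed.replace("G", "")
        if i == length - 1 and right_context[:1] == "G":
            allowed = allowed.replace("C", "")
        prev = str(rng.choice(list(allowed)))
        out.append(prev)
    return "".join(out)


def motif_mutation_library(
    promoter: PromoterRecord,
    motif_sets: dict[str, list[tuple[int, int]]],
    seed: int = 0,
    score_fn=None,
    max_tries: int = 200,
) -> list[MutantConstruct]:
    """One construct per single motif plus one per TF with all motifs hit.

    Each targeted motif interval is replaced by a random CpG-free
    scramble (junctions included).  If ``score_fn`` is given (maps a
    candidate replacement string to a motif log-odds), candidates are
    resampled until the score is negative, guaranteeing the motif is
    destroyed rather than recreated by chance.
    """
    seq = promoter.sequence

    def replace(intervals: list[tuple[int, int]]) -> tuple[str, list[int]]:
        out = seq
        changed: list[int] = []
        for s, e in sorted(intervals):
            if not (0 <= s < e <= len(seq)):
                raise DesignError(f"motif interval [{s},{e}) outside promoter")
            # per-interval stream: the same motif gets the same replacement
            # in its "single" and "all-motifs" constructs
            rng = np.random.default_rng((seed, s, e))
            for _ in range(max_tries):
                cand = random_cpg_free_replacement(e - s, out[:s], out[e:], rng)
                if score_fn is None or score_fn(cand) < 0:
                    break
            else:  # pragma: no cover
                raise DesignError("could not destroy motif under score constraint")
            out = out[:s] + cand + out[e:]
            changed.extend(p for p in range(s, e) if out[p] != seq[p])
        return out, sorted(changed)

    constructs = []
    for tf, intervals in motif_sets.items():
        for j, iv in enumerate(intervals):
            mutated, changed = replace([iv])
            constructs.append(
                MutantConstruct(
                    parent_id=promoter.id,
                    construct_id=f"{promoter.id}_motif_{tf}_{j}",
                    strategy="motif_mutation",
                    sequence=mutated,
                    mutated_positions=changed,
                )
            )
        mutated, changed = replace(list(intervals))
        constructs.append(
            MutantConstruct(
                parent_id=promoter.id,
                construct_id=f"{promoter.id}_motif_{tf}_all",
                strategy="motif_mutation",
                sequence=mutated,
                mutated_positions=changed,
            )
        )
    return constructs


def tiling_replacement_library(
    promoter: PromoterRecord,
    window_size: int = 10,
    seed: int = 0,
) -> list[MutantConstruct]:
    """One construct per complete tile, tile replaced CpG-free.

    The promoter is cut into consecutive ``window_size`` tiles (trailing
    remainder skipped); each construct replaces exactly one tile with a
    random CpG-free sequence that also creates no CG at either junction.
    """
    if window_size < 2:
        raise DesignError("window_size must be >= 2")
    rng = np.random.default_rng(seed)
    seq = promoter.sequence
    n_tiles = len(seq) // window_size
    constructs = []
    for t in range(n_tiles):
        s, e = t * window_size, (t + 1) * window_size
        cand = random_cpg_free_replacement(window_size, seq[:s], seq[e:], rng)
        mutated = seq[:s] + cand + seq[e:]
        constructs.append(
            MutantConstruct(
                parent_id=promoter.id,
                construct_id=f"{promoter.id}_tile_{t}",
                strategy="tiling_replacement",
                sequence=mutated,
                mutated_positions=[p for p in range(s, e) if mutated[p] != seq[p]],
            )
        )
    return constructs


def addback_library(
    promoter: PromoterRecord,
    low_effect_blocks: list[tuple[int, int]],
    addback_counts: list[int],
    seed: int = 0,
) -> tuple[MutantConstruct, list[MutantConstruct]]:
    """CpG-free baseline over low-effect blocks, plus CpG add-back series.

    The baseline replaces every block with random CpG-free sequence; at
    each WT CpG position inside a block the baseline carries "CA", so an
    add-back is the single substitution A->G restoring the CG.  Add-back
    subsets are nested across increasing counts, which makes the OE of
    the series strictly increasing (n_C is constant and the CpG count
    rises by one per added position).
    """
    seq = promoter.sequence
    ordered = sorted(low_effect_blocks)
    for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
        if s2 < e1:
            raise DesignError("blocks overlap")
    for s, e in ordered:
        if not (0 <= s < e <= len(seq)):
            raise DesignError(f"block [{s},{e}) outside promoter")

    # WT CpGs fully inside a block (both C and G positions covered)
    wt_sites = [
        p
        for p in cpg_positions(seq)
        if any(s <= p and p + 2 <= e for s, e in ordered)
    ]
    if any(c > len(wt_sites) for c in addback_counts):
        raise DesignError(
            f"add-back count exceeds available WT CpG positions ({len(wt_sites)})"
        )

    rng = np.random.default_rng(seed)
    baseline_seq = seq
    for s, e in ordered:
        cand = random_cpg_free_replacement(e - s, baseline_seq[:s], baseline_seq[e:], rng)
        baseline_seq = baseline_seq[:s] + cand + baseline_seq[e:]
    # pin CA at WT CpG sites so add-back is one substitution; CA cannot
    # form CG with either neighbour
    b = list(baseline_seq)
    for p in wt_sites:
        b[p], b[p + 1] = "C", "A"
    baseline_seq = "".join(b)
    assert all(
        "CG" not in baseline_seq[s - 1 if s else 0 : e + 1] for s, e in ordered
    )

    baseline = MutantConstruct(
        parent_id=promoter.id,
        construct_id=f"{promoter.id}_addback_baseline",
        strategy="addback",
        sequence=baseline_seq,
        mutated_positions=[p for p in range(len(seq)) if baseline_seq[p] != seq[p]],
        retained_cpg_fraction=0.0,
    )

    order = rng.permutation(len(wt_sites))  # nested subsets via a fixed order
    constructs = []
    for i, count in enumerate(addback_counts):
        chosen = sorted(wt_sites[k] for k in order[:count])
        s_list = list(baseline_seq)
        for p in chosen:
            s_list[p + 1] = "G"
        restored = "".join(s_list)
        constructs.append(
            MutantConstruct(
                parent_id=promoter.id,
                construct_id=f"{promoter.id}_addback_{i}_n{count}",
                strategy="addback",
                sequence=restored,
                mutated_positions=[
                    p for p in range(len(seq)) if restored[p] != seq[p]
                ],
                retained_cpg_fraction=count / len(wt_sites) if wt_sites else 0.0,
            )
        )
    return baseline, constructs


def generate_barcodes(
    pattern: BarcodePattern = PAPER_BARCODE_PATTERN,
    n: int = 0,
    min_pairwise_distance: int = 3,
    seed: int = 0,
    max_tries_factor: int = 200,
) -> list[str]:
    """``n`` distinct pattern-matching barcodes, pairwise Hamming >= d.

    Greedy rejection sampling; raises after a bounded number of draws if
    the request cannot be satisfied (e.g. n too close to the pattern
    space at a large distance).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n > pattern.space_size:
        raise DesignError("more barcodes requested than the pattern space holds")
    rng = np.random.default_rng(seed)
    alphabet = [list(_DEGENERATE[c]) for c in pattern.pattern]
    chosen: list[str] = []
    chosen_arr: list[np.ndarray] = []
    tries = 0
    max_tries = max_tries_factor * max(n, 1)
    while len(chosen) < n:
        tries += 1
        if tries > max_tries:
            raise DesignError(
                f"could not generate {n} barcodes at distance "
                f">={min_pairwise_distance} within {max_tries} draws"
            )
        cand = "".join(rng.choice(col) for col in alphabet)
        arr = np.frombuffer(cand.encode(), dtype=np.uint8)
        if chosen_arr and (
            (np.stack(chosen_arr) != arr).sum(axis=1) < min_pairwise_distance
        ).any():
            continue
        chosen.append(cand)
        chosen_arr.append(arr)
    return chosen
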